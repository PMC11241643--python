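"""53BP1 focus detection, per-nucleus summaries and QC minima."""

import numpy as np
import pytest

import mucoquant as mq
from mucoquant.segmentation import SegmentationParams

from conftest import render_fov


def _single_nucleus_fov(foci_offsets, radius_um=0.6, noise=None, seed=2):
    lay = mq.generate_tissue_geometry((256, 256), 0.25, seed=1)
    cond = mq.Condition("S", 0.0)
    nuc = mq.NucleusGT(0, 128.0, 128.0, 3.5, "suprabasal",
                       False, False, False, False,
                       [radius_um] * len(foci_offsets),
                       [(128 + dy, 128 + dx) for dy, dx in foci_offsets], cond)
    mci = mq.render_fluorescence(lay, [nuc],
                                 noise or mq.NoiseParams.noiseless(), seed)
    labels = mq.segment_nuclei(mci["dapi"], SegmentationParams())
    return mci, labels


FIVE = [(0, 0), (8, 0), (-8, 0), (0, 8), (0, -8)]


class TestDetectFoci:
    def test_focus_free_nucleus_yields_no_records(self):
        mci, labels = _single_nucleus_fov([])
        assert mq.detect_foci(mci["53bp1"], labels) == []

    def test_empty_label_map_yields_no_records(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        assert mq.detect_foci(img, np.zeros((64, 64), dtype=np.int32)) == []

    @pytest.mark.parametrize("noise", [None, mq.NoiseParams()],
                             ids=["noiseless", "default-noise"])
    def test_five_planted_foci_all_detected(self, noise):
        mci, labels = _single_nucleus_fov(FIVE, noise=noise)
        recs = mq.detect_foci(mci["53bp1"], labels, pixel_size_um=0.25)
        assert len(recs) == 5
        assert all(r.nucleus_label == 1 for r in recs)

    @pytest.mark.parametrize("radius_um", [0.75, 1.0])
    def test_half_max_area_matches_planted_disc(self, radius_um):
        offsets = [(0, 0), (9, 0), (-9, 0)]
        mci, labels = _single_nucleus_fov(offsets, radius_um=radius_um)
        recs = mq.detect_foci(mci["53bp1"], labels, pixel_size_um=0.25)
        assert len(recs) == len(offsets)
        expected = np.pi * (radius_um / 0.25) ** 2
        for r in recs:
            assert abs(r.area_px - expected) / expected < 0.20

    def test_counts_invariant_under_translation(self):
        layout, nuclei, mci, _ = render_fov(seed=41, shape=(256, 384))
        labels = mq.segment_nuclei(mci["dapi"],
                                   SegmentationParams(min_area_px=192))

        def embed(arr, dy, dx, pad=24):
            out = np.zeros((arr.shape[0] + 2 * pad, arr.shape[1] + 2 * pad),
                           dtype=arr.dtype)
            out[pad + dy:pad + dy + arr.shape[0],
                pad + dx:pad + dx + arr.shape[1]] = arr
            return out

        counts = []
        for dy, dx in ((0, 0), (7, 11)):
            recs = mq.detect_foci(embed(mci["53bp1"], dy, dx),
                                  embed(labels, dy, dx))
            n = int(labels.max())
            counts.append(np.bincount([r.nucleus_label for r in recs],
                                      minlength=n + 1)[1:].tolist())
        assert counts[0] == counts[1]

    def test_count_recovery_against_planted_poisson(self):
        layout, nuclei, mci, _ = render_fov(
            seed=43, effects=mq.EffectParams(lambda0=3.0, kappa=0.0),
            condition=mq.Condition("S", 0.0))
        labels = mq.segment_nuclei(mci["dapi"],
                                   SegmentationParams(min_area_px=192))
        recs = mq.detect_foci(mci["53bp1"], labels)
        summary = mq.foci_per_nucleus(recs, labels, restrict_p63=False)
        planted_mean = np.mean([n.n_foci for n in nuclei])
        detected_mean = summary.counts.mean()
        assert abs(detected_mean - planted_mean) / planted_mean < 0.10


class TestFociPerNucleus:
    @staticmethod
    def _toy_labels():
        labels = np.zeros((10, 50), dtype=np.int32)
        for k in range(5):
            labels[2:8, k * 10 + 2:k * 10 + 8] = k + 1
        return labels

    @staticmethod
    def _records(counts):
        recs = []
        for label, k in enumerate(counts, start=1):
            recs += [mq.FocusRecord(label, 5.0, 5.0, 10.0, None, 100.0)
                     for _ in range(k)]
        return recs

    def test_no_records_means_all_zero_counts(self):
        s = mq.foci_per_nucleus([], self._toy_labels(), restrict_p63=False)
        assert s.n_nuclei == 5
        assert (s.counts == 0).all()
        assert s.median_count == 0

    def test_quartiles_follow_order_statistics(self):
        s = mq.foci_per_nucleus(self._records([0, 1, 2, 3, 4]),
                                self._toy_labels(), restrict_p63=False)
        assert (s.median_count, s.q1_count, s.q3_count) == (2, 1, 3)
        assert s.n_foci == 10  # sum of counts equals number of records

    def test_p63_restriction_keeps_majority_overlap_nuclei(self):
        labels = self._toy_labels()
        p63 = np.zeros_like(labels, dtype=bool)
        p63[:, :14] = True   # nucleus 1 fully, nucleus 2 only 2/6 columns
        s = mq.foci_per_nucleus(self._records([2, 3, 1, 0, 0]), labels,
                                p63_mask=p63, restrict_p63=True)
        assert s.n_nuclei == 1
        assert s.counts.tolist() == [2]

    def test_empty_p63_mask_fails_qc(self):
        s = mq.foci_per_nucleus([], self._toy_labels(),
                                p63_mask=np.zeros((10, 50), bool),
                                restrict_p63=True)
        assert s.n_nuclei == 0
        assert "empty-p63-mask" in s.qc_flags


class TestQCMinima:
    def _summary(self, n_nuclei, n_foci):
        return mq.FociSummary(
            counts=np.zeros(n_nuclei, dtype=int),
            areas_px=np.ones(n_foci), areas_um2=None,
            n_nuclei=n_nuclei, n_foci=n_foci, median_count=0.0,
            q1_count=0.0, q3_count=0.0, median_area_px=1.0)

    def test_one_below_minimum_fails(self):
        qc = mq.qc_check(self._summary(99, 80), min_nuclei=100, min_foci=75)
        assert not qc["foci_number"]["pass"]
        assert qc["foci_size"]["pass"]

    def test_minimum_is_inclusive(self):
        qc = mq.qc_check(self._summary(100, 75), min_nuclei=100, min_foci=75)
        assert qc["foci_number"]["pass"]
        assert qc["foci_size"]["pass"]
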