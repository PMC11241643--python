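"""Segmentation backend, tissue mask, and analysis-region construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mucoquant as mq
from mucoquant.segmentation import SegmentationParams

from conftest import match_planted, render_fov


class TestThresholdMask:
    def test_strict_inequality_at_threshold(self):
        img = np.full((16, 16), 90, dtype=np.uint8)
        assert mq.threshold_mask(img, 90, "above").sum() == 0
        assert mq.threshold_mask(img, 90, "at_or_below").all()

    def test_saturated_image_fully_positive(self):
        img = np.full((16, 16), 255, dtype=np.uint8)
        assert mq.threshold_mask(img, 90, "above").all()

    def test_checkerboard_splits_exactly_in_half(self):
        img = np.indices((8, 8)).sum(axis=0) % 2 * 255
        mask = mq.threshold_mask(img.astype(np.uint8), 90, "above")
        assert mask.sum() == 32

    def test_rejects_non_8bit_input(self):
        with pytest.raises(ValueError, match="8-bit"):
            mq.threshold_mask(np.zeros((4, 4), dtype=np.uint16), 90)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 254), st.integers(1, 40), st.integers(0, 2 ** 31 - 1))
    def test_raising_threshold_never_adds_pixels(self, t, dt, seed):
        img = np.random.default_rng(seed).integers(
            0, 256, (24, 24)).astype(np.uint8)
        lo = mq.threshold_mask(img, t, "above")
        hi = mq.threshold_mask(img, min(255, t + dt), "above")
        assert not (hi & ~lo).any()


class TestSegmentNuclei:
    def test_blank_image_yields_no_labels(self):
        labels = mq.segment_nuclei(np.zeros((64, 64), dtype=np.uint8))
        assert labels.max() == 0

    def test_well_separated_nuclei_counted_and_located(self):
        lay = mq.generate_tissue_geometry((256, 256), 0.5, seed=1)
        cond = mq.Condition("S", 0.0)
        planted = []
        k = 0
        for y in range(60, 220, 40):
            for x in range(40, 240, 40):
                planted.append(mq.NucleusGT(k, float(y), float(x), 3.5,
                                            "suprabasal", False, False, False,
                                            False, [], [], cond))
                k += 1
        assert len(planted) == 20
        mci = mq.render_fluorescence(lay, planted,
                                     mq.NoiseParams.noiseless(), 2)
        labels = mq.segment_nuclei(mci["dapi"], SegmentationParams())
        assert labels.max() == 20
        from scipy import ndimage as ndi
        cents = np.array(ndi.center_of_mass(labels > 0, labels,
                                            range(1, 21)))
        for n in planted:
            d = np.sqrt(((cents - (n.y, n.x)) ** 2).sum(axis=1)).min()
            assert d < 2.0

    def test_interior_hole_is_filled(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        yy, xx = np.ogrid[:64, :64]
        d2 = (yy - 32) ** 2 + (xx - 32) ** 2
        img[d2 <= 15 ** 2] = 200
        img[d2 <= 4 ** 2] = 0  # interior hole
        labels = mq.segment_nuclei(img, SegmentationParams(min_area_px=10))
        assert labels.max() == 1
        assert (labels == 1).sum() == (d2 <= 15 ** 2).sum()

    def test_recovery_on_default_noise_field(self, standard_fov):
        layout, nuclei, mci, _ = standard_fov
        labels = mq.segment_nuclei(mci["dapi"],
                                   SegmentationParams(min_area_px=192))
        recovered, spurious = match_planted(labels, nuclei, 0.25)
        assert recovered >= 0.95
        assert spurious <= 0.05 * len(nuclei)


class TestTissueMask:
    def test_blank_image_gives_empty_mask(self):
        assert not mq.tissue_mask(np.zeros((64, 64), dtype=np.uint8)).any()

    def test_matches_generator_truth(self, standard_fov):
        layout, _, mci, _ = standard_fov
        mask = mq.tissue_mask(mci["dapi"], blur_sigma_px=16)
        jac = (mask & layout.tissue).sum() / (mask | layout.tissue).sum()
        assert jac >= 0.9

    def test_single_connected_component(self, standard_fov):
        from scipy import ndimage as ndi
        _, _, mci, _ = standard_fov
        mask = mq.tissue_mask(mci["dapi"], blur_sigma_px=16)
        _, n = ndi.label(mask)
        assert n == 1


class TestBorderExclusionZone:
    def test_full_frame_band_matches_index_oracle(self):
        tissue = np.ones((100, 100), dtype=bool)
        band = mq.border_exclusion_zone(tissue, nucleus_diameter_px=10,
                                        n_layers=2)
        ii, jj = np.indices((100, 100))
        edge_dist = np.minimum.reduce([ii, jj, 99 - ii, 99 - jj]) + 1
        assert (band == (edge_dist < 20)).all()

    def test_zero_layers_gives_empty_band(self):
        tissue = np.ones((50, 50), dtype=bool)
        assert not mq.border_exclusion_zone(tissue, 10, n_layers=0).any()

    def test_band_inside_tissue_with_interior_remaining(self):
        yy, xx = np.ogrid[:100, :100]
        tissue = (yy - 50) ** 2 + (xx - 50) ** 2 <= 30 ** 2
        band = mq.border_exclusion_zone(tissue, 10, n_layers=2)
        assert not (band & ~tissue).any()
        assert (tissue & ~band).any()

    def test_rejects_non_positive_diameter(self):
        with pytest.raises(ValueError):
            mq.border_exclusion_zone(np.ones((10, 10), dtype=bool), 0)


class TestP63LayerRegion:
    def test_empty_mask_gives_empty_region(self):
        assert not mq.p63_layer_region(np.zeros((32, 32), dtype=bool), 3).any()

    def test_closing_is_extensive(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:30, 20:30] = True
        region = mq.p63_layer_region(mask, dilation_radius_px=0,
                                     closing_radius_px=2)
        assert (region & mask).sum() == mask.sum()

    def test_closing_bridges_nearby_blobs(self):
        from scipy import ndimage as ndi
        mask = np.zeros((40, 60), dtype=bool)
        mask[10:30, 10:25] = True
        mask[10:30, 28:43] = True  # 3 px gap
        region = mq.p63_layer_region(mask, dilation_radius_px=0,
                                     closing_radius_px=2)
        _, n = ndi.label(region)
        assert n == 1
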