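"""Generator: geometry invariants, phenotype statistics, render calibration."""

import numpy as np
import pytest
from skimage.feature import peak_local_max

import mucoquant as mq
from mucoquant.synthetic import HALF_MAX_SIGMA

from conftest import render_fov


class TestGeometry:
    def test_deterministic_for_fixed_seed(self):
        a = mq.generate_tissue_geometry((256, 256), 0.5, seed=1)
        b = mq.generate_tissue_geometry((256, 256), 0.5, seed=1)
        for name in ("tissue", "epithelium", "basal", "lamina"):
            assert (getattr(a, name) == getattr(b, name)).all()

    def test_distinct_seeds_differ(self):
        a = mq.generate_tissue_geometry((256, 256), 0.5, seed=1)
        b = mq.generate_tissue_geometry((256, 256), 0.5, seed=2)
        assert (a.tissue != b.tissue).sum() >= 1

    def test_compartment_invariants(self):
        lay = mq.generate_tissue_geometry((256, 256), 0.5, seed=3)
        assert lay.basal.sum() > 0
        assert not (lay.basal & ~lay.epithelium).any()
        assert not (lay.epithelium & ~lay.tissue).any()
        assert not (lay.lamina & lay.epithelium).any()
        assert ((lay.lamina | lay.epithelium) == lay.tissue).all()

    @pytest.mark.parametrize("shape", [(32, 128), (64, 64)])
    def test_rejects_too_small_images(self, shape):
        with pytest.raises(ValueError):
            mq.generate_tissue_geometry(shape, 0.5, seed=1)


class TestPhenotypes:
    def test_certain_proliferation_marks_every_basal_nucleus(self):
        eff = mq.EffectParams(p0=1.0, alpha=0.0)
        lay = mq.generate_tissue_geometry((256, 256), 0.5, seed=4)
        nuclei = mq.assign_phenotypes(lay, 80, mq.Condition("S", 0.0), eff, 5)
        basal = [n for n in nuclei if n.compartment == "basal"]
        assert basal and all(n.edu for n in basal)
        # EdU+ implies p63+ throughout
        assert all(n.p63 for n in nuclei if n.edu)

    def test_zero_rate_means_zero_foci(self):
        eff = mq.EffectParams(lambda0=0.0, kappa=0.0)
        lay = mq.generate_tissue_geometry((256, 256), 0.5, seed=6)
        nuclei = mq.assign_phenotypes(lay, 80, mq.Condition("S", 10.0), eff, 7)
        assert all(n.n_foci == 0 for n in nuclei)

    def test_edu_fraction_matches_binomial_oracle(self):
        # pooled layouts give n large enough that a 3-sigma binomial band
        # around the planted probability is a sharp check
        eff = mq.EffectParams(p0=0.3, alpha=0.0)
        flags = []
        for seed in range(8):
            lay = mq.generate_tissue_geometry(
                (512, 512), 0.5, seed=seed, epithelium_frac=0.8,
                basal_thickness_um=100.0)
            nuclei = mq.assign_phenotypes(lay, 900, mq.Condition("S", 0.0),
                                          eff, seed + 50)
            flags += [n.edu for n in nuclei if n.compartment == "basal"]
        n = len(flags)
        assert n > 1200
        frac = np.mean(flags)
        band = 3 * np.sqrt(0.3 * 0.7 / n)
        assert abs(frac - 0.3) < band

    def test_expected_fractions_monotone_in_dose(self):
        eff = mq.EffectParams()
        resp = [eff.dose_response(d) for d in (0, 2.5, 5, 10)]
        p_edu = [r["p_edu"] for r in resp]
        p_tunel = [r["p_tunel"] for r in resp]
        rate = [r["foci_rate"] for r in resp]
        assert p_edu == sorted(p_edu, reverse=True)
        assert p_tunel == sorted(p_tunel)
        assert rate == sorted(rate)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            mq.EffectParams(alpha=-0.1).validate()
        with pytest.raises(ValueError):
            mq.EffectParams().dose_response(-1.0)


class TestFluorescenceRender:
    def test_empty_nuclei_is_pure_background(self):
        lay = mq.generate_tissue_geometry((256, 256), 0.5, seed=8)
        mci = mq.render_fluorescence(lay, [], mq.NoiseParams.noiseless(), 9)
        for ch in mq.FLUOR_CHANNELS:
            assert mci[ch].max() == 0

    def test_single_nucleus_peak_and_threshold_area(self):
        lay = mq.generate_tissue_geometry((256, 256), 0.5, seed=8)
        nuc = mq.NucleusGT(0, 128.0, 128.0, 3.5, "suprabasal",
                           False, False, False, False, [], [],
                           mq.Condition("S", 0.0))
        # keep the default background so threshold 90 sits at half amplitude
        noise = mq.NoiseParams.noiseless(background=6.0)
        mci = mq.render_fluorescence(lay, [nuc], noise, 9)
        dapi = mci["dapi"]
        assert dapi[128, 128] == dapi.max()
        # threshold 90 sits at the blob half-maximum: area ~ pi r^2
        area = (dapi > 90).sum()
        expected = np.pi * (3.5 / 0.5) ** 2
        assert abs(area - expected) / expected < 0.10

    def test_planted_foci_are_distinct_local_maxima(self):
        lay = mq.generate_tissue_geometry((256, 256), 0.25, seed=8)
        offs = [(0, 0), (8, 0), (-8, 0), (0, 8), (0, -8)]
        nuc = mq.NucleusGT(0, 128.0, 128.0, 3.5, "suprabasal",
                           False, False, False, False, [0.6] * 5,
                           [(128 + dy, 128 + dx) for dy, dx in offs],
                           mq.Condition("S", 0.0))
        mci = mq.render_fluorescence(lay, [nuc], mq.NoiseParams.noiseless(), 9)
        ch = mci["53bp1"].astype(float)
        peaks = peak_local_max(ch, min_distance=3,
                               threshold_abs=ch.max() / 2.0)
        # restrict to the nucleus disc
        inside = [(y, x) for y, x in peaks
                  if (y - 128) ** 2 + (x - 128) ** 2 <= (3.5 / 0.25) ** 2]
        assert len(inside) == 5

    def test_render_deterministic_and_seed_sensitive(self):
        lay, nuclei, _, _ = render_fov(seed=21, shape=(256, 384))
        a = mq.render_fluorescence(lay, nuclei, mq.NoiseParams(), 5)
        b = mq.render_fluorescence(lay, nuclei, mq.NoiseParams(), 5)
        c = mq.render_fluorescence(lay, nuclei, mq.NoiseParams(), 6)
        for ch in mq.FLUOR_CHANNELS:
            assert (a[ch] == b[ch]).all()
        assert any((a[ch] != c[ch]).any() for ch in mq.FLUOR_CHANNELS)

    def test_border_artifact_touches_only_tunel(self):
        lay, nuclei, _, _ = render_fov(seed=22, shape=(256, 384))
        off = mq.render_fluorescence(lay, nuclei, mq.NoiseParams(), 5)
        on = mq.render_fluorescence(
            lay, nuclei, mq.NoiseParams(tunel_border_artifact=True), 5)
        for ch in ("dapi", "p63", "edu", "53bp1"):
            assert (off[ch] == on[ch]).all()
        assert (off["tunel"] != on["tunel"]).any()

    def test_half_max_sigma_constant(self):
        # half-max radius of a unit Gaussian is sqrt(2 ln 2) sigma
        assert np.isclose(HALF_MAX_SIGMA, 1.177410022515475)


class TestIHCRender:
    def test_zero_densities_render_white(self):
        lay = mq.generate_tissue_geometry((128, 128), 0.5, seed=2)
        ihc = mq.render_ihc(lay, [], 0.0, seed=3, od_noise_sd=0.0)
        assert (ihc.rgb == 255).all()

    def test_forward_model_matches_beer_lambert(self):
        conc = np.zeros((2, 1, 1))
        conc[1, 0, 0] = 1.0
        rgb = mq.synthesize_rgb(conc, mq.StainMatrix.hdab(), quantize=True)
        expected = np.round(255 * 10.0 ** -np.array([0.268, 0.570, 0.776]))
        assert (rgb[0, 0] == expected).all()

    def test_zero_positive_fraction_means_zero_dab_area(self):
        lay = mq.generate_tissue_geometry((256, 256), 0.5, seed=4)
        nuclei = mq.assign_phenotypes(lay, 60, mq.Condition("S", 0.0),
                                      mq.EffectParams(), 5)
        ihc = mq.render_ihc(lay, nuclei, 0.0, seed=6, od_noise_sd=0.0)
        assert ihc.dab_area_px == 0
        channels = mq.color_deconvolve(ihc.rgb)
        res = mq.positive_area_pct(channels)
        assert res.pct == 0.0

    def test_non_unit_stain_vectors_rejected(self):
        with pytest.raises(ValueError):
            mq.StainMatrix(names=("a", "b"),
                           vectors=np.array([[1.0, 1.0, 1.0],
                                             [0.0, 0.0, 1.0]]))


class TestExperiment:
    def test_manifest_counts_and_determinism(self, tmp_path):
        cfg = mq.ExperimentConfig(samples=["A", "B"], days=[1],
                                  fovs_per_condition=2, shape=(224, 224),
                                  pixel_size_um=0.5, n_nuclei=50,
                                  include_ihc=True)
        m1 = mq.generate_experiment(cfg, seed=7, out_dir=tmp_path / "one")
        assert len(m1) == 2 * 3 * 1 * 2  # samples x arms x days x fovs
        for _, row in m1.iterrows():
            for ch in mq.FLUOR_CHANNELS:
                assert (tmp_path / "one" / row[ch]).exists()
        mq.generate_experiment(cfg, seed=7, out_dir=tmp_path / "two")
        a = (tmp_path / "one" / "ground_truth.csv").read_bytes()
        b = (tmp_path / "two" / "ground_truth.csv").read_bytes()
        assert a == b

    def test_duplicate_arms_rejected(self):
        cfg = mq.ExperimentConfig(arms=[(5.0, "xray"), (5.0, "xray")])
        with pytest.raises(ValueError):
            cfg.validate()

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = mq.ExperimentConfig(samples=["X"], fovs_per_condition=4,
                                  effects=mq.EffectParams(p0=0.25))
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = mq.ExperimentConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back.samples == ["X"]
        assert back.fovs_per_condition == 4
        assert back.effects.p0 == 0.25
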