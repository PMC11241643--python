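"""Shared fixtures: synthetic fields of view at the two working scales."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

import mucoquant as mq


def render_fov(seed: int, *, effects: mq.EffectParams | None = None,
               noise: mq.NoiseParams | None = None,
               shape=(384, 512), pixel_size_um=0.25, n_nuclei=170,
               condition: mq.Condition | None = None,
               **assign_kwargs):
    """Generate one field of view (layout, nuclei, images, condition)."""
    condition = condition or mq.Condition("S1", 5.0, "xray", 1, 1)
    effects = effects or mq.EffectParams()
    layout = mq.generate_tissue_geometry(shape, pixel_size_um, seed)
    nuclei = mq.assign_phenotypes(layout, n_nuclei, condition, effects,
                                  seed + 1, **assign_kwargs)
    mci = mq.render_fluorescence(layout, nuclei, noise or mq.NoiseParams(),
                                 seed + 2)
    return layout, nuclei, mci, condition


def match_planted(labels: np.ndarray, nuclei, pixel_size_um: float):
    """Match planted nuclei to label centroids (hit = centroid within one
    planted radius).  Returns (recovered_fraction, n_spurious)."""
    n_labels = int(labels.max(initial=0))
    if n_labels == 0:
        return 0.0, 0
    cents = np.array(ndi.center_of_mass(labels > 0, labels,
                                        range(1, n_labels + 1)))
    planted = np.array([(n.y, n.x) for n in nuclei])
    radii = np.array([n.radius_um / pixel_size_um for n in nuclei])
    d, idx = cKDTree(cents).query(planted)
    hit = d < radii
    spurious = n_labels - len(set(idx[hit]))
    return float(np.mean(hit)), int(spurious)


@pytest.fixture(scope="session")
def standard_fov():
    """One default-noise field of view at confocal sampling (0.25 µm/px)."""
    return render_fov(seed=11)


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory):
    """A compact generated experiment reused by pipeline-level tests."""
    out = tmp_path_factory.mktemp("experiment")
    cfg = mq.ExperimentConfig(samples=["S1", "S2"], days=[1],
                              fovs_per_condition=2, shape=(256, 384),
                              n_nuclei=120)
    manifest = mq.generate_experiment(cfg, seed=42, out_dir=out)
    return cfg, manifest, out
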