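"""H-DAB color deconvolution and positive-area scoring for brightfield IHC.

Stains are separated by Beer–Lambert optical-density unmixing: per pixel
``OD = -log10(max(I, 1) / 255)`` componentwise, concentrations solve
``c @ M = OD`` in least squares (negative concentrations clipped to 0), and
each stain channel is re-expressed on the transmission convention
``v = round(255 * 10^-c)`` so 255 means "no stain".  The positive-area score
then selects dark (dense-stain) pixels with ``channel <= threshold`` — the
same pixels a "threshold and invert" recipe selects — and reports the
DAB-positive area relative to nuclear (hematoxylin) area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

from .types import Condition, UndefinedResultError

# Standard H-DAB optical-density vectors (RGB space, unit norm).
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
DAB_OD = (0.268, 0.570, 0.776)


@dataclass
class StainMatrix:
    """Named unit-norm optical-density vectors, one row per stain."""

    names: tuple[str, ...]
    vectors: np.ndarray  # (n_stains, 3)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise ValueError("stain vectors must be (n_stains, 3)")
        if not 2 <= self.vectors.shape[0] <= 3:
            raise ValueError("expected 2 or 3 stain vectors")
        if len(self.names) != self.vectors.shape[0]:
            raise ValueError("one name per stain vector required")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(np.abs(norms - 1.0) > 0.02):
            raise ValueError(f"stain vectors must be unit-norm, got norms {norms}")
        if np.linalg.matrix_rank(self.vectors, tol=1e-6) < self.vectors.shape[0]:
            raise ValueError("stain vectors are linearly dependent")

    @classmethod
    def hdab(cls) -> "StainMatrix":
        return cls(names=("hematoxylin", "dab"),
                   vectors=np.array([HEMATOXYLIN_OD, DAB_OD]))


def synthesize_rgb(concentrations: np.ndarray, stains: StainMatrix,
                   quantize: bool = True) -> np.ndarray:
    """Beer–Lambert forward model: concentration maps -> transmitted RGB.

    ``concentrations`` has shape (n_stains, H, W), all values >= 0.  With
    ``quantize`` the result is rounded to uint8; otherwise float transmission
    in [0, 255] is returned (useful for noiseless round-trip checks that
    should not be limited by 8-bit quantization).
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.ndim != 3 or conc.shape[0] != stains.vectors.shape[0]:
        raise ValueError("concentrations must be (n_stains, H, W)")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    od = np.tensordot(conc, stains.vectors, axes=(0, 0))  # (H, W, 3)
    trans = 255.0 * np.power(10.0, -od)
    if quantize:
        return np.clip(np.round(trans), 0, 255).astype(np.uint8)
    return trans


def od_from_rgb(rgb: np.ndarray, floor: float | None = None) -> np.ndarray:
    """Optical density per channel with a floor guarding saturated pixels.

    The default floor is 1 (one ADU) for integer images — the standard guard
    against log(0) on quantized data — and a tiny epsilon for float images,
    where sub-ADU transmissions are meaningful.
    """
    arr = np.asarray(rgb)
    if floor is None:
        floor = 1.0 if np.issubdtype(arr.dtype, np.integer) else 1e-9
    return -np.log10(np.maximum(arr.astype(float), floor) / 255.0)


def deconvolve_concentrations(rgb: np.ndarray, stains: StainMatrix | None = None
                              ) -> np.ndarray:
    """Recover stain concentration maps (n_stains, H, W), clipped to >= 0."""
    stains = stains or StainMatrix.hdab()
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    od = od_from_rgb(rgb)
    pinv = np.linalg.pinv(stains.vectors)  # (3, n_stains)
    conc = od @ pinv                        # (H, W, n_stains)
    return np.clip(np.moveaxis(conc, -1, 0), 0.0, None)


def color_deconvolve(rgb: np.ndarray, stains: StainMatrix | None = None
                     ) -> dict[str, np.ndarray]:
    """Separate stains into per-stain 8-bit transmission images.

    Output channel value ``round(255 * 10^-c)``: 255 = no stain, darker =
    denser stain.  A white input pixel yields 255 in every stain channel.
    """
    stains = stains or StainMatrix.hdab()
    conc = deconvolve_concentrations(rgb, stains)
    out = {}
    for name, c in zip(stains.names, conc):
        out[name] = np.clip(np.round(255.0 * np.power(10.0, -c)), 0, 255
                            ).astype(np.uint8)
    return out


@dataclass
class IHCResult:
    """Marker-positive area relative to nuclear area for one image.

    ``pct`` is stored unclamped: membranous staining can legitimately exceed
    the nuclear area, so values above 100 are possible.
    """

    marker: str
    positive_area_px: int
    nuclear_area_px: int
    pct: float
    nuclei_threshold: int
    dab_threshold: int
    min_particle_area_px: int
    condition: Condition | None = None
    qc_flags: tuple[str, ...] = ()


def _drop_small_particles(mask: np.ndarray, min_area: int) -> np.ndarray:
    if min_area <= 1 or not mask.any():
        return mask
    labels, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return keep[labels]


def positive_area_pct(
    stain_channels: Mapping[str, np.ndarray],
    marker: str = "CD27",
    nuclei_threshold: int = 205,
    dab_threshold: int = 210,
    min_particle_area_px: int = 4,
    *,
    nuclei_channel: str = "hematoxylin",
    dab_channel: str = "dab",
    dark_is_positive: bool = True,
    condition: Condition | None = None,
) -> IHCResult:
    """Score marker-positive area relative to total nuclear area.

    On the transmission convention (255 = unstained) a pixel is positive
    when its stain channel is <= the threshold; marker particles smaller
    than ``min_particle_area_px`` are discarded before the area count.  An
    empty nuclear mask raises :class:`UndefinedResultError`.
    """
    h = np.asarray(stain_channels[nuclei_channel])
    d = np.asarray(stain_channels[dab_channel])
    if h.shape != d.shape:
        raise ValueError("stain channels are not co-registered")
    if dark_is_positive:
        nuclear = h <= nuclei_threshold
        positive = d <= dab_threshold
    else:
        nuclear = h >= nuclei_threshold
        positive = d >= dab_threshold
    positive = _drop_small_particles(positive, min_particle_area_px)
    n_nuc = int(nuclear.sum())
    if n_nuc == 0:
        raise UndefinedResultError(
            "no nuclear (hematoxylin-positive) area in image",
            qc_flag="empty-nuclear-area",
        )
    n_pos = int(positive.sum())
    return IHCResult(
        marker=marker, positive_area_px=n_pos, nuclear_area_px=n_nuc,
        pct=100.0 * n_pos / n_nuc,
        nuclei_threshold=nuclei_threshold, dab_threshold=dab_threshold,
        min_particle_area_px=min_particle_area_px, condition=condition,
    )


def cd45_presence(
    stain_channels: Mapping[str, np.ndarray],
    compartment_masks: Mapping[str, np.ndarray],
    dab_threshold: int = 210,
    min_particle_area_px: int = 4,
    *,
    dab_channel: str = "dab",
) -> dict[str, float]:
    """DAB-positive area fraction within each tissue compartment.

    Used for the qualitative leukocyte (CD45) readout: lymphocytes sit
    mainly in the lamina propria with a minority in the epithelium.  Empty
    compartment masks yield a fraction of 0.
    """
    d = np.asarray(stain_channels[dab_channel])
    positive = _drop_small_particles(d <= dab_threshold, min_particle_area_px)
    out = {}
    for name, mask in compartment_masks.items():
        mask = np.asarray(mask, dtype=bool)
        denom = int(mask.sum())
        out[name] = float((positive & mask).sum() / denom) if denom else 0.0
    return out
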