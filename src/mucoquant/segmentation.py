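"""Nucleus segmentation and analysis-region construction.

The reference nucleus-segmentation backend is classical: global threshold
(fixed 8-bit value or Otsu) → hole filling (flood-fill of enclosed
background) → distance-transform watershed to split touching nuclei →
minimum-area filter.  The backend is pluggable, so a learned model honoring
the same contract (2D image in, integer label map out) can be swapped in.

The region builders implement the two restrictions the apoptosis index
requires: the p63-stained cell layer (morphological closing + dilation of
the p63-positive mask) and the exclusion of the first cell layers at the
tissue border, where bright TUNEL signal is an artifact rather than a
treatment effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import watershed
from skimage.feature import peak_local_max

from .types import as_bool_mask


def threshold_mask(image: np.ndarray, threshold: int,
                   polarity: str = "above") -> np.ndarray:
    """Binary mask from a fixed 8-bit intensity threshold.

    ``polarity="above"`` selects strictly greater intensities (the working
    convention for the EdU threshold of 90); ``"at_or_below"`` is its
    complement.  Non-8-bit input is rejected because the fixed thresholds
    are only meaningful on the 0–255 scale.
    """
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError(
            f"threshold_mask expects an 8-bit image, got dtype {image.dtype}"
        )
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    if polarity == "above":
        return image > threshold
    if polarity == "at_or_below":
        return image <= threshold
    raise ValueError("polarity must be 'above' or 'at_or_below'")


@dataclass
class SegmentationParams:
    """Knobs of the classical reference backend.

    ``threshold=None`` selects Otsu; the default fixed threshold 90 keeps
    the segmentation on the same 8-bit scale as the channel thresholds used
    elsewhere.  ``min_area_px`` plays the role of a detection-strictness
    knob (it is not equivalent to a learned model's probability threshold).
    """

    threshold: int | None = 90
    smooth_sigma_px: float = 1.0
    fill_holes: bool = True
    split_touching: bool = True
    min_area_px: int = 40
    peak_min_distance_px: int | None = None  # None: derived from blob sizes


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def segment_nuclei(
    image: np.ndarray,
    params: SegmentationParams | None = None,
    *,
    backend: Callable[[np.ndarray, SegmentationParams], np.ndarray] | None = None,
) -> np.ndarray:
    """Label nuclei in a single-channel image (0 = background).

    An all-background image yields an empty label map, not an error.
    """
    params = params or SegmentationParams()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if backend is not None:
        return backend(image, params)

    img = image.astype(float)
    if params.smooth_sigma_px > 0:
        img = ndi.gaussian_filter(img, params.smooth_sigma_px)
    if params.threshold is None:
        if np.ptp(img) < 1e-9:
            return np.zeros(image.shape, dtype=np.int32)
        th = threshold_otsu(img)
    else:
        th = float(params.threshold)
    mask = img > th
    if not mask.any():
        return np.zeros(image.shape, dtype=np.int32)
    if params.fill_holes:
        mask = ndi.binary_fill_holes(mask)

    cc, n_cc = ndi.label(mask)
    if params.split_touching and n_cc > 0:
        edt_raw = ndi.distance_transform_edt(mask)
        edt = ndi.gaussian_filter(edt_raw, 1.0)  # suppress plateau duplicates
        if params.peak_min_distance_px is None:
            # Self-calibrate the peak separation from the EDT peak heights,
            # which approximate nucleus radii even when masks merge into
            # large connected clumps.
            cand = peak_local_max(edt, min_distance=3, labels=cc,
                                  exclude_border=False)
            if len(cand):
                r_est = float(np.median(edt_raw[tuple(cand.T)]))
            else:
                r_est = 3.0
            min_dist = max(3, int(round(0.8 * r_est)))
        else:
            min_dist = params.peak_min_distance_px
        peaks = peak_local_max(edt, min_distance=min_dist, labels=cc,
                               exclude_border=False)
        if len(peaks):
            markers = np.zeros(mask.shape, dtype=np.int32)
            markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
            labels = watershed(-edt, markers, mask=mask)
        else:
            labels = cc
    else:
        labels = cc

    if params.min_area_px > 1:
        sizes = np.bincount(labels.ravel())
        too_small = sizes < params.min_area_px
        too_small[0] = False
        labels = np.where(too_small[labels], 0, labels)
    return _relabel_sequential(labels)


def tissue_mask(
    dapi_image: np.ndarray,
    *,
    blur_sigma_px: float = 16.0,
    threshold_factor: float = 0.5,
    closing_radius_px: int = 5,
) -> np.ndarray:
    """Coarse tissue-foreground mask from the DAPI channel.

    Heavy blur → low threshold (a fraction of Otsu on the blurred image) →
    morphological closing → hole fill → largest connected component.  The
    result is a single connected component by construction.
    """
    img = np.asarray(dapi_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    blurred = ndi.gaussian_filter(img, blur_sigma_px)
    if np.ptp(blurred) < 1e-9:
        return np.zeros(img.shape, dtype=bool)
    th = threshold_factor * threshold_otsu(blurred)
    mask = blurred > th
    if not mask.any():
        return mask
    if closing_radius_px > 0:
        mask = ndi.binary_closing(mask, structure=disk(closing_radius_px))
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = labels == int(np.argmax(sizes))
    return mask


def border_exclusion_zone(
    tissue: np.ndarray,
    nucleus_diameter_px: float,
    n_layers: int = 2,
) -> np.ndarray:
    """Band of tissue within ``n_layers`` cell layers of the tissue border.

    A "cell layer" is one nucleus diameter; the band contains every tissue
    pixel closer than ``n_layers * nucleus_diameter_px`` to the tissue
    boundary (image edges count as boundary).  Subtracting this band from
    the analysis region removes edge artifacts such as spuriously bright
    TUNEL rims.
    """
    tissue = as_bool_mask(tissue, "tissue")
    if nucleus_diameter_px <= 0:
        raise ValueError("nucleus_diameter_px must be > 0")
    if n_layers <= 0 or not tissue.any():
        return np.zeros(tissue.shape, dtype=bool)
    padded = np.pad(tissue, 1, constant_values=False)
    dist = ndi.distance_transform_edt(padded)[1:-1, 1:-1]
    return tissue & (dist < n_layers * nucleus_diameter_px)


def p63_layer_region(
    p63_mask: np.ndarray,
    dilation_radius_px: int,
    closing_radius_px: int = 2,
) -> np.ndarray:
    """Analysis region covering the p63-stained cell layer.

    Morphological closing (bridging the gaps between neighbouring p63
    nuclei) followed by dilation.  An empty p63 mask yields an empty region;
    downstream consumers must surface a QC warning in that case.
    """
    p63_mask = as_bool_mask(p63_mask, "p63_mask")
    if dilation_radius_px < 0:
        raise ValueError("dilation_radius_px must be >= 0")
    if not p63_mask.any():
        return np.zeros(p63_mask.shape, dtype=bool)
    region = p63_mask
    if closing_radius_px > 0:
        region = ndi.binary_closing(region, structure=disk(closing_radius_px))
        region |= p63_mask  # closing near image edges must stay extensive
    if dilation_radius_px > 0:
        region = ndi.binary_dilation(region, structure=disk(dilation_radius_px))
    return region


def median_equivalent_diameter(labels: np.ndarray) -> float:
    """Median equivalent diameter (2*sqrt(area/pi)) of labeled nuclei."""
    sizes = np.bincount(labels.ravel())[1:]
    sizes = sizes[sizes > 0]
    if len(sizes) == 0:
        return 0.0
    return float(np.median(2.0 * np.sqrt(sizes / np.pi)))


def save_label_map(path: str | Path, labels: np.ndarray,
                   meta: dict | None = None) -> None:
    """Serialize a label map (or mask) as 16-bit TIFF + JSON sidecar."""
    path = Path(path)
    arr = labels.astype(np.uint16)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit serialization")
    tifffile.imwrite(path, arr)
    if meta is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2, default=str))


def load_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)
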