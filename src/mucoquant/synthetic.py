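"""Synthetic mucosa tissue-slice generator with planted ground truth.

Emulates the statistical structure of irradiated ex vivo mucosa imaging data:
a stratified epithelium whose basal (p63-positive) progenitor layer loses
EdU-incorporating cells with dose, a dose-dependent gain of TUNEL-positive
apoptotic nuclei, Poisson-distributed 53BP1 DNA-damage foci per nucleus, and
an increasing fraction of DAB-stained immune cells in brightfield IHC.
Per-sample heterogeneity enters as multiplicative log-normal factors on the
baseline rates.

The renderer is calibrated so that pixel-level ground truth is well defined:
fluorescent nuclei are 2D Gaussian blobs with sigma = r / sqrt(2 ln 2) and
signal amplitude 168 over a background of 6, which puts the 8-bit intensity
90 exactly at the blob half-maximum — the pixels above the working threshold
of a planted nucleus form a disc of the planted radius r, with area pi r^2.
IHC stains are rendered as hard uniform-density discs through the
Beer–Lambert forward model, so "DAB-positive pixel area" is exact.

Every operation is deterministic for a fixed seed; independent random
streams are used per channel so that optional artifacts (e.g. the bright
TUNEL rim at the tissue border) can be toggled without disturbing any other
draw.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage as ndi

from .ihc import StainMatrix, synthesize_rgb
from .types import FLUOR_CHANNELS, Condition, MultiChannelImage

# Half-max radius of a unit-sigma Gaussian: r_half = sigma * sqrt(2 ln 2).
HALF_MAX_SIGMA = math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# Tissue geometry
# ---------------------------------------------------------------------------

@dataclass
class TissueLayout:
    """Compartment masks of one synthetic tissue slice.

    Invariants: basal ⊆ epithelium ⊆ tissue, lamina = tissue ∖ epithelium.
    """

    shape: tuple[int, int]
    tissue: np.ndarray
    epithelium: np.ndarray
    basal: np.ndarray
    lamina: np.ndarray
    pixel_size_um: float

    def validate(self) -> None:
        for name in ("tissue", "epithelium", "basal", "lamina"):
            m = getattr(self, name)
            if m.shape != self.shape or m.dtype != bool:
                raise ValueError(f"{name} mask malformed")
        if (self.basal & ~self.epithelium).any():
            raise ValueError("basal layer not contained in epithelium")
        if (self.epithelium & ~self.tissue).any():
            raise ValueError("epithelium not contained in tissue")
        if (self.lamina & self.epithelium).any():
            raise ValueError("lamina overlaps epithelium")
        if ((self.lamina | self.epithelium) != self.tissue).any():
            raise ValueError("lamina and epithelium do not partition tissue")

    def compartment_of(self, y: float, x: float) -> str:
        iy, ix = int(round(y)), int(round(x))
        if self.basal[iy, ix]:
            return "basal"
        if self.epithelium[iy, ix]:
            return "suprabasal"
        if self.lamina[iy, ix]:
            return "lamina"
        return "outside"


def generate_tissue_geometry(
    shape: tuple[int, int],
    pixel_size_um: float = 0.25,
    seed: int = 0,
    *,
    margin_frac: float = 0.06,
    epithelium_frac: float = 0.45,
    basal_thickness_um: float = 10.0,
    nominal_nucleus_diameter_um: float = 7.0,
    boundary_amplitude_frac: float = 0.03,
) -> TissueLayout:
    """Generate a horizontal tissue band with epithelium, basal layer, lamina.

    The slice spans the full image width; wavy upper and lower boundaries
    separate it from background.  The epithelium occupies the upper
    ``epithelium_frac`` of the tissue depth and its deepest
    ``basal_thickness_um`` forms the basal (p63-positive) progenitor layer;
    everything below is lamina propria.

    Raises ``ValueError`` if the epithelial band would be thinner than three
    nominal nucleus diameters.
    """
    rows, cols = shape
    if rows < 64 or cols < 64:
        raise ValueError("image must be at least 64x64 pixels")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    rng = np.random.default_rng(seed)
    x = np.arange(cols)

    def wavy(base_row: float, amp: float) -> np.ndarray:
        phases = rng.uniform(0, 2 * np.pi, 3)
        freqs = rng.uniform(0.8, 3.0, 3)
        w = sum(np.sin(2 * np.pi * f * x / cols + p) for f, p in zip(freqs, phases))
        return base_row + amp * w / 3.0

    margin = margin_frac * rows
    amp = boundary_amplitude_frac * rows
    top = wavy(margin + amp, amp)
    bottom = wavy(rows - margin - amp, amp)
    rr = np.arange(rows)[:, None]
    tissue = (rr >= top[None, :]) & (rr < bottom[None, :])

    interface = top + epithelium_frac * (bottom - top)
    epithelium = tissue & (rr < interface[None, :])
    basal_px = basal_thickness_um / pixel_size_um
    basal = epithelium & (rr >= (interface - basal_px)[None, :])
    lamina = tissue & ~epithelium

    min_thickness = float((interface - top).min())
    needed = 3.0 * nominal_nucleus_diameter_um / pixel_size_um
    if min_thickness < needed:
        raise ValueError(
            "shape too small: epithelial band thinner than three nucleus "
            f"diameters ({min_thickness:.0f} px < {needed:.0f} px)"
        )
    layout = TissueLayout(shape, tissue, epithelium, basal, lamina, pixel_size_um)
    layout.validate()
    return layout


# ---------------------------------------------------------------------------
# Dose-response parameters and phenotype assignment
# ---------------------------------------------------------------------------

@dataclass
class EffectParams:
    """Generative dose-response model standing in for the observed trends.

    Proliferation decays exponentially with dose, apoptosis and the 53BP1
    focus rate rise linearly, and the fraction of DAB-positive immune cells
    rises linearly; the observations behind these shapes are monotone trends
    only, so the functional forms are a modelling choice.  Per-sample
    heterogeneity multiplies p0, a0 and lambda0 by log-normal factors.
    """

    p0: float = 0.4                    # baseline EdU+ fraction of basal nuclei
    alpha: float = 0.15                # proliferation decay (per Gy)
    a0: float = 0.03                   # baseline TUNEL+ fraction
    beta: float = 0.02                 # apoptosis slope (per Gy)
    lambda0: float = 0.5               # baseline 53BP1 foci per nucleus
    kappa: float = 0.6                 # foci per nucleus per Gy
    focus_radius_um: float = 0.6       # mean focus radius
    focus_radius_sd_um: float = 0.1
    focus_radius_per_gy_um: float = 0.015
    ihc_frac0: float = 0.06            # baseline marker-positive cell fraction
    ihc_frac_per_gy: float = 0.012
    cd45_lamina_frac: float = 0.5      # CD45+ probability, lamina nuclei
    cd45_epithelium_frac: float = 0.05 # CD45+ probability, epithelial nuclei
    sample_sd: float = 0.2             # log-normal sd of per-sample factors
    proton_rbe: float = 1.1            # effective-dose multiplier for protons
    day_prolif_decay: float = 0.05     # proliferation loss per culture day
    day_apoptosis_slope: float = 0.01  # apoptosis gain per culture day

    def validate(self) -> None:
        for name in ("p0", "alpha", "a0", "beta", "lambda0", "kappa",
                     "focus_radius_um", "focus_radius_sd_um", "ihc_frac0",
                     "ihc_frac_per_gy", "sample_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"EffectParams.{name} must be >= 0")
        for name in ("p0", "a0", "ihc_frac0", "cd45_lamina_frac",
                     "cd45_epithelium_frac"):
            if getattr(self, name) > 1:
                raise ValueError(f"EffectParams.{name} must be <= 1")

    def dose_response(
        self,
        dose_gy: float,
        modality: str = "xray",
        day: int = 0,
        sample_factors: tuple[float, float, float] = (1.0, 1.0, 1.0),
    ) -> dict:
        """Realized event probabilities/rates for one condition."""
        self.validate()
        if dose_gy < 0:
            raise ValueError("dose must be >= 0")
        d = dose_gy * (self.proton_rbe if modality == "proton" else 1.0)
        fp, fa, fl = sample_factors
        p_edu = self.p0 * fp * math.exp(-self.alpha * d - self.day_prolif_decay * day)
        p_tunel = self.a0 * fa + self.day_apoptosis_slope * day + self.beta * d
        rate = max(0.0, self.lambda0 * fl + self.kappa * d)
        return {
            "p_edu": min(1.0, max(0.0, p_edu)),
            "p_tunel": min(1.0, max(0.0, p_tunel)),
            "foci_rate": rate,
            "focus_radius_um": self.focus_radius_um + self.focus_radius_per_gy_um * d,
            "ihc_frac": min(1.0, max(0.0, self.ihc_frac0 + self.ihc_frac_per_gy * d)),
        }


@dataclass
class NucleusGT:
    """Planted ground truth for one nucleus."""

    id: int
    y: float
    x: float
    radius_um: float
    compartment: str          # basal | suprabasal | lamina
    p63: bool
    edu: bool
    tunel: bool
    cd45: bool
    foci_radii_um: list[float] = field(default_factory=list)
    foci_yx: list[tuple[float, float]] = field(default_factory=list)
    condition: Condition | None = None

    def __post_init__(self):
        if self.edu and not self.p63:
            raise ValueError("EdU+ implies p63+ in the generator")
        if len(self.foci_radii_um) != len(self.foci_yx):
            raise ValueError("foci radii and positions out of sync")

    @property
    def n_foci(self) -> int:
        return len(self.foci_radii_um)

    def radius_px(self, pixel_size_um: float) -> float:
        return self.radius_um / pixel_size_um

    def area_px(self, pixel_size_um: float) -> float:
        """Planted half-max disc area in pixels."""
        return math.pi * self.radius_px(pixel_size_um) ** 2


def _sample_centers(
    rng: np.random.Generator,
    allowed: np.ndarray,
    target: int,
    min_dist_px: float,
    taken: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Dart-throwing placement with a hard minimum center distance."""
    coords = np.argwhere(allowed)
    if len(coords) == 0 or target <= 0:
        return []
    placed: list[tuple[float, float]] = []
    existing = list(taken)
    arr = np.array(existing, dtype=float) if existing else np.empty((0, 2))
    d2 = min_dist_px * min_dist_px
    attempts = 0
    max_attempts = 60 * target
    while len(placed) < target and attempts < max_attempts:
        attempts += 1
        y, x = coords[rng.integers(len(coords))] + rng.uniform(-0.5, 0.5, 2)
        if arr.shape[0]:
            if ((arr[:, 0] - y) ** 2 + (arr[:, 1] - x) ** 2).min() < d2:
                continue
        placed.append((float(y), float(x)))
        arr = np.vstack([arr, [y, x]])
    return placed


def _place_foci(
    rng: np.random.Generator,
    nucleus_yx: tuple[float, float],
    nucleus_r_px: float,
    count: int,
    radius_mean_um: float,
    radius_sd_um: float,
    pixel_size_um: float,
    overlap_stress: bool = False,
) -> tuple[list[float], list[tuple[float, float]]]:
    """Place up to ``count`` disjoint foci inside a nucleus.

    Foci that cannot be fitted after many attempts are dropped (the recorded
    truth is always the realized placement).  With ``overlap_stress`` the
    separation constraint is halved so foci may touch.
    """
    radii_um: list[float] = []
    centers: list[tuple[float, float]] = []
    sep_factor = 0.5 if overlap_stress else 1.0
    cy, cx = nucleus_yx
    for _ in range(count):
        r_um = float(np.clip(rng.normal(radius_mean_um, radius_sd_um), 0.25, 1.6))
        r_px = r_um / pixel_size_um
        max_off = nucleus_r_px - r_px - 1.0
        if max_off <= 0:
            continue
        for _attempt in range(60):
            rho = max_off * math.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * math.pi)
            fy, fx = cy + rho * math.sin(theta), cx + rho * math.cos(theta)
            ok = True
            for (oy, ox), or_um in zip(centers, radii_um):
                min_sep = sep_factor * ((r_um + or_um) / pixel_size_um + 1.0)
                if (fy - oy) ** 2 + (fx - ox) ** 2 < min_sep ** 2:
                    ok = False
                    break
            if ok:
                radii_um.append(r_um)
                centers.append((fy, fx))
                break
    return radii_um, centers


def assign_phenotypes(
    layout: TissueLayout,
    n_nuclei: int,
    condition: Condition,
    effects: EffectParams,
    seed: int = 0,
    *,
    sample_factors: tuple[float, float, float] = (1.0, 1.0, 1.0),
    nucleus_radius_um: float = 3.5,
    nucleus_radius_sd_um: float = 0.35,
    min_dist_factor: float = 2.1,
    compartment_weights: dict | None = None,
    overlap_stress: bool = False,
) -> list[NucleusGT]:
    """Place nuclei and draw their phenotype flags and foci.

    Nuclei are dart-thrown with a minimum center distance of
    ``min_dist_factor`` × the mean nucleus radius.  The default 2.1 lets
    neighbouring nuclei touch (so watershed splitting is exercised) without
    interpenetrating, which would make per-nucleus pixel truth ill-defined.
    Targets are allocated to compartments proportionally to weighted
    compartment area and capped by the packing the dart throwing achieves.  Basal nuclei are p63+; EdU positivity is drawn only
    for p63+ nuclei with the dose-responsive probability, TUNEL positivity
    for all nuclei, and foci counts are Poisson with the dose-responsive
    rate.
    """
    if condition.dose_gy < 0:
        raise ValueError("dose must be >= 0")
    rng = np.random.default_rng(seed)
    resp = effects.dose_response(
        condition.dose_gy, condition.modality, condition.day, sample_factors
    )
    ps = layout.pixel_size_um
    r_mean_px = nucleus_radius_um / ps
    min_dist = min_dist_factor * r_mean_px
    weights = compartment_weights or {"basal": 2.0, "suprabasal": 1.0, "lamina": 0.7}

    # keep centers deep enough that most of the blob stays inside the tissue
    depth = ndi.distance_transform_edt(layout.tissue)
    deep = depth > 0.8 * r_mean_px
    comp_masks = {
        "basal": layout.basal & deep,
        "suprabasal": (layout.epithelium & ~layout.basal) & deep,
        "lamina": layout.lamina & deep,
    }
    wa = {c: weights.get(c, 1.0) * m.sum() for c, m in comp_masks.items()}
    total_wa = sum(wa.values()) or 1.0

    nuclei: list[NucleusGT] = []
    taken: list[tuple[float, float]] = []
    nid = 0
    for comp in ("basal", "suprabasal", "lamina"):
        target = int(round(n_nuclei * wa[comp] / total_wa))
        centers = _sample_centers(rng, comp_masks[comp], target, min_dist, taken)
        taken.extend(centers)
        for (y, x) in centers:
            radius_um = float(
                np.clip(rng.normal(nucleus_radius_um, nucleus_radius_sd_um),
                        2.2, 5.0)
            )
            p63 = comp == "basal"
            edu = bool(p63 and rng.uniform() < resp["p_edu"])
            tunel = bool(rng.uniform() < resp["p_tunel"])
            cd45_p = (effects.cd45_lamina_frac if comp == "lamina"
                      else effects.cd45_epithelium_frac)
            cd45 = bool(rng.uniform() < cd45_p)
            k = int(rng.poisson(resp["foci_rate"]))
            radii, centers_f = _place_foci(
                rng, (y, x), radius_um / ps, k,
                resp["focus_radius_um"], effects.focus_radius_sd_um, ps,
                overlap_stress=overlap_stress,
            )
            nuclei.append(NucleusGT(
                id=nid, y=y, x=x, radius_um=radius_um, compartment=comp,
                p63=p63, edu=edu, tunel=tunel, cd45=cd45,
                foci_radii_um=radii, foci_yx=centers_f, condition=condition,
            ))
            nid += 1
    return nuclei


# ---------------------------------------------------------------------------
# Fluorescence rendering
# ---------------------------------------------------------------------------

@dataclass
class NoiseParams:
    """Rendering amplitudes and noise model for the fluorescence channels.

    Nuclei are uniform discs of the planted radius convolved with a Gaussian
    point-spread function of ``psf_sigma_px``; the blurred edge crosses half
    amplitude exactly at the disc boundary, so with the defaults (amplitude
    168 over background 6) the 8-bit threshold 90 recovers the planted disc.
    Foci are diffraction-limited and stay pure Gaussians.  Shot noise is
    Poisson in the expected intensity, plus Gaussian read noise.  The optional TUNEL border artifact plants bright
    non-nuclear blobs within ``artifact_depth_um`` of the tissue edge, using
    an independent random stream so toggling it leaves every other pixel and
    channel untouched.
    """

    background: float = 6.0
    read_noise_sd: float = 2.0
    poisson: bool = True
    signal_amp: float = 168.0
    psf_sigma_px: float = 1.5
    bp1_diffuse_amp: float = 25.0
    focus_amp: float = 150.0
    tunel_border_artifact: bool = False
    artifact_n: int = 12
    artifact_amp: float = 215.0
    artifact_radius_um: float = 1.5
    artifact_depth_um: float = 5.0

    @classmethod
    def noiseless(cls, **overrides) -> "NoiseParams":
        kw = dict(background=0.0, read_noise_sd=0.0, poisson=False)
        kw.update(overrides)
        return cls(**kw)


def _add_gaussian(img: np.ndarray, y: float, x: float, sigma: float,
                  amp: float, trunc: float = 3.2) -> None:
    rows, cols = img.shape
    r = int(math.ceil(trunc * sigma))
    iy, ix = int(round(y)), int(round(x))
    y0, y1 = max(0, iy - r), min(rows, iy + r + 1)
    x0, x1 = max(0, ix - r), min(cols, ix + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1)[:, None] - y
    xx = np.arange(x0, x1)[None, :] - x
    img[y0:y1, x0:x1] += amp * np.exp(-(yy ** 2 + xx ** 2) / (2.0 * sigma ** 2))


def _add_disc(img: np.ndarray, y: float, x: float, radius: float,
              amp: float) -> None:
    """Anti-aliased uniform disc; overlapping discs take the maximum."""
    rows, cols = img.shape
    r = int(math.ceil(radius)) + 1
    iy, ix = int(round(y)), int(round(x))
    y0, y1 = max(0, iy - r), min(rows, iy + r + 1)
    x0, x1 = max(0, ix - r), min(cols, ix + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1)[:, None] - y
    xx = np.arange(x0, x1)[None, :] - x
    dist = np.sqrt(yy ** 2 + xx ** 2)
    cover = np.clip(radius - dist + 0.5, 0.0, 1.0)  # subpixel edge coverage
    region = img[y0:y1, x0:x1]
    np.maximum(region, amp * cover, out=region)


def render_fluorescence(
    layout: TissueLayout,
    nuclei: Sequence[NucleusGT],
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> MultiChannelImage:
    """Render the five fluorescence channels as 8-bit images.

    DAPI shows every nucleus; p63/EdU/TUNEL show the flagged subsets; the
    53BP1 channel shows a faint diffuse nuclear signal plus one bright
    Gaussian spot per planted focus (sigma chosen so the half-max contour has
    the planted radius).
    """
    noise = noise or NoiseParams()
    ps = layout.pixel_size_um
    shape = layout.shape
    rng = np.random.default_rng(seed)
    streams = rng.spawn(len(FLUOR_CHANNELS) + 1)
    chan_streams = dict(zip(FLUOR_CHANNELS, streams[:-1]))
    artifact_stream = streams[-1]

    discs = {ch: np.zeros(shape) for ch in FLUOR_CHANNELS}
    for nuc in nuclei:
        r_px = nuc.radius_px(ps)
        _add_disc(discs["dapi"], nuc.y, nuc.x, r_px, noise.signal_amp)
        if nuc.p63:
            _add_disc(discs["p63"], nuc.y, nuc.x, r_px, noise.signal_amp)
        if nuc.edu:
            _add_disc(discs["edu"], nuc.y, nuc.x, r_px, noise.signal_amp)
        if nuc.tunel:
            _add_disc(discs["tunel"], nuc.y, nuc.x, r_px, noise.signal_amp)
        if noise.bp1_diffuse_amp > 0:
            _add_disc(discs["53bp1"], nuc.y, nuc.x, r_px, noise.bp1_diffuse_amp)

    clean: dict[str, np.ndarray] = {}
    for ch in FLUOR_CHANNELS:
        img = discs[ch]
        if noise.psf_sigma_px > 0 and img.any():
            img = ndi.gaussian_filter(img, noise.psf_sigma_px)
        clean[ch] = img + float(noise.background)
    # diffraction-limited foci: pure Gaussian spots, added after the PSF blur
    for nuc in nuclei:
        for (fy, fx), fr_um in zip(nuc.foci_yx, nuc.foci_radii_um):
            fsigma = (fr_um / ps) / HALF_MAX_SIGMA
            _add_gaussian(clean["53bp1"], fy, fx, fsigma, noise.focus_amp)

    channels: dict[str, np.ndarray] = {}
    for ch in FLUOR_CHANNELS:
        st = chan_streams[ch]
        img = st.poisson(clean[ch]).astype(float) if noise.poisson else clean[ch].copy()
        if noise.read_noise_sd > 0:
            img += st.normal(0.0, noise.read_noise_sd, shape)
        channels[ch] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    if noise.tunel_border_artifact and noise.artifact_n > 0:
        depth = ndi.distance_transform_edt(layout.tissue)
        band = layout.tissue & (depth < noise.artifact_depth_um / ps) & (depth > 0)
        coords = np.argwhere(band)
        if len(coords):
            art = np.zeros(shape)
            sigma = (noise.artifact_radius_um / ps) / HALF_MAX_SIGMA
            picks = artifact_stream.integers(len(coords), size=noise.artifact_n)
            for iy, ix in coords[picks]:
                _add_gaussian(art, float(iy), float(ix), sigma, noise.artifact_amp,
                              trunc=2.5)
            art[art < 0.5] = 0.0  # hard support so the artifact stays local
            art_noisy = (artifact_stream.poisson(art) if noise.poisson
                         else np.round(art))
            tun = channels["tunel"].astype(np.int64) + art_noisy.astype(np.int64)
            channels["tunel"] = np.clip(tun, 0, 255).astype(np.uint8)

    return MultiChannelImage(channels=channels, pixel_size_um=ps)


# ---------------------------------------------------------------------------
# Brightfield IHC rendering
# ---------------------------------------------------------------------------

@dataclass
class IHCRender:
    """RGB brightfield render plus exact planted truth."""

    rgb: np.ndarray
    nuclear_mask: np.ndarray   # planted hematoxylin-positive pixels
    dab_mask: np.ndarray       # planted DAB-positive pixels
    positive_ids: tuple[int, ...]

    @property
    def nuclear_area_px(self) -> int:
        return int(self.nuclear_mask.sum())

    @property
    def dab_area_px(self) -> int:
        return int(self.dab_mask.sum())

    @property
    def positive_area_pct(self) -> float:
        """Planted DAB area relative to planted nuclear area, in percent."""
        return 100.0 * self.dab_area_px / self.nuclear_area_px


def _fill_disc(img: np.ndarray, y: float, x: float, r: float, value: float) -> None:
    rows, cols = img.shape
    ir = int(math.ceil(r))
    iy, ix = int(round(y)), int(round(x))
    y0, y1 = max(0, iy - ir), min(rows, iy + ir + 1)
    x0, x1 = max(0, ix - ir), min(cols, ix + ir + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1)[:, None] - y
    xx = np.arange(x0, x1)[None, :] - x
    disc = yy ** 2 + xx ** 2 <= r * r
    region = img[y0:y1, x0:x1]
    region[disc] = np.maximum(region[disc], value)


def render_ihc(
    layout: TissueLayout,
    nuclei: Sequence[NucleusGT],
    positive_fraction: float,
    stain_matrix: StainMatrix | None = None,
    seed: int = 0,
    *,
    c_hematoxylin: float = 0.5,
    c_dab: float = 0.8,
    dab_radius_factor: float = 0.8,
    od_noise_sd: float = 0.02,
    quantize: bool = True,
    positive_ids: Sequence[int] | None = None,
) -> IHCRender:
    """Render an H-DAB brightfield image via the Beer–Lambert forward model.

    Every nucleus carries a hematoxylin density disc; a planted fraction of
    nuclei (drawn at random unless ``positive_ids`` is given) carries an
    additional DAB disc.  Transmitted RGB per pixel is
    ``255 * 10^-(c_H * V_H + c_DAB * V_DAB)`` componentwise.  Ground truth
    masks record the exact planted stain-positive pixels (pre-noise).
    """
    stains = stain_matrix or StainMatrix.hdab()
    if not 0 <= positive_fraction <= 1:
        raise ValueError("positive_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ps = layout.pixel_size_um
    shape = layout.shape
    c_h_map = np.zeros(shape)
    c_d_map = np.zeros(shape)
    for nuc in nuclei:
        _fill_disc(c_h_map, nuc.y, nuc.x, nuc.radius_px(ps), c_hematoxylin)
    ids = [n.id for n in nuclei]
    if positive_ids is None:
        n_pos = int(round(positive_fraction * len(ids)))
        positive_ids = (tuple(sorted(rng.choice(ids, size=n_pos, replace=False)))
                        if n_pos else ())
    else:
        positive_ids = tuple(positive_ids)
    pos_set = set(positive_ids)
    for nuc in nuclei:
        if nuc.id in pos_set:
            _fill_disc(c_d_map, nuc.y, nuc.x,
                       dab_radius_factor * nuc.radius_px(ps), c_dab)
    nuclear_mask = c_h_map > 0
    dab_mask = c_d_map > 0
    if od_noise_sd > 0:
        c_h_map = np.clip(c_h_map + rng.normal(0, od_noise_sd, shape), 0, None)
        c_d_map = np.clip(c_d_map + rng.normal(0, od_noise_sd, shape), 0, None)
    conc = np.stack([c_h_map, c_d_map])
    rgb = synthesize_rgb(conc, stains, quantize=quantize)
    return IHCRender(rgb=rgb, nuclear_mask=nuclear_mask, dab_mask=dab_mask,
                     positive_ids=positive_ids)


# ---------------------------------------------------------------------------
# Experiment-level generation
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Design of one synthetic experiment (samples × arms × days × FoVs)."""

    samples: list[str] = field(default_factory=lambda: ["S1", "S2"])
    arms: list[tuple[float, str]] = field(
        default_factory=lambda: [(0.0, "xray"), (5.0, "xray"), (10.0, "xray")]
    )
    days: list[int] = field(default_factory=lambda: [1, 3])
    fovs_per_condition: int = 3
    shape: tuple[int, int] = (384, 512)
    pixel_size_um: float = 0.25
    n_nuclei: int = 170
    nucleus_radius_um: float = 3.5
    nucleus_radius_sd_um: float = 0.35
    basal_thickness_um: float = 10.0
    epithelium_frac: float = 0.45
    effects: EffectParams = field(default_factory=EffectParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    include_ihc: bool = True
    ihc_od_noise_sd: float = 0.02

    def validate(self) -> None:
        if self.fovs_per_condition < 1:
            raise ValueError("need at least one FoV per condition")
        arms = [(float(d), m) for d, m in self.arms]
        if len(set(arms)) != len(arms):
            raise ValueError("duplicate condition arms")
        if len(set(self.days)) != len(self.days):
            raise ValueError("duplicate timepoints")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        self.effects.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        kw = dict(raw)
        if "effects" in kw and isinstance(kw["effects"], dict):
            kw["effects"] = EffectParams(**kw["effects"])
        if "noise" in kw and isinstance(kw["noise"], dict):
            kw["noise"] = NoiseParams(**kw["noise"])
        if "arms" in kw:
            kw["arms"] = [(float(d), str(m)) for d, m in kw["arms"]]
        if "shape" in kw:
            kw["shape"] = tuple(kw["shape"])
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["arms"] = [[float(a), m] for a, m in self.arms]
        d["shape"] = list(self.shape)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def ground_truth_frame(nuclei: Sequence[NucleusGT]) -> pd.DataFrame:
    """One row per nucleus, matching the on-disk ground-truth CSV schema."""
    rows = []
    for n in nuclei:
        c = n.condition or Condition(sample="?")
        rows.append({
            "id": n.id, "x": round(n.x, 3), "y": round(n.y, 3),
            "radius_um": round(n.radius_um, 4), "compartment": n.compartment,
            "p63": int(n.p63), "edu": int(n.edu), "tunel": int(n.tunel),
            "cd45": int(n.cd45), "n_foci": n.n_foci,
            "foci_radii_um": ";".join(f"{r:.4f}" for r in n.foci_radii_um),
            **c.as_dict(),
        })
    return pd.DataFrame(rows)


def realized_fractions(gt: pd.DataFrame, pixel_size_um: float) -> dict:
    """Pixel-area fractions realized by the planted truth.

    EdU+/p63+ is an area ratio over p63+ (basal) nuclei; TUNEL is the area
    fraction of TUNEL+ among basal-layer nuclei (the analysis region).
    """
    area = math.pi * (gt["radius_um"] / pixel_size_um) ** 2
    p63 = gt["p63"] == 1
    basal = gt["compartment"] == "basal"
    out = {
        "edu_fraction_pct": float("nan"),
        "tunel_fraction_pct": float("nan"),
        "mean_foci": float(gt["n_foci"].mean()) if len(gt) else float("nan"),
    }
    if area[p63].sum() > 0:
        out["edu_fraction_pct"] = 100.0 * area[p63 & (gt["edu"] == 1)].sum() / area[p63].sum()
    if area[basal].sum() > 0:
        out["tunel_fraction_pct"] = (
            100.0 * area[basal & (gt["tunel"] == 1)].sum() / area[basal].sum()
        )
    return out


def generate_experiment(
    config: ExperimentConfig, seed: int, out_dir: str | Path
) -> pd.DataFrame:
    """Write TIFF images, ground-truth CSV and manifest CSV for a full design.

    Fully reproducible from ``(config, seed)``: per-sample heterogeneity
    factors and per-FoV sub-seeds are drawn from a single root generator in a
    fixed iteration order.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    sd = config.effects.sample_sd
    factors = {
        s: tuple(np.exp(root.normal(-0.5 * sd * sd, sd, 3)))
        for s in config.samples
    }

    gt_frames: list[pd.DataFrame] = []
    manifest_rows: list[dict] = []
    for sample in config.samples:
        for day in config.days:
            for dose, modality in config.arms:
                for fov in range(1, config.fovs_per_condition + 1):
                    geom_s, pheno_s, rend_s, ihc_s = root.integers(2 ** 31, size=4)
                    cond = Condition(sample=sample, dose_gy=float(dose),
                                     modality=modality, day=day, fov=fov)
                    layout = generate_tissue_geometry(
                        config.shape, config.pixel_size_um, int(geom_s),
                        basal_thickness_um=config.basal_thickness_um,
                        epithelium_frac=config.epithelium_frac,
                    )
                    nuclei = assign_phenotypes(
                        layout, config.n_nuclei, cond, config.effects,
                        int(pheno_s), sample_factors=factors[sample],
                        nucleus_radius_um=config.nucleus_radius_um,
                        nucleus_radius_sd_um=config.nucleus_radius_sd_um,
                    )
                    mci = render_fluorescence(layout, nuclei, config.noise,
                                              int(rend_s))
                    stem = (f"{sample}_{dose:g}Gy_{modality}_d{day}_fov{fov}")
                    row = {**cond.as_dict(), "pixel_size_um": config.pixel_size_um}
                    for ch in FLUOR_CHANNELS:
                        fname = f"{stem}_{ch}.tif"
                        tifffile.imwrite(out / fname, mci[ch])
                        row[ch] = fname
                    if config.include_ihc:
                        resp = config.effects.dose_response(
                            float(dose), modality, day, factors[sample])
                        ihc = render_ihc(layout, nuclei, resp["ihc_frac"],
                                         seed=int(ihc_s),
                                         od_noise_sd=config.ihc_od_noise_sd)
                        fname = f"{stem}_ihc.tif"
                        tifffile.imwrite(out / fname, ihc.rgb)
                        row["ihc"] = fname
                        row["ihc_true_positive_pct"] = round(ihc.positive_area_pct, 4)
                    gt_frames.append(ground_truth_frame(nuclei))
                    manifest_rows.append(row)

    gt = pd.concat(gt_frames, ignore_index=True)
    manifest = pd.DataFrame(manifest_rows)
    gt.to_csv(out / "ground_truth.csv", index=False, float_format="%.6g")
    manifest.to_csv(out / "manifest.csv", index=False, float_format="%.6g")
    (out / "generation.json").write_text(
        json.dumps({"seed": int(seed), "config": config.to_dict()},
                   indent=2, default=float)
    )
    return manifest
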