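# Methods

## Readouts and their definitions

All four readouts are deliberately simple, parameter-explicit image
statistics; nothing is fitted.

**Proliferation.** p63 marks the basal progenitor layer of stratified
mucosal epithelium; EdU marks S-phase nuclei. Both are reduced to binary
pixel masks — p63 by nucleus segmentation, EdU by a fixed 8-bit threshold
of 90 (strictly greater; the inequality direction is a convention we fix
and document, since at the blob half-maximum it changes areas by well under
a percent) — and the index is the pixel ratio
`100 · |EdU ∩ p63| / |p63|`. It is an area-weighted positive fraction, not
a cell count: large nuclei weigh more. An empty p63 mask (no healthy
epithelium in the field) makes the index undefined and raises an error
carrying a QC flag, rather than returning 0.

**Apoptosis.** TUNEL and DAPI nuclei are segmented independently; both
label maps are restricted to the analysis region before any counting, and
the index is `100 · |TUNEL ∩ DAPI| / |DAPI|` on the rasterized positive
pixels. The analysis region is (a) the p63-stained cell layer — the
morphological closing of the p63 mask (closing radius 2 µm bridges the
gaps between neighbouring basal nuclei) dilated by 1.5 µm — minus (b) the
border exclusion band: all tissue pixels closer than `n_layers ×` one
nucleus diameter to the tissue boundary (distance transform of the tissue
mask, with image edges counting as boundary). `n_layers` defaults to 2;
"one cell layer" is operationalized as the median equivalent diameter of
the segmented DAPI nuclei in that field, since no pixel definition exists
for a cell layer. Because the exclusion is applied to the pixels before
either count, anything planted strictly inside the band — such as the
bright TUNEL rim frequently seen at cut tissue edges — changes the index
by exactly zero, a property the tests assert bit-for-bit.

**53BP1 foci.** The published protocols defer the focus-counting method to
prior work, so this module is a complete, self-contained re-implementation
with every scale exposed: white top-hat at radius 6 px (larger than any
focus, smaller than the diffuse-signal structure) flattens the nuclear
background; within each nucleus, candidate spot pixels exceed
`mode + k·MAD₋` where the mode is the modal flattened intensity (integer
binning) and MAD₋ is the scaled median deviation *below* the mode. We use
the mode rather than the median deliberately: at six foci per nucleus the
Gaussian skirts of the spots cover most of the nucleus area and drag the
median — but not the mode — off the background. Touching spots are split
by watershed seeded at intensity local maxima (minimum separation 3 px);
spots are filtered by raw area (4–400 px²) and by a minimum peak amplitude
(50 above background) that rejects the low-amplitude rim artifacts the
top-hat leaves at the edge of the diffuse nuclear signal. Focus size is
the FWHM area: pixels above half the spot's peak within the spot's
watershed zone over the whole nucleus (not the thresholded region, which
would clip the footprint whenever the detection threshold sits above
half-maximum). Counts are reported per nucleus (zero included); with
`restrict_foci_to_p63` (default on) only nuclei overlapping the p63 mask
by ≥ 50% of their area are scored. QC minima are per sample, pooled over
fields: ≥ 100 nuclei for count reporting, ≥ 75 foci for size reporting,
both inclusive.

**IHC area.** Brightfield H-DAB images are unmixed by Beer–Lambert
optical-density deconvolution: `OD = −log10(max(I, 1)/255)` per RGB
channel (the floor of one ADU guards saturated dark pixels on quantized
data; float inputs use a tiny epsilon instead, since sub-ADU transmissions
are meaningful there), concentrations solve `c·M = OD` by least squares
with the standard unit-norm H-DAB vectors (H ≈ (0.650, 0.704, 0.286),
DAB ≈ (0.268, 0.570, 0.776)), negatives clipped to zero, and each stain is
re-expressed as transmission `round(255·10^−c)`. On this 255 = unstained
convention, "threshold and invert" reduces to selecting dark pixels:
nuclear mask = hematoxylin ≤ 205, marker mask = DAB ≤ 210 (direction
switchable by config; this threshold-frame ambiguity is the least
determined step of the protocol). Marker particles under 4 px² are
discarded. The score `100 · |marker| / |nuclear|` is stored unclamped —
membranous staining can exceed the nuclear area. 8-bit quantization limits
the deconvolution round trip at high combined densities (at
c_H = c_DAB = 2 the transmitted intensity falls below one ADU and the
floor alone distorts OD by ~0.14), so exactness checks of the unmixing
mathematics use unquantized forward renders; the quantized path is checked
at the printed example values (unit DAB concentration → channel 26).

**Statistics.** Kruskal–Wallis uses the tie-corrected H with a chi-square
reference regardless of group size (groups under 5 are flagged);
all-identical data is reported as H = 0, p = 1 with a flag instead of a
division by zero. Dunn's post hoc z uses the pooled mid-ranks with the
tie term `ΣT = Σ(t³−t)`; the multiple-comparison adjustment is
Bonferroni-style multiplication by default because the upstream tool's
exact convention is undisclosed — Holm is available by config. Mann–Whitney
is exact by enumeration for N ≤ 20 without ties, otherwise the normal
approximation with tie and continuity corrections. Quartiles use
linear-interpolation order statistics (type 7), fixed because quartile
conventions differ across tools. Stars: * < 0.05, ** < 0.01, *** < 0.001,
**** < 0.0001. By default FoVs of all samples are pooled per arm (the
reporting convention of the summaries); nucleus-level metrics pool all
nuclei.

## The synthetic generator

The generator is the package's ground-truth instrument, not a fixture. It
emulates the statistical structure the analysis assumes:

- **Geometry.** A full-width tissue band with wavy boundaries; the upper
  45% of the tissue depth is epithelium, whose deepest 10 µm is the basal
  (p63+) layer; the rest is lamina propria. Invariants
  (basal ⊆ epithelium ⊆ tissue, lamina = tissue ∖ epithelium) are checked
  on construction. Images thinner than three nucleus diameters of
  epithelium are rejected.
- **Nuclei.** Dart-thrown with a hard minimum center distance of 2.1 ×
  the mean nucleus radius (≈ 1.05 diameters): neighbours touch — so the
  watershed split is genuinely exercised — but do not interpenetrate,
  which would make per-nucleus pixel truth ill-defined and dense layers
  unsegmentable in principle. Compartment targets are proportional to
  weighted compartment area (basal 2.0, suprabasal 1.0, lamina 0.7) and
  capped by packing. Radii are normal (3.5 ± 0.35 µm, clipped).
- **Dose response.** EdU probability `p0·exp(−α·dose)` for basal nuclei
  only (EdU+ ⇒ p63+ by construction); TUNEL probability
  `min(1, a0 + β·dose)` for all nuclei; foci counts Poisson with rate
  `λ0 + κ·dose`. Defaults: p0 = 0.4, α = 0.15/Gy, a0 = 0.03, β = 0.02/Gy,
  λ0 = 0.5, κ = 0.6/Gy — the observed behaviour behind these is monotone
  trends only, so the functional forms and magnitudes are our choices,
  picked to give clearly resolvable effects at 0/5/10 Gy. Culture-day
  effects (proliferation decay 0.05/day, apoptosis slope 0.01/day), a
  proton effective-dose factor of 1.1, and a DAB-positive cell fraction
  `0.06 + 0.012·dose` extend the same pattern. Per-sample heterogeneity
  multiplies p0, a0, λ0 by log-normal factors (σ = 0.2, mean-corrected).
- **Rendering.** Nuclei are uniform discs convolved with a Gaussian PSF
  (σ = 1.5 px); the blurred edge crosses half-amplitude exactly at the
  disc boundary, so with amplitude 168 over background 6 the 8-bit
  threshold 90 recovers a disc of the planted radius — pixel-level truth
  is therefore exact by calibration. (Pure Gaussian blobs were rejected:
  their tails stack under realistic packing until whole tissue regions
  exceed the threshold.) Foci are diffraction-limited and stay pure
  Gaussians with σ = r/√(2 ln 2), making the FWHM area πr². Noise is
  Poisson shot noise plus Gaussian read noise (σ = 2). The optional TUNEL
  border artifact plants bright non-nuclear blobs within 5 µm of the
  tissue edge using an independent random stream, so toggling it leaves
  every other pixel, channel and draw untouched.
- **IHC.** Hard uniform-density discs (c_H = 0.5 on every nucleus,
  c_DAB = 0.8 on the planted positive subset, radius 0.8 × the nuclear
  radius) pushed through the Beer–Lambert forward model, with optional
  Gaussian OD noise (σ = 0.02). Densities sit far from the 205/210
  cut-points, so the planted positive area is recovered exactly at zero
  noise.
- **Pixel size.** Default 0.25 µm/px (confocal-grade Nyquist sampling of
  sub-µm foci). At 0.5 µm/px sub-µm foci are ~1 px objects whose disjoint
  placement and FWHM sizing are not meaningful, so the finer default is
  load-bearing for the foci readout; the coarser scale remains available
  for tests of the non-foci readouts.

What the generator does **not** emulate: out-of-focus light and chromatic
shift between channels, irregular (non-circular) nucleus shapes, necrotic
regions, staining gradients across a slide, true proton microdosimetry, or
3D structure (no z-stacks). Passing recovery tests therefore demonstrates
the correctness of the measurement logic under the stated image model, not
robustness to every real-world artifact; the pluggable segmentation
backend exists precisely so a learned model can replace the classical one
on real data without touching the quantification layer.

## Validation conditions and problem sizes

The validation harness (tests and `scripts/acceptance.py`) uses: planted
EdU+ fractions {0, 0.25, 0.5, 1.0} accumulated to ≥ 200 basal nuclei per
fraction (measured proliferation within 5 percentage points of realized
truth; observed ≈ 1.6 pp); focus-rate sweeps λ ∈ {0.5, 3, 6} at ≥ 300
nuclei per rate, run with 0.45 µm foci in 4.2 ± 0.2 µm nuclei — the
configuration in which disjoint placement has enough packing capacity that
Poisson(6) draws are not truncated (with the default 0.6 µm foci in
3.5 µm nuclei, small nuclei cap at ~8 disjoint foci and the planted
dispersion itself drops below Poisson); focus radii 0.75 and 1.0 µm for
size recovery (3–4 px, where FWHM discretization error is a few percent);
a 21 × 21 concentration grid over [0, 2]² for the deconvolution round
trip; 1000 null replicates (3 × 20 values) for the type-I error of the
Kruskal–Wallis test; and a full 2-sample × 3-arm × 2-day × 7-FoV
experiment (~170 nuclei per field) for the end-to-end dose-response
direction checks and Dunn significance. These sizes keep the whole
validation run at a few minutes on one CPU while leaving the statistical
checks 2–3 standard deviations of margin.

## Numerical choices and degenerate inputs

- Segmentation self-calibrates the watershed seed separation as 0.8 × the
  median distance-transform peak height (≈ the typical nucleus radius),
  which stays correct even when masks merge into large clumps; an explicit
  pixel value can override it.
- Hole filling fills background regions not connected to the image border
  (flood-fill semantics of the standard procedure).
- Blank images: segmentation returns an empty label map (not an error);
  the tissue mask of a flat image is empty; an empty tissue mask yields an
  empty exclusion band; an empty p63 mask yields an empty analysis region
  plus a QC flag downstream.
- SEM with n = 1 is reported as 0 with a `single-fov` flag; empty groups
  are omitted from aggregation.
- All CSV output uses a fixed float format (`%.6g`) and deterministic row
  order, so identical inputs reproduce identical bytes.
- Every random draw in the generator descends from one root generator via
  fixed-order sub-seeds below 2³¹; the analysis side contains no
  randomness at all.

## Known limitations

- The classical segmentation backend is calibrated for blob-like nuclei on
  dark background; its fixed threshold 90 is tied to the 8-bit rendering
  convention. Real-data use should supply a tuned or learned backend; the
  detection-strictness knob (minimum area) is not equivalent to a neural
  model's probability threshold.
- The pixel-overlap indices are area-weighted, so they are not directly
  comparable to per-cell positive fractions when nucleus size correlates
  with phenotype.
- Focus size is an FWHM area in px²/µm²; other tools may report diameters
  or areas at different relative thresholds, so absolute sizes are
  convention-bound even though dose trends are not.
- Necrotic-sample exclusion is a manifest-level flag, not an image
  classifier; compartment masks for the CD45 readout come from the
  generator (or manual annotation on real data), not from automated
  epithelium/lamina segmentation.
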