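# mucoquant

Quantification of radiation-toxicity readouts in microscopy of ex vivo
cultured oral-mucosa tissue slices.

Irradiated mucosa slices are scored for four complementary readouts of
radiation damage:

- **Proliferation** — EdU incorporation in the p63-positive basal
  progenitor layer, as the pixel-overlap index
  `proliferation = N(EdU ∩ p63) / N(p63) · 100%`
  with EdU segmented by a fixed 8-bit threshold of 90.
- **Apoptosis** — TUNEL-positive nuclei relative to all DAPI nuclei,
  `apoptosis = N(TUNEL ∩ DAPI) / N(DAPI) · 100%`,
  computed only inside the p63-stained cell layer and after cutting the
  first two cell layers at the tissue border (bright TUNEL rims at the
  slice edge are artifacts, not treatment effects).
- **DNA damage** — 53BP1 foci per nucleus and focus size (FWHM area),
  detected per nucleus by top-hat background flattening, a robust
  modal-background threshold, and local-maxima watershed splitting;
  reported as median with 1st/3rd quartiles, with per-sample QC minima
  (≥ 100 nuclei for counts, ≥ 75 foci for sizes).
- **Inflammation (IHC)** — hematoxylin/DAB color deconvolution by
  Beer–Lambert optical-density unmixing, then CD27- or IL-1β-positive area
  relative to total nuclear area using channel thresholds 205 (nuclei) and
  210 (DAB) on the 255 = unstained transmission convention; qualitative
  CD45 presence per tissue compartment.

Treatment arms (e.g. 0/5/10 Gy X-rays, or X-rays vs protons at equal
physical dose, at days 0–3 of culture) are compared with Kruskal–Wallis +
Dunn's multiple comparisons (or Mann–Whitney for two groups); FoV-level
metrics are summarized as mean ± SEM, nucleus-level metrics as median with
quartiles.

Because the patient-derived images behind these protocols are not publicly
deposited, the package ships a first-class synthetic tissue generator: it
renders seeded multichannel fluorescence and RGB IHC images of a stratified
epithelium (basal p63+ layer, lamina propria with immune cells) with
dose-dependent proliferation loss, apoptosis gain, Poisson-distributed
nuclear foci, stain-area increases, and per-sample heterogeneity — together
with an exact per-nucleus ground-truth table, so every analysis step is
validated by recovery of planted truth.

## Worked example

```python
import mucoquant as mq

cfg = mq.ExperimentConfig(samples=["S1", "S2"], days=[3],
                          fovs_per_condition=3, shape=(256, 384),
                          n_nuclei=120)
mq.generate_experiment(cfg, seed=7, out_dir="demo")
report = mq.run_pipeline("demo/manifest.csv", out_dir="demo_report")

s = report.summary
print(s[s["metric"].isin(["proliferation", "apoptosis"])]
      [["dose_gy", "metric", "mean", "sem", "n"]].round(2))
```

prints the per-arm mean ± SEM over the six FoVs of each dose arm:

```
 dose_gy        metric  mean  sem  n
     0.0     apoptosis  6.42 2.16  6
     0.0 proliferation 31.52 4.45  6
     5.0     apoptosis 17.50 2.27  6
     5.0 proliferation 16.66 3.68  6
    10.0     apoptosis 24.77 5.68  6
    10.0 proliferation  3.64 1.42  6
```

— proliferation collapses and apoptosis rises with dose, mirroring the
planted dose response.  The foci readout (median and quartiles over all
nuclei pooled) and its Dunn post hoc:

```
 dose_gy  median  q1  q3   n          groups              p_adjusted stars
     0.0     0.0 0.0 1.0 114          0Gy_xray vs 5Gy_xray      0.0   ****
     5.0     3.0 2.0 4.0 113          0Gy_xray vs 10Gy_xray     0.0   ****
    10.0     5.0 4.0 6.0 112          5Gy_xray vs 10Gy_xray     0.0   ****
```

`run_pipeline` also writes `fov_results.csv`, `foci_per_nucleus.csv`
(violin-plot-ready long format), `summary.csv`, `stats.csv`, `qc.csv` and a
`run_params.json` log; reruns on the same inputs are byte-identical.

The same steps are available from the shell:

```bash
mucoquant generate -c config.yaml --seed 7 -o demo
mucoquant run-all -m demo/manifest.csv -o demo_report
mucoquant segment dapi.tif -o labels.tif --threshold 90
mucoquant stats values.csv --group-col dose
```

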