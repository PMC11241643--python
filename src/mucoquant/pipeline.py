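"""End-to-end orchestration: segmentation → quantification → statistics.

``run_pipeline`` consumes a dataset manifest (one row per field of view,
with paths to the five fluorescence channels and optionally an RGB IHC
image), runs every readout, and emits per-FoV, per-condition and
statistical CSV tables plus a run log with all parameters.  The analysis
itself is fully deterministic, so reruns on the same inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .foci import FociParams, FociSummary, FocusRecord, detect_foci, foci_per_nucleus
from .ihc import color_deconvolve, positive_area_pct
from .overlap import OverlapResult, aggregate_fovs, apoptosis_pct, proliferation_pct
from .segmentation import (SegmentationParams, border_exclusion_zone,
                           median_equivalent_diameter, p63_layer_region,
                           segment_nuclei, threshold_mask, tissue_mask)
from .stats import StatResult, dunns_posthoc, kruskal_wallis, mann_whitney
from .types import (FLUOR_CHANNELS, Condition, MultiChannelImage,
                    UndefinedResultError)

OVERLAP_METRICS = ("proliferation", "apoptosis")
CSV_FLOAT_FORMAT = "%.6g"


@dataclass
class AnalysisConfig:
    """All tunable parameters of the analysis side of the pipeline."""

    seg_threshold: int | None = 90       # fixed 8-bit threshold; None = Otsu
    edu_threshold: int = 90              # EdU channel pixel threshold
    min_nucleus_area_um2: float = 12.0
    smooth_sigma_px: float = 1.0
    tissue_blur_um: float = 4.0
    border_n_layers: int = 2             # cell layers cut at the tissue edge
    p63_closing_um: float = 2.0
    p63_dilation_um: float = 1.5
    foci: FociParams = field(default_factory=FociParams)
    restrict_foci_to_p63: bool = True
    ihc_marker: str = "CD27"
    ihc_nuclei_threshold: int = 205
    ihc_dab_threshold: int = 210
    ihc_min_particle_area_px: int = 4
    min_nuclei_qc: int = 100             # per-sample QC for foci counts
    min_foci_qc: int = 75                # per-sample QC for focus sizes
    dunn_adjustment: str = "bonferroni"
    strict: bool = False                 # raise on QC failures

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "foci" in raw and isinstance(raw["foci"], dict):
            raw["foci"] = FociParams(**raw["foci"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class FovResult:
    """All measurements of one field of view."""

    condition: Condition
    overlap: list[OverlapResult]
    foci_records: list[FocusRecord]
    foci_summary: FociSummary | None
    ihc: object | None            # IHCResult
    qc_flags: list[str]
    n_dapi_nuclei: int


def analyze_fov(
    images: MultiChannelImage,
    config: AnalysisConfig | None = None,
    condition: Condition | None = None,
    ihc_rgb: np.ndarray | None = None,
) -> FovResult:
    """Run every readout on one co-registered field of view."""
    config = config or AnalysisConfig()
    ps = images.pixel_size_um
    min_area_px = max(4, int(round(config.min_nucleus_area_um2 / ps ** 2)))
    segp = SegmentationParams(threshold=config.seg_threshold,
                              smooth_sigma_px=config.smooth_sigma_px,
                              min_area_px=min_area_px)
    qc: list[str] = []
    overlap: list[OverlapResult] = []

    dapi_labels = segment_nuclei(images["dapi"], segp)
    n_dapi = int(dapi_labels.max(initial=0))
    if n_dapi == 0:
        qc.append("no-dapi-nuclei")
    tissue = tissue_mask(images["dapi"],
                         blur_sigma_px=config.tissue_blur_um / ps)
    med_diam = median_equivalent_diameter(dapi_labels)
    if med_diam <= 0:
        med_diam = 2.0 * np.sqrt(min_area_px / np.pi)
    band = border_exclusion_zone(tissue, med_diam, config.border_n_layers)

    p63_labels = segment_nuclei(images["p63"], segp)
    p63_mask = p63_labels > 0
    edu_mask = threshold_mask(images["edu"], config.edu_threshold, "above")
    try:
        overlap.append(proliferation_pct(edu_mask, p63_mask, condition))
    except UndefinedResultError as err:
        qc.append(err.qc_flag)

    region = p63_layer_region(
        p63_mask,
        dilation_radius_px=int(round(config.p63_dilation_um / ps)),
        closing_radius_px=int(round(config.p63_closing_um / ps)),
    )
    if not region.any():
        qc.append("empty-p63-layer-region")
    tunel_labels = segment_nuclei(images["tunel"], segp)
    try:
        overlap.append(apoptosis_pct(tunel_labels, dapi_labels, region, band,
                                     condition))
    except UndefinedResultError as err:
        qc.append(err.qc_flag)

    foci_records: list[FocusRecord] = []
    foci_summary = None
    if "53bp1" in images.channels:
        foci_records = detect_foci(images["53bp1"], dapi_labels, config.foci,
                                   ps, condition)
        foci_summary = foci_per_nucleus(
            foci_records, dapi_labels, p63_mask,
            restrict_p63=config.restrict_foci_to_p63,
            pixel_size_um=ps, condition=condition,
        )
        qc.extend(foci_summary.qc_flags)

    ihc_result = None
    if ihc_rgb is not None:
        channels = color_deconvolve(ihc_rgb)
        try:
            ihc_result = positive_area_pct(
                channels, marker=config.ihc_marker,
                nuclei_threshold=config.ihc_nuclei_threshold,
                dab_threshold=config.ihc_dab_threshold,
                min_particle_area_px=config.ihc_min_particle_area_px,
                condition=condition,
            )
        except UndefinedResultError as err:
            qc.append(err.qc_flag)

    return FovResult(condition=condition, overlap=overlap,
                     foci_records=foci_records, foci_summary=foci_summary,
                     ihc=ihc_result, qc_flags=qc, n_dapi_nuclei=n_dapi)


@dataclass
class PipelineReport:
    """Bundle of the pipeline's output tables."""

    fov_results: pd.DataFrame       # per (FoV, metric) values
    foci_per_nucleus: pd.DataFrame  # violin-ready long format
    foci_records: pd.DataFrame      # per detected focus
    summary: pd.DataFrame           # per-condition aggregates
    stats: pd.DataFrame             # hypothesis tests
    qc: pd.DataFrame                # per sample/arm QC
    out_dir: Path | None = None


def _load_fov(row: pd.Series, root: Path) -> tuple[MultiChannelImage, np.ndarray | None]:
    channels = {ch: tifffile.imread(root / row[ch]) for ch in FLUOR_CHANNELS
                if ch in row and isinstance(row[ch], str)}
    mci = MultiChannelImage(channels=channels,
                            pixel_size_um=float(row["pixel_size_um"]))
    ihc = None
    if "ihc" in row and isinstance(row.get("ihc"), str):
        ihc = tifffile.imread(root / row["ihc"])
    return mci, ihc


def _stats_for_metric(df: pd.DataFrame, metric: str, value_col: str,
                      adjustment: str) -> list[dict]:
    """KW + Dunn (>=3 arms) or Mann–Whitney (2 arms) per timepoint."""
    rows: list[dict] = []
    for day, day_df in df.groupby("day", sort=True):
        arms = sorted(day_df.groupby(["dose_gy", "modality"], sort=True).groups)
        groups = [day_df[(day_df["dose_gy"] == d) & (day_df["modality"] == m)]
                  [value_col].to_numpy(float) for d, m in arms]
        labels = [f"{d:g}Gy_{m}" for d, m in arms]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2 or sum(len(g) for g in groups) < 3:
            continue
        results: list[StatResult] = []
        if len(groups) >= 3:
            results.append(kruskal_wallis(groups, labels))
            results.extend(dunns_posthoc(groups, adjustment=adjustment,
                                         labels=labels))
        else:
            results.append(mann_whitney(groups[0], groups[1], labels[:2]))
        for r in results:
            rows.append({"day": day, "metric": metric, **r.as_row()})
    return rows


def run_pipeline(
    manifest: pd.DataFrame | str | Path,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Analyze every field of view in a manifest and aggregate the readouts.

    The manifest needs columns sample, dose_gy, modality, day, fov,
    pixel_size_um and per-channel file paths (relative to the manifest's
    directory).  QC failures are reported, not fatal, unless
    ``config.strict`` is set.
    """
    config = config or AnalysisConfig()
    if isinstance(manifest, (str, Path)):
        root = Path(manifest).parent
        manifest = pd.read_csv(manifest)
    else:
        root = Path(".")

    overlap_rows, nucleus_rows, focus_rows, ihc_rows, qc_rows = [], [], [], [], []
    pooled_counts: dict[tuple, list] = {}
    for _, row in manifest.iterrows():
        cond = Condition(sample=str(row["sample"]), dose_gy=float(row["dose_gy"]),
                         modality=str(row["modality"]), day=int(row["day"]),
                         fov=int(row["fov"]))
        mci, ihc_rgb = _load_fov(row, root)
        fr = analyze_fov(mci, config, cond, ihc_rgb)
        for res in fr.overlap:
            overlap_rows.append(res.as_row())
        if fr.foci_summary is not None:
            for count in fr.foci_summary.counts:
                nucleus_rows.append({**cond.as_dict(), "value": int(count),
                                     "metric": "foci_count"})
            for rec in fr.foci_records:
                focus_rows.append(rec.as_row())
            key = (cond.sample, cond.dose_gy, cond.modality, cond.day)
            pooled_counts.setdefault(key, [0, 0])
            pooled_counts[key][0] += fr.foci_summary.n_nuclei
            pooled_counts[key][1] += fr.foci_summary.n_foci
        if fr.ihc is not None:
            ihc_rows.append({**cond.as_dict(), "metric": "ihc_area",
                             "marker": fr.ihc.marker, "pct": fr.ihc.pct,
                             "positive_area_px": fr.ihc.positive_area_px,
                             "nuclear_area_px": fr.ihc.nuclear_area_px})
        if fr.qc_flags:
            qc_rows.append({**cond.as_dict(), "scope": "fov",
                            "flags": ";".join(sorted(set(fr.qc_flags))),
                            "pass": False})

    fov_df = pd.DataFrame(overlap_rows)
    nuc_df = pd.DataFrame(nucleus_rows)
    focus_df = pd.DataFrame(focus_rows)
    ihc_df = pd.DataFrame(ihc_rows)

    # per-sample foci QC, pooled over FoVs (the minima apply per sample)
    for (sample, dose, mod, day), (n_nuc, n_foci) in sorted(pooled_counts.items()):
        qc_rows.append({
            "sample": sample, "dose_gy": dose, "modality": mod, "day": day,
            "fov": 0, "scope": "sample-foci",
            "flags": (("low-nuclei;" if n_nuc < config.min_nuclei_qc else "")
                      + ("low-foci" if n_foci < config.min_foci_qc else "")
                      ).strip(";"),
            "pass": n_nuc >= config.min_nuclei_qc and n_foci >= config.min_foci_qc,
        })
    qc_df = pd.DataFrame(qc_rows)

    # per-condition summaries
    summaries = []
    if not fov_df.empty:
        s = aggregate_fovs(fov_df)
        s.insert(0, "summary_mode", "mean_sem")
        summaries.append(s)
    if not ihc_df.empty:
        s = aggregate_fovs(ihc_df)
        s.insert(0, "summary_mode", "mean_sem")
        summaries.append(s)
    if not nuc_df.empty:
        rows = []
        for (dose, mod, day), grp in nuc_df.groupby(
                ["dose_gy", "modality", "day"], sort=True):
            q1, med, q3 = np.percentile(grp["value"], [25, 50, 75])
            rows.append({"summary_mode": "median_quartiles", "dose_gy": dose,
                         "modality": mod, "day": day, "metric": "foci_count",
                         "median": float(med), "q1": float(q1), "q3": float(q3),
                         "n": len(grp)})
        summaries.append(pd.DataFrame(rows))
    if not focus_df.empty and "area_um2" in focus_df:
        rows = []
        for (dose, mod, day), grp in focus_df.groupby(
                ["dose_gy", "modality", "day"], sort=True):
            vals = grp["area_px"].to_numpy(float)
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({"summary_mode": "median_quartiles", "dose_gy": dose,
                         "modality": mod, "day": day, "metric": "foci_size",
                         "median": float(med), "q1": float(q1), "q3": float(q3),
                         "n": len(grp)})
        summaries.append(pd.DataFrame(rows))
    summary_df = (pd.concat(summaries, ignore_index=True)
                  if summaries else pd.DataFrame())

    # statistics
    stat_rows: list[dict] = []
    if not fov_df.empty:
        for metric in OVERLAP_METRICS:
            sub = fov_df[fov_df["metric"] == metric]
            if not sub.empty:
                stat_rows += _stats_for_metric(sub, metric, "pct",
                                               config.dunn_adjustment)
    if not ihc_df.empty:
        stat_rows += _stats_for_metric(ihc_df, "ihc_area", "pct",
                                       config.dunn_adjustment)
    if not nuc_df.empty:
        stat_rows += _stats_for_metric(nuc_df, "foci_count", "value",
                                       config.dunn_adjustment)
    if not focus_df.empty:
        stat_rows += _stats_for_metric(focus_df, "foci_size", "area_px",
                                       config.dunn_adjustment)
    stats_df = pd.DataFrame(stat_rows)

    report = PipelineReport(
        fov_results=pd.concat([fov_df, ihc_df], ignore_index=True)
        if not ihc_df.empty else fov_df,
        foci_per_nucleus=nuc_df, foci_records=focus_df,
        summary=summary_df, stats=stats_df, qc=qc_df,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.out_dir = out
        for name, df in (("fov_results", report.fov_results),
                         ("foci_per_nucleus", nuc_df),
                         ("foci_records", focus_df),
                         ("summary", summary_df),
                         ("stats", stats_df),
                         ("qc", qc_df)):
            df.to_csv(out / f"{name}.csv", index=False,
                      float_format=CSV_FLOAT_FORMAT)
        (out / "run_params.json").write_text(json.dumps(
            {"mucoquant_version": __version__, "config": config.to_dict()},
            indent=2, default=str))
    if config.strict and not qc_df.empty and not qc_df["pass"].all():
        raise RuntimeError("QC failures under --strict; see qc table")
    return report
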