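"""Pixel-overlap indices: proliferation % and apoptosis %.

Both indices are pure pixel-count ratios:

    proliferation = N(EdU ∩ p63) / N(p63) * 100%
    apoptosis     = N(TUNEL ∩ DAPI) / N(DAPI) * 100%

with the apoptosis inputs first restricted to the p63-stained cell layer
minus the tissue-border exclusion band (the restriction is applied before
either count, so border artifacts cannot enter numerator or denominator).
An optional nucleus-count mode exists for exploration but is not the
published pixel-based definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import Condition, UndefinedResultError, as_bool_mask, check_same_shape


@dataclass
class OverlapResult:
    """One pixel-overlap measurement for one field of view."""

    metric: str                  # "proliferation" | "apoptosis"
    numerator_px: int
    denominator_px: int
    pct: float
    condition: Condition | None = None
    qc_flags: tuple[str, ...] = ()

    def as_row(self) -> dict:
        row = self.condition.as_dict() if self.condition else {}
        row.update(metric=self.metric, numerator_px=self.numerator_px,
                   denominator_px=self.denominator_px, pct=self.pct,
                   qc_flags=";".join(self.qc_flags))
        return row


def proliferation_pct(
    edu_mask: np.ndarray,
    p63_mask: np.ndarray,
    condition: Condition | None = None,
    *,
    low_denominator_px: int | None = None,
) -> OverlapResult:
    """Percentage of p63-positive pixels that are also EdU-positive.

    Raises :class:`UndefinedResultError` when no p63-positive pixels exist
    (no healthy epithelium in the field — such samples are excluded).
    """
    edu_mask = as_bool_mask(edu_mask, "edu_mask")
    p63_mask = as_bool_mask(p63_mask, "p63_mask")
    check_same_shape(edu_mask, p63_mask)
    den = int(p63_mask.sum())
    if den == 0:
        raise UndefinedResultError(
            "no p63-positive pixels: proliferation undefined",
            qc_flag="empty-p63-region",
        )
    num = int((edu_mask & p63_mask).sum())
    flags = ()
    if low_denominator_px is not None and den < low_denominator_px:
        flags = ("low-p63-area",)
    return OverlapResult("proliferation", num, den, 100.0 * num / den,
                         condition, flags)


def apoptosis_pct(
    tunel_labels: np.ndarray,
    dapi_labels: np.ndarray,
    analysis_region: np.ndarray,
    exclusion_band: np.ndarray,
    condition: Condition | None = None,
) -> OverlapResult:
    """Percentage of DAPI-nucleus pixels that are also TUNEL-positive.

    Both label maps are restricted to ``analysis_region`` minus
    ``exclusion_band`` and rasterized to positive-pixel masks before
    counting, so the index is invariant to label numbering and to anything
    planted inside the excluded border band.
    """
    analysis_region = as_bool_mask(analysis_region, "analysis_region")
    exclusion_band = as_bool_mask(exclusion_band, "exclusion_band")
    check_same_shape(tunel_labels, dapi_labels, analysis_region, exclusion_band)
    flags: tuple[str, ...] = ()
    if not analysis_region.any():
        flags = ("empty-region",)
    region = analysis_region & ~exclusion_band
    dapi = (np.asarray(dapi_labels) > 0) & region
    den = int(dapi.sum())
    if den == 0:
        raise UndefinedResultError(
            "no DAPI-nucleus pixels inside the analysis region",
            qc_flag="empty-dapi-region" if not flags else flags[0],
        )
    num = int(((np.asarray(tunel_labels) > 0) & dapi).sum())
    return OverlapResult("apoptosis", num, den, 100.0 * num / den,
                         condition, flags)


def aggregate_fovs(
    results: Iterable[OverlapResult] | pd.DataFrame,
    by: Sequence[str] = ("dose_gy", "modality", "day"),
    value: str = "pct",
) -> pd.DataFrame:
    """Per-group mean and SEM (sd/sqrt(n), ddof=1) over FoV-level values.

    Groups with a single FoV report SEM 0 with an ``n=1`` QC flag; empty
    groups simply do not appear.  Output order is deterministic (sorted by
    the grouping keys), independent of input order.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        df = pd.DataFrame([r.as_row() for r in results])
    if df.empty:
        return pd.DataFrame(columns=[*by, "metric", "mean", "sem", "n", "qc"])
    group_cols = [*by, "metric"] if "metric" in df.columns else list(by)
    rows = []
    for key, grp in df.groupby(group_cols, sort=True):
        vals = grp[value].to_numpy(dtype=float)
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append({
            **dict(zip(group_cols, key if isinstance(key, tuple) else (key,))),
            "mean": float(np.mean(vals)), "sem": sem, "n": n,
            "qc": "single-fov" if n == 1 else "",
        })
    return pd.DataFrame(rows)
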