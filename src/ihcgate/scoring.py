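"""H-score computation, category bands, per-group summaries and tumor-to-background ratios.

The H-score of an annotated tissue region is a weighted percentage of
DAB-positive cells,

    H = 1 * (% cells 1+) + 2 * (% cells 2+) + 3 * (% cells 3+),

ranging 0-300 and weighting high-intensity staining more heavily.  Group
summaries are medians (plus min/max) of per-section H-scores, where a
section's value is the arithmetic mean of its same-tissue-type annotation
H-scores.  The tumor-to-background ratio (TBR) of a lesion group is its
median H-score divided by the healthy-tissue median; TBR > 2 is the
conventional favorability bound for fluorescence-guided surgery tracers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationScore",
    "GroupSummary",
    "TBRRecord",
    "UndefinedRatioError",
    "hscore",
    "categorize",
    "score_annotation",
    "score_cells",
    "summarize_sections",
    "tbr",
    "round_half_away",
    "summary_table",
]

#: category bands are half-open on the left edge; the top band closes at 300.
CATEGORY_BANDS = ((0.0, 50.0, "low"), (50.0, 250.0, "medium"), (250.0, 300.0, "high"))


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a TBR is requested against a zero healthy median."""

    def __init__(self, group_median: float, healthy_median: float):
        super().__init__(
            f"TBR undefined: healthy median is {healthy_median} "
            f"(lesion median {group_median})"
        )
        self.group_median = group_median
        self.healthy_median = healthy_median


@dataclass(frozen=True)
class AnnotationScore:
    annotation_id: str
    tissue_type: str
    marker_id: str
    n_cells: int
    pct_class: tuple[float, float, float, float]
    h_score: float
    category: str

    def __post_init__(self):
        if abs(sum(self.pct_class) - 100.0) > 1e-6:
            raise ValueError("class percentages must sum to 100")


@dataclass(frozen=True)
class GroupSummary:
    marker_id: str
    tissue_group: str
    n_sections: int
    median_h: float
    min_h: float
    max_h: float

    def __post_init__(self):
        if self.n_sections <= 0:
            raise ValueError("empty group")
        if not self.min_h <= self.median_h <= self.max_h:
            raise ValueError("min <= median <= max violated")


@dataclass(frozen=True)
class TBRRecord:
    marker_id: str
    tissue_group: str
    tbr: float
    tbr_rounded: float
    favorable: bool
    inverse: bool


def hscore(pct_class: Sequence[float]) -> float:
    """Weighted H-score from the four class percentages (0, 1+, 2+, 3+).

    Percentages must be non-negative and sum to 100 (tolerance 1e-6).
    """
    p = [float(x) for x in pct_class]
    if len(p) != 4:
        raise ValueError("expected four class percentages")
    if any(x < 0 for x in p):
        raise ValueError("negative class percentage")
    if abs(sum(p) - 100.0) > 1e-6:
        raise ValueError(f"class percentages sum to {sum(p)}, not 100")
    return 1.0 * p[1] + 2.0 * p[2] + 3.0 * p[3]


def categorize(h: float) -> str:
    """Map an H-score to its staining category: low / medium / high."""
    if not 0.0 <= h <= 300.0:
        raise ValueError(f"H-score {h} outside [0, 300]")
    for lo, hi, label in CATEGORY_BANDS:
        if lo <= h < hi:
            return label
    return "high"  # h == 300


def score_annotation(
    classes: Sequence[int] | np.ndarray,
    annotation_id: str = "",
    tissue_type: str = "",
    marker_id: str = "",
) -> AnnotationScore:
    """Score one annotation from its per-cell intensity classes (integers 0-3)."""
    arr = np.asarray(classes, dtype=int)
    if arr.size == 0:
        raise ValueError("annotation has no cells")
    if arr.min() < 0 or arr.max() > 3:
        raise ValueError("intensity classes must lie in 0..3")
    counts = np.bincount(arr, minlength=4)
    pct = tuple(100.0 * c / arr.size for c in counts)
    h = hscore(pct)
    return AnnotationScore(
        annotation_id=annotation_id,
        tissue_type=tissue_type,
        marker_id=marker_id,
        n_cells=int(arr.size),
        pct_class=pct,
        h_score=h,
        category=categorize(h),
    )


def score_cells(cells: pd.DataFrame, marker_id: str = "") -> pd.DataFrame:
    """Per-annotation scores from a cell table.

    ``cells`` needs columns ``annotation_id`` and ``intensity_class``; an
    optional ``tissue_type`` column is carried through.  Returns one row per
    annotation with class percentages, H-score and category.
    """
    required = {"annotation_id", "intensity_class"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    rows = []
    for ann_id, grp in cells.groupby("annotation_id", sort=True):
        tissue = ""
        if "tissue_type" in grp.columns and len(grp):
            tissue = str(grp["tissue_type"].iloc[0])
        s = score_annotation(
            grp["intensity_class"].to_numpy(),
            annotation_id=str(ann_id),
            tissue_type=tissue,
            marker_id=marker_id,
        )
        rows.append(
            {
                "annotation_id": s.annotation_id,
                "tissue_type": s.tissue_type,
                "marker": s.marker_id,
                "n_cells": s.n_cells,
                "pct_0": s.pct_class[0],
                "pct_1": s.pct_class[1],
                "pct_2": s.pct_class[2],
                "pct_3": s.pct_class[3],
                "h_score": s.h_score,
                "category": s.category,
            }
        )
    return pd.DataFrame(rows)


def summarize_sections(
    section_scores: Mapping[str, Sequence[float]] | Iterable[tuple[str, Sequence[float]]],
    tissue_group: str,
    marker_id: str = "",
) -> GroupSummary:
    """Median/min/max of per-section H-scores for one tissue group.

    ``section_scores`` maps section (patient) id to the H-scores of that
    section's annotations *of the group's own tissue type*; a section's value
    is their arithmetic mean.  The median of an even section count is the
    midpoint of the two central values.
    """
    items = dict(section_scores)
    if not items:
        raise ValueError(f"no sections for group {tissue_group!r}")
    per_section = []
    for sec, scores in items.items():
        vals = [float(v) for v in scores]
        if not vals:
            raise ValueError(f"section {sec!r} contributes no annotations")
        per_section.append(sum(vals) / len(vals))
    return GroupSummary(
        marker_id=marker_id,
        tissue_group=tissue_group,
        n_sections=len(per_section),
        median_h=float(np.median(per_section)),
        min_h=float(min(per_section)),
        max_h=float(max(per_section)),
    )


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used for reported TBRs)."""
    factor = 10**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def tbr(group: GroupSummary, healthy: GroupSummary) -> TBRRecord:
    """Tumor-to-background ratio of a lesion group against the healthy group.

    Computed on unrounded medians; ``tbr_rounded`` is the one-decimal
    half-away-from-zero value used for reporting.  ``favorable`` (> 2) and
    ``inverse`` (< 1) are derived from the unrounded ratio.
    """
    if healthy.median_h <= 0:
        raise UndefinedRatioError(group.median_h, healthy.median_h)
    ratio = group.median_h / healthy.median_h
    return TBRRecord(
        marker_id=group.marker_id,
        tissue_group=group.tissue_group,
        tbr=ratio,
        tbr_rounded=round_half_away(ratio, 1),
        favorable=ratio > 2.0,
        inverse=ratio < 1.0,
    )


def summary_table(
    summaries: Sequence[GroupSummary], healthy_group: str = "healthy"
) -> pd.DataFrame:
    """Assemble a report table: one row per (marker, group) with TBR columns.

    The healthy row of each marker carries NaN TBRs (it is the background).
    """
    by_marker: dict[str, dict[str, GroupSummary]] = {}
    for s in summaries:
        by_marker.setdefault(s.marker_id, {})[s.tissue_group] = s
    rows = []
    for marker, groups in by_marker.items():
        healthy = groups.get(healthy_group)
        for group_name, s in groups.items():
            row = {
                "marker": marker,
                "tissue_group": group_name,
                "n": s.n_sections,
                "median_h": s.median_h,
                "min_h": s.min_h,
                "max_h": s.max_h,
                "tbr": float("nan"),
                "tbr_rounded": float("nan"),
                "favorable": False,
                "inverse": False,
            }
            if group_name != healthy_group and healthy is not None:
                rec = tbr(s, healthy)
                row.update(
                    tbr=rec.tbr,
                    tbr_rounded=rec.tbr_rounded,
                    favorable=rec.favorable,
                    inverse=rec.inverse,
                )
            rows.append(row)
    return pd.DataFrame(rows)
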