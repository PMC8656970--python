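"""Four-criterion fluorescence-guided-surgery target gate and per-patient
favorability classification.

A marker qualifies as an FGS tracer target when, across the evaluated lesion
groups, all of the following hold:

1. its lesion median H-score is at least ``tbr_min`` (default 2) times the
   healthy-tissue median AND the stromal median (healthy-only, with an
   explicit downgrade flag, when no stromal summary exists);
2. its lesion median H-score is at least ``hscore_min`` (default 25);
3. its expression is homogeneous throughout the tumor (evaluated on the
   malignant groups, where "the tumor" lives; precursor lesions are
   physiologically basal-restricted even for good targets);
4. it is expressed on the cell membrane (where a tracer can bind).

Criteria 3-4 are qualitative in origin; the gate accepts curated
``MarkerMetadata`` (the default) and, alternatively, a quantitative
surrogate computed from cell positions (``homogeneity_score``): positive
fraction, a join-count clustering z-score on the k-nearest-neighbor cell
graph, and a basal-depth restriction index.

The per-patient favorability rule compares each lesion tissue's mean
H-score on a section against the same section's healthy tissue: green if
every present lesion ratio exceeds 2, orange if the malignant ratio is <= 2
but the premalignant ratio exceeds 2, red if every present ratio is <= 1;
ratios stranded in (1, 2] without qualifying as orange are reported as
"unfavorable" and counted with red in cohort fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .scoring import GroupSummary, TBRRecord

__all__ = [
    "GateConfig",
    "MarkerMetadata",
    "CriterionResult",
    "GateVerdict",
    "PatientProfile",
    "PatientClass",
    "CohortFraction",
    "evaluate_gate",
    "homogeneity_score",
    "HomogeneityResult",
    "classify_patient",
    "cohort_fraction",
]

LOCALIZATIONS = ("membrane", "cytoplasmic", "mixed", "none_observed")
PATTERN_LABELS = ("homogeneous", "patchy", "restricted", "heterogeneous", "absent")

MALIGNANT_GROUPS = ("VSCC_HPV_independent", "VSCC_HPV_dependent")
LESION_GROUPS = ("dVIN", "VSCC_HPV_independent", "HSIL", "VSCC_HPV_dependent")


@dataclass(frozen=True)
class GateConfig:
    tbr_min: float = 2.0
    hscore_min: float = 25.0
    positive_fraction_min: float = 0.05
    clustering_z_max: float = 3.0
    depth_restriction_max: float = 0.5
    favorable_ratio: float = 2.0  # patient-level TBR bound

    def __post_init__(self):
        if self.tbr_min <= 1:
            raise ValueError("tbr_min must exceed 1")
        if self.hscore_min <= 0:
            raise ValueError("hscore_min must be positive")


@dataclass(frozen=True)
class MarkerMetadata:
    marker_id: str
    localization: str
    pattern_by_group: Mapping[str, str]

    def __post_init__(self):
        if self.localization not in LOCALIZATIONS:
            raise ValueError(f"unknown localization {self.localization!r}")
        for g, p in self.pattern_by_group.items():
            if p not in PATTERN_LABELS:
                raise ValueError(f"unknown pattern label {p!r} for group {g}")


@dataclass(frozen=True)
class CriterionResult:
    passed: bool
    evidence: Mapping[str, float | str | bool]


@dataclass(frozen=True)
class GateVerdict:
    marker_id: str
    c1_tbr: Mapping[str, CriterionResult]
    c2_median: Mapping[str, CriterionResult]
    c3_homogeneity: Mapping[str, CriterionResult]
    c4_localization: CriterionResult
    candidate: bool
    stroma_available: bool
    per_group_candidate: Mapping[str, bool]

    def failed_criteria(self) -> list[str]:
        out = []
        if not all(r.passed for r in self.c1_tbr.values()):
            out.append("c1")
        if not all(r.passed for r in self.c2_median.values()):
            out.append("c2")
        if not all(r.passed for r in self.c3_homogeneity.values()):
            out.append("c3")
        if not self.c4_localization.passed:
            out.append("c4")
        return out

    def to_dict(self) -> dict:
        def crit(d: Mapping[str, CriterionResult]):
            return {
                g: {"pass": r.passed, "evidence": dict(r.evidence)}
                for g, r in d.items()
            }

        return {
            "marker": self.marker_id,
            "criteria": {
                "c1": crit(self.c1_tbr),
                "c2": crit(self.c2_median),
                "c3": crit(self.c3_homogeneity),
                "c4": {
                    "pass": self.c4_localization.passed,
                    "evidence": dict(self.c4_localization.evidence),
                },
            },
            "candidate": self.candidate,
            "stroma_available": self.stroma_available,
        }


def evaluate_gate(
    summaries: Mapping[str, GroupSummary],
    meta: MarkerMetadata,
    cfg: GateConfig = GateConfig(),
    lesion_groups: Sequence[str] = LESION_GROUPS,
    malignant_groups: Sequence[str] = MALIGNANT_GROUPS,
    stromal_summary: GroupSummary | None = None,
) -> GateVerdict:
    """Apply the four-criterion gate to one marker.

    ``summaries`` maps tissue group (including ``healthy``) to its
    ``GroupSummary``.  ``candidate`` is the strict-mode conjunction: criteria
    1-2 over every lesion group, criterion 3 over the malignant groups,
    criterion 4 marker-wide.
    """
    if "healthy" not in summaries:
        raise KeyError("healthy summary required")
    missing = [g for g in lesion_groups if g not in summaries]
    if missing:
        raise KeyError(f"missing lesion summaries: {missing}")
    healthy_med = summaries["healthy"].median_h
    stroma_med = stromal_summary.median_h if stromal_summary is not None else None

    c1: dict[str, CriterionResult] = {}
    c2: dict[str, CriterionResult] = {}
    for g in lesion_groups:
        med = summaries[g].median_h
        ok1 = med >= cfg.tbr_min * healthy_med
        evidence = {
            "median": med,
            "healthy_median": healthy_med,
            "tbr_vs_healthy": med / healthy_med if healthy_med > 0 else float("inf"),
        }
        if stroma_med is not None:
            ok1 = ok1 and med >= cfg.tbr_min * stroma_med
            evidence["stroma_median"] = stroma_med
        else:
            evidence["healthy_only"] = True
        c1[g] = CriterionResult(bool(ok1), evidence)
        c2[g] = CriterionResult(
            bool(med >= cfg.hscore_min), {"median": med, "min_required": cfg.hscore_min}
        )

    c3: dict[str, CriterionResult] = {}
    for g in malignant_groups:
        pattern = meta.pattern_by_group.get(g)
        if pattern is None:
            raise KeyError(f"no pattern label for malignant group {g}")
        c3[g] = CriterionResult(pattern == "homogeneous", {"pattern": pattern})
    c4 = CriterionResult(
        meta.localization == "membrane", {"localization": meta.localization}
    )

    per_group = {
        g: (
            c1[g].passed
            and c2[g].passed
            and (c3[g].passed if g in c3 else True)
            and c4.passed
        )
        for g in lesion_groups
    }
    candidate = (
        all(r.passed for r in c1.values())
        and all(r.passed for r in c2.values())
        and all(r.passed for r in c3.values())
        and c4.passed
    )
    return GateVerdict(
        marker_id=meta.marker_id,
        c1_tbr=c1,
        c2_median=c2,
        c3_homogeneity=c3,
        c4_localization=c4,
        candidate=candidate,
        stroma_available=stroma_med is not None,
        per_group_candidate=per_group,
    )


# ---------------------------------------------------------------------------
# quantitative pattern surrogate


@dataclass(frozen=True)
class HomogeneityResult:
    positive_fraction: float
    clustering_index: float  # join-count z-score
    depth_restriction_index: float
    label: str


def homogeneity_score(
    cells: pd.DataFrame,
    cfg: GateConfig = GateConfig(),
    k: int = 6,
    n_permutations: int = 199,
    seed: int = 0,
) -> HomogeneityResult:
    """Quantitative spatial-pattern surrogate for one annotation.

    ``cells`` needs columns ``x_px``, ``y_px``, ``intensity_class`` and
    optionally ``depth`` (normalized distance from the basal axis).  The
    clustering index is the z-score of the positive-positive join count on
    the k-nearest-neighbor graph against a label-permutation null; the depth
    restriction index is the ratio of the median depth of positive cells to
    the median depth of all cells.
    """
    n = len(cells)
    if n < 50:
        raise ValueError(f"need >= 50 cells, got {n}")
    pos = (cells["intensity_class"].to_numpy() >= 1).astype(int)
    pf = float(pos.mean())

    z = 0.0
    if 0 < pos.sum() < n:
        xy = cells[["x_px", "y_px"]].to_numpy(float)
        tree = cKDTree(xy)
        _, nbr = tree.query(xy, k=k + 1)
        nbr = nbr[:, 1:]  # drop self

        def joins(labels: np.ndarray) -> int:
            return int((labels[:, None] * labels[nbr]).sum())

        obs = joins(pos)
        rng = np.random.default_rng(seed)
        null = np.array(
            [joins(rng.permutation(pos)) for _ in range(n_permutations)], float
        )
        sd = null.std()
        z = float((obs - null.mean()) / sd) if sd > 0 else 0.0

    dri = 1.0
    if "depth" in cells.columns and pos.sum() > 0:
        depths = cells["depth"].to_numpy(float)
        med_all = float(np.median(depths))
        if med_all > 0:
            dri = float(np.median(depths[pos == 1])) / med_all

    if pf < cfg.positive_fraction_min:
        label = "absent"
    elif dri < cfg.depth_restriction_max:
        label = "restricted"
    elif z > cfg.clustering_z_max:
        label = "patchy"
    else:
        label = "homogeneous"
    return HomogeneityResult(pf, z, dri, label)


# ---------------------------------------------------------------------------
# per-patient favorability


@dataclass(frozen=True)
class PatientProfile:
    """Mean H-score per tissue role present on one patient's section."""

    patient_id: str
    hpv_status: str
    mean_h: Mapping[str, float]  # keys among {healthy, premalignant, malignant}


@dataclass(frozen=True)
class PatientClass:
    patient_id: str
    hpv_status: str
    label: str  # green | orange | red | unfavorable | unclassifiable
    tbr_malignant: float | None
    tbr_premalignant: float | None


def classify_patient(
    profile: PatientProfile, cfg: GateConfig = GateConfig()
) -> PatientClass:
    """Green/orange/red favorability of one patient's section."""
    healthy = profile.mean_h.get("healthy")
    if healthy is None or healthy <= 0:
        raise ValueError("healthy mean H-score required and positive")
    r_mal = (
        profile.mean_h["malignant"] / healthy if "malignant" in profile.mean_h else None
    )
    r_pre = (
        profile.mean_h["premalignant"] / healthy
        if "premalignant" in profile.mean_h
        else None
    )
    present = [r for r in (r_mal, r_pre) if r is not None]
    bound = cfg.favorable_ratio
    if not present:
        label = "unclassifiable"
    elif all(r > bound for r in present):
        label = "green"
    elif r_mal is not None and r_mal <= bound and r_pre is not None and r_pre > bound:
        label = "orange"
    elif all(r <= 1.0 for r in present):
        label = "red"
    else:
        label = "unfavorable"
    return PatientClass(
        patient_id=profile.patient_id,
        hpv_status=profile.hpv_status,
        label=label,
        tbr_malignant=r_mal,
        tbr_premalignant=r_pre,
    )


@dataclass(frozen=True)
class CohortFraction:
    stratum: str
    n_green: int
    n_classifiable: int
    percent_green: float
    percent_display: int


def cohort_fraction(classes: Sequence[PatientClass], stratum: str) -> CohortFraction:
    """Percentage of green-classified patients in one HPV stratum."""
    pool = [
        c for c in classes if c.hpv_status == stratum and c.label != "unclassifiable"
    ]
    if not pool:
        raise ValueError(f"no classifiable patients in stratum {stratum!r}")
    n_green = sum(1 for c in pool if c.label == "green")
    pct = 100.0 * n_green / len(pool)
    return CohortFraction(
        stratum=stratum,
        n_green=n_green,
        n_classifiable=len(pool),
        percent_green=pct,
        percent_display=int(round(pct)),
    )
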