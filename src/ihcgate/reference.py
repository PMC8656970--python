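"""Published vulvar-cohort reference values used for calibration and validation.

Nine membrane-marker candidates for fluorescence-guided surgery (FGS) of
vulvar squamous cell carcinoma were scored by digital image analysis on a
cohort of 15 healthy, 10 dVIN, 16 HPV-independent VSCC, 15 HSIL and 13
HPV-dependent VSCC tissue sections.  This module records, as plain data:

* the reported per-group median/min/max H-scores and the printed
  one-decimal TBR column (``TABLE2``);
* the narrative staining metadata (subcellular localization and spatial
  pattern per group) that feeds the qualitative gate criteria
  (``MARKER_METADATA``);
* the per-patient favorability counts of the individual-section analysis
  (``FIG3_COUNTS``) and a profile builder reproducing them.

Four cells of the printed TBR column are arithmetically inconsistent with
the printed medians they are derived from (most plausibly rounding of
unrounded medians upstream, or transcription slips); they are listed in
``KNOWN_TBR_DISCREPANCIES`` and the package reports the value computed from
the printed medians while flagging the mismatch, rather than echoing the
printed number.
"""

from __future__ import annotations

from .fgsgate import MarkerMetadata, PatientProfile

#: canonical tissue-group order used throughout reports.
GROUP_ORDER = ("healthy", "dVIN", "VSCC_HPV_independent", "HSIL", "VSCC_HPV_dependent")

LESION_GROUPS = GROUP_ORDER[1:]
MALIGNANT_GROUPS = ("VSCC_HPV_independent", "VSCC_HPV_dependent")

#: reported cohort section counts per group.
COHORT_COUNTS = {
    "healthy": 15,
    "dVIN": 10,
    "VSCC_HPV_independent": 16,
    "HSIL": 15,
    "VSCC_HPV_dependent": 13,
}

#: marker -> group -> (median, min, max, printed one-decimal TBR or None).
TABLE2: dict[str, dict[str, tuple[float, float, float, float | None]]] = {
    "avb6": {
        "healthy": (9, 2, 31, None),
        "dVIN": (59, 20, 216, 6.6),
        "VSCC_HPV_independent": (118, 0, 231, 13.1),
        "HSIL": (42, 3, 145, 4.7),
        "VSCC_HPV_dependent": (93, 7, 213, 10.3),
    },
    "CAIX": {
        "healthy": (2, 0, 19, None),
        "dVIN": (7, 1, 65, 3.5),
        "VSCC_HPV_independent": (9, 1, 77, 4.5),
        "HSIL": (5, 1, 92, 2.5),
        "VSCC_HPV_dependent": (6, 1, 102, 3.0),
    },
    "CD44v6": {
        "healthy": (240, 173, 283, None),
        "dVIN": (248, 123, 275, 1.0),
        "VSCC_HPV_independent": (196, 96, 271, 0.8),
        "HSIL": (223, 119, 279, 0.9),
        "VSCC_HPV_dependent": (118, 51, 267, 0.5),
    },
    "EGFR": {
        "healthy": (61, 2, 200, None),
        "dVIN": (40, 2, 138, 0.7),
        "VSCC_HPV_independent": (129, 4, 253, 2.2),
        "HSIL": (10, 0, 213, 0.2),
        "VSCC_HPV_dependent": (25, 5, 106, 0.4),
    },
    "EpCAM": {
        "healthy": (2, 0, 12, None),
        "dVIN": (5, 0, 11, 2.5),
        "VSCC_HPV_independent": (3, 0, 17, 1.5),
        "HSIL": (2, 0, 17, 1.0),
        "VSCC_HPV_dependent": (7, 0, 91, 3.5),
    },
    "FRa": {
        "healthy": (3, 1, 43, None),
        "dVIN": (1, 1, 3, 0.3),
        "VSCC_HPV_independent": (4, 2, 7, 1.3),
        "HSIL": (2, 0, 28, 0.7),
        "VSCC_HPV_dependent": (4, 2, 60, 0.3),
    },
    "MRP1": {
        "healthy": (4, 0, 29, None),
        "dVIN": (8, 0, 24, 2.0),
        "VSCC_HPV_independent": (13, 0, 42, 0.3),
        "HSIL": (2, 0, 22, 0.5),
        "VSCC_HPV_dependent": (2, 0, 17, 0.5),
    },
    "MUC1": {
        "healthy": (11, 1, 81, None),
        "dVIN": (63, 20, 206, 5.7),
        "VSCC_HPV_independent": (34, 3, 184, 3.1),
        "HSIL": (40, 3, 201, 3.6),
        "VSCC_HPV_dependent": (62, 14, 176, 5.6),
    },
    "uPAR": {
        "healthy": (6, 1, 22, None),
        "dVIN": (12, 2, 35, 2.0),
        "VSCC_HPV_independent": (37, 5, 91, 6.2),
        "HSIL": (6, 0, 73, 1.0),
        "VSCC_HPV_dependent": (19, 1, 125, 3.1),
    },
}

#: (marker, group) cells where printed TBR != ratio of printed medians,
#: mapped to (printed, computed-from-printed-medians at one decimal).
KNOWN_TBR_DISCREPANCIES: dict[tuple[str, str], tuple[float, float]] = {
    ("EGFR", "VSCC_HPV_independent"): (2.2, 2.1),
    ("MRP1", "VSCC_HPV_independent"): (0.3, 3.3),
    ("FRa", "VSCC_HPV_dependent"): (0.3, 1.3),
    ("uPAR", "VSCC_HPV_dependent"): (3.1, 3.2),
}

#: reported missing sections per (marker, group); subtracted from COHORT_COUNTS.
MISSING_SECTIONS: dict[tuple[str, str], int] = {
    ("avb6", "dVIN"): 2,
    ("avb6", "HSIL"): 2,
    ("CAIX", "dVIN"): 2,
    ("CAIX", "VSCC_HPV_independent"): 1,
    ("CD44v6", "VSCC_HPV_dependent"): 1,
    ("FRa", "VSCC_HPV_independent"): 1,
    ("MRP1", "VSCC_HPV_independent"): 3,
    ("MUC1", "VSCC_HPV_independent"): 1,
    ("uPAR", "dVIN"): 2,
    ("uPAR", "VSCC_HPV_independent"): 3,
    ("uPAR", "HSIL"): 3,
    ("uPAR", "VSCC_HPV_dependent"): 1,
    ("EpCAM", "VSCC_HPV_dependent"): 1,
}

# Narrative staining descriptions condensed to gate-facing labels.  The
# spatial-pattern vocabulary: homogeneous / patchy / restricted (to the
# spinosal-basal epithelial layers) / heterogeneous / absent.
MARKER_METADATA: dict[str, MarkerMetadata] = {
    "avb6": MarkerMetadata(
        marker_id="avb6",
        localization="membrane",
        pattern_by_group={
            "dVIN": "restricted",
            "VSCC_HPV_independent": "homogeneous",
            "HSIL": "restricted",
            "VSCC_HPV_dependent": "homogeneous",
        },
    ),
    "CAIX": MarkerMetadata(
        marker_id="CAIX",
        localization="membrane",
        pattern_by_group={g: "patchy" for g in LESION_GROUPS},
    ),
    "CD44v6": MarkerMetadata(
        marker_id="CD44v6",
        localization="membrane",
        pattern_by_group={g: "homogeneous" for g in LESION_GROUPS},
    ),
    "EGFR": MarkerMetadata(
        marker_id="EGFR",
        localization="membrane",
        pattern_by_group={g: "heterogeneous" for g in LESION_GROUPS},
    ),
    "EpCAM": MarkerMetadata(
        # membrane staining seen only on vessel endothelium, not lesional cells
        marker_id="EpCAM",
        localization="none_observed",
        pattern_by_group={g: "absent" for g in LESION_GROUPS},
    ),
    "FRa": MarkerMetadata(
        marker_id="FRa",
        localization="none_observed",
        pattern_by_group={g: "absent" for g in LESION_GROUPS},
    ),
    "MRP1": MarkerMetadata(
        marker_id="MRP1",
        localization="mixed",
        pattern_by_group={g: "absent" for g in LESION_GROUPS},
    ),
    "MUC1": MarkerMetadata(
        marker_id="MUC1",
        localization="membrane",
        pattern_by_group={g: "patchy" for g in LESION_GROUPS},
    ),
    "uPAR": MarkerMetadata(
        marker_id="uPAR",
        localization="membrane",
        pattern_by_group={g: "heterogeneous" for g in LESION_GROUPS},
    ),
}

#: individual-section favorability counts: stratum -> label -> count.
FIG3_COUNTS = {
    "independent": {"green": 7, "red": 2},
    "dependent": {"green": 4, "orange": 3, "red": 3},
}


def fig3_patient_profiles() -> list[PatientProfile]:
    """Synthetic per-patient mean H-score profiles matching the reported
    green/orange/red counts of the individual-section favorability analysis
    (7 green + 2 red HPV-independent; 4 green + 3 orange + 3 red
    HPV-dependent).  H-score levels are representative, not measured."""
    profiles: list[PatientProfile] = []
    k = 0

    def add(status, healthy, pre, mal):
        nonlocal k
        k += 1
        profiles.append(
            PatientProfile(
                patient_id=f"P{k:02d}",
                hpv_status=status,
                mean_h={
                    "healthy": healthy,
                    "premalignant": pre,
                    "malignant": mal,
                },
            )
        )

    for _ in range(7):  # HPV-independent, both ratios > 2
        add("independent", 10.0, 55.0, 120.0)
    for _ in range(2):  # HPV-independent, both ratios <= 1
        add("independent", 60.0, 40.0, 30.0)
    for _ in range(4):  # HPV-dependent, both ratios > 2
        add("dependent", 10.0, 45.0, 95.0)
    for _ in range(3):  # HPV-dependent, premalignant > 2 only
        add("dependent", 20.0, 50.0, 30.0)
    for _ in range(3):  # HPV-dependent, both ratios <= 1
        add("dependent", 80.0, 60.0, 40.0)
    return profiles


def table2_summaries():
    """``GroupSummary`` objects for every marker x group of the reference table."""
    from .scoring import GroupSummary

    out = []
    for marker, groups in TABLE2.items():
        for group, (med, lo, hi, _) in groups.items():
            n = COHORT_COUNTS[group] - MISSING_SECTIONS.get((marker, group), 0)
            out.append(
                GroupSummary(
                    marker_id=marker,
                    tissue_group=group,
                    n_sections=n,
                    median_h=float(med),
                    min_h=float(lo),
                    max_h=float(hi),
                )
            )
    return out
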