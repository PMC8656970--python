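"""Stage orchestration: simulate -> quantify -> score -> compare -> gate -> report.

Each stage reads the previous stage's artifacts from the run directory and
writes its own, so stages can be re-run independently; identical
(config, seed) reproduces every artifact byte for byte.  Layout of a run
directory::

    run/
      config.yaml            # the resolved configuration
      annotations/<patient>.geojson
      images/<marker>/<patient>.tiff
      truth/<marker>/<patient>.csv
      cells.csv              # measured per-cell table, all markers
      summary.csv            # per-group medians, min/max, TBRs
      stats.csv              # the six predefined Mann-Whitney comparisons
      gate.json, gate.csv    # four-criterion verdict per marker
      patients.csv, report.json
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import fgsgate, imagequant, scoring, stats, synthslide
from .io import (
    PipelineConfig,
    config_hash,
    read_annotations,
    read_cell_table,
    read_image,
    validate_cell_table,
    write_annotations,
    write_cell_table,
    write_image,
)

__all__ = ["run_pipeline", "PipelineDependencyError", "ALL_STAGES", "quantify_slide"]

log = logging.getLogger("ihcgate")

ALL_STAGES = ("simulate", "quantify", "score", "compare", "gate", "report")

_MALIGNANT = set(fgsgate.MALIGNANT_GROUPS)
_PREMALIGNANT = {"dVIN", "HSIL"}


class PipelineDependencyError(FileNotFoundError):
    """A stage's required upstream artifact is missing."""


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineDependencyError(
            f"stage {stage!r} requires missing artifact: {path}"
        )
    return path


def quantify_slide(
    image: np.ndarray,
    annotations: Sequence[Mapping],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Measure every annotated region of one slide (stains separated once)."""
    od = imagequant.rgb_to_od(image)
    hema, dab = imagequant.separate_stains(od, config.stains)
    params = config.detection_params()
    frames = []
    for ann in annotations:
        region_mask = imagequant.rasterize_polygon(ann["polygon"], hema.shape)
        nuclei = imagequant.detect_nuclei(np.where(region_mask, hema, 0.0), params)
        cell_masks = imagequant.expand_cells(
            nuclei,
            config.expansion_um,
            ann["polygon"],
            microns_per_pixel=params.microns_per_pixel,
        )
        detected = imagequant.classify_cells(
            cell_masks,
            dab,
            config.thresholds,
            nucleus_labels=nuclei,
            microns_per_pixel=params.microns_per_pixel,
            annotation_id=f"{ann['patient_id']}:{ann['region_id']}",
        )
        frame = imagequant.cells_to_frame(detected)
        frame["patient_id"] = ann["patient_id"]
        frame["tissue_type"] = ann["tissue_type"]
        frame["hpv_status"] = ann["hpv_status"]
        frames.append(frame)
    if not frames:
        return imagequant.cells_to_frame([])
    return pd.concat(frames, ignore_index=True)


def _stage_simulate(config: PipelineConfig, out: Path) -> None:
    plans = synthslide.plan_cohort(config.cohort, config.seed)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": config_hash(config), "seed": config.seed}
    for plan in plans:
        write_annotations(plan, out / "annotations" / f"{plan.patient_id}.geojson", prov)
    for marker in sorted(config.markers):
        spec = config.markers[marker]
        profiles = {
            tt: synthslide.profile_for_target_hscore(
                target,
                pattern=spec.patterns.get(tt, "homogeneous"),
                marker_id=marker,
                tissue_type=tt,
            )
            for tt, target in spec.target_hscores.items()
        }
        img_dir = out / "images" / marker
        truth_dir = out / "truth" / marker
        img_dir.mkdir(parents=True, exist_ok=True)
        truth_dir.mkdir(parents=True, exist_ok=True)
        for plan in plans:
            cells = synthslide.sample_cells(plan, profiles)
            image = synthslide.render_slide(
                plan, cells, config.stains, noise_sd=config.noise_sd
            )
            write_image(image, img_dir / f"{plan.patient_id}.tiff")
            truth = synthslide.truth_to_frame(cells)
            truth.insert(0, "patient_id", plan.patient_id)
            truth.to_csv(truth_dir / f"{plan.patient_id}.csv", index=False, lineterminator="\n")
            log.debug("simulated %s/%s: %d cells", marker, plan.patient_id, len(cells))


def _stage_quantify(config: PipelineConfig, out: Path) -> None:
    ann_dir = _require(out / "annotations", "quantify")
    frames = []
    for marker in sorted(config.markers):
        img_dir = _require(out / "images" / marker, "quantify")
        for img_path in sorted(img_dir.glob("*.tiff")):
            patient = img_path.stem
            anns = read_annotations(_require(ann_dir / f"{patient}.geojson", "quantify"))
            frame = quantify_slide(read_image(img_path), anns, config)
            frame["marker"] = marker
            frame["predefined_group"] = anns[0]["tissue_type"] if anns else ""
            frames.append(frame)
    cells = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    bad = validate_cell_table(cells, config.thresholds) if len(cells) else []
    if bad:  # classify_cells writes consistent classes; flag any drift loudly
        log.warning("quantify: %d rows with class/OD inconsistency", len(bad))
    write_cell_table(
        cells,
        out / "cells.csv",
        provenance={"config_hash": config_hash(config), "seed": config.seed},
    )


def _section_scores(
    cells: pd.DataFrame, marker: str
) -> dict[str, dict[str, list[float]]]:
    """group -> patient -> H-scores of that patient's same-group annotations.

    Only annotations matching the patient's predefined tissue type count
    toward the group analysis; adjacent-tissue annotations feed the patient
    report instead.
    """
    sub = cells[cells["marker"] == marker]
    per_ann = scoring.score_cells(sub, marker_id=marker)
    meta = (
        sub.groupby("annotation_id")[["patient_id", "tissue_type", "predefined_group"]]
        .first()
        .reset_index()
    )
    per_ann = per_ann.merge(meta, on="annotation_id", suffixes=("", "_m"))
    out: dict[str, dict[str, list[float]]] = {}
    for _, row in per_ann.iterrows():
        if row["tissue_type_m"] != row["predefined_group"]:
            continue
        out.setdefault(row["predefined_group"], {}).setdefault(
            row["patient_id"], []
        ).append(float(row["h_score"]))
    return out


def _stage_score(config: PipelineConfig, out: Path) -> None:
    cells = read_cell_table(_require(out / "cells.csv", "score"))
    summaries = []
    for marker in sorted(config.markers):
        groups = _section_scores(cells, marker)
        for group in sorted(groups):
            summaries.append(
                scoring.summarize_sections(groups[group], group, marker_id=marker)
            )
    table = scoring.summary_table(summaries)
    table = table.sort_values(["marker", "tissue_group"], kind="stable")
    table.to_csv(out / "summary.csv", index=False, lineterminator="\n")


def _stage_compare(config: PipelineConfig, out: Path) -> None:
    cells = read_cell_table(_require(out / "cells.csv", "score"))
    rows = []
    for marker in sorted(config.markers):
        groups = _section_scores(cells, marker)
        by_group = {
            g: [float(np.mean(v)) for _, v in sorted(p.items())]
            for g, p in groups.items()
        }
        pairs = [
            (a, b) for a, b in stats.PREDEFINED_PAIRS if a in by_group and b in by_group
        ]
        for res in stats.pairwise_comparisons(by_group, pairs=pairs, seed=config.seed):
            rows.append(
                {
                    "marker": marker,
                    "pair": f"{res.pair[0]}/{res.pair[1]}",
                    "nA": res.n_a,
                    "nB": res.n_b,
                    "U": res.u_statistic,
                    "p": res.p_two_sided,
                    "method": res.method,
                    "stars": res.stars,
                }
            )
    pd.DataFrame(rows).to_csv(out / "stats.csv", index=False, lineterminator="\n")


def _computed_metadata(
    cells: pd.DataFrame, marker: str, config: PipelineConfig
) -> fgsgate.MarkerMetadata:
    """Metadata surrogate: majority homogeneity label per lesion group."""
    sub = cells[(cells["marker"] == marker)]
    labels: dict[str, str] = {}
    for group, grp in sub.groupby("predefined_group"):
        if group == "healthy":
            continue
        votes = []
        for _, ann in grp.groupby("annotation_id"):
            if ann["tissue_type"].iloc[0] != group or len(ann) < 50:
                continue
            votes.append(
                fgsgate.homogeneity_score(ann, config.gate, seed=config.seed).label
            )
        if votes:
            labels[group] = max(set(votes), key=votes.count)
    spec = config.markers[marker]
    return fgsgate.MarkerMetadata(
        marker_id=marker, localization=spec.localization, pattern_by_group=labels
    )


def _stage_gate(config: PipelineConfig, out: Path, computed_pattern: bool) -> None:
    summary = pd.read_csv(_require(out / "summary.csv", "gate"))
    cells = None
    verdicts = []
    for marker in sorted(config.markers):
        sub = summary[summary["marker"] == marker]
        summaries = {
            row["tissue_group"]: scoring.GroupSummary(
                marker_id=marker,
                tissue_group=row["tissue_group"],
                n_sections=int(row["n"]),
                median_h=float(row["median_h"]),
                min_h=float(row["min_h"]),
                max_h=float(row["max_h"]),
            )
            for _, row in sub.iterrows()
        }
        stroma = summaries.pop("stroma", None)
        if computed_pattern:
            if cells is None:
                cells = read_cell_table(_require(out / "cells.csv", "gate"))
            meta = _computed_metadata(cells, marker, config)
        else:
            meta = config.markers[marker].metadata()
        lesion = [g for g in fgsgate.LESION_GROUPS if g in summaries]
        malignant = [g for g in fgsgate.MALIGNANT_GROUPS if g in summaries]
        verdicts.append(
            fgsgate.evaluate_gate(
                summaries,
                meta,
                config.gate,
                lesion_groups=lesion,
                malignant_groups=malignant,
                stromal_summary=stroma,
            )
        )
    doc = {v.marker_id: v.to_dict() for v in verdicts}
    (out / "gate.json").write_text(json.dumps(doc, indent=1, sort_keys=True))
    flat = []
    for v in verdicts:
        flat.append(
            {
                "marker": v.marker_id,
                "c1_pass": all(r.passed for r in v.c1_tbr.values()),
                "c2_pass": all(r.passed for r in v.c2_median.values()),
                "c3_pass": all(r.passed for r in v.c3_homogeneity.values()),
                "c4_pass": v.c4_localization.passed,
                "candidate": v.candidate,
            }
        )
    pd.DataFrame(flat).to_csv(out / "gate.csv", index=False, lineterminator="\n")


def _patient_profiles(cells: pd.DataFrame, marker: str) -> list[fgsgate.PatientProfile]:
    sub = cells[cells["marker"] == marker]
    per_ann = scoring.score_cells(sub, marker_id=marker)
    meta = (
        sub.groupby("annotation_id")[["patient_id", "tissue_type", "hpv_status"]]
        .first()
        .reset_index()
    )
    per_ann = per_ann.merge(meta, on="annotation_id", suffixes=("", "_m"))
    profiles = []
    for patient, grp in per_ann.groupby("patient_id"):
        roles: dict[str, list[float]] = {}
        for _, row in grp.iterrows():
            tt = row["tissue_type_m"]
            role = (
                "malignant"
                if tt in _MALIGNANT
                else "premalignant"
                if tt in _PREMALIGNANT
                else "healthy"
                if tt == "healthy"
                else None
            )
            if role:
                roles.setdefault(role, []).append(float(row["h_score"]))
        if "healthy" not in roles or len(roles) < 2:
            continue  # no adjacent tissue: patient not individually evaluable
        profiles.append(
            fgsgate.PatientProfile(
                patient_id=str(patient),
                hpv_status=str(grp["hpv_status"].iloc[0]),
                mean_h={k: float(np.mean(v)) for k, v in roles.items()},
            )
        )
    return profiles


def _stage_report(config: PipelineConfig, out: Path) -> dict:
    cells = read_cell_table(_require(out / "cells.csv", "report"))
    gate_doc = json.loads(_require(out / "gate.json", "report").read_text())
    rows = []
    fractions: dict[str, dict] = {}
    for marker in sorted(config.markers):
        profiles = _patient_profiles(cells, marker)
        classes = [fgsgate.classify_patient(p, config.gate) for p in profiles]
        for c in classes:
            rows.append(
                {
                    "marker": marker,
                    "patient_id": c.patient_id,
                    "hpv_status": c.hpv_status,
                    "label": c.label,
                    "tbr_malignant": c.tbr_malignant,
                    "tbr_premalignant": c.tbr_premalignant,
                }
            )
        for stratum in ("independent", "dependent"):
            pool = [c for c in classes if c.hpv_status == stratum]
            if any(c.label != "unclassifiable" for c in pool):
                f = fgsgate.cohort_fraction(classes, stratum)
                fractions.setdefault(marker, {})[stratum] = {
                    "green": f.n_green,
                    "classifiable": f.n_classifiable,
                    "percent": f.percent_display,
                }
    pd.DataFrame(rows).to_csv(out / "patients.csv", index=False, lineterminator="\n")
    report = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "summary_csv": "summary.csv",
        "stats_csv": "stats.csv",
        "gate": gate_doc,
        "patient_fractions": fractions,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    stages: Sequence[str] = ALL_STAGES,
    computed_pattern: bool = False,
) -> dict | None:
    """Execute the requested stages in canonical order; returns the report
    dict when the report stage runs."""
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report = None
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        log.info("stage %s", stage)
        if stage == "simulate":
            _stage_simulate(config, out)
        elif stage == "quantify":
            _stage_quantify(config, out)
        elif stage == "score":
            _stage_score(config, out)
        elif stage == "compare":
            _stage_compare(config, out)
        elif stage == "gate":
            _stage_gate(config, out, computed_pattern)
        elif stage == "report":
            report = _stage_report(config, out)
    return report
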