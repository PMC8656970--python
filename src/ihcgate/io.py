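"""File formats and configuration for the pipeline.

Conventions, fixed for bit-exact cross-platform outputs:

* images: 8-bit RGB TIFF (PNG also accepted), pixel origin top-left,
  x right / y down, 0-based;
* annotations: GeoJSON FeatureCollection, one Feature per region, polygon
  coordinates in pixel units, properties
  ``{patient_id, tissue_type, region_id, basal_axis}``;
* tables: UTF-8 CSV, comma separator, ``.`` decimal, LF line endings;
  comment lines starting ``#`` carry the config hash and seed of the run;
* config: YAML mapping that round-trips losslessly through
  ``PipelineConfig.from_dict(cfg.to_dict())``.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image
from shapely.geometry import Polygon, mapping, shape

from .fgsgate import GateConfig, MarkerMetadata
from .imagequant import (
    CELL_TABLE_COLUMNS,
    DEFAULT_STAINS,
    DetectionParams,
    IntensityThresholds,
    StainMatrix,
)
from .synthslide import CohortConfig, SlidePlan

__all__ = [
    "MarkerSpec",
    "PipelineConfig",
    "config_hash",
    "read_cell_table",
    "write_cell_table",
    "validate_cell_table",
    "read_annotations",
    "write_annotations",
    "read_image",
    "write_image",
    "read_marker_metadata",
    "write_marker_metadata",
]

#: generator pattern -> narrative metadata label
_PATTERN_TO_META = {
    "homogeneous": "homogeneous",
    "patchy": "patchy",
    "basal_restricted": "restricted",
    "gradient": "heterogeneous",
    "absent": "absent",
}


@dataclass(frozen=True)
class MarkerSpec:
    """How one marker is simulated and how the gate should read it."""

    marker_id: str
    #: tissue type -> target median H-score of the generative profile
    target_hscores: Mapping[str, float]
    #: tissue type -> generator pattern (homogeneous/patchy/basal_restricted/
    #: gradient/absent); defaults to homogeneous
    patterns: Mapping[str, str] = field(default_factory=dict)
    localization: str = "membrane"
    #: gate-facing label per lesion group; derived from ``patterns`` if empty
    meta_patterns: Mapping[str, str] = field(default_factory=dict)

    def metadata(self) -> MarkerMetadata:
        labels = dict(self.meta_patterns)
        if not labels:
            labels = {
                g: _PATTERN_TO_META[self.patterns.get(g, "homogeneous")]
                for g in self.target_hscores
                if g != "healthy"
            }
        return MarkerMetadata(
            marker_id=self.marker_id,
            localization=self.localization,
            pattern_by_group=labels,
        )


def _default_markers() -> dict[str, "MarkerSpec"]:
    # the flagship integrin target, calibrated to the published group medians
    return {
        "avb6": MarkerSpec(
            marker_id="avb6",
            target_hscores={
                "healthy": 9.0,
                "dVIN": 59.0,
                "VSCC_HPV_independent": 118.0,
                "HSIL": 42.0,
                "VSCC_HPV_dependent": 93.0,
            },
            localization="membrane",
        )
    }


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    markers: Mapping[str, MarkerSpec] = field(default_factory=_default_markers)
    stains: StainMatrix = DEFAULT_STAINS
    thresholds: IntensityThresholds = field(default_factory=IntensityThresholds)
    detection: DetectionParams | None = None  # None: derive from cohort mpp
    gate: GateConfig = field(default_factory=GateConfig)
    noise_sd: float = 0.02
    expansion_um: float = 5.0
    seed: int = 0

    def detection_params(self) -> DetectionParams:
        if self.detection is not None:
            return self.detection
        return DetectionParams(microns_per_pixel=self.cohort.microns_per_pixel)

    # -- lossless dict round trip ------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "cohort": {
                "group_counts": dict(self.cohort.group_counts),
                "adjacent_counts": dict(self.cohort.adjacent_counts),
                "image_size": list(self.cohort.image_size),
                "microns_per_pixel": self.cohort.microns_per_pixel,
                "cell_density": self.cohort.cell_density,
                "margin_px": self.cohort.margin_px,
            },
            "markers": {
                m: {
                    "target_hscores": dict(s.target_hscores),
                    "patterns": dict(s.patterns),
                    "localization": s.localization,
                    "meta_patterns": dict(s.meta_patterns),
                }
                for m, s in self.markers.items()
            },
            "stains": {
                "hematoxylin": list(self.stains.hematoxylin),
                "dab": list(self.stains.dab),
            },
            "thresholds": [self.thresholds.t1, self.thresholds.t2, self.thresholds.t3],
            "detection": (None if self.detection is None else asdict(self.detection)),
            "gate": asdict(self.gate),
            "noise_sd": self.noise_sd,
            "expansion_um": self.expansion_um,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        cohort = CohortConfig(
            group_counts=dict(d["cohort"]["group_counts"]),
            adjacent_counts=dict(d["cohort"]["adjacent_counts"]),
            image_size=tuple(d["cohort"]["image_size"]),
            microns_per_pixel=d["cohort"]["microns_per_pixel"],
            cell_density=d["cohort"]["cell_density"],
            margin_px=d["cohort"]["margin_px"],
        )
        markers = {
            m: MarkerSpec(
                marker_id=m,
                target_hscores=dict(s["target_hscores"]),
                patterns=dict(s.get("patterns", {})),
                localization=s.get("localization", "membrane"),
                meta_patterns=dict(s.get("meta_patterns", {})),
            )
            for m, s in d["markers"].items()
        }
        stains = StainMatrix(
            tuple(d["stains"]["hematoxylin"]), tuple(d["stains"]["dab"])
        )
        t1, t2, t3 = d["thresholds"]
        det = d.get("detection")
        return cls(
            cohort=cohort,
            markers=markers,
            stains=stains,
            thresholds=IntensityThresholds(t1, t2, t3),
            detection=None if det is None else DetectionParams(**det),
            gate=GateConfig(**d["gate"]),
            noise_sd=d["noise_sd"],
            expansion_um=d["expansion_um"],
            seed=d["seed"],
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# cell tables


def write_cell_table(
    cells: pd.DataFrame,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """CSV with the measurement schema; extra columns are preserved.

    ``provenance`` (config hash, seed, ...) is embedded as ``#``-prefixed
    header comment lines.
    """
    missing = [c for c in CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing mandatory columns: {missing}")
    ordered = [c for c in CELL_TABLE_COLUMNS if c in cells.columns]
    ordered += [c for c in cells.columns if c not in ordered]
    buf = _io.StringIO()
    for key, val in (provenance or {}).items():
        buf.write(f"# {key}: {val}\n")
    cells[ordered].to_csv(buf, index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a cell-table CSV; unknown columns are kept, comments skipped."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    if len(df) and not np.issubdtype(df["mean_dab_od"].dtype, np.number):
        raise ValueError(f"{path}: non-numeric mean_dab_od")
    return df


def validate_cell_table(
    cells: pd.DataFrame, thresholds: IntensityThresholds
) -> list[int]:
    """Row indices whose stored class disagrees with their mean OD under the
    configured thresholds (returned, not raised: callers warn)."""
    if len(cells) == 0:
        return []
    expected = thresholds.classify(cells["mean_dab_od"].to_numpy(float))
    bad = cells.index[expected != cells["intensity_class"].to_numpy(int)]
    return [int(i) for i in bad]


# ---------------------------------------------------------------------------
# annotations (GeoJSON)


def write_annotations(
    plan: SlidePlan, path: str | Path, provenance: Mapping[str, object] | None = None
) -> None:
    features = []
    for r in plan.regions:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(r.polygon),
                "properties": {
                    "patient_id": plan.patient_id,
                    "tissue_type": r.tissue_type,
                    "region_id": r.region_id,
                    "basal_axis": [list(r.basal_axis[0]), list(r.basal_axis[1])],
                    "hpv_status": plan.hpv_status,
                    "microns_per_pixel": plan.microns_per_pixel,
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    if provenance:
        doc["provenance"] = dict(provenance)
    Path(path).write_text(json.dumps(doc, sort_keys=True), encoding="utf-8")


def read_annotations(path: str | Path) -> list[dict]:
    """Features as dicts with keys region_id, tissue_type, polygon, basal_axis,
    patient_id, hpv_status, microns_per_pixel."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for f in doc["features"]:
        props = f["properties"]
        geom = shape(f["geometry"])
        if not isinstance(geom, Polygon):
            raise ValueError(f"{path}: non-polygon annotation {props.get('region_id')}")
        axis = props.get("basal_axis")
        out.append(
            {
                "region_id": props["region_id"],
                "tissue_type": props["tissue_type"],
                "patient_id": props["patient_id"],
                "hpv_status": props.get("hpv_status", "none"),
                "microns_per_pixel": props.get("microns_per_pixel"),
                "polygon": geom,
                "basal_axis": (
                    None
                    if axis is None
                    else (tuple(axis[0]), tuple(axis[1]))
                ),
            }
        )
    return out


# ---------------------------------------------------------------------------
# images


def write_image(image: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image, photometric="rgb")
    else:
        Image.fromarray(image).save(path)


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(Image.open(path).convert("RGB"))


# ---------------------------------------------------------------------------
# marker metadata YAML


def write_marker_metadata(
    metadata: Mapping[str, MarkerMetadata], path: str | Path
) -> None:
    doc = {
        m: {
            "localization": md.localization,
            "pattern_by_group": dict(md.pattern_by_group),
        }
        for m, md in metadata.items()
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


def read_marker_metadata(path: str | Path) -> dict[str, MarkerMetadata]:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return {
        m: MarkerMetadata(
            marker_id=m,
            localization=d["localization"],
            pattern_by_group=dict(d["pattern_by_group"]),
        )
        for m, d in doc.items()
    }
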