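"""Brightfield H-DAB quantification: stain separation, nucleus detection,
cell expansion and per-cell DAB intensity classification.

The measurement chain mirrors a standard digital-pathology workflow on
hematoxylin (blue, nuclear counterstain) + DAB (brown, antibody chromogen)
slides:

1. convert 8-bit RGB transmitted light to optical density (OD),
   ``OD = -log10(I/255)`` per channel, where stain amounts add linearly
   (Beer-Lambert);
2. unmix each pixel's OD vector into hematoxylin and DAB concentrations by
   least-squares projection onto the two stain absorbance directions;
3. detect nuclei on the hematoxylin channel (Gaussian smoothing, OD
   threshold, hole filling, small-object removal, watershed split of
   touching blobs);
4. expand each nucleus into a cell mask (contested pixels go to the nearest
   nucleus) clipped to the annotation polygon;
5. classify each cell 0 / 1+ / 2+ / 3+ by its mean DAB OD against three
   thresholds, lower bound inclusive.

The three intensity thresholds default to (0.2, 0.4, 0.6) OD, a common
convention for DAB H-score work; every H-score downstream depends on them,
so they are exposed everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from skimage.draw import polygon2mask
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import expand_labels, watershed

__all__ = [
    "StainMatrix",
    "IntensityThresholds",
    "DetectionParams",
    "DetectedCell",
    "DEFAULT_STAINS",
    "DEFAULT_THRESHOLDS",
    "rgb_to_od",
    "separate_stains",
    "detect_nuclei",
    "expand_cells",
    "classify_cells",
    "rasterize_polygon",
    "quantify_annotation",
    "cells_to_frame",
    "CELL_TABLE_COLUMNS",
]

CELL_TABLE_COLUMNS = [
    "cell_id",
    "annotation_id",
    "x_px",
    "y_px",
    "nucleus_area_um2",
    "mean_dab_od",
    "intensity_class",
]


@dataclass(frozen=True)
class StainMatrix:
    """RGB absorbance directions of the two stains (unit norm, non-negative)."""

    hematoxylin: tuple[float, float, float]
    dab: tuple[float, float, float]
    max_condition: float = 1e3

    def __post_init__(self):
        m = self.matrix
        if np.any(m < 0):
            raise ValueError("stain vectors must be non-negative")
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain vectors must have unit norm")
        if np.linalg.cond(m) > self.max_condition:
            raise ValueError("degenerate stain matrix (near-collinear vectors)")

    @property
    def matrix(self) -> np.ndarray:
        """3x2 matrix with stain vectors as columns (hematoxylin, DAB)."""
        return np.column_stack([self.hematoxylin, self.dab]).astype(float)

    @classmethod
    def from_unnormalized(cls, hematoxylin: Sequence[float], dab: Sequence[float]):
        h = np.asarray(hematoxylin, float)
        d = np.asarray(dab, float)
        return cls(
            tuple(float(x) for x in h / np.linalg.norm(h)),
            tuple(float(x) for x in d / np.linalg.norm(d)),
        )


#: standard published H-DAB absorbance directions.
DEFAULT_STAINS = StainMatrix.from_unnormalized((0.651, 0.701, 0.290), (0.269, 0.568, 0.778))


@dataclass(frozen=True)
class IntensityThresholds:
    """DAB mean-OD cutpoints separating classes 0|1+|2+|3+ (lower-inclusive)."""

    t1: float = 0.2
    t2: float = 0.4
    t3: float = 0.6

    def __post_init__(self):
        if not 0 < self.t1 < self.t2 < self.t3:
            raise ValueError("thresholds must satisfy 0 < t1 < t2 < t3")

    def as_array(self) -> np.ndarray:
        return np.array([self.t1, self.t2, self.t3])

    def classify(self, mean_od):
        """Intensity class = number of thresholds <= mean OD."""
        return np.searchsorted(self.as_array(), np.asarray(mean_od), side="right")


DEFAULT_THRESHOLDS = IntensityThresholds()


@dataclass(frozen=True)
class DetectionParams:
    microns_per_pixel: float = 0.5
    sigma_px: float = 1.5
    threshold_od: float = 0.1
    use_otsu: bool = False
    min_area_um2: float = 7.0
    #: minimum watershed-seed separation, in µm (about one nucleus radius)
    min_peak_distance_um: float = 3.0


@dataclass(frozen=True)
class DetectedCell:
    cell_id: int
    annotation_id: str
    centroid: tuple[float, float]  # (x, y) pixels
    nucleus_area_um2: float
    mean_dab_od: float
    intensity_class: int

    def __post_init__(self):
        if self.mean_dab_od < 0:
            raise ValueError("mean DAB OD must be non-negative")


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Per-channel optical density of an 8-bit RGB image.

    ``OD = -log10(max(I, 1) / 255)``; white maps to 0, the clamp at 1 bounds
    OD at ``-log10(1/255) ~ 2.4065``.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    i = np.maximum(img.astype(float), 1.0)
    return -np.log10(i / 255.0)


def separate_stains(od_image: np.ndarray, stains: StainMatrix = DEFAULT_STAINS):
    """Least-squares unmixing of an OD image into stain concentrations.

    Returns ``(hematoxylin, dab)`` concentration images; negative
    least-squares solutions are clamped to 0.
    """
    od = np.asarray(od_image, float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError("expected an OD image (H, W, 3)")
    pinv = np.linalg.pinv(stains.matrix)  # 2x3
    conc = od.reshape(-1, 3) @ pinv.T
    conc = np.clip(conc, 0.0, None).reshape(od.shape[0], od.shape[1], 2)
    return conc[..., 0], conc[..., 1]


def detect_nuclei(
    hema_channel: np.ndarray, params: DetectionParams = DetectionParams()
) -> np.ndarray:
    """Labeled nucleus mask from the hematoxylin OD channel."""
    hema = np.asarray(hema_channel, float)
    if hema.ndim != 2 or hema.size == 0:
        raise ValueError("expected a non-empty single-channel OD image")
    smoothed = gaussian(hema, sigma=params.sigma_px, preserve_range=True)
    if params.use_otsu:
        thr = threshold_otsu(smoothed) if smoothed.max() > smoothed.min() else np.inf
    else:
        thr = params.threshold_od
    mask = smoothed > thr
    if not mask.any():
        return np.zeros(hema.shape, dtype=np.int32)
    mask = ndi.binary_fill_holes(mask)
    min_area_px = max(1, int(round(params.min_area_um2 / params.microns_per_pixel**2)))
    comp, n_comp = ndi.label(mask)
    if n_comp:
        sizes = ndi.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n_comp + 1))
        mask = np.isin(comp, np.flatnonzero(sizes >= min_area_px) + 1)
    if not mask.any():
        return np.zeros(hema.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    min_dist_px = max(2, int(round(params.min_peak_distance_um / params.microns_per_pixel)))
    peaks = peak_local_max(
        distance, min_distance=min_dist_px, labels=mask, exclude_border=False
    )
    if len(peaks) == 0:
        labels, _ = ndi.label(mask)
        return labels.astype(np.int32)
    markers = np.zeros(hema.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask)
    return labels.astype(np.int32)


def rasterize_polygon(polygon: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of a (possibly holed) polygon in (row, col) = (y, x) space."""
    ext = np.array(polygon.exterior.coords)[:, ::-1]  # (x, y) -> (row, col)
    mask = polygon2mask(shape, ext)
    for interior in polygon.interiors:
        hole = np.array(interior.coords)[:, ::-1]
        mask &= ~polygon2mask(shape, hole)
    return mask


def expand_cells(
    nucleus_labels: np.ndarray,
    radius_um: float = 5.0,
    annotation_polygon: Polygon | None = None,
    microns_per_pixel: float = 0.5,
) -> np.ndarray:
    """Grow each nucleus into a cell mask; contested pixels go to the nearest
    nucleus; masks are clipped to the annotation polygon and pairwise disjoint."""
    if radius_um < 0:
        raise ValueError("expansion radius must be non-negative")
    labels = np.asarray(nucleus_labels)
    cells = expand_labels(labels, distance=radius_um / microns_per_pixel)
    if annotation_polygon is not None:
        mask = rasterize_polygon(annotation_polygon, labels.shape)
        cells = np.where(mask, cells, 0)
    return cells.astype(np.int32)


def classify_cells(
    cell_masks: np.ndarray,
    dab_channel: np.ndarray,
    thresholds: IntensityThresholds = DEFAULT_THRESHOLDS,
    nucleus_labels: np.ndarray | None = None,
    microns_per_pixel: float = 0.5,
    annotation_id: str = "",
) -> list[DetectedCell]:
    """Mean DAB OD per cell mask, mapped to intensity classes.

    ``nucleus_labels`` (matching ids) provides centroids and nucleus areas;
    if omitted, the cell masks themselves are used.
    """
    cells = np.asarray(cell_masks)
    dab = np.asarray(dab_channel, float)
    if cells.shape != dab.shape:
        raise ValueError("cell masks and DAB channel differ in shape")
    ids = np.unique(cells)
    ids = ids[ids > 0]
    if ids.size == 0:
        return []
    mean_od = ndi.mean(dab, labels=cells, index=ids)
    nuc = cells if nucleus_labels is None else np.asarray(nucleus_labels)
    # a cell whose nucleus was clipped away entirely keeps its cell-mask stats
    nuc_ids_present = np.isin(ids, np.unique(nuc))
    centroids = np.full((ids.size, 2), np.nan)
    areas = np.zeros(ids.size)
    if nuc_ids_present.any():
        present = ids[nuc_ids_present]
        com = ndi.center_of_mass(nuc > 0, labels=nuc, index=present)
        areas_px = ndi.sum_labels(np.ones_like(nuc), labels=nuc, index=present)
        centroids[nuc_ids_present] = np.atleast_2d(com)
        areas[nuc_ids_present] = areas_px
    classes = thresholds.classify(mean_od)
    out = []
    for i, cid in enumerate(ids):
        if np.sum(cells == cid) == 0:  # pragma: no cover - ids come from cells
            raise ValueError(f"empty mask for cell {cid}")
        out.append(
            DetectedCell(
                cell_id=int(cid),
                annotation_id=annotation_id,
                centroid=(float(centroids[i, 1]), float(centroids[i, 0])),
                nucleus_area_um2=float(areas[i]) * microns_per_pixel**2,
                mean_dab_od=float(mean_od[i]),
                intensity_class=int(classes[i]),
            )
        )
    return out


def cells_to_frame(cells: Sequence[DetectedCell]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": c.cell_id,
            "annotation_id": c.annotation_id,
            "x_px": c.centroid[0],
            "y_px": c.centroid[1],
            "nucleus_area_um2": c.nucleus_area_um2,
            "mean_dab_od": c.mean_dab_od,
            "intensity_class": c.intensity_class,
        }
        for c in cells
    ]
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)


def quantify_annotation(
    image: np.ndarray,
    polygon: Polygon,
    annotation_id: str = "",
    stains: StainMatrix = DEFAULT_STAINS,
    params: DetectionParams = DetectionParams(),
    thresholds: IntensityThresholds = DEFAULT_THRESHOLDS,
    expansion_um: float = 5.0,
) -> list[DetectedCell]:
    """End-to-end measurement of one annotated region of an RGB slide image."""
    od = rgb_to_od(image)
    hema, dab = separate_stains(od, stains)
    region = rasterize_polygon(polygon, hema.shape)
    nuclei = detect_nuclei(np.where(region, hema, 0.0), params)
    cell_masks = expand_cells(
        nuclei, expansion_um, polygon, microns_per_pixel=params.microns_per_pixel
    )
    return classify_cells(
        cell_masks,
        dab,
        thresholds,
        nucleus_labels=nuclei,
        microns_per_pixel=params.microns_per_pixel,
        annotation_id=annotation_id,
    )
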