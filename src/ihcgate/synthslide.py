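"""Synthetic annotated H-DAB slide cohorts with known per-cell ground truth.

No pixel data accompany the published vulvar cohort, so every downstream
stage is exercised on simulated sections that reproduce the cohort's
statistical and spatial structure:

* five tissue groups with the reported section counts (15 healthy, 10 dVIN,
  16 HPV-independent VSCC, 15 HSIL, 13 HPV-dependent VSCC);
* marker-by-tissue expression profiles whose expected H-score is calibrated
  to a target (e.g. a published group median);
* the narrative spatial patterns: homogeneous, patchy (clustered positive
  cells via a thresholded smooth random field), basal-restricted (positive
  cells only near the basal epithelial axis), gradient, and absent;
* carcinoma sections optionally carrying adjacent premalignant and healthy
  tissue as concentric bands, so one section can hold all three tissue
  roles;
* Beer-Lambert hematoxylin/DAB stain mixing with optional OD noise.

Cells are placed by a hard-core point process (minimum nucleus separation)
at a configurable density.  Each cell's true DAB OD is drawn inside the
intensity band of its true class (with a small guard margin), which makes
the generator's ground truth recoverable by the classifier in the
noiseless limit.

All randomness flows through ``numpy.random.SeedSequence`` children of the
caller's seed: identical (config, seed) yields identical plans, cells and
pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, Polygon, box

from .imagequant import DEFAULT_STAINS, DEFAULT_THRESHOLDS, StainMatrix

__all__ = [
    "TISSUE_TYPES",
    "PATTERNS",
    "MarkerTissueProfile",
    "Region",
    "SlidePlan",
    "GroundTruthCell",
    "CohortConfig",
    "PlacementError",
    "plan_cohort",
    "sample_cells",
    "render_slide",
    "profile_for_target_hscore",
    "truth_to_frame",
]

TISSUE_TYPES = (
    "healthy",
    "dVIN",
    "HSIL",
    "VSCC_HPV_independent",
    "VSCC_HPV_dependent",
    "stroma",
    "sebaceous_gland",
)

PATTERNS = ("homogeneous", "patchy", "basal_restricted", "gradient", "absent")

#: OD ceiling of the top intensity band (class 3+ cells draw below this).
OD_CEILING = 1.2
#: guard margin (OD) keeping true ODs away from class boundaries, so 8-bit
#: quantization cannot flip a noiseless class.
OD_MARGIN = 0.02

NUCLEUS_RADIUS_UM = 3.0
MIN_SEPARATION_UM = 7.0
#: depth cutoff for basal-restricted positivity (normalized depth units).
BASAL_DEPTH_CUTOFF = 0.4


class PlacementError(RuntimeError):
    """Raised when the requested regions cannot be placed in the image."""


@dataclass(frozen=True)
class MarkerTissueProfile:
    """Generative description of one marker's expression in one tissue type."""

    marker_id: str
    tissue_type: str
    class_fractions: tuple[float, float, float, float]
    pattern: str = "homogeneous"
    patch_scale_um: float = 60.0

    def __post_init__(self):
        p = self.class_fractions
        if len(p) != 4 or any(x < 0 for x in p):
            raise ValueError("class_fractions must be four non-negative numbers")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.pattern == "absent" and abs(p[0] - 1.0) > 1e-9:
            raise ValueError("pattern 'absent' requires p0 == 1")
        if self.tissue_type not in TISSUE_TYPES:
            raise ValueError(f"unknown tissue type {self.tissue_type!r}")

    @property
    def expected_hscore(self) -> float:
        p = self.class_fractions
        return 100.0 * (p[1] + 2.0 * p[2] + 3.0 * p[3])

    @property
    def positive_fraction(self) -> float:
        return 1.0 - self.class_fractions[0]


@dataclass(frozen=True)
class Region:
    region_id: str
    tissue_type: str
    polygon: Polygon
    #: oriented segment ((x0, y0), (x1, y1)) marking the basal epithelial edge
    basal_axis: tuple[tuple[float, float], tuple[float, float]]


@dataclass(frozen=True)
class SlidePlan:
    patient_id: str
    hpv_status: str  # independent | dependent | none
    image_size: tuple[int, int]  # (width, height) px
    microns_per_pixel: float
    regions: tuple[Region, ...]
    cell_density: float  # cells per mm^2
    seed: int

    def __post_init__(self):
        w, h = self.image_size
        bounds = box(0, 0, w, h)
        for r in self.regions:
            if not r.polygon.is_valid or not r.polygon.is_simple:
                raise ValueError(f"region {r.region_id} polygon is not simple")
            if not bounds.contains(r.polygon):
                raise ValueError(f"region {r.region_id} exceeds image bounds")
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1 :]:
                if a.tissue_type != b.tissue_type and a.polygon.intersects(b.polygon):
                    if a.polygon.intersection(b.polygon).area > 1e-9:
                        raise ValueError(
                            f"regions {a.region_id}/{b.region_id} of different "
                            "tissue types overlap"
                        )


@dataclass(frozen=True)
class GroundTruthCell:
    cell_id: str
    region_id: str
    centroid: tuple[float, float]  # (x, y) px
    true_class: int
    true_dab_od: float
    nucleus_radius_um: float = NUCLEUS_RADIUS_UM


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout; the defaults are the reported section counts and the
    reported fractions of carcinoma sections carrying evaluable adjacent
    healthy/premalignant tissue (9/16 HPV-independent, 10/13 HPV-dependent)."""

    group_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "healthy": 15,
            "dVIN": 10,
            "VSCC_HPV_independent": 16,
            "HSIL": 15,
            "VSCC_HPV_dependent": 13,
        }
    )
    adjacent_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "VSCC_HPV_independent": 9,
            "VSCC_HPV_dependent": 10,
        }
    )
    image_size: tuple[int, int] = (2048, 2048)
    microns_per_pixel: float = 0.5
    cell_density: float = 3000.0
    #: margin between the image edge and tissue, px
    margin_px: int = 24

    def __post_init__(self):
        for g, n in self.group_counts.items():
            if n < 0:
                raise ValueError(f"negative section count for {g}")
            if g not in TISSUE_TYPES:
                raise ValueError(f"unknown tissue group {g!r}")


_PRECURSOR_OF = {"VSCC_HPV_independent": "dVIN", "VSCC_HPV_dependent": "HSIL"}
_HPV_STATUS = {
    "VSCC_HPV_independent": "independent",
    "VSCC_HPV_dependent": "dependent",
}


def _top_edge_axis(poly: Polygon):
    x0, y0, x1, _ = poly.bounds
    return ((x0, y0), (x1, y0))


def _simple_section_regions(cfg: CohortConfig, tissue: str) -> tuple[Region, ...]:
    w, h = cfg.image_size
    m = cfg.margin_px
    poly = box(m, m, w - m, h - m)
    return (Region("r0", tissue, poly, _top_edge_axis(poly)),)


def _banded_section_regions(cfg: CohortConfig, tumor: str) -> tuple[Region, ...]:
    """Concentric layout: tumor core, premalignant rim, healthy margin."""
    w, h = cfg.image_size
    m = cfg.margin_px
    cx, cy = w / 2.0, h / 2.0
    r_out = min(w, h) / 2.0 - m
    if r_out < 30:
        raise PlacementError("image too small for a banded section")
    r_core = r_out * 0.5
    r_rim = r_out * 0.75
    gap = 1.0  # px, keeps bands of different tissue types disjoint
    core = Point(cx, cy).buffer(r_core, quad_segs=64)
    rim = Point(cx, cy).buffer(r_rim, quad_segs=64).difference(
        Point(cx, cy).buffer(r_core + gap, quad_segs=64)
    )
    margin = Point(cx, cy).buffer(r_out, quad_segs=64).difference(
        Point(cx, cy).buffer(r_rim + gap, quad_segs=64)
    )
    precursor = _PRECURSOR_OF[tumor]
    return (
        Region("r0", tumor, core, _top_edge_axis(core)),
        Region("r1", precursor, rim, _top_edge_axis(rim)),
        Region("r2", "healthy", margin, _top_edge_axis(margin)),
    )


def plan_cohort(config: CohortConfig | None = None, seed: int = 0) -> list[SlidePlan]:
    """One ``SlidePlan`` per section, deterministic given (config, seed).

    Carcinoma sections are banded (tumor + adjacent precursor + healthy
    margin) for the first ``adjacent_counts[group]`` sections of the group,
    plain otherwise.
    """
    cfg = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    plans: list[SlidePlan] = []
    order = [g for g in ("healthy", "dVIN", "VSCC_HPV_independent", "HSIL", "VSCC_HPV_dependent") if g in cfg.group_counts]
    order += [g for g in cfg.group_counts if g not in order]
    idx = 0
    for group in order:
        n = cfg.group_counts[group]
        n_adj = cfg.adjacent_counts.get(group, 0)
        for k in range(n):
            child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(idx,))
            plan_seed = int(child.generate_state(1)[0] % (2**31))
            if group in _PRECURSOR_OF and k < n_adj:
                regions = _banded_section_regions(cfg, group)
            else:
                regions = _simple_section_regions(cfg, group)
            plans.append(
                SlidePlan(
                    patient_id=f"{group}_{k + 1:02d}",
                    hpv_status=_HPV_STATUS.get(group, "none"),
                    image_size=cfg.image_size,
                    microns_per_pixel=cfg.microns_per_pixel,
                    regions=regions,
                    cell_density=cfg.cell_density,
                    seed=plan_seed,
                )
            )
            idx += 1
    return plans


# ---------------------------------------------------------------------------
# cell sampling


def _hardcore_points(
    poly: Polygon, n: int, min_sep_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Dart throwing with a uniform grid for neighbor lookup; returns up to n
    points at pairwise distance >= min_sep_px, uniformly over the polygon."""
    if n <= 0:
        return np.empty((0, 2))
    x0, y0, x1, y1 = poly.bounds
    cell = max(min_sep_px, 1e-6)
    nx = max(1, int(math.ceil((x1 - x0) / cell)))
    ny = max(1, int(math.ceil((y1 - y0) / cell)))
    grid: dict[tuple[int, int], list[int]] = {}
    pts: list[tuple[float, float]] = []
    from shapely import contains_xy

    max_attempts = 60 * n
    attempts = 0
    batch = max(256, n)
    while len(pts) < n and attempts < max_attempts:
        xs = rng.uniform(x0, x1, batch)
        ys = rng.uniform(y0, y1, batch)
        inside = contains_xy(poly, xs, ys)
        for x, y in zip(xs[inside], ys[inside]):
            if len(pts) >= n:
                break
            gx, gy = int((x - x0) / cell), int((y - y0) / cell)
            ok = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for j in grid.get((gx + dx, gy + dy), ()):
                        px, py = pts[j]
                        if (px - x) ** 2 + (py - y) ** 2 < min_sep_px**2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                grid.setdefault((gx, gy), []).append(len(pts))
                pts.append((x, y))
        attempts += batch
    return np.asarray(pts) if pts else np.empty((0, 2))


def _normalized_depths(points: np.ndarray, region: Region) -> np.ndarray:
    """Perpendicular distance to the basal axis line, normalized by the
    region's maximum extent from that line."""
    (ax0, ay0), (ax1, ay1) = region.basal_axis
    d = np.array([ax1 - ax0, ay1 - ay0])
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError("degenerate basal axis")
    normal = np.array([-d[1], d[0]]) / nrm
    def dist(xy):
        return np.abs((xy - np.array([ax0, ay0])) @ normal)
    depths = dist(points)
    verts = np.array(region.polygon.exterior.coords)
    max_depth = float(dist(verts).max())
    return depths / max_depth if max_depth > 0 else np.zeros(len(points))


def _smooth_field_values(
    points: np.ndarray,
    plan: SlidePlan,
    patch_scale_um: float,
    rng: np.random.Generator,
    coarse_px: int = 8,
) -> np.ndarray:
    """Gaussian-smoothed white noise evaluated at the cell positions."""
    w, h = plan.image_size
    gw = max(2, int(math.ceil(w / coarse_px)))
    gh = max(2, int(math.ceil(h / coarse_px)))
    sigma = max(patch_scale_um / plan.microns_per_pixel / coarse_px, 0.5)
    field = gaussian_filter(rng.standard_normal((gh, gw)), sigma=sigma, mode="wrap")
    ix = np.clip((points[:, 0] / coarse_px).astype(int), 0, gw - 1)
    iy = np.clip((points[:, 1] / coarse_px).astype(int), 0, gh - 1)
    return field[iy, ix]


def _assign_positive_classes(
    n_pos: int, fractions: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """Classes 1..3 for positive cells, proportional to (p1, p2, p3)."""
    p = np.asarray(fractions[1:], float)
    if p.sum() <= 0:
        return np.ones(n_pos, dtype=int)
    return rng.choice([1, 2, 3], size=n_pos, p=p / p.sum())


def _od_for_classes(classes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """True DAB OD uniform inside each class's (margin-guarded) band."""
    t = DEFAULT_THRESHOLDS.as_array()
    edges = np.array([0.0, t[0], t[1], t[2], OD_CEILING])
    lo = edges[classes] + np.where(classes > 0, OD_MARGIN, 0.0)
    hi = edges[classes + 1] - OD_MARGIN
    return rng.uniform(lo, hi)


def sample_cells(
    plan: SlidePlan,
    profiles: Mapping[str, MarkerTissueProfile],
    seed: int | None = None,
    min_separation_um: float = MIN_SEPARATION_UM,
    basal_cutoff: float = BASAL_DEPTH_CUTOFF,
) -> list[GroundTruthCell]:
    """Ground-truth cells for one slide, honoring each region's profile.

    ``profiles`` maps tissue type to its marker profile; every tissue type
    present in the plan must be covered.
    """
    for r in plan.regions:
        if r.tissue_type not in profiles:
            raise KeyError(f"no profile for tissue type {r.tissue_type!r}")
    root = np.random.SeedSequence(plan.seed if seed is None else seed)
    cells: list[GroundTruthCell] = []
    mpp = plan.microns_per_pixel
    for ridx, region in enumerate(plan.regions):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=root.entropy, spawn_key=(ridx,))
        )
        prof = profiles[region.tissue_type]
        area_mm2 = region.polygon.area * mpp**2 / 1e6
        n = int(round(plan.cell_density * area_mm2))
        pts = _hardcore_points(region.polygon, n, min_separation_um / mpp, rng)
        if len(pts) == 0:
            continue
        classes = _classes_for_pattern(pts, prof, region, plan, rng, basal_cutoff)
        ods = _od_for_classes(classes, rng)
        ods[classes == 0] *= 0.0  # negative cells carry no DAB
        for j, ((x, y), c, od) in enumerate(zip(pts, classes, ods)):
            cells.append(
                GroundTruthCell(
                    cell_id=f"{region.region_id}_c{j}",
                    region_id=region.region_id,
                    centroid=(float(x), float(y)),
                    true_class=int(c),
                    true_dab_od=float(od),
                )
            )
    return cells


def _classes_for_pattern(
    pts: np.ndarray,
    prof: MarkerTissueProfile,
    region: Region,
    plan: SlidePlan,
    rng: np.random.Generator,
    basal_cutoff: float,
) -> np.ndarray:
    n = len(pts)
    p = np.asarray(prof.class_fractions, float)
    if prof.pattern == "absent":
        return np.zeros(n, dtype=int)
    if prof.pattern == "homogeneous":
        return rng.choice(4, size=n, p=p / p.sum())
    if prof.pattern == "patchy":
        vals = _smooth_field_values(pts, plan, prof.patch_scale_um, rng)
        classes = np.zeros(n, dtype=int)
        pos_frac = prof.positive_fraction
        if pos_frac > 0:
            thr = np.quantile(vals, 1.0 - pos_frac)
            pos = vals >= thr
            classes[pos] = _assign_positive_classes(int(pos.sum()), p, rng)
        return classes
    if prof.pattern in ("basal_restricted", "gradient"):
        depths = _normalized_depths(pts, region)
        classes = np.zeros(n, dtype=int)
        pos_frac = prof.positive_fraction
        if pos_frac <= 0:
            return classes
        if prof.pattern == "basal_restricted":
            eligible = depths < basal_cutoff
            frac_elig = max(eligible.mean(), 1e-12)
            p_local = min(1.0, pos_frac / frac_elig)
            pos = eligible & (rng.uniform(size=n) < p_local)
        else:  # gradient: positivity decays linearly with depth
            p_depth = np.clip(2.0 * pos_frac * (1.0 - depths), 0.0, 1.0)
            pos = rng.uniform(size=n) < p_depth
        classes[pos] = _assign_positive_classes(int(pos.sum()), p, rng)
        return classes
    raise ValueError(f"unknown pattern {prof.pattern!r}")  # pragma: no cover


def truth_to_frame(cells: Sequence[GroundTruthCell]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "region_id": c.region_id,
                "x_px": c.centroid[0],
                "y_px": c.centroid[1],
                "true_class": c.true_class,
                "true_dab_od": c.true_dab_od,
            }
            for c in cells
        ],
        columns=["cell_id", "region_id", "x_px", "y_px", "true_class", "true_dab_od"],
    )


# ---------------------------------------------------------------------------
# rendering


HEMA_NUCLEUS_OD = 0.7
# DAB paint radius beyond the nucleus radius; deliberately larger than the
# default 5 µm measurement expansion so a measured cell mask never reaches
# unpainted background (ownership of contested pixels matches the
# nearest-nucleus rule used at measurement time).
CELL_PAINT_EXTRA_UM = 8.0


def render_slide(
    plan: SlidePlan,
    cells: Sequence[GroundTruthCell],
    stains: StainMatrix = DEFAULT_STAINS,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Transmitted-light RGB rendering of a planned slide.

    Per pixel the total OD is the hematoxylin nuclear disc profile plus the
    cell's DAB OD (painted over a disc around the nucleus, contested pixels
    owned by the nearest nucleus) plus optional white Gaussian OD noise;
    channel intensity is ``255 * 10**(-OD)`` along each stain's absorbance
    direction, quantized to 8 bits.  Background pixels are white.
    """
    w, h = plan.image_size
    mpp = plan.microns_per_pixel
    hema_od = np.zeros((h, w))
    dab_od = np.zeros((h, w))
    owner_dist = np.full((h, w), np.inf)

    r_paint = (NUCLEUS_RADIUS_UM + CELL_PAINT_EXTRA_UM) / mpp
    rp = int(math.ceil(r_paint)) + 1
    for c in cells:
        x, y = c.centroid
        r_nuc = c.nucleus_radius_um / mpp
        xi, yi = int(round(x)), int(round(y))
        x0, x1 = max(0, xi - rp), min(w, xi + rp + 1)
        y0, y1 = max(0, yi - rp), min(h, yi + rp + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx - x, yy - y)
        take = (dist <= r_paint) & (dist < owner_dist[y0:y1, x0:x1])
        # always write, even 0: a cell's territory must not keep a
        # neighbor's DAB painted in an earlier iteration
        sub = dab_od[y0:y1, x0:x1]
        sub[take] = c.true_dab_od
        owner_sub = owner_dist[y0:y1, x0:x1]
        owner_sub[take] = dist[take]
        # nucleus disc with half-pixel antialias at the rim
        nuc = np.clip(r_nuc + 0.5 - dist, 0.0, 1.0) * HEMA_NUCLEUS_OD
        hema_sub = hema_od[y0:y1, x0:x1]
        np.maximum(hema_sub, nuc, out=hema_sub)

    if noise_sd > 0:
        rng = np.random.default_rng(plan.seed if seed is None else seed)
        hema_od = np.clip(hema_od + rng.normal(0, noise_sd, hema_od.shape), 0, None)
        dab_od = np.clip(dab_od + rng.normal(0, noise_sd, dab_od.shape), 0, None)

    m = stains.matrix  # 3x2
    od_rgb = hema_od[..., None] * m[:, 0] + dab_od[..., None] * m[:, 1]
    rgb = 255.0 * np.power(10.0, -od_rgb)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# calibration


def profile_for_target_hscore(
    target_h: float,
    pattern: str = "homogeneous",
    marker_id: str = "marker",
    tissue_type: str = "healthy",
    patch_scale_um: float = 60.0,
) -> MarkerTissueProfile:
    """Class fractions whose expected H-score equals ``target_h``.

    Among all feasible fraction vectors the maximum-entropy one is returned;
    it has the Gibbs form ``p_k proportional to exp(lam * k)`` with ``lam``
    solved so the mean class is ``target_h / 100``.
    """
    if not 0.0 <= target_h <= 300.0:
        raise ValueError(f"target H-score {target_h} outside [0, 300]")
    m = target_h / 100.0
    if m < 1e-12:
        fr = (1.0, 0.0, 0.0, 0.0)
    elif m > 3.0 - 1e-12:
        fr = (0.0, 0.0, 0.0, 1.0)
    else:
        from scipy.optimize import brentq

        ks = np.arange(4)

        def mean_class(lam: float) -> float:
            wts = np.exp(lam * ks - lam * ks.max() * (lam > 0))
            return float((ks * wts).sum() / wts.sum())

        lam = brentq(lambda L: mean_class(L) - m, -60.0, 60.0, xtol=1e-15, rtol=1e-15)
        wts = np.exp(lam * ks - lam * ks.max() * (lam > 0))
        p = wts / wts.sum()
        fr = tuple(float(x) for x in p)
    prof = MarkerTissueProfile(
        marker_id=marker_id,
        tissue_type=tissue_type,
        class_fractions=fr,
        pattern=pattern,
        patch_scale_um=patch_scale_um,
    )
    if abs(prof.expected_hscore - target_h) > 1e-6:
        raise AssertionError("calibration failed to meet tolerance")
    return prof
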