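"""Generator contracts: cohort layout, determinism, calibration, spatial
patterns and the Beer-Lambert rendering round trip."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from ihcgate import imagequant as iq
from ihcgate import synthslide as ss
from ihcgate.scoring import hscore


def _plan_fingerprint(plan):
    return (
        plan.patient_id,
        plan.seed,
        tuple((r.region_id, r.tissue_type, r.polygon.wkt, r.basal_axis) for r in plan.regions),
    )


class TestPlanCohort:
    def test_default_cohort_has_reported_counts(self):
        plans = ss.plan_cohort(seed=1)
        assert len(plans) == 69
        by_group = {}
        for p in plans:
            g = p.patient_id.rsplit("_", 1)[0]
            by_group[g] = by_group.get(g, 0) + 1
        assert by_group == {
            "healthy": 15,
            "dVIN": 10,
            "VSCC_HPV_independent": 16,
            "HSIL": 15,
            "VSCC_HPV_dependent": 13,
        }
        # reported adjacent-tissue availability: banded = 3 regions
        banded = [p for p in plans if len(p.regions) == 3]
        strata = {"independent": 0, "dependent": 0}
        for p in banded:
            strata[p.hpv_status] += 1
        assert strata == {"independent": 9, "dependent": 10}

    def test_zero_counts_give_empty_cohort(self):
        cfg = ss.CohortConfig(group_counts={"healthy": 0}, adjacent_counts={})
        assert ss.plan_cohort(cfg, seed=1) == []

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ss.CohortConfig(group_counts={"healthy": -1})

    def test_determinism_under_fixed_seed(self):
        cfg = ss.CohortConfig(
            group_counts={"healthy": 2, "dVIN": 1}, adjacent_counts={}
        )
        a = ss.plan_cohort(cfg, seed=7)
        b = ss.plan_cohort(cfg, seed=7)
        assert [_plan_fingerprint(p) for p in a] == [_plan_fingerprint(p) for p in b]

    def test_banded_sections_hold_three_disjoint_tissue_types(self):
        cfg = ss.CohortConfig(
            group_counts={"VSCC_HPV_dependent": 1},
            adjacent_counts={"VSCC_HPV_dependent": 1},
            image_size=(512, 512),
        )
        (plan,) = ss.plan_cohort(cfg, seed=0)
        types = [r.tissue_type for r in plan.regions]
        assert types == ["VSCC_HPV_dependent", "HSIL", "healthy"]
        for i, a in enumerate(plan.regions):
            for b in plan.regions[i + 1 :]:
                assert a.polygon.intersection(b.polygon).area < 1e-9


class TestProfileCalibration:
    @pytest.mark.parametrize(
        "target,expected",
        [(300.0, (0.0, 0.0, 0.0, 1.0)), (0.0, (1.0, 0.0, 0.0, 0.0))],
    )
    def test_extremes_are_forced(self, target, expected):
        assert ss.profile_for_target_hscore(target).class_fractions == expected

    @pytest.mark.parametrize("target", [9, 25, 42, 59, 93, 118, 150, 240, 299.5])
    def test_expected_hscore_hits_target(self, target):
        prof = ss.profile_for_target_hscore(target)
        assert abs(prof.expected_hscore - target) < 1e-6

    def test_max_entropy_tiebreak_is_uniform_at_midpoint(self):
        # mean class 1.5 <-> the unconstrained entropy maximum
        prof = ss.profile_for_target_hscore(150.0)
        assert np.allclose(prof.class_fractions, 0.25, atol=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ss.profile_for_target_hscore(301.0)

    def test_montecarlo_hscore_concentration(self):
        # for calibrated homogeneous profiles, the H-score of 2,000 sampled
        # cells stays within +-10 of the target in >=95% of replicates
        rng = np.random.default_rng(42)
        for target in (42.0, 118.0):
            fr = np.array(ss.profile_for_target_hscore(target).class_fractions)
            hits = 0
            for _ in range(200):
                classes = rng.choice(4, size=2000, p=fr)
                pct = np.bincount(classes, minlength=4) / 2000 * 100
                if abs(hscore(pct) - target) <= 10:
                    hits += 1
            assert hits >= 190


class TestSampleCells:
    def _plain_plan(self, tissue="healthy", size=500, mpp=1.0, density=2000.0):
        cfg = ss.CohortConfig(
            group_counts={tissue: 1},
            adjacent_counts={},
            image_size=(size, size),
            microns_per_pixel=mpp,
            cell_density=density,
            margin_px=8,
        )
        return ss.plan_cohort(cfg, seed=3)[0]

    def test_missing_profile_raises(self):
        plan = self._plain_plan()
        with pytest.raises(KeyError):
            ss.sample_cells(plan, {})

    def test_absent_pattern_all_negative(self):
        plan = self._plain_plan()
        prof = ss.MarkerTissueProfile(
            "m", "healthy", (1.0, 0.0, 0.0, 0.0), pattern="absent"
        )
        cells = ss.sample_cells(plan, {"healthy": prof})
        assert cells and all(c.true_class == 0 for c in cells)

    def test_degenerate_fractions_all_top_class(self):
        plan = self._plain_plan()
        prof = ss.MarkerTissueProfile("m", "healthy", (0.0, 0.0, 0.0, 1.0))
        cells = ss.sample_cells(plan, {"healthy": prof})
        assert len(cells) >= 400
        assert all(c.true_class == 3 for c in cells)

    def test_homogeneous_fractions_obey_law_of_large_numbers(self):
        plan = self._plain_plan(size=1900, density=3000.0)  # ~10,000 cells
        prof = ss.MarkerTissueProfile("m", "healthy", (0.25, 0.25, 0.25, 0.25))
        cells = ss.sample_cells(plan, {"healthy": prof}, seed=3)
        classes = np.array([c.true_class for c in cells])
        assert len(classes) >= 9000
        frac = np.bincount(classes, minlength=4) / len(classes)
        assert np.abs(frac - 0.25).max() < 0.02

    def test_hardcore_minimum_separation(self):
        plan = self._plain_plan(density=3000.0)
        prof = ss.MarkerTissueProfile("m", "healthy", (1.0, 0.0, 0.0, 0.0))
        cells = ss.sample_cells(plan, {"healthy": prof})
        pts = np.array([c.centroid for c in cells])
        d, _ = cKDTree(pts).query(pts, k=2)
        min_sep_px = ss.MIN_SEPARATION_UM / plan.microns_per_pixel
        assert d[:, 1].min() >= min_sep_px - 1e-9

    def test_determinism(self):
        plan = self._plain_plan()
        prof = ss.MarkerTissueProfile("m", "healthy", (0.5, 0.2, 0.2, 0.1))
        a = ss.sample_cells(plan, {"healthy": prof})
        b = ss.sample_cells(plan, {"healthy": prof})
        assert a == b

    def test_true_od_lies_in_class_band(self):
        plan = self._plain_plan()
        prof = ss.MarkerTissueProfile("m", "healthy", (0.25, 0.25, 0.25, 0.25))
        edges = np.array([0.0, 0.2, 0.4, 0.6, ss.OD_CEILING])
        for c in ss.sample_cells(plan, {"healthy": prof}):
            lo, hi = edges[c.true_class], edges[c.true_class + 1]
            if c.true_class == 0:
                assert c.true_dab_od == 0.0
            else:
                assert lo <= c.true_dab_od < hi

    def test_patchy_clusters_more_than_homogeneous(self):
        # join-count statistic on the 6-NN graph: the patchy field must show
        # clearly more positive-positive adjacency at equal class fractions
        from ihcgate.fgsgate import homogeneity_score
        from ihcgate.imagequant import cells_to_frame

        plan = self._plain_plan(size=700, density=3000.0)
        fr = (0.5, 0.5 / 3, 0.5 / 3, 0.5 / 3)
        z = {}
        for pattern in ("homogeneous", "patchy"):
            prof = ss.MarkerTissueProfile(
                "m", "healthy", fr, pattern=pattern, patch_scale_um=60.0
            )
            cells = ss.sample_cells(plan, {"healthy": prof}, seed=11)
            import pandas as pd

            df = pd.DataFrame(
                {
                    "x_px": [c.centroid[0] for c in cells],
                    "y_px": [c.centroid[1] for c in cells],
                    "intensity_class": [c.true_class for c in cells],
                }
            )
            z[pattern] = homogeneity_score(df, seed=1).clustering_index
        assert z["patchy"] > z["homogeneous"] + 3.0

    def test_basal_restricted_positives_stay_below_cutoff(self):
        plan = self._plain_plan()
        prof = ss.MarkerTissueProfile(
            "m", "healthy", (0.7, 0.1, 0.1, 0.1), pattern="basal_restricted"
        )
        cells = ss.sample_cells(plan, {"healthy": prof})
        pts = np.array([c.centroid for c in cells])
        depths = ss._normalized_depths(pts, plan.regions[0])
        pos = np.array([c.true_class >= 1 for c in cells])
        assert pos.any()
        assert depths[pos].max() < ss.BASAL_DEPTH_CUTOFF


class TestRenderSlide:
    def _one_cell_setup(self):
        cfg = ss.CohortConfig(
            group_counts={"healthy": 1},
            adjacent_counts={},
            image_size=(120, 120),
            microns_per_pixel=0.5,
            cell_density=0.0,
            margin_px=5,
        )
        plan = ss.plan_cohort(cfg, seed=0)[0]
        cell = ss.GroundTruthCell(
            cell_id="c0", region_id="r0", centroid=(60.0, 60.0),
            true_class=2, true_dab_od=0.5,
        )
        return plan, cell

    def test_no_cells_renders_white(self):
        plan, _ = self._one_cell_setup()
        img = ss.render_slide(plan, [], noise_sd=0.0)
        assert img.dtype == np.uint8
        assert (img == 255).all()

    def test_forward_inverse_od_round_trip(self):
        # unmixing the rendered pixels must recover the imposed ODs to
        # within the 8-bit quantization bound
        plan, cell = self._one_cell_setup()
        img = ss.render_slide(plan, [cell], noise_sd=0.0)
        od = iq.rgb_to_od(img)
        hema, dab = iq.separate_stains(od)
        # cytoplasmic ring: DAB only
        assert abs(dab[60, 72] - 0.5) < 1e-2
        assert abs(hema[60, 72]) < 1e-2
        # nucleus center: both stains
        assert abs(dab[60, 60] - 0.5) < 1e-2
        assert abs(hema[60, 60] - ss.HEMA_NUCLEUS_OD) < 1e-2
        # background white
        assert od[5, 5].max() == 0.0

    def test_render_determinism_with_noise(self):
        plan, cell = self._one_cell_setup()
        a = ss.render_slide(plan, [cell], noise_sd=0.05, seed=9)
        b = ss.render_slide(plan, [cell], noise_sd=0.05, seed=9)
        assert np.array_equal(a, b)

    def test_degenerate_stain_matrix_rejected(self):
        v = (0.577, 0.577, 0.578)
        with pytest.raises(ValueError):
            iq.StainMatrix.from_unnormalized(v, v)
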