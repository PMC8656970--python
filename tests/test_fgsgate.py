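"""Target-gate logic, the quantitative pattern surrogate, and per-patient
green/orange/red favorability classification."""

import numpy as np
import pandas as pd
import pytest

from ihcgate import fgsgate, reference, synthslide as ss
from ihcgate.scoring import GroupSummary


def _summaries(marker, medians):
    return {
        g: GroupSummary(
            marker_id=marker, tissue_group=g, n_sections=10,
            median_h=float(m), min_h=0.0, max_h=300.0,
        )
        for g, m in medians.items()
    }


def _reference_summaries(marker):
    return _summaries(
        marker, {g: v[0] for g, v in reference.TABLE2[marker].items()}
    )


class TestEvaluateGate:
    def test_reference_cohort_single_candidate(self):
        verdicts = {
            m: fgsgate.evaluate_gate(
                _reference_summaries(m), reference.MARKER_METADATA[m]
            )
            for m in reference.TABLE2
        }
        assert [m for m, v in verdicts.items() if v.candidate] == ["avb6"]

    @pytest.mark.parametrize(
        "marker,failed",
        [
            ("CAIX", "c2"),
            ("EpCAM", "c2"),
            ("MRP1", "c2"),
            ("CD44v6", "c1"),
            ("EGFR", "c1"),
            ("MUC1", "c3"),
            ("uPAR", "c3"),
        ],
    )
    def test_reported_failure_reasons(self, marker, failed):
        v = fgsgate.evaluate_gate(
            _reference_summaries(marker), reference.MARKER_METADATA[marker]
        )
        assert failed in v.failed_criteria()

    def test_cd44v6_fails_only_on_tbr(self):
        v = fgsgate.evaluate_gate(
            _reference_summaries("CD44v6"), reference.MARKER_METADATA["CD44v6"]
        )
        assert v.failed_criteria() == ["c1"]

    def test_stromal_background_also_gates_c1(self):
        meta = fgsgate.MarkerMetadata(
            "m", "membrane", {g: "homogeneous" for g in fgsgate.LESION_GROUPS}
        )
        sums = _summaries(
            "m",
            {
                "healthy": 10,
                "dVIN": 50,
                "VSCC_HPV_independent": 50,
                "HSIL": 50,
                "VSCC_HPV_dependent": 50,
            },
        )
        stroma = GroupSummary(
            marker_id="m", tissue_group="stroma", n_sections=5,
            median_h=30.0, min_h=0.0, max_h=80.0,
        )
        ok = fgsgate.evaluate_gate(sums, meta)
        assert ok.candidate and not ok.stroma_available
        blocked = fgsgate.evaluate_gate(sums, meta, stromal_summary=stroma)
        assert blocked.stroma_available
        assert not blocked.candidate  # 50 < 2 x 30
        assert blocked.failed_criteria() == ["c1"]

    def test_monotonicity_raising_a_median_never_breaks_a_pass(self):
        meta = fgsgate.MarkerMetadata(
            "m", "membrane", {g: "homogeneous" for g in fgsgate.LESION_GROUPS}
        )
        base = {
            "healthy": 10,
            "dVIN": 30,
            "VSCC_HPV_independent": 40,
            "HSIL": 25,
            "VSCC_HPV_dependent": 35,
        }
        v0 = fgsgate.evaluate_gate(_summaries("m", base), meta)
        for g in fgsgate.LESION_GROUPS:
            bumped = dict(base)
            bumped[g] += 50
            v1 = fgsgate.evaluate_gate(_summaries("m", bumped), meta)
            for grp in fgsgate.LESION_GROUPS:
                assert v1.c1_tbr[grp].passed >= v0.c1_tbr[grp].passed
                assert v1.c2_median[grp].passed >= v0.c2_median[grp].passed

    def test_missing_lesion_summary_rejected(self):
        meta = reference.MARKER_METADATA["avb6"]
        sums = _reference_summaries("avb6")
        del sums["HSIL"]
        with pytest.raises(KeyError):
            fgsgate.evaluate_gate(sums, meta)


def _cells_frame(cells):
    return pd.DataFrame(
        {
            "x_px": [c.centroid[0] for c in cells],
            "y_px": [c.centroid[1] for c in cells],
            "intensity_class": [c.true_class for c in cells],
        }
    )


def _plan(size=600, density=3000.0):
    cfg = ss.CohortConfig(
        group_counts={"VSCC_HPV_independent": 1},
        adjacent_counts={},
        image_size=(size, size),
        microns_per_pixel=1.0,
        cell_density=density,
        margin_px=8,
    )
    return ss.plan_cohort(cfg, seed=2)[0]


class TestHomogeneityScore:
    def test_all_negative_is_absent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "x_px": rng.uniform(0, 100, 80),
                "y_px": rng.uniform(0, 100, 80),
                "intensity_class": np.zeros(80, int),
            }
        )
        assert fgsgate.homogeneity_score(df).label == "absent"

    def test_too_few_cells_rejected(self):
        df = pd.DataFrame({"x_px": [0.0], "y_px": [0.0], "intensity_class": [1]})
        with pytest.raises(ValueError):
            fgsgate.homogeneity_score(df)

    def test_iid_positives_labeled_homogeneous(self):
        plan = _plan()
        prof = ss.MarkerTissueProfile(
            "m", "VSCC_HPV_independent", (0.3, 0.3, 0.2, 0.2)
        )
        cells = ss.sample_cells(plan, {"VSCC_HPV_independent": prof}, seed=4)
        res = fgsgate.homogeneity_score(_cells_frame(cells), seed=1)
        assert res.label == "homogeneous"
        assert res.positive_fraction == pytest.approx(0.7, abs=0.05)

    def test_patchy_generator_detected_as_patchy(self):
        # generator/classifier concordance across simulated annotations
        plan = _plan(size=420)
        hits = 0
        n_rep = 30
        for rep in range(n_rep):
            prof = ss.MarkerTissueProfile(
                "m", "VSCC_HPV_independent", (0.3, 0.3, 0.2, 0.2),
                pattern="patchy", patch_scale_um=60.0,
            )
            cells = ss.sample_cells(
                plan, {"VSCC_HPV_independent": prof}, seed=100 + rep
            )
            res = fgsgate.homogeneity_score(_cells_frame(cells), seed=1)
            hits += res.label == "patchy"
        assert hits / n_rep >= 0.9

    def test_depth_restriction_index(self):
        rng = np.random.default_rng(1)
        n = 200
        depth = rng.uniform(0, 1, n)
        cls = (depth < 0.3).astype(int)  # positives only near the basal axis
        df = pd.DataFrame(
            {
                "x_px": rng.uniform(0, 500, n),
                "y_px": depth * 500,
                "intensity_class": cls,
                "depth": depth,
            }
        )
        res = fgsgate.homogeneity_score(df, seed=1)
        assert res.depth_restriction_index < 0.5
        assert res.label == "restricted"


def _profile(patient, status, healthy, pre=None, mal=None):
    mean_h = {"healthy": healthy}
    if pre is not None:
        mean_h["premalignant"] = pre
    if mal is not None:
        mean_h["malignant"] = mal
    return fgsgate.PatientProfile(patient, status, mean_h)


class TestClassifyPatient:
    @pytest.mark.parametrize(
        "pre,mal,label",
        [
            (30, 25, "green"),
            (30, 15, "orange"),
            (8, 9, "red"),
            (15, 12, "unfavorable"),  # ratios in (1, 2], not orange-qualifying
            (None, 25, "green"),
            (None, 9, "red"),
        ],
    )
    def test_rule(self, pre, mal, label):
        p = _profile("p", "independent", 10.0, pre, mal)
        assert fgsgate.classify_patient(p).label == label

    def test_no_lesion_tissue_unclassifiable(self):
        p = _profile("p", "independent", 10.0)
        assert fgsgate.classify_patient(p).label == "unclassifiable"

    def test_missing_healthy_rejected(self):
        p = fgsgate.PatientProfile("p", "independent", {"malignant": 30.0})
        with pytest.raises(ValueError):
            fgsgate.classify_patient(p)

    @pytest.mark.parametrize("c", [0.2, 5.0])
    def test_scale_invariance(self, c):
        base = _profile("p", "dependent", 10.0, 30.0, 15.0)
        scaled = _profile(
            "p", "dependent", 10.0 * c, 30.0 * c, 15.0 * c
        )
        assert (
            fgsgate.classify_patient(base).label
            == fgsgate.classify_patient(scaled).label
        )


class TestFullPipelineGateRecovery:
    """Pixels-to-verdict robustness: a marker simulated with the published
    favorable-target profile must gate in, an inverse-profile marker must
    gate out, across seeded replicates."""

    MARKERS = {
        "avb6": {
            "healthy": 9.0,
            "dVIN": 59.0,
            "VSCC_HPV_independent": 118.0,
            "HSIL": 42.0,
            "VSCC_HPV_dependent": 93.0,
        },
        "cd44v6_like": {
            "healthy": 240.0,
            "dVIN": 248.0,
            "VSCC_HPV_independent": 196.0,
            "HSIL": 223.0,
            "VSCC_HPV_dependent": 118.0,
        },
    }

    def _gate_one(self, marker, targets, seed):
        from ihcgate.io import PipelineConfig
        from ihcgate.pipeline import quantify_slide
        from ihcgate.scoring import score_cells, summarize_sections

        cohort = ss.CohortConfig(
            group_counts={g: 1 for g in targets},
            adjacent_counts={},
            image_size=(300, 300),
            microns_per_pixel=1.0,
            cell_density=3000.0,
            margin_px=8,
        )
        config = PipelineConfig(cohort=cohort, markers={}, seed=seed, noise_sd=0.02)
        summaries = {}
        for plan in ss.plan_cohort(cohort, seed=seed):
            group = plan.regions[0].tissue_type
            prof = ss.profile_for_target_hscore(
                targets[group], tissue_type=group, marker_id=marker
            )
            cells = ss.sample_cells(plan, {group: prof})
            image = ss.render_slide(plan, cells, noise_sd=config.noise_sd)
            anns = [
                {
                    "polygon": plan.regions[0].polygon,
                    "patient_id": plan.patient_id,
                    "region_id": "r0",
                    "tissue_type": group,
                    "hpv_status": plan.hpv_status,
                }
            ]
            frame = quantify_slide(image, anns, config)
            h = score_cells(frame, marker_id=marker)["h_score"].iloc[0]
            summaries[group] = summarize_sections(
                {plan.patient_id: [float(h)]}, group, marker_id=marker
            )
        meta = fgsgate.MarkerMetadata(
            marker, "membrane", {g: "homogeneous" for g in fgsgate.LESION_GROUPS}
        )
        return fgsgate.evaluate_gate(summaries, meta)

    def test_candidate_recovered_in_95pct_of_replicates(self):
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            good = self._gate_one("avb6", self.MARKERS["avb6"], seed=1000 + rep)
            bad = self._gate_one(
                "cd44v6_like", self.MARKERS["cd44v6_like"], seed=1000 + rep
            )
            hits += good.candidate and not bad.candidate
        assert hits >= int(0.95 * n_rep)


class TestCohortFraction:
    def test_reported_counts_reproduce_reported_percentages(self):
        classes = [
            fgsgate.classify_patient(p) for p in reference.fig3_patient_profiles()
        ]
        indep = fgsgate.cohort_fraction(classes, "independent")
        dep = fgsgate.cohort_fraction(classes, "dependent")
        assert (indep.n_green, indep.n_classifiable, indep.percent_display) == (7, 9, 78)
        assert (dep.n_green, dep.n_classifiable, dep.percent_display) == (4, 10, 40)

    def test_zero_green(self):
        classes = [
            fgsgate.classify_patient(_profile(f"p{i}", "dependent", 10.0, 8.0, 7.0))
            for i in range(4)
        ]
        f = fgsgate.cohort_fraction(classes, "dependent")
        assert f.percent_display == 0

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            fgsgate.cohort_fraction([], "independent")
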