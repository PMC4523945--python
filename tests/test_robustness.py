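"""Subgroup stratification, leave-one-out sensitivity, Egger asymmetry."""

import numpy as np
import pytest

from snpmeta.effects import EffectEstimate, estimate_effect
from snpmeta.genetic_models import GeneticModel, build_contrast
from snpmeta.pooling import InsufficientStudiesError, pool_auto
from snpmeta.robustness import egger_test, leave_one_out, subgroup_analysis
from snpmeta.study_data import Dataset, GenotypeCounts, StudyRecord


def _uniform_panel(k):
    """k identical studies with HWE-plausible genotype counts."""
    studies = tuple(
        StudyRecord(f"s{i}", "Asian", "rsX", GenotypeCounts(30, 90, 80), GenotypeCounts(20, 80, 100))
        for i in range(k)
    )
    return Dataset("rsX", "T", "C", studies)


class TestSubgroups:
    def test_ethnicity_partition_is_exact(self, rs12443621):
        rep = subgroup_analysis(rs12443621, "ethnicity", [GeneticModel.ALLELE])
        ks = {lvl: row[GeneticModel.ALLELE].k for lvl, row in rep.rows.items()}
        assert ks == {"Asian": 7, "Caucasian": 6, "African": 2}
        assert sum(ks.values()) == len(rs12443621)

    def test_published_subgroup_allele_ors(self, rs12443621, rs8051542):
        rep4 = subgroup_analysis(rs12443621, "ethnicity", [GeneticModel.ALLELE])
        assert rep4.rows["Asian"][GeneticModel.ALLELE].or_value == pytest.approx(1.000, abs=0.03)
        assert rep4.rows["Caucasian"][GeneticModel.ALLELE].or_value == pytest.approx(1.125, abs=0.03)
        rep5 = subgroup_analysis(rs8051542, "ethnicity", [GeneticModel.ALLELE])
        assert rep5.rows["Asian"][GeneticModel.ALLELE].or_value == pytest.approx(1.148, abs=0.03)

    def test_single_level_grouping_matches_whole_dataset_pool(self, rs8051542):
        uniform = Dataset(
            rs8051542.snp_id,
            rs8051542.risk_allele,
            rs8051542.ref_allele,
            tuple(
                StudyRecord(s.study_id, "All", s.snp_id, s.cases, s.controls)
                for s in rs8051542.studies
            ),
        )
        rep = subgroup_analysis(uniform, "ethnicity", [GeneticModel.ALLELE])
        whole = pool_auto([build_contrast(s, GeneticModel.ALLELE) for s in rs8051542.studies])
        assert rep.rows["All"][GeneticModel.ALLELE].or_value == pytest.approx(
            whole.or_value, rel=1e-12
        )

    def test_single_study_level_is_flagged(self):
        ds = Dataset(
            "rsX",
            "T",
            "C",
            (
                StudyRecord("a", "Asian", "rsX", GenotypeCounts(30, 90, 80), GenotypeCounts(20, 80, 100)),
                StudyRecord("b", "Asian", "rsX", GenotypeCounts(25, 95, 80), GenotypeCounts(22, 78, 100)),
                StudyRecord("c", "African", "rsX", GenotypeCounts(30, 90, 80), GenotypeCounts(20, 80, 100)),
            ),
        )
        rep = subgroup_analysis(ds, "ethnicity", [GeneticModel.DOMINANT])
        assert rep.rows["African"][GeneticModel.DOMINANT].single_study
        assert not rep.rows["Asian"][GeneticModel.DOMINANT].single_study

    def test_unlabeled_studies_are_excluded(self):
        ds = Dataset(
            "rsX",
            "T",
            "C",
            (
                StudyRecord("a", "", "rsX", GenotypeCounts(30, 90, 80), GenotypeCounts(20, 80, 100)),
                StudyRecord("b", "Asian", "rsX", GenotypeCounts(25, 95, 80), GenotypeCounts(22, 78, 100)),
            ),
        )
        rep = subgroup_analysis(ds, "ethnicity", [GeneticModel.ALLELE])
        assert set(rep.rows) == {"Asian"}

    def test_extra_label_stratification(self):
        mk = lambda sid, er: StudyRecord(
            sid, "Asian", "rsX", GenotypeCounts(30, 90, 80), GenotypeCounts(20, 80, 100),
            extra_labels={"er_status": er},
        )
        ds = Dataset("rsX", "T", "C", (mk("a", "ER+"), mk("b", "ER+"), mk("c", "ER-")))
        rep = subgroup_analysis(ds, "er_status", [GeneticModel.ALLELE])
        assert {lvl: r[GeneticModel.ALLELE].k for lvl, r in rep.rows.items()} == {
            "ER+": 2,
            "ER-": 1,
        }


class TestLeaveOneOut:
    def test_identical_studies_yield_identical_omissions(self):
        rep = leave_one_out(_uniform_panel(5), GeneticModel.ALLELE)
        ors = {r.or_value for r in rep.rows.values()}
        assert len(rep.rows) == 5
        assert all(r.k == 4 for r in rep.rows.values())
        assert max(ors) == pytest.approx(min(ors), rel=1e-12)
        assert rep.max_abs_shift == pytest.approx(0.0, abs=1e-12)

    def test_fixture_omissions_stay_within_baseline_ci(self, rs8051542):
        rep = leave_one_out(rs8051542, GeneticModel.ALLELE)
        lo, hi = rep.baseline.ci_low, rep.baseline.ci_high
        assert len(rep.rows) == 15
        for r in rep.rows.values():
            assert lo < r.or_value < hi

    def test_mean_effect_study_is_least_influential(self):
        # five equal-precision studies; the middle one sits at the pooled mean
        studies = []
        for i, shift in enumerate([-10, -5, 0, 5, 10]):
            cases = GenotypeCounts(30 + shift, 90, 80 - shift)
            studies.append(
                StudyRecord(f"s{i}", "X", "rsX", cases, GenotypeCounts(30, 90, 80))
            )
        ds = Dataset("rsX", "T", "C", tuple(studies))
        rep = leave_one_out(ds, GeneticModel.ALLELE)
        shifts = {sid: abs(r.y - rep.baseline.y) for sid, r in rep.rows.items()}
        assert min(shifts, key=shifts.get) == "s2"

    def test_requires_three_studies(self):
        with pytest.raises(InsufficientStudiesError):
            leave_one_out(_uniform_panel(2), GeneticModel.ALLELE)


class TestEgger:
    def test_symmetric_pairs_give_zero_intercept(self):
        effects = []
        for i, se in enumerate([0.1, 0.2, 0.4]):
            effects.append(EffectEstimate(f"p{i}", 0.3, se))
            effects.append(EffectEstimate(f"m{i}", -0.3, se))
        rep = egger_test(effects)
        assert rep.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert len(rep.points) == 6

    def test_matches_statsmodels_ols(self, rs8051542):
        sm = pytest.importorskip("statsmodels.api")
        effects = [
            estimate_effect(build_contrast(s, GeneticModel.ALLELE)) for s in rs8051542.studies
        ]
        rep = egger_test(effects)
        x = np.array([1 / e.se for e in effects])
        z = np.array([e.y / e.se for e in effects])
        fit = sm.OLS(z, sm.add_constant(x)).fit()
        assert rep.egger_intercept == pytest.approx(fit.params[0], rel=1e-10)
        assert rep.egger_se == pytest.approx(fit.bse[0], rel=1e-10)
        assert rep.egger_p == pytest.approx(fit.pvalues[0], rel=1e-10)

    def test_equal_precisions_are_rank_deficient(self):
        effects = [EffectEstimate(f"s{i}", 0.1 * i, 0.2) for i in range(3)]
        with pytest.raises(np.linalg.LinAlgError):
            egger_test(effects)

    def test_requires_three_studies(self):
        with pytest.raises(InsufficientStudiesError):
            egger_test([EffectEstimate("a", 0, 0.1), EffectEstimate("b", 0, 0.2)])

    def test_suppressing_small_negative_studies_skews_intercept_positive(self):
        """Simulated small-study suppression is detected at alpha = 0.1."""
        rng = np.random.default_rng(20240915)
        detected = 0
        reps = 20
        for _ in range(reps):
            ses = np.exp(rng.uniform(np.log(0.05), np.log(0.6), size=40))
            ys = rng.normal(0.0, ses)
            kept = [
                EffectEstimate(f"s{i}", y, se)
                for i, (y, se) in enumerate(zip(ys, ses))
                if se < 0.2 or y > 0  # small studies only published when positive
            ]
            rep = egger_test(kept)
            if rep.egger_intercept > 0 and rep.egger_p < 0.1:
                detected += 1
        assert detected > reps / 2
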