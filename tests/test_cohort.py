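"""Grouping, cut-point search, Cox fits and the spatial-information LRT."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import multivariate_logrank_test

from conftest import make_cell_table
from mifspat import (
    InfeasibleCutpointError,
    MifspatError,
    NonNestedGroupingError,
    abundance,
    assign_group_bivariate,
    assign_group_univariate,
    assign_groups_univariate,
    build_cohort,
    coarsen_bivariate,
    coarsen_univariate,
    fit_cox_groups,
    lrt_spatial_vs_abundance,
    multigroup_logrank,
    optimal_cutpoints_cv,
    predicted_survival_curves,
    simulate_cohort_summary,
)
from mifspat.cohort import candidate_cutpoints, feasible_candidates
from mifspat.synthetic import TRUE_ABUNDANCE_CUT, TRUE_DEGREE_CUT

NULL_LOG_HR = {g: 0.0 for g in ("None", "LL", "LH", "HL", "HH")}


def _grouped_cohort(seed=0, **kwargs):
    cohort, _ = simulate_cohort_summary(seed=seed, **kwargs)
    cohort["group"] = assign_groups_univariate(
        cohort["abundance_pct"], cohort["degree"], TRUE_ABUNDANCE_CUT, TRUE_DEGREE_CUT
    )
    cohort["group_abundance"] = coarsen_univariate(cohort["group"])
    return cohort


class TestAbundance:
    def test_zero_and_fractional(self):
        t0 = make_cell_table(np.zeros((500, 2)), {"CD3": np.zeros(500, int)})
        assert abundance(t0, "CD3") == 0.0
        flags = np.zeros(1000, int)
        flags[:30] = 1
        t1 = make_cell_table(np.zeros((1000, 2)), {"CD3": flags})
        assert abundance(t1, "CD3") == pytest.approx(3.0)


class TestGroupAssignment:
    @pytest.mark.parametrize(
        "ab,deg,expected",
        [
            (0.0, 1e9, "None"),       # zero abundance wins regardless of degree
            (5.0, -100.0, "HL"),
            (5.0, 900.0, "HH"),
            (1.0, 900.0, "LH"),
            (1.0, -5.0, "LL"),
            (2.0, 0.0, "HL"),          # abundance exactly at cut goes High
            (5.0, 500.0, "HH"),        # degree exactly at cut goes High
            (5.0, np.nan, "HL"),       # single positive cell: Low clustering
        ],
    )
    def test_univariate_rules(self, ab, deg, expected):
        assert assign_group_univariate(ab, deg, (2.0, 500.0)) == expected

    @pytest.mark.parametrize(
        "n1,n2,deg,expected",
        [
            (0, 0, np.nan, "AAN"),
            (0, 5, np.nan, "APN"),
            (3, 0, np.nan, "PAN"),
            (3, 4, 900.0, "PPH"),
            (3, 4, 100.0, "PPL"),
            (1, 1, 600.0, "PPH"),  # present with a single cell of each type
        ],
    )
    def test_bivariate_rules(self, n1, n2, deg, expected):
        assert assign_group_bivariate(n1, n2, deg, 500.0) == expected

    def test_labels_partition_samples(self):
        cohort = _grouped_cohort(seed=3)
        counts = cohort["group"].value_counts()
        assert counts.sum() == len(cohort)
        assert set(counts.index) <= {"None", "LL", "LH", "HL", "HH"}

    def test_coarsening_consistency(self):
        cohort = _grouped_cohort(seed=4)
        merged = coarsen_univariate(cohort["group"])
        expected = np.where(
            cohort["group"] == "None", "None", np.where(cohort["group"].str.startswith("H"), "High", "Low")
        )
        np.testing.assert_array_equal(merged, expected)
        np.testing.assert_array_equal(
            coarsen_bivariate(["AAN", "PPL", "PPH"]), ["AAN", "PP", "PP"]
        )


class TestLogrank:
    def test_matches_lifelines_on_small_instances(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 20))
            time = rng.exponential(10, n)
            event = rng.integers(0, 2, n)
            group = rng.integers(0, 3, n)
            if event.sum() == 0 or len(np.unique(group)) < 2:
                continue
            chi2, df, p = multigroup_logrank(time, event, group)
            ref = multivariate_logrank_test(time, group, event)
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)


class TestCutpoints:
    def test_candidate_grid_is_midpoints(self):
        c = candidate_cutpoints([1.0, 2.0, 4.0])
        np.testing.assert_allclose(c, [1.5, 3.0])

    def test_constraint_never_admits_small_groups(self, rng):
        """Exhaustive fuzz: every feasible candidate keeps all four groups >= min."""
        for _ in range(30):
            n = int(rng.integers(60, 140))
            ab = rng.uniform(0, 6, n) * rng.integers(0, 2, n)  # some zeros
            de = rng.normal(300, 400, n)
            a_c = candidate_cutpoints(ab[ab > 0], max_candidates=12)
            d_c = candidate_cutpoints(de[ab > 0], max_candidates=12)
            if a_c.size == 0 or d_c.size == 0:
                continue
            ok = feasible_candidates(ab, de, a_c, d_c, min_group=10)
            for ia in range(len(a_c)):
                for id_ in range(len(d_c)):
                    labels = assign_groups_univariate(ab, de, a_c[ia], d_c[id_])
                    counts = pd.Series(labels)[ab > 0].value_counts()
                    min_count = min(counts.get(g, 0) for g in ("LL", "LH", "HL", "HH"))
                    assert ok[ia, id_] == (min_count >= 10)

    def test_infeasible_cohort_raises_naming_constraint(self):
        cohort = _grouped_cohort(seed=5, n_subjects=12, samples_per_subject=1)
        with pytest.raises(InfeasibleCutpointError, match="nonzero-abundance"):
            optimal_cutpoints_cv(cohort, min_group=10)

    def test_same_seed_same_cuts_and_order_invariance(self):
        cohort = _grouped_cohort(seed=6, n_subjects=60, samples_per_subject=2)
        a = optimal_cutpoints_cv(cohort, k_folds=4, min_group=5, seed=2)
        b = optimal_cutpoints_cv(cohort.sample(frac=1.0, random_state=0), k_folds=4, min_group=5, seed=2)
        assert (a.abundance_cut, a.degree_cut) == (b.abundance_cut, b.degree_cut)
        assert len(a.per_fold_optima) == 4

    def test_trace_respects_constraint(self):
        cohort = _grouped_cohort(seed=7, n_subjects=60, samples_per_subject=2)
        res = optimal_cutpoints_cv(cohort, k_folds=3, min_group=5, seed=1)
        # re-check every traced candidate on its fold's training data
        rng = np.random.default_rng(1)
        subjects = np.array(sorted(cohort["subject_id"].astype(str).unique()))
        folds = np.array_split(rng.permutation(subjects), 3)
        for f, held in enumerate(folds):
            train = cohort[~cohort["subject_id"].isin(held)]
            sub = res.trace[res.trace["fold"] == f]
            for _, row in sub.sample(min(len(sub), 20), random_state=0).iterrows():
                labels = assign_groups_univariate(
                    train["abundance_pct"], train["degree"], row["abundance_cut"], row["degree_cut"]
                )
                counts = pd.Series(labels)[train["abundance_pct"].to_numpy() > 0].value_counts()
                assert min(counts.get(g, 0) for g in ("LL", "LH", "HL", "HH")) >= 5

    def test_recovers_generating_cuts_functionally(self):
        """Strong effects: recovered cuts reproduce the generating labels."""
        strong = {"None": 0.0, "LL": -0.6, "LH": -3.0, "HL": -5.0, "HH": -1.8}
        hits = 0
        for s in range(5):
            cohort, _ = simulate_cohort_summary(
                seed=300 + s, log_hr=strong, n_subjects=300, samples_per_subject=1
            )
            res = optimal_cutpoints_cv(cohort, seed=s)
            labels = assign_groups_univariate(
                cohort["abundance_pct"], cohort["degree"], res.abundance_cut, res.degree_cut
            )
            hits += (labels == cohort["true_group"]).mean() >= 0.95
        assert hits >= 4


class TestCox:
    def test_reference_group_unit_hazard(self):
        cohort = _grouped_cohort(seed=8)
        fit = fit_cox_groups(cohort, "group", reference="None")
        ref = fit.summary[fit.summary["group"] == "None"].iloc[0]
        assert ref["hr"] == 1.0
        others = fit.summary[fit.summary["group"] != "None"]
        assert ((others["ci_low"] <= others["hr"]) & (others["hr"] <= others["ci_high"])).all()
        assert (others["hr"] > 0).all()
        assert fit.overall_df == 4

    def test_single_group_errors(self):
        cohort = _grouped_cohort(seed=9)
        cohort["group"] = "HL"
        with pytest.raises(MifspatError):
            fit_cox_groups(cohort, "group", reference="HL")

    def test_missing_reference_errors(self):
        cohort = _grouped_cohort(seed=10)
        cohort = cohort[cohort["group"] != "None"]
        with pytest.raises(MifspatError, match="reference"):
            fit_cox_groups(cohort, "group", reference="None")

    def test_robust_interval_wider_than_naive_with_repeats(self):
        cohort = _grouped_cohort(seed=11)
        rob = fit_cox_groups(cohort, "group", reference="None", robust=True)
        naive = fit_cox_groups(cohort, "group", reference="None", robust=False)
        width = lambda f: (np.log(f.summary["ci_high"]) - np.log(f.summary["ci_low"])).dropna().mean()
        assert width(rob) > width(naive)
        # coefficients are identical; only the variance changes
        np.testing.assert_allclose(rob.summary["hr"].to_numpy(), naive.summary["hr"].to_numpy(), rtol=1e-8)

    def test_survival_curves_long_format(self):
        cohort = _grouped_cohort(seed=12)
        fit = fit_cox_groups(cohort, "group", reference="None")
        curves = predicted_survival_curves(fit, cohort)
        assert set(curves.columns) == {"group", "time", "survival"}
        assert set(curves["group"]) == set(cohort["group"].unique())
        assert curves["survival"].between(0, 1).all()


class TestLRT:
    def test_identical_groupings_give_p_one(self):
        cohort = _grouped_cohort(seed=13)
        cohort["group3"] = coarsen_univariate(cohort["group"])
        cohort["group3b"] = cohort["group3"]
        res = lrt_spatial_vs_abundance(cohort, "group3", "group3b")
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == 1.0
        assert res.df == 0

    def test_univariate_df_is_two(self):
        cohort = _grouped_cohort(seed=14)
        res = lrt_spatial_vs_abundance(cohort)
        assert res.df == 2
        assert 0 <= res.p_value <= 1
        assert res.log_likelihood_full >= res.log_likelihood_reduced - 1e-9

    def test_non_nested_labelings_rejected(self):
        cohort = _grouped_cohort(seed=15)
        rng = np.random.default_rng(0)
        cohort["bad"] = rng.choice(["Low", "High"], size=len(cohort))
        with pytest.raises(NonNestedGroupingError):
            lrt_spatial_vs_abundance(cohort, "group", "bad")


class TestBuildCohort:
    def test_join_and_validation(self):
        degree_df = pd.DataFrame(
            {"sample_id": ["a", "b"], "subject_id": ["P1", "P1"], "abundance_pct": [1.0, 3.0], "degree": [0.0, 700.0]}
        )
        clinical = pd.DataFrame(
            {"subject_id": ["P1"], "time_months": [20.0], "event": [1], "age_dx": [60.0], "stage": ["III"]}
        )
        cohort = build_cohort(degree_df, clinical)
        assert len(cohort) == 2
        assert (cohort["time_months"] == 20.0).all()
        with pytest.raises(MifspatError):
            build_cohort(degree_df.assign(subject_id=["P1", "P9"]), clinical)
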