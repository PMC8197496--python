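"""Altered-status rule, Cox fitting, Wilcoxon gate and the stage-2 screen."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gecna import (ClinicalTable, CnaMatrix, MutationTable, SyntheticConfig,
                   compute_altered_status, compute_burden,
                   expression_difference_test, fit_cox, generate, run_screen,
                   run_survival_screen, select_covariates)
from gecna.validation import _child_seeds, simulate_survival_cohort


def _cna(calls: dict[str, list], subjects: list[str]) -> CnaMatrix:
    return CnaMatrix(pd.DataFrame.from_dict(calls, orient="index",
                                            columns=subjects, dtype=float))


def _muts(pairs) -> MutationTable:
    return MutationTable(pd.DataFrame(
        [{"gene_id": g, "subject_id": s, "variant_classification": "Missense"}
         for g, s in pairs], columns=["gene_id", "subject_id",
                                      "variant_classification"]))


class TestAlteredStatus:
    SUBJECTS = ["S1", "S2", "S3", "S4"]

    def test_high_level_and_mutation_rules(self):
        cna = _cna({"G1": [2, 1, 0, -2]}, self.SUBJECTS)
        mut = _muts([("G1", "S3")])
        st = compute_altered_status("G1", cna, mut)
        assert list(st.altered) == [True, False, True, True]
        assert (st.n_altered, st.n_unaltered) == (3, 1)

    def test_low_level_call_without_mutation_is_unaltered(self):
        cna = _cna({"G1": [1, -1, 0, 0]}, self.SUBJECTS)
        st = compute_altered_status("G1", cna, _muts([]))
        assert st.n_altered == 0

    def test_missing_call_is_unaltered(self):
        cna = _cna({"G1": [np.nan, 2, 0, 0]}, self.SUBJECTS)
        st = compute_altered_status("G1", cna, _muts([]))
        assert list(st.altered) == [False, True, False, False]

    def test_absent_gene_is_error(self):
        cna = _cna({"G1": [0, 0, 0, 0]}, self.SUBJECTS)
        with pytest.raises(KeyError):
            compute_altered_status("G2", cna, _muts([]))

    def test_promoting_call_to_high_level_grows_altered_set(self):
        rng = np.random.default_rng(6)
        subjects = [f"S{i}" for i in range(30)]
        base = rng.choice([-2, -1, 0, 1, 2], size=30).astype(float)
        cna = _cna({"G1": base}, subjects)
        before = set(compute_altered_status("G1", cna, _muts([])).altered.pipe(
            lambda s: s[s].index))
        promotable = np.flatnonzero(np.abs(base) == 1)
        bumped = base.copy()
        bumped[promotable] = np.sign(bumped[promotable]) * 2
        after = set(compute_altered_status("G1", _cna({"G1": bumped}, subjects),
                                           _muts([])).altered.pipe(lambda s: s[s].index))
        assert before <= after


class TestSelectCovariates:
    def test_planted_age_and_stage_recovered_race_excluded(self):
        hits = {"age": 0, "race2": 0, "stage4": 0}
        for seed in _child_seeds(101, 20):
            ds = generate(SyntheticConfig(seed=seed, n_subjects=500,
                                          survival_log_hrs=()))
            for c in select_covariates(ds.clinical):
                hits[c] += 1
        assert hits["age"] >= 16 and hits["stage4"] >= 16
        assert hits["race2"] <= 4

    def test_null_covariates_selected_at_alpha_rate(self):
        hits = {"age": 0, "race2": 0, "stage4": 0}
        for seed in _child_seeds(202, 20):
            ds = generate(SyntheticConfig(seed=seed, n_subjects=500,
                                          survival_log_hrs=(), age_log_hr=0.0,
                                          stage_log_hr=0.0))
            for c in select_covariates(ds.clinical):
                hits[c] += 1
        for c, n in hits.items():  # Bin(20, 0.05): P(>4) < 0.003
            assert n <= 4, (c, n)

    def test_constant_age_unselectable(self):
        ds = generate(SyntheticConfig(seed=3, n_subjects=200, survival_log_hrs=()))
        clin = ClinicalTable(ds.clinical.data.assign(age=60.0))
        assert "age" not in select_covariates(clin)


class TestFitCox:
    def test_scale_invariance(self):
        time, event, altered = simulate_survival_cohort(300, math.log(2), 0.3, seed=4)
        a = fit_cox(time, event, altered)
        b = fit_cox(time * 7.3, event, altered)
        assert a.hazard_ratio == pytest.approx(b.hazard_ratio, rel=1e-6)
        assert a.hr_p_value == pytest.approx(b.hr_p_value, rel=1e-6)

    def test_null_alteration_wald_calibration(self):
        """Altered status independent of survival: Wald p approximately
        uniform, type-I error at 0.05 within [0.04, 0.06] (1,000 cohorts)."""
        rng = np.random.default_rng(77)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            time, event, _ = simulate_survival_cohort(
                120, 0.0, 0.3, seed=int(rng.integers(2**31)))
            altered = (rng.random(120) < 0.3).astype(float)
            res = fit_cox(time, event, altered)
            if not res.degenerate and res.hr_p_value < 0.05:
                rejections += 1
        assert 0.04 <= rejections / n_rep <= 0.06

    def test_all_events_one_side_flagged(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        altered = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        res = fit_cox(time, event, altered)
        assert res.degenerate

    def test_single_censored_altered_subject_flagged(self):
        time = np.array([0.01, 5.0, 7.0, 9.0, 11.0])
        event = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
        altered = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        assert fit_cox(time, event, altered).degenerate

    def test_no_events_is_error(self):
        with pytest.raises(ValueError, match="no events"):
            fit_cox([1.0, 2.0], [0.0, 0.0], [1.0, 0.0])


def exact_rank_sum_p(a, b):
    """Independent oracle: exact two-sided rank-sum p by enumerating every
    assignment of the pooled ranks to the first group."""
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1  # tie-free inputs only
    n1 = len(a)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestExpressionDifference:
    def test_fully_separated_three_vs_three(self):
        expr = pd.Series([5.0, 6, 7, 1, 2, 3], index=list("abcdef"))
        altered = pd.Series([True, True, True, False, False, False],
                            index=list("abcdef"))
        p, direction = expression_difference_test(expr, altered)
        assert p == pytest.approx(0.1)
        assert direction == "over"

    def test_exact_matches_rank_enumeration(self):
        rng = np.random.default_rng(11)
        for n1, n2 in [(3, 5), (4, 4), (5, 8), (8, 6)]:
            a, b = rng.normal(size=n1), rng.normal(0.8, 1, size=n2)
            expr = pd.Series(np.concatenate([a, b]),
                             index=[f"s{i}" for i in range(n1 + n2)])
            altered = pd.Series([True] * n1 + [False] * n2, index=expr.index)
            p, _ = expression_difference_test(expr, altered)
            assert p == pytest.approx(exact_rank_sum_p(a, b), rel=1e-9)

    def test_all_missing_group_gives_missing_p(self):
        expr = pd.Series([np.nan, np.nan, 1.0, 2.0], index=list("abcd"))
        altered = pd.Series([True, True, False, False], index=list("abcd"))
        p, direction = expression_difference_test(expr, altered)
        assert np.isnan(p) and direction == "none"

    def test_under_direction(self):
        expr = pd.Series(np.r_[np.zeros(10) - 2, np.zeros(30)],
                         index=[f"s{i}" for i in range(40)])
        altered = pd.Series([True] * 10 + [False] * 30, index=expr.index)
        _, direction = expression_difference_test(expr, altered)
        assert direction == "under"


@pytest.fixture(scope="module")
def survival_run():
    cfg = SyntheticConfig(seed=42, n_subjects=400)
    ds = generate(cfg)
    res = run_screen(ds.expression, compute_burden(ds.cna))
    table, summary = run_survival_screen(
        res.classification, ds.cna, ds.mutations, ds.clinical, ds.expression)
    return ds, table, summary


class TestRunSurvivalScreen:
    def test_protective_gene_keeps_hr_below_1(self, survival_run):
        ds, table, _ = survival_run
        truth = ds.truth
        protective = truth.loc[truth["log_hr"] < 0, "gene_id"]
        rows = table[table["gene_id"].isin(protective) & ~table["degenerate"]]
        assert len(rows) > 0
        assert (rows["hazard_ratio"] < 1).all()

    def test_hr_partition_exhaustive(self, survival_run):
        _, table, summary = survival_run
        passing = table[table["passes_screen"]]
        assert summary["n_hr_gt_1"] + summary["n_hr_lt_1"] == len(
            passing[passing["hazard_ratio"] != 1.0])

    def test_source_lists_annotated(self, survival_run):
        _, table, _ = survival_run
        assert (table["source_lists"].str.len() > 0).all()

    def test_null_survival_coupling_rarely_passes(self):
        """With no planted survival effect the two independent 0.05 gates
        pass together at ~0.0025 per candidate."""
        total_pass = total_cand = 0
        for seed in _child_seeds(303, 2):
            ds = generate(SyntheticConfig(seed=seed, survival_log_hrs=()))
            res = run_screen(ds.expression, compute_burden(ds.cna))
            table, summary = run_survival_screen(
                res.classification, ds.cna, ds.mutations, ds.clinical,
                ds.expression)
            total_pass += summary["n_passing"]
            total_cand += summary["n_candidates"]
        assert total_cand > 0
        assert total_pass <= max(4, 0.05 * total_cand)
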