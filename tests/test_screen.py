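"""Extreme-group selection, the pooled t-test, q-values and the screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gecna import (BurdenProfile, ExpressionMatrix, SyntheticConfig,
                   compute_burden, compute_qvalues, generate, run_screen,
                   select_extreme_groups, storey_pi0)
from gecna import test_gene as pooled_t  # alias: keep pytest from collecting it


class TestSelectExtremeGroups:
    def test_distinct_values_take_rank_tails(self):
        vals = pd.Series(np.arange(25.0), index=[f"S{i:02d}" for i in range(25)])
        high, low = select_extreme_groups(vals, k=10)
        assert low == [f"S{i:02d}" for i in range(10)]
        assert high == [f"S{i:02d}" for i in range(15, 25)]
        assert not set(high) & set(low)

    def test_boundary_tie_broken_by_subject_id(self):
        # ranks 10 and 11 share the value 5.0 -> lower subject id goes low
        vals = pd.Series([0, 1, 2, 3, 4, 5.0, 5.0, 6, 7, 8, 9, 10],
                         index=[f"S{i:02d}" for i in range(12)])
        high, low = select_extreme_groups(vals, k=6)
        assert "S05" in low and "S06" in high
        # permuting input order changes nothing
        perm = vals.sample(frac=1.0, random_state=1)
        assert select_extreme_groups(perm, k=6) == (high, low)

    def test_all_equal_values_still_size_k(self):
        vals = pd.Series(np.ones(20), index=[f"S{i:02d}" for i in range(20)])
        high, low = select_extreme_groups(vals, k=10)
        assert len(high) == len(low) == 10

    def test_too_few_values_raises(self):
        vals = pd.Series([1.0, 2.0, np.nan] * 6, index=[f"S{i}" for i in range(18)])
        with pytest.raises(ValueError, match="non-missing"):
            select_extreme_groups(vals, k=10)


class TestStudentT:
    def test_closed_form_two_vs_two(self):
        # means 3 vs 2, pooled variance 2, df 2 -> t = 1/sqrt(2)
        t, p, mh, ml = pooled_t([2.0, 4.0], [1.0, 3.0])
        assert t == pytest.approx(1.0 / np.sqrt(2.0))
        assert (mh, ml) == (3.0, 2.0)
        # exact df=2 tail: p = 1 - t/sqrt(2 + t^2)
        assert p == pytest.approx(0.5527864045000421, rel=1e-12)

    def test_identical_constant_groups(self):
        t, p, *_ = pooled_t([5.0] * 10, [5.0] * 10)
        assert (t, p) == (0.0, 1.0)

    def test_zero_variance_unequal_means_is_degenerate(self):
        t, p, *_ = pooled_t([5.0] * 10, [4.0] * 10)
        assert np.isinf(t) and p == 0.0

    def test_too_small_groups_unusable(self):
        t, p, *_ = pooled_t([1.0], [0.0, 2.0])
        assert np.isnan(p)

    def test_matches_scipy_on_random_groups(self):
        from scipy import stats
        rng = np.random.default_rng(4)
        for _ in range(25):
            a, b = rng.normal(size=9), rng.normal(1, 2, size=12)
            t, p, *_ = pooled_t(np.concatenate([a, [np.nan] * 3]), b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)


class TestQValues:
    def test_bh_hand_example(self):
        q = compute_qvalues([0.01, 0.02, 0.03, 0.04], method="bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert (compute_qvalues([1.0] * 50) == 1.0).all()

    def test_empty_input(self):
        assert compute_qvalues([]).size == 0

    def test_pi0_on_uniform_pvalues(self):
        rng = np.random.default_rng(8)
        p = rng.random(20_000)
        assert 0.9 <= storey_pi0(p) <= 1.1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_qvalues([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=300),
           st.sampled_from(["storey", "bh"]))
    def test_q_monotone_in_p(self, pvals, method):
        p = np.asarray(pvals)
        q = compute_qvalues(p, method=method)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()


def _profile_from_amp(amp, subjects):
    amp = np.asarray(amp, dtype=int)
    return BurdenProfile(pd.DataFrame(
        {"total": amp, "amp": amp, "del": 0, "n_evaluated": amp.max() + 1},
        index=pd.Index(subjects, name="subject_id")))


class TestRunScreen:
    def test_constructed_facilitator_example(self):
        """A gene whose top-10 expressors carry visibly more CNA is classified
        as a facilitator, mirroring the worked MMP13-style selection."""
        rng = np.random.default_rng(0)
        subjects = [f"S{i:02d}" for i in range(30)]
        expr = pd.DataFrame(rng.standard_normal((5, 30)),
                            index=[f"N{i}" for i in range(5)], columns=subjects)
        expr.loc["MMP13L"] = np.arange(30.0)  # expression ranks = subject order
        amp = np.concatenate([rng.poisson(20, 20), rng.poisson(80, 10)])
        res = run_screen(ExpressionMatrix(expr), _profile_from_amp(amp, subjects),
                         channels=("amp",), q_method="bh")
        rec = res.records.set_index("gene_id").loc["MMP13L"]
        assert rec["direction"] == "facilitator"
        assert rec["mean_high"] > rec["mean_low"]
        assert "MMP13L" in res.classification.amp_facilitators

    def test_all_missing_genes_excluded_and_counted(self, default_dataset,
                                                    default_screen):
        excluded = default_screen.excluded
        n_all_missing = (excluded["reason"] == "all_missing").sum()
        assert n_all_missing == len(default_dataset.expression.all_missing_genes())
        tested = set(default_screen.records["gene_id"])
        assert not tested & set(excluded["gene_id"])

    def test_record_shape_and_invariants(self, default_screen):
        rec = default_screen.records
        assert set(rec["channel"]) == {"total", "amp", "del"}
        ok = rec["p_value"].notna()
        assert rec.loc[ok, "p_value"].between(0, 1).all()
        assert rec.loc[ok, "q_value"].between(0, 1).all()
        assert (rec["n_high_used"] <= 10).all() and (rec["n_low_used"] <= 10).all()
        sign = np.sign(rec["mean_high"] - rec["mean_low"])
        fac = rec["direction"] == "facilitator"
        sup = rec["direction"] == "suppressor"
        assert (sign[fac] > 0).all() and (sign[sup] < 0).all()

    def test_classification_lists_disjoint_by_channel(self, default_screen):
        default_screen.classification.validate()  # raises on overlap

    def test_gene_order_does_not_matter(self, small_dataset):
        prof = compute_burden(small_dataset.cna)
        res1 = run_screen(small_dataset.expression, prof)
        shuffled = small_dataset.expression.values.sample(frac=1.0, random_state=3)
        res2 = run_screen(ExpressionMatrix(shuffled), prof)
        pd.testing.assert_frame_equal(res1.records, res2.records)
        assert res1.classification.as_dict() == res2.classification.as_dict()

    def test_directional_antisymmetry(self):
        """Negating the planted coupling swaps facilitator and suppressor lists."""
        cfg = dict(n_genes=800, n_subjects=200, n_amp_facilitators=12,
                   n_del_facilitators=12, n_amp_suppressors=12,
                   n_del_suppressors=12, survival_log_hrs=(), seed=13)
        pos = generate(SyntheticConfig(effect_beta=0.6, **cfg))
        neg = generate(SyntheticConfig(effect_beta=-0.6, **cfg))
        res = run_screen(neg.expression, compute_burden(neg.cna))
        truth = neg.truth
        amp_fac = set(truth.loc[truth["role"] == "amp_facilitator", "gene_id"])
        # planted 'facilitators' with negative coupling surface as suppressors
        assert len(amp_fac & set(res.classification.amp_suppressors)) >= 9
        assert not amp_fac & set(res.classification.amp_facilitators)
        # and the positive-coupling cohort puts the same roles in (iii)
        res_pos = run_screen(pos.expression, compute_burden(pos.cna))
        assert len(amp_fac & set(res_pos.classification.amp_facilitators)) >= 9

    def test_no_common_subjects_is_error(self, small_dataset):
        prof = compute_burden(small_dataset.cna)
        renamed = small_dataset.expression.values.copy()
        renamed.columns = [f"X{i}" for i in range(renamed.shape[1])]
        with pytest.raises(ValueError, match="common subjects"):
            run_screen(ExpressionMatrix(renamed), prof)
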