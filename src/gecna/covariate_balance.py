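"""Confounding check: are a gene's 20 extreme expressors clinically typical?

For each screened gene, the 2k subjects whose extreme expression defined the
screen groups ("included") are compared against the remaining subjects
("control") on three covariates: tumor stage (Fisher-Freeman-Halton exact
test on the 2 x 4 included/control x stage table), gender (Pearson
chi-squared without continuity correction on the 2 x 2 table) and age
(two-sample Student t-test).  Each covariate's p-value family across genes
is adjusted to q-values.  Subjects missing a covariate are dropped from that
covariate's test only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .gecna_screen import ScreenResult, compute_qvalues, student_t_test
from .io_cbioportal import ClinicalTable

logger = logging.getLogger(__name__)

#: Monte-Carlo fallback settings for the exact test
MC_PERMUTATIONS = 100_000
MC_SEED = 20210525
#: enumeration budget: product of free-cell ranges
ENUMERATION_BUDGET = 2_000_000


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_2xc(table: np.ndarray,
                     enumeration_budget: int = ENUMERATION_BUDGET,
                     mc_permutations: int = MC_PERMUTATIONS,
                     mc_seed: int = MC_SEED) -> float:
    """Two-sided Fisher-Freeman-Halton exact test for a 2 x c table.

    The two-sided p-value is the total probability, under the multivariate
    hypergeometric null with the observed margins, of tables no more
    probable than the observed one.  All tables are enumerated when the
    free-cell grid fits the budget (always true for the screen's 2 x 4
    tables with an included margin of 2k); otherwise a seeded Monte-Carlo
    estimate over ``mc_permutations`` margin-preserving draws is returned.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x c table")
    if (table < 0).any():
        raise ValueError("negative cell count")
    cols = table.sum(axis=0)
    keep = cols > 0
    table, cols = table[:, keep], cols[keep]
    n1 = int(table[0].sum())
    N = int(table.sum())
    c = table.shape[1]
    if N == 0 or n1 == 0 or n1 == N or c < 2:
        return 1.0

    denom = _log_binom(N, n1)
    logp_obs = float(_log_binom(cols, table[0]).sum() - denom)
    tol = 1e-7 * abs(logp_obs) + 1e-12

    grid_size = int(np.prod([min(int(cj), n1) + 1 for cj in cols[:-1]]))
    if grid_size <= enumeration_budget:
        ranges = [range(min(int(cj), n1) + 1) for cj in cols[:-1]]
        free = np.array(list(itertools.product(*ranges)), dtype=int)
        last = n1 - free.sum(axis=1)
        valid = (last >= 0) & (last <= cols[-1])
        free, last = free[valid], last[valid]
        logp = (_log_binom(cols[:-1], free).sum(axis=1)
                + _log_binom(cols[-1], last) - denom)
        return float(min(1.0, np.exp(logp[logp <= logp_obs + tol]).sum()))

    rng = np.random.default_rng(mc_seed)
    draws = rng.multivariate_hypergeometric(cols, n1, size=mc_permutations)
    logp = _log_binom(cols, draws).sum(axis=1) - denom
    return float(min(1.0, np.mean(logp <= logp_obs + tol)))


@dataclass
class BalanceRecord:
    gene_id: str
    p_stage: float
    p_gender: float
    p_age: float


def balance_test(included: set[str], clinical: ClinicalTable) -> BalanceRecord:
    """Stage/gender/age balance tests for one gene's included subjects."""
    clin = clinical.data
    member = clin.index.to_series().isin(included)

    # stage: 2 x 4 exact test
    stage = clin["stage4"]
    ok = stage.notna()
    p_stage = np.nan
    if ok.any() and member[ok].any() and (~member[ok]).any():
        tab = np.zeros((2, 4), dtype=int)
        for row, grp_mask in enumerate((member, ~member)):
            counts = stage[ok & grp_mask].value_counts()
            for level in (1, 2, 3, 4):
                tab[row, level - 1] = int(counts.get(float(level), 0))
        p_stage = fisher_exact_2xc(tab)
    else:
        logger.warning("balance_test: empty stage margin, p_stage missing")

    # gender: 2 x 2 chi-squared, no continuity correction
    sex = clin["sex"]
    ok = sex.notna()
    p_gender = np.nan
    tab = pd.crosstab(member[ok], sex[ok])
    if tab.shape == (2, 2) and (tab.to_numpy().sum(axis=0) > 0).all():
        with np.errstate(invalid="ignore"):
            chi2, p_gender, _, expected = stats.chi2_contingency(
                tab.to_numpy(), correction=False)
        if (expected < 5).any():
            logger.warning("balance_test: chi-squared cell expectation < 5")
        p_gender = float(p_gender)
    else:
        logger.warning("balance_test: degenerate gender table, p_gender missing")

    # age: two-sample Student t
    age = clin["age"]
    ok = age.notna()
    a_in = age[ok & member].to_numpy(float)
    a_out = age[ok & ~member].to_numpy(float)
    p_age = np.nan
    if len(a_in) >= 2 and len(a_out) >= 2:
        n = max(len(a_in), len(a_out))
        pad = lambda a: np.concatenate([a, np.full(n - len(a), np.nan)])  # noqa: E731
        _, p_age, *_ = student_t_test(pad(a_in), pad(a_out))
    return BalanceRecord("", p_stage, p_gender, p_age)


def run_balance(screen: ScreenResult, clinical: ClinicalTable,
                genes: list[str] | None = None,
                q_method: str = "storey") -> pd.DataFrame:
    """Balance tests for every screened gene (or a restricted list).

    Returns one row per gene with p and q per covariate family; q-values are
    computed separately within the stage, gender and age families.
    """
    if genes is None:
        genes = sorted(screen.groups)
    rows = []
    for gene in genes:
        high, low = screen.groups[gene]
        rec = balance_test(set(high) | set(low), clinical)
        rows.append({"gene_id": gene, "p_stage": rec.p_stage,
                     "p_gender": rec.p_gender, "p_age": rec.p_age})
    out = pd.DataFrame(rows)
    for cov in ("stage", "gender", "age"):
        p = out[f"p_{cov}"]
        q = np.full(len(out), np.nan)
        ok = p.notna().to_numpy()
        if ok.any():
            q[ok] = compute_qvalues(p[ok].to_numpy(), method=q_method)
        out[f"q_{cov}"] = q
    return out
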