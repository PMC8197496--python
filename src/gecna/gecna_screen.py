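"""Stage-1 genome-wide extreme-expressor screen.

For every gene, the k subjects with the highest and the k with the lowest
expression z-scores (default k = 10) form a "high expressor" and a "low
expressor" group.  The per-subject CNA burden (total / amplification /
deletion channel) is compared between the two groups with a classical
pooled-variance Student t-test, the per-channel p-value family is adjusted
to q-values (Storey by default, Benjamini-Hochberg optionally), and genes
with q < alpha are classified by sign as burden *facilitators*
(mean burden higher among high expressors) or *suppressors* (lower),
yielding six lists: the total, amplification and deletion channels crossed
with the two directions.

The screen is an extreme-group design on purpose — it asks whether the
tails of a gene's expression distribution separate the burden distribution,
not whether a linear correlation exists across the whole cohort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .burden import BurdenProfile
from .io_cbioportal import ExpressionMatrix, intersect_subjects

logger = logging.getLogger(__name__)

CHANNELS = ("total", "amp", "del")


# ---------------------------------------------------------------------------
# extreme-group selection
# ---------------------------------------------------------------------------


def select_extreme_groups(expr_row: pd.Series, k: int = 10) -> tuple[list[str], list[str]]:
    """Top-k and bottom-k expressing subjects for one gene.

    Missing expression values are dropped first; fewer than 2k usable values
    raises ``ValueError`` (the caller records the gene as excluded).  Ties at
    the rank-k boundary are broken deterministically by sorting on
    (expression value, subject id), so identical inputs always yield
    identical groups.
    """
    vals = expr_row.dropna()
    if len(vals) < 2 * k:
        raise ValueError(
            f"need >= {2 * k} non-missing expression values, have {len(vals)}"
        )
    ids = vals.index.to_numpy(dtype=object)
    order = np.lexsort((ids, vals.to_numpy()))  # primary: value, tie-break: id
    low = [str(i) for i in ids[order[:k]]]
    high = [str(i) for i in ids[order[-k:]]]
    return high, low


# ---------------------------------------------------------------------------
# pooled-variance Student t-test (vectorized, nan-aware)
# ---------------------------------------------------------------------------


def student_t_test(high: np.ndarray, low: np.ndarray):
    """Two-sided pooled-variance (classical Student) t-test along the last axis.

    ``high`` and ``low`` may be 1-D (one gene) or 2-D (genes x group members);
    nan entries are treated as missing group members.  Degenerate inputs
    follow fixed conventions: both groups zero-variance with equal means
    gives t = 0, p = 1; zero-variance with unequal means gives t = ±inf,
    p = 0 (callers flag this); fewer than 2 usable values in either group
    gives nan, nan.

    Returns ``(t, p, mean_high, mean_low, n_high, n_low)``.
    """
    high = np.atleast_2d(np.asarray(high, dtype=float))
    low = np.atleast_2d(np.asarray(low, dtype=float))
    n1 = (~np.isnan(high)).sum(axis=1)
    n2 = (~np.isnan(low)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.nanmean(np.where(np.isnan(high), np.nan, high), axis=1)
        m2 = np.nanmean(np.where(np.isnan(low), np.nan, low), axis=1)
        ss1 = np.nansum((high - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((low - m2[:, None]) ** 2, axis=1)
        df = n1 + n2 - 2
        sp2 = (ss1 + ss2) / np.where(df > 0, df, 1)
        se = np.sqrt(sp2 * (1.0 / np.where(n1 > 0, n1, 1) + 1.0 / np.where(n2 > 0, n2, 1)))
        diff = m1 - m2
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), np.where(df > 0, df, 1))
    # degenerate zero-variance conventions
    with np.errstate(invalid="ignore"):
        zero_var = (sp2 == 0) & (df > 0)
        eq = zero_var & (diff == 0)
        ne = zero_var & (diff != 0)
        t = np.where(eq, 0.0, t)
        p = np.where(eq, 1.0, p)
        t = np.where(ne, np.sign(diff) * np.inf, t)
        p = np.where(ne, 0.0, p)
    unusable = (n1 < 2) | (n2 < 2)
    t = np.where(unusable, np.nan, t)
    p = np.where(unusable, np.nan, p)
    if high.shape[0] == 1:
        return float(t[0]), float(p[0]), float(m1[0]), float(m2[0]), int(n1[0]), int(n2[0])
    return t, p, m1, m2, n1, n2


def test_gene(high_burden, low_burden):
    """Single-gene burden comparison: ``(t, p, mean_high, mean_low)``."""
    t, p, m1, m2, *_ = student_t_test(np.asarray(high_burden, float),
                                      np.asarray(low_burden, float))
    return t, p, m1, m2


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------


def storey_pi0(p_values: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on a lambda
    grid (0.05 .. 0.95 by 0.05), a cubic polynomial is fit through the curve
    and evaluated at the largest lambda; the result is clamped to (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if m < 100:
        # the smoother is unstable for tiny families; fall back to the
        # conservative pi0 = 1 (plain BH)
        return 1.0
    coef = np.polyfit(lambdas, pi0_l, 3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    if not math.isfinite(pi0) or pi0 <= 0:
        positive = pi0_l[pi0_l > 0]
        pi0 = float(positive.min()) if positive.size else 1.0 / m
    return min(1.0, pi0)


def compute_qvalues(p_values, method: str = "storey") -> np.ndarray:
    """q-values for a family of p-values.

    ``storey`` (default): q_i = pi0_hat * m * p_(i) / i with a trailing
    cumulative minimum, pi0_hat from :func:`storey_pi0`.  ``bh``:
    Benjamini-Hochberg step-up adjusted p-values (pi0 = 1).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method != "storey":
        raise ValueError(f"unknown q-value method {method!r}")
    pi0 = storey_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# screen driver
# ---------------------------------------------------------------------------


@dataclass
class GeneClassification:
    """The six significant-gene lists of the screen."""

    all_facilitators: list[str] = field(default_factory=list)     # (i)
    all_suppressors: list[str] = field(default_factory=list)      # (ii)
    amp_facilitators: list[str] = field(default_factory=list)     # (iii)
    del_facilitators: list[str] = field(default_factory=list)     # (iv)
    amp_suppressors: list[str] = field(default_factory=list)      # (v)
    del_suppressors: list[str] = field(default_factory=list)      # (vi)

    _CHANNEL_KEY = {"total": "all", "amp": "amp", "del": "del"}

    def list_for(self, channel: str, direction: str) -> list[str]:
        return getattr(self, f"{self._CHANNEL_KEY[channel]}_{direction}s")

    def as_dict(self) -> dict[str, list[str]]:
        return {
            name: list(getattr(self, name))
            for name in ("all_facilitators", "all_suppressors", "amp_facilitators",
                         "del_facilitators", "amp_suppressors", "del_suppressors")
        }

    def union(self) -> list[str]:
        out: set[str] = set()
        for genes in self.as_dict().values():
            out.update(genes)
        return sorted(out)

    def validate(self) -> None:
        d = self.as_dict()
        for a, b in (("all_facilitators", "all_suppressors"),
                     ("amp_facilitators", "amp_suppressors"),
                     ("del_facilitators", "del_suppressors")):
            overlap = set(d[a]) & set(d[b])
            if overlap:
                raise ValueError(f"gene in both directions of one channel: {sorted(overlap)[:3]}")


@dataclass
class ScreenResult:
    """Full screen output: per-gene-per-channel records plus the six lists."""

    records: pd.DataFrame
    classification: GeneClassification
    #: gene -> (high group, low group), shared across channels
    groups: dict[str, tuple[list[str], list[str]]]
    excluded: pd.DataFrame  # gene_id, reason
    subjects_used: list[str]
    params: dict

    def significant(self) -> pd.DataFrame:
        return self.records[self.records["significant"]]


def write_screen_outputs(result: "ScreenResult", out_dir) -> None:
    """Write per-channel tables, the six lists, exclusions and a summary JSON."""
    import json
    from pathlib import Path

    from .io_cbioportal import write_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for channel in result.params["channels"]:
        sub = result.records[result.records["channel"] == channel]
        write_table(sub.drop(columns=["high_subjects", "low_subjects"]),
                    out_dir / f"screen_{channel}.tsv", sort_by=["gene_id"])
    groups = pd.DataFrame(
        [{"gene_id": g, "high_subjects": ",".join(h), "low_subjects": ",".join(l)}
         for g, (h, l) in result.groups.items()])
    write_table(groups, out_dir / "screen_groups.tsv", sort_by=["gene_id"])
    lists = result.classification.as_dict()
    for name, genes in lists.items():
        write_table(pd.DataFrame({"gene_id": genes}),
                    out_dir / f"list_{name}.tsv", sort_by=["gene_id"])
    write_table(result.excluded, out_dir / "excluded_genes.tsv", sort_by=["gene_id"])
    summary = {name: len(genes) for name, genes in lists.items()}
    summary["n_genes_tested"] = int(result.records["gene_id"].nunique())
    summary["n_subjects"] = len(result.subjects_used)
    summary["params"] = result.params
    (out_dir / "screen_summary.json").write_text(json.dumps(summary, indent=2) + "\n")


def run_screen(
    expr: ExpressionMatrix,
    burden: BurdenProfile,
    channels: tuple[str, ...] = CHANNELS,
    k: int = 10,
    alpha: float = 0.05,
    q_method: str = "storey",
    pool_channels: bool = False,
) -> ScreenResult:
    """Run the extreme-expressor burden screen over every eligible gene.

    Subjects are intersected between the expression matrix and the burden
    profile.  Genes all-missing in expression, or with fewer than 2k
    non-missing values, are excluded and recorded with a reason.  q-values
    are computed within each channel's family by default (``pool_channels``
    pools the three families into one).
    """
    unknown = set(channels) - set(CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")
    subjects = intersect_subjects(expr.subject_ids, burden.subject_ids, label="screen")
    if len(subjects) < 2 * k:
        raise ValueError(f"only {len(subjects)} common subjects; need >= {2 * k}")
    E = expr.values[subjects]

    excluded_rows = []
    all_missing = set(ExpressionMatrix(E).all_missing_genes())
    n_nonmissing = E.notna().sum(axis=1)
    groups: dict[str, tuple[list[str], list[str]]] = {}
    kept_genes: list[str] = []
    for gene in E.index:
        if gene in all_missing:
            excluded_rows.append({"gene_id": gene, "reason": "all_missing"})
            continue
        if n_nonmissing[gene] < 2 * k:
            excluded_rows.append({"gene_id": gene, "reason": "fewer_than_2k_values"})
            continue
        groups[gene] = select_extreme_groups(E.loc[gene], k=k)
        kept_genes.append(gene)
    logger.info(
        "screen: %d genes tested, %d all-missing excluded, %d below-2k excluded",
        len(kept_genes), len(all_missing),
        sum(r["reason"] == "fewer_than_2k_values" for r in excluded_rows),
    )
    if not kept_genes:
        raise ValueError("no genes survive the screen preconditions")

    # burden values per group, padded with nan for subjects absent from the profile
    b = burden.data
    high_idx = [groups[g][0] for g in kept_genes]
    low_idx = [groups[g][1] for g in kept_genes]

    def group_burden(channel: str, idx_lists: list[list[str]]) -> np.ndarray:
        series = b[channel]
        out = np.full((len(idx_lists), k), np.nan)
        for i, ids in enumerate(idx_lists):
            present = [s for s in ids if s in series.index]
            out[i, : len(present)] = series.loc[present].to_numpy()
        return out

    frames = []
    for channel in channels:
        hi = group_burden(channel, high_idx)
        lo = group_burden(channel, low_idx)
        t, p, m1, m2, n1, n2 = student_t_test(hi, lo)
        degenerate = np.isinf(t) | np.isnan(p)
        direction = np.where(m1 > m2, "facilitator",
                             np.where(m1 < m2, "suppressor", "none"))
        frames.append(pd.DataFrame({
            "gene_id": kept_genes,
            "channel": channel,
            "high_subjects": [",".join(ids) for ids in high_idx],
            "low_subjects": [",".join(ids) for ids in low_idx],
            "n_high_used": n1,
            "n_low_used": n2,
            "mean_high": m1,
            "mean_low": m2,
            "t_stat": t,
            "p_value": p,
            "direction": direction,
            "degenerate": degenerate,
        }))
    records = pd.concat(frames, ignore_index=True)

    usable = records["p_value"].notna()
    records["q_value"] = np.nan
    if pool_channels:
        records.loc[usable, "q_value"] = compute_qvalues(
            records.loc[usable, "p_value"].to_numpy(), method=q_method)
    else:
        for channel in channels:
            sel = usable & (records["channel"] == channel)
            records.loc[sel, "q_value"] = compute_qvalues(
                records.loc[sel, "p_value"].to_numpy(), method=q_method)
    records["significant"] = (
        (records["q_value"] < alpha) & ~records["degenerate"] & usable
    )

    classification = GeneClassification()
    sig = records[records["significant"] & (records["direction"] != "none")]
    for channel in channels:
        for direction in ("facilitator", "suppressor"):
            sel = (sig["channel"] == channel) & (sig["direction"] == direction)
            classification.list_for(channel, direction).extend(
                sorted(sig.loc[sel, "gene_id"]))
    classification.validate()

    records = records.sort_values(["channel", "gene_id"], kind="stable").reset_index(drop=True)
    excluded = pd.DataFrame(excluded_rows, columns=["gene_id", "reason"])
    params = {"k": k, "alpha": alpha, "q_method": q_method,
              "channels": list(channels), "pool_channels": pool_channels,
              "min_magnitude": burden.min_magnitude}
    return ScreenResult(records, classification, groups, excluded, subjects, params)
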