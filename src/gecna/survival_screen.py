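"""Stage-2 screen: does alteration of a screen-positive gene move survival?

A subject is *altered* for a gene when it carries a high-level amplification
(GISTIC +2), a homozygous deletion (GISTIC -2) or at least one somatic
mutation in that gene — the cBioPortal altered/unaltered convention.
Low-level gains/losses (GISTIC +/-1) do not confer altered status.

For every candidate gene the altered indicator enters a Cox
proportional-hazards model of overall survival (partial likelihood, Efron
tie handling) adjusted for the clinical covariates that pass a univariate
Cox pre-selection at p < 0.05 (age as continuous years, race as
White/Other, tumor stage as a 4-level categorical with a variable-level
likelihood-ratio p).  The altered and unaltered groups' expression levels
are additionally compared with a two-sided Wilcoxon rank-sum test.  A gene
passes the screen when both the Cox Wald p and the Wilcoxon p fall below
alpha and the fit is non-degenerate.  Complete-case analysis throughout:
subjects missing a model's covariate are excluded from that model only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .gecna_screen import GeneClassification, compute_qvalues
from .io_cbioportal import (ClinicalTable, CnaMatrix, ExpressionMatrix,
                            MutationTable, intersect_subjects)

logger = logging.getLogger(__name__)

#: |log HR| beyond this is treated as monotone-likelihood separation
_COEF_BOUND = 15.0


@dataclass
class AlteredStatus:
    gene_id: str
    altered: pd.Series  # bool per subject

    @property
    def n_altered(self) -> int:
        return int(self.altered.sum())

    @property
    def n_unaltered(self) -> int:
        return int((~self.altered).sum())


def compute_altered_status(gene_id: str, cna: CnaMatrix, mutations: MutationTable,
                           subjects: list[str] | None = None) -> AlteredStatus:
    """Altered = (call == +2) or (call == -2) or (>=1 mutation record)."""
    if gene_id not in cna.calls.index:
        raise KeyError(f"gene {gene_id!r} absent from CNA matrix")
    if subjects is None:
        subjects = cna.subject_ids
    calls = cna.calls.loc[gene_id, subjects]
    high_level = calls.abs() == 2  # nan-safe: nan != 2
    mutated_set = mutations.mutated_subjects(gene_id)
    mutated = pd.Series([s in mutated_set for s in subjects], index=calls.index)
    return AlteredStatus(gene_id, (high_level.fillna(False) | mutated).astype(bool))


# ---------------------------------------------------------------------------
# covariate pre-selection
# ---------------------------------------------------------------------------


def _stage_dummies(stage4: pd.Series) -> pd.DataFrame:
    """Indicator coding of the 4-level stage, stage 1 as reference."""
    out = pd.DataFrame(index=stage4.index)
    for level in (2, 3, 4):
        out[f"stage_{level}"] = (stage4 == float(level)).astype(float)
    out[stage4.isna()] = np.nan
    return out


def _fit_cph(df: pd.DataFrame) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="os_time", event_col="os_event")
    return cph


def select_covariates(clinical: ClinicalTable, alpha: float = 0.05) -> list[str]:
    """Univariate Cox pre-selection of {age, race2, stage4} at p < alpha.

    Age and race use the Wald p of the single coefficient; stage uses the
    3-df likelihood-ratio p of its dummy block.  Complete cases per fit;
    zero-variance covariates are unselectable.  Requires >= 10 events.
    """
    clin = clinical.data
    base = clin[["os_time", "os_event"]]
    if base["os_event"].fillna(0).sum() < 10:
        raise ValueError("fewer than 10 events; survival screen not identifiable")
    selected = []
    for name in ("age", "race2", "stage4"):
        col = clin[name]
        ok = col.notna() & base.notna().all(axis=1)
        if col[ok].nunique() <= 1:
            logger.warning("select_covariates: %s has no variance, skipping", name)
            continue
        if name == "stage4":
            X = _stage_dummies(col)
        elif name == "race2":
            X = pd.DataFrame({"race_other": (col == "Other").astype(float)})
            X[col.isna()] = np.nan
        else:
            X = col.to_frame("age")
        df = pd.concat([base, X], axis=1).dropna()
        try:
            cph = _fit_cph(df)
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as err:
            logger.warning("select_covariates: %s univariate fit failed (%s)", name, err)
            continue
        if name == "stage4":
            p = float(cph.log_likelihood_ratio_test().p_value)
        else:
            p = float(cph.summary["p"].iloc[0])
        if p < alpha:
            selected.append(name)
    if not selected:
        logger.warning("select_covariates: no covariate selected")
    return selected


def covariate_frame(clinical: ClinicalTable, covariates: list[str]) -> pd.DataFrame:
    """Design columns for the selected covariates (stage expanded to dummies)."""
    clin = clinical.data
    parts = []
    for name in covariates:
        if name == "stage4":
            parts.append(_stage_dummies(clin["stage4"]))
        elif name == "race2":
            X = pd.DataFrame({"race_other": (clin["race2"] == "Other").astype(float)})
            X[clin["race2"].isna()] = np.nan
            parts.append(X)
        elif name == "age":
            parts.append(clin["age"].to_frame("age"))
        else:
            raise ValueError(f"unknown covariate {name!r}")
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=clin.index)


# ---------------------------------------------------------------------------
# per-gene models
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    gene_id: str
    hazard_ratio: float
    hr_p_value: float
    covariates_used: list[str]
    n_events: int
    n_altered: int
    n_unaltered: int
    degenerate: bool
    wilcoxon_p: float = np.nan
    expression_direction: str = "none"
    passes_screen: bool = False


def fit_cox(time, event, altered, covariates: pd.DataFrame | None = None,
            gene_id: str = "") -> CoxResult:
    """Covariate-adjusted Cox PH fit of the altered indicator.

    Degenerate situations (no events in a group, monotone likelihood /
    separation, non-convergence) yield a flagged result instead of raising;
    flagged results never pass the screen.
    """
    df = pd.DataFrame({"os_time": np.asarray(time, float),
                       "os_event": np.asarray(event, float),
                       "altered": np.asarray(altered, float)})
    cov_names: list[str] = []
    if covariates is not None and covariates.shape[1]:
        cov = covariates.reset_index(drop=True)
        cov_names = list(covariates.columns)
        df = pd.concat([df, cov], axis=1)
    df = df.dropna()
    n_events = int(df["os_event"].sum())
    n_alt = int(df["altered"].sum())
    n_unalt = int(len(df) - n_alt)

    def flagged() -> CoxResult:
        return CoxResult(gene_id, np.nan, np.nan, cov_names, n_events,
                         n_alt, n_unalt, degenerate=True)

    if n_events == 0:
        raise ValueError("no events in survival data")
    if n_alt == 0 or n_unalt == 0:
        return flagged()
    ev = df.groupby(df["altered"] > 0)["os_event"].sum()
    if ev.min() == 0:  # all events on one side: monotone likelihood
        return flagged()
    try:
        cph = _fit_cph(df)
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as err:
        logger.warning("fit_cox(%s): %s", gene_id, err)
        return flagged()
    coef = float(cph.summary.loc["altered", "coef"])
    if not np.isfinite(coef) or abs(coef) > _COEF_BOUND:
        return flagged()
    return CoxResult(gene_id, float(np.exp(coef)),
                     float(cph.summary.loc["altered", "p"]),
                     cov_names, n_events, n_alt, n_unalt, degenerate=False)


def expression_difference_test(expr_row: pd.Series, altered: pd.Series):
    """Two-sided Wilcoxon rank-sum altered-vs-unaltered expression test.

    The exact null distribution is used when both groups have <= 25
    non-missing values and the data are tie-free; otherwise the normal
    approximation with tie correction.  Returns ``(p, direction)`` where
    direction is 'over' when the altered group sits higher.
    """
    altered = altered.reindex(expr_row.index).astype(bool)
    a = expr_row[altered].dropna().to_numpy(float)
    u = expr_row[~altered].dropna().to_numpy(float)
    if len(a) == 0 or len(u) == 0:
        return np.nan, "none"
    pooled = np.concatenate([a, u])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 25 and len(u) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, u, alternative="two-sided", method=method)
    med_a, med_u = np.median(a), np.median(u)
    if med_a > med_u or (med_a == med_u and a.mean() > u.mean()):
        direction = "over"
    elif med_a < med_u or a.mean() < u.mean():
        direction = "under"
    else:
        direction = "none"
    return float(res.pvalue), direction


# ---------------------------------------------------------------------------
# screen driver
# ---------------------------------------------------------------------------

_LIST_LABELS = {
    "all_facilitators": "i", "all_suppressors": "ii", "amp_facilitators": "iii",
    "del_facilitators": "iv", "amp_suppressors": "v", "del_suppressors": "vi",
}


def run_survival_screen(
    classification: GeneClassification,
    cna: CnaMatrix,
    mutations: MutationTable,
    clinical: ClinicalTable,
    expr: ExpressionMatrix,
    candidates: str = "union",
    alpha: float = 0.05,
    adjust: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Survival screen over the stage-1 significant genes.

    ``candidates`` is ``union`` (all six lists) or ``all_cna`` (the two
    total-channel lists only).  ``adjust='bh'`` optionally replaces the raw
    p < alpha gates with BH-adjusted ones.  Returns the per-gene table and a
    summary dict (HR>1 / HR<1 partition of the passing genes).
    """
    if candidates == "union":
        genes = classification.union()
    elif candidates == "all_cna":
        genes = sorted(set(classification.all_facilitators)
                       | set(classification.all_suppressors))
    else:
        raise ValueError(f"unknown candidate rule {candidates!r}")

    mut_subjects = mutations.subject_ids
    groups = [cna.subject_ids, clinical.subject_ids]
    if mut_subjects:
        groups.append(mut_subjects)
    subjects = intersect_subjects(*groups, label="survival")
    clin_sub = ClinicalTable(clinical.data.loc[subjects])
    covariates = select_covariates(clin_sub, alpha=alpha)
    cov_frame = covariate_frame(clin_sub, covariates)

    source_of: dict[str, list[str]] = {}
    for name, members in classification.as_dict().items():
        for g in members:
            source_of.setdefault(g, []).append(_LIST_LABELS[name])

    rows = []
    for gene in genes:
        if gene not in cna.calls.index:
            logger.warning("survival screen: %s absent from CNA matrix, skipped", gene)
            continue
        status = compute_altered_status(gene, cna, mutations, subjects)
        res = fit_cox(clin_sub.data["os_time"], clin_sub.data["os_event"],
                      status.altered.to_numpy(float), cov_frame, gene_id=gene)
        if gene in expr.values.index:
            wp, direction = expression_difference_test(
                expr.values.loc[gene, [s for s in subjects if s in expr.values.columns]],
                status.altered)
        else:
            wp, direction = np.nan, "none"
        res.wilcoxon_p, res.expression_direction = wp, direction
        rows.append({
            "gene_id": gene,
            "source_lists": ",".join(source_of.get(gene, [])),
            "n_altered": res.n_altered,
            "n_unaltered": res.n_unaltered,
            "n_events": res.n_events,
            "hazard_ratio": res.hazard_ratio,
            "cox_p": res.hr_p_value,
            "covariates": ",".join(covariates),
            "wilcoxon_p": res.wilcoxon_p,
            "expression_direction": res.expression_direction,
            "degenerate": res.degenerate,
        })
    table = pd.DataFrame(rows, columns=[
        "gene_id", "source_lists", "n_altered", "n_unaltered", "n_events",
        "hazard_ratio", "cox_p", "covariates", "wilcoxon_p",
        "expression_direction", "degenerate"])

    cox_p = table["cox_p"].to_numpy(float) if len(table) else np.array([])
    wil_p = table["wilcoxon_p"].to_numpy(float) if len(table) else np.array([])
    if adjust == "bh" and len(table):
        ok = np.isfinite(cox_p)
        cox_p = cox_p.copy()
        cox_p[ok] = compute_qvalues(cox_p[ok], method="bh")
        ok = np.isfinite(wil_p)
        wil_p = wil_p.copy()
        wil_p[ok] = compute_qvalues(wil_p[ok], method="bh")
    if len(table):
        table["passes_screen"] = ((cox_p < alpha) & (wil_p < alpha)
                                  & ~table["degenerate"].to_numpy())
        table = table.sort_values("gene_id", kind="stable").reset_index(drop=True)
    else:
        table["passes_screen"] = pd.Series(dtype=bool)

    passing = table[table.get("passes_screen", pd.Series(dtype=bool)).astype(bool)] \
        if len(table) else table
    summary = {
        "n_candidates": int(len(table)),
        "n_passing": int(len(passing)),
        "n_hr_gt_1": int((passing["hazard_ratio"] > 1).sum()) if len(passing) else 0,
        "n_hr_lt_1": int((passing["hazard_ratio"] < 1).sum()) if len(passing) else 0,
        "covariates_used": covariates,
        "n_subjects": len(subjects),
    }
    return table, summary
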