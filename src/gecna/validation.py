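"""Simulation studies that characterize the pipeline's operating behavior.

Each function runs a self-contained calibration or recovery experiment on
synthetic cohorts and returns summary numbers: type-I error of the
extreme-group t-test, discovery counts under a global-null screen, planted
facilitator/suppressor recovery, Cox log-hazard-ratio recovery and
agreement with an independent Cox reference, and sensitivity of the
two-stage funnel for planted survival genes.  The acceptance script and
the test suite both drive the pipeline through these entry points, so the
numbers they report are always recomputed from scratch.

All randomness flows from an integer seed through ``numpy.random``
SeedSequence spawning; derived child seeds stay below 2^31.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .burden import compute_burden
from .gecna_screen import run_screen, student_t_test
from .survival_screen import fit_cox, run_survival_screen
from .synthetic_data import SyntheticConfig, generate


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % (2**31)]


# ---------------------------------------------------------------------------
# t-test calibration
# ---------------------------------------------------------------------------


def extreme_t_type1_error(n_replicates: int = 10_000, k: int = 10,
                          alpha: float = 0.05, distribution: str = "normal",
                          seed: int = 0) -> float:
    """Empirical type-I error of the screen's pooled t-test under the null.

    Both groups of k burdens are drawn from one distribution (``normal``:
    standard normal; ``negative_binomial``: the generator's default burden
    law, mean 80, dispersion 8) and the rejection rate at ``alpha`` over
    ``n_replicates`` replicates is returned.
    """
    rng = np.random.default_rng(seed)
    if distribution == "normal":
        high = rng.standard_normal((n_replicates, k))
        low = rng.standard_normal((n_replicates, k))
    elif distribution == "negative_binomial":
        size, mu = 8.0, 80.0
        p = size / (size + mu)
        high = rng.negative_binomial(size, p, (n_replicates, k)).astype(float)
        low = rng.negative_binomial(size, p, (n_replicates, k)).astype(float)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    _, pvals, *_ = student_t_test(high, low)
    return float(np.mean(pvals < alpha))


# ---------------------------------------------------------------------------
# screen calibration and recovery
# ---------------------------------------------------------------------------


def null_screen_discoveries(n_seeds: int = 10, seed: int = 0,
                            alpha: float = 0.05) -> list[int]:
    """Significant-record count per seed for a beta = 0 (global-null) screen.

    The generator's planted genes are given zero expression-burden coupling,
    so every q < alpha discovery in any channel is a false one.
    """
    counts = []
    for child in _child_seeds(seed, n_seeds):
        cfg = SyntheticConfig(seed=child, effect_beta=0.0, survival_log_hrs=())
        ds = generate(cfg)
        res = run_screen(ds.expression, compute_burden(ds.cna), alpha=alpha)
        counts.append(int(res.records["significant"].sum()))
    return counts


def planted_recovery(n_seeds: int = 10, seed: int = 0,
                     config_overrides: dict | None = None) -> dict[str, float]:
    """Recovery of planted amp facilitators / del suppressors at defaults.

    Returns pooled-over-seeds fractions: sensitivity of list (iii) for
    planted amplification facilitators, of list (vi) for planted deletion
    suppressors, and the cross-channel leakage rate (planted amp-channel
    genes appearing in either deletion-channel list and vice versa).
    """
    overrides = config_overrides or {}
    n_iii = n_vi = 0
    hit_iii = hit_vi = 0
    n_channel = leaked = 0
    for child in _child_seeds(seed, n_seeds):
        cfg = SyntheticConfig(seed=child, **overrides)
        ds = generate(cfg)
        res = run_screen(ds.expression, compute_burden(ds.cna))
        cls = res.classification
        truth = ds.truth
        amp_fac = set(truth.loc[truth["role"] == "amp_facilitator", "gene_id"])
        del_sup = set(truth.loc[truth["role"] == "del_suppressor", "gene_id"])
        amp_planted = set(truth.loc[truth["channel"] == "amp", "gene_id"])
        del_planted = set(truth.loc[truth["channel"] == "del", "gene_id"])
        n_iii += len(amp_fac)
        n_vi += len(del_sup)
        hit_iii += len(amp_fac & set(cls.amp_facilitators))
        hit_vi += len(del_sup & set(cls.del_suppressors))
        del_lists = set(cls.del_facilitators) | set(cls.del_suppressors)
        amp_lists = set(cls.amp_facilitators) | set(cls.amp_suppressors)
        n_channel += len(amp_planted) + len(del_planted)
        leaked += len(amp_planted & del_lists) + len(del_planted & amp_lists)
    return {
        "amp_facilitator_recovery": hit_iii / n_iii if n_iii else float("nan"),
        "del_suppressor_recovery": hit_vi / n_vi if n_vi else float("nan"),
        "cross_channel_leakage": leaked / n_channel if n_channel else float("nan"),
    }


# ---------------------------------------------------------------------------
# Cox model checks
# ---------------------------------------------------------------------------


def simulate_survival_cohort(n: int, log_hr: float, altered_frac: float,
                             seed: int, baseline: float = 0.01,
                             censoring_rate: float = 0.3):
    """Minimal two-arm exponential survival cohort for Cox calibration."""
    rng = np.random.default_rng(seed)
    altered = (rng.random(n) < altered_frac).astype(float)
    rates = baseline * np.exp(log_hr * altered)
    t_event = rng.exponential(1.0 / rates)
    if censoring_rate > 0:
        # single-rate censoring tuned roughly to the target fraction
        c = baseline * censoring_rate / max(1e-12, 1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / c, n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(float)
    return time, event, altered


def cox_lnhr_recovery(n_cohorts: int = 50, n: int = 500, hr: float = 2.0,
                      altered_frac: float = 0.3, tol: float = 0.35,
                      seed: int = 0) -> dict[str, float]:
    """Fraction of simulated cohorts whose fitted ln HR lands within ``tol``."""
    target = math.log(hr)
    hits, estimates = 0, []
    for child in _child_seeds(seed, n_cohorts):
        time, event, altered = simulate_survival_cohort(n, target, altered_frac, child)
        res = fit_cox(time, event, altered)
        est = math.log(res.hazard_ratio) if not res.degenerate else float("nan")
        estimates.append(est)
        if math.isfinite(est) and abs(est - target) <= tol:
            hits += 1
    return {"recovery_rate": hits / n_cohorts,
            "mean_lnhr": float(np.nanmean(estimates))}


def cox_reference_agreement(n_datasets: int = 20, n: int = 300,
                            seed: int = 0) -> float:
    """Max relative coefficient difference vs an independent Cox reference.

    The reference is scikit-survival's Cox proportional-hazards estimator
    with Efron tie handling, imported lazily (it is a test-time dependency,
    not a pipeline one).
    """
    from sksurv.linear_model import CoxPHSurvivalAnalysis

    worst = 0.0
    for child in _child_seeds(seed, n_datasets):
        rng = np.random.default_rng(child)
        altered = (rng.random(n) < 0.3).astype(float)
        age = rng.normal(65, 10, n)
        x2 = rng.standard_normal(n)
        lp = 0.7 * altered + 0.02 * (age - 65) + 0.3 * x2
        t_event = rng.exponential(np.exp(-lp) / 0.01)
        t_cens = rng.exponential(1.0 / 0.005, n)
        time = np.round(np.minimum(t_event, t_cens), 1)  # month-ish ties
        time = np.maximum(time, 0.1)
        event = t_event <= t_cens
        cov = pd.DataFrame({"age": age, "x2": x2})
        res_df = pd.DataFrame({"os_time": time, "os_event": event.astype(float),
                               "altered": altered, "age": age, "x2": x2})
        from lifelines import CoxPHFitter
        cph = CoxPHFitter().fit(res_df, "os_time", "os_event")
        ours = cph.params_[["altered", "age", "x2"]].to_numpy()
        X = pd.DataFrame({"altered": altered, "age": age, "x2": x2})
        y = np.array(list(zip(event, time)), dtype=[("e", bool), ("t", float)])
        ref = CoxPHSurvivalAnalysis(ties="efron", tol=1e-12, n_iter=200).fit(X, y)
        rel = np.max(np.abs(ours - ref.coef_) / np.maximum(np.abs(ref.coef_), 1e-8))
        worst = max(worst, float(rel))
    return worst


# ---------------------------------------------------------------------------
# two-stage funnel sensitivity
# ---------------------------------------------------------------------------


def survival_screen_sensitivity(n_seeds: int = 10, seed: int = 0,
                                n_subjects: int = 500, hr: float = 2.5,
                                altered_frac: float = 0.2) -> float:
    """Pooled sensitivity for planted survival genes through both stages."""
    log_hr = math.log(hr)
    n_truth = n_hit = 0
    for child in _child_seeds(seed, n_seeds):
        cfg = SyntheticConfig(seed=child, n_subjects=n_subjects,
                              survival_log_hrs=tuple([log_hr] * 6),
                              survival_altered_frac=altered_frac)
        ds = generate(cfg)
        res = run_screen(ds.expression, compute_burden(ds.cna))
        table, _ = run_survival_screen(res.classification, ds.cna, ds.mutations,
                                       ds.clinical, ds.expression)
        surv_genes = set(ds.truth.loc[ds.truth["is_survival_gene"], "gene_id"])
        passed = set(table.loc[table["passes_screen"], "gene_id"])
        n_truth += len(surv_genes)
        n_hit += len(surv_genes & passed)
    return n_hit / n_truth if n_truth else float("nan")
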