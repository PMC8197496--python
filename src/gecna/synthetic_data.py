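"""Synthetic TCGA-shaped cohort generator with known ground truth.

Emulates the structure of a PanCancer-Atlas-style download at desk scale:
a gene x subject expression z-score matrix (with a small fraction of
all-missing genes), a sparse discrete GISTIC call matrix, a MAF-like
mutation table and a clinical table with Cox-model survival times.

The generative model, per subject j and channel c in {amp, del}:

1.  A latent instability score z_cj ~ N(0,1) sets the subject's burden
    mean  mu_cj = base_rate_c * exp(sigma * z_cj - sigma^2/2)  (normalized
    lognormal multiplier, so E[burden] = base_rate_c); the realized burden
    count K_cj is negative binomial with that mean and a fixed dispersion.
2.  The K_cj nonzero calls land on uniformly chosen genes (disjoint between
    channels within a subject), magnitude 2 with probability
    ``frac_high_level`` else 1, positive sign for amp, negative for del.
3.  Null-gene expression is standard normal.  A planted facilitator
    (suppressor) of channel c has expression
    beta * standardized(K_c) + sqrt(1-beta^2) * noise  (negated for
    suppressors), so beta is its expression-burden correlation.
4.  Background mutations are Bernoulli(mutation_rate) per gene x subject.
5.  A handful of survival-effect genes, drawn from the planted
    screen-positive genes, receive extra alterations (high-level calls or
    mutations) in a Bernoulli(``survival_altered_frac``) subject subset;
    altered subjects' expression of that gene is shifted by
    ``altered_expr_shift`` z-units in the direction of the alteration
    (amplified genes overexpress, deleted genes underexpress).  The death
    hazard is  baseline * exp(sum_g logHR_g * altered_gj
    + 0.02*(age-age_mean) + 0.3*(stage-1)),  with exponential event times
    and independent exponential censoring calibrated to the target
    censoring fraction.

Everything is drawn from one ``numpy`` Generator, so a config (including
its seed) reproduces the dataset bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .io_cbioportal import ClinicalTable, CnaMatrix, ExpressionMatrix, MutationTable

_LN = math.log

#: planted-role labels, in the order survival genes are drawn from them
ROLES = ("amp_facilitator", "del_facilitator", "amp_suppressor", "del_suppressor")


@dataclass
class SyntheticConfig:
    """Generator knobs; defaults define the reference desk-scale cohort."""

    n_genes: int = 2000
    n_subjects: int = 200
    frac_all_missing_genes: float = 0.01

    n_amp_facilitators: int = 20
    n_del_facilitators: int = 20
    n_amp_suppressors: int = 20
    n_del_suppressors: int = 20
    #: expression-burden correlation of planted genes (sign flips direction)
    effect_beta: float = 0.6

    #: expected nonzero-call count per subject, per channel
    amp_base_rate: float = 80.0
    del_base_rate: float = 80.0
    #: negative-binomial size parameter (smaller = more overdispersed)
    burden_dispersion: float = 8.0
    #: sd of the latent log-instability multiplier
    latent_sigma: float = 0.5
    #: fraction of nonzero calls at magnitude 2 (high-level)
    frac_high_level: float = 0.2

    mutation_rate: float = 0.01

    #: per-gene log hazard ratios of the planted survival-effect genes
    survival_log_hrs: tuple[float, ...] = (
        _LN(2.5), _LN(2.5), _LN(2.5), _LN(2.5), _LN(0.4), _LN(0.4),
    )
    survival_altered_frac: float = 0.2
    #: expression shift (z-units) in altered subjects of survival genes
    altered_expr_shift: float = 1.5

    baseline_hazard: float = 0.01  # per month
    censoring_rate: float = 0.35
    age_mean: float = 65.0
    age_sd: float = 10.0
    age_log_hr: float = 0.02  # per year
    stage_log_hr: float = 0.3  # per stage level
    stage_probs: tuple[float, ...] = (0.45, 0.25, 0.2, 0.1)

    seed: int = 0

    def validate(self) -> None:
        n_planted = (self.n_amp_facilitators + self.n_del_facilitators
                     + self.n_amp_suppressors + self.n_del_suppressors)
        n_missing = round(self.frac_all_missing_genes * self.n_genes)
        if n_planted + n_missing > self.n_genes:
            raise ValueError("more planted + all-missing genes than genes")
        if len(self.survival_log_hrs) > n_planted:
            raise ValueError("more survival genes than planted screen-positive genes")
        if not -1.0 <= self.effect_beta <= 1.0:
            raise ValueError("effect_beta must lie in [-1, 1]")
        for p in (self.frac_all_missing_genes, self.frac_high_level,
                  self.mutation_rate, self.survival_altered_frac, self.censoring_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9 or len(self.stage_probs) != 4:
            raise ValueError("stage_probs must be a 4-vector summing to 1")
        if min(self.n_genes, self.n_subjects) < 1:
            raise ValueError("need at least one gene and one subject")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "SyntheticConfig":
        """Load a config from YAML/JSON, with keyword overrides."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("survival_log_hrs", "stage_probs"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    cna: CnaMatrix
    mutations: MutationTable
    clinical: ClinicalTable
    #: per planted gene: role, channel, direction, effect sizes
    truth: pd.DataFrame
    config: SyntheticConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------


def _censoring_scale(event_rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean P(C < T) equal to ``target``."""
    if target <= 0.0:
        return 0.0

    def frac_censored(log_c: float) -> float:
        c = math.exp(log_c)
        return float(np.mean(c / (c + event_rates))) - target

    return math.exp(brentq(frac_censored, -30.0, 30.0))


_STAGE_ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV"}
_RACE_RAW = ("White", "Black or African American", "Asian", "Unknown")
_RACE_P = (0.72, 0.12, 0.10, 0.06)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one cohort from the generative model; reproducible from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, S = config.n_genes, config.n_subjects
    gene_ids = np.array([f"G{i:05d}" for i in range(G)])
    subject_ids = np.array([f"SYN-{j:04d}" for j in range(S)])

    # --- role assignment -------------------------------------------------
    n_missing = round(config.frac_all_missing_genes * G)
    perm = rng.permutation(G)
    missing_idx = perm[:n_missing]
    cursor = n_missing
    role_idx: dict[str, np.ndarray] = {}
    for role, n_role in zip(ROLES, (config.n_amp_facilitators, config.n_del_facilitators,
                                    config.n_amp_suppressors, config.n_del_suppressors)):
        role_idx[role] = np.sort(perm[cursor:cursor + n_role])
        cursor += n_role

    # --- CNA burden and call matrix --------------------------------------
    sigma = config.latent_sigma
    calls = np.zeros((G, S), dtype=float)
    burden = {}
    for channel, base in (("amp", config.amp_base_rate), ("del", config.del_base_rate)):
        z = rng.standard_normal(S)
        mu = base * np.exp(sigma * z - 0.5 * sigma**2)
        size = config.burden_dispersion
        k = rng.negative_binomial(size, size / (size + mu))
        burden[channel] = k.astype(float)
    sign = {"amp": 1.0, "del": -1.0}
    for j in range(S):
        k_amp = int(min(burden["amp"][j], G))
        k_del = int(min(burden["del"][j], G - k_amp))
        order = rng.permutation(G)
        for channel, lo, hi in (("amp", 0, k_amp), ("del", k_amp, k_amp + k_del)):
            idx = order[lo:hi]
            mag = np.where(rng.random(idx.size) < config.frac_high_level, 2.0, 1.0)
            calls[idx, j] = sign[channel] * mag
        burden["amp"][j], burden["del"][j] = k_amp, k_del

    # --- expression -------------------------------------------------------
    expr = rng.standard_normal((G, S))
    beta = config.effect_beta
    load = math.sqrt(max(0.0, 1.0 - beta * beta))
    for role in ROLES:
        channel = role.split("_")[0]
        b = burden[channel]
        std = (b - b.mean()) / (b.std() if b.std() > 0 else 1.0)
        direction = 1.0 if role.endswith("facilitator") else -1.0
        idx = role_idx[role]
        expr[idx] = direction * beta * std[None, :] + load * expr[idx]

    # --- background mutations --------------------------------------------
    mut_mask = rng.random((G, S)) < config.mutation_rate

    # --- survival-effect genes -------------------------------------------
    survival_rows = []
    pool_cursor = {role: 0 for role in ROLES}
    log_hr_of: dict[int, float] = {}
    for i, log_hr in enumerate(config.survival_log_hrs):
        # round-robin over the four planted role sets
        for off in range(len(ROLES)):
            role = ROLES[(i + off) % len(ROLES)]
            if pool_cursor[role] < len(role_idx[role]):
                break
        else:  # pragma: no cover - excluded by validate()
            raise ValueError("ran out of planted genes for survival effects")
        g = int(role_idx[role][pool_cursor[role]])
        pool_cursor[role] += 1
        alter_sign = 1.0 if role.startswith("amp") else -1.0
        altered = rng.random(S) < config.survival_altered_frac
        for j in np.flatnonzero(altered):
            if rng.random() < 0.5:
                mut_mask[g, j] = True
            else:
                calls[g, j] = alter_sign * 2.0
        expr[g] += config.altered_expr_shift * alter_sign * altered
        log_hr_of[g] = log_hr
        survival_rows.append((g, role, log_hr, alter_sign))

    # recompute channel burdens after survival-gene call planting
    burden["amp"] = (calls > 0).sum(axis=0).astype(float)
    burden["del"] = (calls < 0).sum(axis=0).astype(float)

    expr[missing_idx] = np.nan

    # --- clinical + survival ---------------------------------------------
    age = np.clip(np.round(rng.normal(config.age_mean, config.age_sd, S)), 30, 90)
    sex = rng.choice(["Male", "Female"], size=S)
    race = rng.choice(_RACE_RAW, size=S, p=_RACE_P)
    stage_num = rng.choice([1, 2, 3, 4], size=S, p=config.stage_probs)
    sub = rng.choice(["", "A", "B"], size=S, p=(0.2, 0.4, 0.4))
    stage_raw = np.array(
        [f"Stage {_STAGE_ROMAN[s]}{x}" for s, x in zip(stage_num, sub)]
    )

    lp = config.age_log_hr * (age - config.age_mean) + config.stage_log_hr * (stage_num - 1)
    altered_any = (np.abs(calls) == 2) | mut_mask
    for g, log_hr in log_hr_of.items():
        lp = lp + log_hr * altered_any[g]
    rates = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rates)
    c_rate = _censoring_scale(rates, config.censoring_rate)
    t_cens = rng.exponential(1.0 / c_rate, S) if c_rate > 0 else np.full(S, np.inf)
    os_event = (t_event <= t_cens).astype(float)
    os_time = np.round(np.minimum(t_event, t_cens), 2)
    os_time = np.maximum(os_time, 0.01)

    # --- assemble domain objects ------------------------------------------
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"),
                     columns=pd.Index(subject_ids, name="subject_id"))
    )
    cna = CnaMatrix(
        pd.DataFrame(calls, index=pd.Index(gene_ids, name="gene_id"),
                     columns=pd.Index(subject_ids, name="subject_id"))
    )
    gi, sj = np.nonzero(mut_mask)
    mutations = MutationTable(pd.DataFrame({
        "gene_id": gene_ids[gi],
        "subject_id": subject_ids[sj],
        "variant_classification": "Missense_Mutation",
    }))
    clin = pd.DataFrame({
        "age": age,
        "sex": np.char.lower(sex.astype(str)),
        "race2": np.where(race == "White", "White", "Other"),
        "stage_raw": stage_raw,
        "stage4": stage_num.astype(float),
        "os_time": os_time,
        "os_event": os_event,
    }, index=pd.Index(subject_ids, name="subject_id"))
    clin["complete"] = True
    clinical = ClinicalTable(clin)

    rows = []
    survival_gene_ids = {g for g, *_ in survival_rows}
    for role in ROLES:
        channel, kind = role.split("_")
        for g in role_idx[role]:
            rows.append({
                "gene_id": gene_ids[g], "role": role, "channel": channel,
                "direction": kind, "effect_beta": beta,
                "is_survival_gene": int(g) in survival_gene_ids,
                "log_hr": np.nan, "alter_sign": np.nan,
            })
    truth = pd.DataFrame(rows)
    for g, role, log_hr, alter_sign in survival_rows:
        sel = truth["gene_id"] == gene_ids[g]
        truth.loc[sel, "log_hr"] = log_hr
        truth.loc[sel, "alter_sign"] = alter_sign
    truth = truth.sort_values("gene_id", kind="stable").reset_index(drop=True)

    return SyntheticDataset(expression, cna, mutations, clinical, truth, config)


# ---------------------------------------------------------------------------
# flat-file fixture writer
# ---------------------------------------------------------------------------

_CLINICAL_HEADER_META = (
    "#Patient Identifier\tDiagnosis Age\tSex\tRace Category\t"
    "Neoplasm Disease Stage\tOverall Survival (Months)\tOverall Survival Status\n"
    "#Identifier of a patient\tAge at diagnosis\tSex\tRace\tAJCC stage\t"
    "Survival in months\tSurvival status\n"
    "#STRING\tNUMBER\tSTRING\tSTRING\tSTRING\tNUMBER\tSTRING\n"
    "#1\t1\t1\t1\t1\t1\t1\n"
)


def write_cbioportal_fixture(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as four cBioPortal-style flat files plus ``truth.tsv``.

    The files round-trip through :mod:`gecna.io_cbioportal` readers
    value-for-value (floats use shortest-repr formatting).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    expr = dataset.expression.values.copy()
    expr.insert(0, "Entrez_Gene_Id", np.arange(1, len(expr) + 1))
    expr.insert(0, "Hugo_Symbol", expr.index)
    paths["expression"] = out / "data_mrna_seq_v2_rsem_zscores.txt"
    expr.to_csv(paths["expression"], sep="\t", index=False, na_rep="NA")

    cna = dataset.cna.calls.copy()
    mask = cna.notna()
    cna = cna.astype(object).where(~mask, cna.where(mask).astype("Int64"))
    cna.insert(0, "Hugo_Symbol", cna.index)
    paths["cna"] = out / "data_cna.txt"
    cna.to_csv(paths["cna"], sep="\t", index=False, na_rep="NA")

    mut = dataset.mutations.records.rename(columns={
        "gene_id": "Hugo_Symbol",
        "subject_id": "Tumor_Sample_Barcode",
        "variant_classification": "Variant_Classification",
    })
    paths["mutations"] = out / "data_mutations.txt"
    mut.to_csv(paths["mutations"], sep="\t", index=False)

    clin = dataset.clinical.data
    out_clin = pd.DataFrame({
        "PATIENT_ID": clin.index,
        "AGE": clin["age"].astype(int),
        "SEX": clin["sex"].str.capitalize(),
        "RACE": clin["race2"].map({"White": "White"}).fillna("Other"),
        "AJCC_PATHOLOGIC_TUMOR_STAGE": clin["stage_raw"],
        "OS_MONTHS": clin["os_time"],
        "OS_STATUS": clin["os_event"].map({1.0: "1:DECEASED", 0.0: "0:LIVING"}),
    })
    paths["clinical"] = out / "data_clinical.txt"
    with open(paths["clinical"], "w") as fh:
        fh.write(_CLINICAL_HEADER_META)
        out_clin.to_csv(fh, sep="\t", index=False)

    paths["truth"] = out / "truth.tsv"
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False, na_rep="NA")
    return paths
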