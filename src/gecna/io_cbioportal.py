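"""Readers and writers for cBioPortal-style flat files.

The pipeline consumes four tab-delimited files as exported by cBioPortal for
a TCGA PanCancer Atlas study: a gene x sample mRNA z-score matrix, a gene x
sample discrete GISTIC 2.0 copy-number call matrix (values in {-2,-1,0,+1,+2}),
a MAF-like somatic mutation table, and a per-patient clinical table (age, sex,
race, tumor stage, overall survival).  Everything is validated on read: the
goal is that a malformed cell fails loudly with its gene/sample coordinates
rather than silently propagating.

Conventions
-----------
* Missing markers accepted on read: the empty string, ``NA`` and ``NaN``
  (case-insensitive).  Internally missing values are ``numpy.nan``.
* Duplicate gene symbols keep the first occurrence; the rest are logged.
* Sample ids are matched by exact string equality after whitespace trimming.
* Decimal point only; no thousands separators.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tokens (lower-cased, stripped) treated as missing on read
MISSING_TOKENS = frozenset({"", "na", "nan"})

#: legal discrete GISTIC 2.0 calls
GISTIC_CALLS = frozenset({-2, -1, 0, 1, 2})

_GENE_ID_COLUMNS = ("Hugo_Symbol", "GENE_ID", "Gene")
_DROP_COLUMNS = ("Entrez_Gene_Id",)


class ParseError(ValueError):
    """A flat file violated the expected cBioPortal dialect."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x subject continuous mRNA z-scores; ``nan`` marks missing."""

    values: pd.DataFrame  # index = gene symbols, columns = sample ids, float64

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate subject identifiers in expression matrix")
        arr = self.values.to_numpy()
        if np.isinf(arr).any():
            raise ValueError("non-finite (infinite) expression value")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.columns)

    def all_missing_genes(self) -> list[str]:
        """Genes whose expression is missing for every subject."""
        mask = self.values.isna().all(axis=1)
        return list(self.values.index[mask])


@dataclass
class CnaMatrix:
    """Gene x subject discrete GISTIC calls in {-2,-1,0,+1,+2}; ``nan`` missing."""

    calls: pd.DataFrame  # float64 so that nan can mark missing

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in CNA matrix")
        if self.calls.columns.has_duplicates:
            raise ValueError("duplicate subject identifiers in CNA matrix")
        arr = self.calls.to_numpy()
        finite = arr[~np.isnan(arr)]
        if finite.size and not np.isin(finite, list(GISTIC_CALLS)).all():
            bad = finite[~np.isin(finite, list(GISTIC_CALLS))][0]
            raise ValueError(f"CNA call {bad!r} outside {{-2,-1,0,1,2}}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.calls.columns)


@dataclass
class MutationTable:
    """MAF-like long table of somatic mutations.

    A (gene, subject) pair may repeat — one row per mutation event.  The
    distinct ``Tumor_Sample_Barcode`` values double as the table's sample
    universe for subject intersection purposes.
    """

    records: pd.DataFrame  # columns gene_id, subject_id, variant_classification

    def __post_init__(self) -> None:
        required = {"gene_id", "subject_id"}
        if not required.issubset(self.records.columns):
            raise ValueError("mutation table needs gene_id and subject_id columns")
        if len(self.records):
            if (self.records["gene_id"].astype(str).str.len() == 0).any():
                raise ValueError("empty gene identifier in mutation table")
            if (self.records["subject_id"].astype(str).str.len() == 0).any():
                raise ValueError("empty subject identifier in mutation table")

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.records["subject_id"].unique()) if len(self.records) else []

    def mutated_subjects(self, gene_id: str) -> set[str]:
        if not len(self.records):
            return set()
        hit = self.records["gene_id"] == gene_id
        return set(self.records.loc[hit, "subject_id"])


@dataclass
class ClinicalTable:
    """Per-subject clinical record.

    ``stage4`` collapses AJCC sub-stages (IA, IB, ...) onto a 1–4 integer
    scale; ``race2`` collapses race onto {White, Other}.  Subjects with
    missing required covariates are flagged (``complete`` column), never
    dropped at read time — each downstream model applies its own
    complete-case rule.
    """

    data: pd.DataFrame  # index subject_id; columns age, sex, race2, stage_raw,
    #                     stage4, os_time, os_event, complete

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate subject identifiers in clinical table")
        t = self.data["os_time"].dropna()
        if (t < 0).any():
            raise ValueError("negative overall-survival time")
        ev = self.data["os_event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValueError("os_event outside {0,1}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)


# ---------------------------------------------------------------------------
# matrix readers
# ---------------------------------------------------------------------------


def _read_raw_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: malformed header — need a gene column and >=1 sample")
    gene_col = next((c for c in _GENE_ID_COLUMNS if c in df.columns), df.columns[0])
    sample_cols = [c for c in df.columns if c != gene_col and c not in _DROP_COLUMNS]
    if not sample_cols:
        raise ParseError(f"{path}: zero sample columns")
    genes = df[gene_col].astype(str).str.strip()
    dup = genes.duplicated(keep="first")
    if dup.any():
        logger.warning(
            "%s: %d duplicate gene symbols, keeping first occurrence (e.g. %s)",
            path.name, int(dup.sum()), genes[dup].iloc[0],
        )
        df = df.loc[~dup.values]
        genes = genes.loc[~dup.values]
    out = df[sample_cols].copy()
    out.index = pd.Index(genes, name="gene_id")
    out.columns = pd.Index([c.strip() for c in sample_cols], name="subject_id")
    if out.columns.has_duplicates:
        raise ParseError(f"{path}: duplicate sample identifiers in header")
    return out


def _to_numeric(raw: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Parse string cells to float, mapping missing tokens to nan.

    A cell that is neither numeric nor a missing marker is a hard error
    naming its gene and sample.
    """
    stripped = raw.apply(lambda c: c.str.strip())
    missing = stripped.apply(lambda c: c.str.lower().isin(MISSING_TOKENS))
    num = stripped.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & ~missing.to_numpy()
    if bad.to_numpy().any():
        gi, sj = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{Path(path).name}: unparseable value {stripped.iat[gi, sj]!r} "
            f"at gene {raw.index[gi]!r}, sample {raw.columns[sj]!r}"
        )
    return num.astype(float)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a cBioPortal mRNA z-score matrix.

    Blank/NA cells become nan.  The count of genes missing in every subject
    is logged (they are kept; the screen excludes them explicitly).
    """
    values = _to_numeric(_read_raw_matrix(path), path)
    matrix = ExpressionMatrix(values)
    n_all_missing = len(matrix.all_missing_genes())
    logger.info(
        "read_expression: %d genes x %d subjects, %d all-missing genes",
        len(matrix.gene_ids), len(matrix.subject_ids), n_all_missing,
    )
    return matrix


def read_cna(path: str | Path) -> CnaMatrix:
    """Read a discrete GISTIC 2.0 call matrix; out-of-range calls are errors."""
    values = _to_numeric(_read_raw_matrix(path), path)
    arr = values.to_numpy()
    finite_mask = ~np.isnan(arr)
    ok = np.isin(arr, list(GISTIC_CALLS)) | ~finite_mask
    if not ok.all():
        gi, sj = np.argwhere(~ok)[0]
        raise ParseError(
            f"{Path(path).name}: CNA call {arr[gi, sj]!r} outside {{-2,-1,0,1,2}} "
            f"at gene {values.index[gi]!r}, sample {values.columns[sj]!r}"
        )
    return CnaMatrix(values)


# ---------------------------------------------------------------------------
# mutation + clinical readers
# ---------------------------------------------------------------------------

_MUT_GENE_COLS = ("Hugo_Symbol", "gene_id", "Gene")
_MUT_SAMPLE_COLS = ("Tumor_Sample_Barcode", "subject_id", "Sample_ID")
_MUT_CLASS_COLS = ("Variant_Classification", "variant_classification")


def read_mutations(path: str | Path) -> MutationTable:
    """Read a MAF-like mutation TSV (gene symbol + sample barcode at minimum)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    gene_col = next((c for c in _MUT_GENE_COLS if c in df.columns), None)
    sample_col = next((c for c in _MUT_SAMPLE_COLS if c in df.columns), None)
    if gene_col is None or sample_col is None:
        raise ParseError(
            f"{path.name}: missing required column (need a Hugo_Symbol-style gene "
            "column and a Tumor_Sample_Barcode-style sample column)"
        )
    class_col = next((c for c in _MUT_CLASS_COLS if c in df.columns), None)
    records = pd.DataFrame(
        {
            "gene_id": df[gene_col].astype(str).str.strip(),
            "subject_id": df[sample_col].astype(str).str.strip(),
            "variant_classification": (
                df[class_col].astype(str).str.strip() if class_col is not None else ""
            ),
        }
    )
    logger.info("read_mutations: %d records, %d subjects", len(records),
                records["subject_id"].nunique() if len(records) else 0)
    return MutationTable(records)


_STAGE_RE = re.compile(r"^STAGE\s+(IV|III|II|I)[ABC]?$")
_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4}


def parse_stage(stage_raw: str | float) -> float:
    """Collapse an AJCC stage string ('Stage IIIB') onto the 1–4 scale."""
    if not isinstance(stage_raw, str):
        return np.nan
    m = _STAGE_RE.match(stage_raw.strip().upper())
    return float(_ROMAN[m.group(1)]) if m else np.nan


def collapse_race(race_raw: str | float) -> str | float:
    """Two-level race: 'White' vs 'Other' (small groups combined)."""
    if not isinstance(race_raw, str) or race_raw.strip().lower() in MISSING_TOKENS:
        return np.nan
    return "White" if race_raw.strip().upper() == "WHITE" else "Other"


def _parse_os_status(value: str) -> float:
    v = value.strip().upper()
    if v in {"1:DECEASED", "DECEASED", "1", "DEAD"}:
        return 1.0
    if v in {"0:LIVING", "LIVING", "0", "ALIVE"}:
        return 0.0
    if v.lower() in MISSING_TOKENS:
        return np.nan
    raise ParseError(f"unrecognized OS_STATUS value {value!r}")


def _parse_sex(value: str) -> str | float:
    v = value.strip().lower()
    if v in {"male", "m"}:
        return "male"
    if v in {"female", "f"}:
        return "female"
    return np.nan


_CLIN_ID_COLS = ("PATIENT_ID", "SAMPLE_ID", "SUBJECT_ID")
_CLIN_STAGE_COLS = ("AJCC_PATHOLOGIC_TUMOR_STAGE", "TUMOR_STAGE", "STAGE")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a cBioPortal clinical TSV (leading ``#`` metadata lines allowed)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    id_col = next((c for c in _CLIN_ID_COLS if c in df.columns), None)
    stage_col = next((c for c in _CLIN_STAGE_COLS if c in df.columns), None)
    required = {"AGE", "SEX", "RACE", "OS_MONTHS", "OS_STATUS"}
    missing_cols = required - set(df.columns)
    if id_col is None or stage_col is None or missing_cols:
        raise ParseError(
            f"{path.name}: missing required clinical column(s): "
            f"{sorted(missing_cols) or [id_col and stage_col or 'stage/id']}"
        )

    def _num(col: str) -> pd.Series:
        s = df[col].astype(str).str.strip()
        s = s.where(~s.str.lower().isin(MISSING_TOKENS), other=np.nan)
        out = pd.to_numeric(s, errors="coerce")
        bad = out.isna() & s.notna()
        if bad.any():
            raise ParseError(f"{path.name}: unparseable {col} value {s[bad].iloc[0]!r}")
        return out

    data = pd.DataFrame(
        {
            "age": _num("AGE"),
            "sex": df["SEX"].map(_parse_sex),
            "race2": df["RACE"].map(collapse_race),
            "stage_raw": df[stage_col].astype(str).str.strip(),
            "stage4": df[stage_col].map(parse_stage),
            "os_time": _num("OS_MONTHS"),
            "os_event": df["OS_STATUS"].map(_parse_os_status),
        }
    )
    data.index = pd.Index(df[id_col].astype(str).str.strip(), name="subject_id")
    data["complete"] = (
        data[["age", "sex", "race2", "stage4", "os_time", "os_event"]].notna().all(axis=1)
    )
    n_flagged = int((~data["complete"]).sum())
    if n_flagged:
        logger.warning("read_clinical: %d subjects flagged with missing covariates", n_flagged)
    return ClinicalTable(data)


# ---------------------------------------------------------------------------
# result-table writer, subject intersection, manifest
# ---------------------------------------------------------------------------


def write_table(records: pd.DataFrame, path: str | Path,
                sort_by: Sequence[str] | None = None) -> Path:
    """Write a result table as TSV with header and deterministic row order.

    ``sort_by`` defaults to all columns present, so the output is a pure
    function of the record set regardless of in-memory ordering.
    """
    path = Path(path)
    df = records.copy()
    keys = [c for c in (sort_by or df.columns) if c in df.columns]
    if keys and len(df):
        df = df.sort_values(keys, kind="stable").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def intersect_subjects(*id_groups: Iterable[str], label: str = "") -> list[str]:
    """Sorted intersection of subject-id collections, sizes logged once."""
    sets = [set(g) for g in id_groups]
    common = sorted(set.intersection(*sets)) if sets else []
    logger.info(
        "subject intersection%s: %s -> %d common",
        f" ({label})" if label else "", "/".join(str(len(s)) for s in sets), len(common),
    )
    return common


def write_manifest(path: str | Path, files: dict[str, str | Path],
                   subject_counts: dict[str, int], params: dict) -> Path:
    """JSON run manifest: input file SHA-256 hashes, subject counts, parameters."""
    hashes = {}
    for name, fp in files.items():
        fp = Path(fp)
        hashes[name] = hashlib.sha256(fp.read_bytes()).hexdigest() if fp.exists() else None
    manifest = {"files": hashes, "subject_counts": subject_counts, "params": params}
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path
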