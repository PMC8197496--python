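"""Over-representation analysis of the screen's gene lists.

One-sided hypergeometric test of each named gene set against a hit list,
with Benjamini-Hochberg control across sets.  The background universe
should be the genes that actually entered the stage-1 screen (post
all-missing exclusion) — enrichment is conditioned on testability, not on
the whole genome.  Gene sets are supplied as standard GMT files
(set name, description, members, tab-delimited).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gecna_screen import compute_qvalues

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    universe: set[str]
    descriptions: dict[str, str] | None = None

    def __post_init__(self) -> None:
        harmonized = {}
        for name, members in self.sets.items():
            inside = set(members) & self.universe
            dropped = len(members) - len(inside)
            if dropped:
                logger.info("gene set %s: %d members outside universe dropped",
                            name, dropped)
            if inside:
                harmonized[name] = inside
            else:
                logger.warning("gene set %s empty after harmonization, dropped", name)
        self.sets = harmonized


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file; ``universe`` defaults to the union of all members."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, members): {line!r}")
        name, desc, *members = parts
        members = [m.strip() for m in members if m.strip()]
        sets[name] = set(members)
        descriptions[name] = desc
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets, set(universe), descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for name in sorted(collection.sets):
        desc = (collection.descriptions or {}).get(name, "")
        lines.append("\t".join([name, desc, *sorted(collection.sets[name])]))
    path.write_text("\n".join(lines) + "\n")
    return path


def ora(hits: list[str], collection: GeneSetCollection,
        alpha: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    For a universe of M genes, a set of K and n hits with overlap k, the
    p-value is P(X >= k) for X ~ Hypergeom(M, K, n).  BH adjustment across
    sets; ``significant`` marks adjusted p < alpha.  Hits outside the
    universe are logged and dropped.
    """
    hit_set = set(hits)
    outside = hit_set - collection.universe
    if outside:
        logger.warning("ora: %d hits outside universe dropped (e.g. %s)",
                       len(outside), sorted(outside)[:3])
        hit_set &= collection.universe
    M, n = len(collection.universe), len(hit_set)
    columns = ["set_name", "set_size", "n_hits", "overlap", "fold_enrichment",
               "p_value", "p_adjusted", "significant", "overlap_genes"]
    if n == 0 or not collection.sets:
        return pd.DataFrame(columns=columns)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        K = len(members)
        overlap = sorted(hit_set & members)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        fold = (k / n) / (K / M) if k else 0.0
        rows.append({"set_name": name, "set_size": K, "n_hits": n, "overlap": k,
                     "fold_enrichment": fold, "p_value": p,
                     "overlap_genes": ",".join(overlap)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = compute_qvalues(out["p_value"].to_numpy(), method="bh")
    out["significant"] = out["p_adjusted"] < alpha
    return out.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)[columns]
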