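"""Per-subject copy-number-alteration burden.

The burden statistic is a gene count over the discrete GISTIC call matrix:
for each subject, the number of genes whose call is nonzero (total), with a
positive call (amplification channel) or a negative call (deletion channel).
Missing calls are excluded from both the counts and the per-subject number
of evaluated genes.  ``min_magnitude=2`` restricts the count to high-level
events (amplification +2 / homozygous deletion -2), exposed for sensitivity
analysis; the screen's default counts any nonzero call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_cbioportal import CnaMatrix


@dataclass
class BurdenProfile:
    """Per-subject integer CNA counts in three channels.

    Invariants: ``amp + del == total`` and ``0 <= burden <= n_evaluated``
    for every subject.
    """

    data: pd.DataFrame  # index subject_id; columns total, amp, del, n_evaluated
    min_magnitude: int = 1

    def __post_init__(self) -> None:
        d = self.data
        if not (d["amp"] + d["del"] == d["total"]).all():
            raise ValueError("channel additivity violated: amp + del != total")
        for col in ("total", "amp", "del"):
            if ((d[col] < 0) | (d[col] > d["n_evaluated"])).any():
                raise ValueError(f"{col} burden outside [0, n_evaluated]")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    def channel(self, name: str) -> pd.Series:
        """Burden series for channel ``total``, ``amp`` or ``del``."""
        return self.data[name]


def compute_burden(cna: CnaMatrix, min_magnitude: int = 1) -> BurdenProfile:
    """Count per-subject CNA burden from a GISTIC call matrix.

    total = #{genes: |call| >= min_magnitude}, amp = #{call >= +min_magnitude},
    del = #{call <= -min_magnitude}; nan calls are ignored everywhere.
    """
    if min_magnitude not in (1, 2):
        raise ValueError("min_magnitude must be 1 or 2")
    calls = cna.calls.to_numpy()
    if calls.size == 0:
        raise ValueError("empty CNA matrix")
    # nan comparisons are False, so missing calls never count
    amp = (calls >= min_magnitude).sum(axis=0)
    dele = (calls <= -min_magnitude).sum(axis=0)
    n_eval = (~np.isnan(calls)).sum(axis=0)
    data = pd.DataFrame(
        {
            "total": (amp + dele).astype(int),
            "amp": amp.astype(int),
            "del": dele.astype(int),
            "n_evaluated": n_eval.astype(int),
        },
        index=pd.Index(cna.subject_ids, name="subject_id"),
    )
    return BurdenProfile(data, min_magnitude=min_magnitude)
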