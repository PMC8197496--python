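#!/usr/bin/env python
"""Per-subject CNA burden of the reference cohort.

Reads the GISTIC call matrix written by 01_simulate_cohort.py, counts each
subject's total / amplification / deletion burden (any nonzero call, the
screen's default), and writes results/burden.tsv.  Also reports the
high-level-only counts (|call| = 2) for comparison.
"""

from pathlib import Path

from gecna import compute_burden, read_cna, write_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cna = read_cna(ROOT / "cohort" / "data_cna.txt")
    profile = compute_burden(cna, min_magnitude=1)
    write_table(profile.data.reset_index(), ROOT / "burden.tsv",
                sort_by=["subject_id"])
    d = profile.data
    print(f"burden over {len(d)} subjects "
          f"(n_evaluated = {int(d['n_evaluated'].iloc[0])} genes each):")
    for ch in ("total", "amp", "del"):
        print(f"  {ch:>5}: mean {d[ch].mean():7.1f}  sd {d[ch].std():6.1f}  "
              f"range {int(d[ch].min())}..{int(d[ch].max())}")
    high = compute_burden(cna, min_magnitude=2).data
    print(f"  high-level only: mean total {high['total'].mean():.1f} "
          f"(amp {high['amp'].mean():.1f}, del {high['del'].mean():.1f})")
    print(f"wrote {ROOT / 'burden.tsv'}")


if __name__ == "__main__":
    main()
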