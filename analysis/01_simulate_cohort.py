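#!/usr/bin/env python
"""Generate the reference synthetic cohort used by the downstream analyses.

Writes a 2,000-gene x 200-subject cohort in cBioPortal flat-file form under
results/cohort/ (expression z-scores, GISTIC calls, mutations, clinical,
plus the planted-gene truth table and a run manifest).  The cohort plants
20 facilitators and 20 suppressors per channel at expression-burden
correlation 0.6, and six survival-effect genes among them.
"""

import dataclasses
import sys
from pathlib import Path

from gecna import SyntheticConfig, generate, write_cbioportal_fixture, write_manifest

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 0


def main(seed: int = SEED) -> None:
    cfg = SyntheticConfig(seed=seed)
    ds = generate(cfg)
    paths = write_cbioportal_fixture(ds, OUT)
    write_manifest(OUT / "manifest.json", paths,
                   {"subjects": cfg.n_subjects}, dataclasses.asdict(cfg))
    print(f"cohort: {cfg.n_genes} genes x {cfg.n_subjects} subjects (seed {seed})")
    print(f"  all-missing expression genes: {len(ds.expression.all_missing_genes())}")
    print(f"  planted screen genes: {len(ds.truth)} "
          f"({int(ds.truth['is_survival_gene'].sum())} with survival effects)")
    print(f"  mutation records: {len(ds.mutations.records)}")
    print(f"  deaths observed: {int(ds.clinical.data['os_event'].sum())}/{cfg.n_subjects}")
    print(f"wrote {len(paths)} files under {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else SEED)
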