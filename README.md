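# gecna — expression-to-CNA-burden screening with a survival follow-up

Chromosome instability (CIN) shapes tumor evolution, therapy response and
prognosis, and genomic copy-number alterations (CNA) are its most accessible
surrogate in tumor sequencing cohorts.  `gecna` implements a two-stage
data-mining screen over cBioPortal/TCGA-style flat files that asks, for every
gene in the genome:

1. **Does the gene's expression track how much CNA a tumor carries?**
   For each gene *g*, the *k* = 10 subjects with the highest and lowest mRNA
   z-scores form a "high expressor" and "low expressor" group.  Their
   per-subject CNA burden — the number of genes with a nonzero GISTIC 2.0
   call, counted separately as total, amplification (calls > 0) and deletion
   (calls < 0) channels — is compared with a pooled-variance Student
   *t*-test.  Each channel's p-value family is adjusted to Storey q-values,
   and genes with *q* < 0.05 are classified by direction as CNA
   **facilitators** (high expression ↔ more CNA) or **suppressors** (high
   expression ↔ fewer CNA), yielding six lists: total/amp/del × two
   directions.
2. **Does alteration of a screen-positive gene move overall survival?**
   A subject is *altered* for a gene when it carries a high-level
   amplification (GISTIC +2), a homozygous deletion (−2) or any somatic
   mutation in that gene.  For each candidate the altered indicator enters a
   Cox proportional-hazards model of overall survival, *h(t | x) =
   h₀(t) · exp(β·altered + γᵀz)*, adjusted for the clinical covariates
   (age, race as White/Other, 4-level tumor stage) that pass a univariate
   Cox pre-selection at *p* < 0.05.  Expression in the altered vs unaltered
   groups is additionally compared with a Wilcoxon rank-sum test; genes with
   both *p* < 0.05 are the screen's survival-critical output, partitioned by
   hazard ratio above/below 1.

The package is written for cancer-genomics analysts who work with cBioPortal
PanCancer-Atlas downloads (for example the TCGA lung adenocarcinoma cohort,
study id `luad_tcga_pan_can_atlas_2018`): a gene × sample mRNA z-score
matrix, a gene × sample discrete GISTIC call matrix, a MAF-like mutation
table, and a clinical table.  A synthetic-cohort generator with planted
ground truth (known facilitators, suppressors, and survival-effect genes)
makes every stage testable at desk scale with no downloads.  A per-gene
covariate-balance check (Fisher–Freeman–Halton exact stage test, chi-squared
gender test, *t*-test on age) and a hypergeometric over-representation
module for GMT gene-set collections round out the pipeline.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on the
reference synthetic cohort (2,000 genes × 200 subjects, seed 0) and write
their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_cna_burden.py
python analysis/03_expression_screen.py
python analysis/04_covariate_balance.py
python analysis/05_survival_screen.py
python analysis/06_pathway_enrichment.py
```

Stage 1 prints:

```
screened 1980 genes (20 excluded); 82 significant at q < 0.05
    all_facilitators: 29
     all_suppressors: 29
    amp_facilitators: 23
    del_facilitators: 19
     amp_suppressors: 20
     del_suppressors: 20
  planted amp_facilitator: 20/20 recovered
  planted del_facilitator: 18/20 recovered
  planted amp_suppressor: 20/20 recovered
  planted del_suppressor: 20/20 recovered
```

i.e. the 20 genes with all-missing expression are excluded up front, 82 of
1,980 screened genes reach *q* < 0.05 somewhere, and 78 of the 80 planted
genes land in their intended list.  The balance check comes back clean (the
generator draws clinical covariates independently of expression):

```
   stage: min adjusted p = 0.424  (0 genes significant)
  gender: min adjusted p = 0.525  (0 genes significant)
     age: min adjusted p = 0.318  (0 genes significant)
```

and the survival stage reports, for the 82 candidates:

```
survival screen over 82 candidate genes (200 subjects; covariates: ['stage4'])
  passing both gates: 4 (4 with HR > 1, 0 with HR < 1)
  planted survival genes recovered: 3/6
```

At this cohort size roughly half the planted survival effects (true
HR = 2.5 / 0.4 at altered fraction 0.2) clear both gates; the pooled
sensitivity reaches ≈ 0.93 at *n* = 500 (see the acceptance report below).

The same pipeline is available from the shell — `gecna simulate`, `gecna
burden`, `gecna screen`, `gecna balance`, `gecna survive`, `gecna enrich` —
each a thin wrapper over the library; see `gecna --help`.

On a real PanCancer-Atlas lung adenocarcinoma download the screen operates
at genome scale (≈20,500 genes × 510 expression subjects, with the
~340 all-missing genes excluded automatically) and the two-stage output is
the cohort's facilitator/suppressor lists and its survival-critical subset;
no network access is built in, the four flat files are simply passed by
path.

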