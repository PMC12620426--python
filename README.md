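# pvtrigger

Drug-trigger discovery for juvenile idiopathic arthritis (JIA): an
integrative pharmacovigilance pipeline that screens spontaneous
adverse-event reports for drugs that may precipitate or worsen the disease,
then cross-examines the candidates with molecular-structure risk models and
transcriptomic signature enrichment.

The package is aimed at pharmacovigilance and computational drug-safety
researchers. It implements, as tested and reusable components:

* **Disproportionality analysis** of FAERS-style report tables — ROR, PRR
  with Yates χ², the BCPNN information component (closed-form posterior,
  IC025), and the MGPS empirical-Bayes gamma-Poisson shrinker (EBGM,
  EBGM05) — with field-standard positivity criteria, a four-algorithm
  consensus rule, and a co-medication sensitivity rerun.
* **Time-to-onset analysis** — Weibull maximum likelihood with
  observed-information CIs, hazard-profile classification (early / random /
  wear-out failure by the shape parameter β and its CI), and a
  parametric-bootstrap Kolmogorov–Smirnov fit test.
* **Structure-based risk models** — an RBF-SVM on 83 pinned 2D descriptors
  or MACCS/ECFP4 fingerprints, a graph convolutional network, and a
  directed message-passing network (bond-level messages excluding
  reverse-bond back-flow, optionally descriptor-augmented), as
  sklearn-style estimators with seeded 8:1:1 splits, 5-fold CV,
  Mann–Whitney AUC, and a consensus high-risk rule (all scores > 0.60).
* **Signature enrichment** — from-scratch ssGSEA for bulk samples (one-way
  ANOVA across subtypes) and binned-control module scoring for single cells
  (QC filtering, Wilcoxon rank-sum with BH correction across cell types).
* **Target overlap** — relevance-filtered disease gene lists intersected
  with drug-target lists, hypergeometric significance.
* **Synthetic study data** with planted ground truth — FAERS-like reports
  with planted relative risks and Weibull onset times, a labelled SMILES
  library whose positive class carries a proton-pump-inhibitor-like
  structural motif, and bulk/single-cell expression with a planted drug
  signature — so every stage can be validated end-to-end.

## Worked example

Run the full pipeline on the built-in synthetic demo study. One drug
(`DRUG01`) is planted with a reporting signal (relative risk 10, Weibull
onset with scale 60 days and shape 0.6), the learnable structural motif,
and an expression signature enriched in the systemic-JIA subtype and in
monocytes; decoys carry only the motif (`DRUG02`) or only the signal
(`DRUG03`).

```bash
pv run --out demo_run --seed 0
# final hits: ['DRUG01']
```

or from Python:

```python
from pvtrigger.pipeline import PipelineConfig, run_all

manifest = run_all(PipelineConfig(out_dir="demo_run", seed=0))
print(manifest["stages"]["consensus"])   # ['DRUG01']
print(manifest["final_hits"])            # ['DRUG01']
print(manifest["stages"]["tto"])         # {'DRUG01': 'early_failure'}
```

The run directory contains each stage's output: `signals.tsv` (per-drug
a/b/c/d counts, ROR with CI, PRR, χ², IC, IC025, EBGM, EBGM05, per-algorithm
flags, consensus), `signals_sensitivity.tsv` (the same after removing
co-medicated reports), `tto.json` (Weibull fits and classifications),
`predictions.tsv` (per-drug scores from the three models and the consensus
flag), `ssgsea_tests.json` and `celltype_tests.tsv` (signature enrichment),
`overlap.json`, and `manifest.json` with every seed and parameter.

In the seed-0 demo, `DRUG01` is reported with the target event 303 times
among its ~3,000 reports (ROR ≈ 7.1, IC025 ≈ 1.8, EBGM ≈ 4.1 — flagged by
all four algorithms); its onset sample fits a Weibull shape β < 1 with CI
below 1, an early-failure (falling-hazard) profile; all three structure
models score it above 0.60 (0.995 / 0.972 / 1.000) while the signal-only
decoy fails the models and the motif-only decoy fails the reporting signal;
and its signature's ssGSEA scores separate the systemic subtype at ANOVA
p ≈ 2e-28 with monocytes the top-ranked cell type. The final hit list is
exactly `['DRUG01']`.

Individual stages are available as subcommands (`pv simulate`, `pv signals`,
`pv tto`, `pv featurize`, `pv train`, `pv score`) and as plain library
functions.

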