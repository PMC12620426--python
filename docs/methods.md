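# Methods

`pvtrigger` implements an integrative screen for drugs that may trigger or
aggravate juvenile idiopathic arthritis (JIA): disproportionality analysis of
spontaneous adverse-event reports, time-to-onset modelling, molecular-structure
risk models, transcriptomic signature scoring, and target-overlap analysis.
Because the real inputs (a full FAERS extract, patient RNA-seq) are not
shippable, the package includes a first-class synthetic-data module that
emulates their structure with planted ground truth; every downstream method is
validated by its ability to recover what was planted.

## Disproportionality statistics

For a drug–event pair the deduplicated report table is collapsed to a 2×2
contingency table (a: drug & event; b: drug only; c: event only; d: neither;
N = a+b+c+d). Four statistics are computed:

* **ROR** = (a·d)/(b·c), with a 95% CI from the log-scale standard error
  √(1/a+1/b+1/c+1/d). Any zero cell triggers the Haldane–Anscombe +0.5
  correction and the result is flagged `corrected`.
* **PRR** = [a/(a+b)] / [c/(c+d)], accompanied by the Yates-corrected Pearson
  chi-square of the table, Σ(|O−E|−0.5)²/E.
* **BCPNN IC** under the closed-form gamma approximation of the information
  component posterior (priors α₁=β₁=1 on the margins, α=β=2 on the joint
  cell, γ₁₁=1, γ scaled so E(IC)=0 under exact independence);
  IC025 = E(IC) − 2·√V(IC). The closed form was chosen over Monte-Carlo
  Dirichlet sampling for determinism; its point estimate converges to
  log₂(aN/((a+b)(a+c))) only as counts grow — at a≈10 the Bayesian shrinkage
  toward 0 is deliberate and substantial.
* **MGPS EBGM**: the relative reporting rate λ = a/E (E = (a+b)(a+c)/N) gets a
  two-component gamma mixture prior whose five parameters are fitted by
  maximising the negative-binomial marginal likelihood of the observed counts
  over the full drug×event grid restricted to a ≥ 1, from the classical
  starting values (0.2, 0.1, 2, 4, 1/3) plus seeded multi-start perturbations
  (L-BFGS-B on log/logit-transformed parameters). The posterior is again a
  gamma mixture; EBGM = exp(E[ln λ]) via the digamma function and EBGM05
  solves the mixture CDF = 0.05 by bracketed root-finding.

Per-algorithm positivity uses the field-standard criteria — ROR: a ≥ 3 and CI
lower bound > 1; PRR: a ≥ 3, PRR ≥ 2, χ² ≥ 4; BCPNN: IC025 > 0; MGPS:
EBGM05 > 2 — all configurable, with a consensus signal requiring all four.
On a simulated 200-drug null cohort (50,000 reports) each algorithm flags
≤ 10% of drugs and the consensus ≤ 1%; a planted relative risk of 10 is
recovered essentially always. The co-medication sensitivity analysis simply
drops every report whose (normalized, '|'-split, parenthesis-stripped,
uppercased) drug list intersects a configurable exclusion list; the shipped
default covers NSAIDs, csDMARDs, glucocorticoids, biologics and other
immunosuppressants commonly co-reported with JIA.

Deduplication keeps, per case id, the row with the latest receipt date (ties:
last in file order), mirroring standard FAERS preprocessing. Partial or
malformed dates are rejected at ingestion with a logged warning; the synthetic
generator never emits them.

## Time-to-onset

Onset is the day gap between drug start and event date; rows with missing or
unparseable dates or with the event preceding the start are excluded and
counted by reason. Same-day onsets are mapped to 0.5 days so the sample stays
inside the positive Weibull support without a degenerate likelihood. The
two-parameter Weibull fit maximises the likelihood via the 1-D profile
equation for the shape (bracketed root-finding; the scale then has a closed
form), with 95% CIs from the observed Fisher information on (ln α, ln β)
(numerical Hessian, step 1e-5). Shape classification follows the hazard
taxonomy: early failure (β < 1, CI above excluded), random failure (CI
contains 1), wear-out failure (β > 1, CI below excluded); samples under 10
observations are reported `indeterminate`. Because the parameters are
estimated from the same sample, the Kolmogorov–Smirnov p-value uses a
parametric bootstrap (default 500 refitted replicates, seeded) rather than
the asymptotic table.

One caveat the synthetic pipeline makes visible: report tables carry dates,
so onset times are integer days. For β well below 1 this discretization
biases the fitted shape upward (mass near zero collapses onto 0.5); shape
*recovery* is therefore assessed on continuous samples, while the date-based
pipeline is assessed on the classification it implies.

## Molecular featurization and risk models

SMILES are "washed" before featurization: largest organic fragment,
neutralization of standard acid/base groups, canonicalization; unparseable
records are flagged and excluded rather than raised. Four representations
are produced: a pinned, ordered panel of 83 2D descriptors (shipped as
`data/descriptors_83.txt`; the exact panel is a package contract — molecular
weight, Crippen logP, H-bond donors/acceptors, TPSA, kappa indices, BertzCT,
ring counts, E-state aggregates, VSA bins, …), the 166 keyed MACCS bits (the
toolkit's placeholder bit 0 dropped), Morgan radius-2 fingerprints folded to
1024 bits, and heavy-atom molecular graphs (atom features: element one-hot
over {C,N,O,S,F,Cl,Br,I,P,other}, scaled degree, formal charge, aromatic
flag, scaled H count; bond features: order one-hot, conjugation, ring flag;
every bond contributes two directed edges with reverse pointers).

Three classifiers score molecules, exposed as sklearn-style estimators:

* **RBF-SVM** on z-scored descriptor or fingerprint matrices, probability
  calibrated (sigmoid, internal 3-fold).
* **GCN**: stacked graph convolutions with neighbour-mean aggregation
  (including self), learned linear maps, ReLU, residual connections and an
  MLP head over the mean-pooled graph embedding.
* **DMPNN**: hidden states on directed bonds; the update for bond k→m sums
  incoming bond states at k *excluding* the reverse bond m→k, preventing
  immediate message back-flow; after T steps bond states are aggregated to
  atoms, transformed, mean-pooled, optionally concatenated with a
  molecule-level descriptor/fingerprint vector (the "-Des"/"-ECFP4"
  variants), and passed to a feed-forward head.

The graph networks are implemented directly in numpy with hand-derived
reverse-mode gradients (validated against finite differences in the test
suite) and trained full-batch with Adam and class-weighted cross-entropy.
At the package's design scale (≤ 300 molecules) this trains in seconds on
one CPU. Hyperparameters are chosen by seeded random search against the
validation split of a seeded 8:1:1 partition — a deterministic, desk-scale
stand-in for Bayesian optimisation — and robustness is assessed with 5-fold
cross-validation. Discrimination is the Mann–Whitney AUC with tie correction.
A drug is a **consensus high-risk** compound when all three models score it
above a threshold (default 0.60).

The synthetic molecule generator draws from a built-in library of ~200
validated drug-like SMILES in which positives are enriched (p ≥ 0.9) for a
sulfinyl-benzimidazole motif — the proton-pump-inhibitor core — chosen so
that descriptors, MACCS, ECFP4 and graphs all carry the signal. Labels
correlate with, but are not identical to, motif presence, so perfect AUC is
not expected by construction.

## Expression signature scoring

**Bulk (ssGSEA).** Per sample, genes are ranked by expression (average
ties). Walking the list from the highest-expressed gene, the enrichment
score is the running sum of the difference between the weighted in-set ECDF
(weights rank^α, α = 0.25, the published exponent) and the unweighted
out-of-set ECDF — the integral rather than supremum form. Raw scores are
min-max normalised across the run's samples. Scores are rank-based and hence
invariant to any strictly monotone per-sample transform. Group differences
(e.g. sJIA / non-sJIA / control) use one-way ANOVA. Batch adjustment is
per-gene batch-mean centering that preserves the overall gene mean — a
deliberate linear simplification of empirical-Bayes batch removal, adequate
for additive offsets on log expression.

**Single-cell (module score).** Cells first pass QC: > 16% mitochondrial
content (`MT-` prefix), < 3% ribosomal content (`RPS`/`RPL`), any hemoglobin
counts (`HBA`/`HBB`), or < 200 expressed genes exclude a cell; genes
expressed in < 3 remaining cells are then dropped. The module score bins all
genes into 24 expression-average bins, draws 100 seeded control genes per
signature gene from its own bin (with replacement when a bin is small — at
~1,000 simulated genes every bin is), and scores each cell as mean signature
expression minus mean control expression. Raw counts are library-size
normalised to the median total and log1p-transformed first (the scale on
which module scores are conventionally defined; on raw counts the top
expression bin is heavy-tailed and control matching breaks down — disable
via `log_normalize=False` when the input is already normalised). Cell-type
enrichment uses one-vs-rest Wilcoxon rank-sum tests (one-sided, "greater")
with Benjamini–Hochberg correction across cell types.

The single-cell generator produces negative-binomial counts (gene means
log-normal, dispersion 0.5 — a standard scRNA noise model), named
mitochondrial/ribosomal/hemoglobin genes calibrated to ~5%/~10%/0% of counts
in clean cells, and a configurable fraction of cells engineered to
decisively violate exactly one QC rule each, so the filter's behaviour can
be checked against truth labels cell-by-cell.

## Target overlap

Disease gene lists arrive scored; genes with relevance ≥ 10 (inclusive) are
retained, duplicates keep their maximum score, symbols are uppercased. The
overlap with a drug-target list is exact set intersection, and its size is
tested against a hypergeometric upper tail P(X ≥ k) over an explicit,
caller-supplied gene universe (never inferred silently).

## The end-to-end demo study

`pipeline.run_all` wires all stages with a single YAML-loadable config and
one master seed (stage seeds derived by fixed offsets; reruns are
byte-identical). The demo roster plants three distinguishable drugs: one
with a reporting signal (RR 10, Weibull(60 d, 0.6) onset), the structural
motif *and* an enriched expression signature; one motif-only decoy (models
flag it, no reporting signal); one signal-only decoy (RR 6, no motif). A
co-medicated confounder rides along on 20% of signal reports and is removed
by the sensitivity rerun. The pipeline's final hit list — consensus signal ∧
all model scores > 0.60 ∧ signature ANOVA p < 0.05 — should contain exactly
the fully-planted drug, and the acceptance suite asserts that it does.

Default problem sizes (30,000 reports, 120 training molecules, 60 bulk
samples, 800 cells, 250 training epochs, search budget 3) were chosen as the
smallest sizes at which the planted effects are comfortably identifiable;
they complete in well under a minute on one CPU.

## What the synthetic data does and does not show

The generators reproduce the *structure* of the real inputs — report layout
and duplication, name normalisation quirks (`CELECOXIB.|CELECOXIB`),
onset-time distributions, count noise, QC failure modes — but not their
content: no MedDRA hierarchy, no real reporting biases beyond the planted
confounder, no correlated gene networks, and molecule labels defined by an
explicit motif rather than by clinical adversity. Passing tests therefore
demonstrate that each method recovers effects of the planted kind at the
stated sizes, not that the original clinical findings replicate; headline
quantities from real-data studies (specific AUCs, drug counts, cohort
percentages) are functions of those datasets and are out of scope here.

## Numerical choices and limitations

* MGPS fitting can in principle converge to a degenerate mixture on tiny
  grids; the multi-start keeps the best likelihood and raises if no start
  converges.
* EBGM05 root-finding brackets from 1e-12 upward, doubling until the CDF
  exceeds 5%.
* The Weibull profile root is bracketed by doubling the upper bound; Fisher
  CIs are asymptotic and can under-cover for n below a few dozen.
* ssGSEA tie handling uses average ranks with a stable descending walk, so
  tied genes contribute deterministically.
* The GCN/DMPNN are intentionally compact (tens of thousands of parameters);
  they are not meant to match large-scale chemprop-style training and their
  scores on 12-molecule test splits are coarse (granularity 1/36).
* Interval-censored onset likelihoods, tautomer enumeration, 3D conformers,
  real FAERS quarterly parsing, and network/pathway enrichment are all out
  of scope.
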