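# Methods

## Pair indicators and canonicalisation

The elementary feature is the within-sample ordering indicator
I_ab(s) = 1{expr[a, s] > expr[b, s]}.  Ties score 0, by a strict reading
of "greater than"; this matters for FPKM data where both genes of a pair
are often exactly 0, and makes zero–zero pairs deterministically 0.  Pairs
are stored once, in the canonical orientation gene_a < gene_b
(lexicographic): the reverse orientation is the complement up to ties and
would only duplicate perfectly anti-correlated features.  Pair matrices
over a gene panel enumerate all C(n, 2) unordered pairs; no
within-pathway-only restriction is applied.

Because the indicator depends only on the ordering of two values inside a
single sample, any strictly increasing per-sample map of expression —
log-transforms, affine platform scalings, power distortions — leaves the
pair matrix bit-identical.  This is a theorem about the construction, and
the test suite verifies it both directly (hypothesis-generated monotone
maps) and through the generator's distortion machinery.

## Invariance filter

A pair is excluded iff in **any** cohort its majority class (all-0 or
all-1) covers strictly more than 80% of samples; a pair at exactly 80% is
kept ("more than" is strict).  The filter is evaluated per cohort on the
cohort's own pair matrix; kept ∪ excluded always partitions the
candidate list.  Threshold configurable (`filter_invariant_pairs(...,
threshold=)`).

## Prognostic screen

Each surviving pair is fit in a univariate Cox proportional-hazards model
(lifelines; Efron tie handling; Wald p-values).  Pairs with p < 0.05 are
kept.  No multiple-testing correction enters the selection — the screen is
a deliberately liberal pre-filter ahead of the much stricter resampled
LASSO stage — but Benjamini–Hochberg adjusted p-values are reported in the
screen table for transparency.  Constant indicators and non-converging
fits (e.g. complete separation) are flagged degenerate and dropped rather
than raised, since they are expected in routine operation.

## Robust LASSO selection

For each of `n_iter` (default 1000) iterations, 80% of samples are drawn
without replacement (bootstrap resampling available by flag), an
L1-penalised Cox path is fitted (scikit-survival Coxnet), and the penalty
is chosen by 3-fold cross-validated Breslow partial likelihood computed on
held-out folds; pairs with nonzero coefficients at the chosen penalty are
recorded.  A pair is *robust* if selected in strictly more than `min_freq`
(default 50) iterations.  Subsampling — not merely CV-fold randomness — is
what makes the selection frequencies informative about stability.
Iterations with too few events or numerical failure are skipped and
counted in a warning.

## Forward AUROC construction

Candidates are ordered by selection frequency (descending), ties broken by
univariate p (ascending).  For each prefix of the ordered list an
unpenalised multivariate Cox model is fitted and its linear predictor is
scored by time-dependent AUC at a single user-chosen horizon (default 3
cohort time-units); the first prefix attaining the maximum AUC becomes the
signature, with that fit's coefficients (unpenalised refit by
construction).  Degenerate prefixes are skipped with a warning.  The full
prefix-AUC trace is stored in the model's provenance for audit.

The risk cutoff is the Youden-J maximiser (J = TPR − FPR) over the
winning model's time-dependent ROC thresholds, ties resolved toward the
smaller threshold; samples scoring strictly above the cutoff are
high-risk.  The horizon, the cutoff rule, the trace and the seed are
recorded in the serialised model (JSON, schema-versioned).

## Time-dependent ROC

Cumulative-case / dynamic-control estimator with
inverse-probability-of-censoring weights: at horizon t, cases are subjects
with an observed event at or before t, weighted 1/G(T−) where G is the
Kaplan–Meier estimate of the censoring survival function (left limit);
controls are subjects observed beyond t.  TPR/FPR are weighted exceedance
fractions over the observed score thresholds, AUC the trapezoid area
including the virtual all-positive endpoint.  This estimator is monotone
in the threshold by construction and reduces exactly to the empirical
binary ROC when no censoring occurs before the horizon (asserted in
tests).  The nearest-neighbour/KM-subgroup variant found in some R tools
was deliberately not used because it does not guarantee monotone curves.

## Survival machinery

Kaplan–Meier, log-rank (chi-square across ≥2 groups) and multivariate Cox
fits delegate to lifelines.  Harrell's C follows the standard convention:
usable pairs require the earlier member's event to be observed; risk ties
count 1/2.  All four estimators are cross-checked in the test suite
against independent brute-force implementations (explicit product-limit
products, O−E/V enumeration, pair enumeration, direct IPCW evaluation) to
1e-10 on small instances.

## Consensus subtyping

Samples are clustered on binary pair profiles by hierarchical clustering
with Jaccard distance and average linkage (both configurable), repeated
over `n_resamples` random 80% subsamples; the consensus matrix records
co-clustering frequencies among co-sampled pairs of samples, and final
labels cut a hierarchical tree on 1 − consensus at the user's k.  k is
never chosen automatically; a PAC (proportion of ambiguous clustering)
report assists the choice.  Two all-zero profiles have Jaccard distance 0
by convention (identical samples).

## Microenvironment scores

* **Marker abundance**: arithmetic mean of log2 expression of a panel's
  present markers (user-supplied GMT panels; published marker/coefficient
  sets are not redistributed).
* **Single-sample set score**: genes ranked ascending within a sample
  (average ranks on ties); score = 2·(meanRank(S) − (G+1)/2)/(G−1) ∈
  [−1, 1].  This documented rank-mean statistic replaces kernel-CDF
  enrichment scoring; it shares the monotone-invariance property of the
  pair transform, and a hook exists to substitute any external scorer
  producing a set × sample table.
* **Immune/stromal composites**: set scores of the two panels; the
  combined score is their sum.
* **Differential signatures**: effect = difference of group mean scores
  (set scores can be negative, so a log-ratio fold change is undefined;
  the |effect| > 0.2 threshold semantics are preserved), two-sided
  rank-sum p, BH adjustment across sets, flag iff |effect| > 0.2 and
  adjusted p < 0.05.
* **Immune quadrants**: per-gene median cutpoints on CD274 and CD8A by
  default (configurable and logged; there is no canonical cutpoint);
  values exactly at a cutpoint count as low.  Quadrant I (both high) is
  the favourable-immunotherapy type.
* **Checkpoint genes**: default list {PDCD1, CD274, CTLA4, LAG3, HAVCR2,
  TIGIT, PDCD1LG2}, fully overridable — the conventional clinically
  assayed panel.

## Decision curves and summaries

Net benefit NB(pt) = TP/n − (FP/n)·pt/(1−pt) with positivity at predicted
probability ≥ pt; pt = 1 is rejected (undefined odds).  Risk scores map
to event probabilities via a one-covariate Cox fit:
1 − S0(t)^exp(β·(score − mean)).  Cohort summary tables count missing
values as an explicit "Unknown" category and round percentages half-up to
one decimal.

## Synthetic generator

Per cohort: gene baseline log-expression ~ Normal(μ_g, σ_g) with μ_g ~
N(1, 1), σ_g ~ U(0.3, 1) drawn once globally (so cohorts share gene-level
structure); expression is exponentiated to a positive FPKM-like scale.
Each planted pair's indicator is Bernoulli(prevalence), realised by
swapping the two genes' draws within a sample — the planted ordering
therefore survives any monotone distortion by construction.  Survival is
exponential with rate h₀·exp(Σ β_p·I_p) (proportional hazards hold
exactly, matching the downstream Cox assumptions), censoring uniform on
(0, censor_max) independent of covariates, observed time the minimum.
Optional structure: per-cohort monotone distortions (identity / affine
a·x+b with a>0 / power x^γ with γ>0), marker-panel elevation in a random
half of samples (log-scale shift δ), and a metastasis label with log-odds
proportional to centred true risk.  Planted pairs must be gene-disjoint;
sharing a gene would couple the planted indicators.  Identical seeds give
bit-identical output; per-cohort streams are derived from the master seed.

What the generator does **not** emulate: realistic FPKM marginals,
gene–gene correlation beyond the planted swaps, informative censoring,
competing risks, copy-number/mutation structure.  Passing recovery tests
therefore demonstrate correctness of the machinery under the stated
model, not performance on real tumour cohorts.

## Validation studies and problem sizes

The benchmark studies (`pairsig.benchmarks`) fix these conditions:

* *Recovery*: 5 planted pairs (β = 1.5, prevalence 0.5) plus 50 null
  pairs on disjoint genes (110 genes total); two training cohorts of 150
  and one held-out cohort of 150; h₀ = 0.01 with censor_max = 10 giving
  ≈30% censoring; LASSO at the full 1000 iterations with min_freq 50;
  horizon 3; 20 seeds.  Null pairs are built from genes disjoint from the
  planted ones because any pair sharing a planted gene inherits real
  signal through the within-sample swap and is not a negative control.
* *Screen calibration*: 1000 independent single-pair null cohorts of
  n = 100.
* *Consensus*: two 30-sample blocks over 40 pairs with 5% indicator
  flips.
* *Oracle comparisons*: enumerable instances of ≤ 8 subjects.

## Known limitations

Multi-probe platforms must be collapsed to one row per gene upstream
(duplicate gene ids are rejected, never silently merged).  Time units are
cohort-local and never converted; horizons are the caller's
responsibility.  The forward-AUROC search evaluates training AUC and can
admit a correlated extra pair past the planted set (observed precision
< 1 in some seeds); no internal validation split is attempted because the
construction mirrors a sequential-inclusion design.  The pipeline's
`--resume`-style partial re-execution is not implemented; determinism is
provided by full re-runs being byte-identical.
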