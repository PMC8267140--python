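# pairsig

Rank-based gene-pair prognostic signatures for multi-cohort survival
transcriptomics.

## The problem

Expression-based prognostic signatures usually break when moved across
platforms: absolute FPKM/array intensities need renormalisation, and batch
effects leak into the score. `pairsig` builds signatures from
**within-sample gene-pair orderings** (the top-scoring-pairs family): for a
pair of genes (a, b) and sample *s* the feature is the binary indicator

    I_ab(s) = 1  if expr[a, s] > expr[b, s], else 0

which depends only on the relative ordering of two genes inside one sample
and is therefore invariant to any per-sample monotone distortion — no
cross-cohort normalisation required.

## The method

Starting from gene-by-sample expression matrices and survival tables for
one or more cohorts, the pipeline:

1. **extracts** a gene panel from pathway collections (GMT; e.g. all
   `*_METABOLISM` KEGG sets), intersected across cohorts;
2. **builds** the C(n, 2) binary pair matrix per cohort and **filters**
   pairs whose majority class exceeds 80% of samples in any cohort
   (near-constant indicators carry no information);
3. **screens** each pair with a univariate Cox proportional-hazards model,
   keeping pairs with Wald p < 0.05;
4. optionally **clusters** samples into molecular subtypes by resampled
   consensus clustering of the binary profiles (Jaccard distance);
5. **selects** robust pairs by 1000 subsampled L1-penalised Cox fits
   (penalty chosen per iteration by cross-validated partial likelihood);
   a pair is robust if selected in more than 50 iterations;
6. **constructs** the signature by walking the frequency-ordered robust
   list: the prefix whose multivariate Cox linear predictor maximises the
   time-dependent (cumulative/dynamic, IPCW) AUC at a chosen horizon wins;
   the risk score is `sum_i beta_i * I_i(s)` and the high/low cutoff is the
   Youden optimum of the winning model's time-dependent ROC;
7. **evaluates** with Kaplan–Meier/log-rank risk-group comparisons,
   Harrell's C, stratified and crossed analyses, decision curves, and
   microenvironment scores (marker abundance, rank-based single-sample set
   scores, immune/stromal composites, CD274xCD8A immune quadrants).

A seeded synthetic generator (`pairsig.simulate`) produces multi-cohort
log-normal expression with planted prognostic pair-orderings, exponential
proportional-hazards survival, uniform censoring and per-sample monotone
platform distortions, so every stage is testable without external data.

## Worked example

`examples/02_build_signature.py` simulates three cohorts (two training,
one held out) with three planted pairs (log hazard ratio 1.5) and runs the
full cascade:

```
selection funnel: {'genes': 16, 'pairs_built': 120, 'pairs_kept_after_filter': 67,
                   'pairs_screened': 42, 'pairs_robust': 23, 'pairs_final': 4}
signature pairs: ['G00004|G00005', 'G00002|G00003', 'G00003|G00006', 'G00000|G00001']
coefficients: [1.971, 0.897, -0.808, 1.224]
risk cutoff: 1.224 (Youden optimum at horizon 5.0)
held-out log-rank: statistic=42.16, p=8.39e-11
```

The funnel counts pairs surviving each stage; the final model contains the
three planted pairs (plus one correlated partner), and the high/low split
it induces on the untouched held-out cohort separates survival at
p ≈ 10⁻¹¹.  The other examples cover simulation (`01`), consensus
subtyping (`03`), microenvironment scoring (`04`) and decision curves
(`05`); each prints a short interpretation of its output.

A thin CLI mirrors the library for file-based runs:
`pairsig simulate --config sim.json --out fixtures/` and
`pairsig run --config run.json`.

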