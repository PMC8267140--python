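"""Generate synthetic multi-cohort survival transcriptomics data.

Builds two cohorts with one planted prognostic pair-ordering and a
platform distortion on the second cohort, then prints the planted
indicator prevalence and the observed event rates.
"""

from pairsig import PlantedPair, SimulationConfig, build_pair_matrix, simulate
from pairsig.simulate import gene_name

config = SimulationConfig(
    n_genes=20,
    cohorts=(("discovery", 120), ("validation", 60)),
    planted_pairs=(PlantedPair(gene_name(0), gene_name(1), beta=1.5),),
    baseline_hazard=0.05,
    censor_max=15.0,
    batch_distortion={"validation": ("power", 0.4)},
    seed=7,
)

for (name, _), (expr, clin) in zip(config.cohorts, simulate(config)):
    pm = build_pair_matrix(expr, [gene_name(0), gene_name(1)])
    print(f"{name}: {expr.n_genes} genes x {expr.n_samples} samples, "
          f"event rate {clin.event.mean():.2f}, "
          f"planted indicator prevalence {pm.values.mean():.2f}")

# The prevalence sits near 0.5 in BOTH cohorts although the validation
# cohort's expression went through a strong monotone platform distortion:
# within-sample orderings are untouched, which is the point of pair scoring.
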