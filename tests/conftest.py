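import numpy as np
import pandas as pd
import pytest

from pairsig import (
    ClinicalTable,
    ExpressionMatrix,
    PlantedPair,
    SimulationConfig,
    simulate,
)
from pairsig.simulate import gene_name


def expr_from(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def clin_from(time, event, samples=None, **extra) -> ClinicalTable:
    samples = samples or [f"s{j}" for j in range(len(time))]
    return ClinicalTable(
        pd.DataFrame({"time": time, "event": event, **extra},
                     index=pd.Index(samples, name="sample_id"))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def planted_cohort():
    """One simulated cohort with a strongly prognostic planted pair."""
    config = SimulationConfig(
        n_genes=8,
        cohorts=(("A", 200),),
        planted_pairs=(PlantedPair(gene_name(0), gene_name(1), 1.5),),
        baseline_hazard=0.05,
        censor_max=20.0,
        seed=42,
    )
    expr, clin = simulate(config)[0]
    return config, expr, clin
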