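import numpy as np
import pytest

from micropheno import syndata, tables


@pytest.fixture
def small_counts():
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(12, 6))
    counts[:, 0] += 1  # keep one taxon ubiquitous so no sample row is empty
    return tables.CountTable(
        [f"S{i}" for i in range(12)], [f"T{j}" for j in range(6)], counts
    )


@pytest.fixture
def cohort300():
    """Simulated cohort with 5 planted taxa at strong effects (n=300)."""
    cfg = syndata.SimulationConfig(
        n_samples=300,
        library_size_mean=40_000,
        n_causal_taxa=5,
        beta1_effects=np.full(5, 1.5),
        beta2_effects=np.full(5, 1.5),
        noise_sd=1.0,
        sex_effect=0.2,
        cage_effect_sd=0.1,
        seed=0,
    )
    counts = syndata.gen_count_table(cfg)
    pheno, truth = syndata.gen_phenotype(counts, cfg)
    pheno = tables.residualize(pheno)
    abund = tables.to_relative(counts)
    return counts, abund, pheno, truth
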