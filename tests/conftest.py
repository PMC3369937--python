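import numpy as np
import pandas as pd
import pytest

from egwas.simulate import SimulationConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def small_null_study():
    """A small two-cohort, two-tissue study with no planted effects."""
    cfg = SimulationConfig(n_subjects=120, n_snps=300, n_probes=60, seed=7)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def planted_study():
    """A study with strong planted cis effects of heterogeneous size and
    sign, shared across cohorts and tissues."""
    import dataclasses

    from egwas.simulate import plant_effects, simulate_map_and_annotation

    cfg = SimulationConfig(
        n_subjects=200,
        n_snps=400,
        n_probes=80,
        maf_range=(0.1, 0.5),
        sigma_subject=0.0,
        sigma_noise=1.0,
        n_catalog=60,
        catalog_enrichment=1.0,
        seed=11,
    )
    gen = np.random.default_rng(cfg.seed)
    snp_map, annotation = simulate_map_and_annotation(cfg, gen)
    base = plant_effects(annotation, snp_map, 15, 1.0, gen, cfg.window_bp)
    betas = np.linspace(0.8, 2.0, 15) * np.where(np.arange(15) % 2, 1.0, -1.0)
    effects = [(p, s, float(b)) for (p, s, _), b in zip(base, betas)]
    return simulate_study(dataclasses.replace(cfg, effect_table=effects))


@pytest.fixture
def tiny_annotation():
    return pd.DataFrame(
        {
            "probe": ["PRA", "PRB"],
            "symbol": ["GENEA", "GENEB"],
            "chrom": ["1", "2"],
            "start": [1_000_000, 5_000_000],
            "end": [1_010_000, 5_020_000],
        }
    )
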