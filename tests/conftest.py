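import numpy as np
import pytest

from cnvconcord import (
    SimConfig,
    derive_assemblies,
    design_probes,
    generate_genomes,
    simulate_hybridization,
)
from cnvconcord.hitcount import build_hit_table


def small_config(**overrides) -> SimConfig:
    """A fast study: ~100 kb backbone, 24 genes, 12 planted families."""
    base = dict(
        seed=11,
        genome_length=100_000,
        n_genes=24,
        gene_length=300,
        n_cnv_regions=12,
        copy_range_a=(1, 5),
        copy_range_b=(1, 5),
        collapse_probability=0.5,
        divergence_rate=0.0,
        noise_sd=0.3,
        gc_bias_coeff=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Zero noise, zero GC bias, no collapse: every stage should recover
    the planted truth exactly."""
    cfg = small_config(noise_sd=0.0, collapse_probability=0.0)
    return _build(cfg)


@pytest.fixture(scope="session")
def collapsed_dataset():
    """Deterministic full collapse, noiseless arrays: the inter-platform
    signal is exactly the planted collapse pattern."""
    cfg = small_config(noise_sd=0.0, collapse_probability=1.0)
    return _build(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Study conditions for the qualitative platform-ordering result."""
    cfg = small_config()
    return _build(cfg)


def _build(cfg):
    genome_a, genome_b, annotation, truth = generate_genomes(cfg)
    a_long, a_short = derive_assemblies(genome_a, truth, cfg)
    b_long, b_short = derive_assemblies(genome_b, truth, cfg)
    probeset = design_probes(genome_a, annotation, cfg)
    signals = simulate_hybridization(probeset, truth, cfg)
    assemblies = {"a_long": a_long, "a_short": a_short, "b_long": b_long, "b_short": b_short}
    hit_table = build_hit_table(probeset, assemblies)
    return {
        "config": cfg,
        "genome_a": genome_a,
        "genome_b": genome_b,
        "annotation": annotation,
        "truth": truth,
        "assemblies": assemblies,
        "probeset": probeset,
        "signals": signals,
        "hit_table": hit_table,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
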