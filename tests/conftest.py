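import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from beefcand.simulate import SimConfig, gen_annotation, gen_counts

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_config(seed: int = 0, **kw) -> SimConfig:
    """A scaled-down study: 800 genes on six 60-Mb chromosomes.

    Keeps the screen-placement geometry feasible while making per-test
    simulation cheap; counts default to 4 animals per group.
    """
    defaults = dict(
        seed=seed,
        n_genes=800,
        chrom_lengths={str(i): 60_000_000 for i in range(1, 7)},
        n_samples_per_group=4,
        n_planted_degs=20,
        n_annotated_degs=15,
        n_pseudogene_degs=2,
        n_qtl_pass=5,
        planted_candidate_fraction=3 / 5,
        n_qtls=20,
        n_snps=20,
        log2fc_range=(2.0, 4.0),
        nb_dispersion=0.02,
        library_size_range=(2e6, 3e6),
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def sim_small():
    """One small simulated study shared across read-only tests."""
    cfg = small_config(seed=11)
    genes = gen_annotation(cfg)
    counts, truth = gen_counts(genes, cfg)
    return cfg, genes, counts, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
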