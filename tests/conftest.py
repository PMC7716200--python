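import numpy as np
import pandas as pd
import pytest

from lpeval.simdata import (
    SimConfig,
    simulate_individuals,
    simulate_panel,
    simulate_phenotypes,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_panel_haplotypes=60,
        n_variants=400,
        chromosome_length=4_000_000,
        n_populations=2,
        divergence=0.15,
        recomb_rate=1e-6,
        n_target_animals=12,
        pedigree_depth=2,
        n_qtl=30,
        h2_true=0.5,
        coverage=1.0,
        base_error=0.01,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return simulate_panel(small_cfg)


@pytest.fixture(scope="session")
def small_world(small_cfg, small_panel):
    pedigree, truth = simulate_individuals(small_panel, small_cfg)
    phenos = simulate_phenotypes(truth, small_cfg)
    pileup = simulate_reads(truth, small_cfg)
    return {
        "cfg": small_cfg,
        "panel": small_panel,
        "pedigree": pedigree,
        "truth": truth,
        "phenotypes": phenos,
        "pileup": pileup,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_pedigree(rng, n=50, n_founders=10):
    """Random acyclic pedigree for oracle comparisons."""
    animal = [f"X{i}" for i in range(n)]
    sire, dam = [], []
    for i in range(n):
        if i < n_founders:
            sire.append("0")
            dam.append("0")
        else:
            s, d = rng.choice(i, size=2, replace=False)
            sire.append(animal[s])
            dam.append(animal[d])
    return pd.DataFrame({"animal": animal, "sire": sire, "dam": dam})
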