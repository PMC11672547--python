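"""Shared fixtures: synthetic benchmarks are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from pepevo import (MSA, Alphabet, PottsPseudolikelihood, Scaffold,
                    SamplerConfig, sample_sequences)
from pepevo.synthetic_data import (benchmark_family, enumerate_distribution,
                                   make_planted_model,
                                   standard_planted_benchmark)


@pytest.fixture(scope="session")
def planted_benchmark():
    """The standard coupling-recovery benchmark and its fitted model."""
    planted, msa = standard_planted_benchmark()
    results = PottsPseudolikelihood(msa).fit()
    return planted, msa, results


@pytest.fixture(scope="session")
def bench_family():
    """The full-pipeline synthetic family (records, scaffold, truth)."""
    return benchmark_family(seed=0)


@pytest.fixture(scope="session")
def tiny_boltzmann():
    """A tiny enumerable Potts model (L=4, q=4) with its exact distribution
    and two sampling runs of different depth (10^3 and 10^5 recorded states).
    """
    planted = make_planted_model(L=4, q=4, n_conserved=1, n_pairs=1,
                                 field_scale=1.5, coupling_scale=1.5,
                                 background_field_sd=0.3,
                                 background_coupling_sd=0.2, seed=7)
    model = planted.potts
    sequences, probs = enumerate_distribution(model)
    exact = dict(zip(sequences, probs))

    def run(total_records: int, seed: int):
        per_chain = total_records // 10
        cfg = SamplerConfig(n_chains=10, steps=1000 + per_chain * 20,
                            burn_in=1000, thinning=20, temperature=1.0,
                            seed=seed, init="random_scaffold_conformant")
        return sample_sequences(model, model.scaffold, cfg)

    return {"model": model, "exact": exact,
            "shallow": run(1_000, 123), "deep": run(100_000, 123)}


@pytest.fixture
def small_msa():
    """Deterministic 8-sequence random alignment on a free L=5, q=6 scaffold."""
    rng = np.random.default_rng(42)
    alphabet = Alphabet("ACDEFG")
    scaffold = Scaffold(L=5, fixed={}, name="free-5")
    matrix = rng.integers(6, size=(8, 5))
    return MSA(ids=[f"s{i}" for i in range(8)], matrix=matrix,
               scaffold=scaffold, alphabet=alphabet)
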