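"""Shared fixtures: small deterministic sequences and simulated chromosomes."""

import numpy as np
import pytest

from centroscape.simulate import SimConfig, simulate_chromosome


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)


def random_seq(rng, n, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


@pytest.fixture(scope="session")
def small_sim():
    """A small (1.2 Mb) simulated chromosome shared across tests."""
    cfg = SimConfig(
        chromosome_length=1_200_000,
        cent_span=250_000,
        peri_spans=(150_000, 150_000),
        telomere_span=3_000,
        n_ltr_per_compartment={
            "centromere": {"ALE": 5, "CRM": 3},
            "pericentromere": {"Tekay": 4, "Retand": 3},
            "arm": {"ALE": 1, "Athila": 1},
        },
        seed=424_242,
    )
    seq, truth = simulate_chromosome(cfg)
    return seq, truth


@pytest.fixture(scope="session")
def default_sim():
    """The default 3 Mb study-condition chromosome."""
    seq, truth = simulate_chromosome(SimConfig(seed=77))
    return seq, truth
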