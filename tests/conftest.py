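"""Shared fixtures: small networks, truth parameters and simulated datasets."""

import numpy as np
import pytest

import grndesign as gd


def simulate_dataset(network, truth, noise, times, species=None, perturbation=gd.WILDTYPE,
                     seed=0, noise_free=False, condition_id="c0"):
    """Vend a (possibly noise-free) dataset from a known truth."""
    system = gd.build_rhs(network, truth, perturbation)
    traj = gd.integrate(system, network.x0(), times)
    species = species or network.species
    rng = np.random.default_rng(seed)
    rows = []
    for sp in species:
        x = np.maximum(traj.states[network.species_index[sp]], 0.0)
        y = x if noise_free else gd.simulate_measurement(x, noise, rng)
        rows += [(condition_id, sp, float(t), float(v)) for t, v in zip(times, y)]
    return gd.Dataset.from_records(rows, {condition_id: perturbation}, noise)


@pytest.fixture(scope="session")
def noise():
    return gd.NoiseModel()  # sigma_abs 0.1, sigma_rel 0.2, clipping on


@pytest.fixture(scope="session")
def single_gene():
    net = gd.GeneNetwork(genes=("1",))
    truth = gd.ParameterVector.for_network(
        net, values={"pro_1": 2.0, "rbs_1": 1.5, "delta_p": 0.5}
    )
    return net, truth


@pytest.fixture(scope="session")
def single_gene_times():
    return np.linspace(0.5, 10, 20)


@pytest.fixture(scope="session")
def single_gene_noisy(single_gene, noise, single_gene_times):
    net, truth = single_gene
    return simulate_dataset(net, truth, noise, single_gene_times, seed=42)


@pytest.fixture(scope="session")
def two_gene():
    """A two-gene feedback circuit with a known truth (seeded generator)."""
    return gd.synth_network(2, 2, seed=5)


@pytest.fixture(scope="session")
def three_gene():
    return gd.synth_network(3, 3, seed=1)
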