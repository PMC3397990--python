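"""Network containers, rate laws and perturbation rewrites."""

import numpy as np
import pytest
import yaml
from hypothesis import given, settings, strategies as st

import grndesign as gd
from grndesign.grn_model import (
    ACTIVATION,
    REPRESSION,
    Interaction,
    parameter_names,
    perturbation_multipliers,
)


@pytest.mark.parametrize(
    "name, expected",
    [("grn6", 29), ("grn7", 35), ("grn9", 49)],
)
def test_bundled_networks_parameter_counts(name, expected):
    net = gd.bundled_network(name)
    assert gd.count_parameters(net) == expected
    assert len(parameter_names(net)) == expected
    assert len(net.species) == 2 * net.n_genes


def test_single_gene_has_three_parameters(single_gene):
    net, _ = single_gene
    assert gd.count_parameters(net) == 3


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(1, 10), st.integers(0, 20), st.integers(0, 10**6))
def test_parameter_count_matches_enumeration(G, I, seed):
    """2G + 1 + 2I equals a brute-force count of the named parameters."""
    I = min(I, G * (G - 1))
    net, _ = gd.synth_network(G, I, seed)
    names = parameter_names(net)
    brute = (
        sum(1 for n in names if n.startswith("pro_"))
        + sum(1 for n in names if n.startswith("rbs_"))
        + sum(1 for n in names if n == "delta_p")
        + sum(1 for n in names if n.startswith(("h_", "kd_")))
    )
    assert len(set(names)) == brute == gd.count_parameters(net) == 2 * G + 1 + 2 * I


def test_network_validation():
    with pytest.raises(ValueError):
        gd.GeneNetwork(genes=("1", "1"))
    with pytest.raises(ValueError):
        gd.GeneNetwork(genes=("1",), interactions=(Interaction("1", "2", ACTIVATION),))
    with pytest.raises(ValueError):
        gd.GeneNetwork(
            genes=("1", "2"),
            interactions=(
                Interaction("1", "2", ACTIVATION),
                Interaction("1", "2", REPRESSION),
            ),
        )
    with pytest.raises(ValueError):
        gd.GeneNetwork(genes=("1",), initial_conditions={"p9": 1.0})


def test_network_yaml_roundtrip(tmp_path):
    net = gd.bundled_network("grn6")
    path = tmp_path / "net.yaml"
    path.write_text(yaml.safe_dump(net.to_dict()))
    again = gd.load_network(path)
    assert again == net


def test_regulation_rate_reference_points():
    # half saturation, and the two saturation limits
    assert gd.regulation_rate(1.0, ACTIVATION, 2.0, 1.0, 3.0) == pytest.approx(1.5)
    assert gd.regulation_rate(0.0, ACTIVATION, 2.0, 1.0, 3.0) == 0.0
    assert gd.regulation_rate(0.0, REPRESSION, 2.0, 1.0, 3.0) == pytest.approx(3.0)
    # strong repressor far above Kd shuts transcription off
    assert gd.regulation_rate(100.0, REPRESSION, 8.0, 1.0, 3.0) < 1e-12
    with pytest.raises(ValueError):
        gd.regulation_rate(-0.1, ACTIVATION, 2.0, 1.0, 3.0)


def test_transcription_rate_sums_over_regulators():
    net = gd.GeneNetwork(
        genes=("1", "2", "3"),
        interactions=(
            Interaction("1", "3", ACTIVATION),
            Interaction("2", "3", ACTIVATION),
        ),
    )
    params = gd.ParameterVector.for_network(
        net,
        values={
            "pro_1": 1.0, "pro_2": 1.0, "pro_3": 2.0,
            "rbs_1": 1.0, "rbs_2": 1.0, "rbs_3": 1.0,
            "delta_p": 1.0,
            "h_1": 2.0, "kd_1": 0.7, "h_2": 3.0, "kd_2": 1.3,
        },
    )
    # both activators exactly at their Kd: each contributes half saturation
    levels = {"1": 0.7, "2": 1.3, "3": 0.0}
    assert gd.transcription_rate(net, "3", levels, params) == pytest.approx(2.0 * (0.5 + 0.5))
    assert gd.transcription_rate(net, "1", levels, params) == pytest.approx(1.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10**6), st.floats(0.0, 1e4))
def test_rates_non_negative(seed, level):
    """All transcription rates stay non-negative for non-negative states."""
    net, truth = gd.synth_network(3, 4, seed % 1000)
    levels = {g: level for g in net.genes}
    for g in net.genes:
        assert gd.transcription_rate(net, g, levels, truth) >= 0.0


def test_apply_perturbation_rewrites(two_gene):
    net, truth = two_gene
    sirna = gd.apply_perturbation(net, truth, gd.Perturbation("sirna", "1"))
    assert sirna.delta_m[0] == pytest.approx(5.0)
    assert sirna.delta_m[1] == pytest.approx(1.0)

    boost = gd.apply_perturbation(net, truth, gd.Perturbation("rbs_boost", "2"))
    assert boost["rbs_2"] == pytest.approx(2.0 * truth["rbs_2"])
    assert boost["rbs_1"] == pytest.approx(truth["rbs_1"])

    wt = gd.apply_perturbation(net, truth, gd.WILDTYPE)
    np.testing.assert_allclose(wt.values, truth.values)

    ko = gd.apply_perturbation(net, truth, gd.Perturbation("knockout", "1"))
    assert ko["pro_1"] == 0.0 and ko["rbs_1"] == 0.0
    twice = gd.apply_perturbation(net, ko, gd.Perturbation("knockout", "1"))
    np.testing.assert_allclose(twice.values, ko.values)

    extra = gd.apply_perturbation(
        net, truth, gd.Perturbation("sirna", "1", extra=(("pro_2", 0.5),))
    )
    assert extra["pro_2"] == pytest.approx(0.5 * truth["pro_2"])


def test_knockout_trajectories_decay(two_gene):
    net, truth = two_gene
    system = gd.build_rhs(net, truth, gd.Perturbation("knockout", "1"))
    times = np.linspace(0.5, 20, 20)
    x0 = np.full(4, 0.5)
    traj = gd.integrate(system, x0, times)
    m1 = traj.species_row("mRNA1")
    p1 = traj.species_row("p1")
    assert np.all(np.diff(m1) <= 1e-12) and m1[-1] < 0.01
    assert p1[-1] < p1[0]


def test_perturbation_multiplier_chain(two_gene):
    """Sensitivity chain factors vanish exactly for knocked-out parameters."""
    net, truth = two_gene
    mult, dm = perturbation_multipliers(net, truth, gd.Perturbation("knockout", "2"))
    assert mult[truth.index("pro_2")] == 0.0
    assert mult[truth.index("rbs_2")] == 0.0
    assert np.all(dm == 1.0)


def test_build_rhs_rejects_wrong_length(two_gene):
    net, _ = two_gene
    other = gd.GeneNetwork(genes=("1",))
    params = gd.ParameterVector.for_network(other)
    with pytest.raises(ValueError):
        gd.build_rhs(net, params)
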