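"""Design enumeration, trajectory-spread scoring and ranking."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import grndesign as gd
from grndesign.estimation import LikelihoodObjective, fit
from grndesign.experiment_design import (
    DesignState,
    ExperimentDesign,
    GelShift,
    Microarray,
    ProteinPair,
    design_step,
    enumerate_designs,
    rank_designs,
    readout_species,
    readout_times,
    score_designs,
    extrapolation_uncertainty,
)
from grndesign.profile_likelihood import ProfileOptions, confidence_interval, profile_all
from grndesign.virtual_lab import CostTable
from conftest import simulate_dataset

COSTS = CostTable()

LOOP_OPTS = ProfileOptions(
    step_init=0.4, step_max=1.0, max_steps=4, target_divisor=2.0,
    reopt_method="wls", reopt_maxiter=10, reopt_gtol=1e-6,
)


@pytest.mark.parametrize(
    "name, expected", [("grn6", 331), ("grn7", 516), ("grn9", 1079)]
)
def test_design_space_sizes(name, expected):
    net = gd.bundled_network(name)
    assert len(enumerate_designs(net, COSTS)) == expected


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(2, 10), st.integers(0, 20), st.integers(0, 10**6))
def test_enumeration_matches_brute_force(G, I, seed):
    I = min(I, G * (G - 1))
    net, _ = gd.synth_network(G, I, seed)
    designs = enumerate_designs(net, COSTS)
    # brute-force reconstruction of the combinatorics
    n_perts = 3 * G + 1
    n_readouts = math.comb(G, 2) + 2
    assert len(designs) == n_perts * n_readouts + I
    labels = [d.label for d in designs]
    assert len(set(labels)) == len(labels)  # no duplicates


def test_readout_grids_and_point_counts():
    net = gd.bundled_network("grn6")
    pair = ProteinPair(("1", "2"))
    assert len(readout_times(pair)) == 40 and len(readout_species(net, pair)) == 2
    ma_hi = Microarray("high")
    assert len(readout_times(ma_hi)) * len(readout_species(net, ma_hi)) == 120
    ma_lo = Microarray("low")
    assert len(readout_times(ma_lo)) == 10
    with pytest.raises(ValueError):
        ProteinPair(("1", "1"))
    with pytest.raises(ValueError):
        Microarray("medium")


def test_design_validation():
    with pytest.raises(ValueError):
        ExperimentDesign(gd.WILDTYPE, GelShift(0), 1600.0)
    with pytest.raises(ValueError):
        ExperimentDesign(None, Microarray("low"), 600.0)
    with pytest.raises(ValueError):
        ExperimentDesign(gd.WILDTYPE, Microarray("low"), 0.0)


def test_predict_readout_conditions(two_gene):
    net, truth = two_gene
    pair = ExperimentDesign(gd.WILDTYPE, ProteinPair(("1", "2")), 400.0)
    wt = gd.predict_readout(net, truth, pair)
    free = gd.integrate(gd.build_rhs(net, truth), net.x0(), wt.times)
    np.testing.assert_allclose(wt.species_row("p1"), free.species_row("p1"), rtol=1e-5)
    ko = ExperimentDesign(
        gd.Perturbation("knockout", "1"), ProteinPair(("1", "2")), 950.0
    )
    ko_traj = gd.predict_readout(net, truth, ko)
    assert ko_traj.species_row("p1")[-1] < 1e-3  # knocked-out protein dies out


def test_score_design_matches_manual_recomputation(two_gene, noise):
    net, truth = two_gene
    z_hat = truth.log10
    s_tilde = np.vstack([z_hat, z_hat + 0.15, z_hat - 0.1])
    design = ExperimentDesign(gd.WILDTYPE, Microarray("low"), 600.0)
    score = gd.score_design(net, s_tilde, design, noise, z_hat, truth)
    # independent recomputation from raw trajectories
    times = readout_times(design.readout)
    trajs = [
        gd.integrate(gd.build_rhs(net, truth.with_log10(z)), net.x0(), times,
                     rtol=1e-6, atol=1e-9)
        for z in s_tilde
    ]
    ref = trajs[0]
    best = 0.0
    for sp in readout_species(net, design.readout):
        rows = np.array([t.species_row(sp) for t in trajs])
        sd = gd.combined_sd(np.maximum(ref.species_row(sp), 0.0), noise)
        best = max(best, np.max((rows.max(0) - rows.min(0)) / np.maximum(sd, 1e-12)))
    assert score.R == pytest.approx(best, rel=1e-6)
    assert score.R > 0


def test_score_invariances(two_gene, noise):
    net, truth = two_gene
    z_hat = truth.log10
    design = ExperimentDesign(gd.WILDTYPE, Microarray("low"), 600.0)
    # identical parameter vectors: zero spread
    same = np.vstack([z_hat, z_hat])
    assert gd.score_design(net, same, design, noise, z_hat, truth).R == pytest.approx(0.0, abs=1e-9)
    spread = np.vstack([z_hat, z_hat + 0.2, z_hat - 0.2])
    r1 = gd.score_design(net, spread, design, noise, z_hat, truth).R
    r2 = gd.score_design(net, spread[::-1], design, noise, z_hat, truth).R
    assert r1 == pytest.approx(r2)
    r_sum = gd.score_design(net, spread, design, noise, z_hat, truth, aggregate="sum").R
    assert r_sum >= r1  # summation over the grid dominates the maximum
    with pytest.raises(ValueError):
        gd.score_design(net, z_hat[None, :], design, noise, z_hat, truth)


def _mk_score(R, cost, label="x"):
    d = ExperimentDesign(gd.WILDTYPE, Microarray("low"), cost)
    return gd.DesignScore(d, R)


def test_rank_designs_cost_tiebreak_and_budget():
    scores = [_mk_score(5.0, 1000.0), _mk_score(5.0, 750.0), _mk_score(1.0, 400.0)]
    ranked, excluded = rank_designs(scores, budget=2000.0)
    assert [s.cost for s in ranked[:2]] == [750.0, 1000.0]  # cheaper first on ties
    assert ranked[-1].R == 1.0 and not excluded
    only, excl = rank_designs(scores, budget=800.0)
    assert {s.cost for s in only} == {750.0, 400.0} and len(excl) == 1
    none, excl = rank_designs(scores, budget=100.0)
    assert none == [] and len(excl) == 3
    single, _ = rank_designs([_mk_score(2.0, 400.0)], budget=500.0)
    assert len(single) == 1


@pytest.fixture(scope="module")
def calibrated_two_gene(two_gene, noise):
    """Weak initial data (wild-type mRNA only) with fit and profiles."""
    net, truth = two_gene
    ds = simulate_dataset(
        net, truth, noise, np.linspace(2.0, 20, 10),
        species=[s for s in net.species if s.startswith("mRNA")], seed=3,
    )
    obj = LikelihoodObjective(net, ds, rtol=1e-6, atol=1e-8, variance="data")
    res = fit(obj, truth.log10, method="wls", maxiter=150)
    ens = profile_all(obj, res.z, res.loglik, options=LOOP_OPTS)
    return net, truth, ds, obj, res, ens


def test_design_step_report_and_gelshift_rule(calibrated_two_gene, noise):
    net, truth, ds, obj, res, ens = calibrated_two_gene
    state = DesignState(
        network=net, dataset=ds, noise=noise, z_hat=res.z, ll_star=res.loglik,
        ensemble=ens, cost_table=COSTS, budget_remaining=10000.0,
        template=obj.template, max_per_profile=5,
    )
    report = design_step(state)
    assert report.n_non_identifiable > 0
    affordable = [s for s in report.scores if s.cost <= 10000.0]
    for s in affordable:  # completeness: every affordable design is listed
        assert s.design.label in report.text
    assert not report.stop_recommended
    # with non-identifiable Hill parameters, gel-shifts rank with R = inf
    from grndesign.profile_likelihood import classify_identifiability, IDENTIFIABLE

    hill_nonid = any(
        classify_identifiability(p) != IDENTIFIABLE
        for p in ens if p.name.startswith(("h_", "kd_"))
    )
    gels = [s for s in report.recommended if s.design.is_gelshift]
    if hill_nonid:
        assert any(np.isinf(s.R) for s in gels)


def test_purchasing_top_design_closes_the_ci(calibrated_two_gene, noise):
    """End-to-end: buying the top-ranked experiment resolves the planted
    non-identifiability (the profile CI becomes finite)."""
    net, truth, ds, obj, res, ens = calibrated_two_gene
    from grndesign.profile_likelihood import classify_identifiability, IDENTIFIABLE

    open_idx = [p.index for p in ens if classify_identifiability(p) != IDENTIFIABLE]
    assert open_idx
    state = DesignState(
        network=net, dataset=ds, noise=noise, z_hat=res.z, ll_star=res.loglik,
        ensemble=ens, cost_table=COSTS, budget_remaining=10000.0,
        template=obj.template, max_per_profile=5,
    )
    report = design_step(state)
    top = next(s for s in report.recommended if not s.design.is_gelshift)
    extra = simulate_dataset(
        net, truth, noise, readout_times(top.design.readout),
        species=readout_species(net, top.design.readout),
        perturbation=top.design.perturbation, seed=9, condition_id="bought",
    )
    obj2 = LikelihoodObjective(net, ds + extra, rtol=1e-6, atol=1e-8, variance="data")
    res2 = fit(obj2, res.z, method="wls", maxiter=200)
    ens2 = profile_all(obj2, res2.z, res2.loglik, options=LOOP_OPTS)
    before = sum(1 for p in ens if classify_identifiability(p) != IDENTIFIABLE)
    after = sum(1 for p in ens2 if classify_identifiability(p) != IDENTIFIABLE)
    assert after < before


def test_extrapolation_uncertainty_ranks_uncertain_parameters(calibrated_two_gene, noise):
    net, truth, ds, obj, res, ens = calibrated_two_gene
    table = extrapolation_uncertainty(
        net, ens, gd.Perturbation("sirna", "1"), noise, obj.template, n_times=15
    )
    assert set(table.columns) == {"parameter", "index", "spread"}
    assert table["spread"].iloc[0] >= table["spread"].iloc[-1]
    from grndesign.profile_likelihood import classify_identifiability, IDENTIFIABLE

    nonid_names = {p.name for p in ens if classify_identifiability(p) != IDENTIFIABLE}
    assert table.iloc[0]["parameter"] in nonid_names  # uncertainty drives spread


def test_tight_profiles_recommend_stopping(single_gene, noise, single_gene_noisy):
    """Rich, fully identifying data: all spreads small, loop should stop."""
    net, truth = single_gene
    rich = single_gene_noisy + simulate_dataset(
        net, truth, noise, np.linspace(0.5, 20, 40), seed=8, condition_id="c9"
    )
    obj = LikelihoodObjective(net, rich, rtol=1e-6, atol=1e-8, variance="data")
    res = fit(obj, truth.log10, method="wls", maxiter=200)
    ens = profile_all(
        obj, res.z, res.loglik,
        options=ProfileOptions(step_init=0.02, step_max=0.1, target_divisor=3.0,
                               reopt_method="wls", reopt_maxiter=20),
    )
    state = DesignState(
        network=net, dataset=rich, noise=noise, z_hat=res.z, ll_star=res.loglik,
        ensemble=ens, cost_table=COSTS, budget_remaining=10000.0,
        template=obj.template, max_per_profile=5,
    )
    report = design_step(state)
    assert report.n_non_identifiable == 0
    assert report.stop_recommended
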