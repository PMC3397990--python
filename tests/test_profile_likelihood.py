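"""Profile likelihoods: closed-form checks, classification, and S-tilde."""

import numpy as np
import pytest
from scipy import stats

import grndesign as gd
from grndesign.estimation import LikelihoodObjective, fit
from grndesign.profile_likelihood import (
    IDENTIFIABLE,
    PRACTICALLY_NON_IDENTIFIABLE,
    STRUCTURALLY_NON_IDENTIFIABLE,
    ProfileOptions,
    classify_identifiability,
    confidence_interval,
    count_non_identifiable,
    profile,
    profile_all,
    profile_parameter_set,
)
from conftest import simulate_dataset

from test_estimation import QuadraticToy

ECONOMY = ProfileOptions(
    step_init=0.05, step_max=0.1, target_divisor=3.0, reopt_gtol=1e-5, reopt_maxiter=40
)


@pytest.fixture(scope="module")
def gaussian_toy():
    cov = np.array([[0.04, 0.01, 0.0], [0.01, 0.09, -0.02], [0.0, -0.02, 0.0625]])
    toy = QuadraticToy([0.2, -0.4, 1.0], cov)
    ens = profile_all(toy, toy.mu, 0.0, options=ECONOMY)
    return toy, ens


def test_profile_matches_quadratic_theory(gaussian_toy):
    """PL(c) = LL* - (c - mu_i)^2 / (2 s_i^2) with s_i from the covariance."""
    toy, ens = gaussian_toy
    for i in range(3):
        prof = ens[i]
        s = np.sqrt(toy.cov[i, i])
        expected = -((prof.grid - toy.mu[i]) ** 2) / (2 * s**2)
        np.testing.assert_allclose(prof.pl, expected, atol=1e-6)
        assert prof.pl.max() == pytest.approx(0.0, abs=1e-9)  # passes through LL*


def test_confidence_interval_equals_normal_quantiles(gaussian_toy):
    toy, ens = gaussian_toy
    for i in range(3):
        lo, hi, open_lo, open_hi = confidence_interval(ens[i])
        s = np.sqrt(toy.cov[i, i])
        assert not (open_lo or open_hi)
        assert lo == pytest.approx(toy.mu[i] - 1.9600 * s, abs=1e-3)
        assert hi == pytest.approx(toy.mu[i] + 1.9600 * s, abs=1e-3)
    # alpha -> 0 degenerates to the point estimate
    lo, hi, *_ = confidence_interval(ens[0], alpha=0.0)
    assert lo == hi == pytest.approx(toy.mu[0])


def test_flat_profile_is_structural():
    """A parameter absent from the model has a flat profile, open both ways."""
    toy = QuadraticToy(
        [0.5, 0.0], [[0.04, 0.0], [0.0, 1e6]], lb=[-2.0, -2.0], ub=[2.0, 2.0]
    )  # second parameter carries no information at all
    toy.prec = np.array([[25.0, 0.0], [0.0, 0.0]])
    prof = profile(toy, toy.mu, 0.0, index=1, options=ECONOMY)
    assert prof.hit_lower and prof.hit_upper
    assert classify_identifiability(prof) == STRUCTURALLY_NON_IDENTIFIABLE
    lo, hi, open_lo, open_hi = confidence_interval(prof)
    assert open_lo and open_hi


def test_one_sided_bound_hit_is_practical():
    """A profile still above threshold at the domain border is open there."""
    toy = QuadraticToy([4.5, 0.0], [[4.0, 0.0], [0.0, 0.04]])  # wide along z0
    prof = profile(toy, toy.mu, 0.0, index=0, options=ECONOMY)
    assert prof.hit_upper  # mu=4.5, s=2: the upper bound at 5 is inside the CI
    assert classify_identifiability(prof) == PRACTICALLY_NON_IDENTIFIABLE
    tight = profile(toy, toy.mu, 0.0, index=1, options=ECONOMY)
    assert classify_identifiability(tight) == IDENTIFIABLE


def test_count_non_identifiable_and_hill_exclusion(gaussian_toy):
    toy, ens = gaussian_toy
    assert count_non_identifiable(ens) == 0
    flat = QuadraticToy([0.0], [[1.0]])
    flat.prec = np.array([[0.0]])
    prof = profile(flat, flat.mu, 0.0, index=0, options=ECONOMY)
    prof.name = "h_1"
    ens2 = gd.ProfileEnsemble(
        profiles={0: prof}, z_hat=flat.mu, ll_star=0.0, alpha=0.95, names=("h_1",)
    )
    assert count_non_identifiable(ens2) == 1
    assert count_non_identifiable(ens2, exclude_hill=True) == 0


def test_profile_parameter_set_properties(gaussian_toy):
    toy, ens = gaussian_toy
    only_best = profile_parameter_set(ens, max_per_profile=1)
    np.testing.assert_allclose(only_best, np.atleast_2d(toy.mu), atol=1e-9)
    s_tilde = profile_parameter_set(ens, max_per_profile=7)
    assert len(s_tilde) > 1
    for z in s_tilde:  # defining property, re-evaluated
        assert toy.loglik(z) >= -ens.delta - 1e-6
    # endpoints reach the CI edges up to one profiling step
    for i in range(3):
        lo, hi, *_ = confidence_interval(ens[i])
        vals = s_tilde[:, i]
        assert vals.min() <= lo + ECONOMY.step_max + 1e-9
        assert vals.max() >= hi - ECONOMY.step_max - 1e-9


def test_profile_on_real_model_stays_below_optimum(single_gene, single_gene_noisy):
    net, truth = single_gene
    obj = LikelihoodObjective(net, single_gene_noisy, rtol=1e-7, atol=1e-9)
    res = fit(obj, truth.log10)
    prof = profile(obj, res.z, res.loglik, 0, options=ECONOMY)
    assert np.nanmax(prof.pl) <= res.loglik + 1e-6
    assert classify_identifiability(prof) == IDENTIFIABLE
    lo, hi, *_ = confidence_interval(prof)
    assert lo < res.z[0] < hi


def test_rich_data_resolves_non_identifiability(two_gene, noise):
    """mRNA-only wild-type data leave translation parameters unbounded;
    adding protein and perturbation measurements closes those profiles.
    Hill pairs of saturated interactions may legitimately stay open, which
    is why identifiability reports can exclude them."""
    net, truth = two_gene
    opts = ProfileOptions(
        step_init=0.4, step_max=1.0, max_steps=10, target_divisor=2.0,
        reopt_method="wls", reopt_maxiter=10, reopt_gtol=1e-6,
    )
    mrna = simulate_dataset(
        net, truth, noise, np.linspace(1.0, 20, 10),
        species=[s for s in net.species if s.startswith("mRNA")], seed=1,
    )
    obj = LikelihoodObjective(net, mrna, rtol=1e-6, atol=1e-8, variance="data")
    res = fit(obj, truth.log10, method="wls", maxiter=150)
    ens = profile_all(obj, res.z, res.loglik, options=opts)
    n_weak = count_non_identifiable(ens)
    assert n_weak > 0

    rich = mrna + simulate_dataset(
        net, truth, noise, np.linspace(0.5, 20, 40),
        species=[s for s in net.species if s.startswith("p")], seed=2, condition_id="c1",
    )
    rich = rich + simulate_dataset(
        net, truth, noise, np.linspace(0.5, 20, 20),
        perturbation=gd.Perturbation("sirna", "1"), seed=3, condition_id="c2",
    )
    rich = rich + simulate_dataset(
        net, truth, noise, np.linspace(0.5, 20, 20),
        perturbation=gd.Perturbation("knockout", "2"), seed=4, condition_id="c3",
    )
    obj2 = LikelihoodObjective(net, rich, rtol=1e-6, atol=1e-8, variance="data")
    res2 = fit(obj2, truth.log10, method="wls", maxiter=300)
    ens2 = profile_all(obj2, res2.z, res2.loglik, options=opts)
    assert count_non_identifiable(ens2) < n_weak
    # every production / translation / degradation parameter is now bounded
    for prof in ens2:
        if not prof.name.startswith(("h_", "kd_")):
            assert classify_identifiability(prof) == IDENTIFIABLE, prof.name
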