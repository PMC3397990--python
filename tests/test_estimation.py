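"""LHS sampling, objective gradients, local fits and multistart clustering."""

import numpy as np
import pytest
from scipy import stats

import grndesign as gd
from grndesign.estimation import LikelihoodObjective, fit, lhs_sample, multistart_fit
from grndesign.ode_engine import IntegrationError

from conftest import simulate_dataset


class QuadraticToy:
    """LL(z) = -1/2 (z - mu)' A (z - mu); the analytic stand-in for an
    asymptotic likelihood with known covariance A^{-1}."""

    def __init__(self, mu, cov, lb=None, ub=None):
        self.mu = np.asarray(mu, dtype=float)
        self.cov = np.asarray(cov, dtype=float)
        self.prec = np.linalg.inv(self.cov)
        d = len(self.mu)
        self.lb = np.full(d, -5.0) if lb is None else np.asarray(lb, float)
        self.ub = np.full(d, 5.0) if ub is None else np.asarray(ub, float)

    def loglik(self, z):
        r = z - self.mu
        return float(-0.5 * r @ self.prec @ r)

    def loglik_and_grad(self, z):
        r = z - self.mu
        return float(-0.5 * r @ self.prec @ r), -self.prec @ r


class DoubleWellToy:
    """Bimodal by construction: LL(z) = -(z^2 - 1)^2 with maxima at +-1."""

    lb = np.array([-3.0])
    ub = np.array([3.0])

    def loglik(self, z):
        return float(-((z[0] ** 2 - 1.0) ** 2))

    def loglik_and_grad(self, z):
        return self.loglik(z), np.array([-4.0 * z[0] * (z[0] ** 2 - 1.0)])


def test_lhs_stratification_definition():
    lb, ub = np.array([-2.0, 0.0]), np.array([3.0, 1.0])
    for n in (1, 4, 9):
        pts = lhs_sample(n, lb, ub, seed=3)
        assert pts.shape == (n, 2)
        for d in range(2):
            strata = np.floor((pts[:, d] - lb[d]) / (ub[d] - lb[d]) * n).astype(int)
            assert sorted(strata) == list(range(n))  # each stratum exactly once


def test_lhs_pooled_uniformity():
    lb, ub = np.full(3, -2.0), np.full(3, 3.0)
    pts = lhs_sample(1000, lb, ub, seed=0)
    for d in range(3):
        counts, _ = np.histogram(pts[:, d], bins=10, range=(lb[d], ub[d]))
        assert stats.chisquare(counts).pvalue > 0.01
    with pytest.raises(ValueError):
        lhs_sample(0, lb, ub, seed=0)
    with pytest.raises(ValueError):
        lhs_sample(5, lb, np.full(3, np.inf), seed=0)


def test_objective_gradient_matches_finite_differences(single_gene, single_gene_noisy):
    net, truth = single_gene
    obj = LikelihoodObjective(net, single_gene_noisy)
    z0 = truth.log10 + 0.1
    _, g = obj.loglik_and_grad(z0)
    for j in range(3):
        h = 1e-5
        zp, zm = z0.copy(), z0.copy()
        zp[j] += h
        zm[j] -= h
        fd = (obj.loglik(zp) - obj.loglik(zm)) / (2 * h)
        assert g[j] == pytest.approx(fd, rel=1e-4, abs=1e-6)


def test_fit_is_stationary_and_monotone(single_gene, single_gene_noisy):
    net, truth = single_gene
    obj = LikelihoodObjective(net, single_gene_noisy)
    res = fit(obj, truth.log10, record_path=True)
    assert res.success
    # accepted L-BFGS-B iterates never decrease the log-likelihood
    path = np.array(res.ll_path)
    best_so_far = np.maximum.accumulate(path)
    assert path[-1] >= best_so_far[-1] - 1e-9
    _, g = obj.loglik_and_grad(res.z)
    interior = (res.z > obj.lb + 1e-9) & (res.z < obj.ub - 1e-9)
    assert np.abs(g[interior]).max() < 1e-3


def test_fit_with_fixed_parameters(single_gene, single_gene_noisy):
    net, truth = single_gene
    obj = LikelihoodObjective(net, single_gene_noisy)
    pinned = truth.log10[0] + 0.2
    res = fit(obj, truth.log10, fixed={0: pinned})
    assert res.z[0] == pytest.approx(pinned)


def test_convex_toy_all_starts_agree():
    toy = QuadraticToy([0.3, -0.7], [[0.5, 0.1], [0.1, 0.2]])
    ms = multistart_fit(toy, 8, seed=1)
    assert ms.unique_optimum
    for f in ms.converged:
        np.testing.assert_allclose(f.z, toy.mu, atol=1e-4)


def test_double_well_reports_two_clusters():
    ms = multistart_fit(DoubleWellToy(), 12, seed=2)
    labels = {lab for f, lab in zip(ms.fits, ms.labels) if f.success}
    assert len(labels) == 2
    assert len(ms.clusters_within_threshold()) == 2  # equal-height optima
    assert not ms.unique_optimum


def test_chi2_threshold_for_29_parameters():
    toy = QuadraticToy(np.zeros(29), np.eye(29))
    ms = multistart_fit(toy, 2, seed=0)
    assert ms.threshold == pytest.approx(stats.chi2.ppf(0.95, 29))


def test_failed_starts_become_failed_fit_results():
    class Fragile(QuadraticToy):
        def loglik_and_grad(self, z):
            if z[0] > 0:
                raise IntegrationError("solver diverged", time=1.0)
            return super().loglik_and_grad(z)

        def loglik(self, z):
            if z[0] > 0:
                raise IntegrationError("solver diverged", time=1.0)
            return super().loglik(z)

    toy = Fragile([-1.0], [[0.3]])
    bad = fit(toy, np.array([2.0]))
    assert not bad.success and bad.z is None
    ms = multistart_fit(toy, 10, seed=4)
    assert any(not f.success for f in ms.fits) and ms.best.success


def test_waterfall_plateau_on_rich_two_gene_data(two_gene, noise):
    """A clear share of converged starts lands in the best optimum's basin."""
    net, truth = two_gene
    ds = simulate_dataset(net, truth, noise, np.linspace(0.5, 20, 15), seed=3)
    obj = LikelihoodObjective(
        net, ds, template=gd.ParameterVector.for_network(net), rtol=1e-6, atol=1e-8,
        variance="data",
    )
    ms = multistart_fit(obj, 15, seed=7, method="wls", maxiter=150)
    conv = ms.converged
    best_cluster = sum(
        1
        for f, lab in zip(ms.fits, ms.labels)
        if f.success and lab >= 0 and 2 * (ms.best.loglik - f.loglik) <= ms.threshold
    )
    assert len(conv) >= 5
    assert best_cluster / len(conv) >= 0.2
    assert list(ms.waterfall()) == sorted(ms.waterfall(), reverse=True)
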