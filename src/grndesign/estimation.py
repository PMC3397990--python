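"""Maximum-likelihood estimation in log10 parameter space.

The objective couples the GRN ODE model to the error-model likelihood;
its gradient comes from forward sensitivities via the chain rule

    dLL/dz_j = sum_records  (dll/dx)  *  S[species, j, time],

with z = log10(theta).  Starts are drawn by latin hypercube sampling on the
log-bounded box and each start is optimized by a local, gradient-based
method.  Local optima are discriminated with the 95 % chi-square quantile
at dof = number of parameters (on the -2 LL scale), the threshold used for
joint confidence regions: only optima within that band of the best fit are
statistically indistinguishable from it.

Three optimizers are available:

``lbfgs`` (default)
    bound-constrained quasi-Newton with line search; monotone in LL.
``trust-constr``
    scipy's trust-region interior-point method.
``wls``
    trust-region-reflective least squares with the variance frozen at the
    observed values (sigma(y) weights); fast, and exact at noise-free data,
    but it drops the log-variance term of the full likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import chi2, qmc

from .error_model import Dataset, NoiseModel, combined_sd, record_loglik_and_grad
from .grn_model import GeneNetwork, ParameterVector, Perturbation, WILDTYPE, build_rhs
from .ode_engine import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    IntegrationError,
    integrate_with_sensitivities,
)

__all__ = [
    "lhs_sample",
    "LikelihoodObjective",
    "FitResult",
    "MultistartResult",
    "fit",
    "multistart_fit",
]


def lhs_sample(n: int, lb: np.ndarray, ub: np.ndarray, seed: int) -> np.ndarray:
    """Latin hypercube sample of ``n`` log10 vectors on the box [lb, ub].

    Each component's range is split into ``n`` equal log-width strata and
    every stratum is hit exactly once; placement within a stratum is uniform.
    """
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    if n < 1:
        raise ValueError("n must be at least 1")
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))) or np.any(ub <= lb):
        raise ValueError("finite bounds with ub > lb required for LHS")
    sampler = qmc.LatinHypercube(d=len(lb), seed=seed)
    return qmc.scale(sampler.random(n), lb, ub)


class LikelihoodObjective:
    """Log-likelihood of a dataset under a GRN model, as a function of z = log10(theta).

    Exposes ``loglik(z)``, ``loglik_and_grad(z)`` and, for the WLS mode,
    ``residuals(z)`` / ``residuals_jac(z)``.  Conditions are taken from the
    dataset's condition-to-perturbation mapping; each condition is
    integrated separately with forward sensitivities when gradients are
    requested.
    """

    def __init__(
        self,
        network: GeneNetwork,
        dataset: Dataset,
        noise: NoiseModel | None = None,
        template: ParameterVector | None = None,
        clipped: bool = False,
        rtol: float = DEFAULT_RTOL,
        atol: float = DEFAULT_ATOL,
        variance: str = "model",
    ):
        self.network = network
        self.dataset = dataset
        self.noise = noise or dataset.noise
        if self.noise is None:
            raise ValueError("a noise model is required (on the dataset or explicit)")
        self.template = template or ParameterVector.for_network(network)
        self.clipped = clipped
        if variance not in ("model", "data"):
            raise ValueError("variance must be 'model' or 'data'")
        # "model": full likelihood, sigma evaluated at the model value
        # (including the log-variance terms); "data": sigma frozen at the
        # observed values, an ordinary weighted Gaussian likelihood that is
        # exactly the WLS objective — the fast mode used for design loops.
        self.variance = variance
        self.rtol = rtol
        self.atol = atol
        self.x0 = network.x0()
        sp_index = network.species_index
        self._conds = []
        for cid in dataset.condition_ids:
            sub = dataset.for_condition(cid)
            pert = dataset.conditions.get(cid, WILDTYPE)
            times = np.unique(sub["time"].values)
            if np.any(times < 0):
                raise ValueError("negative measurement times")
            t_idx = np.searchsorted(times, sub["time"].values)
            s_idx = np.array([sp_index[s] for s in sub["species"].values])
            self._conds.append(
                {
                    "id": cid,
                    "pert": pert,
                    "times": times,
                    "t_idx": t_idx,
                    "s_idx": s_idx,
                    "y": sub["value"].values.astype(float),
                    "sd_y": combined_sd(sub["value"].values.astype(float), self.noise),
                }
            )
        self.n_params = len(self.template)
        self.n_records = len(dataset)
        self._cache: dict = {}

    # ------------------------------------------------------------- bounds
    @property
    def lb(self) -> np.ndarray:
        return self.template.lb

    @property
    def ub(self) -> np.ndarray:
        return self.template.ub

    # --------------------------------------------------------- evaluation
    def _simulate(self, z: np.ndarray, cond: dict, with_sens: bool):
        # optimizers evaluate residuals and Jacobian back-to-back at the
        # same point; one cached slot per condition avoids the double solve
        key = (cond["id"], z.tobytes())
        hit = self._cache.get(key)
        if hit is not None and (hit.sensitivities is not None or not with_sens):
            return hit
        params = self.template.with_log10(z)
        system = build_rhs(self.network, params, cond["pert"])
        if with_sens:
            traj = integrate_with_sensitivities(
                system, self.x0, cond["times"], rtol=self.rtol, atol=self.atol
            )
        else:
            from .ode_engine import integrate

            traj = integrate(system, self.x0, cond["times"], rtol=self.rtol, atol=self.atol)
        self._cache = {key: traj}
        return traj

    @staticmethod
    def _model_values(traj, cond):
        # integrator error can leave states a hair below zero; the error
        # model is defined for non-negative true levels only
        return np.maximum(traj.states[cond["s_idx"], cond["t_idx"]], 0.0)

    def _terms(self, cond, x):
        if self.variance == "data":
            sd = cond["sd_y"]
            r = (cond["y"] - x) / sd
            ll = -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * r**2
            return ll, r / sd
        return record_loglik_and_grad(cond["y"], x, self.noise, self.clipped)

    def loglik(self, z: np.ndarray) -> float:
        total = 0.0
        for cond in self._conds:
            traj = self._simulate(z, cond, with_sens=False)
            ll, _ = self._terms(cond, self._model_values(traj, cond))
            total += float(np.sum(ll))
        return total

    def loglik_and_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        total = 0.0
        grad = np.zeros(self.n_params)
        for cond in self._conds:
            traj = self._simulate(z, cond, with_sens=True)
            x = self._model_values(traj, cond)
            S = traj.sensitivities[cond["s_idx"], :, cond["t_idx"]]  # (records, n_params)
            ll, dll = self._terms(cond, x)
            total += float(np.sum(ll))
            grad += dll @ S
        return total, grad

    # ------------------------------------------------------- WLS residuals
    def residuals(self, z: np.ndarray) -> np.ndarray:
        out = []
        for cond in self._conds:
            traj = self._simulate(z, cond, with_sens=False)
            x = self._model_values(traj, cond)
            out.append((cond["y"] - x) / cond["sd_y"])
        return np.concatenate(out)

    def residuals_and_jac(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        res, jac = [], []
        for cond in self._conds:
            traj = self._simulate(z, cond, with_sens=True)
            x = self._model_values(traj, cond)
            S = traj.sensitivities[cond["s_idx"], :, cond["t_idx"]]
            res.append((cond["y"] - x) / cond["sd_y"])
            jac.append(-S / cond["sd_y"][:, None])
        return np.concatenate(res), np.vstack(jac)


# ---------------------------------------------------------------- fitting

@dataclass
class FitResult:
    """One converged (or failed) local optimization."""

    z: np.ndarray | None
    loglik: float
    success: bool
    message: str = ""
    start_index: int = -1
    n_iter: int = 0
    ll_path: list[float] = field(default_factory=list)

    def __repr__(self):
        status = "ok" if self.success else "failed"
        return f"FitResult({status}, LL={self.loglik:.4g}, start={self.start_index})"


def _embed(z_red, free_idx, z_full):
    z = z_full.copy()
    z[free_idx] = z_red
    return z


def fit(
    objective,
    start: np.ndarray,
    method: str = "lbfgs",
    fixed: Mapping[int, float] | None = None,
    gtol: float = 1e-6,
    xtol: float = 1e-8,
    maxiter: int = 500,
    start_index: int = -1,
    record_path: bool = False,
) -> FitResult:
    """Local maximization of ``objective.loglik`` from ``start`` (log10 scale).

    ``objective`` needs ``loglik_and_grad(z)``, ``lb`` and ``ub`` (the WLS
    mode additionally needs ``residuals_and_jac``).  ``fixed`` maps
    parameter indices to pinned log10 values (used by profiling and by
    direct parameter measurements); those components are excluded from the
    optimization.  Integrator failures yield a failed :class:`FitResult`
    rather than an exception.
    """
    lb, ub = np.asarray(objective.lb, float), np.asarray(objective.ub, float)
    z_full = np.clip(np.asarray(start, dtype=float), lb, ub)
    fixed = dict(fixed or {})
    for i, v in fixed.items():
        z_full[i] = v
    free_idx = np.array([i for i in range(len(z_full)) if i not in fixed], dtype=int)
    if len(free_idx) == 0:
        try:
            ll = objective.loglik(z_full)
        except IntegrationError as err:
            return FitResult(None, -np.inf, False, str(err), start_index)
        return FitResult(z_full, ll, True, "all parameters fixed", start_index)

    path: list[float] = []

    def neg_ll(z_red):
        ll, g = objective.loglik_and_grad(_embed(z_red, free_idx, z_full))
        if record_path:
            path.append(ll)
        return -ll, -g[free_idx]

    bounds_red = list(zip(lb[free_idx], ub[free_idx]))
    try:
        if method == "lbfgs":
            res = optimize.minimize(
                neg_ll,
                z_full[free_idx],
                jac=True,
                method="L-BFGS-B",
                bounds=bounds_red,
                options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-14},
            )
        elif method == "trust-constr":
            res = optimize.minimize(
                neg_ll,
                z_full[free_idx],
                jac=True,
                method="trust-constr",
                bounds=optimize.Bounds(lb[free_idx], ub[free_idx]),
                options={"maxiter": maxiter, "gtol": gtol, "xtol": xtol},
            )
        elif method == "wls":
            def res_fun(z_red):
                return objective.residuals(_embed(z_red, free_idx, z_full))

            def jac_fun(z_red):
                _, J = objective.residuals_and_jac(_embed(z_red, free_idx, z_full))
                return J[:, free_idx]

            res = optimize.least_squares(
                res_fun,
                z_full[free_idx],
                jac=jac_fun,
                method="trf",
                bounds=(lb[free_idx], ub[free_idx]),
                gtol=gtol,
                xtol=xtol,
                max_nfev=maxiter,
            )
        else:
            raise ValueError(f"unknown fit method {method!r}")
    except IntegrationError as err:
        return FitResult(None, -np.inf, False, f"integrator failure: {err}", start_index)
    z_hat = _embed(np.asarray(res.x, dtype=float), free_idx, z_full)
    try:
        ll_hat = objective.loglik(z_hat)
    except IntegrationError as err:
        return FitResult(None, -np.inf, False, f"integrator failure at optimum: {err}", start_index)
    # iteration-capped terminations still return the best feasible iterate
    success = (
        bool(res.success)
        or (method == "lbfgs" and res.status == 1)
        or (method == "wls" and res.status == 0)
    )
    n_iter = int(getattr(res, "nit", getattr(res, "nfev", 0)))
    return FitResult(z_hat, ll_hat, success, str(res.message), start_index, n_iter, path)


@dataclass
class MultistartResult:
    """Sorted multistart fits with chi-square local-optimum discrimination.

    ``threshold`` is the 95 % chi-square quantile with dof = n_parameters on
    the -2 LL scale; optima whose LL deficit ``2 (LL* - LL)`` is below it are
    statistically compatible with the best fit.
    """

    fits: list[FitResult]
    threshold: float
    labels: np.ndarray
    cluster_tol: float

    @property
    def best(self) -> FitResult:
        return self.fits[0]

    @property
    def converged(self) -> list[FitResult]:
        return [f for f in self.fits if f.success]

    def clusters_within_threshold(self) -> list[int]:
        """Cluster labels whose best LL is within the joint-CI band."""
        best_ll = self.best.loglik
        keep = []
        for f, lab in zip(self.fits, self.labels):
            if f.success and lab >= 0 and 2.0 * (best_ll - f.loglik) <= self.threshold:
                if lab not in keep:
                    keep.append(lab)
        return keep

    @property
    def unique_optimum(self) -> bool:
        """True when no second optimum survives the statistical threshold."""
        return len(self.clusters_within_threshold()) == 1

    def waterfall(self) -> np.ndarray:
        """Sorted LL values of converged fits (descending), for waterfall plots."""
        return np.array([f.loglik for f in self.converged])


def multistart_fit(
    objective,
    n_starts: int,
    seed: int,
    method: str = "lbfgs",
    alpha: float = 0.95,
    cluster_tol: float = 0.1,
    extra_starts: Sequence[np.ndarray] = (),
    **fit_kwargs,
) -> MultistartResult:
    """Fit from ``n_starts`` latin-hypercube starts (plus optional extras).

    Results are sorted by LL (failed fits last); optima are clustered by an
    infinity-norm match of the estimates within ``cluster_tol`` log10 units.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be at least 1")
    starts = list(lhs_sample(n_starts, objective.lb, objective.ub, seed))
    starts += [np.asarray(s, dtype=float) for s in extra_starts]
    fits = [
        fit(objective, s, method=method, start_index=i, **fit_kwargs)
        for i, s in enumerate(starts)
    ]
    if not any(f.success for f in fits):
        raise RuntimeError("all multistart fits failed")
    fits.sort(key=lambda f: (not f.success, -f.loglik))
    dof = len(objective.lb)
    threshold = float(chi2.ppf(alpha, dof))
    labels = np.full(len(fits), -1, dtype=int)
    reps: list[np.ndarray] = []
    for i, f in enumerate(fits):
        if not f.success:
            continue
        for lab, rep in enumerate(reps):
            if np.max(np.abs(f.z - rep)) < cluster_tol:
                labels[i] = lab
                break
        else:
            labels[i] = len(reps)
            reps.append(f.z)
    return MultistartResult(fits=fits, threshold=threshold, labels=labels, cluster_tol=cluster_tol)
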