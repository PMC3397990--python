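"""Stiff integration of GRN ODEs and their forward sensitivity equations.

The default integrator is LSODA (through the low-overhead
:func:`scipy.integrate.odeint` interface), which switches automatically to
variable-order BDF on stiff stretches and runs with an analytic state
Jacobian; scipy's pure-Python ``BDF`` method is available as an option.
Fixed-step solvers are deliberately not offered.
First-order sensitivities ``S = dx/d log10(theta)`` are propagated by
augmenting the state with the matrix ODE

    dS/dt = (df/dx) S + df/d log10(theta),   S(0) = dx0/d log10(theta)

which is exact for initial conditions that do not depend on the
parameters (the default, S(0) = 0).  Finite differences across an adaptive
solver are noisy; the augmented system shares the solver's error control
with the states, which is what gradient-based optimization of the
likelihood needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import odeint, solve_ivp

__all__ = ["Trajectory", "IntegrationError", "integrate", "integrate_with_sensitivities"]

#: default relative / absolute tolerances; strict, because profile
#: re-optimization amplifies integration noise.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Raised when the solver fails; carries the time where it gave up."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


@dataclass
class Trajectory:
    """Solution states (and optional sensitivities) on a requested time grid.

    ``states`` has shape (n_species, n_times); ``sensitivities``, if present,
    has shape (n_species, n_params, n_times) on the log10-parameter scale.
    """

    times: np.ndarray
    states: np.ndarray
    sensitivities: np.ndarray | None = None
    species: tuple[str, ...] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) < 0):
            raise ValueError("times must be a non-decreasing 1-d array")
        if self.states.shape[-1] != len(self.times):
            raise ValueError("states/time shape mismatch")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("non-finite states in trajectory")
        if self.sensitivities is not None and (
            self.sensitivities.shape[0] != self.states.shape[0]
            or self.sensitivities.shape[-1] != len(self.times)
        ):
            raise ValueError("sensitivity array shape inconsistent")

    @property
    def n_species(self) -> int:
        return self.states.shape[0]

    def species_row(self, name: str) -> np.ndarray:
        if self.species is None:
            raise ValueError("trajectory has no species labels")
        return self.states[self.species.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format (species, time, value) table."""
        sp = self.species or tuple(str(i) for i in range(self.n_species))
        return pd.DataFrame(
            {
                "species": np.repeat(sp, len(self.times)),
                "time": np.tile(self.times, self.n_species),
                "value": self.states.ravel(),
            }
        )


def _check_args(x0, times, rtol, atol):
    x0 = np.asarray(x0, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial state must be non-negative")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    if times.ndim != 1 or len(times) == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and non-empty")
    return x0, times


def _lsoda(fun, jac, y0, times, rtol, atol, t0, what):
    """LSODA via the low-overhead odeint interface (callbacks dominate the
    cost of these small systems, and odeint's wrapper is the cheapest)."""
    import warnings

    prepend = times[0] > t0
    grid = np.concatenate([[t0], times]) if prepend else times
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # failures surface as IntegrationError
        y, info = _odeint_call(fun, jac, y0, grid, rtol, atol)
    if info["message"] != "Integration successful.":
        t_fail = float(np.atleast_1d(info["tcur"])[-1])
        raise IntegrationError(f"{what} failed at t={t_fail:g}: {info['message']}", t_fail)
    return (y[1:] if prepend else y).T


def _odeint_call(fun, jac, y0, grid, rtol, atol):
    return odeint(
        fun,
        y0,
        grid,
        Dfun=jac,
        rtol=rtol,
        atol=atol,
        tfirst=True,
        full_output=True,
        printmessg=False,
    )


def integrate(
    rhs,
    x0,
    times,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    jac=None,
    t0: float = 0.0,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate ``dx/dt = rhs(t, x)`` from ``t0`` and sample at ``times``.

    ``rhs`` may be any callable; if it exposes a ``jac_x`` method (as the
    systems built by :func:`grndesign.grn_model.build_rhs` do) that Jacobian
    is used by the implicit solver automatically.
    """
    x0, times = _check_args(x0, times, rtol, atol)
    if jac is None and hasattr(rhs, "jac_x"):
        jac = rhs.jac_x
    if times[0] < t0:
        raise ValueError("requested times precede the initial time")
    fun = rhs
    if hasattr(rhs, "kernel_args"):
        from .grn_model import grn_rhs_kernel

        args = rhs.kernel_args()
        fun = lambda t, y: grn_rhs_kernel(t, y, *args)  # noqa: E731
    species = getattr(getattr(rhs, "network", None), "species", None)
    if method == "LSODA":
        states = _lsoda(fun, jac, x0, times, rtol, atol, t0, "integration")
        return Trajectory(times=times, states=states, species=species)
    sol = solve_ivp(
        fun,
        (t0, float(times[-1])),
        x0,
        method=method,
        t_eval=times,
        rtol=rtol,
        atol=atol,
        jac=jac,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else t0
        raise IntegrationError(f"integration failed at t={t_fail:g}: {sol.message}", t_fail)
    return Trajectory(times=times, states=sol.y, species=species)


def integrate_with_sensitivities(
    system,
    x0,
    times,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    s0: np.ndarray | None = None,
    t0: float = 0.0,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate states and forward sensitivities of an :class:`OdeSystem`.

    ``system`` must provide ``__call__(t, x)``, ``jac_x(t, x)``,
    ``jac_theta_log(t, x)`` and ``n_params``.  ``s0`` is the initial
    sensitivity matrix (defaults to zero: parameter-independent x0).
    """
    x0, times = _check_args(x0, times, rtol, atol)
    n = len(x0)
    npar = system.n_params
    if s0 is None:
        s0 = np.zeros((n, npar))
    # S is stored column-major (one contiguous block per parameter) so the
    # Jacobian of the sensitivity block is exactly block-diagonal in J.
    y0 = np.concatenate([x0, np.asarray(s0, dtype=float).ravel(order="F")])

    if hasattr(system, "kernel_args"):
        from .grn_model import grn_aug_rhs_kernel

        args = system.kernel_args()
        rhs_aug = lambda t, y: grn_aug_rhs_kernel(t, y, *args)  # noqa: E731
    else:
        fused = getattr(system, "rhs_and_jacs", None)

        def rhs_aug(t, y):
            x = y[:n]
            S = y[n:].reshape((n, npar), order="F")
            if fused is not None:
                f, J, F = fused(t, x)
            else:
                f, J, F = system(t, x), system.jac_x(t, x), system.jac_theta_log(t, x)
            out = np.empty(n * (npar + 1))
            out[:n] = f
            out[n:] = (J @ S + F).ravel(order="F")
            return out

    n_aug = n * (npar + 1)

    def jac_aug(t, y):
        # quasi-Newton Jacobian: the exact augmented Jacobian adds
        # (d2f/dx2 . S) coupling blocks, which only affect Newton
        # convergence speed, not the error-controlled solution.
        J = system.jac_x(t, y[:n])
        out = np.zeros((n_aug, n_aug))
        for k in range(npar + 1):
            out[k * n : (k + 1) * n, k * n : (k + 1) * n] = J
        return out

    species = getattr(getattr(system, "network", None), "species", None)
    if method == "LSODA":
        y = _lsoda(rhs_aug, jac_aug, y0, times, rtol, atol, t0, "sensitivity integration")
    else:
        sol = solve_ivp(
            rhs_aug,
            (t0, float(times[-1])),
            y0,
            method=method,
            t_eval=times,
            rtol=rtol,
            atol=atol,
            jac=jac_aug,
        )
        if not sol.success:
            t_fail = float(sol.t[-1]) if sol.t.size else t0
            raise IntegrationError(
                f"sensitivity integration failed at t={t_fail:g}: {sol.message}", t_fail
            )
        y = sol.y
    states = y[:n]
    sens = y[n:].reshape((n, npar, len(times)), order="F")
    species = getattr(getattr(system, "network", None), "species", None)
    return Trajectory(times=times, states=states, sensitivities=sens, species=species)
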