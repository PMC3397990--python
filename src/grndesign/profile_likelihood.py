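"""Profile-likelihood identifiability analysis.

The profile of parameter i is PL(c) = max over all other parameters of
LL(theta | theta_i = c): the i-th component is stepped away from the
optimum in both directions and the remaining parameters are re-optimized at
every step, warm-started from the previous companion vector.  Likelihood-
based confidence intervals at level alpha collect all c with

    PL(c) >= LL* - 1/2 * chi2_quantile(alpha, dof=1),

a profile that stays above that threshold all the way to a parameter bound
is open-ended there (practical non-identifiability); a profile that is flat
over the whole domain is structurally non-identifiable.

Each profile point carries the re-optimized companion vector; pooled over
all profiles and filtered by the threshold these form the parameter set
used for experimental design (trajectory-spread scoring).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import chi2

from .estimation import FitResult, fit

__all__ = [
    "ProfileOptions",
    "ProfileResult",
    "ProfileEnsemble",
    "profile",
    "profile_all",
    "confidence_interval",
    "classify_identifiability",
    "count_non_identifiable",
    "profile_parameter_set",
    "IDENTIFIABLE",
    "PRACTICALLY_NON_IDENTIFIABLE",
    "STRUCTURALLY_NON_IDENTIFIABLE",
]

IDENTIFIABLE = "identifiable"
PRACTICALLY_NON_IDENTIFIABLE = "practically_non_identifiable"
STRUCTURALLY_NON_IDENTIFIABLE = "structurally_non_identifiable"

#: LL-units tolerance below which a profile counts as flat
FLAT_TOL = 1e-3


@dataclass(frozen=True)
class ProfileOptions:
    """Stepping and re-optimization controls for one profile.

    The target decrease per step is ``delta / target_divisor`` with step
    halving on overshoot and a hard cap on the log10 step width; there is no
    canonical stepping rule, these defaults trade resolution against the
    number of re-optimizations.
    """

    step_init: float = 0.05
    step_max: float = 0.2
    step_min: float = 1e-3
    target_divisor: float = 10.0
    overshoot_factor: float = 3.0
    max_steps: int = 40
    reopt_method: str = "lbfgs"
    reopt_maxiter: int = 200
    reopt_gtol: float = 1e-6


@dataclass
class ProfileResult:
    """Profile of one parameter: grid (ascending log10), PL values and
    companion vectors, plus bound-hit flags."""

    index: int
    name: str
    grid: np.ndarray
    pl: np.ndarray
    companions: list[np.ndarray]
    failed: np.ndarray
    ll_star: float
    z_hat_value: float
    alpha: float
    delta: float
    hit_lower: bool
    hit_upper: bool
    lb: float
    ub: float

    @property
    def threshold(self) -> float:
        return self.ll_star - self.delta


def _delta(alpha: float) -> float:
    return 0.5 * float(chi2.ppf(alpha, 1)) if alpha > 0 else 0.0


def profile(
    objective,
    z_hat: np.ndarray,
    ll_star: float,
    index: int,
    alpha: float = 0.95,
    options: ProfileOptions = ProfileOptions(),
    fixed: Mapping[int, float] | None = None,
) -> ProfileResult:
    """Profile parameter ``index`` of a converged optimum ``z_hat``.

    ``fixed`` pins additional components (e.g. directly measured
    parameters) during every re-optimization.  Re-optimization failures are
    flagged and skipped; profiling continues with a fresh step.
    """
    z_hat = np.asarray(z_hat, dtype=float)
    delta = _delta(alpha)
    lb, ub = float(objective.lb[index]), float(objective.ub[index])
    grid = [float(z_hat[index])]
    pl = [float(ll_star)]
    companions = [z_hat.copy()]
    failed = [False]
    hit = {+1: False, -1: False}
    target = delta / options.target_divisor if delta > 0 else np.inf
    base_fixed = dict(fixed or {})

    for direction in (+1, -1):
        z = z_hat.copy()
        ll_prev = ll_star
        step = options.step_init
        bound = ub if direction > 0 else lb
        for _ in range(options.max_steps):
            remaining = direction * (bound - z[index])
            if remaining <= 1e-12:
                hit[direction] = True
                break
            at_bound = False
            while True:
                step = min(step, options.step_max)
                move = min(step, remaining)
                at_bound = move >= remaining - 1e-12
                c = z[index] + direction * move
                res = fit(
                    objective,
                    z,
                    method=options.reopt_method,
                    fixed={**base_fixed, index: c},
                    gtol=options.reopt_gtol,
                    maxiter=options.reopt_maxiter,
                )
                if not res.success or res.z is None:
                    grid.append(c)
                    pl.append(np.nan)
                    companions.append(z.copy())
                    failed.append(True)
                    res = None
                    break
                drop = ll_prev - res.loglik
                if (
                    drop > options.overshoot_factor * target
                    and step > options.step_min
                    and not at_bound
                ):
                    step = max(step / 2.0, options.step_min)
                    continue
                break
            if res is None:
                continue
            grid.append(c)
            pl.append(res.loglik)
            companions.append(res.z)
            failed.append(False)
            z = res.z
            drop = ll_prev - res.loglik
            ll_prev = res.loglik
            if res.loglik <= ll_star - delta:
                break
            if at_bound:
                hit[direction] = True
                break
            if drop < target / 2.0:
                step = min(step * 1.6, options.step_max)

    order = np.argsort(grid)
    return ProfileResult(
        index=index,
        name=getattr(objective, "template", None).names[index]
        if getattr(objective, "template", None) is not None
        else f"theta_{index}",
        grid=np.asarray(grid)[order],
        pl=np.asarray(pl)[order],
        companions=[companions[i] for i in order],
        failed=np.asarray(failed)[order],
        ll_star=float(ll_star),
        z_hat_value=float(z_hat[index]),
        alpha=alpha,
        delta=delta,
        hit_lower=hit[-1],
        hit_upper=hit[+1],
        lb=lb,
        ub=ub,
    )


@dataclass
class ProfileEnsemble:
    """Profiles of all (or selected) parameters of one optimum."""

    profiles: dict[int, ProfileResult]
    z_hat: np.ndarray
    ll_star: float
    alpha: float
    names: tuple[str, ...]

    @property
    def delta(self) -> float:
        return _delta(self.alpha)

    def __iter__(self):
        return iter(self.profiles.values())

    def __getitem__(self, index: int) -> ProfileResult:
        return self.profiles[index]


def profile_all(
    objective,
    z_hat: np.ndarray,
    ll_star: float,
    indices: Iterable[int] | None = None,
    alpha: float = 0.95,
    options: ProfileOptions = ProfileOptions(),
    fixed: Mapping[int, float] | None = None,
) -> ProfileEnsemble:
    z_hat = np.asarray(z_hat, dtype=float)
    fixed = dict(fixed or {})
    if indices is None:
        indices = [i for i in range(len(z_hat)) if i not in fixed]
    profiles = {
        i: profile(objective, z_hat, ll_star, i, alpha=alpha, options=options, fixed=fixed)
        for i in indices
    }
    names = (
        objective.template.names
        if getattr(objective, "template", None) is not None
        else tuple(f"theta_{i}" for i in range(len(z_hat)))
    )
    return ProfileEnsemble(
        profiles=profiles, z_hat=z_hat, ll_star=float(ll_star), alpha=alpha, names=names
    )


# ------------------------------------------------------------- inference

def _crossing(grid, pl, thr, lo_i, hi_i):
    """Locate the PL/threshold crossing between grid indices via a local
    quadratic (exact for parabolic profiles), falling back to linear."""
    ga, gb = grid[lo_i], grid[hi_i]
    pts = [i for i in (lo_i - 1, lo_i, hi_i, hi_i + 1) if 0 <= i < len(grid)]
    pts = sorted(set(pts))
    gs, ps = grid[pts], pl[pts]
    ok = np.isfinite(ps)
    if ok.sum() >= 3:
        coef = np.polyfit(gs[ok], ps[ok], 2)
        shifted = coef.copy()
        shifted[2] -= thr
        roots = np.roots(shifted)
        roots = roots[np.isreal(roots)].real
        roots = roots[(roots >= min(ga, gb) - 1e-12) & (roots <= max(ga, gb) + 1e-12)]
        if len(roots):
            return float(roots[np.argmin(np.abs(roots - 0.5 * (ga + gb)))])
    # linear fallback
    pa, pb = pl[lo_i], pl[hi_i]
    if not (np.isfinite(pa) and np.isfinite(pb)) or pa == pb:
        return float(gb)
    return float(ga + (thr - pa) * (gb - ga) / (pb - pa))


def confidence_interval(prof: ProfileResult, alpha: float | None = None):
    """Likelihood-based CI: ``{c : PL(c) >= LL* - 1/2 chi2(alpha, 1)}``.

    Returns ``(lower, upper, open_lower, open_upper)``; an end is open when
    the profile ends (at a parameter bound, or because the stepping budget
    ran out) while still above the threshold — i.e. the data did not bound
    the parameter on that side as far as the profile reaches.
    """
    delta = prof.delta if alpha is None else _delta(alpha)
    thr = prof.ll_star - delta
    grid, pl = prof.grid, prof.pl
    i_hat = int(np.nanargmin(np.abs(grid - prof.z_hat_value)))
    if delta == 0:
        return prof.z_hat_value, prof.z_hat_value, False, False

    def scan(direction):
        i = i_hat
        while True:
            j = i + direction
            if j < 0 or j >= len(grid):
                # no crossing found before the profile ended (parameter
                # bound reached, or stepping budget exhausted) -> open end
                return float(grid[i if np.isfinite(pl[i]) else i_hat]), True
            if not np.isfinite(pl[j]):
                i = j
                continue
            if pl[j] < thr:
                lo_i, hi_i = (j, i) if direction < 0 else (i, j)
                return _crossing(grid, pl, thr, lo_i, hi_i), False
            i = j

    lower, open_lower = scan(-1)
    upper, open_upper = scan(+1)
    return lower, upper, open_lower, open_upper


def classify_identifiability(prof: ProfileResult) -> str:
    """Identifiable, practically or structurally non-identifiable.

    Flat within :data:`FLAT_TOL` across the whole domain (both bounds
    reached) is structural; an open CI end is practical; otherwise the
    parameter is identifiable at the profile's alpha level.
    """
    finite = np.isfinite(prof.pl)
    if (
        prof.hit_lower
        and prof.hit_upper
        and finite.any()
        and np.nanmax(prof.pl[finite]) - np.nanmin(prof.pl[finite]) < FLAT_TOL
    ):
        return STRUCTURALLY_NON_IDENTIFIABLE
    _, _, open_lo, open_hi = confidence_interval(prof)
    if open_lo or open_hi:
        return PRACTICALLY_NON_IDENTIFIABLE
    return IDENTIFIABLE


def count_non_identifiable(ensemble: ProfileEnsemble, exclude_hill: bool = False) -> int:
    """Number of non-identifiable parameters; Hill coefficients can be
    excluded because truths sitting on the restricted Hill boundary create
    artificial bound hits."""
    n = 0
    for prof in ensemble:
        if exclude_hill and prof.name.startswith("h_"):
            continue
        if classify_identifiability(prof) != IDENTIFIABLE:
            n += 1
    return n


def profile_parameter_set(
    ensemble: ProfileEnsemble,
    max_per_profile: int = 10,
    include_best: bool = True,
) -> np.ndarray:
    """Pooled companion vectors along all profiles, below the threshold.

    Up to ``max_per_profile`` vectors per profile, spaced uniformly in grid
    position; the optimum itself is always included.  Failed grid points are
    excluded.  Returns an array of log10 vectors, one per row.
    """
    rows = [ensemble.z_hat] if include_best else []
    for prof in ensemble:
        ok = np.isfinite(prof.pl) & ~prof.failed & (prof.pl >= prof.threshold - 1e-9)
        idx = np.flatnonzero(ok)
        if len(idx) == 0:
            continue
        # the optimum's grid point is always part of the subset; the rest is
        # spread uniformly along the profile
        i_hat = int(idx[np.argmin(np.abs(prof.grid[idx] - prof.z_hat_value))])
        take = {i_hat}
        if max_per_profile > 1:
            uniform = idx[
                np.round(np.linspace(0, len(idx) - 1, min(max_per_profile, len(idx)))).astype(int)
            ]
            for i in uniform:
                if len(take) >= max_per_profile and i_hat in take:
                    break
                take.add(int(i))
        rows.extend(prof.companions[i] for i in sorted(take))
    out = np.unique(np.array(rows), axis=0)
    return out
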