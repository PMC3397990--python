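"""Enumeration and profile-based scoring of purchasable experiments.

A candidate experiment is a (perturbation, readout) pair: any of the
3 G + 1 perturbation conditions (wild type, or knockout / siRNA / rbs
doubling of each gene) combined with either a two-protein time course or a
microarray of all mRNAs at low or high time resolution — plus one gel-shift
experiment per interaction, which returns that interaction's Hill
coefficient and Kd exactly instead of a time course.

Designs are scored by propagating the profile-derived parameter set S
through the model: for each readout species i and time t, the spread

    R(D) = max_{i,t}  [ max_{z in S} x_i(t; z)  -  min_{z in S} x_i(t; z) ] / sigma_i(t)

is normalized by the measurement noise at the best-fit trajectory, so R is
the number of error bars separating the extreme predictions — experiments
with large R discriminate between parameter vectors that the current data
cannot tell apart.  Ranking is by descending R with a cheaper-first
tie-break among designs of similar score.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .error_model import Dataset, NoiseModel, combined_sd
from .grn_model import (
    GeneNetwork,
    ParameterVector,
    Perturbation,
    WILDTYPE,
    build_rhs,
)
from .ode_engine import IntegrationError, Trajectory, integrate
from .profile_likelihood import (
    IDENTIFIABLE,
    ProfileEnsemble,
    classify_identifiability,
    count_non_identifiable,
    profile_parameter_set,
)

__all__ = [
    "ProteinPair",
    "Microarray",
    "GelShift",
    "ExperimentDesign",
    "DesignScore",
    "DesignState",
    "DesignReport",
    "READOUT_POINTS",
    "DEFAULT_HORIZON",
    "enumerate_designs",
    "readout_species",
    "readout_times",
    "predict_readout",
    "score_design",
    "score_designs",
    "rank_designs",
    "extrapolation_uncertainty",
    "design_step",
]

#: measurement points per species for each readout class; the two-protein
#: purchase vends 40 points per protein (80 in total), a high-density
#: microarray 20 points per mRNA, a low-density microarray 10.
READOUT_POINTS = {"protein_pair": 40, "microarray_high": 20, "microarray_low": 10}

#: default simulated time horizon of a purchased time course (time units)
DEFAULT_HORIZON = 20.0

#: solver tolerances for design scoring (forward simulation only; looser
#: than estimation defaults because no gradients are taken)
SCORE_RTOL = 1e-6
SCORE_ATOL = 1e-9


@dataclass(frozen=True)
class ProteinPair:
    """Time course of two distinct proteins (unordered pair of genes)."""

    genes: tuple[str, str]

    def __post_init__(self):
        a, b = self.genes
        if a == b:
            raise ValueError("protein pair must name two distinct genes")
        object.__setattr__(self, "genes", tuple(sorted((str(a), str(b)))))

    @property
    def label(self) -> str:
        return f"pair:{self.genes[0]},{self.genes[1]}"


@dataclass(frozen=True)
class Microarray:
    """All-mRNA time course at low or high time resolution."""

    density: str

    def __post_init__(self):
        if self.density not in ("low", "high"):
            raise ValueError("microarray density must be 'low' or 'high'")

    @property
    def label(self) -> str:
        return f"ma:{self.density}"


@dataclass(frozen=True)
class GelShift:
    """Direct, noise-free measurement of one interaction's h and Kd."""

    interaction_index: int  # 0-based

    @property
    def label(self) -> str:
        return f"gelshift:{self.interaction_index + 1}"


@dataclass(frozen=True)
class ExperimentDesign:
    """A purchasable experiment: perturbation + readout + cost in credits."""

    perturbation: Perturbation | None
    readout: object
    cost: float

    def __post_init__(self):
        if self.cost <= 0:
            raise ValueError("design cost must be positive")
        if isinstance(self.readout, GelShift):
            if self.perturbation is not None:
                raise ValueError("gel-shift experiments carry no perturbation")
        elif self.perturbation is None:
            raise ValueError("time-course designs need a perturbation")

    @property
    def is_gelshift(self) -> bool:
        return isinstance(self.readout, GelShift)

    @property
    def label(self) -> str:
        if self.is_gelshift:
            return self.readout.label
        return f"{self.perturbation.label}+{self.readout.label}"


def readout_species(network: GeneNetwork, readout) -> list[str]:
    if isinstance(readout, ProteinPair):
        return [f"p{g}" for g in readout.genes]
    if isinstance(readout, Microarray):
        return [f"mRNA{g}" for g in network.genes]
    raise ValueError(f"readout {readout!r} has no species")


def readout_times(readout, horizon: float = DEFAULT_HORIZON) -> np.ndarray:
    if isinstance(readout, ProteinPair):
        n = READOUT_POINTS["protein_pair"]
    elif isinstance(readout, Microarray):
        n = READOUT_POINTS[f"microarray_{readout.density}"]
    else:
        raise ValueError(f"readout {readout!r} has no time grid")
    return np.linspace(horizon / n, horizon, n)


def enumerate_designs(network: GeneNetwork, cost_table) -> list[ExperimentDesign]:
    """All distinct purchasable experiments for a network.

    ``(3 G + 1)`` perturbation conditions times ``(C(G,2) + 2)`` time-course
    readouts, plus one gel-shift per interaction:
    ``(3G + 1)(C(G,2) + 2) + I`` designs in total.
    """
    perts = [WILDTYPE]
    for g in network.genes:
        perts += [
            Perturbation("knockout", g),
            Perturbation("sirna", g),
            Perturbation("rbs_boost", g),
        ]
    readouts: list[object] = [
        ProteinPair(pair) for pair in itertools.combinations(network.genes, 2)
    ]
    readouts += [Microarray("low"), Microarray("high")]
    designs = [
        ExperimentDesign(p, r, cost_table.cost_of(p, r)) for p in perts for r in readouts
    ]
    designs += [
        ExperimentDesign(None, GelShift(k), cost_table.cost_of(None, GelShift(k)))
        for k in range(network.n_interactions)
    ]
    return designs


def predict_readout(
    network: GeneNetwork,
    params: ParameterVector,
    design: ExperimentDesign,
    horizon: float = DEFAULT_HORIZON,
    rtol: float = SCORE_RTOL,
    atol: float = SCORE_ATOL,
) -> Trajectory:
    """Simulate the design's perturbed condition, restricted to its readout."""
    if design.is_gelshift:
        raise ValueError("gel-shift designs have no trajectory readout")
    times = readout_times(design.readout, horizon)
    system = build_rhs(network, params, design.perturbation)
    traj = integrate(system, network.x0(), times, rtol=rtol, atol=atol)
    species = readout_species(network, design.readout)
    idx = [network.species_index[s] for s in species]
    return Trajectory(times=times, states=traj.states[idx], species=tuple(species))


@dataclass
class DesignScore:
    """Noise-normalized trajectory spread of one design over S."""

    design: ExperimentDesign
    R: float
    argmax_species: str | None = None
    argmax_time: float | None = None
    n_failed: int = 0

    @property
    def cost(self) -> float:
        return self.design.cost


class _TrajectoryCache:
    """Full-state trajectories keyed by (perturbation, parameter row); all
    readouts of one perturbation share a single integration on the union
    time grid."""

    def __init__(self, network, template, times, horizon, rtol, atol):
        self.network = network
        self.template = template
        self.times = times
        self.rtol = rtol
        self.atol = atol
        self._cache: dict = {}

    def get(self, pert: Perturbation, z_key, z: np.ndarray):
        key = (pert.label, z_key)
        if key not in self._cache:
            params = self.template.with_log10(z)
            system = build_rhs(self.network, params, pert)
            try:
                self._cache[key] = integrate(
                    system, self.network.x0(), self.times, rtol=self.rtol, atol=self.atol
                )
            except IntegrationError:
                self._cache[key] = None
        return self._cache[key]


def score_designs(
    network: GeneNetwork,
    s_tilde: np.ndarray,
    designs: Sequence[ExperimentDesign],
    noise: NoiseModel,
    z_hat: np.ndarray,
    template: ParameterVector | None = None,
    aggregate: str = "max",
    horizon: float = DEFAULT_HORIZON,
) -> list[DesignScore]:
    """Score many designs sharing one trajectory cache (gel-shifts skipped)."""
    template = template or ParameterVector.for_network(network)
    s_tilde = np.atleast_2d(np.asarray(s_tilde, dtype=float))
    if len(s_tilde) < 2:
        raise ValueError("need at least two parameter vectors to measure spread")
    if aggregate not in ("max", "sum"):
        raise ValueError("aggregate must be 'max' or 'sum'")
    tc_designs = [d for d in designs if not d.is_gelshift]
    grids = {
        d.label: readout_times(d.readout, horizon) for d in tc_designs
    }
    union_times = np.unique(np.concatenate(list(grids.values()))) if grids else np.array([])
    cache = _TrajectoryCache(network, template, union_times, horizon, SCORE_RTOL, SCORE_ATOL)
    scores = []
    for design in tc_designs:
        times = grids[design.label]
        t_idx = np.searchsorted(union_times, times)
        species = readout_species(network, design.readout)
        s_idx = [network.species_index[s] for s in species]
        ref = cache.get(design.perturbation, "hat", z_hat)
        if ref is None:
            scores.append(DesignScore(design, np.nan, n_failed=len(s_tilde)))
            continue
        sd = combined_sd(np.maximum(ref.states[np.ix_(s_idx, t_idx)], 0.0), noise)
        sd = np.maximum(sd, 1e-12)
        lo = np.full(sd.shape, np.inf)
        hi = np.full(sd.shape, -np.inf)
        n_failed = 0
        for row, z in enumerate(s_tilde):
            traj = cache.get(design.perturbation, row, z)
            if traj is None:
                n_failed += 1
                continue
            x = traj.states[np.ix_(s_idx, t_idx)]
            lo = np.minimum(lo, x)
            hi = np.maximum(hi, x)
        if n_failed == len(s_tilde):
            raise IntegrationError(f"no parameter vector could be simulated for {design.label}")
        spread = (hi - lo) / sd
        if aggregate == "max":
            flat = int(np.argmax(spread))
            i, j = np.unravel_index(flat, spread.shape)
            scores.append(
                DesignScore(design, float(spread[i, j]), species[i], float(times[j]), n_failed)
            )
        else:
            per_species = spread.sum(axis=1)
            i = int(np.argmax(per_species))
            scores.append(DesignScore(design, float(per_species[i]), species[i], None, n_failed))
    return scores


def score_design(
    network: GeneNetwork,
    s_tilde: np.ndarray,
    design: ExperimentDesign,
    noise: NoiseModel,
    z_hat: np.ndarray,
    template: ParameterVector | None = None,
    aggregate: str = "max",
    horizon: float = DEFAULT_HORIZON,
) -> DesignScore:
    return score_designs(
        network, s_tilde, [design], noise, z_hat, template, aggregate, horizon
    )[0]


def rank_designs(
    scores: Iterable[DesignScore],
    budget: float,
    rel_tol: float = 0.1,
) -> tuple[list[DesignScore], list[DesignScore]]:
    """Order scores by descending R, cheaper-first among near-ties.

    Designs within ``rel_tol`` relative R of a group's best are considered
    similarly informative and sorted by cost.  Designs exceeding the budget
    are excluded from the recommendation but returned separately.
    """
    scores = [s for s in scores if np.isfinite(s.R) or np.isinf(s.R)]
    affordable = sorted(
        (s for s in scores if s.cost <= budget), key=lambda s: -s.R if np.isfinite(s.R) else -np.inf
    )
    affordable.sort(key=lambda s: (0 if np.isinf(s.R) else 1, -s.R if np.isfinite(s.R) else 0))
    excluded = [s for s in scores if s.cost > budget]
    ranked: list[DesignScore] = []
    i = 0
    while i < len(affordable):
        leader = affordable[i].R
        group = [affordable[i]]
        j = i + 1
        while j < len(affordable):
            r = affordable[j].R
            same = (np.isinf(leader) and np.isinf(r)) or (
                np.isfinite(leader) and r >= leader * (1.0 - rel_tol)
            )
            if not same:
                break
            group.append(affordable[j])
            j += 1
        group.sort(key=lambda s: s.cost)
        ranked.extend(group)
        i = j
    return ranked, excluded


def extrapolation_uncertainty(
    network: GeneNetwork,
    ensemble: ProfileEnsemble,
    prediction: Perturbation,
    noise: NoiseModel,
    template: ParameterVector | None = None,
    max_per_profile: int = 10,
    horizon: float = DEFAULT_HORIZON,
    n_times: int = 40,
) -> pd.DataFrame:
    """Per-parameter spread of the prediction trajectories.

    For each parameter, its own profile subset is propagated through the
    prediction condition and the noise-normalized spread over all species
    and times is reported; parameters are sorted by impact, i.e. by how much
    their remaining uncertainty moves the prediction.
    """
    template = template or ParameterVector.for_network(network)
    times = np.linspace(horizon / n_times, horizon, n_times)
    ref_params = template.with_log10(ensemble.z_hat)
    ref = integrate(
        build_rhs(network, ref_params, prediction),
        network.x0(),
        times,
        rtol=SCORE_RTOL,
        atol=SCORE_ATOL,
    )
    sd = np.maximum(combined_sd(np.maximum(ref.states, 0.0), noise), 1e-12)
    rows = []
    for prof in ensemble:
        single = ProfileEnsemble(
            profiles={prof.index: prof},
            z_hat=ensemble.z_hat,
            ll_star=ensemble.ll_star,
            alpha=ensemble.alpha,
            names=ensemble.names,
        )
        subset = profile_parameter_set(single, max_per_profile=max_per_profile)
        lo = np.full(ref.states.shape, np.inf)
        hi = np.full(ref.states.shape, -np.inf)
        for z in subset:
            try:
                traj = integrate(
                    build_rhs(network, template.with_log10(z), prediction),
                    network.x0(),
                    times,
                    rtol=SCORE_RTOL,
                    atol=SCORE_ATOL,
                )
            except IntegrationError:
                continue
            lo = np.minimum(lo, traj.states)
            hi = np.maximum(hi, traj.states)
        spread = float(np.max((hi - lo) / sd)) if np.all(np.isfinite(lo)) else np.nan
        rows.append({"parameter": prof.name, "index": prof.index, "spread": spread})
    return (
        pd.DataFrame(rows)
        .sort_values("spread", ascending=False, ignore_index=True)
    )


# ------------------------------------------------------------ orchestration

@dataclass
class DesignState:
    """Everything one design iteration needs: current data, fit, profiles
    and the remaining budget."""

    network: GeneNetwork
    dataset: Dataset
    noise: NoiseModel
    z_hat: np.ndarray
    ll_star: float
    ensemble: ProfileEnsemble
    cost_table: object
    budget_remaining: float
    template: ParameterVector | None = None
    horizon: float = DEFAULT_HORIZON
    max_per_profile: int = 10
    #: spread below which an experiment is considered uninformative
    stop_r_threshold: float = 1.0


@dataclass
class DesignReport:
    """Ranked purchase recommendation; the final choice stays with the user."""

    scores: list[DesignScore]
    recommended: list[DesignScore]
    excluded: list[DesignScore]
    n_non_identifiable: int
    n_non_identifiable_no_hill: int
    stop_recommended: bool
    text: str


def design_step(state: DesignState) -> DesignReport:
    """One iteration of the design loop: profiles -> S -> scores -> ranking.

    Gel-shift designs are not trajectory-scored; they enter the ranking with
    infinite R when either of their interaction's parameters is currently
    non-identifiable (they then resolve it exactly), and score 0 otherwise.
    """
    template = state.template or ParameterVector.for_network(state.network)
    s_tilde = profile_parameter_set(state.ensemble, max_per_profile=state.max_per_profile)
    designs = enumerate_designs(state.network, state.cost_table)
    scores = score_designs(
        state.network,
        s_tilde,
        designs,
        state.noise,
        state.z_hat,
        template,
        horizon=state.horizon,
    )
    classes = {
        prof.index: classify_identifiability(prof) for prof in state.ensemble
    }
    name_to_index = {n: i for i, n in enumerate(template.names)}
    for design in designs:
        if not design.is_gelshift:
            continue
        k = design.readout.interaction_index
        idx_h = name_to_index[f"h_{k + 1}"]
        idx_kd = name_to_index[f"kd_{k + 1}"]
        nonid = any(
            classes.get(i, IDENTIFIABLE) != IDENTIFIABLE for i in (idx_h, idx_kd)
        )
        scores.append(DesignScore(design, np.inf if nonid else 0.0))
    recommended, excluded = rank_designs(scores, state.budget_remaining)
    n_nonid = count_non_identifiable(state.ensemble)
    n_nonid_nh = count_non_identifiable(state.ensemble, exclude_hill=True)
    finite = [s.R for s in recommended if np.isfinite(s.R)]
    stop = (
        n_nonid == 0
        and not any(np.isinf(s.R) for s in recommended)
        and (not finite or max(finite) <= state.stop_r_threshold)
    )
    lines = [
        f"non-identifiable parameters: {n_nonid} "
        f"({n_nonid_nh} excluding Hill coefficients)",
        f"remaining budget: {state.budget_remaining:g} credits",
        f"profile parameter set size: {len(s_tilde)}",
        "",
        f"{'design':40s} {'R':>10s} {'cost':>8s}",
    ]
    for s in recommended:
        lines.append(f"{s.design.label:40s} {s.R:>10.3f} {s.cost:>8.0f}")
    for s in excluded:
        lines.append(f"{s.design.label:40s} {s.R:>10.3f} {s.cost:>8.0f}  (over budget)")
    if stop:
        lines.append(
            "\nAll parameters identifiable and predicted spreads are within "
            "measurement noise: recommend stopping."
        )
    elif recommended:
        lines.append(f"\nRecommended purchase: {recommended[0].design.label}")
    return DesignReport(
        scores=scores,
        recommended=recommended,
        excluded=excluded,
        n_non_identifiable=n_nonid,
        n_non_identifiable_no_hill=n_nonid_nh,
        stop_recommended=stop,
        text="\n".join(lines),
    )
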