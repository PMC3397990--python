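"""Hill-kinetics gene-regulatory-network models.

A network couples G genes through signed transcription-factor interactions.
Each gene ``g`` contributes two state variables, its transcript ``mRNA<g>``
and its protein ``p<g>``.  Transcription of a regulated gene follows Hill
kinetics in the regulating proteins; the rates of several regulators acting
on one promoter are added and share a single production strength.
Translation is linear mass action with a per-gene ribosomal-binding-site
(rbs) strength, one protein degradation rate shared by all proteins, and
mRNA degradation rates fixed to one (which sets the unit of time).

The free parameters of a network with G genes and I interactions are

===============  =====  ==================================
parameter        count  meaning
===============  =====  ==================================
``pro_<g>``      G      maximal transcription rate
``rbs_<g>``      G      translation rate constant
``delta_p``      1      shared protein degradation rate
``h_<k>``        I      Hill coefficient of interaction k
``kd_<k>``       I      half-saturation level of interaction k
===============  =====  ==================================

for a total of ``2 G + 1 + 2 I`` unknowns.  All estimation downstream
happens on the log10 of these values.

Perturbations rewrite the parameterization before simulation: a knockout
zeroes both production strengths of the targeted gene, an siRNA knock-down
multiplies the gene's mRNA degradation rate five-fold, and an rbs
perturbation doubles the translation strength.  Extra multiplicative
rewrites on named parameters are supported for prediction-only conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

try:  # compiled RHS kernels; the numpy path below remains the reference
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

__all__ = [
    "ACTIVATION",
    "REPRESSION",
    "Interaction",
    "GeneNetwork",
    "ParameterVector",
    "Perturbation",
    "WILDTYPE",
    "OdeSystem",
    "count_parameters",
    "parameter_names",
    "regulation_rate",
    "transcription_rate",
    "apply_perturbation",
    "perturbation_multipliers",
    "build_rhs",
    "load_network",
    "bundled_network",
]

ACTIVATION = "activation"
REPRESSION = "repression"
_SIGNS = (ACTIVATION, REPRESSION)

LN10 = math.log(10.0)

#: default initial concentration for every species; exactly zero initial
#: conditions are numerically fragile for the sensitivity system, so a small
#: positive value is used instead (configurable per species).
DEFAULT_X0 = 1e-6

#: default box for non-Hill parameters, log10 scale (about 5 decades).
DEFAULT_BOUNDS = (-2.0, 3.0)
#: Hill-coefficient domain, linear scale: wide and narrow modes.
HILL_BOUNDS_WIDE = (1.0, 10.0)
HILL_BOUNDS_NARROW = (1.0, 8.0)


@dataclass(frozen=True)
class Interaction:
    """One signed regulatory edge: ``regulator``'s protein acts on ``target``'s promoter."""

    regulator: str
    target: str
    sign: str

    def __post_init__(self):
        if self.sign not in _SIGNS:
            raise ValueError(f"sign must be one of {_SIGNS}, got {self.sign!r}")


@dataclass(frozen=True)
class GeneNetwork:
    """Topology of a gene regulatory network.

    Parameters
    ----------
    genes
        Ordered gene identifiers; gene ``g`` owns species ``mRNA<g>`` and
        ``p<g>``.
    interactions
        Signed edges; at most one edge per (regulator, target) pair.
    initial_conditions
        Optional per-species overrides of the default initial level.
    """

    genes: tuple[str, ...]
    interactions: tuple[Interaction, ...] = ()
    initial_conditions: Mapping[str, float] | None = None

    def __post_init__(self):
        genes = tuple(str(g) for g in self.genes)
        object.__setattr__(self, "genes", genes)
        inter = tuple(
            i if isinstance(i, Interaction) else Interaction(*i) for i in self.interactions
        )
        object.__setattr__(self, "interactions", inter)
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene identifiers")
        if not genes:
            raise ValueError("network needs at least one gene")
        gene_set = set(genes)
        seen = set()
        for it in inter:
            if it.regulator not in gene_set or it.target not in gene_set:
                raise ValueError(f"interaction {it} references unknown gene")
            key = (it.regulator, it.target)
            if key in seen:
                raise ValueError(f"duplicate interaction {key}")
            seen.add(key)
        if self.initial_conditions is not None:
            unknown = set(self.initial_conditions) - set(self.species)
            if unknown:
                raise ValueError(f"initial conditions for unknown species {sorted(unknown)}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_interactions(self) -> int:
        return len(self.interactions)

    @property
    def species(self) -> tuple[str, ...]:
        """State ordering: all mRNAs first, then all proteins."""
        return tuple(f"mRNA{g}" for g in self.genes) + tuple(f"p{g}" for g in self.genes)

    @property
    def species_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species)}

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)

    def x0(self) -> np.ndarray:
        """Initial state vector (defaults plus per-species overrides)."""
        x0 = np.full(2 * self.n_genes, DEFAULT_X0)
        if self.initial_conditions:
            idx = self.species_index
            for sp, v in self.initial_conditions.items():
                x0[idx[sp]] = float(v)
        return x0

    def incoming(self, gene: str) -> list[tuple[int, Interaction]]:
        """(interaction index, interaction) pairs regulating ``gene``."""
        return [(k, it) for k, it in enumerate(self.interactions) if it.target == gene]

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        d = {
            "genes": list(self.genes),
            "interactions": [
                {"from": it.regulator, "to": it.target, "sign": it.sign}
                for it in self.interactions
            ],
        }
        if self.initial_conditions:
            d["initial_conditions"] = dict(self.initial_conditions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneNetwork":
        inter = tuple(
            Interaction(str(e["from"]), str(e["to"]), e.get("sign", ACTIVATION))
            for e in d.get("interactions", [])
        )
        return cls(
            genes=tuple(str(g) for g in d["genes"]),
            interactions=inter,
            initial_conditions=d.get("initial_conditions"),
        )


def load_network(path: str | Path) -> GeneNetwork:
    """Load a network description from a YAML (or JSON) file."""
    with open(path) as fh:
        return GeneNetwork.from_dict(yaml.safe_load(fh))


def bundled_network(name: str) -> GeneNetwork:
    """Load one of the bundled benchmark topologies: grn6, grn7 or grn9."""
    path = Path(__file__).parent / "networks" / f"{name}.yaml"
    if not path.exists():
        raise ValueError(f"no bundled network named {name!r}")
    return load_network(path)


# --------------------------------------------------------------- parameters

def count_parameters(network: GeneNetwork) -> int:
    """Number of free kinetic parameters: ``2 G + 1 + 2 I``."""
    return 2 * network.n_genes + 1 + 2 * network.n_interactions


def parameter_names(network: GeneNetwork) -> tuple[str, ...]:
    names = [f"pro_{g}" for g in network.genes]
    names += [f"rbs_{g}" for g in network.genes]
    names.append("delta_p")
    for k in range(network.n_interactions):
        names += [f"h_{k + 1}", f"kd_{k + 1}"]
    return tuple(names)


@dataclass
class ParameterVector:
    """Named kinetic parameters on linear scale with log10 bounds.

    ``delta_m`` holds the fixed per-gene mRNA degradation rates (1 unless a
    perturbation rewrites them); they are not part of the free vector.
    """

    names: tuple[str, ...]
    values: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    genes: tuple[str, ...]
    delta_m: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        if self.delta_m is None:
            self.delta_m = np.ones(len(self.genes))
        else:
            self.delta_m = np.asarray(self.delta_m, dtype=float)
        n = len(self.names)
        if not (len(self.values) == len(self.lb) == len(self.ub) == n):
            raise ValueError("names, values and bounds must have equal length")
        if len(self.delta_m) != len(self.genes):
            raise ValueError("delta_m must have one entry per gene")

    # ------------------------------------------------------------ builders
    @classmethod
    def for_network(
        cls,
        network: GeneNetwork,
        values: Sequence[float] | Mapping[str, float] | None = None,
        bounds: tuple[float, float] = DEFAULT_BOUNDS,
        hill_bounds: tuple[float, float] = HILL_BOUNDS_WIDE,
    ) -> "ParameterVector":
        names = parameter_names(network)
        lb = np.full(len(names), bounds[0])
        ub = np.full(len(names), bounds[1])
        hill = np.array([n.startswith("h_") for n in names])
        lb[hill] = math.log10(hill_bounds[0])
        ub[hill] = math.log10(hill_bounds[1])
        if values is None:
            vals = np.ones(len(names))
        elif isinstance(values, Mapping):
            vals = np.array([float(values[n]) for n in names])
        else:
            vals = np.asarray(values, dtype=float)
        return cls(names=names, values=vals, lb=lb, ub=ub, genes=network.genes)

    def copy(self) -> "ParameterVector":
        return replace(
            self,
            values=self.values.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            delta_m=self.delta_m.copy(),
        )

    def with_values(self, values: np.ndarray) -> "ParameterVector":
        out = self.copy()
        out.values = np.asarray(values, dtype=float)
        return out

    def with_log10(self, z: np.ndarray) -> "ParameterVector":
        return self.with_values(10.0 ** np.asarray(z, dtype=float))

    # ----------------------------------------------------------- accessors
    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.index(name)])

    @property
    def log10(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log10(self.values)

    @property
    def is_hill(self) -> np.ndarray:
        return np.array([n.startswith("h_") for n in self.names])

    def validate(self) -> None:
        """Check positivity and bound membership of a free (unperturbed) vector."""
        if np.any(self.values <= 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("parameter values must be strictly positive and finite")
        z = self.log10
        if np.any(z < self.lb - 1e-12) or np.any(z > self.ub + 1e-12):
            raise ValueError("parameter values outside their log10 bounds")

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "values": [float(v) for v in self.values],
            "lb": [float(v) for v in self.lb],
            "ub": [float(v) for v in self.ub],
            "genes": list(self.genes),
            "delta_m": [float(v) for v in self.delta_m],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterVector":
        return cls(
            names=tuple(d["names"]),
            values=np.asarray(d["values"], dtype=float),
            lb=np.asarray(d["lb"], dtype=float),
            ub=np.asarray(d["ub"], dtype=float),
            genes=tuple(d["genes"]),
            delta_m=np.asarray(d["delta_m"], dtype=float),
        )


# ------------------------------------------------------------ perturbations

_PERT_KINDS = ("wildtype", "knockout", "sirna", "rbs_boost")

#: factor applied to a gene's mRNA degradation rate under siRNA knock-down
SIRNA_FACTOR = 5.0
#: factor applied to a gene's rbs strength under an rbs perturbation
RBS_FACTOR = 2.0


@dataclass(frozen=True)
class Perturbation:
    """Experimental condition rewriting the model parameterization."""

    kind: str = "wildtype"
    gene: str | None = None
    extra: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        if self.kind not in _PERT_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if (self.gene is None) != (self.kind == "wildtype"):
            raise ValueError("gene must be given iff kind is not wildtype")
        object.__setattr__(self, "extra", tuple((str(n), float(c)) for n, c in self.extra))

    @property
    def label(self) -> str:
        base = self.kind if self.gene is None else f"{self.kind}:{self.gene}"
        if self.extra:
            base += "+" + ",".join(f"{n}x{c:g}" for n, c in self.extra)
        return base

    def to_dict(self) -> dict:
        return {"kind": self.kind, "gene": self.gene, "extra": [list(e) for e in self.extra]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Perturbation":
        return cls(
            kind=d.get("kind", "wildtype"),
            gene=d.get("gene"),
            extra=tuple((e[0], e[1]) for e in d.get("extra", ())),
        )


WILDTYPE = Perturbation()


def perturbation_multipliers(
    network: GeneNetwork, params: ParameterVector, perturbation: Perturbation
) -> tuple[np.ndarray, np.ndarray]:
    """Multipliers on the free vector and the rewritten per-gene delta_m.

    The multiplicative form keeps the chain rule for log-parameter
    sensitivities trivial: the vector field depends on ``c_j * theta_j`` only.
    """
    mult = np.ones(len(params))
    delta_m = params.delta_m.copy()
    G = network.n_genes
    if perturbation.kind != "wildtype":
        g = network.gene_index(perturbation.gene)
        if perturbation.kind == "knockout":
            mult[g] = 0.0  # pro_g
            mult[G + g] = 0.0  # rbs_g
        elif perturbation.kind == "sirna":
            delta_m[g] *= SIRNA_FACTOR
        elif perturbation.kind == "rbs_boost":
            mult[G + g] *= RBS_FACTOR
    for name, c in perturbation.extra:
        mult[params.index(name)] *= c
    return mult, delta_m


def apply_perturbation(
    network: GeneNetwork, params: ParameterVector, perturbation: Perturbation
) -> ParameterVector:
    """Return the perturbed parameterization (the input is left untouched)."""
    mult, delta_m = perturbation_multipliers(network, params, perturbation)
    out = params.with_values(params.values * mult)
    out.delta_m = delta_m
    return out


# ------------------------------------------------------------------- rates

def regulation_rate(
    regulator_level: float | np.ndarray,
    sign: str,
    h: float,
    kd: float,
    production_strength: float,
) -> float | np.ndarray:
    """Hill-kinetics transcription rate of a single regulatory edge.

    Activation: ``pro * (x/Kd)^h / (1 + (x/Kd)^h)``; repression:
    ``pro / (1 + (x/Kd)^h)``.
    """
    x = np.asarray(regulator_level, dtype=float)
    if np.any(x < 0):
        raise ValueError("regulator level must be non-negative")
    if sign not in _SIGNS:
        raise ValueError(f"sign must be one of {_SIGNS}")
    if h <= 0 or kd <= 0 or production_strength <= 0:
        raise ValueError("h, Kd and production strength must be positive")
    with np.errstate(over="ignore"):
        u = np.minimum((x / kd) ** h, 1e150)
    frac = u / (1.0 + u) if sign == ACTIVATION else 1.0 / (1.0 + u)
    out = production_strength * frac
    return float(out) if np.isscalar(regulator_level) else out


def transcription_rate(
    network: GeneNetwork,
    gene: str,
    protein_levels: Mapping[str, float],
    params: ParameterVector,
) -> float:
    """Total transcription rate of ``gene``: summed Hill terms sharing one
    production strength, or the bare production strength if unregulated."""
    if gene not in network.genes:
        raise ValueError(f"unknown gene {gene!r}")
    pro = params[f"pro_{gene}"]
    incoming = network.incoming(gene)
    if not incoming:
        return pro
    total = 0.0
    for k, it in incoming:
        total += regulation_rate(
            protein_levels[it.regulator],
            it.sign,
            params[f"h_{k + 1}"],
            params[f"kd_{k + 1}"],
            pro,
        )
    return total


# ----------------------------------------------------------- ODE assembly

class OdeSystem:
    """Callable vector field with analytic Jacobians for a perturbed GRN.

    ``system(t, x)`` evaluates dx/dt; ``jac_x`` is the state Jacobian and
    ``jac_theta_log`` the parameter Jacobian with respect to the *log10 of
    the base (unperturbed) parameters*, with perturbation multipliers folded
    in via the chain rule.
    """

    def __init__(
        self,
        network: GeneNetwork,
        params: ParameterVector,
        perturbation: Perturbation = WILDTYPE,
    ):
        self.network = network
        self.perturbation = perturbation
        G = network.n_genes
        self.G = G
        self.n_states = 2 * G
        self.n_params = len(params)
        mult, delta_m = perturbation_multipliers(network, params, perturbation)
        theta_eff = params.values * mult
        self.theta_eff = theta_eff
        #: chain-rule factor d theta_eff / d log10(theta_base)
        self.chain = LN10 * theta_eff
        self.pro = theta_eff[:G]
        self.rbs = theta_eff[G : 2 * G]
        self.delta_p = theta_eff[2 * G]
        self.delta_m = delta_m
        self.i_dp = 2 * G
        I = network.n_interactions
        self.I = I
        if I:
            self.reg = np.array([network.gene_index(it.regulator) for it in network.interactions])
            self.tgt = np.array([network.gene_index(it.target) for it in network.interactions])
            self.act = np.array([it.sign == ACTIVATION for it in network.interactions])
            self.i_h = np.arange(I) * 2 + 2 * G + 1
            self.i_kd = self.i_h + 1
            self.h = theta_eff[self.i_h]
            self.kd = theta_eff[self.i_kd]
            regulated = np.zeros(G, dtype=bool)
            regulated[self.tgt] = True
            self.basal = np.where(regulated, 0.0, 1.0)
        else:
            self.basal = np.ones(G)
        if not I:
            self.reg = np.zeros(0, dtype=np.int64)
            self.tgt = np.zeros(0, dtype=np.int64)
            self.act = np.zeros(0, dtype=bool)
            self.i_h = np.zeros(0, dtype=np.int64)
            self.i_kd = np.zeros(0, dtype=np.int64)
            self.h = np.zeros(0)
            self.kd = np.zeros(0)
        # hot-path index caches (the RHS is called thousands of times per fit)
        self._ar = np.arange(G)
        self._arG = self._ar + G
        self._i_pro = self._ar
        self._i_rbs = self._arG

    # -------------------------------------------------------- hill pieces
    def _hill(self, p: np.ndarray, derivs: bool = False):
        """Hill fractions (and optionally their x/h/Kd derivatives) per edge."""
        xr = np.maximum(p[self.reg], 0.0)
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            ratio = xr / self.kd
            u = np.minimum(ratio**self.h, 1e150)
            frac = np.where(self.act, u / (1.0 + u), 1.0 / (1.0 + u))
        if not derivs:
            return frac
        sgn = np.where(self.act, 1.0, -1.0)
        denom = (1.0 + u) ** 2
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            du_dx = self.h * ratio ** (self.h - 1.0) / self.kd
            du_dx = np.where(np.isfinite(du_dx), du_dx, 0.0)
            du_dkd = -self.h * u / self.kd
            logratio = np.where(xr > 0, np.log(np.maximum(ratio, 1e-300)), 0.0)
            du_dh = u * logratio
            dfrac_du = sgn / denom
            dfrac_du = np.where(np.isfinite(dfrac_du), dfrac_du, 0.0)
        d_dx = dfrac_du * du_dx
        d_dkd = dfrac_du * du_dkd
        d_dh = dfrac_du * du_dh
        return frac, d_dx, d_dkd, d_dh

    def _transcription(self, p: np.ndarray) -> np.ndarray:
        total = self.basal.copy()
        if self.I:
            total = total + np.bincount(self.tgt, weights=self._hill(p), minlength=self.G)
        return self.pro * total

    # ---------------------------------------------------------- interface
    def __call__(self, t: float, x: np.ndarray) -> np.ndarray:
        G = self.G
        m, p = x[:G], x[G:]
        out = np.empty(2 * G)
        out[:G] = self._transcription(p) - self.delta_m * m
        out[G:] = self.rbs * m - self.delta_p * p
        return out

    def jac_x(self, t: float, x: np.ndarray) -> np.ndarray:
        G = self.G
        J = np.zeros((2 * G, 2 * G))
        J[self._ar, self._ar] = -self.delta_m
        J[self._arG, self._ar] = self.rbs
        J[self._arG, self._arG] = -self.delta_p
        if self.I:
            _, d_dx, _, _ = self._hill(x[G:], derivs=True)
            np.add.at(J, (self.tgt, G + self.reg), self.pro[self.tgt] * d_dx)
        return J

    def jac_theta_log(self, t: float, x: np.ndarray) -> np.ndarray:
        """d f / d log10(theta_base), shape (n_states, n_params)."""
        G = self.G
        m, p = x[:G], x[G:]
        F = np.zeros((2 * G, self.n_params))
        hill_sum = self.basal
        if self.I:
            frac, _, d_dkd, d_dh = self._hill(p, derivs=True)
            hill_sum = hill_sum + np.bincount(self.tgt, weights=frac, minlength=G)
            F[self.tgt, self.i_h] = self.pro[self.tgt] * d_dh
            F[self.tgt, self.i_kd] = self.pro[self.tgt] * d_dkd
        F[self._ar, self._i_pro] = hill_sum  # d(dm)/d pro
        F[self._arG, self._i_rbs] = m  # d(dp)/d rbs
        F[self._arG, self.i_dp] = -p
        F *= self.chain[None, :]
        return F

    def rhs_and_jacs(self, t: float, x: np.ndarray):
        """Fused (f, df/dx, df/dlog10 theta) evaluation sharing one Hill pass;
        this is the hot path of the augmented sensitivity system."""
        G = self.G
        m, p = x[:G], x[G:]
        f = np.empty(2 * G)
        J = np.zeros((2 * G, 2 * G))
        F = np.zeros((2 * G, self.n_params))
        J[self._ar, self._ar] = -self.delta_m
        J[self._arG, self._ar] = self.rbs
        J[self._arG, self._arG] = -self.delta_p
        hill_sum = self.basal
        if self.I:
            frac, d_dx, d_dkd, d_dh = self._hill(p, derivs=True)
            hill_sum = hill_sum + np.bincount(self.tgt, weights=frac, minlength=G)
            pro_t = self.pro[self.tgt]
            np.add.at(J, (self.tgt, G + self.reg), pro_t * d_dx)
            F[self.tgt, self.i_h] = pro_t * d_dh
            F[self.tgt, self.i_kd] = pro_t * d_dkd
        f[:G] = self.pro * hill_sum - self.delta_m * m
        f[G:] = self.rbs * m - self.delta_p * p
        F[self._ar, self._i_pro] = hill_sum
        F[self._arG, self._i_rbs] = m
        F[self._arG, self.i_dp] = -p
        F *= self.chain[None, :]
        return f, J, F

    def x0(self) -> np.ndarray:
        return self.network.x0()

    def kernel_args(self) -> tuple:
        """Argument pack for the compiled RHS kernels."""
        return (
            self.G,
            self.n_params,
            np.ascontiguousarray(self.pro),
            np.ascontiguousarray(self.rbs),
            float(self.delta_p),
            np.ascontiguousarray(self.delta_m),
            np.ascontiguousarray(self.reg, dtype=np.int64),
            np.ascontiguousarray(self.tgt, dtype=np.int64),
            np.where(self.act, 1.0, -1.0),
            np.ascontiguousarray(self.h),
            np.ascontiguousarray(self.kd),
            np.ascontiguousarray(self.basal),
            np.ascontiguousarray(self.chain),
            int(self.i_dp),
            np.ascontiguousarray(self.i_h, dtype=np.int64),
            np.ascontiguousarray(self.i_kd, dtype=np.int64),
        )


def _hill_pieces_scalar(xr, h, kd, sgn):
    # shared scalar Hill algebra of the compiled kernels
    if xr < 0.0:
        xr = 0.0
    ratio = xr / kd
    u = ratio**h
    if u > 1e150:
        u = 1e150
    om = 1.0 + u
    frac = u / om if sgn > 0.0 else 1.0 / om
    dfrac_du = sgn / (om * om)
    du_dx = h * ratio ** (h - 1.0) / kd
    if not np.isfinite(du_dx):
        du_dx = 0.0
    d_dx = dfrac_du * du_dx
    d_dkd = dfrac_du * (-h * u / kd)
    if xr > 0.0 and u > 0.0:
        d_dh = dfrac_du * (u * np.log(ratio))
    else:
        d_dh = 0.0
    return frac, d_dx, d_dkd, d_dh


def _grn_rhs_py(t, y, G, npar, pro, rbs, dp, dm, reg, tgt, sgn, h, kd, basal, chain, i_dp, i_h, i_kd):
    out = np.empty(2 * G)
    hill_sum = basal.copy()
    for k in range(reg.shape[0]):
        frac, _, _, _ = _hill_pieces_scalar(y[G + reg[k]], h[k], kd[k], sgn[k])
        hill_sum[tgt[k]] += frac
    for g in range(G):
        out[g] = pro[g] * hill_sum[g] - dm[g] * y[g]
        out[G + g] = rbs[g] * y[g] - dp * y[G + g]
    return out


def _grn_aug_rhs_py(t, y, G, npar, pro, rbs, dp, dm, reg, tgt, sgn, h, kd, basal, chain, i_dp, i_h, i_kd):
    n = 2 * G
    nI = reg.shape[0]
    out = np.zeros(n * (npar + 1))
    hill_sum = basal.copy()
    d_dx = np.empty(nI)
    d_dkd = np.empty(nI)
    d_dh = np.empty(nI)
    for k in range(nI):
        frac, dx, dkd, dh = _hill_pieces_scalar(y[G + reg[k]], h[k], kd[k], sgn[k])
        hill_sum[tgt[k]] += frac
        d_dx[k] = dx
        d_dkd[k] = dkd
        d_dh[k] = dh
    J = np.zeros((n, n))
    for g in range(G):
        out[g] = pro[g] * hill_sum[g] - dm[g] * y[g]
        out[G + g] = rbs[g] * y[g] - dp * y[G + g]
        J[g, g] = -dm[g]
        J[G + g, g] = rbs[g]
        J[G + g, G + g] = -dp
    for k in range(nI):
        J[tgt[k], G + reg[k]] += pro[tgt[k]] * d_dx[k]
    # sensitivity columns are stored contiguously per parameter (F order)
    for j in range(npar):
        base = n + j * n
        for i in range(n):
            acc = 0.0
            for l in range(n):
                acc += J[i, l] * y[base + l]
            out[base + i] = acc
    for g in range(G):
        out[n + g * n + g] += pro[g] * hill_sum[g] * LN10  # d dm_g/d log10 pro_g
        jr = G + g
        out[n + jr * n + (G + g)] += y[g] * chain[jr]  # d dp_g/d log10 rbs_g
        out[n + i_dp * n + (G + g)] += -y[G + g] * chain[i_dp]
    for k in range(nI):
        row = tgt[k]
        out[n + i_h[k] * n + row] += pro[row] * d_dh[k] * chain[i_h[k]]
        out[n + i_kd[k] * n + row] += pro[row] * d_dkd[k] * chain[i_kd[k]]
    return out


if _njit is not None:
    _hill_pieces_scalar = _njit(cache=True)(_hill_pieces_scalar)
    grn_rhs_kernel = _njit(cache=True)(_grn_rhs_py)
    grn_aug_rhs_kernel = _njit(cache=True)(_grn_aug_rhs_py)
else:  # pragma: no cover
    grn_rhs_kernel = _grn_rhs_py
    grn_aug_rhs_kernel = _grn_aug_rhs_py


def build_rhs(
    network: GeneNetwork,
    params: ParameterVector,
    perturbation: Perturbation = WILDTYPE,
) -> OdeSystem:
    """Assemble the perturbed vector field; the result is callable as f(t, x)."""
    if len(params) != count_parameters(network):
        raise ValueError(
            f"parameter vector of length {len(params)} does not match the "
            f"{count_parameters(network)} free parameters of the network"
        )
    return OdeSystem(network, params, perturbation)
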