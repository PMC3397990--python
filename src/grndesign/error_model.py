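"""Measurement error model and the (optionally zero-clipped) log-likelihood.

A measurement of a species at true level x is

    y = max(0, x + eps_abs + eps_rel),
    eps_abs ~ N(0, sigma_abs^2),  eps_rel ~ N(0, (sigma_rel * x)^2),

i.e. additive Gaussian noise plus 20 % (by default) relative Gaussian noise,
with negative realizations clipped to zero.  Because the two error terms are
independent Gaussians, the unclipped value is N(x, sigma(x)^2) with

    sigma(x)^2 = sigma_abs^2 + (sigma_rel * x)^2.

The plain Gaussian log-likelihood uses that density for every record.  The
clipped variant replaces the density of records with y = 0 by the
probability mass of all negative realizations, log Phi(-x / sigma(x)), so
that the per-record measure (density on y > 0 plus an atom at 0) integrates
to one.  The relative term is taken on the noise-free model value, which
makes the combined variance above exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special

from .grn_model import Perturbation
from .ode_engine import Trajectory

__all__ = [
    "NoiseModel",
    "Dataset",
    "AlignmentError",
    "combined_sd",
    "simulate_measurement",
    "record_loglik",
    "record_loglik_and_grad",
    "loglik_gaussian",
    "loglik_clipped",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class NoiseModel:
    """Absolute + relative Gaussian measurement noise with optional clipping.

    The absolute component is not printed legibly in the challenge
    description this emulates; 0.1 is the package default and should be set
    explicitly when emulating a specific data source.
    """

    sigma_abs: float = 0.1
    sigma_rel: float = 0.2
    clip_at_zero: bool = True

    def __post_init__(self):
        if self.sigma_abs < 0 or self.sigma_rel < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.sigma_abs == 0 and self.sigma_rel == 0:
            raise ValueError("at least one noise component must be positive")

    def to_dict(self) -> dict:
        return {
            "sigma_abs": self.sigma_abs,
            "sigma_rel": self.sigma_rel,
            "clip_at_zero": self.clip_at_zero,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NoiseModel":
        return cls(**dict(d))


def combined_sd(x, noise: NoiseModel):
    """Standard deviation of the unclipped measurement at true level ``x``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("true levels must be non-negative")
    out = np.sqrt(noise.sigma_abs**2 + (noise.sigma_rel * x) ** 2)
    return float(out) if out.ndim == 0 else out


def simulate_measurement(x, noise: NoiseModel, rng: np.random.Generator):
    """Draw noisy measurements at true levels ``x`` (vectorized, seedable)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("true levels must be non-negative")
    y = x + rng.normal(0.0, noise.sigma_abs, size=x.shape) + rng.normal(
        0.0, 1.0, size=x.shape
    ) * (noise.sigma_rel * x)
    if noise.clip_at_zero:
        y = np.maximum(y, 0.0)
    return float(y) if y.ndim == 0 else y


# ------------------------------------------------------------------ dataset

class Dataset:
    """Observed (condition, species, time, value) records.

    Thin wrapper around a pandas DataFrame with the condition-to-perturbation
    mapping and the noise model that generated (or is assumed for) the data.
    """

    COLUMNS = ("condition_id", "species", "time", "value")

    def __init__(
        self,
        df: pd.DataFrame | None = None,
        conditions: Mapping[str, Perturbation] | None = None,
        noise: NoiseModel | None = None,
    ):
        if df is None:
            df = pd.DataFrame({c: [] for c in self.COLUMNS})
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        self.df = df.reset_index(drop=True)[list(self.COLUMNS)].astype(
            {"condition_id": str, "species": str, "time": float, "value": float}
        )
        self.conditions = dict(conditions or {})
        self.noise = noise
        if noise is not None and noise.clip_at_zero and np.any(self.df["value"].values < 0):
            raise ValueError("negative values in a zero-clipped dataset")

    @classmethod
    def from_records(cls, records, conditions=None, noise=None) -> "Dataset":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)), conditions, noise)

    def __len__(self) -> int:
        return len(self.df)

    def __add__(self, other: "Dataset") -> "Dataset":
        conditions = {**self.conditions, **other.conditions}
        return Dataset(
            pd.concat([self.df, other.df], ignore_index=True),
            conditions,
            self.noise or other.noise,
        )

    @property
    def condition_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["condition_id"]))

    def for_condition(self, condition_id: str) -> pd.DataFrame:
        return self.df[self.df["condition_id"] == condition_id]

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, conditions=None, noise=None) -> "Dataset":
        return cls(pd.read_csv(path), conditions, noise)


class AlignmentError(ValueError):
    """A dataset record has no matching point in the simulated trajectory."""


def _lookup(trajectory: Trajectory, species: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Model values at each record's (species, time); exact time match required."""
    if trajectory.species is None:
        raise AlignmentError("trajectory carries no species labels")
    sp_index = {s: i for i, s in enumerate(trajectory.species)}
    t_idx = np.searchsorted(trajectory.times, times)
    t_idx = np.clip(t_idx, 0, len(trajectory.times) - 1)
    left = np.clip(t_idx - 1, 0, None)
    use_left = np.abs(trajectory.times[left] - times) < np.abs(trajectory.times[t_idx] - times)
    t_idx = np.where(use_left, left, t_idx)
    if np.any(np.abs(trajectory.times[t_idx] - times) > 1e-9):
        bad = times[np.abs(trajectory.times[t_idx] - times) > 1e-9][0]
        raise AlignmentError(f"no trajectory point at time {bad:g}")
    try:
        s_idx = np.array([sp_index[s] for s in species])
    except KeyError as err:
        raise AlignmentError(f"species {err} not in trajectory") from err
    return trajectory.states[s_idx, t_idx]


# --------------------------------------------------------------- likelihood

def record_loglik(y, x, noise: NoiseModel, clipped: bool | None = None):
    """Per-record log-likelihood contribution (vectorized).

    With clipping, records at y = 0 contribute ``log Phi(-x/sigma(x))``;
    all others the Gaussian log-density ``log N(y; x, sigma(x)^2)``.
    """
    ll, _ = record_loglik_and_grad(y, x, noise, clipped)
    return ll


def record_loglik_and_grad(y, x, noise: NoiseModel, clipped: bool | None = None):
    """Contributions and their derivatives with respect to the model value x."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if clipped is None:
        clipped = noise.clip_at_zero
    if clipped and np.any(y < 0):
        raise ValueError("negative observations are invalid under a clipped error model")
    sd = combined_sd(x, noise)
    var = sd**2
    dsd_dx = noise.sigma_rel**2 * x / sd
    resid = y - x
    ll = -_LOG_SQRT_2PI - np.log(sd) - 0.5 * resid**2 / var
    dll = resid / var + (resid**2 / var - 1.0) * dsd_dx / sd
    if clipped:
        zero = y == 0
        if np.any(zero):
            z = x / sd
            ll_zero = special.log_ndtr(-z)
            # d/dx log Phi(-z) with dz/dx = sigma_abs^2 / sigma^3
            dz_dx = noise.sigma_abs**2 / sd**3
            log_pdf = -_LOG_SQRT_2PI - 0.5 * z**2
            dll_zero = -np.exp(log_pdf - ll_zero) * dz_dx
            ll = np.where(zero, ll_zero, ll)
            dll = np.where(zero, dll_zero, dll)
    if ll.ndim == 0:
        return float(ll), float(dll)
    return ll, dll


def _loglik(dataset: Dataset, trajectories, noise: NoiseModel, clipped: bool) -> float:
    if isinstance(trajectories, Trajectory):
        if len(dataset.condition_ids) > 1:
            raise AlignmentError("multi-condition dataset needs a mapping of trajectories")
        trajectories = {cid: trajectories for cid in dataset.condition_ids}
    total = 0.0
    for cid in dataset.condition_ids:
        sub = dataset.for_condition(cid)
        # clamp integrator round-off below zero; the error model needs x >= 0
        x = np.maximum(_lookup(trajectories[cid], sub["species"].values, sub["time"].values), 0.0)
        ll, _ = record_loglik_and_grad(sub["value"].values, x, noise, clipped)
        total += float(np.sum(ll))
    return total


def loglik_gaussian(dataset: Dataset, trajectories, noise: NoiseModel) -> float:
    """Gaussian log-likelihood ignoring the clipping of negative draws.

    ``trajectories`` is a single :class:`Trajectory` (one condition) or a
    mapping from condition id to trajectory.
    """
    return _loglik(dataset, trajectories, noise, clipped=False)


def loglik_clipped(dataset: Dataset, trajectories, noise: NoiseModel) -> float:
    """Log-likelihood accounting for zero-clipping; equals the Gaussian
    form exactly on datasets without zeros."""
    return _loglik(dataset, trajectories, noise, clipped=True)
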