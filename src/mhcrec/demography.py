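"""Logistic (Verhulst) growth, harmonic-mean effective size, and ρ = 4·Ne·c.

A founded population that expands to a plateau is summarised by the logistic
trajectory N_t = N0·K / (N0 + (K − N0)·e^{−r0·t}).  The effective size
relevant to coalescent quantities over the whole post-founding period is the
harmonic mean of N_t, which is dominated by the small early generations —
the reason Ne estimates for such populations are so sensitive to the
demographic parameters, and why converting a population recombination
parameter ρ = 4·Ne·c into a per-generation rate c is ill-conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VerhulstParams",
    "NeSummary",
    "verhulst_size",
    "harmonic_mean_ne",
    "ne_grid",
    "rho_to_c",
    "c_to_ne",
]


@dataclass(frozen=True)
class VerhulstParams:
    """Logistic-growth parameters.

    n0: founder size (animals); k: carrying capacity per generation;
    r0: intrinsic growth rate per generation.
    """

    n0: float
    k: float
    r0: float

    def __post_init__(self) -> None:
        if not 0 < self.n0 <= self.k:
            raise ValueError("require 0 < N0 <= K")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")

    @classmethod
    def from_annual_rate(
        cls, n0: float, k: float, r_per_year: float, generation_time: float
    ) -> "VerhulstParams":
        """Convenience constructor when the growth rate is quoted per year."""
        return cls(n0=n0, k=k, r0=r_per_year * generation_time)


@dataclass(frozen=True)
class NeSummary:
    ne: float
    trajectory: np.ndarray  # N_t for t = 1..T
    generations: int


def verhulst_size(params: VerhulstParams, t) -> np.ndarray | float:
    """Population size N_t of the logistic model at generation(s) t (continuous)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    n0, k, r0 = params.n0, params.k, params.r0
    out = n0 * k / (n0 + (k - n0) * np.exp(-r0 * t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def harmonic_mean_ne(params: VerhulstParams, generations: int) -> NeSummary:
    """Harmonic-mean effective size over generations t = 1..T.

    The founder generation t = 0 is excluded: the summary describes the
    population that existed after the founding event.
    """
    if generations < 1:
        raise ValueError("need at least one generation")
    t = np.arange(1, generations + 1)
    traj = verhulst_size(params, t)
    ne = generations / np.sum(1.0 / traj)
    return NeSummary(ne=float(ne), trajectory=traj, generations=generations)


def ne_grid(
    n0_values: Sequence[float],
    r0_values: Sequence[float],
    k: float,
    t_values: Sequence[int],
) -> pd.DataFrame:
    """Harmonic-mean Ne over a demographic grid; one row per combination.

    The returned frame carries ``ne_min``/``ne_max`` attrs with the overall
    extremes.
    """
    if not (len(n0_values) and len(r0_values) and len(t_values)):
        raise ValueError("grids must be non-empty")
    rows = []
    for n0 in n0_values:
        for r0 in r0_values:
            p = VerhulstParams(n0=n0, k=k, r0=r0)
            for t in t_values:
                rows.append(
                    {
                        "n0": n0,
                        "r0": r0,
                        "k": k,
                        "generations": t,
                        "ne": harmonic_mean_ne(p, t).ne,
                    }
                )
    frame = pd.DataFrame(rows)
    frame.attrs["ne_min"] = float(frame["ne"].min())
    frame.attrs["ne_max"] = float(frame["ne"].max())
    return frame


def rho_to_c(rho: float, ne: float) -> float:
    """Per-generation recombination rate from the population parameter: c = ρ/(4·Ne)."""
    if rho <= 0 or ne <= 0:
        raise ValueError("rho and Ne must be positive")
    return rho / (4.0 * ne)


def c_to_ne(rho: float, c: float) -> float:
    """Effective size implied by ρ and a per-generation rate: Ne = ρ/(4·c)."""
    if rho <= 0 or c <= 0:
        raise ValueError("rho and c must be positive")
    return rho / (4.0 * c)
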