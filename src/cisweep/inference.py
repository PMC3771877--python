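"""Fitting fecundity parameters to observed infection-frequency changes.

Deterministic inversions of the recursions: scalar root-solves for the
relative fecundity that maps one observed frequency to another over a given
number of generations, sensitivity grids over (mu, F) combinations, and the
minimal CI-strain fecundity required to displace a resident strain within a
time horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dynamics import PopState, iterate, iterate_single, step_single_noCI
from .params import SingleStrainParams, TwoStrainParams

__all__ = [
    "GenerationCalendar",
    "FrequencyObservation",
    "FitResult",
    "fit_F_single",
    "trajectory_grid",
    "required_FR",
    "years_to_generations",
]


@dataclass(frozen=True)
class GenerationCalendar:
    """Conversion between calendar years and host generations."""

    generations_per_year: float

    def __post_init__(self) -> None:
        if not self.generations_per_year > 0:
            raise ValueError("generations_per_year must be positive")


@dataclass(frozen=True)
class FrequencyObservation:
    """A single infection-frequency estimate at a site and date."""

    p: float
    year: float
    n: Optional[int] = None
    site: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p={self.p!r} must lie in [0, 1]")
        if self.n is not None and self.n < 0:
            raise ValueError("n must be >= 0")


def years_to_generations(years: float, cal: GenerationCalendar) -> int:
    """Number of generations elapsed in ``years``, rounded to nearest."""
    if years < 0:
        raise ValueError("years must be >= 0")
    return int(math.floor(years * cal.generations_per_year + 0.5))


@dataclass(frozen=True)
class FitResult:
    F: float
    bracket: tuple[float, float]
    residual: float


def _forward(F: float, p0: float, mu: float, n_gens: int) -> float:
    params = SingleStrainParams(F=F, mu=mu)
    p = p0
    for _ in range(n_gens):
        p = step_single_noCI(p, params)
    return p


def fit_F_single(
    p0: float,
    p1: float,
    n_gens: int,
    mu: float,
    bracket: tuple[float, float] = (0.5, 2.0),
    full_result: bool = False,
) -> float | FitResult:
    """Fecundity F such that ``n_gens`` non-CI steps map ``p0`` to ``p1``.

    The final frequency is monotone increasing in F, so the root is
    bracketed and solved with Brent's method (xtol 1e-12); the default
    bracket [0.5, 2] is expanded on demand.  Raises a diagnostic error if
    ``p1`` is unattainable for any F (the leakage-limited ceiling for the
    final frequency is below the target).
    """
    if not (0.0 < p0 < 1.0 and 0.0 < p1 < 1.0):
        raise ValueError("p0 and p1 must lie in (0, 1)")
    if n_gens < 1:
        raise ValueError("n_gens must be >= 1")
    if not (0.0 <= mu < 1.0):
        raise ValueError("mu must lie in [0, 1)")

    def g(F: float) -> float:
        return _forward(F, p0, mu, n_gens) - p1

    lo, hi = bracket
    for _ in range(60):
        if g(lo) <= 0.0:
            break
        lo *= 0.5
    else:
        raise RuntimeError("could not bracket below: p1 unattainably small")
    for _ in range(60):
        if g(hi) >= 0.0:
            break
        hi *= 2.0
    else:
        ceiling = _forward(hi, p0, mu, n_gens)
        raise RuntimeError(
            f"target p1={p1} unattainable: final frequency is capped near "
            f"{ceiling:.6f} by leakage mu={mu} for any fecundity"
        )
    F = brentq(g, lo, hi, xtol=1e-12)
    residual = abs(_forward(F, p0, mu, n_gens) - p1)
    if residual > 1e-8:
        raise RuntimeError(f"fit residual {residual} exceeds tolerance 1e-8")
    if full_result:
        return FitResult(F=float(F), bracket=(lo, hi), residual=float(residual))
    return float(F)


def trajectory_grid(
    p0: float,
    n_gens: int,
    combos: Sequence[SingleStrainParams],
    observed_lower: Optional[float] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trajectories for a set of (F, mu) combinations plus a summary table.

    Returns ``(trajectories, summary)``.  ``trajectories`` is long-format
    with columns combo, F, mu, generation, p.  ``summary`` has one row per
    combo with the final frequency and, when ``observed_lower`` is given, a
    boolean ``sufficient`` flag: final frequency >= the observed estimate's
    lower confidence bound.
    """
    if not combos:
        raise ValueError("combos must be non-empty")
    traj_rows = []
    summary_rows = []
    for i, params in enumerate(combos):
        traj = iterate_single(p0, params, n_gens)
        traj_rows.append(
            pd.DataFrame(
                {
                    "combo": i,
                    "F": params.F,
                    "mu": params.mu,
                    "generation": np.arange(n_gens + 1),
                    "p": traj,
                }
            )
        )
        row: dict = {
            "combo": i,
            "F": params.F,
            "mu": params.mu,
            "p_final": traj[-1],
        }
        if observed_lower is not None:
            row["sufficient"] = bool(traj[-1] >= observed_lower)
        summary_rows.append(row)
    return pd.concat(traj_rows, ignore_index=True), pd.DataFrame(summary_rows)


def required_FR(
    start: PopState,
    params_except_FR: TwoStrainParams,
    threshold: float,
    horizon: int,
    bracket: tuple[float, float] = (0.5, 2.0),
    tol: float = 1e-4,
) -> float:
    """Minimal F_R that drives p_A below ``threshold`` within ``horizon``.

    Bisection on F_R (displacement is monotone in F_R) to absolute
    tolerance ``tol``.  Raises a diagnostic error when displacement is not
    achievable at the upper bracket edge.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")

    def displaced(F_R: float) -> bool:
        traj = iterate(start, params_except_FR.replace_F_R(F_R), horizon)
        return bool(np.any(traj.p_A[1:] < threshold))

    lo, hi = bracket
    if displaced(lo):
        return float(lo)
    if not displaced(hi):
        raise RuntimeError(
            f"displacement below {threshold} within {horizon} generations is "
            f"not achievable for any F_R <= {hi}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if displaced(mid):
            hi = mid
        else:
            lo = mid
    return float(hi)
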