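"""Discrete-generation infection-frequency recursions and their equilibria.

One- and two-strain deterministic recursions for a maternally inherited
endosymbiont under imperfect maternal transmission, relative fecundity
effects, and (optionally) cytoplasmic incompatibility; interior equilibria,
stability classification and rare-invasion conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .params import SingleStrainParams, TwoStrainParams

__all__ = [
    "PopState",
    "Trajectory",
    "EquilibriumResult",
    "step_single_noCI",
    "step_single_CI",
    "equilibrium_single_noCI",
    "equilibria_single_CI",
    "invert_equilibrium_for_F",
    "step_two_strain",
    "iterate",
    "iterate_single",
    "invasion_when_rare",
    "recursion_slope",
]

_SUM_TOL = 1e-9
_BOUNDARY_TOL = 1e-12
Regime = Literal["fisherian", "bistable", "no_invasion"]


def _check_freq(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name}={p!r} must lie in [0, 1]")


@dataclass(frozen=True)
class PopState:
    """Frequencies of the three cytoplasm classes among adults.

    ``p_A``: A-infected (non-CI strain), ``p_R``: R-infected (CI strain),
    ``p_O``: uninfected.  The three must sum to 1; the constructor
    renormalizes exactly after validating to within 1e-9.
    """

    p_A: float
    p_R: float
    p_O: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.p_O is None:
            object.__setattr__(self, "p_O", 1.0 - self.p_A - self.p_R)
        for name in ("p_A", "p_R", "p_O"):
            v = getattr(self, name)
            if not (-_SUM_TOL <= v <= 1.0 + _SUM_TOL):
                raise ValueError(f"{name}={v!r} must lie in [0, 1]")
        total = self.p_A + self.p_R + self.p_O
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"class frequencies sum to {total!r}, not 1")
        # exact renormalization so downstream invariants hold to 1e-12
        object.__setattr__(self, "p_A", max(self.p_A, 0.0) / total)
        object.__setattr__(self, "p_R", max(self.p_R, 0.0) / total)
        object.__setattr__(self, "p_O", max(self.p_O, 0.0) / total)

    def as_array(self) -> np.ndarray:
        return np.array([self.p_A, self.p_R, self.p_O])


@dataclass(frozen=True)
class Trajectory:
    """Sequence of population states indexed by generation 0, 1, ..., n."""

    states: tuple[PopState, ...]

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[tuple[int, PopState]]:
        return iter(enumerate(self.states))

    def __getitem__(self, t: int) -> PopState:
        return self.states[t]

    @property
    def p_A(self) -> np.ndarray:
        return np.array([s.p_A for s in self.states])

    @property
    def p_R(self) -> np.ndarray:
        return np.array([s.p_R for s in self.states])

    @property
    def p_O(self) -> np.ndarray:
        return np.array([s.p_O for s in self.states])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(len(self.states)),
                "p_A": self.p_A,
                "p_R": self.p_R,
                "p_O": self.p_O,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the trajectory as CSV (full double precision)."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def first_below(self, threshold: float, component: str = "p_A") -> Optional[int]:
        """First generation at which the given component drops below threshold."""
        values = getattr(self, component)
        hits = np.nonzero(values < threshold)[0]
        return int(hits[0]) if hits.size else None


@dataclass(frozen=True)
class EquilibriumResult:
    """Equilibria of a single-strain recursion with their regime.

    ``fisherian``: the infection increases from any positive frequency
    (p_u = 0) towards a unique positive stable equilibrium ``p_s``.
    ``bistable``: 0 < p_u < p_s < 1; the infection spreads only above p_u.
    ``no_invasion``: no positive attractor exists.
    """

    regime: Regime
    p_u: Optional[float]
    p_s: Optional[float]

    def __post_init__(self) -> None:
        if self.regime == "fisherian":
            assert self.p_u == 0.0 and self.p_s is not None
        elif self.regime == "bistable":
            assert self.p_u is not None and self.p_s is not None
            assert 0.0 < self.p_u < self.p_s < 1.0
        else:
            assert self.p_s is None


def step_single_noCI(p: float, params: SingleStrainParams) -> float:
    """One generation of the non-CI single-strain recursion.

    p' = F (1 - mu) p / (1 + (F - 1) p): the numerator is the fraction of
    infected ova, the denominator the mean fecundity.
    """
    _check_freq("p", p)
    F, mu = params.F, params.mu
    return F * (1.0 - mu) * p / (1.0 + (F - 1.0) * p)


def step_single_CI(p: float, params: SingleStrainParams) -> float:
    """One generation of the CI single-strain recursion.

    p' = F(1-mu)p / [F(1-mu)p + ((1-p) + F mu p)(1 - s_h p)].  Infected ova
    are compatible with all sperm; uninfected ova (whether from uninfected
    mothers or via leakage from infected mothers) hatch at relative rate
    1 - s_h p when fertilized at random.  With H = 1 this reduces exactly
    to :func:`step_single_noCI`.
    """
    _check_freq("p", p)
    F, mu, s_h = params.F, params.mu, params.s_h
    num = F * (1.0 - mu) * p
    den = num + ((1.0 - p) + F * mu * p) * (1.0 - s_h * p)
    if den <= 0.0:
        raise ValueError("mean fitness is zero: no offspring produced")
    return num / den


def equilibrium_single_noCI(params: SingleStrainParams) -> EquilibriumResult:
    """Equilibria of the non-CI recursion.

    When F(1-mu) > 1 the infection behaves like a favoured haploid type
    under recurrent 'mutation' to the uninfected class, with stable
    equilibrium p_s = 1 - F mu / (F - 1); otherwise it cannot persist.
    """
    F, mu = params.F, params.mu
    if params.growth_when_rare > 1.0:
        p_s = 1.0 - F * mu / (F - 1.0)
        return EquilibriumResult(regime="fisherian", p_u=0.0, p_s=p_s)
    return EquilibriumResult(regime="no_invasion", p_u=None, p_s=None)


def invert_equilibrium_for_F(p_hat: float, mu: float) -> float:
    """Fecundity that sustains a non-CI stable equilibrium at ``p_hat``.

    Exact inversion of the equilibrium expression: F = (1-p̂)/((1-p̂)-mu).
    Raises if ``mu >= 1 - p_hat`` (no finite F gives that equilibrium).
    """
    if not (0.0 < p_hat < 1.0):
        raise ValueError(f"p_hat={p_hat!r} must lie in (0, 1)")
    if not (0.0 <= mu < 1.0 - p_hat):
        raise ValueError(
            f"mu={mu!r} must satisfy 0 <= mu < 1 - p_hat = {1.0 - p_hat!r}"
        )
    return (1.0 - p_hat) / ((1.0 - p_hat) - mu)


def recursion_slope(
    p: float, params: SingleStrainParams, *, h: float = 1e-7
) -> float:
    """Central-difference slope of the single-strain recursion at ``p``.

    Uses the CI step (which subsumes the non-CI step at H = 1).  A fixed
    point with |slope| < 1 is stable, > 1 unstable.
    """
    lo, hi = max(p - h, 0.0), min(p + h, 1.0)
    return (step_single_CI(hi, params) - step_single_CI(lo, params)) / (hi - lo)


def _quadratic_roots(a: float, b: float, c: float) -> list[float]:
    """Real roots of a x^2 + b x + c = 0, numerically stable, ascending."""
    if abs(a) < 1e-14:  # degenerate: linear equation
        if abs(b) < 1e-14:
            return []
        return [-c / b]
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        return []
    sq = math.sqrt(disc)
    # avoid cancellation: compute the larger-magnitude root first
    q = -0.5 * (b + math.copysign(sq, b)) if b != 0.0 else 0.5 * sq
    if q == 0.0:  # b == 0 and disc == 0, or c == 0
        return sorted({0.0, -b / a})
    return sorted({q / a, c / q})


def equilibria_single_CI(params: SingleStrainParams) -> EquilibriumResult:
    """Equilibria and regime of the CI single-strain recursion.

    Interior fixed points are roots in (0, 1) of

        s_h (1 - F mu) p^2 + (F(1-mu) + F mu - 1 - s_h) p + (1 - F(1-mu)) = 0.

    With F(1-mu) > 1 the origin repels and the regime is Fisherian
    (p_u = 0, p_s the positive root, which equals 1 when mu = 0).  With
    F(1-mu) <= 1 two interior roots give bistable dynamics; none gives
    no_invasion.
    """
    F, mu, s_h = params.F, params.mu, params.s_h
    if s_h == 0.0:
        return equilibrium_single_noCI(params)
    a = s_h * (1.0 - F * mu)
    b = F * (1.0 - mu) + F * mu - 1.0 - s_h
    c = 1.0 - F * (1.0 - mu)
    roots = _quadratic_roots(a, b, c)
    interior = [r for r in roots if _BOUNDARY_TOL < r < 1.0 - _BOUNDARY_TOL]

    if params.growth_when_rare > 1.0:
        if interior:
            p_s = max(interior)
        else:
            # mu = 0 (or H = 0): fixation is the stable equilibrium
            candidates = [r for r in roots if abs(r - 1.0) <= 1e-9]
            p_s = 1.0 if (candidates or mu == 0.0) else None
            if p_s is None:
                raise RuntimeError("no stable equilibrium found despite F(1-mu)>1")
        return EquilibriumResult(regime="fisherian", p_u=0.0, p_s=p_s)

    if len(interior) == 2:
        p_u, p_s = interior
        return EquilibriumResult(regime="bistable", p_u=p_u, p_s=p_s)
    return EquilibriumResult(regime="no_invasion", p_u=None, p_s=None)


def step_two_strain(state: PopState, params: TwoStrainParams) -> PopState:
    """One generation of the three-class (uninfected / A / R) recursion.

    Unnormalized next-generation weights, each the product of an ova-share
    term and a hatch term (R-infected ova are compatible with all sperm;
    all other ova hatch at relative rate 1 - s_h p_R):

        w_O = [p_O + F_A mu_A p_A + F_R mu_R p_R] (1 - s_h p_R)
        w_A = [F_A (1 - mu_A) p_A] (1 - s_h p_R)
        w_R = [F_R (1 - mu_R) p_R]
    """
    p_A, p_R, p_O = state.p_A, state.p_R, state.p_O
    hatch = 1.0 - params.s_h * p_R
    w_O = (p_O + params.F_A * params.mu_A * p_A + params.F_R * params.mu_R * p_R) * hatch
    w_A = params.F_A * (1.0 - params.mu_A) * p_A * hatch
    w_R = params.F_R * (1.0 - params.mu_R) * p_R
    W = w_O + w_A + w_R
    if W <= 0.0:
        raise ValueError("mean fitness is zero: no offspring produced")
    return PopState(p_A=w_A / W, p_R=w_R / W, p_O=w_O / W)


def iterate(state0: PopState, params: TwoStrainParams, n_gens: int) -> Trajectory:
    """Iterate the two-strain recursion; returns states at generations 0..n."""
    if n_gens < 0:
        raise ValueError(f"n_gens={n_gens!r} must be >= 0")
    states = [state0]
    s = state0
    for _ in range(int(n_gens)):
        s = step_two_strain(s, params)
        states.append(s)
    return Trajectory(states=tuple(states))


def iterate_single(p0: float, params: SingleStrainParams, n_gens: int) -> np.ndarray:
    """Single-strain frequency trajectory of length n_gens + 1."""
    if n_gens < 0:
        raise ValueError(f"n_gens={n_gens!r} must be >= 0")
    step = step_single_CI if params.s_h > 0.0 else step_single_noCI
    out = np.empty(int(n_gens) + 1)
    out[0] = p0
    p = p0
    for t in range(1, int(n_gens) + 1):
        p = step(p, params)
        out[t] = p
    return out


def invasion_when_rare(
    params: TwoStrainParams,
    invader: Literal["A", "R"],
    resident: Optional[Literal["A", "R"]] = None,
) -> bool:
    """Whether a vanishingly rare invader strain tends to increase.

    Into an uninfected population the condition is F(1-mu) > 1 for either
    strain (CI is inoperative when the CI strain is rare).  For R invading
    a population with A at its equilibrium, the condition reduces to
    F_R (1 - mu_R) > F_A (1 - mu_A).  For A invading R at equilibrium, the
    rare A class suffers CI from the resident males:
    F_A (1 - mu_A) (1 - s_h p_s) > F_R (1 - mu_R).

    All conditions are strict; equality means no increase.
    """
    if invader not in ("A", "R"):
        raise ValueError(f"invader must be 'A' or 'R', got {invader!r}")
    if resident not in (None, "A", "R"):
        raise ValueError(f"resident must be None, 'A' or 'R', got {resident!r}")
    if invader == resident:
        raise ValueError("invader and resident must differ")

    growth_A = params.F_A * (1.0 - params.mu_A)
    growth_R = params.F_R * (1.0 - params.mu_R)

    if resident is None:
        return (growth_A if invader == "A" else growth_R) > 1.0
    if resident == "A":
        if growth_A <= 1.0:
            raise ValueError(
                "resident strain A does not persist: F_A(1-mu_A) <= 1"
            )
        return growth_R > growth_A
    # resident == "R", invader == "A"
    eq = equilibria_single_CI(params.strain_r)
    if eq.p_s is None:
        raise ValueError("resident strain R has no stable equilibrium")
    return growth_A * (1.0 - params.s_h * eq.p_s) > growth_R
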