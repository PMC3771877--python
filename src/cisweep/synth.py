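"""Synthetic survey and isofemale-line data generators.

Surveys are multinomial samples of infection states drawn from
deterministic model trajectories per site; line data are beta-binomially
overdispersed transmission-leakage counts.  All generators take explicit
integer seeds and never touch global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import PopState, step_two_strain
from .field_stats import LineTable, SurveyTable
from .params import TwoStrainParams

__all__ = [
    "SiteDesign",
    "SurveyDesign",
    "LineDesign",
    "generate_survey",
    "generate_lines",
]


@dataclass(frozen=True)
class SiteDesign:
    """One site: when each strain is introduced and at what frequency.

    An introduction at generation g sets the strain's frequency to its
    initial value at the start of that generation, scaling the other
    classes down proportionally.  ``None`` means the strain never arrives.
    """

    name: str
    intro_gen_A: Optional[int] = None
    p0_A: float = 0.0
    intro_gen_R: Optional[int] = None
    p0_R: float = 0.0

    def __post_init__(self) -> None:
        for g in (self.intro_gen_A, self.intro_gen_R):
            if g is not None and g < 0:
                raise ValueError("introduction generations must be >= 0")
        for p in (self.p0_A, self.p0_R):
            if not (0.0 <= p <= 1.0):
                raise ValueError("initial frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class SurveyDesign:
    sites: tuple[SiteDesign, ...]
    years: tuple[float, ...]
    n_per_sample: int
    generations_per_year: float
    params: TwoStrainParams
    start_year: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_per_sample < 1:
            raise ValueError("n_per_sample must be >= 1")
        if self.generations_per_year <= 0:
            raise ValueError("generations_per_year must be positive")
        if list(self.years) != sorted(self.years):
            raise ValueError("sampling years must be sorted")
        if any(y < self.start_year for y in self.years):
            raise ValueError("sampling year precedes generation 0")
        object.__setattr__(self, "sites", tuple(self.sites))
        object.__setattr__(self, "years", tuple(self.years))


def _introduce(state: PopState, strain: str, p0: float) -> PopState:
    """Set one strain to frequency p0, scaling the rest proportionally."""
    rest = 1.0 - (state.p_A if strain == "A" else state.p_R)
    scale = (1.0 - p0) / rest if rest > 0 else 0.0
    if strain == "A":
        return PopState(p_A=p0, p_R=state.p_R * scale, p_O=state.p_O * scale)
    return PopState(p_A=state.p_A * scale, p_R=p0, p_O=state.p_O * scale)


def site_trajectory(
    site: SiteDesign, params: TwoStrainParams, n_gens: int
) -> list[PopState]:
    """Deterministic trajectory for one site honouring its introductions."""
    state = PopState(p_A=0.0, p_R=0.0, p_O=1.0)
    states = []
    for t in range(n_gens + 1):
        if site.intro_gen_A == t:
            state = _introduce(state, "A", site.p0_A)
        if site.intro_gen_R == t:
            state = _introduce(state, "R", site.p0_R)
        states.append(state)
        state = step_two_strain(state, params)
    return states


def generate_survey(design: SurveyDesign) -> SurveyTable:
    """Multinomial infection-state counts at each (site, year).

    Expected sampled frequencies equal the deterministic trajectory values
    at the corresponding generation; reproducible for a fixed seed.
    """
    rng = np.random.default_rng(design.seed)
    gens = [
        int(math.floor((y - design.start_year) * design.generations_per_year + 0.5))
        for y in design.years
    ]
    n_gens = max(gens) if gens else 0
    rows = []
    for site in design.sites:
        traj = site_trajectory(site, design.params, n_gens)
        for year, g in zip(design.years, gens):
            state = traj[g]
            n_A, n_R, n_O = rng.multinomial(
                design.n_per_sample, [state.p_A, state.p_R, state.p_O]
            )
            rows.append(
                {
                    "site": site.name,
                    "year": year,
                    "n_wAu": int(n_A),
                    "n_wRi": int(n_R),
                    "n_uninf": int(n_O),
                }
            )
    return SurveyTable(pd.DataFrame(rows))


@dataclass(frozen=True)
class LineDesign:
    """Isofemale-line assay design.

    ``rho`` is the intra-class correlation of the beta-binomial leakage
    model; rho = 0 collapses to pure binomial sampling with per-line
    leakage exactly ``mu``.  Field heterogeneity is unquantified, so rho is
    a free knob.
    """

    n_lines: int
    progeny_range: tuple[int, int]
    mu: float
    rho: float
    seed: int
    mother_strain: str = "wAu"

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        lo, hi = self.progeny_range
        if not (1 <= lo <= hi):
            raise ValueError("progeny_range must satisfy 1 <= lo <= hi")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must lie in [0, 1]")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")


def generate_lines(design: LineDesign) -> LineTable:
    """Per-line progeny counts with beta-binomial leakage.

    Per-line leakage q_i ~ Beta with mean ``mu`` and intra-class
    correlation ``rho``; uninfected progeny counts are Binomial(n_i, q_i).
    """
    rng = np.random.default_rng(design.seed)
    lo, hi = design.progeny_range
    n_progeny = rng.integers(lo, hi + 1, size=design.n_lines)
    if design.rho == 0.0 or design.mu in (0.0, 1.0):
        q = np.full(design.n_lines, design.mu)
    else:
        a = design.mu * (1.0 - design.rho) / design.rho
        b = (1.0 - design.mu) * (1.0 - design.rho) / design.rho
        q = rng.beta(a, b, size=design.n_lines)
    n_uninfected = rng.binomial(n_progeny, q)
    return LineTable(
        pd.DataFrame(
            {
                "line_id": [f"L{i:03d}" for i in range(design.n_lines)],
                "mother_strain": design.mother_strain,
                "n_progeny": n_progeny.astype(int),
                "n_infected": (n_progeny - n_uninfected).astype(int),
            }
        )
    )
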