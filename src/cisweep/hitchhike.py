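"""Joint dynamics of infection classes and mitochondrial haplotypes.

Because the symbiont and mtDNA are co-inherited maternally, the haplotype
carried by an infected matriline spreads with the infection — including
into the uninfected class via transmission leakage — so an infection that
persists drives 'its' haplotype towards fixation even among uninfected
individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import PopState
from .params import TwoStrainParams

__all__ = [
    "CytoState",
    "HaplotypeSummary",
    "step_cyto",
    "iterate_cyto",
    "cyto_trajectory_frame",
    "haplotype_summary",
]

DEFAULT_HAPLOTYPES = ("A", "R", "anc")
_SUM_TOL = 1e-9


@dataclass(frozen=True)
class CytoState:
    """Infection classes with the uninfected class split by mtDNA haplotype.

    ``u`` holds population frequencies of uninfected individuals by
    haplotype (summing to the uninfected class frequency).  Infected
    classes carry fixed haplotypes: the A strain is associated with
    haplotype 'A', the R strain with 'R'.  The haplotype alphabet is
    extensible but must contain 'A' and 'R'.
    """

    p_A: float
    p_R: float
    u: np.ndarray
    haplotypes: tuple[str, ...] = DEFAULT_HAPLOTYPES

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        if u.shape != (len(self.haplotypes),):
            raise ValueError("u must have one entry per haplotype")
        if "A" not in self.haplotypes or "R" not in self.haplotypes:
            raise ValueError("haplotype alphabet must contain 'A' and 'R'")
        if (u < -_SUM_TOL).any() or self.p_A < -_SUM_TOL or self.p_R < -_SUM_TOL:
            raise ValueError("all components must be >= 0")
        total = self.p_A + self.p_R + u.sum()
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"components sum to {total!r}, not 1")
        u = np.clip(u, 0.0, None) / total
        u.setflags(write=False)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "p_A", max(self.p_A, 0.0) / total)
        object.__setattr__(self, "p_R", max(self.p_R, 0.0) / total)

    @property
    def p_O(self) -> float:
        return float(self.u.sum())

    def index(self, haplotype: str) -> int:
        return self.haplotypes.index(haplotype)

    def marginal(self) -> PopState:
        """Collapse haplotypes to the three-class population state."""
        return PopState(p_A=self.p_A, p_R=self.p_R, p_O=self.p_O)

    @classmethod
    def from_popstate(
        cls,
        state: PopState,
        uninfected_haplotypes: Optional[dict[str, float]] = None,
        haplotypes: tuple[str, ...] = DEFAULT_HAPLOTYPES,
    ) -> "CytoState":
        """Attach a haplotype composition (fractions of the uninfected
        class, default all-ancestral) to a population state."""
        if uninfected_haplotypes is None:
            uninfected_haplotypes = {"anc": 1.0}
        u = np.zeros(len(haplotypes))
        for h, frac in uninfected_haplotypes.items():
            u[haplotypes.index(h)] = frac
        if state.p_O > 0 and abs(u.sum() - 1.0) > _SUM_TOL:
            raise ValueError("uninfected haplotype fractions must sum to 1")
        return cls(p_A=state.p_A, p_R=state.p_R, u=u * state.p_O, haplotypes=haplotypes)


def step_cyto(
    state: CytoState,
    params: TwoStrainParams,
    paternal_leak: float = 0.0,
) -> CytoState:
    """One generation of the joint infection/haplotype recursion.

    Class weights are those of the three-class recursion; the uninfected
    weight is decomposed by mother: uninfected mothers contribute their own
    haplotype, leakage from A-infected mothers contributes haplotype 'A'
    and from R-infected mothers haplotype 'R'.  All uninfected and
    A-infected ova share the hatch factor 1 - s_h p_R.

    ``paternal_leak`` (default 0, the empirically supported value) mixes
    the uninfected-class haplotype composition towards the current
    population haplotype distribution at the given per-generation rate.
    """
    if not (0.0 <= paternal_leak < 1.0):
        raise ValueError("paternal_leak must lie in [0, 1)")
    hatch = 1.0 - params.s_h * state.p_R
    i_A, i_R = state.index("A"), state.index("R")

    w_A = params.F_A * (1.0 - params.mu_A) * state.p_A * hatch
    w_R = params.F_R * (1.0 - params.mu_R) * state.p_R
    w_u = state.u * hatch
    w_u = w_u.copy()
    w_u[i_A] += params.F_A * params.mu_A * state.p_A * hatch
    w_u[i_R] += params.F_R * params.mu_R * state.p_R * hatch
    W = w_A + w_R + w_u.sum()
    if W <= 0.0:
        raise ValueError("mean fitness is zero: no offspring produced")

    if paternal_leak > 0.0 and w_u.sum() > 0.0:
        pop = state.u.copy()
        pop[i_A] += state.p_A
        pop[i_R] += state.p_R
        w_u = (1.0 - paternal_leak) * w_u + paternal_leak * w_u.sum() * pop

    return CytoState(
        p_A=w_A / W, p_R=w_R / W, u=w_u / W, haplotypes=state.haplotypes
    )


def iterate_cyto(
    state0: CytoState,
    params: TwoStrainParams,
    n_gens: int,
    paternal_leak: float = 0.0,
) -> list[CytoState]:
    """States at generations 0..n_gens of the joint recursion."""
    if n_gens < 0:
        raise ValueError("n_gens must be >= 0")
    states = [state0]
    s = state0
    for _ in range(int(n_gens)):
        s = step_cyto(s, params, paternal_leak)
        states.append(s)
    return states


def cyto_trajectory_frame(states: Sequence[CytoState]) -> pd.DataFrame:
    """Long trajectory table: generation, p_A, p_R, u_<haplotype>..."""
    haps = states[0].haplotypes
    data = {
        "generation": np.arange(len(states)),
        "p_A": [s.p_A for s in states],
        "p_R": [s.p_R for s in states],
    }
    for j, h in enumerate(haps):
        data[f"u_{h}"] = [s.u[j] for s in states]
    return pd.DataFrame(data)


@dataclass(frozen=True)
class HaplotypeSummary:
    """Haplotype distributions at the population level and within the
    uninfected class (None when there are no uninfected individuals)."""

    population: dict[str, float]
    within_uninfected: Optional[dict[str, float]]


def haplotype_summary(state: CytoState) -> HaplotypeSummary:
    pop = state.u.copy()
    pop[state.index("A")] += state.p_A
    pop[state.index("R")] += state.p_R
    pop = pop / pop.sum()
    p_O = state.p_O
    within = None
    if p_O > 0.0:
        within = {
            h: float(state.u[j] / p_O) for j, h in enumerate(state.haplotypes)
        }
    return HaplotypeSummary(
        population={h: float(pop[j]) for j, h in enumerate(state.haplotypes)},
        within_uninfected=within,
    )
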