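"""One-dimensional deme-lattice simulator for spatial spread.

Deterministic per-deme dynamics (infinite local populations) coupled by
nearest-neighbour migration with reflecting boundaries, plus optional
stochastic long-distance jump events.  Illustrates the contrast between
bistable waves (which require the local frequency to exceed the unstable
equilibrium, and stall when it exceeds 1/2) and Fisherian waves (which
advance from arbitrarily low local frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .dynamics import PopState
from .params import TwoStrainParams

__all__ = ["Lattice", "step_lattice", "run_lattice", "front_position", "lattice_frame"]


@dataclass(frozen=True)
class Lattice:
    """Row of demes, each holding a (p_A, p_R, p_O) state.

    ``m`` is the migration fraction exchanged with each nearest neighbour
    per generation (reflecting boundaries).  ``jump_rate`` is the expected
    number of long-distance jump events per generation; each event mixes a
    fraction ``jump_mass`` of a uniformly chosen source deme's state into a
    uniformly chosen destination deme.
    """

    states: np.ndarray  # shape (n_demes, 3): columns p_A, p_R, p_O
    m: float
    jump_rate: float = 0.0
    jump_mass: float = 0.1

    def __post_init__(self) -> None:
        arr = np.asarray(self.states, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("states must have shape (n_demes, 3)")
        if (arr < -1e-9).any():
            raise ValueError("deme frequencies must be >= 0")
        sums = arr.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError("every deme state must sum to 1")
        arr = np.clip(arr, 0.0, None) / sums[:, None]
        arr.setflags(write=False)
        object.__setattr__(self, "states", arr)
        if not (0.0 <= self.m <= 0.5):
            raise ValueError(f"m={self.m!r} must lie in [0, 0.5]")
        if self.jump_rate < 0.0:
            raise ValueError("jump_rate must be >= 0")
        if not (0.0 < self.jump_mass <= 1.0):
            raise ValueError("jump_mass must lie in (0, 1]")

    @property
    def n_demes(self) -> int:
        return self.states.shape[0]

    @classmethod
    def uniform(
        cls, n_demes: int, state: PopState, m: float, **kwargs
    ) -> "Lattice":
        arr = np.tile(state.as_array(), (n_demes, 1))
        return cls(states=arr, m=m, **kwargs)

    def with_deme(self, index: int, state: PopState) -> "Lattice":
        arr = self.states.copy()
        arr[index] = state.as_array()
        return replace(self, states=arr)


def _local_step(states: np.ndarray, params: TwoStrainParams) -> np.ndarray:
    """Vectorized two-strain step applied to every deme (same algebra as
    :func:`cisweep.dynamics.step_two_strain`)."""
    p_A, p_R, p_O = states[:, 0], states[:, 1], states[:, 2]
    hatch = 1.0 - params.s_h * p_R
    w_O = (p_O + params.F_A * params.mu_A * p_A + params.F_R * params.mu_R * p_R) * hatch
    w_A = params.F_A * (1.0 - params.mu_A) * p_A * hatch
    w_R = params.F_R * (1.0 - params.mu_R) * p_R
    W = w_O + w_A + w_R
    if (W <= 0.0).any():
        raise ValueError("mean fitness is zero in at least one deme")
    return np.column_stack([w_A / W, w_R / W, w_O / W])


def _migrate(states: np.ndarray, m: float) -> np.ndarray:
    if m == 0.0 or states.shape[0] == 1:
        return states
    padded = np.pad(states, ((1, 1), (0, 0)), mode="edge")  # reflecting
    return (1.0 - 2.0 * m) * states + m * (padded[:-2] + padded[2:])


def step_lattice(
    lat: Lattice,
    params: TwoStrainParams,
    rng: Optional[np.random.Generator] = None,
) -> Lattice:
    """One generation: jumps (if any), migration, then local dynamics."""
    arr = lat.states
    if lat.jump_rate > 0.0:
        if rng is None:
            raise ValueError("jump_rate > 0 requires an rng")
        arr = arr.copy()
        for _ in range(rng.poisson(lat.jump_rate)):
            src, dst = rng.integers(0, lat.n_demes, size=2)
            arr[dst] = (1.0 - lat.jump_mass) * arr[dst] + lat.jump_mass * arr[src]
    arr = _migrate(arr, lat.m)
    arr = _local_step(arr, params)
    return replace(lat, states=arr)


def run_lattice(
    lat: Lattice,
    params: TwoStrainParams,
    n_gens: int,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Snapshots of shape (n_gens + 1, n_demes, 3), generation 0 first."""
    if n_gens < 0:
        raise ValueError("n_gens must be >= 0")
    rng = np.random.default_rng(seed) if seed is not None else None
    if lat.jump_rate > 0.0 and rng is None:
        raise ValueError("jump_rate > 0 requires a seed")
    out = np.empty((n_gens + 1, lat.n_demes, 3))
    out[0] = lat.states
    current = lat
    for t in range(1, n_gens + 1):
        current = step_lattice(current, params, rng)
        out[t] = current.states
    return out


def front_position(
    lat: Lattice | np.ndarray,
    threshold: float,
    interpolate: bool = False,
) -> Optional[float]:
    """Rightmost deme index with p_R >= threshold (None if no deme crosses).

    With ``interpolate=True`` and a descending crossing to the right
    neighbour, the position is linearly interpolated between demes, giving
    a continuous front coordinate suitable for speed estimation.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    states = lat.states if isinstance(lat, Lattice) else np.asarray(lat)
    p_R = states[:, 1]
    above = np.nonzero(p_R >= threshold)[0]
    if above.size == 0:
        return None
    i = int(above[-1])
    if not interpolate:
        return i
    if i == len(p_R) - 1 or p_R[i + 1] >= p_R[i]:
        return float(i)
    return float(i + (p_R[i] - threshold) / (p_R[i] - p_R[i + 1]))


def lattice_frame(snapshots: np.ndarray) -> pd.DataFrame:
    """Long table of lattice snapshots: generation, deme, p_A, p_R, p_O."""
    n_gens1, n_demes, _ = snapshots.shape
    gen = np.repeat(np.arange(n_gens1), n_demes)
    deme = np.tile(np.arange(n_demes), n_gens1)
    flat = snapshots.reshape(-1, 3)
    return pd.DataFrame(
        {
            "generation": gen,
            "deme": deme,
            "p_A": flat[:, 0],
            "p_R": flat[:, 1],
            "p_O": flat[:, 2],
        }
    )
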