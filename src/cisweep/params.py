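"""Parameter containers for the infection-frequency recursions.

Symbols follow the standard cytoplasmic-incompatibility (CI) literature:

* ``F``  -- fecundity of infected females relative to uninfected females.
* ``mu`` -- transmission leakage, the fraction of uninfected ova produced
  by an infected mother (``1 - mu`` is the maternal transmission fidelity).
* ``H``  -- relative hatch rate of incompatible fertilizations; ``H = 1``
  encodes the absence of CI and ``s_h = 1 - H`` is the incompatibility
  strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


def _check_unit(name: str, value: float, *, open_left: bool = False) -> None:
    lo_ok = value > 0 if open_left else value >= 0
    if not (lo_ok and value <= 1):
        interval = "(0, 1]" if open_left else "[0, 1]"
        raise ValueError(f"{name}={value!r} must lie in {interval}")


@dataclass(frozen=True)
class SingleStrainParams:
    """Parameters of a single endosymbiont strain.

    Parameters
    ----------
    F : float
        Relative fecundity of infected females (> 0).
    mu : float
        Fraction of uninfected ova produced by infected mothers, in [0, 1].
    H : float, optional
        Relative hatch rate of incompatible fertilizations, in [0, 1].
        Defaults to 1 (no CI).
    """

    F: float
    mu: float
    H: float = 1.0

    def __post_init__(self) -> None:
        if not self.F > 0:
            raise ValueError(f"F={self.F!r} must be positive")
        _check_unit("mu", self.mu)
        _check_unit("H", self.H)

    @property
    def s_h(self) -> float:
        """Incompatibility strength ``1 - H``."""
        return 1.0 - self.H

    @property
    def growth_when_rare(self) -> float:
        """Per-generation growth factor of a rare infection, ``F (1 - mu)``."""
        return self.F * (1.0 - self.mu)


@dataclass(frozen=True)
class TwoStrainParams:
    """Parameters of the two-strain model.

    Strain A causes no CI; strain R expresses CI (hatch rate ``H``) against
    both uninfected and A-infected ova.  R-infected ova are compatible with
    all sperm.
    """

    F_A: float
    mu_A: float
    F_R: float
    mu_R: float
    H: float

    def __post_init__(self) -> None:
        for name in ("F_A", "F_R"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        _check_unit("mu_A", self.mu_A)
        _check_unit("mu_R", self.mu_R)
        _check_unit("H", self.H)

    @property
    def s_h(self) -> float:
        return 1.0 - self.H

    @property
    def strain_a(self) -> SingleStrainParams:
        """Single-strain view of the non-CI strain."""
        return SingleStrainParams(F=self.F_A, mu=self.mu_A, H=1.0)

    @property
    def strain_r(self) -> SingleStrainParams:
        """Single-strain view of the CI strain."""
        return SingleStrainParams(F=self.F_R, mu=self.mu_R, H=self.H)

    def replace_F_R(self, F_R: float) -> "TwoStrainParams":
        return TwoStrainParams(self.F_A, self.mu_A, F_R, self.mu_R, self.H)


_CONFIG_KEYS = {
    "FA": "F_A", "F_A": "F_A",
    "muA": "mu_A", "mu_A": "mu_A",
    "FR": "F_R", "F_R": "F_R",
    "muR": "mu_R", "mu_R": "mu_R",
    "H": "H",
}


def read_params_config(path: str | Path) -> TwoStrainParams:
    """Read two-strain parameters from a plain ``key = value`` text file.

    Accepted keys: FA/F_A, muA/mu_A, FR/F_R, muR/mu_R, H.  Blank lines and
    lines starting with ``#`` are ignored.
    """
    values: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in _CONFIG_KEYS:
            raise ValueError(f"unknown config key: {key!r}")
        values[_CONFIG_KEYS[key]] = float(val.strip())
    missing = {"F_A", "mu_A", "F_R", "mu_R", "H"} - values.keys()
    if missing:
        raise ValueError(f"config missing keys: {sorted(missing)}")
    return TwoStrainParams(**values)
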