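"""Survey statistics: exact binomial CIs, pooling, G-tests, and
line-structured bootstrap estimation of maternal transmission leakage."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurveyTable",
    "LineTable",
    "GTestResult",
    "TransmissionEstimate",
    "frequency_ci",
    "pooled_frequency",
    "g_test",
    "transmission_estimate",
]

SURVEY_COLUMNS = ["site", "year", "n_wAu", "n_wRi", "n_uninf"]
LINE_COLUMNS = ["line_id", "mother_strain", "n_progeny", "n_infected"]
_STRAIN_COLUMN = {"wAu": "n_wAu", "wRi": "n_wRi", "uninfected": "n_uninf"}


@dataclass(frozen=True)
class SurveyTable:
    """Site-by-date infection counts (columns site, year, n_wAu, n_wRi, n_uninf)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.rename(columns={"n_uninfected": "n_uninf"}).copy()
        missing = set(SURVEY_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"survey table missing columns: {sorted(missing)}")
        counts = df[["n_wAu", "n_wRi", "n_uninf"]]
        if (counts < 0).any().any():
            raise ValueError("survey counts must be >= 0")
        if (counts.sum(axis=1) <= 0).any():
            raise ValueError("every survey row must have a positive total count")
        object.__setattr__(self, "frame", df[SURVEY_COLUMNS].reset_index(drop=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SurveyTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def contingency(self) -> pd.DataFrame:
        """Site x infection-category contingency table (summed over years)."""
        return self.frame.groupby("site")[["n_wAu", "n_wRi", "n_uninf"]].sum()


@dataclass(frozen=True)
class LineTable:
    """Isofemale-line progeny infection counts."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = set(LINE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"line table missing columns: {sorted(missing)}")
        if (df["n_progeny"] < 0).any() or (df["n_infected"] < 0).any():
            raise ValueError("line counts must be >= 0")
        if (df["n_infected"] > df["n_progeny"]).any():
            raise ValueError("n_infected cannot exceed n_progeny")
        object.__setattr__(self, "frame", df[LINE_COLUMNS].reset_index(drop=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "LineTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def frequency_ci(
    x: int, n: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Point estimate and exact (Clopper-Pearson) binomial confidence interval.

    The endpoints are the beta-quantile form of the binomial tail
    equations; lower = 0 iff x = 0 and upper = 1 iff x = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= x <= n):
        raise ValueError(f"x={x!r} must lie in [0, {n}]")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return x / n, lower, upper


def pooled_frequency(
    table: SurveyTable,
    strain: str,
    where: Optional[Callable[[pd.DataFrame], pd.Series]] = None,
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Pooled frequency of one class over (optionally filtered) survey rows.

    Counts are summed across rows before the exact CI is computed.
    ``strain`` is one of 'wAu', 'wRi', 'uninfected'.
    """
    if strain not in _STRAIN_COLUMN:
        raise ValueError(f"strain must be one of {sorted(_STRAIN_COLUMN)}")
    df = table.frame
    if where is not None:
        df = df[where(df)]
    if df.empty:
        raise ValueError("no survey rows selected")
    x = int(df[_STRAIN_COLUMN[strain]].sum())
    n = int(df[["n_wAu", "n_wRi", "n_uninf"]].sum().sum())
    est, lo, hi = frequency_ci(x, n, level)
    return est, (lo, hi)


class GTestResult(NamedTuple):
    G: float
    df: int
    p_value: float


def g_test(counts) -> GTestResult:
    """Log-likelihood-ratio test of independence for a contingency table.

    G = 2 sum O ln(O/E) with expectations from the row/column margins
    (observed zeros contribute 0); df = (r-1)(c-1); p from the chi-square
    tail.  No Williams or Yates correction is applied.  All-zero rows or
    columns are dropped with a warning.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    if (obs < 0).any():
        raise ValueError("counts must be >= 0")
    row_ok = obs.sum(axis=1) > 0
    col_ok = obs.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping all-zero rows/columns from contingency table")
        obs = obs[row_ok][:, col_ok]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table is degenerate after dropping zeros")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    G = float(2.0 * terms.sum())
    G = max(G, 0.0)  # guard against -0.0 / rounding on homogeneous tables
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return GTestResult(G=G, df=df, p_value=float(stats.chi2.sf(G, df)))


@dataclass(frozen=True)
class TransmissionEstimate:
    """Pooled leakage estimate with binomial and line-bootstrap CIs."""

    mu_hat: float
    binomial_ci: tuple[float, float]
    bootstrap_ci: tuple[float, float]
    n_lines: int
    n_progeny: int
    n_uninfected: int
    n_boot: int
    seed: int


def transmission_estimate(
    lines: LineTable,
    n_boot: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> TransmissionEstimate:
    """Maternal transmission leakage from isofemale-line progeny counts.

    The point estimate pools counts across lines (total uninfected progeny
    over total progeny).  The bootstrap resamples *lines* with replacement
    and recomputes the pooled ratio (percentile CI), which widens the
    interval relative to the binomial CI when leakage is heterogeneous
    across mothers.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    df = lines.frame
    if df.empty:
        raise ValueError("line table is empty")
    progeny = df["n_progeny"].to_numpy()
    uninfected = (df["n_progeny"] - df["n_infected"]).to_numpy()
    n_total = int(progeny.sum())
    if n_total <= 0:
        raise ValueError("total progeny count is zero")
    x_total = int(uninfected.sum())
    mu_hat, lo, hi = frequency_ci(x_total, n_total, level)

    rng = np.random.default_rng(seed)
    n_lines = len(df)
    idx = rng.integers(0, n_lines, size=(n_boot, n_lines))
    boot_ratio = uninfected[idx].sum(axis=1) / progeny[idx].sum(axis=1)
    alpha = 1.0 - level
    b_lo, b_hi = np.quantile(boot_ratio, [alpha / 2.0, 1.0 - alpha / 2.0])
    return TransmissionEstimate(
        mu_hat=mu_hat,
        binomial_ci=(lo, hi),
        bootstrap_ci=(float(b_lo), float(b_hi)),
        n_lines=n_lines,
        n_progeny=n_total,
        n_uninfected=x_total,
        n_boot=n_boot,
        seed=seed,
    )
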