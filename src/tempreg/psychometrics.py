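"""Psychometric aggregation and Spearman-Karber PSS/JND estimation.

The Spearman-Karber method treats the discrete derivative of the response
proportions as a probability mass function over the stimulus axis and reads
the PSS and JND off its first two moments — no assumption about the shape
of the psychometric function.  The level series is padded with a lower
bound at proportion 0 and an upper bound at proportion 1 (±250 ms by
default) so the mass normalizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.isotonic import IsotonicRegression


@dataclass(frozen=True)
class PsychometricData:
    """Per-level 2AFC counts: ``p_i = n_positive_i / n_trials_i``."""

    levels: tuple[float, ...]
    n_trials: tuple[int, ...]
    n_positive: tuple[int, ...]

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        nt = np.asarray(self.n_trials)
        npos = np.asarray(self.n_positive)
        if not (len(lv) == len(nt) == len(npos)):
            raise ValueError("levels, n_trials, n_positive must align")
        if len(lv) < 2:
            raise ValueError("need at least two levels")
        if not np.all(np.diff(lv) > 0):
            raise ValueError("levels must be strictly increasing")
        if np.any(nt < 1) or np.any(npos < 0) or np.any(npos > nt):
            raise ValueError("need 0 <= n_positive <= n_trials, n_trials >= 1")

    @property
    def proportions(self) -> np.ndarray:
        return np.asarray(self.n_positive) / np.asarray(self.n_trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level_ms": self.levels,
                "n_trials": self.n_trials,
                "n_positive": self.n_positive,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PsychometricData":
        f = frame.sort_values("level_ms")
        return cls(
            tuple(f["level_ms"].astype(float)),
            tuple(f["n_trials"].astype(int)),
            tuple(f["n_positive"].astype(int)),
        )


@dataclass(frozen=True)
class SKEstimate:
    """PSS and JND from the Spearman-Karber moments."""

    pss: float
    jnd: float
    used_lower_bound: float
    used_upper_bound: float
    monotonized: bool


def aggregate(
    responses: pd.DataFrame, level_field: str, positive_label: str
) -> PsychometricData:
    """Collapse a response table into per-level positive-response counts."""
    if len(responses) == 0:
        raise ValueError("response table is empty")
    if level_field not in responses.columns:
        raise KeyError(f"unknown level field {level_field!r}")
    grouped = responses.groupby(level_field, sort=True)["response"]
    counts = grouped.agg(
        n_trials="size", n_positive=lambda s: int((s == positive_label).sum())
    )
    return PsychometricData(
        tuple(float(x) for x in counts.index),
        tuple(int(x) for x in counts["n_trials"]),
        tuple(int(x) for x in counts["n_positive"]),
    )


def sk_estimate(
    data: PsychometricData,
    lower_bound: float = -250.0,
    upper_bound: float = 250.0,
) -> SKEstimate:
    """Spearman-Karber first and second moments of the response differential.

    Midpoints ``s_i`` of consecutive padded levels carry mass
    ``dp_i = p_{i+1} - p_i``;  PSS = Σ s_i dp_i / Σ dp_i and
    JND = sqrt(Σ dp_i (s_i − PSS)² / Σ dp_i), i.e. one standard deviation —
    the offset from the PSS that yields the .16/.84 proportions for a
    Gaussian-shaped curve.  Non-monotone proportions are first monotonized
    by pooled adjacent violators (weighted by trial counts) and the
    ``monotonized`` flag is set.
    """
    levels = np.asarray(data.levels, dtype=float)
    if not (lower_bound < levels[0] and levels[-1] < upper_bound):
        raise ValueError("bounds must strictly bracket the levels")
    p = data.proportions
    monotonized = bool(np.any(np.diff(p) < 0))
    if monotonized:
        iso = IsotonicRegression(y_min=0.0, y_max=1.0)
        p = iso.fit_transform(levels, p, sample_weight=data.n_trials)

    soa = np.concatenate([[lower_bound], levels, [upper_bound]])
    pp = np.concatenate([[0.0], p, [1.0]])
    s = (soa[1:] + soa[:-1]) / 2.0
    dp = np.diff(pp)
    total = dp.sum()  # 1 after padding; kept explicit
    pss = float(np.sum(s * dp) / total)
    jnd = float(np.sqrt(np.sum(dp * (s - pss) ** 2) / total))
    return SKEstimate(pss, jnd, lower_bound, upper_bound, monotonized)


def probit_bounded(
    p: float | np.ndarray, lower: float = 0.01, upper: float = 0.99
) -> float | np.ndarray:
    """Inverse-normal transform of a proportion clipped into [lower, upper]."""
    if lower >= upper:
        raise ValueError("lower bound must be below upper bound")
    z = norm.ppf(np.clip(p, lower, upper))
    return float(z) if np.isscalar(p) else z
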