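"""Two-noisy-criteria model of regularity judgments.

An observer reports 'regular' when the sensed anisochrony of the final
tone falls between an early (negative) and a late (positive) criterion,
each drawn per trial from its own Gaussian.  The resulting psychometric
curve is a difference of two cumulative Gaussians,

    P(regular | x) = Phi((x - c_early)/sigma_early)
                   - Phi((x - c_late)/sigma_late),

with four parameters: the two criterion locations and the two slope
(sd) parameters.  Fitting is binomial maximum likelihood with multi-start
Nelder-Mead under box constraints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .psychometrics import PsychometricData

# box constraints for the optimizer
_CRIT_BOUND = 500.0
_SIGMA_LO, _SIGMA_HI = 1.0, 500.0
_P_CLIP = 1e-6  # probability floor guarding the log-likelihood


@dataclass(frozen=True)
class TwoCriteriaFit:
    """Fitted criteria and slopes of the regularity-judgment model.

    ``sigma_early``/``sigma_late`` are the sds of the two cumulative
    Gaussians; the density at each criterion, 1/(sigma * sqrt(2*pi)),
    is available as ``slope_at_early``/``slope_at_late`` for conventions
    that report the slope at threshold instead.
    """

    c_early: float
    c_late: float
    sigma_early: float
    sigma_late: float
    neg_log_likelihood: float
    converged: bool
    n_starts_used: int = 0
    diagnostic: str = ""

    @property
    def slope_at_early(self) -> float:
        return 1.0 / (self.sigma_early * np.sqrt(2.0 * np.pi))

    @property
    def slope_at_late(self) -> float:
        return 1.0 / (self.sigma_late * np.sqrt(2.0 * np.pi))


def predict_p_regular(
    x: float | np.ndarray, fit: TwoCriteriaFit
) -> float | np.ndarray:
    """Probability of a 'regular' response at anisochrony ``x`` (ms)."""
    p = norm.cdf(
        (np.asarray(x, dtype=float) - fit.c_early) / fit.sigma_early
    ) - norm.cdf((np.asarray(x, dtype=float) - fit.c_late) / fit.sigma_late)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(x) else p


def _nll(theta: np.ndarray, x: np.ndarray, n: np.ndarray, k: np.ndarray):
    c_e, c_l, s_e, s_l = theta
    if c_e >= c_l:
        return np.inf
    p = norm.cdf((x - c_e) / s_e) - norm.cdf((x - c_l) / s_l)
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))


def _moment_starts(
    levels: np.ndarray, p: np.ndarray, n_starts: int, rng: np.random.Generator
) -> np.ndarray:
    """Moment-based start, then jittered copies.

    The half-crossings of p on each side of its peak give rough criterion
    locations; spread between the crossing and the nearest extreme level
    seeds the sigmas.
    """
    i_peak = int(np.argmax(p))
    span = levels[-1] - levels[0]

    def crossing(side: str) -> float:
        if side == "early":
            seg_lv, seg_p = levels[: i_peak + 1], p[: i_peak + 1]
        else:
            seg_lv, seg_p = levels[i_peak:][::-1], p[i_peak:][::-1]
        half = p[i_peak] / 2.0
        below = np.nonzero(seg_p < half)[0]
        if len(below) == 0:
            return seg_lv[0]
        return seg_lv[below[-1]]

    c_e0 = min(crossing("early"), -1.0)
    c_l0 = max(crossing("late"), 1.0)
    if c_e0 >= c_l0:
        c_e0, c_l0 = -span / 4.0, span / 4.0
    s0 = max(span / 10.0, _SIGMA_LO)
    base = np.array([c_e0, c_l0, s0, s0])

    starts = [base]
    for _ in range(n_starts - 1):
        jit = base + rng.normal(0.0, [span / 8, span / 8, s0 / 2, s0 / 2])
        jit[2:] = np.clip(jit[2:], _SIGMA_LO, _SIGMA_HI)
        jit[:2] = np.clip(jit[:2], -_CRIT_BOUND, _CRIT_BOUND)
        if jit[0] >= jit[1]:
            jit[[0, 1]] = jit[[1, 0]] + [-1.0, 1.0]
        starts.append(jit)
    return np.array(starts)


def fit_two_criteria(
    data: PsychometricData, n_starts: int = 20, seed: int = 0
) -> TwoCriteriaFit:
    """Binomial MLE of the four-parameter two-criteria model.

    Degenerate data (all responses 'regular' or all 'irregular') cannot
    identify the criteria and returns ``converged=False`` with a
    diagnostic.  Requires at least 4 levels (four free parameters).
    """
    levels = np.asarray(data.levels, dtype=float)
    n = np.asarray(data.n_trials, dtype=float)
    k = np.asarray(data.n_positive, dtype=float)
    if len(levels) < 4:
        raise ValueError("need at least 4 levels to fit 4 parameters")
    p = k / n
    if np.all(k == n) or np.all(k == 0):
        return TwoCriteriaFit(
            c_early=np.nan, c_late=np.nan,
            sigma_early=np.nan, sigma_late=np.nan,
            neg_log_likelihood=np.nan, converged=False,
            diagnostic="degenerate: responses identical at every level",
        )

    rng = np.random.default_rng(seed)
    bounds = [
        (-_CRIT_BOUND, _CRIT_BOUND),
        (-_CRIT_BOUND, _CRIT_BOUND),
        (_SIGMA_LO, _SIGMA_HI),
        (_SIGMA_LO, _SIGMA_HI),
    ]
    best = None
    best_ok = False
    for theta0 in _moment_starts(levels, p, n_starts, rng):
        res = minimize(
            _nll, theta0, args=(levels, n, k), method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": 4000, "xatol": 1e-4, "fatol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best, best_ok = res, bool(res.success)
    c_e, c_l, s_e, s_l = best.x
    return TwoCriteriaFit(
        c_early=float(c_e), c_late=float(c_l),
        sigma_early=float(s_e), sigma_late=float(s_l),
        neg_log_likelihood=float(best.fun), converged=best_ok,
        n_starts_used=n_starts,
    )


def simulate_from_model(
    fit: TwoCriteriaFit,
    levels: list[float] | np.ndarray,
    n_per_level: int,
    seed: int,
) -> PsychometricData:
    """Binomial draws from the model's psychometric curve at given levels."""
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    levels = np.sort(np.asarray(levels, dtype=float))
    rng = np.random.default_rng(seed)
    p = predict_p_regular(levels, fit)
    k = rng.binomial(n_per_level, p)
    return PsychometricData(
        tuple(levels), tuple([n_per_level] * len(levels)), tuple(int(x) for x in k)
    )


def fits_to_frame(fits: dict[str, TwoCriteriaFit]) -> pd.DataFrame:
    """Tabulate per-observer fits in the CSV interchange layout."""
    rows = [
        {
            "observer_id": obs,
            "c_early_ms": f.c_early,
            "c_late_ms": f.c_late,
            "sigma_early_ms": f.sigma_early,
            "sigma_late_ms": f.sigma_late,
            "slope_at_early": f.slope_at_early,
            "slope_at_late": f.slope_at_late,
            "nll": f.neg_log_likelihood,
            "converged": f.converged,
        }
        for obs, f in fits.items()
    ]
    return pd.DataFrame(rows)
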