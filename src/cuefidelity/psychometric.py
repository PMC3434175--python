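"""Weibull psychometric functions for forced-choice up/down categorisation.

A two-alternative forced-choice observer guesses at chance (p = 0.5) when the
signal is invisible and approaches perfect performance (p = 1.0) for large
signals.  The probability of a correct response at absolute signal level ``x``
is modelled with a Weibull function

    p(x) = A + (B - A) * (1 - exp(-(x / x0) ** m))

with the asymptotes fixed at ``A = 0.5`` (chance) and ``B = 1.0``.  ``x0`` is
the scale parameter (the level at which p ~ 0.816) and ``m`` the slope.  The
*threshold* reported throughout the package is the level at which the fitted
curve crosses 81% correct.

Fitting is by maximum likelihood under independent Bernoulli trials, with a
coarse grid initialisation followed by derivative-free (Nelder-Mead) local
refinement in log-parameters; the procedure is deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import DegenerateFitError, DomainError, InsufficientDataError

logger = logging.getLogger(__name__)

CHANCE = 0.5
CEILING = 1.0
#: probability-correct criterion at which thresholds are reported
THRESHOLD_CRITERION = 0.81

CONDITIONS = ("audio", "motion", "both")
RESPONSES = ("up", "down", "none")


@dataclass(frozen=True)
class TrialRecord:
    """One forced-choice trial.

    ``level`` is the signed control-input magnitude Xc (collective inches;
    negative means down).  ``correct`` is derived: the response sign matches
    the signal sign.  Trials with ``response == "none"`` are excluded from all
    fits.
    """

    subject_id: str
    condition: str
    level: float
    response: str

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise DomainError(f"unknown condition {self.condition!r}")
        if self.response not in RESPONSES:
            raise DomainError(f"unknown response {self.response!r}")
        if not math.isfinite(self.level):
            raise DomainError("level must be finite")

    @property
    def correct(self) -> bool:
        if self.response == "none":
            return False
        sign = 1.0 if self.response == "up" else -1.0
        return sign * self.level > 0


@dataclass
class PsychometricFit:
    """Maximum-likelihood Weibull fit to one subject-condition data set."""

    x0: float
    m: float
    A: float = CHANCE
    B: float = CEILING
    threshold81: float = float("nan")
    n_trials_per_level: Mapping[float, int] = field(default_factory=dict)
    loglik: float = float("nan")
    subject_id: str | None = None
    condition: str | None = None

    def predict(self, x) -> np.ndarray | float:
        """Probability correct at absolute level(s) ``x``."""
        return weibull_p(x, self.x0, self.m, self.A, self.B)


def weibull_p(x, x0: float, m: float, A: float = CHANCE, B: float = CEILING):
    """Weibull probability-correct at absolute level ``x``.

    Monotone non-decreasing in ``x``; equals ``A`` at x = 0 and tends to ``B``
    as x grows.  Accepts scalars or arrays.
    """
    if not np.isfinite(x0) or x0 <= 0:
        raise DomainError(f"x0 must be finite and > 0, got {x0}")
    if not np.isfinite(m) or m <= 0:
        raise DomainError(f"m must be finite and > 0, got {m}")
    if not (np.isfinite(A) and np.isfinite(B)) or not (0 <= A < B <= 1):
        raise DomainError(f"asymptotes must satisfy 0 <= A < B <= 1, got A={A}, B={B}")
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x < 0):
        raise DomainError("x must be finite and >= 0")
    p = A + (B - A) * (1.0 - np.exp(-((x / x0) ** m)))
    return p if p.ndim else float(p)


def threshold_at(fit: PsychometricFit, p_target: float = THRESHOLD_CRITERION) -> float:
    """Level at which the fitted curve crosses ``p_target``.

    Closed form: ``x = x0 * (-ln((B - p) / (B - A))) ** (1/m)``.
    """
    A, B = fit.A, fit.B
    if not (A < p_target < B):
        raise DomainError(
            f"p_target must lie strictly between the asymptotes ({A}, {B}), got {p_target}"
        )
    return fit.x0 * (-math.log((B - p_target) / (B - A))) ** (1.0 / fit.m)


def _as_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    rows = [
        (t.subject_id, t.condition, t.level, t.response) for t in trials
    ]
    return pd.DataFrame(rows, columns=["subject_id", "condition", "level", "response"])


def aggregate_counts(trials, pool_updown: bool = True) -> pd.DataFrame:
    """Collapse a trial table to (level, n, n_correct) counts.

    "none" responses are discounted.  With ``pool_updown`` the up and down
    directions are merged onto absolute levels.
    """
    df = _as_frame(trials)
    valid = df[df["response"] != "none"].copy()
    if len(valid) < len(df):
        logger.info("excluded %d no-response trials", len(df) - len(valid))
    if valid.empty:
        raise InsufficientDataError("no valid (responded) trials")
    sign = np.where(valid["response"] == "up", 1.0, -1.0)
    valid["correct"] = sign * valid["level"].to_numpy() > 0
    if pool_updown:
        valid["x"] = valid["level"].abs()
    else:
        signs = np.sign(valid["level"].to_numpy())
        if len(set(signs[signs != 0])) > 1:
            raise DomainError(
                "pool_updown=False requires single-direction data; got mixed signs"
            )
        valid["x"] = valid["level"].abs()
    counts = (
        valid.groupby("x", sort=True)["correct"]
        .agg(n="size", n_correct="sum")
        .reset_index()
    )
    zero_rows = counts["n"] == 0
    if zero_rows.any():  # pragma: no cover - groupby('size') cannot emit 0
        logger.warning("dropping levels with zero valid trials")
        counts = counts[~zero_rows]
    return counts


def _nll(logx0, logm, x, n, c, A, B):
    """Vectorised negative log-likelihood on a grid of log-parameters."""
    # overflow (huge parameters from wandering simplex steps) maps to the
    # asymptotes and is neutralised by the clip below
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        x0 = np.exp(np.asarray(logx0, dtype=float))[..., None]
        m = np.exp(np.asarray(logm, dtype=float))[..., None]
        p = A + (B - A) * (1.0 - np.exp(-((x / x0) ** m)))
    p = np.clip(np.nan_to_num(p, nan=1.0), 1e-12, 1 - 1e-12)
    return -(c * np.log(p) + (n - c) * np.log1p(-p)).sum(axis=-1)


def fit_psychometric(
    trials,
    pool_updown: bool = True,
    A: float = CHANCE,
    B: float = CEILING,
    subject_id: str | None = None,
    condition: str | None = None,
) -> PsychometricFit:
    """Maximum-likelihood Weibull fit to forced-choice trials.

    Parameters
    ----------
    trials
        DataFrame with columns ``subject_id, condition, level, response`` or an
        iterable of :class:`TrialRecord`, all from one subject and condition.
    pool_updown
        Merge equivalent up and down levels onto ``|level|`` before fitting
        (the default, used once direction effects have been ruled out).

    Raises
    ------
    InsufficientDataError
        Fewer than two distinct absolute levels with valid trials.
    DegenerateFitError
        All-correct or all-incorrect data, or chance-only data where the
        likelihood is maximised only as x0 -> infinity (no finite threshold).
    """
    counts = aggregate_counts(trials, pool_updown=pool_updown)
    if len(counts) < 2:
        raise InsufficientDataError(
            f"need >= 2 distinct absolute levels, got {len(counts)}"
        )
    x = counts["x"].to_numpy(float)
    n = counts["n"].to_numpy(float)
    c = counts["n_correct"].to_numpy(float)
    summary = counts.to_dict("records")
    if np.all(c == n):
        raise DegenerateFitError(
            "all trials correct at every level: likelihood unbounded (x0 -> 0)",
            summary=summary,
        )
    if np.all(c == 0):
        raise DegenerateFitError(
            "all trials incorrect at every level: below-chance data cannot be fitted",
            summary=summary,
        )

    # Coarse grid over (log x0, log m), then Nelder-Mead from the best points.
    lo, hi = x.min(), x.max()
    logx0_grid = np.log(np.geomspace(lo / 20.0, hi * 200.0, 49))
    logm_grid = np.log(np.geomspace(0.2, 16.0, 33))
    LX, LM = np.meshgrid(logx0_grid, logm_grid, indexing="ij")
    grid_nll = _nll(LX.ravel(), LM.ravel(), x, n, c, A, B)
    order = np.argsort(grid_nll)

    def objective(theta):
        return _nll(theta[0], theta[1], x, n, c, A, B)

    best = None
    for idx in order[:3]:
        start = np.array([LX.ravel()[idx], LM.ravel()[idx]])
        res = minimize(
            objective, start, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    x0_hat, m_hat = float(np.exp(best.x[0])), float(np.exp(best.x[1]))

    # Chance-only data drives x0 towards the upper search bound: no finite
    # threshold exists within any reasonable extrapolation of the level range.
    if x0_hat > 100.0 * hi:
        raise DegenerateFitError(
            "fitted scale escaped to infinity (performance at chance everywhere)",
            summary=summary,
        )

    fit = PsychometricFit(
        x0=x0_hat,
        m=m_hat,
        A=A,
        B=B,
        n_trials_per_level={float(k): int(v) for k, v in zip(x, n)},
        loglik=-float(best.fun),
        subject_id=subject_id,
        condition=condition,
    )
    fit.threshold81 = threshold_at(fit, THRESHOLD_CRITERION)
    return fit
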