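"""Quick pooling analysis of unimodal and bimodal detection thresholds.

When two redundant cues (here: turbine audio and platform motion) are
presented together, the combined threshold T relates to the single-cue
thresholds T_i through a Minkowski pooling rule

    sum_i (T / T_i) ** k = 1

with pooling exponent k.  In normalised "threshold units" u = T_am / T_a and
v = T_am / T_m each observer becomes a point, and every observer with the same
pooling rule sits on the unit contour u**k + v**k = 1.  The exponent
diagnoses the integration regime:

* k = 1   — linear (early) summation of the signals,
* k = 2   — optimal reliability-weighted (Euclidean) integration,
* k ~ 4   — probability summation over independent channel decisions,
* k -> oo — independent channels; the joint threshold equals the better
  single-cue threshold and no facilitation is observed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .errors import DomainError, NoFacilitationError

K_MIN = 0.1
K_MAX = 64.0
#: exponents above this are reported as the independent-channels regime
K_INDEPENDENCE = 8.0


class Regime(str, Enum):
    linear = "linear"                      # k ~ 1
    optimal = "optimal"                    # k ~ 2
    probability_summation = "probability_summation"  # k ~ 4
    independence = "independence"          # k > K_INDEPENDENCE


@dataclass(frozen=True)
class ThresholdTriple:
    """Audio, motion and bimodal 81%-correct thresholds for one subject."""

    subject_id: str
    T_a: float
    T_m: float
    T_am: float

    def __post_init__(self):
        for name in ("T_a", "T_m", "T_am"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise DomainError(f"{name} must be finite and > 0, got {v}")


@dataclass
class PoolingFit:
    """Fitted Minkowski exponent with residuals and regime classification."""

    k: float
    residuals: np.ndarray
    regime: Regime
    objective: float
    points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


def classify_regime(k: float) -> Regime:
    if k > K_INDEPENDENCE or math.isinf(k):
        return Regime.independence
    centres = {1.0: Regime.linear, 2.0: Regime.optimal, 4.0: Regime.probability_summation}
    return centres[min(centres, key=lambda c: abs(k - c))]


def normalize_thresholds(triple: ThresholdTriple) -> tuple[float, float]:
    """Bimodal threshold in threshold units of each cue: (T_am/T_a, T_am/T_m)."""
    return triple.T_am / triple.T_a, triple.T_am / triple.T_m


def predict_combined_threshold(unimodal, k: float) -> float:
    """Combined threshold T solving sum_i (T/T_i)**k = 1.

    Closed form T = (sum T_i**-k) ** (-1/k); always below min(T_i) for two or
    more cues and approaches min(T_i) as k -> infinity.
    """
    T = np.asarray(unimodal, dtype=float)
    if T.size == 0:
        raise DomainError("need at least one unimodal threshold")
    if np.any(~np.isfinite(T)) or np.any(T <= 0):
        raise DomainError("unimodal thresholds must be finite and > 0")
    if not math.isfinite(k) or k <= 0:
        raise DomainError(f"k must be finite and > 0, got {k}")
    # factor out min(T) for numerical stability at large k
    tmin = T.min()
    return float(tmin * np.sum((tmin / T) ** k) ** (-1.0 / k))


def k_from_triple(triple: ThresholdTriple, lenient: bool = False) -> float:
    """Pooling exponent of a single subject, by root finding.

    Solves (T_am/T_a)**k + (T_am/T_m)**k = 1; the left side is strictly
    decreasing in k when both ratios are < 1, so the root is unique.

    With no facilitation (T_am >= min unimodal threshold) the exponent is
    undefined; strict mode raises :class:`NoFacilitationError`, lenient mode
    returns ``inf`` (independent-channels sentinel).
    """
    u, v = normalize_thresholds(triple)
    if u >= 1.0 or v >= 1.0:
        if lenient:
            return float("inf")
        raise NoFacilitationError(
            f"subject {triple.subject_id}: T_am={triple.T_am} is not below both "
            f"unimodal thresholds (T_a={triple.T_a}, T_m={triple.T_m})"
        )

    def g(k):
        return u ** k + v ** k - 1.0

    if g(K_MIN) < 0:
        raise DomainError("facilitation too strong: implied k below search range")
    if g(K_MAX) > 0:
        # ratios so close to 1 that k exceeds the search ceiling
        if lenient:
            return float("inf")
        raise NoFacilitationError(
            f"subject {triple.subject_id}: implied k exceeds {K_MAX} (near-independence)"
        )
    return float(brentq(g, K_MIN, K_MAX, xtol=1e-12, rtol=1e-14))


def fit_pooling_k_group(points, strict: bool = True) -> PoolingFit:
    """Group Minkowski exponent from normalised (u, v) points.

    Minimises the sum of squared radial residuals
    ``((u**k + v**k)**(1/k) - 1)**2`` over k in [0.1, 64].  For a single point
    with facilitation this reduces to the exact :func:`k_from_triple` solution.

    In strict mode any subject with both coordinates >= 1 (no facilitation at
    all) is an error; lenient mode keeps such points and lets them pull k up.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0 or pts.shape[1] != 2:
        raise DomainError("points must be a non-empty collection of (u, v) pairs")
    if np.any(~np.isfinite(pts)) or np.any(pts <= 0):
        raise DomainError("normalised coordinates must be finite and > 0")
    bad = np.where((pts[:, 0] >= 1.0) & (pts[:, 1] >= 1.0))[0]
    if strict and bad.size:
        raise NoFacilitationError(
            f"no facilitation for point(s) at index {bad.tolist()}: "
            "both normalised coordinates >= 1"
        )
    u, v = pts[:, 0], pts[:, 1]

    def radial_residuals(k):
        # (u^k + v^k)^(1/k) via log-sum-exp for stability at large k
        a = np.maximum(u, v)
        r = a * (1.0 + (np.minimum(u, v) / a) ** k) ** (1.0 / k)
        return r - 1.0

    def objective(logk):
        return float(np.sum(radial_residuals(np.exp(logk)) ** 2))

    grid = np.log(np.geomspace(K_MIN, K_MAX, 256))
    vals = [objective(lk) for lk in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    k_hat = float(np.exp(res.x))
    resid = radial_residuals(k_hat)
    return PoolingFit(
        k=k_hat,
        residuals=resid,
        regime=classify_regime(k_hat),
        objective=float(np.sum(resid ** 2)),
        points=pts,
    )


def plot_pooling_fit(fit: PoolingFit, ax=None):
    """Diagnostic plot: normalised thresholds with the fitted unit contour."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    u = np.linspace(1e-3, 1.0, 400)
    v = (1.0 - u ** fit.k) ** (1.0 / fit.k)
    ax.plot(u, v, "k--", label=f"k = {fit.k:.2f}")
    ax.plot([0, 1], [1, 0], "k-", lw=0.8, label="k = 1 (linear)")
    ax.plot(fit.points[:, 0], fit.points[:, 1], "o")
    ax.set_xlabel("bimodal threshold / audio threshold")
    ax.set_ylabel("bimodal threshold / motion threshold")
    ax.set_xlim(0, 1.2)
    ax.set_ylim(0, 1.2)
    ax.legend(frameon=False)
    return ax
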