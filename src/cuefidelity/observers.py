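"""Mechanistic observer models generating synthetic forced-choice sessions.

The up/down categorisation task has no deposited human data, so cohorts of
simulated observers stand in.  Each mechanism is chosen to *provably* realise
one of the canonical cue-integration regimes, so that the psychometric and
pooling machinery can be validated end to end:

``single_channel``
    One cue only: internal value s = x + eps, eps ~ N(0, sigma^2); respond
    sign(s).  Percent correct is the Gaussian CDF Phi(|x|/sigma).
``optimal_gaussian``
    Unimodal conditions as above; in the bimodal condition the two noisy
    estimates are combined by inverse-variance (reliability) weighting before
    a single sign decision.  Combined noise obeys
    1/sigma_c^2 = 1/sigma_a^2 + 1/sigma_m^2, hence Euclidean threshold
    combination and pooling exponent k = 2.
``linear_late_noise``
    The two channel signals are summed with fixed gains g_i = 1/sigma_i into
    one decision variable carrying a single late noise source (sigma = 1).
    Sensitivities add linearly, giving k = 1.
``probability_summation``
    Each channel independently "detects" with Weibull probability
    1 - exp(-(|x|/T_i)**m_channel) and, when it detects, reports the true
    sign; if no channel detects the observer guesses.  The OR rule over
    Weibull channels with exponent m yields pooling exponent k = m exactly.

All sessions are deterministic given the observer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DomainError, SpecMismatchError

KINDS = ("single_channel", "linear_late_noise", "optimal_gaussian", "probability_summation")

#: default signed level set of the categorisation task (collective inches)
DEFAULT_LEVELS = tuple(
    s * x for x in (0.1, 0.2, 0.3, 0.4, 0.5) for s in (+1, -1)
)

# Channel noise defaults calibrated so unimodal 81% thresholds land near the
# 0.2-0.3 range typical of untrained observers in this task
# (threshold ~ 0.878 * sigma for a Gaussian channel).
DEFAULT_SIGMA_A = 0.31
DEFAULT_SIGMA_M = 0.24


@dataclass(frozen=True)
class ObserverSpec:
    """Parameters of one simulated observer."""

    kind: str = "optimal_gaussian"
    sigma_a: float = DEFAULT_SIGMA_A
    sigma_m: float = DEFAULT_SIGMA_M
    #: channel Weibull slope, probability_summation only
    m_channel: float = 4.0
    seed: int = 0
    subject_id: str = "S1"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise DomainError(f"unknown observer kind {self.kind!r}")
        if not (self.sigma_a > 0 and self.sigma_m > 0):
            raise DomainError("sigma_a and sigma_m must be > 0")
        if not self.m_channel > 0:
            raise DomainError("m_channel must be > 0")


@dataclass(frozen=True)
class SessionDesign:
    """Level x condition x repetition layout of a session.

    Levels are nonzero in real session designs; level 0 is accepted for
    chance-floor calibration runs (a nominal direction is then drawn at
    random so that correctness remains defined and is 50% in the long run).
    """

    levels: Sequence[float] = DEFAULT_LEVELS
    trials_per_level: int = 100
    conditions: Sequence[str] = ("audio", "motion", "both")

    def __post_init__(self):
        if self.trials_per_level < 1:
            raise DomainError("trials_per_level must be >= 1")
        if not all(np.isfinite(self.levels)):
            raise DomainError("levels must be finite")
        bad = set(self.conditions) - {"audio", "motion", "both"}
        if bad:
            raise DomainError(f"unknown conditions {sorted(bad)}")


def _channel_sigma(spec: ObserverSpec, condition: str) -> float:
    return spec.sigma_a if condition == "audio" else spec.sigma_m


def _decision_signs(spec: ObserverSpec, condition: str, x: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Signed responses (+1 up / -1 down) for an array of signed levels."""
    n = x.size
    if spec.kind == "single_channel":
        if condition == "both":
            raise SpecMismatchError(
                "single_channel observer cannot run the bimodal condition"
            )
        s = x + rng.normal(0.0, _channel_sigma(spec, condition), n)
        return np.where(s >= 0, 1.0, -1.0)

    if spec.kind == "optimal_gaussian":
        if condition != "both":
            s = x + rng.normal(0.0, _channel_sigma(spec, condition), n)
        else:
            sa = x + rng.normal(0.0, spec.sigma_a, n)
            sm = x + rng.normal(0.0, spec.sigma_m, n)
            wa, wm = spec.sigma_a ** -2, spec.sigma_m ** -2
            s = (wa * sa + wm * sm) / (wa + wm)
        return np.where(s >= 0, 1.0, -1.0)

    if spec.kind == "linear_late_noise":
        ga, gm = 1.0 / spec.sigma_a, 1.0 / spec.sigma_m
        gain = {"audio": ga, "motion": gm, "both": ga + gm}[condition]
        s = gain * x + rng.normal(0.0, 1.0, n)
        return np.where(s >= 0, 1.0, -1.0)

    # probability_summation
    guesses = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    true_sign = np.sign(x)
    detect = np.zeros(n, dtype=bool)
    for ch, T in (("audio", spec.sigma_a), ("motion", spec.sigma_m)):
        if condition in (ch, "both"):
            p_det = 1.0 - np.exp(-((np.abs(x) / T) ** spec.m_channel))
            detect |= rng.random(n) < p_det
    # a detecting channel reports the stimulus sign (audio-wins tie-break is
    # moot: every detecting channel reports the same, true, sign)
    return np.where(detect & (true_sign != 0), true_sign, guesses)


def analytic_p_correct(spec: ObserverSpec, condition: str, level: float) -> float:
    """Closed-form long-run proportion correct at a signed level."""
    x = abs(level)
    if x == 0:
        return 0.5
    if spec.kind in ("single_channel", "optimal_gaussian"):
        if condition == "both":
            if spec.kind == "single_channel":
                raise SpecMismatchError("single_channel has no bimodal condition")
            sigma = (spec.sigma_a ** -2 + spec.sigma_m ** -2) ** -0.5
        else:
            sigma = _channel_sigma(spec, condition)
        return float(norm.cdf(x / sigma))
    if spec.kind == "linear_late_noise":
        ga, gm = 1.0 / spec.sigma_a, 1.0 / spec.sigma_m
        gain = {"audio": ga, "motion": gm, "both": ga + gm}[condition]
        return float(norm.cdf(gain * x))
    # probability_summation: OR of Weibull channels, guess otherwise
    q = 1.0
    for ch, T in (("audio", spec.sigma_a), ("motion", spec.sigma_m)):
        if condition in (ch, "both"):
            q *= np.exp(-((x / T) ** spec.m_channel))
    return float(1.0 - 0.5 * q)


def simulate_session(spec: ObserverSpec, design: SessionDesign) -> pd.DataFrame:
    """Simulate one full session; one row per (condition, level, repetition).

    Returns a trial table with columns ``subject_id, condition, level,
    response, correct``.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for condition in design.conditions:
        for level in design.levels:
            x = np.full(design.trials_per_level, float(level))
            signs = _decision_signs(spec, condition, x, rng)
            if level == 0:
                nominal = np.where(rng.random(x.size) < 0.5, 1.0, -1.0)
            else:
                nominal = np.sign(x)
            frames.append(pd.DataFrame({
                "subject_id": spec.subject_id,
                "condition": condition,
                "level": x,
                "response": np.where(signs > 0, "up", "down"),
                "correct": signs == nominal,
            }))
    return pd.concat(frames, ignore_index=True)


def make_cohort(
    n_subjects: int,
    base: ObserverSpec | None = None,
    heterogeneity: float = 0.15,
    seed: int = 0,
) -> list[ObserverSpec]:
    """Cohort of observers with log-normal between-subject noise scaling.

    Per-subject channel sigmas are ``base_sigma * exp(N(0, heterogeneity^2))``;
    with ``heterogeneity=0`` every spec equals the base.  Deterministic given
    ``seed``.
    """
    if n_subjects < 1:
        raise DomainError("n_subjects must be >= 1")
    if heterogeneity < 0:
        raise DomainError("heterogeneity must be >= 0")
    base = base or ObserverSpec()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        fa, fm = np.exp(rng.normal(0.0, heterogeneity, 2))
        cohort.append(replace(
            base,
            sigma_a=base.sigma_a * fa,
            sigma_m=base.sigma_m * fm,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
            subject_id=f"S{i + 1}",
        ))
    return cohort
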