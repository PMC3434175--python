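"""Performance metrics and statistics for factorial tracking and transfer studies.

The tracking score is the median absolute height error (ft) between target and
flown trajectories.  Cue contributions are assessed in a within-subject
2x2x...x2 factorial design: per-factor *main effects* (mean error at each
level, averaged over all other cells) and a repeated-measures ANOVA with
subjects as a random factor, where each two-level factor is tested with

    F = MS_factor / MS_(factor x subject),   df = (1, n_subjects - 1).

Transfer-of-training analyses use paired t-tests on matched pre/post
conditions and a learning-inclusion filter: a straight line is fitted to the
mean tracking error over the four training phases, and a participant is
included only if the fitted improvement from the first to the last phase is
at least 0.15 ft.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateFitError,
    DomainError,
    IncompleteDesignError,
    SeriesAlignmentError,
)

#: experiment-2 factor labels: error beep, turbine, motion platform, difficulty
DEFAULT_FACTORS = ("e", "t", "m", "d")


@dataclass(frozen=True)
class LearningFilterConfig:
    """Inclusion rule for training cohorts."""

    min_improvement: float = 0.15  # ft, over the four training phases
    n_phases: int = 4


@dataclass
class LearningFilterResult:
    included: bool
    slope: float        # ft per phase
    improvement: float  # predicted(T1) - predicted(Tlast), ft


def median_abs_error(target, flown) -> float:
    """Median over time of |target - flown| (ft); robust to outlier excursions."""
    target = np.asarray(target, dtype=float)
    flown = np.asarray(flown, dtype=float)
    if target.shape != flown.shape:
        raise SeriesAlignmentError(
            f"series lengths differ: {target.shape} vs {flown.shape}"
        )
    if target.size == 0:
        raise DomainError("empty series")
    return float(np.median(np.abs(target - flown)))


def _check_complete(runs: pd.DataFrame, factors: Sequence[str],
                    subject: str) -> None:
    cells = list(product((0, 1), repeat=len(factors)))
    missing = []
    for sid, g in runs.groupby(subject):
        have = set(map(tuple, g[list(factors)].to_numpy(int)))
        missing.extend((sid, cell) for cell in cells if cell not in have)
    if missing:
        raise IncompleteDesignError(
            f"incomplete factorial design; {len(missing)} missing "
            f"(subject, cell) combination(s): {missing[:8]}...",
            missing=missing,
        )


def _subject_level_means(runs: pd.DataFrame, factor: str,
                         factors: Sequence[str], subject: str,
                         response: str) -> pd.DataFrame:
    """Per-subject mean response at each level of one factor (subjects x 2)."""
    table = runs.groupby([subject, factor])[response].mean().unstack(factor)
    if table.isna().any().any() or set(table.columns) != {0, 1}:
        raise IncompleteDesignError(f"factor {factor!r} missing a level for some subject")
    return table


def main_effects(
    runs: pd.DataFrame,
    factors: Sequence[str] = DEFAULT_FACTORS,
    response: str = "median_abs_error",
    subject: str = "subject_id",
) -> pd.DataFrame:
    """Per-factor main effects of a complete within-subject 2^k design.

    For each factor: the mean response at level 0 and level 1 (averaged over
    all other cells, per subject, then across subjects) and the difference
    level0 - level1 (positive when switching the cue *on* reduces the error,
    under the on=1 coding).
    """
    _check_complete(runs, factors, subject)
    rows = []
    for factor in factors:
        table = _subject_level_means(runs, factor, factors, subject, response)
        m0, m1 = table[0].mean(), table[1].mean()
        rows.append({"factor": factor, "mean_level0": m0, "mean_level1": m1,
                     "difference": m0 - m1})
    return pd.DataFrame(rows).set_index("factor")


def rm_anova(
    runs: pd.DataFrame,
    factors: Sequence[str] = DEFAULT_FACTORS,
    response: str = "median_abs_error",
    subject: str = "subject_id",
) -> pd.DataFrame:
    """Repeated-measures ANOVA main effects with subjects as a random factor.

    Each two-level factor is tested on subject-by-level cell means:
    F = MS_factor / MS_(factor x subject) with df (1, n_subjects - 1).
    Requires a complete balanced design (no imputation).
    """
    _check_complete(runs, factors, subject)
    counts = runs.groupby([subject] + list(factors)).size()
    if counts.nunique() != 1:
        raise IncompleteDesignError(
            "unbalanced design: unequal replicate counts across cells"
        )
    n_subj = runs[subject].nunique()
    if n_subj < 2:
        raise DomainError("need >= 2 subjects for a random-subjects ANOVA")
    rows = []
    for factor in factors:
        Y = _subject_level_means(runs, factor, factors, subject, response).to_numpy()
        grand = Y.mean()
        level_means = Y.mean(axis=0)
        subj_means = Y.mean(axis=1)
        ss_factor = n_subj * float(np.sum((level_means - grand) ** 2))
        resid = Y - subj_means[:, None] - level_means[None, :] + grand
        ss_inter = float(np.sum(resid ** 2))
        df1, df2 = 1, n_subj - 1
        ms_factor = ss_factor / df1
        ms_inter = ss_inter / df2
        if ms_inter > 0:
            F = ms_factor / ms_inter
            p = float(stats.f.sf(F, df1, df2))
        elif ms_factor == 0:
            # factor perfectly inert and no subject-by-factor variation
            F, p = 0.0, 1.0
        else:
            F, p = np.inf, 0.0
        rows.append({"factor": factor, "F": F, "df1": df1, "df2": df2, "p": p})
    return pd.DataFrame(rows).set_index("factor")


def paired_compare(a, b, alternative: str = "two-sided"):
    """Paired t-test between matched per-subject scores.

    Returns ``(t, df, p)``.  ``alternative`` follows scipy's convention
    ("two-sided", "less", "greater", relative to a - b).  Identical inputs
    return (0.0, n-1, 1.0) by convention; a nonzero constant difference has
    zero variance and raises :class:`DegenerateFitError`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise SeriesAlignmentError("paired scores must be equal-length 1-D arrays")
    if a.size < 2:
        raise DomainError("need at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, a.size - 1, 1.0
        raise DegenerateFitError(
            "zero variance of nonzero paired differences: t undefined"
        )
    res = stats.ttest_rel(a, b, alternative=alternative)
    return float(res.statistic), int(res.df), float(res.pvalue)


def holm_correct(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in reports)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def learning_filter(
    training_errors: Sequence[float],
    cfg: LearningFilterConfig = LearningFilterConfig(),
) -> LearningFilterResult:
    """Apply the training-improvement inclusion rule.

    Fits a least-squares line to the mean tracking error over the training
    phases T1..Tn; the improvement is the fitted drop from the first to the
    last phase, and the participant is included iff it reaches
    ``cfg.min_improvement`` (default 0.15 ft).
    """
    y = np.asarray(training_errors, dtype=float)
    if y.size != cfg.n_phases:
        raise DomainError(f"expected {cfg.n_phases} phase errors, got {y.size}")
    if np.any(~np.isfinite(y)):
        raise DomainError("training errors must be finite")
    phases = np.arange(1, cfg.n_phases + 1, dtype=float)
    slope, _ = np.polyfit(phases, y, 1)
    improvement = -slope * (cfg.n_phases - 1)
    return LearningFilterResult(
        included=bool(improvement >= cfg.min_improvement),
        slope=float(slope),
        improvement=float(improvement),
    )
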