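"""Configuration and end-to-end experiment composition.

:class:`PipelineConfig` collects every tunable constant of the pipeline with
defaults matching the simulated apparatus (Z0 = 4.8, Zw in {-0.1, -0.5},
levels +-0.1..0.5, the 81% threshold criterion, 0.04 g/Xc motion calibration,
80 ms kinematic delay, 3 dB audio excursion, 0.15 ft learning-inclusion
rule).  Unknown config keys are rejected.

:func:`run_experiment1_replica` chains the detection-experiment analysis:
simulate a cohort of observers, fit per-subject Weibull thresholds for the
audio, motion and bimodal conditions, normalise, and fit the group pooling
exponent.  :func:`make_fixtures` emits small canonical datasets for tests and
examples.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cfio
from .errors import DomainError, InsufficientDataError
from .heave import CueChannelParams, HeaveParams, TargetPathSpec
from .observers import ObserverSpec, SessionDesign, make_cohort, simulate_session
from .pooling import PoolingFit, ThresholdTriple, fit_pooling_k_group, normalize_thresholds
from .psychometric import THRESHOLD_CRITERION, PsychometricFit, fit_psychometric

logger = logging.getLogger(__name__)

DEFAULT_ABS_LEVELS = (0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class ObserversConfig:
    kind: str = "optimal_gaussian"
    n_subjects: int = 10
    sigma_a: float = 0.31
    sigma_m: float = 0.24
    m_channel: float = 4.0
    heterogeneity: float = 0.15
    trials_per_level: int = 500
    abs_levels: tuple[float, ...] = DEFAULT_ABS_LEVELS


@dataclass(frozen=True)
class AnalysisConfig:
    criterion: float = THRESHOLD_CRITERION
    pool_updown: bool = True
    strict_facilitation: bool = True
    min_improvement: float = 0.15


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    observers: ObserversConfig = field(default_factory=ObserversConfig)
    heave: HeaveParams = field(default_factory=HeaveParams)
    cues: CueChannelParams = field(default_factory=CueChannelParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def _from_dict(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise DomainError(f"unknown config key(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        if isinstance(value, dict):
            sub = {
                "observers": ObserversConfig, "heave": HeaveParams,
                "cues": CueChannelParams, "analysis": AnalysisConfig,
            }.get(name)
            if sub is None:
                raise DomainError(f"config key {name!r} does not take a mapping")
            value = _from_dict(sub, value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; every key optional, unknown keys rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise DomainError("config file must contain a mapping")
    cfg = _from_dict(PipelineConfig, data)
    logger.info("resolved config: %s", cfg)
    return cfg


@dataclass
class Experiment1Report:
    """Per-subject threshold fits and the group pooling fit."""

    fits: dict            # subject_id -> {condition -> PsychometricFit}
    triples: list[ThresholdTriple]
    pooling: PoolingFit

    def summary(self) -> str:
        lines = ["subject   T_audio  T_motion  T_both"]
        for tr in self.triples:
            lines.append(f"{tr.subject_id:<9} {tr.T_a:7.3f}  {tr.T_m:7.3f} {tr.T_am:7.3f}")
        lines.append(f"group pooling exponent k = {self.pooling.k:.2f} "
                     f"({self.pooling.regime.value} regime)")
        return "\n".join(lines)


def signed_levels(abs_levels) -> tuple[float, ...]:
    return tuple(s * x for x in abs_levels for s in (+1, -1))


def run_experiment1_replica(config: PipelineConfig | None = None) -> Experiment1Report:
    """Simulate the detection experiment and run its full analysis chain.

    Deterministic given ``config.seed``.  Raises the underlying stage error
    (e.g. :class:`InsufficientDataError` for a zero-trial design).
    """
    config = config or PipelineConfig()
    obs_cfg = config.observers
    if obs_cfg.trials_per_level < 1:
        raise InsufficientDataError("trials_per_level must be >= 1")
    base = ObserverSpec(kind=obs_cfg.kind, sigma_a=obs_cfg.sigma_a,
                        sigma_m=obs_cfg.sigma_m, m_channel=obs_cfg.m_channel)
    cohort = make_cohort(obs_cfg.n_subjects, base,
                         heterogeneity=obs_cfg.heterogeneity, seed=config.seed)
    design = SessionDesign(levels=signed_levels(obs_cfg.abs_levels),
                           trials_per_level=obs_cfg.trials_per_level)
    fits: dict[str, dict[str, PsychometricFit]] = {}
    triples = []
    for spec in cohort:
        trials = simulate_session(spec, design)
        per_cond = {}
        for condition in design.conditions:
            sub = trials[trials["condition"] == condition]
            per_cond[condition] = fit_psychometric(
                sub, pool_updown=config.analysis.pool_updown,
                subject_id=spec.subject_id, condition=condition,
            )
        fits[spec.subject_id] = per_cond
        triples.append(ThresholdTriple(
            subject_id=spec.subject_id,
            T_a=per_cond["audio"].threshold81,
            T_m=per_cond["motion"].threshold81,
            T_am=per_cond["both"].threshold81,
        ))
    points = [normalize_thresholds(tr) for tr in triples]
    pooling = fit_pooling_k_group(points, strict=config.analysis.strict_facilitation)
    return Experiment1Report(fits=fits, triples=triples, pooling=pooling)


def make_fixtures(outdir, seed: int = 0) -> dict[str, Path]:
    """Emit a small canonical dataset bundle; byte-stable given ``seed``.

    Contents: one modest session per observer kind, a threshold table fitted
    from an optimal-observer cohort (unimodal magnitudes land near 0.27/0.21
    by the channel-noise calibration), and a sampled target path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    rng = np.random.default_rng(seed)

    design = SessionDesign(trials_per_level=50)
    uni_design = SessionDesign(trials_per_level=50, conditions=("audio", "motion"))
    for kind in ("single_channel", "linear_late_noise", "optimal_gaussian",
                 "probability_summation"):
        spec = ObserverSpec(kind=kind, seed=int(rng.integers(0, 2 ** 31 - 1)),
                            subject_id=f"{kind}_S1")
        d = uni_design if kind == "single_channel" else design
        p = outdir / f"session_{kind}.csv"
        cfio.write_trials(simulate_session(spec, d), p)
        paths[f"session_{kind}"] = p

    cfg = PipelineConfig(
        seed=seed,
        observers=ObserversConfig(n_subjects=4, trials_per_level=300,
                                  heterogeneity=0.1),
    )
    report = run_experiment1_replica(cfg)
    p = outdir / "thresholds.csv"
    cfio.write_thresholds(report.triples, p)
    paths["thresholds"] = p

    from .heave import target_path
    path = target_path(TargetPathSpec(duration=60.0, dt=0.1, seed=seed))
    p = outdir / "target_path.csv"
    with open(p, "w") as fh:
        fh.write(cfio.FORMAT_COMMENT + "\n")
        fh.write("t,height\n")
        for ti, hi in zip(path.t, path.height):
            fh.write(f"{ti:.3f},{hi:.6g}\n")
    paths["target_path"] = p
    return paths
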