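"""Synthetic trial generator for the previewed six-click task.

Emulates the statistical structure the downstream analysis assumes: each
subject completes 60 trials (every withheld-target condition ten times in
seeded random order, or full previews in the all-targets-shown mode), the
first six trials are practice, response times are the generating model's
level times plus Gaussian trial noise, and a small fraction of times are
replaced by long outliers that the 3-s filter is meant to remove.

Subjects are heterogeneous: each subject's level times, noise, and preview
behaviour are drawn from configurable population distributions. One global
seed drives an independent substream per subject, so adding subjects never
reshuffles earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Sequence

import numpy as np

from .models import ModelName, build_model, predicted_times

__all__ = [
    "Mode",
    "FieldDist",
    "SubjectDistribution",
    "SubjectParams",
    "ExperimentConfig",
    "TrialRecord",
    "sample_subject",
    "simulate_experiment",
]

#: response times are floored here (seconds); a click cannot take zero time
MIN_TIME = 0.05

_MAX_RESAMPLE = 1000


class Mode(str, Enum):
    """Trial regime: one target withheld from the preview, or none."""

    WITHHELD_ONE = "withheld_one"
    FULL_PREVIEW = "full_preview"


@dataclass(frozen=True)
class FieldDist:
    """Normal population distribution for one subject-level parameter."""

    loc: float
    scale: float = 0.0

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.normal(self.loc, self.scale)) if self.scale > 0 else self.loc


@dataclass(frozen=True)
class SubjectDistribution:
    """Population distributions for every :class:`SubjectParams` field.

    Defaults echo the group means of the withheld-target experiments:
    fully prepared responses near 0.67 s, partly prepared near 0.79 s,
    unprepared near 1.23 s, previews a few seconds long and shorter when
    target 1 is withheld.
    """

    level_time_1: FieldDist = FieldDist(0.67, 0.08)
    level_time_2: FieldDist = FieldDist(0.79, 0.08)
    level_time_3: FieldDist = FieldDist(1.23, 0.12)
    noise_sd: FieldDist = FieldDist(0.15, 0.03)
    outlier_prob: FieldDist = FieldDist(0.005, 0.0)
    outlier_low: FieldDist = FieldDist(3.5, 0.0)
    outlier_high: FieldDist = FieldDist(10.0, 0.0)
    preview_base: FieldDist = FieldDist(3.1, 1.0)
    preview_first_missing_delta: FieldDist = FieldDist(0.5, 0.15)
    preview_sd: FieldDist = FieldDist(0.8, 0.0)


@dataclass(frozen=True)
class SubjectParams:
    """One subject's generative parameters.

    ``level_times`` are the times (s) for preparation levels 1..3, weakly
    ascending; ``noise_sd`` is the trial-to-trial Gaussian noise on each
    response time; with probability ``outlier_prob`` a response time is
    replaced by a uniform draw from ``outlier_range`` (whose low end sits
    above the 3-s analysis cutoff, so the filter removes exactly the
    injected contamination).
    """

    level_times: tuple[float, float, float]
    noise_sd: float
    outlier_prob: float
    outlier_range: tuple[float, float]
    preview_base: float
    preview_first_missing_delta: float
    preview_sd: float

    def __post_init__(self) -> None:
        t = self.level_times
        if not (0 < t[0] <= t[1] <= t[2]):
            raise ValueError("level_times must be positive and ascending")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.outlier_prob <= 1:
            raise ValueError("outlier_prob must be a probability")
        lo, hi = self.outlier_range
        if not (3.0 < lo <= hi):
            raise ValueError("outlier_range low end must exceed the 3-s cutoff")
        if self.preview_base <= 0 or self.preview_sd < 0:
            raise ValueError("preview parameters must be positive")


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of one simulated experiment.

    In WITHHELD_ONE mode ``n_trials`` must equal ``6 * reps_per_condition``
    (the default 60-trial design: each condition ten times in random
    order). ``generating_model`` selects whose level matrix produces the
    response times; it is ignored in FULL_PREVIEW mode, where every
    response is fully prepared (level 1) and no target is withheld.
    """

    n_subjects: int
    seed: int
    mode: Mode = Mode.WITHHELD_ONE
    generating_model: ModelName = ModelName.FAST_PRECRASTINATION
    n_trials: int = 60
    reps_per_condition: int = 10
    n_practice: int = 6
    subject_param_distribution: SubjectDistribution = field(
        default_factory=SubjectDistribution
    )
    subject_prefix: str = "S"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode(self.mode))
        object.__setattr__(self, "generating_model", ModelName(self.generating_model))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.mode is Mode.WITHHELD_ONE and self.n_trials != 6 * self.reps_per_condition:
            raise ValueError("WITHHELD_ONE design requires n_trials = 6 * reps_per_condition")
        if not 0 <= self.n_practice < self.n_trials:
            raise ValueError("n_practice must be fewer than n_trials")


@dataclass(frozen=True)
class TrialRecord:
    """One trial: who, when, which condition, and the seven times.

    ``missing_target`` is 1..6 in WITHHELD_ONE mode and ``None`` in
    FULL_PREVIEW mode. ``response_times`` are T1..T6 in seconds; entries
    may be NaN after filtering (an excluded observation), never in freshly
    simulated data.
    """

    subject_id: str
    trial_index: int  # 1-based
    missing_target: int | None
    preview_time: float
    response_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.response_times) != 6:
            raise ValueError("exactly six response times required")
        if self.missing_target is not None and not 1 <= self.missing_target <= 6:
            raise ValueError("missing_target must be 1..6 or None")


def _draw_positive(dist: FieldDist, rng: np.random.Generator, minimum: float) -> float:
    """Draw until >= minimum; a point mass below the minimum is impossible."""
    for _ in range(_MAX_RESAMPLE):
        v = dist.draw(rng)
        if v >= minimum:
            return v
        if dist.scale == 0:
            break
    raise ValueError(
        f"distribution {dist} cannot produce a value >= {minimum}"
    )


def sample_subject(dist: SubjectDistribution, rng: np.random.Generator) -> SubjectParams:
    """Draw one subject's parameters; level times are sorted after the draw
    so the ascending invariant holds for any population spread."""
    raw = [
        _draw_positive(dist.level_time_1, rng, MIN_TIME),
        _draw_positive(dist.level_time_2, rng, MIN_TIME),
        _draw_positive(dist.level_time_3, rng, MIN_TIME),
    ]
    t1, t2, t3 = sorted(raw)
    noise_sd = _draw_positive(dist.noise_sd, rng, 0.0)
    p_out = min(max(dist.outlier_prob.draw(rng), 0.0), 1.0)
    lo = _draw_positive(dist.outlier_low, rng, 3.0 + 1e-9)
    hi = _draw_positive(dist.outlier_high, rng, lo)
    # a subject's mean preview below half a second is not realistic for a
    # six-item display; truncate the population draw there
    base = _draw_positive(dist.preview_base, rng, 0.5)
    delta = dist.preview_first_missing_delta.draw(rng)
    psd = max(dist.preview_sd.draw(rng), 0.0)
    return SubjectParams(
        level_times=(t1, t2, t3),
        noise_sd=noise_sd,
        outlier_prob=p_out,
        outlier_range=(lo, hi),
        preview_base=base,
        preview_first_missing_delta=delta,
        preview_sd=psd,
    )


def _subject_rngs(seed: int, n: int) -> list[np.random.Generator]:
    # SeedSequence children are stable under extension: child i does not
    # depend on how many siblings are spawned.
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def simulate_experiment(config: ExperimentConfig) -> list[TrialRecord]:
    """Simulate every trial of the configured experiment.

    Deterministic given the config (including seed). Practice trials are
    generated exactly like main trials; only preprocessing treats them
    specially.
    """
    records: list[TrialRecord] = []
    model = build_model(config.generating_model)
    for si, rng in enumerate(_subject_rngs(config.seed, config.n_subjects)):
        subject_id = f"{config.subject_prefix}{si + 1:03d}"
        params = sample_subject(config.subject_param_distribution, rng)
        pred = predicted_times(model, params.level_times)  # 6x6
        if config.mode is Mode.WITHHELD_ONE:
            conditions = np.repeat(np.arange(1, 7), config.reps_per_condition)
            conditions = rng.permutation(conditions)
        else:
            conditions = np.zeros(config.n_trials, dtype=int)  # 0 = no target withheld

        t1 = params.level_times[0]
        for ti, m in enumerate(conditions, start=1):
            if m > 0:
                base_times = pred[m - 1]
            else:
                base_times = np.full(6, t1)
            times = base_times + rng.normal(0.0, params.noise_sd, size=6)
            times = np.maximum(times, MIN_TIME)
            out_mask = rng.random(6) < params.outlier_prob
            if out_mask.any():
                lo, hi = params.outlier_range
                times[out_mask] = rng.uniform(lo, hi, size=int(out_mask.sum()))
            mean_preview = params.preview_base - (
                params.preview_first_missing_delta if m == 1 else 0.0
            )
            preview = max(rng.normal(mean_preview, params.preview_sd), MIN_TIME)
            records.append(
                TrialRecord(
                    subject_id=subject_id,
                    trial_index=ti,
                    missing_target=int(m) if m > 0 else None,
                    preview_time=preview,
                    response_times=tuple(float(x) for x in times),
                )
            )
    return records


def config_to_dict(config: ExperimentConfig) -> dict:
    """JSON-ready dict form of a config (enums as strings)."""
    d = asdict(config)
    d["mode"] = config.mode.value
    d["generating_model"] = config.generating_model.value
    return d


def config_from_dict(d: dict) -> ExperimentConfig:
    """Inverse of :func:`config_to_dict`; unknown keys are rejected."""
    d = dict(d)
    dist = d.pop("subject_param_distribution", None)
    known = set(ExperimentConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if dist is not None:
        fields = set(SubjectDistribution.__dataclass_fields__)
        extra = set(dist) - fields
        if extra:
            raise ValueError(f"unknown subject distribution keys: {sorted(extra)}")
        dist = SubjectDistribution(
            **{k: FieldDist(**v) if isinstance(v, dict) else v for k, v in dist.items()}
        )
        d["subject_param_distribution"] = dist
    return ExperimentConfig(**d)
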