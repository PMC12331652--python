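"""Cycle segmentation, grid thinning, standardization and input patterns.

The refinement network consumes fixed-length sequences: every gait cycle is
thinned to a 20-sample grid, z-scored with training-fold statistics, and
arranged into one of three experimental input patterns:

* ``One-Quarter`` — one muscle, one quarter of the cycle (5 samples),
* ``One-Entire``  — one muscle, the entire cycle (20 samples),
* ``All-Entire``  — every muscle, the entire cycle.

The single-muscle patterns pair with temporal attention, the all-muscle
pattern with spatial (channel) attention.  Evaluation uses
leave-one-subject-out cross-validation: each fold holds out all cycles of
one subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .cycles import ActivationCycle, PairedCycle

__all__ = [
    "InputPattern",
    "ModelSample",
    "Normalization",
    "segment_cycles",
    "resample_to_grid",
    "standardize",
    "build_pattern",
    "loso_splits",
]

logger = logging.getLogger(__name__)

PATTERN_NAMES = ("One-Quarter", "One-Entire", "All-Entire")
QUARTER_LEN = 5


@dataclass(frozen=True)
class InputPattern:
    """One of the three experimental input configurations.

    ``attention_kind`` is fixed by the pattern: temporal attention for the
    single-muscle patterns, spatial attention for the all-muscle pattern.
    ``quarter_index`` selects which quarter (0..3) One-Quarter uses; the
    first quarter is the default.
    """

    name: str
    target_muscle: str
    quarter_index: int = 0

    def __post_init__(self) -> None:
        if self.name not in PATTERN_NAMES:
            raise ValueError(f"pattern name must be one of {PATTERN_NAMES}, got {self.name!r}")
        if not 0 <= self.quarter_index <= 3:
            raise ValueError("quarter_index must be in 0..3")

    @property
    def attention_kind(self) -> str:
        return "spatial" if self.name == "All-Entire" else "temporal"

    def steps(self, grid: int = 20) -> int:
        return grid // 4 if self.name == "One-Quarter" else grid


@dataclass
class ModelSample:
    """One network training/evaluation unit.

    ``input_sequence`` is ``(steps, input_channels)`` of simulated
    activation; ``target_sequence`` is ``(steps, 1)`` of the target
    muscle's measured activation.  ``cycle_fractions`` locates each step
    within the gait cycle (0 = heel strike, 1 = next heel strike).
    """

    input_sequence: np.ndarray
    target_sequence: np.ndarray
    identity: tuple[str, int, int]
    input_labels: list[str] = field(default_factory=list)
    target_label: str = ""
    cycle_fractions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.input_sequence = np.atleast_2d(np.asarray(self.input_sequence, float))
        self.target_sequence = np.asarray(self.target_sequence, float).reshape(-1, 1)
        if self.input_sequence.shape[0] != self.target_sequence.shape[0]:
            raise ValueError("input and target step counts differ")

    @property
    def subject_id(self) -> str:
        return self.identity[0]


def segment_cycles(
    series: ActivationCycle, event_times: Sequence[float]
) -> list[ActivationCycle]:
    """Cut a continuous recording at gait events (e.g. heel strikes).

    Samples with time in ``[event_i, event_{i+1})`` form cycle ``i``
    (half-open: a sample lying exactly on an event starts the later
    cycle).  Samples outside the first/last event are discarded.
    """
    events = np.asarray(event_times, float)
    if events.size < 2:
        raise ValueError("need at least 2 event times to form a cycle")
    if not np.all(np.diff(events) > 0):
        raise ValueError("event_times must be strictly increasing")
    t = series.sample_times
    cycles = []
    for i in range(events.size - 1):
        mask = (t >= events[i]) & (t < events[i + 1])
        cycles.append(
            ActivationCycle(
                values=series.values[:, mask],
                sample_times=t[mask],
                muscle_names=list(series.muscle_names),
                subject_id=series.subject_id,
                speed_id=series.speed_id,
                cycle_index=i,
            )
        )
    return cycles


def resample_to_grid(cycle: ActivationCycle, n: int = 20) -> ActivationCycle:
    """Thin a cycle to ``n`` evenly spaced samples by linear interpolation.

    The grid spans ``[first, last]`` sample time inclusive, so endpoints
    are preserved exactly and resampling is idempotent on the target grid.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if cycle.n_samples < 2:
        raise ValueError("cycle must contain at least 2 samples")
    t = cycle.sample_times
    grid = np.linspace(t[0], t[-1], n)
    values = np.stack([np.interp(grid, t, row) for row in cycle.values])
    return replace(cycle, values=values, sample_times=grid)


@dataclass
class Normalization:
    """Per-channel z-score record fitted on a training fold only."""

    input_mean: np.ndarray
    input_sd: np.ndarray
    target_mean: float
    target_sd: float

    @classmethod
    def fit(cls, samples: Sequence[ModelSample]) -> "Normalization":
        if not samples:
            raise ValueError("training fold is empty")
        x = np.concatenate([s.input_sequence for s in samples], axis=0)
        y = np.concatenate([s.target_sequence for s in samples], axis=0)
        in_sd = x.std(axis=0, ddof=0)
        zero = in_sd < 1e-12
        if np.any(zero):
            logger.warning(
                "zero-variance input channel(s) %s: sd replaced by 1",
                np.flatnonzero(zero).tolist(),
            )
            in_sd = np.where(zero, 1.0, in_sd)
        t_sd = float(y.std(ddof=0))
        if t_sd < 1e-12:
            logger.warning("zero-variance target channel: sd replaced by 1")
            t_sd = 1.0
        return cls(
            input_mean=x.mean(axis=0),
            input_sd=in_sd,
            target_mean=float(y.mean()),
            target_sd=t_sd,
        )

    def transform(self, sample: ModelSample) -> ModelSample:
        return replace(
            sample,
            input_sequence=(sample.input_sequence - self.input_mean) / self.input_sd,
            target_sequence=(sample.target_sequence - self.target_mean) / self.target_sd,
        )

    def transform_input(self, input_sequence: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(input_sequence) - self.input_mean) / self.input_sd

    def inverse_target(self, standardized: np.ndarray) -> np.ndarray:
        return standardized * self.target_sd + self.target_mean

    def inverse(self, sample: ModelSample) -> ModelSample:
        return replace(
            sample,
            input_sequence=sample.input_sequence * self.input_sd + self.input_mean,
            target_sequence=sample.target_sequence * self.target_sd + self.target_mean,
        )

    def to_dict(self) -> dict:
        return {
            "input_mean": self.input_mean.tolist(),
            "input_sd": self.input_sd.tolist(),
            "target_mean": self.target_mean,
            "target_sd": self.target_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Normalization":
        return cls(
            input_mean=np.asarray(d["input_mean"], float),
            input_sd=np.asarray(d["input_sd"], float),
            target_mean=float(d["target_mean"]),
            target_sd=float(d["target_sd"]),
        )


def standardize(
    samples: Sequence[ModelSample],
    stats_source: Sequence[ModelSample] | None = None,
) -> tuple[list[ModelSample], Normalization]:
    """Z-score a sample collection using statistics from ``stats_source``.

    ``stats_source`` must be the training fold; when omitted, ``samples``
    itself is treated as the training fold.  Test folds are transformed
    with training statistics only — no held-out value ever enters the fit.
    """
    record = Normalization.fit(list(stats_source if stats_source is not None else samples))
    return [record.transform(s) for s in samples], record


def build_pattern(pair: PairedCycle, pattern: InputPattern) -> ModelSample:
    """Arrange one paired cycle into a network sample for ``pattern``.

    Inputs are always drawn from the simulated member, targets from the
    measured member's target muscle; the two never mix.
    """
    ti = pair.measured.channel_index(pattern.target_muscle)
    n = pair.simulated.n_samples
    fractions = np.arange(n) / max(n - 1, 1)
    if pattern.name == "All-Entire":
        x = pair.simulated.values.T  # (steps, channels)
        y = pair.measured.values[ti]
        labels = list(pair.muscle_names)
    else:
        x = pair.simulated.values[ti][:, None]
        y = pair.measured.values[ti]
        labels = [pattern.target_muscle]
        if pattern.name == "One-Quarter":
            q = n // 4
            sl = slice(pattern.quarter_index * q, (pattern.quarter_index + 1) * q)
            x, y, fractions = x[sl], y[sl], fractions[sl]
    return ModelSample(
        input_sequence=x,
        target_sequence=y,
        identity=pair.identity,
        input_labels=labels,
        target_label=pattern.target_muscle,
        cycle_fractions=fractions,
    )


@dataclass
class Fold:
    subject_id: str
    train: list
    test: list


def loso_splits(items: Iterable, subject_of=None) -> list[Fold]:
    """Leave-one-subject-out folds over any items carrying a subject id.

    Works on ``ModelSample``/``PairedCycle`` collections (anything whose
    ``identity[0]`` is the subject).  Folds are ordered by subject id and
    partition the dataset: each item appears in exactly one test fold.
    """
    items = list(items)
    if subject_of is None:
        subject_of = lambda it: it.identity[0]
    subjects = sorted({subject_of(it) for it in items})
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [
        Fold(
            subject_id=s,
            train=[it for it in items if subject_of(it) != s],
            test=[it for it in items if subject_of(it) == s],
        )
        for s in subjects
    ]
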