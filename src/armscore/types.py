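"""Domain types for sensor-based upper-limb clinical score estimation.

The objects here model one rehabilitation-study visit: a subject wearing a
set of body-worn accelerometers performs up to three repetitions of eight
Wolf Motor Function Test (WMFT) tasks, each repetition recorded as a short
multi-channel acceleration time series, and a clinician assigns the
ground-truth labels — an upper-extremity Fugl-Meyer Assessment total
(FMA, 0–66, higher = less impaired) and a per-task Functional Ability
Scale rating (FAS, 0–5, higher = better movement quality).

All acceleration values are in units of g.  Every type has a
``validate()`` method that raises :class:`ValidationError` with the
offending subject/trial identified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLACEMENTS",
    "TWO_AXIS_PLACEMENTS",
    "TASKS",
    "REACH_TASKS",
    "MANIPULATION_TASKS",
    "ValidationError",
    "SensorChannel",
    "SensorTrial",
    "SubjectSession",
    "FeatureVector",
    "ScoreEstimate",
]


class ValidationError(ValueError):
    """An invariant of a domain object is violated."""


#: Canonical ordering of sensor placements. The finger units carry
#: two-axis accelerometers; every other unit carries three axes.
PLACEMENTS = (
    "chest",
    "arm_affected",
    "arm_unaffected",
    "wrist_affected",
    "wrist_unaffected",
    "thumb_affected",
    "index_affected",
)

TWO_AXIS_PLACEMENTS = frozenset({"thumb_affected", "index_affected"})

#: The eight WMFT items used: four arm-reaching tasks and four
#: manipulation tasks.
REACH_TASKS = ("WMFT-1", "WMFT-3", "WMFT-5", "WMFT-8")
MANIPULATION_TASKS = ("WMFT-9", "WMFT-10", "WMFT-13", "WMFT-15")
TASKS = REACH_TASKS + MANIPULATION_TASKS

DIAGNOSES = ("stroke", "TBI")
VISITS = ("baseline", "discharge")
SCALES = ("FAS", "FMA")
METHODS = ("fas_rf", "m1_linreg", "m2_rf", "m3_balanced_rf", "m4_proposed")

#: Low-pass cut-off of the filtering pipeline; sampling must satisfy
#: Nyquist above this cut-off.
_MIN_FS_HZ = 16.0


@dataclass
class SensorChannel:
    """One accelerometer unit's recording for one trial.

    Parameters
    ----------
    placement : str
        One of :data:`PLACEMENTS`.
    samples : ndarray, shape (n_samples, n_axes)
        Acceleration in g.
    fs : float
        Sampling frequency in Hz; must exceed twice the 8 Hz low-pass
        cut-off used downstream.
    """

    placement: str
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]

    @property
    def n_axes(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def validate(self, where: str = "") -> None:
        ctx = f" ({where})" if where else ""
        if self.placement not in PLACEMENTS:
            raise ValidationError(f"unknown placement {self.placement!r}{ctx}")
        expected = 2 if self.placement in TWO_AXIS_PLACEMENTS else 3
        if self.n_axes != expected:
            raise ValidationError(
                f"placement {self.placement!r} requires {expected} axes, "
                f"got {self.n_axes}{ctx}"
            )
        if not self.fs > _MIN_FS_HZ:
            raise ValidationError(
                f"fs={self.fs} Hz too low for the 8 Hz low-pass pipeline{ctx}"
            )
        if self.n_samples < 1:
            raise ValidationError(f"empty channel {self.placement!r}{ctx}")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(f"non-finite samples in {self.placement!r}{ctx}")


@dataclass
class SensorTrial:
    """One repetition of one WMFT task across all worn sensors.

    ``start_marker``/``end_marker`` delimit the half-open sample window
    ``[start, end)`` during which the task was actually performed (the
    digital marker recorded at acquisition time).
    """

    task_id: str
    repetition: int
    channels: dict[str, SensorChannel]
    start_marker: int = 0
    end_marker: int | None = None

    def __post_init__(self) -> None:
        if self.end_marker is None and self.channels:
            self.end_marker = min(c.n_samples for c in self.channels.values())

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).n_samples

    def validate(self, where: str = "") -> None:
        ctx = f" ({where})" if where else ""
        if self.task_id not in TASKS:
            raise ValidationError(f"unknown task {self.task_id!r}{ctx}")
        if not 1 <= int(self.repetition) <= 3:
            raise ValidationError(
                f"repetition {self.repetition} outside 1..3{ctx}"
            )
        if not self.channels:
            raise ValidationError(f"trial has no channels{ctx}")
        lengths = set()
        rates = set()
        for name, ch in self.channels.items():
            if name != ch.placement:
                raise ValidationError(
                    f"channel key {name!r} != placement {ch.placement!r}{ctx}"
                )
            ch.validate(where=f"{where} {self.task_id} rep{self.repetition}")
            lengths.add(ch.n_samples)
            rates.add(float(ch.fs))
        if len(rates) > 1:
            raise ValidationError(f"channels disagree on fs {sorted(rates)}{ctx}")
        if len(lengths) > 1:
            raise ValidationError(
                f"channels disagree on length {sorted(lengths)}{ctx}"
            )
        n = lengths.pop()
        if not (0 <= self.start_marker < self.end_marker <= n):
            raise ValidationError(
                f"markers [{self.start_marker}, {self.end_marker}) invalid "
                f"for length {n}{ctx}"
            )


@dataclass
class SubjectSession:
    """A subject's visit: trials plus clinician-assigned ground truth."""

    subject_id: str
    diagnosis: str
    visit: str
    fma_true: int
    fas_true_per_task: dict[str, float]
    trials: list[SensorTrial] = field(default_factory=list)
    demographics: dict | None = None

    def trials_for_task(self, task_id: str) -> list[SensorTrial]:
        return [t for t in self.trials if t.task_id == task_id]

    def validate(self) -> None:
        ctx = f"subject {self.subject_id}"
        if self.diagnosis not in DIAGNOSES:
            raise ValidationError(f"{ctx}: unknown diagnosis {self.diagnosis!r}")
        if self.visit not in VISITS:
            raise ValidationError(f"{ctx}: unknown visit {self.visit!r}")
        if not 0 <= self.fma_true <= 66:
            raise ValidationError(f"{ctx}: fma_true {self.fma_true} outside 0..66")
        for task, fas in self.fas_true_per_task.items():
            if task not in TASKS:
                raise ValidationError(f"{ctx}: unknown task {task!r} in FAS map")
            if not 0.0 <= float(fas) <= 5.0:
                raise ValidationError(
                    f"{ctx}: FAS {fas} for {task} outside [0, 5]"
                )
            if not self.trials_for_task(task):
                raise ValidationError(
                    f"{ctx}: FAS labelled task {task} has no trials"
                )
        for trial in self.trials:
            trial.validate(where=ctx)


@dataclass
class FeatureVector:
    """Named scalar features extracted from one trial."""

    names: list[str]
    values: np.ndarray
    task_id: str
    subject_id: str
    repetition: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def validate(self) -> None:
        if len(self.names) != len(self.values):
            raise ValidationError(
                f"{len(self.names)} names vs {len(self.values)} values "
                f"(subject {self.subject_id}, {self.task_id})"
            )
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ValidationError(
                f"non-finite features {bad} (subject {self.subject_id}, "
                f"{self.task_id} rep {self.repetition})"
            )


@dataclass
class ScoreEstimate:
    """A clinical score estimate with its provenance.

    ``value`` is clipped to the scale range on construction: [0, 5] for
    FAS and [0, 66] for FMA.
    """

    subject_id: str
    scale: str
    method: str
    value: float
    fold_id: str = ""

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        hi = 5.0 if self.scale == "FAS" else 66.0
        self.value = float(np.clip(self.value, 0.0, hi))
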