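"""Core data containers for the sit-to-stand analysis pipeline.

Everything downstream of the raw sensor stream is expressed with a small
set of containers:

* :class:`AccelerometerRecording` -- a raw triaxial series in device axes,
  in units of g, from one body site (thigh or chest).
* :class:`CalibrationPose` -- the gravity direction estimated from a static
  standing trial, used to rotate device axes into anatomical axes.
* :class:`AnatomicalSignal` -- the same series expressed in the
  anterior-posterior (AP), medial-lateral (ML) and cranial-caudal (CC)
  anatomical axes.  By convention the CC component of a quiet standing pose
  is +1 g.
* :class:`TransitionEvent` -- one delineated sit-to-stand (``si_st``) or
  stand-to-sit (``st_si``) transition, with its sit, stand and
  mid-transition sample indices and the two transition halves.
* :class:`CSTTrial` -- a delineated 30-second chair stand test.
* :class:`ActivityBout` -- a maximal run of one activity label in a
  free-living stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SITES = ("thigh", "chest")
ACTIVITY_CLASSES = ("walk", "stand", "sit", "lie", "other")
AXES = ("ap", "ml", "cc")
TRANSITION_TYPES = ("si_st", "st_si")
CONTEXTS = ("supervised_cst", "unsupervised_cst", "daily_life")


class CalibrationQualityError(ValueError):
    """Raised when a static calibration trial is unusable (norm far from 1 g)."""


class NoDominantFrequencyError(ValueError):
    """Raised when a series carries no usable spectral peak in the search band."""


@dataclass
class AccelerometerRecording:
    """Raw triaxial accelerometer series in device axes.

    Parameters
    ----------
    site
        Body site, ``"thigh"`` or ``"chest"``.
    sampling_rate_hz
        Uniform sampling rate.  250 Hz for supervised sessions, 62.5 Hz for
        unsupervised / free-living monitoring.
    samples
        Array of shape ``(n, 3)`` in units of g (device x, y, z).
    start_time
        Seconds offset of the first sample relative to the stream origin.
    """

    site: str
    sampling_rate_hz: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown sensor site {self.site!r}; expected one of {SITES}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if self.samples.shape[0] < 2:
            raise ValueError("a recording needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass
class CalibrationPose:
    """Gravity direction in device axes, estimated from quiet standing."""

    gravity_unit_vector: np.ndarray
    mean_norm_g: float
    site: str = "thigh"

    def __post_init__(self) -> None:
        self.gravity_unit_vector = np.asarray(self.gravity_unit_vector, dtype=float)
        if self.gravity_unit_vector.shape != (3,):
            raise ValueError("gravity_unit_vector must be a 3-vector")
        norm = float(np.linalg.norm(self.gravity_unit_vector))
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError("gravity_unit_vector must be unit norm")


@dataclass
class AnatomicalSignal:
    """Triaxial series in anatomical axes (AP, ML, CC), units of g."""

    ap: np.ndarray
    ml: np.ndarray
    cc: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.ap = np.asarray(self.ap, dtype=float)
        self.ml = np.asarray(self.ml, dtype=float)
        self.cc = np.asarray(self.cc, dtype=float)
        if not (self.ap.shape == self.ml.shape == self.cc.shape) or self.ap.ndim != 1:
            raise ValueError("AP, ML and CC must be 1-d series of equal length")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.ap.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def axis(self, name: str) -> np.ndarray:
        name = name.lower()
        if name not in AXES:
            raise ValueError(f"unknown axis {name!r}")
        return getattr(self, name)

    def as_array(self) -> np.ndarray:
        """Return an (n, 3) array with columns AP, ML, CC."""
        return np.column_stack([self.ap, self.ml, self.cc])


@dataclass
class TransitionEvent:
    """One sit-to-stand or stand-to-sit transition.

    ``sit_index`` and ``stand_index`` are the sample indices of the sit
    (CC minimum) and stand (CC maximum) events; ``mid_index`` is the
    mid-transition sample (50%-amplitude crossing of the low-pass-filtered
    CC component).  ``half1`` and ``half2`` are half-open index ranges
    ``[start, mid)`` and ``[mid, end)`` that partition the transition span.
    """

    type: str
    sit_index: int
    stand_index: int
    mid_index: int
    duration_s: float
    half1: tuple[int, int]
    half2: tuple[int, int]
    context: str
    sampling_rate_hz: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.type not in TRANSITION_TYPES:
            raise ValueError(f"unknown transition type {self.type!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        lo, hi = self.start_index, self.end_index
        if not (lo < self.mid_index < hi):
            raise ValueError("mid_index must lie strictly inside the transition span")
        if self.half1 != (lo, self.mid_index) or self.half2 != (self.mid_index, hi):
            raise ValueError("halves must partition [start, end) at mid_index")

    @property
    def start_index(self) -> int:
        return min(self.sit_index, self.stand_index)

    @property
    def end_index(self) -> int:
        return max(self.sit_index, self.stand_index)

    @property
    def sit_time_s(self) -> float:
        return self.sit_index / self.sampling_rate_hz

    @property
    def stand_time_s(self) -> float:
        return self.stand_index / self.sampling_rate_hz

    @property
    def mid_time_s(self) -> float:
        return self.mid_index / self.sampling_rate_hz


@dataclass
class CSTTrial:
    """A delineated 30-second chair stand test.

    ``repetition_count`` counts completed stands (one per ``si_st`` event);
    a partial rise truncated by the end of the test does not count.
    """

    events: list[TransitionEvent]
    repetition_count: int
    thigh: AnatomicalSignal | None = None
    chest: AnatomicalSignal | None = None
    flags: list[str] = field(default_factory=list)
    lpf_cc: np.ndarray | None = None
    dominant_frequency_hz: float | None = None

    def events_of(self, phase: str) -> list[TransitionEvent]:
        return [e for e in self.events if e.type == phase]

    def durations_of(self, phase: str) -> np.ndarray:
        return np.array([e.duration_s for e in self.events_of(phase)], dtype=float)


@dataclass
class ActivityBout:
    """Maximal contiguous run of one activity label."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in ACTIVITY_CLASSES:
            raise ValueError(f"unknown activity label {self.label!r}")
        if self.end_s <= self.start_s:
            raise ValueError("bout must have end_s > start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s
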