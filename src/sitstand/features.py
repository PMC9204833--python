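"""Context-specific performance-metric catalogs with full provenance.

Three catalogs are computed from delineated transitions:

* **supervised_cst** (one 30 s chair-stand trial): 9 temporal features
  (average/median/max/min of si-st and st-si transition times, plus the
  repetition count) and 144 acceleration features (6 statistics x 3 axes x
  2 phases x 2 halves x 2 sensors = 72 per sensor) computed on the
  5-20 Hz band-passed signals within each transition half, aggregated
  across the repetitions of the trial.
* **unsupervised_cst** (all chair-stand assessments of the monitoring
  period; a participant needs at least four to be eligible): 19 temporal
  summary metrics plus the same 144-feature acceleration scheme pooled
  across assessments, 163 in total.
* **daily_life** (accepted free-living transitions): 10 temporal features
  (min/max/average/median/CV per phase) and an acceleration scheme that
  adds the CV of the peak and of the minimum to the supervised statistics
  (8 statistics x 3 axes x 2 phases x 2 halves x 2 sensors = 192).

Every feature value maps to exactly one :class:`FeatureDescriptor`
recording context, family, sensor, axis, phase, half and statistic.
"Peak" is the signed maximum and "minimum" the signed minimum of the
band-passed signal (minima are typically negative); percentiles are taken
over the pooled band-passed samples of the phase-half across transitions,
with linear interpolation; the CV is the sample standard deviation
(n-1 denominator) divided by the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AnatomicalSignal, CSTTrial, TransitionEvent
from .signal_prep import butterworth_bandpass

AXES = ("ap", "ml", "cc")
PHASES = ("si_st", "st_si")
HALVES = (1, 2)
SENSORS = ("thigh", "chest")

TEMPORAL_STATS_SUPERVISED = ("avg", "med", "max", "min")
TEMPORAL_STATS_DAILY = ("min", "max", "avg", "med", "cv")
ACCEL_STATS_CST = ("avg_of_peak", "med_of_peak", "avg_of_min", "med_of_min", "p95", "p5")
ACCEL_STATS_DAILY = (
    "avg_of_peak", "med_of_peak", "cv_of_peak",
    "avg_of_min", "med_of_min", "cv_of_min",
    "p95", "p5",
)
MIN_UNSUPERVISED_TRIALS = 4

_DISPLAY_STAT = {
    "avg": "Avg", "med": "Median", "max": "Max", "min": "Min", "cv": "CV",
    "avg_of_peak": "Avg of Peak", "med_of_peak": "Median of Peak",
    "cv_of_peak": "CV of Peak", "avg_of_min": "Avg of Min",
    "med_of_min": "Median of Min", "cv_of_min": "CV of Min",
    "p95": "95th Percentile", "p5": "5th Percentile",
}


@dataclass(frozen=True)
class FeatureDescriptor:
    """Provenance of one performance metric."""

    context: str
    family: str  # "temporal" | "acceleration"
    statistic: str
    sensor: str = "none"
    axis: str = "none"
    phase: str = "none"
    half: int | None = None
    units: str = "s"

    @property
    def name(self) -> str:
        if self.family == "temporal":
            phase = f"_{self.phase}" if self.phase != "none" else ""
            return f"{self.statistic}{phase}"
        return f"{self.sensor}_{self.statistic}_{self.axis}_{self.phase}_h{self.half}"

    @property
    def display(self) -> str:
        """Human-readable label, e.g. 'Avg of (Chest) Min CC Accel Si-St (2)'."""
        phase = self.phase.replace("si_st", "Si-St").replace("st_si", "St-Si")
        if self.family == "temporal":
            stat = _DISPLAY_STAT.get(self.statistic, self.statistic)
            if self.statistic == "n_repetitions":
                return "30CST Performance (# Reps)"
            return f"{stat} {phase} Time (s)"
        stat = _DISPLAY_STAT[self.statistic]
        head, _, tail = stat.partition(" of ")
        sensor = self.sensor.capitalize()
        axis = self.axis.upper()
        if tail:
            return f"{head} of ({sensor}) {tail} {axis} Accel {phase} ({self.half}) (g)"
        return f"{stat} ({sensor}) {axis} Accel {phase} ({self.half}) (g)"


@dataclass
class FeatureVector:
    """Named feature values for one participant in one context."""

    participant_id: str
    context: str
    values: dict[str, float] = field(default_factory=dict)
    n_transitions_used: int = 0
    flags: list[str] = field(default_factory=list)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.participant_id, dtype=float)


def _accel_descriptors(context: str, stats: tuple[str, ...]) -> list[FeatureDescriptor]:
    return [
        FeatureDescriptor(
            context=context, family="acceleration", statistic=stat,
            sensor=sensor, axis=axis, phase=phase, half=half, units="g",
        )
        for sensor in SENSORS
        for stat in stats
        for axis in AXES
        for phase in PHASES
        for half in HALVES
    ]


def supervised_catalog() -> list[FeatureDescriptor]:
    """9 temporal + 144 acceleration descriptors for the supervised trial."""
    ctx = "supervised_cst"
    temporal = [
        FeatureDescriptor(context=ctx, family="temporal", statistic=stat, phase=phase)
        for stat in TEMPORAL_STATS_SUPERVISED
        for phase in PHASES
    ]
    temporal.append(
        FeatureDescriptor(context=ctx, family="temporal", statistic="n_repetitions",
                          units="count")
    )
    return temporal + _accel_descriptors(ctx, ACCEL_STATS_CST)


UNSUPERVISED_TEMPORAL = (
    # pooled over all transitions of all assessments
    [("avg", p) for p in PHASES] + [("med", p) for p in PHASES]
    # mean repetition count per assessment
    + [("avg_repetitions", "none")]
    # mean over assessments of per-assessment extremes
    + [("avg_of_max", p) for p in PHASES] + [("avg_of_min_time", p) for p in PHASES]
    # median over assessments of per-assessment extremes
    + [("med_of_max", p) for p in PHASES] + [("med_of_min_time", p) for p in PHASES]
    # pooled percentiles
    + [("p5", p) for p in PHASES] + [("p95", p) for p in PHASES]
    # median over assessments of per-assessment averages
    + [("med_of_avg", p) for p in PHASES]
)


def unsupervised_catalog() -> list[FeatureDescriptor]:
    """19 temporal + 144 acceleration descriptors (163 total)."""
    ctx = "unsupervised_cst"
    temporal = [
        FeatureDescriptor(
            context=ctx, family="temporal", statistic=stat, phase=phase,
            units="count" if stat == "avg_repetitions" else "s",
        )
        for stat, phase in UNSUPERVISED_TEMPORAL
    ]
    return temporal + _accel_descriptors(ctx, ACCEL_STATS_CST)


def daily_catalog() -> list[FeatureDescriptor]:
    """10 temporal + 192 acceleration descriptors for daily life."""
    ctx = "daily_life"
    temporal = [
        FeatureDescriptor(context=ctx, family="temporal", statistic=stat, phase=phase)
        for stat in TEMPORAL_STATS_DAILY
        for phase in PHASES
    ]
    return temporal + _accel_descriptors(ctx, ACCEL_STATS_DAILY)


def bandpass_signal(sig: AnatomicalSignal, low_hz: float = 5.0, high_hz: float = 20.0) -> AnatomicalSignal:
    """Band-pass every axis of an anatomical signal (feature pre-filter)."""
    fs = sig.sampling_rate_hz
    return AnatomicalSignal(
        ap=butterworth_bandpass(sig.ap, low_hz, high_hz, fs),
        ml=butterworth_bandpass(sig.ml, low_hz, high_hz, fs),
        cc=butterworth_bandpass(sig.cc, low_hz, high_hz, fs),
        sampling_rate_hz=fs,
    )


def _half_slice(event: TransitionEvent, half: int) -> tuple[int, int]:
    return event.half1 if half == 1 else event.half2


def peak_min_per_half(
    bandpassed: AnatomicalSignal, event: TransitionEvent
) -> dict[tuple[str, int], tuple[float, float]]:
    """Per-axis, per-half signed (peak, minimum) of a band-passed signal.

    12 values per sensor per event (3 axes x 2 halves x {max, min}).
    Halves shorter than 3 samples yield NaN (marked missing).
    """
    out: dict[tuple[str, int], tuple[float, float]] = {}
    for axis in AXES:
        x = bandpassed.axis(axis)
        for half in HALVES:
            lo, hi = _half_slice(event, half)
            seg = x[lo:hi]
            if seg.size < 3:
                out[(axis, half)] = (float("nan"), float("nan"))
            else:
                out[(axis, half)] = (float(seg.max()), float(seg.min()))
    return out


def _cv(values: np.ndarray) -> float:
    if values.size < 2:
        return float("nan")
    mean = float(values.mean())
    if mean == 0:
        return float("nan")
    return float(values.std(ddof=1) / mean)


def _temporal_stat(stat: str, durations: np.ndarray) -> float:
    if durations.size == 0:
        return float("nan")
    if stat == "avg":
        return float(durations.mean())
    if stat == "med":
        return float(np.median(durations))
    if stat == "max":
        return float(durations.max())
    if stat == "min":
        return float(durations.min())
    if stat == "cv":
        return _cv(durations)
    raise ValueError(f"unknown temporal statistic {stat!r}")


def _collect_accel(
    events: list[TransitionEvent],
    signals: dict[str, AnatomicalSignal],
) -> dict[tuple[str, str, str, int], dict[str, list]]:
    """Peaks, minima and pooled samples per (sensor, axis, phase, half)."""
    store: dict[tuple[str, str, str, int], dict[str, list]] = {
        (sensor, axis, phase, half): {"peaks": [], "mins": [], "pooled": []}
        for sensor in signals
        for axis in AXES
        for phase in PHASES
        for half in HALVES
    }
    for sensor, sig in signals.items():
        if sig is None:
            continue
        for event in events:
            for axis in AXES:
                x = sig.axis(axis)
                for half in HALVES:
                    lo, hi = _half_slice(event, half)
                    seg = x[lo:hi]
                    if seg.size < 3:
                        continue
                    cell = store[(sensor, axis, event.type, half)]
                    cell["peaks"].append(float(seg.max()))
                    cell["mins"].append(float(seg.min()))
                    cell["pooled"].append(seg)
    return store


def _accel_value(stat: str, cell: dict[str, list]) -> float:
    peaks = np.asarray(cell["peaks"], dtype=float)
    mins = np.asarray(cell["mins"], dtype=float)
    if peaks.size == 0:
        return float("nan")
    pooled = np.concatenate(cell["pooled"])
    if stat == "avg_of_peak":
        return float(peaks.mean())
    if stat == "med_of_peak":
        return float(np.median(peaks))
    if stat == "cv_of_peak":
        return _cv(peaks)
    if stat == "avg_of_min":
        return float(mins.mean())
    if stat == "med_of_min":
        return float(np.median(mins))
    if stat == "cv_of_min":
        return _cv(mins)
    if stat == "p95":
        return float(np.percentile(pooled, 95))
    if stat == "p5":
        return float(np.percentile(pooled, 5))
    raise ValueError(f"unknown acceleration statistic {stat!r}")


def _accel_values(
    catalog: list[FeatureDescriptor],
    events: list[TransitionEvent],
    signals: dict[str, AnatomicalSignal],
) -> dict[str, float]:
    store = _collect_accel(events, {s: sig for s, sig in signals.items() if sig is not None})
    values: dict[str, float] = {}
    for desc in catalog:
        if desc.family != "acceleration":
            continue
        key = (desc.sensor, desc.axis, desc.phase, desc.half)
        cell = store.get(key)
        values[desc.name] = _accel_value(desc.statistic, cell) if cell else float("nan")
    return values


def supervised_cst_features(
    trial: CSTTrial, participant_id: str = "unknown"
) -> FeatureVector:
    """Supervised 30CST feature vector (153 features)."""
    catalog = supervised_catalog()
    vec = FeatureVector(participant_id=participant_id, context="supervised_cst")
    if trial.repetition_count == 0:
        vec.values = {d.name: float("nan") for d in catalog}
        vec.values["n_repetitions"] = 0.0
        vec.flags.append("no_repetitions")
        return vec
    for desc in catalog:
        if desc.family != "temporal":
            continue
        if desc.statistic == "n_repetitions":
            vec.values[desc.name] = float(trial.repetition_count)
        else:
            vec.values[desc.name] = _temporal_stat(desc.statistic, trial.durations_of(desc.phase))
    signals = {
        "thigh": bandpass_signal(trial.thigh) if trial.thigh is not None else None,
        "chest": bandpass_signal(trial.chest) if trial.chest is not None else None,
    }
    vec.values.update(_accel_values(catalog, trial.events, signals))
    vec.n_transitions_used = len(trial.events)
    return vec


def unsupervised_cst_features(
    trials: list[CSTTrial],
    participant_id: str = "unknown",
    min_trials: int = MIN_UNSUPERVISED_TRIALS,
) -> FeatureVector:
    """Summary features across all unsupervised 30CST assessments (163).

    Participants with fewer than ``min_trials`` assessments are flagged
    ineligible and no features are emitted.
    """
    vec = FeatureVector(participant_id=participant_id, context="unsupervised_cst")
    usable = [t for t in trials if t.repetition_count > 0]
    if len(usable) < min_trials:
        vec.flags.append("ineligible")
        return vec

    catalog = unsupervised_catalog()
    per_phase_pooled = {p: np.concatenate([t.durations_of(p) for t in usable]) for p in PHASES}
    per_phase_stats = {
        p: {
            "max": np.array([t.durations_of(p).max() for t in usable if t.durations_of(p).size]),
            "min": np.array([t.durations_of(p).min() for t in usable if t.durations_of(p).size]),
            "avg": np.array([t.durations_of(p).mean() for t in usable if t.durations_of(p).size]),
        }
        for p in PHASES
    }
    for desc in catalog:
        if desc.family != "temporal":
            continue
        stat, phase = desc.statistic, desc.phase
        if stat == "avg_repetitions":
            vec.values[desc.name] = float(np.mean([t.repetition_count for t in usable]))
        elif stat in ("avg", "med"):
            pooled = per_phase_pooled[phase]
            vec.values[desc.name] = (
                float(pooled.mean()) if stat == "avg" else float(np.median(pooled))
            )
        elif stat in ("p5", "p95"):
            pooled = per_phase_pooled[phase]
            q = 5 if stat == "p5" else 95
            vec.values[desc.name] = float(np.percentile(pooled, q)) if pooled.size else float("nan")
        else:
            agg, _, per = stat.partition("_of_")
            key = {"max": "max", "min": "min", "min_time": "min", "avg": "avg"}[per]
            arr = per_phase_stats[phase][key]
            if arr.size == 0:
                vec.values[desc.name] = float("nan")
            else:
                vec.values[desc.name] = float(arr.mean() if agg == "avg" else np.median(arr))

    all_events: list[TransitionEvent] = []
    store_totals = 0
    # acceleration statistics pool events across assessments; each trial has
    # its own signals, so collect per-trial and merge
    merged: dict[tuple[str, str, str, int], dict[str, list]] = {}
    for trial in usable:
        signals = {
            "thigh": bandpass_signal(trial.thigh) if trial.thigh is not None else None,
            "chest": bandpass_signal(trial.chest) if trial.chest is not None else None,
        }
        part = _collect_accel(trial.events, {s: v for s, v in signals.items() if v is not None})
        for key, cell in part.items():
            target = merged.setdefault(key, {"peaks": [], "mins": [], "pooled": []})
            for field_name in ("peaks", "mins", "pooled"):
                target[field_name].extend(cell[field_name])
        all_events.extend(trial.events)
        store_totals += len(trial.events)
    for desc in catalog:
        if desc.family != "acceleration":
            continue
        cell = merged.get((desc.sensor, desc.axis, desc.phase, desc.half))
        vec.values[desc.name] = (
            _accel_value(desc.statistic, cell) if cell and cell["peaks"] else float("nan")
        )
    vec.n_transitions_used = store_totals
    return vec


def daily_life_features(
    events: list[TransitionEvent],
    thigh: AnatomicalSignal | None,
    chest: AnatomicalSignal | None,
    participant_id: str = "unknown",
) -> FeatureVector:
    """Daily-life feature vector over all accepted free-living transitions."""
    catalog = daily_catalog()
    vec = FeatureVector(participant_id=participant_id, context="daily_life")
    for desc in catalog:
        if desc.family != "temporal":
            continue
        durations = np.array([e.duration_s for e in events if e.type == desc.phase])
        vec.values[desc.name] = _temporal_stat(desc.statistic, durations)
    signals = {
        "thigh": bandpass_signal(thigh) if thigh is not None else None,
        "chest": bandpass_signal(chest) if chest is not None else None,
    }
    vec.values.update(_accel_values(catalog, events, signals))
    vec.n_transitions_used = len(events)
    if not events:
        vec.flags.append("no_transitions")
    return vec


def catalog_frame(catalog: list[FeatureDescriptor]) -> pd.DataFrame:
    """Machine-readable descriptor table (one row per feature)."""
    return pd.DataFrame(
        [
            {
                "name": d.name, "display": d.display, "context": d.context,
                "family": d.family, "sensor": d.sensor, "axis": d.axis,
                "phase": d.phase, "half": d.half if d.half is not None else "none",
                "statistic": d.statistic, "units": d.units,
            }
            for d in catalog
        ]
    )
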