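"""Seed-controlled synthetic accelerometer streams with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, for two body-worn triaxial accelerometers (right thigh, chest):

* **Quasi-static orientation model.**  At rest the accelerometer reads the
  gravity reaction, so the per-sample vector norm of a noiseless static
  recording is exactly 1 g.  The thigh cranial-caudal (CC) gravity
  component sits near 1 g while standing (thigh vertical) and near 0 g
  while sitting (thigh horizontal); transitions move it between the two
  levels along a smooth cubic (smoothstep) ramp.  The anterior-posterior
  component is completed so the gravity vector keeps unit norm.  The chest
  stays near CC = 1 g in both postures, with a configurable transient dip
  during transitions and CC ~ 0 g only when lying.
* **Dynamics.**  Optional 5-20 Hz Gaussian-windowed bursts at transition
  midpoints (exercising the band-pass feature path), a ~1.8 Hz gait
  oscillation during walking, broadband high-variance content for the
  "other" class, and white Gaussian measurement noise per axis.
* **Mounting misalignment.**  Device axes are rotated from the anatomical
  axes by a configurable tilt; a static standing calibration recording is
  generated with the same rotation, so the calibration/alignment stage has
  something real to undo.

Ground truth records every embedded sit<->stand transition (type, ramp
start, ramp end) and the activity-bout tiling of free-living streams, so
detection and delineation can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ACTIVITY_CLASSES, AccelerometerRecording, ActivityBout, SITES

# Orientation levels (thigh CC gravity component, g).  Sitting is set near
# 0 g and standing near 1 g so that a 0.5 g crossing separates the postures
# by construction.
#: "other" covers running and stair climbing: upright postures with large
#: broadband dynamics, so its orientation baseline is near standing.
THIGH_CC_LEVELS = {"walk": 0.95, "stand": 0.98, "sit": 0.05, "lie": 0.05, "other": 0.9}
CHEST_CC_LEVELS = {"walk": 0.99, "stand": 0.995, "sit": 0.97, "lie": 0.05, "other": 0.95}

#: Labels whose thigh posture is upright; a boundary between one of these and
#: a sitting bout embeds a ground-truth transition.
UPRIGHT_LABELS = ("stand", "walk")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic stream generator.

    Durations are in seconds, amplitudes in g.  ``si_st_duration_s`` /
    ``st_si_duration_s`` may be scalars or per-event sequences.  The
    defaults describe a realistic instrumented 30-second chair stand test:
    ~10 repetitions of ~1.2 s transitions with short static holds, 250 Hz
    sampling, a few-degree mounting tilt, modest transient bursts and
    0.02 g sensor noise.
    """

    seed: int = 0
    sampling_rate_hz: float = 250.0
    si_st_duration_s: float | Sequence[float] = 1.2
    st_si_duration_s: float | Sequence[float] = 1.2
    n_repetitions: int = 10
    noise_sd_g: float = 0.02
    mounting_tilt_deg: float = 5.0
    burst_amplitude_g: float = 0.05
    activity_schedule: list[tuple[str, float]] | None = None
    sit_hold_s: float = 0.25
    stand_hold_s: float = 0.25
    lead_in_s: float = 3.0
    tail_s: float = 3.0
    sit_level_g: float = 0.05
    stand_level_g: float = 0.98
    chest_dip_g: float = 0.15
    strict_30s: bool = False

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.noise_sd_g < 0 or self.burst_amplitude_g < 0:
            raise ValueError("noise and burst amplitudes must be nonnegative")
        for d in (*np.atleast_1d(self.si_st_duration_s), *np.atleast_1d(self.st_si_duration_s)):
            if d <= 0:
                raise ValueError("transition durations must be positive")


@dataclass
class TruthTransition:
    """Ground-truth transition: ramp start/end in stream seconds."""

    type: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def mid_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


@dataclass
class GroundTruth:
    """Everything the generator knows about a stream or cohort."""

    transitions: list[TruthTransition] = field(default_factory=list)
    activity_bouts: list[ActivityBout] = field(default_factory=list)
    group_assignments: dict[str, int] = field(default_factory=dict)
    ages: dict[str, float] = field(default_factory=dict)

    def transitions_of(self, kind: str) -> list[TruthTransition]:
        return [t for t in self.transitions if t.type == kind]

    def per_sample_labels(self, fs: float, n: int) -> np.ndarray:
        """Expand the bout tiling into one label per sample."""
        labels = np.empty(n, dtype=object)
        for bout in self.activity_bouts:
            i0 = int(round(bout.start_s * fs))
            i1 = min(n, int(round(bout.end_s * fs)))
            labels[i0:i1] = bout.label
        return labels


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _rotation_about_y(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _to_device(anat: np.ndarray, tilt_deg: float) -> np.ndarray:
    """Express anatomical-axis rows in tilted device axes (v_dev = R^T v_anat)."""
    return anat @ _rotation_about_y(tilt_deg)


def _per_event(value: float | Sequence[float], n: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.full(n, arr[0])
    if arr.size != n:
        raise ValueError(f"{name} must be scalar or length {n}, got length {arr.size}")
    return arr.copy()


def generate_calibration(config: SimulationConfig, site: str) -> AccelerometerRecording:
    """30 s static standing calibration recording for one site.

    The noiseless mean is the unit gravity vector along the site's nominal
    CC axis, rotated by the configured mounting tilt.
    """
    if site not in SITES:
        raise ValueError(f"unknown sensor site {site!r}; expected one of {SITES}")
    rng = np.random.default_rng(config.seed)
    n = int(round(30.0 * config.sampling_rate_hz))
    anat = np.tile([0.0, 0.0, 1.0], (n, 1))
    dev = _to_device(anat, config.mounting_tilt_deg)
    if config.noise_sd_g > 0:
        dev = dev + rng.normal(0.0, config.noise_sd_g, size=dev.shape)
    return AccelerometerRecording(site=site, sampling_rate_hz=config.sampling_rate_hz, samples=dev)


def _burst(t: np.ndarray, center_s: float, amp: float, freq: float, phase: float, width_s: float) -> np.ndarray:
    """Gaussian-windowed in-band tone centred on a transition midpoint."""
    w = np.exp(-0.5 * ((t - center_s) / width_s) ** 2)
    return amp * w * np.sin(2 * np.pi * freq * (t - center_s) + phase)


def _assemble_site(
    cc_orient: np.ndarray,
    dyn: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    site: str,
) -> AccelerometerRecording:
    """Quasi-static orientation + dynamics -> device-axis recording."""
    ap_orient = np.sqrt(np.clip(1.0 - cc_orient**2, 0.0, None))
    anat = np.column_stack([ap_orient + dyn[:, 0], dyn[:, 1], cc_orient + dyn[:, 2]])
    dev = _to_device(anat, config.mounting_tilt_deg)
    if config.noise_sd_g > 0:
        dev = dev + rng.normal(0.0, config.noise_sd_g, size=dev.shape)
    return AccelerometerRecording(site=site, sampling_rate_hz=config.sampling_rate_hz, samples=dev)


def generate_cst_trial(
    config: SimulationConfig,
) -> tuple[AccelerometerRecording, AccelerometerRecording, GroundTruth]:
    """One chair-stand trial: thigh and chest recordings plus ground truth.

    The timeline is: lead-in sit, then per repetition a sit-to-stand ramp,
    stand hold, stand-to-sit ramp and sit hold, then a tail sit.  Ground
    truth records each ramp's start/end, so truth durations equal the
    configured ramp durations exactly (to one sample period).
    """
    fs = config.sampling_rate_hz
    n_rep = config.n_repetitions
    d_up = _per_event(config.si_st_duration_s, n_rep, "si_st_duration_s")
    d_down = _per_event(config.st_si_duration_s, n_rep, "st_si_duration_s")

    total = config.lead_in_s + config.tail_s + float(
        np.sum(d_up + d_down) + n_rep * (config.sit_hold_s + config.stand_hold_s)
    )
    if config.strict_30s and total > 30.0 + 1e-9:
        raise ValueError(f"scheduled trial duration {total:.2f} s exceeds 30 s")

    n = int(round(total * fs))
    t = np.arange(n) / fs
    lo, hi = config.sit_level_g, config.stand_level_g
    thigh_cc = np.full(n, lo)
    chest_cc = np.ones(n)
    truth = GroundTruth()

    rng = np.random.default_rng(config.seed)
    thigh_dyn = np.zeros((n, 3))
    chest_dyn = np.zeros((n, 3))

    cursor = config.lead_in_s
    for k in range(n_rep):
        for kind, dur in (("si_st", d_up[k]), ("st_si", d_down[k])):
            i0, i1 = int(round(cursor * fs)), int(round((cursor + dur) * fs))
            u = _smoothstep((t[i0:i1] - cursor) / dur)
            thigh_cc[i0:i1] = lo + (hi - lo) * (u if kind == "si_st" else 1.0 - u)
            if kind == "si_st":
                thigh_cc[i1:] = hi
            else:
                thigh_cc[i1:] = lo
            # chest transient dip over the ramp
            chest_cc[i0:i1] = 1.0 - config.chest_dip_g * np.sin(
                np.pi * np.clip((t[i0:i1] - cursor) / dur, 0, 1)
            )
            truth.transitions.append(TruthTransition(kind, cursor, cursor + dur))
            if config.burst_amplitude_g > 0:
                mid = cursor + dur / 2
                width = max(0.05, 0.1 * dur)
                sel = (t > mid - 4 * width) & (t < mid + 4 * width)
                for dyn in (thigh_dyn, chest_dyn):
                    scale = 1.0 if dyn is thigh_dyn else 0.6
                    for ax in range(3):
                        dyn[sel, ax] += _burst(
                            t[sel],
                            mid,
                            scale * config.burst_amplitude_g * rng.uniform(0.6, 1.0),
                            rng.uniform(7.0, 14.0),
                            rng.uniform(0, 2 * np.pi),
                            width,
                        )
            cursor += dur
            cursor += config.stand_hold_s if kind == "si_st" else config.sit_hold_s

    thigh = _assemble_site(thigh_cc, thigh_dyn, config, rng, "thigh")
    chest = _assemble_site(chest_cc, chest_dyn, config, rng, "chest")
    return thigh, chest, truth


def generate_daily_stream(
    config: SimulationConfig,
) -> tuple[dict[str, AccelerometerRecording], GroundTruth]:
    """Free-living streams realising ``config.activity_schedule``.

    Activity labels tile the stream without overlap.  Every boundary
    between an upright label (stand, walk) and a sitting bout embeds a
    transition of the configured duration, centred on the boundary, and is
    recorded in the ground truth.  Other label boundaries are smoothed with
    a short generic ramp but carry no transition.
    """
    if not config.activity_schedule:
        raise ValueError("activity_schedule must be a non-empty list of (label, duration_s)")
    for label, dur in config.activity_schedule:
        if label not in ACTIVITY_CLASSES:
            raise ValueError(f"unknown activity label {label!r}")
        if dur <= 0:
            raise ValueError("schedule durations must be positive")

    fs = config.sampling_rate_hz
    bounds = np.concatenate([[0.0], np.cumsum([d for _, d in config.activity_schedule])])
    total = float(bounds[-1])
    n = int(round(total * fs))
    t = np.arange(n) / fs
    labels = [lbl for lbl, _ in config.activity_schedule]

    truth = GroundTruth(
        activity_bouts=[
            ActivityBout(lbl, float(bounds[i]), float(bounds[i + 1]))
            for i, lbl in enumerate(labels)
        ]
    )

    lo = config.sit_level_g
    thigh_levels = dict(THIGH_CC_LEVELS, sit=lo, stand=config.stand_level_g)
    thigh_cc = np.empty(n)
    chest_cc = np.empty(n)
    for i, lbl in enumerate(labels):
        i0, i1 = int(round(bounds[i] * fs)), int(round(bounds[i + 1] * fs))
        thigh_cc[i0:i1] = thigh_levels[lbl]
        chest_cc[i0:i1] = CHEST_CC_LEVELS[lbl]

    d_up = float(np.atleast_1d(config.si_st_duration_s)[0])
    d_down = float(np.atleast_1d(config.st_si_duration_s)[0])

    # smooth every boundary; record transitions at upright<->sit boundaries
    for i in range(1, len(labels)):
        prev, nxt = labels[i - 1], labels[i]
        if prev == nxt:
            continue
        tb = float(bounds[i])
        if prev in UPRIGHT_LABELS and nxt == "sit":
            dur, kind = d_down, "st_si"
        elif prev == "sit" and nxt in UPRIGHT_LABELS:
            dur, kind = d_up, "si_st"
        else:
            dur, kind = 1.5, None
        half = dur / 2
        start = max(0.0, tb - half)
        end = min(total, tb + half)
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        u = _smoothstep((t[i0:i1] - start) / max(end - start, 1e-9))
        for arr, levels in ((thigh_cc, thigh_levels), (chest_cc, CHEST_CC_LEVELS)):
            a, b = levels[prev], levels[nxt]
            arr[i0:i1] = a + (b - a) * u
        if kind is not None:
            truth.transitions.append(TruthTransition(kind, start, end))

    rng = np.random.default_rng(config.seed)
    thigh_dyn = np.zeros((n, 3))
    chest_dyn = np.zeros((n, 3))

    # per-label dynamics
    for i, lbl in enumerate(labels):
        i0, i1 = int(round(bounds[i] * fs)), int(round(bounds[i + 1] * fs))
        seg_t = t[i0:i1]
        if lbl == "walk":
            phase = rng.uniform(0, 2 * np.pi)
            gait = np.sin(2 * np.pi * 1.8 * seg_t + phase)
            thigh_dyn[i0:i1, 0] += 0.25 * gait
            thigh_dyn[i0:i1, 2] += 0.20 * gait
            chest_dyn[i0:i1, 0] += 0.10 * gait
            chest_dyn[i0:i1, 2] += 0.08 * gait
        elif lbl == "other":
            thigh_dyn[i0:i1] += rng.normal(0.0, 0.30, size=(i1 - i0, 3))
            chest_dyn[i0:i1] += rng.normal(0.0, 0.30, size=(i1 - i0, 3))

    # transient bursts at embedded transitions
    if config.burst_amplitude_g > 0:
        for tr in truth.transitions:
            width = max(0.05, 0.1 * tr.duration_s)
            sel = (t > tr.mid_s - 4 * width) & (t < tr.mid_s + 4 * width)
            for dyn, scale in ((thigh_dyn, 1.0), (chest_dyn, 0.6)):
                for ax in range(3):
                    dyn[sel, ax] += _burst(
                        t[sel],
                        tr.mid_s,
                        scale * config.burst_amplitude_g * rng.uniform(0.6, 1.0),
                        rng.uniform(7.0, 14.0),
                        rng.uniform(0, 2 * np.pi),
                        width,
                    )

    thigh = _assemble_site(thigh_cc, thigh_dyn, config, rng, "thigh")
    chest = _assemble_site(chest_cc, chest_dyn, config, rng, "chest")
    return {"thigh": thigh, "chest": chest}, truth


def random_daily_schedule(
    total_s: float,
    rng: np.random.Generator,
    night_every_s: float = 16 * 3600.0,
    night_s: float = 8 * 3600.0,
) -> list[tuple[str, float]]:
    """Plausible free-living schedule: stand/walk/sit cycles with nightly lying.

    Sitting bouts are drawn between 40 s and 15 min so they all clear the
    30 s extraction gate; stands flanking them are at least 25 s so
    candidate windows at consecutive bout boundaries never overlap.
    """
    schedule: list[tuple[str, float]] = []
    elapsed = 0.0
    since_night = 0.0

    def push(label: str, dur: float) -> None:
        nonlocal elapsed, since_night
        dur = min(dur, total_s - elapsed)
        if dur > 0:
            schedule.append((label, float(dur)))
            elapsed += dur
            since_night += dur

    while elapsed < total_s:
        if since_night >= night_every_s:
            # sit on the bed edge before and after lying, as people do;
            # keeps every thigh-orientation change at a sit boundary
            push("stand", rng.uniform(30, 60))
            push("sit", rng.uniform(60, 120))
            push("lie", night_s)
            push("sit", rng.uniform(60, 120))
            push("stand", rng.uniform(30, 60))
            since_night = 0.0
            continue
        push("stand", rng.uniform(25, 90))
        push("sit", rng.uniform(40, 900))
        push("stand", rng.uniform(25, 90))
        push("walk", rng.uniform(60, 240))
        if rng.random() < 0.15:
            push("other", rng.uniform(30, 120))
            push("walk", rng.uniform(30, 90))
    return schedule


DEFAULT_AGE_PARAMS = {0: (44.7, 12.4), 1: (55.2, 10.3)}


def generate_cohort(
    n_group_a: int,
    n_group_b: int,
    feature_effect_sizes: dict[str, float] | None = None,
    age_params: dict[int, tuple[float, float]] | None = None,
    seed: int = 0,
    n_null_features: int = 0,
    confounded_features: Sequence[str] = (),
    confounder_slope: float = 0.7,
    feature_names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-group cohort with configured per-feature effect sizes.

    Each named feature is unit-variance Gaussian; groups are shifted by
    ``d`` pooled standard deviations for the features named in
    ``feature_effect_sizes`` (0 for the ``n_null_features`` additional null
    features).  Ages are drawn per group from ``age_params`` (mean, SD in
    years; defaults resemble an MS fall-risk cohort where the impaired
    group is older).  Features listed in ``confounded_features`` are driven
    by age alone (slope ``confounder_slope`` on standardised age, unit
    total variance): with age-shifted groups they separate the groups
    without any direct group effect, which is the scenario a
    covariate-adjusted AUC must neutralise.

    Returns ``(participants, features)``: a participant table
    (id, age_years, group) and a feature table indexed by participant id.
    """
    if n_group_a < 2 or n_group_b < 2:
        raise ValueError("need at least 2 participants per group")
    effects = dict(feature_effect_sizes or {})
    if feature_names is not None:
        names = list(feature_names)
        unknown = set(effects) - set(names)
        if unknown:
            raise ValueError(
                f"effect size specified for unknown features: {sorted(unknown)}"
            )
    else:
        names = list(effects)
    names += [f"null_{i:03d}" for i in range(n_null_features)]
    for cname in confounded_features:
        if cname not in names:
            names.append(cname)
    if not names:
        raise ValueError("no features requested")
    ages_spec = age_params or DEFAULT_AGE_PARAMS

    rng = np.random.default_rng(seed)
    groups = np.concatenate([np.zeros(n_group_a, dtype=int), np.ones(n_group_b, dtype=int)])
    n = groups.size
    ids = [f"P{i:04d}" for i in range(n)]
    ages = np.array([rng.normal(*ages_spec[g]) for g in groups])
    age_z = (ages - ages.mean()) / ages.std(ddof=1)

    columns = {}
    for name in names:
        if name in confounded_features:
            resid_sd = float(np.sqrt(max(1.0 - confounder_slope**2, 1e-6)))
            columns[name] = confounder_slope * age_z + rng.normal(0.0, resid_sd, size=n)
        else:
            d = effects.get(name, 0.0)
            shift = np.where(groups == 1, d / 2.0, -d / 2.0)
            columns[name] = shift + rng.normal(0.0, 1.0, size=n)

    participants = pd.DataFrame({"id": ids, "age_years": ages, "group": groups})
    features = pd.DataFrame(columns, index=pd.Index(ids, name="id"))
    return participants, features


def cohort_simulation_configs(
    n_group_a: int,
    n_group_b: int,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
    group_b_duration_scale: float = 1.3,
) -> tuple[pd.DataFrame, dict[str, SimulationConfig]]:
    """Per-participant stream configs for an end-to-end cohort run.

    Group B (the impaired group) transitions ``group_b_duration_scale``
    times slower, which propagates into slower si-st/st-si times and fewer
    repetitions -- the qualitative structure of an impaired cohort.
    """
    base = base_config or SimulationConfig()
    rng = np.random.default_rng(seed)
    groups = np.concatenate([np.zeros(n_group_a, dtype=int), np.ones(n_group_b, dtype=int)])
    ids = [f"P{i:04d}" for i in range(groups.size)]
    ages = np.array([rng.normal(*DEFAULT_AGE_PARAMS[g]) for g in groups])
    configs = {}
    for pid, g in zip(ids, groups):
        scale = group_b_duration_scale if g == 1 else 1.0
        jitter = rng.uniform(0.9, 1.1)
        configs[pid] = replace(
            base,
            seed=int(rng.integers(0, 2**31 - 1)),
            si_st_duration_s=float(np.atleast_1d(base.si_st_duration_s)[0] * scale * jitter),
            st_si_duration_s=float(np.atleast_1d(base.st_si_duration_s)[0] * scale * jitter),
        )
    participants = pd.DataFrame({"id": ids, "age_years": ages, "group": groups})
    return participants, configs
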