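"""Free-living sit<->stand transition detection with validation gates.

Sitting bouts longer than 30 s (strict) are extracted from the classified
bout sequence.  Around each bout boundary an 18 s candidate window is cut
(9 s either side): the bout start is a stand-to-sit candidate, the bout
end a sit-to-stand candidate.  Within each window the thigh CC component
is low-pass filtered (3rd-order Butterworth, 0.4 Hz) and the sit/stand
events closest to the transition point are located; the candidate is kept
only if all three validation gates pass:

1. the filtered CC crosses 0.5 g within the window,
2. the filtered CC spans more than 0.5 g of total range, and
3. the sit-to-stand (or stand-to-sit) duration is less than 4.5 s.

Rejections are returned as reason-coded results rather than errors so that
every discarded window is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ActivityBout, AnatomicalSignal, TransitionEvent
from .cst import split_halves
from .signal_prep import butterworth_lowpass

MIN_SITTING_BOUT_S = 30.0
WINDOW_HALF_SPAN_S = 9.0
LPF_CUTOFF_HZ = 0.4
CROSSING_G = 0.5
MIN_RANGE_G = 0.5
MAX_DURATION_S = 4.5

#: Fraction of the anchor slope that delimits the transition region; the
#: sit/stand extrema are the points where the filtered CC leaves/rejoins
#: its plateaus around the transition.
SLOPE_FRACTION = 0.1
#: Absolute floor (g/s) below which no transition-like motion exists.
MIN_SLOPE_G_PER_S = 0.05


@dataclass
class CandidateWindow:
    """An 18 s raw-data window around one sitting-bout boundary."""

    center_time_s: float
    start_index: int
    stop_index: int
    boundary_kind: str  # "bout_start" (st_si candidate) | "bout_end" (si_st candidate)
    truncated: bool = False
    bout_index: int | None = None

    @property
    def expected_type(self) -> str:
        return "st_si" if self.boundary_kind == "bout_start" else "si_st"


@dataclass
class ValidationResult:
    passed: bool
    reasons: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.reasons = frozenset(self.reasons)
        allowed = {"no_halfg_crossing", "insufficient_range", "too_long", "no_extrema"}
        if not self.reasons <= allowed:
            raise ValueError(f"unknown rejection reasons {self.reasons - allowed}")
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be equivalent to an empty reason set")


def extract_sitting_bouts(
    bouts: list[ActivityBout], min_s: float = MIN_SITTING_BOUT_S
) -> list[ActivityBout]:
    """Sitting bouts strictly longer than ``min_s``, order preserved."""
    return [b for b in bouts if b.label == "sit" and b.duration_s > min_s]


def make_candidate_windows(
    sitting_bouts: list[ActivityBout],
    thigh: AnatomicalSignal,
    half_span_s: float = WINDOW_HALF_SPAN_S,
) -> list[CandidateWindow]:
    """Two candidate windows per interior sitting bout.

    Boundaries coinciding with the stream edges produce no window (no
    transition can exist there); windows that merely extend past an edge
    are truncated and flagged.
    """
    fs = thigh.sampling_rate_hz
    n = thigh.n_samples
    total_s = n / fs
    windows: list[CandidateWindow] = []
    for bi, bout in enumerate(sitting_bouts):
        if bout.start_s < 0 or bout.end_s > total_s + 1e-9:
            raise ValueError(f"sitting bout {bi} lies outside the recording")
        for boundary, kind in ((bout.start_s, "bout_start"), (bout.end_s, "bout_end")):
            if boundary <= 1.0 / fs or boundary >= total_s - 1.0 / fs:
                continue
            i0 = int(round((boundary - half_span_s) * fs))
            i1 = i0 + int(round(2 * half_span_s * fs))
            truncated = i0 < 0 or i1 > n
            windows.append(
                CandidateWindow(
                    center_time_s=float(boundary),
                    start_index=max(0, i0),
                    stop_index=min(n, i1),
                    boundary_kind=kind,
                    truncated=truncated,
                    bout_index=bi,
                )
            )
    return windows


def _transition_region(
    lpf: np.ndarray, fs: float, center_offset: int
) -> tuple[int, int] | None:
    """Bounds of the transition region inside one filtered window.

    The anchor is the 0.5 g crossing nearest the window centre (falling
    back to the steepest sample); the region extends while the signed
    slope stays above ``SLOPE_FRACTION`` of the anchor-direction peak
    slope.  Returns None when no transition-like motion is present.
    """
    slope = np.gradient(lpf) * fs
    signs = np.sign(lpf - CROSSING_G)
    crossings = np.flatnonzero(signs[:-1] * signs[1:] <= 0)
    if crossings.size:
        anchor = int(crossings[np.argmin(np.abs(crossings - center_offset))])
    else:
        anchor = int(np.argmax(np.abs(slope)))
    direction = np.sign(slope[anchor])
    if direction == 0:
        return None
    directed = direction * slope
    peak = directed[max(0, anchor - int(fs)) : anchor + int(fs) + 1].max()
    if peak < MIN_SLOPE_G_PER_S:
        return None
    thresh = SLOPE_FRACTION * peak
    lo = anchor
    while lo > 0 and directed[lo - 1] >= thresh:
        lo -= 1
    hi = anchor
    while hi < directed.size - 1 and directed[hi + 1] >= thresh:
        hi += 1
    if hi - lo < 2:
        return None
    return lo, hi


def _fit_ramp(
    lpf: np.ndarray, fs: float, lo: int, hi: int, lpf_cutoff_hz: float
) -> tuple[float, float] | None:
    """Deconvolved (center_s, duration_s) of the transition ramp.

    The 0.4 Hz low-pass broadens any ramp by roughly the filter rise time,
    so the raw extremum-to-extremum span reads high for short transitions.
    A smooth cubic ramp (the assumed sit<->stand kinematic shape) of
    unknown centre and duration is passed through the *same* filter and
    least-squares fitted to the observed window; the fitted duration is the
    instrument-corrected transition time.  Returns None on degenerate fits.
    """
    from scipy.optimize import minimize_scalar

    t = np.arange(lpf.size) / fs
    pre = lpf[max(0, lo - int(2 * fs)) : lo]
    post = lpf[hi : hi + int(2 * fs)]
    a = float(np.median(pre)) if pre.size else float(lpf[lo])
    b = float(np.median(post)) if post.size else float(lpf[hi])
    if abs(b - a) < 1e-6:
        return None
    # centre: crossing of the mid level nearest the region centre
    level = 0.5 * (a + b)
    signs = np.sign(lpf - level)
    crossings = np.flatnonzero(signs[:-1] * signs[1:] <= 0)
    if crossings.size == 0:
        return None
    region_mid = 0.5 * (lo + hi)
    c = float(t[int(crossings[np.argmin(np.abs(crossings - region_mid))])])

    fit_lo = max(0, lo - int(2 * fs))
    fit_hi = min(lpf.size, hi + int(2 * fs))
    obs = lpf[fit_lo:fit_hi]

    def residual(d: float) -> float:
        u = np.clip((t - c) / d + 0.5, 0.0, 1.0)
        model = a + (b - a) * (u * u * (3.0 - 2.0 * u))
        model_f = butterworth_lowpass(model, lpf_cutoff_hz, fs)
        return float(np.sum((model_f[fit_lo:fit_hi] - obs) ** 2))

    res = minimize_scalar(residual, bounds=(2.0 / fs, 10.0), method="bounded",
                          options={"xatol": 1e-3})
    if not res.success:
        return None
    return c, float(res.x)


def detect_and_validate(
    window: CandidateWindow,
    thigh: AnatomicalSignal,
    lpf_cutoff_hz: float = LPF_CUTOFF_HZ,
    crossing_g: float = CROSSING_G,
    min_range_g: float = MIN_RANGE_G,
    max_duration_s: float = MAX_DURATION_S,
) -> tuple[TransitionEvent | None, ValidationResult]:
    """Detect a transition in one candidate window and apply the gates.

    All gates are always evaluated so that the rejection reasons are
    complete (the audit trail replacing manual inspection).  The returned
    event's indices refer to the full stream.
    """
    fs = thigh.sampling_rate_hz
    seg = thigh.cc[window.start_index : window.stop_index]
    if seg.size < int(2 * fs):
        return None, ValidationResult(False, frozenset({"no_extrema"}))
    lpf = butterworth_lowpass(seg, lpf_cutoff_hz, fs)

    reasons: set[str] = set()
    signs = np.sign(lpf - crossing_g)
    if not np.any(signs[:-1] * signs[1:] <= 0) or np.all(signs == signs[0]):
        reasons.add("no_halfg_crossing")
    if float(lpf.max() - lpf.min()) <= min_range_g:
        reasons.add("insufficient_range")

    center_offset = int(round(window.center_time_s * fs)) - window.start_index
    center_offset = int(np.clip(center_offset, 0, seg.size - 1))
    region = _transition_region(lpf, fs, center_offset)
    if region is None:
        reasons.add("no_extrema")
        return None, ValidationResult(False, frozenset(reasons))

    lo, hi = region
    fit = _fit_ramp(lpf, fs, lo, hi, lpf_cutoff_hz)
    if fit is not None:
        center_s, duration = fit
        lo = int(np.clip(round((center_s - duration / 2) * fs), 0, seg.size - 2))
        hi = int(np.clip(round((center_s + duration / 2) * fs), lo + 2, seg.size - 1))
        duration = (hi - lo) / fs
    else:
        duration = (hi - lo) / fs
    if duration >= max_duration_s:
        reasons.add("too_long")

    if reasons:
        return None, ValidationResult(False, frozenset(reasons))

    rising = lpf[hi] > lpf[lo]
    sit_local, stand_local = (lo, hi) if rising else (hi, lo)
    kind = "si_st" if rising else "st_si"
    mid_local, flat = split_halves(lo, hi, lpf)
    off = window.start_index
    event = TransitionEvent(
        type=kind,
        sit_index=off + sit_local,
        stand_index=off + stand_local,
        mid_index=off + mid_local,
        duration_s=duration,
        half1=(off + lo, off + mid_local),
        half2=(off + mid_local, off + hi),
        context="daily_life",
        sampling_rate_hz=fs,
        flags=(["flat_midpoint"] if flat else [])
        + (["type_mismatch"] if kind != window.expected_type else [])
        + (["truncated_window"] if window.truncated else []),
    )
    return event, ValidationResult(True, frozenset())


@dataclass
class RejectionLogEntry:
    window_index: int
    center_time_s: float
    boundary_kind: str
    reasons: tuple[str, ...]


def detect_daily_transitions(
    bouts: list[ActivityBout],
    thigh: AnatomicalSignal,
    min_sitting_s: float = MIN_SITTING_BOUT_S,
) -> tuple[list[TransitionEvent], list[RejectionLogEntry]]:
    """Full free-living detection: bouts -> candidates -> gated events.

    Returns the accepted events and a reason-coded rejection log with one
    entry per rejected window.
    """
    sitting = extract_sitting_bouts(bouts, min_s=min_sitting_s)
    windows = make_candidate_windows(sitting, thigh)
    events: list[TransitionEvent] = []
    rejections: list[RejectionLogEntry] = []
    for wi, window in enumerate(windows):
        event, result = detect_and_validate(window, thigh)
        if event is not None:
            events.append(event)
        else:
            rejections.append(
                RejectionLogEntry(
                    window_index=wi,
                    center_time_s=window.center_time_s,
                    boundary_kind=window.boundary_kind,
                    reasons=tuple(sorted(result.reasons)),
                )
            )
    return events, rejections


def recheck_gates(event: TransitionEvent, thigh: AnatomicalSignal) -> bool:
    """Re-assert the three validation gates on a stored accepted event."""
    fs = thigh.sampling_rate_hz
    center = 0.5 * (event.start_index + event.end_index) / fs
    half = int(round(WINDOW_HALF_SPAN_S * fs))
    mid = int(round(center * fs))
    i0, i1 = max(0, mid - half), min(thigh.n_samples, mid + half)
    lpf = butterworth_lowpass(thigh.cc[i0:i1], LPF_CUTOFF_HZ, fs)
    signs = np.sign(lpf - CROSSING_G)
    crosses = bool(np.any(signs[:-1] * signs[1:] <= 0)) and not np.all(signs == signs[0])
    has_range = float(lpf.max() - lpf.min()) > MIN_RANGE_G
    short_enough = event.duration_s < MAX_DURATION_S
    return crosses and has_range and short_enough


def score_against_truth(
    events: list[TransitionEvent],
    truth_transitions,
    tolerance_s: float = 2.5,
    max_truth_duration_s: float | None = None,
) -> dict:
    """Sensitivity/precision of accepted events against generator truth.

    Matching is greedy on type and mid-transition time.  Truth transitions
    longer than ``max_truth_duration_s`` (if given) are excluded from the
    sensitivity denominator, mirroring the detector's duration gate.
    """
    truth = [
        t
        for t in truth_transitions
        if max_truth_duration_s is None or t.duration_s <= max_truth_duration_s
    ]
    used: set[int] = set()
    matched = 0
    for ev in events:
        best, best_dt = None, tolerance_s
        for ti, tr in enumerate(truth):
            if ti in used or tr.type != ev.type:
                continue
            dt = abs(ev.mid_time_s - tr.mid_s)
            if dt <= best_dt:
                best, best_dt = ti, dt
        if best is not None:
            used.add(best)
            matched += 1
    sensitivity = matched / len(truth) if truth else float("nan")
    precision = matched / len(events) if events else float("nan")
    return {
        "n_truth": len(truth),
        "n_detected": len(events),
        "n_matched": matched,
        "sensitivity": sensitivity,
        "precision": precision,
    }
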