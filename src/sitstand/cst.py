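"""Delineation of 30-second chair stand tests from the thigh CC component.

The thigh cranial-caudal gravity component alternates between a sitting
level (~0 g, thigh horizontal) and a standing level (~1 g, thigh vertical)
once per repetition.  The series is low-pass filtered at the trial's
dominant frequency (the repetition rate), stand events are identified as
prominent local maxima of the filtered CC, and sit events as the refined
minimum of each inter-stand segment (including the segments before the
first and after the last stand, when they dip deep enough).  This
construction enforces the alternating sit/stand grammar directly: events
are the consecutive (sit, stand) and (stand, sit) pairs.

The mid-transition point of each event is the first crossing of the
50%-amplitude level between its sit and stand extrema, and splits the
event into its two halves.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import AnatomicalSignal, CSTTrial, NoDominantFrequencyError, TransitionEvent
from .signal_prep import butterworth_lowpass, dominant_frequency

#: Minimum prominence (g) a filtered-CC maximum must have to count as a
#: stand.  Robust against residual ripple after the dominant-frequency LPF.
MIN_PROMINENCE_G = 0.2
#: Minimum separation between stand peaks (s).
MIN_PEAK_SEPARATION_S = 1.0


def _refined_extremum(segment: np.ndarray, offset: int, kind: str) -> int:
    """Index of a segment's extremum, taking the middle of a flat plateau.

    On noiseless signals the initial/final sitting phases are exactly flat;
    the representative sit sample is then the plateau centre rather than an
    arbitrary first occurrence.
    """
    vals = segment if kind == "max" else -segment
    best = vals.max()
    near = np.flatnonzero(vals >= best - 1e-9)
    # restrict to the contiguous run containing the argmax
    arg = int(np.argmax(vals))
    left = right = int(np.searchsorted(near, arg))
    while left > 0 and near[left - 1] == near[left] - 1:
        left -= 1
    while right < near.size - 1 and near[right + 1] == near[right] + 1:
        right += 1
    return offset + int((near[left] + near[right]) // 2)


def split_halves(
    start_index: int,
    end_index: int,
    cc_lpf: np.ndarray,
) -> tuple[int, bool]:
    """Mid-transition index: first 50%-amplitude crossing from start to end.

    Returns ``(mid_index, flat_fallback)``.  If the segment never crosses
    the midpoint value (degenerate flat segment) the temporal midpoint is
    used and flagged.
    """
    lo, hi = int(start_index), int(end_index)
    if not 0 <= lo < hi < len(cc_lpf):
        raise ValueError("event indices out of range")
    target = 0.5 * (cc_lpf[lo] + cc_lpf[hi])
    seg = cc_lpf[lo : hi + 1] - target
    if np.all(np.abs(seg) < 1e-12):
        return lo + (hi - lo) // 2, True
    signs = np.sign(seg)
    crossings = np.flatnonzero(signs[:-1] * signs[1:] < 0)
    exact = np.flatnonzero(signs[1:-1] == 0)
    candidates = []
    if crossings.size:
        candidates.append(crossings[0] + 1)
    if exact.size:
        candidates.append(exact[0] + 1)
    if candidates:
        mid = lo + int(min(candidates))
        return int(np.clip(mid, lo + 1, hi - 1)), False
    return lo + (hi - lo) // 2, True


def _build_event(
    kind: str,
    sit_index: int,
    stand_index: int,
    cc_lpf: np.ndarray,
    fs: float,
    context: str,
) -> TransitionEvent:
    lo, hi = min(sit_index, stand_index), max(sit_index, stand_index)
    mid, flat = split_halves(lo, hi, cc_lpf)
    return TransitionEvent(
        type=kind,
        sit_index=int(sit_index),
        stand_index=int(stand_index),
        mid_index=mid,
        duration_s=(hi - lo) / fs,
        half1=(lo, mid),
        half2=(mid, hi),
        context=context,
        sampling_rate_hz=fs,
        flags=["flat_midpoint"] if flat else [],
    )


def _mirror_boundary_sit(
    event: TransitionEvent,
    lpf: np.ndarray,
    fs: float,
    context: str,
    level: float | None,
) -> TransitionEvent:
    """Re-estimate a boundary event's sit and mid indices.

    The first and last sit phases of a trial extend to the recording edge,
    where the filtered minimum is both an edge artifact and far deeper than
    the interior sit minima (the long static plateau passes the low-pass
    filter unattenuated).  The stand extremum is interior and reliable, so:
    the mid-transition is recomputed as the first crossing of the trial's
    median 50% amplitude ``level`` (instead of the event's own, biased,
    midpoint value), and the sit sample is the stand mirrored through that
    mid under the ramp-symmetry assumption.
    """
    lo0, hi0 = event.start_index, event.end_index
    mid = event.mid_index
    if level is not None:
        seg = lpf[lo0 : hi0 + 1] - level
        signs = np.sign(seg)
        crossings = np.flatnonzero(signs[:-1] * signs[1:] <= 0)
        if crossings.size:
            mid = lo0 + int(crossings[0]) + 1
    mirrored = 2 * mid - event.stand_index
    mirrored = int(np.clip(mirrored, 0, lpf.size - 1))
    lo, hi = min(mirrored, event.stand_index), max(mirrored, event.stand_index)
    if hi - lo < 3:
        return event
    mid = int(np.clip(mid, lo + 1, hi - 1))
    return TransitionEvent(
        type=event.type,
        sit_index=mirrored,
        stand_index=event.stand_index,
        mid_index=mid,
        duration_s=(hi - lo) / fs,
        half1=(lo, mid),
        half2=(mid, hi),
        context=context,
        sampling_rate_hz=fs,
        flags=event.flags + ["mirrored_boundary"],
    )


def delineate_cst(
    thigh: AnatomicalSignal,
    chest: AnatomicalSignal | None = None,
    context: str = "supervised_cst",
    min_prominence_g: float = MIN_PROMINENCE_G,
    min_separation_s: float = MIN_PEAK_SEPARATION_S,
    edge_exclude_s: float = 0.0,
) -> CSTTrial:
    """Segment a chair-stand trial into si-st and st-si transitions.

    Returns an empty trial flagged ``"no_repetitions"`` when no repetition
    structure is present (no dominant frequency, or no prominent stand
    peak), rather than raising.
    """
    fs = thigh.sampling_rate_hz
    cc = thigh.cc
    try:
        f0 = dominant_frequency(cc, fs)
    except (NoDominantFrequencyError, ValueError):
        return CSTTrial(events=[], repetition_count=0, thigh=thigh, chest=chest,
                        flags=["no_repetitions"])
    lpf = butterworth_lowpass(cc, f0, fs)

    distance = max(1, int(round(min_separation_s * fs)))
    stands, _ = sps.find_peaks(lpf, prominence=min_prominence_g, distance=distance)
    if edge_exclude_s > 0:
        margin = int(round(edge_exclude_s * fs))
        stands = stands[(stands >= margin) & (stands < lpf.size - margin)]
    if stands.size == 0:
        return CSTTrial(events=[], repetition_count=0, thigh=thigh, chest=chest,
                        flags=["no_repetitions"], lpf_cc=lpf, dominant_frequency_hz=f0)

    # sit candidates: one refined minimum per segment between/around stands
    boundaries = np.concatenate([[0], stands, [lpf.size]])
    n_seg = len(boundaries) - 1
    sits: list[int | None] = []
    for i in range(n_seg):
        lo, hi = int(boundaries[i]), int(boundaries[i + 1])
        if hi - lo < 2:
            sits.append(None)
            continue
        seg = lpf[lo:hi]
        idx = _refined_extremum(seg, lo, "min")
        # a sit must dip at least the prominence below the adjacent stand,
        # otherwise the segment is a partial repetition (e.g. a rise cut off
        # by the end of the test)
        neighbor = stands[i] if i < stands.size else stands[i - 1]
        depth = lpf[neighbor] - lpf[idx]
        if depth < min_prominence_g:
            sits.append(None)
            continue
        if i == 0 or i == n_seg - 1:
            # boundary segments end at the recording edge, where the filtered
            # minimum is an edge artifact; snap to the plateau-departure
            # sample nearest the adjacent stand instead
            band = lpf[idx] + 0.05 * depth
            in_band = np.flatnonzero(seg <= band)
            idx = lo + int(in_band[-1] if i == 0 else in_band[0])
        sits.append(int(idx))

    interior_sits = [s for s in sits[1:-1] if s is not None]
    level = None
    if interior_sits:
        level = 0.5 * (
            float(np.median(lpf[interior_sits])) + float(np.median(lpf[stands]))
        )

    events: list[TransitionEvent] = []
    for i, stand in enumerate(stands):
        before, after = sits[i], sits[i + 1]
        if before is not None and int(stand) - before >= 3:
            ev = _build_event("si_st", before, int(stand), lpf, fs, context)
            if i == 0:
                ev = _mirror_boundary_sit(ev, lpf, fs, context, level)
            events.append(ev)
        if after is not None and after - int(stand) >= 3:
            ev = _build_event("st_si", after, int(stand), lpf, fs, context)
            if i == stands.size - 1:
                ev = _mirror_boundary_sit(ev, lpf, fs, context, level)
            events.append(ev)

    events.sort(key=lambda e: e.start_index)
    repetition_count = sum(1 for e in events if e.type == "si_st")
    flags = [] if repetition_count else ["no_repetitions"]
    return CSTTrial(
        events=events,
        repetition_count=repetition_count,
        thigh=thigh,
        chest=chest,
        flags=flags,
        lpf_cc=lpf,
        dominant_frequency_hz=f0,
    )


def match_events_to_truth(
    events,
    truth_transitions,
    tolerance_s: float = 0.3,
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of detected events to ground truth.

    Events and truth transitions are matched by type and mid-transition
    time (the 50%-crossing time is the most filter-invariant landmark of a
    transition).  Returns (event_position, truth_position) pairs.
    """
    pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    for ei, ev in enumerate(events):
        best, best_dt = None, tolerance_s
        for ti, tr in enumerate(truth_transitions):
            if ti in used or tr.type != ev.type:
                continue
            dt = abs(ev.mid_time_s - tr.mid_s)
            if dt <= best_dt:
                best, best_dt = ti, dt
        if best is not None:
            used.add(best)
            pairs.append((ei, best))
    return pairs
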