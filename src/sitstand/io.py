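"""CSV interchange formats, configuration and run manifests.

All interchange is plain CSV with headers (no wearable-vendor format is
assumed): raw recordings (``time_s, ax_g, ay_g, az_g``), aligned signals
(``time_s, ap_g, ml_g, cc_g``), event tables, bout tables, ground-truth
annotations and wide feature tables.  Timestamps are seconds from stream
start; wall-clock information, if any, lives in the run manifest only.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import AccelerometerRecording, ActivityBout, AnatomicalSignal, TransitionEvent

RAW_COLUMNS = ["time_s", "ax_g", "ay_g", "az_g"]
ALIGNED_COLUMNS = ["time_s", "ap_g", "ml_g", "cc_g"]
JITTER_TOLERANCE = 0.01


def write_recording(rec: AccelerometerRecording, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "time_s": rec.times,
            "ax_g": rec.samples[:, 0],
            "ay_g": rec.samples[:, 1],
            "az_g": rec.samples[:, 2],
        }
    )
    frame.to_csv(path, index=False)


def read_recording(
    path: str | Path, site: str = "thigh", expected_fs: float | None = None
) -> AccelerometerRecording:
    """Read and validate a raw recording CSV.

    Rejects NaN rows and duplicated timestamps (naming the row), and
    non-uniform sampling beyond 1% jitter.  The sampling rate is inferred
    from the median time step and, when ``expected_fs`` is given, checked
    against it with the same 1% tolerance.
    """
    frame = pd.read_csv(path)
    missing = [c for c in RAW_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = frame[RAW_COLUMNS].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"{path}: NaN values at row {int(np.flatnonzero(bad)[0])}")
    t = frame["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    dup = np.flatnonzero(dt <= 0)
    if dup.size:
        raise ValueError(f"{path}: non-increasing timestamp at row {int(dup[0]) + 1}")
    median_dt = float(np.median(dt))
    if np.max(np.abs(dt - median_dt)) > JITTER_TOLERANCE * median_dt:
        raise ValueError(f"{path}: non-uniform sampling beyond {JITTER_TOLERANCE:.0%} jitter")
    fs = 1.0 / median_dt
    if expected_fs is not None and abs(fs - expected_fs) > JITTER_TOLERANCE * expected_fs:
        raise ValueError(f"{path}: inferred rate {fs:.3f} Hz != configured {expected_fs} Hz")
    samples = frame[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    return AccelerometerRecording(
        site=site, sampling_rate_hz=fs, samples=samples, start_time=float(t[0])
    )


def write_aligned(sig: AnatomicalSignal, path: str | Path) -> None:
    t = np.arange(sig.n_samples) / sig.sampling_rate_hz
    pd.DataFrame(
        {"time_s": t, "ap_g": sig.ap, "ml_g": sig.ml, "cc_g": sig.cc}
    ).to_csv(path, index=False)


def read_aligned(path: str | Path) -> AnatomicalSignal:
    frame = pd.read_csv(path)
    missing = [c for c in ALIGNED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    t = frame["time_s"].to_numpy(dtype=float)
    fs = 1.0 / float(np.median(np.diff(t)))
    return AnatomicalSignal(
        ap=frame["ap_g"].to_numpy(float),
        ml=frame["ml_g"].to_numpy(float),
        cc=frame["cc_g"].to_numpy(float),
        sampling_rate_hz=fs,
    )


def events_frame(events: list[TransitionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "type": e.type,
                "sit_time_s": e.sit_time_s,
                "stand_time_s": e.stand_time_s,
                "mid_time_s": e.mid_time_s,
                "duration_s": e.duration_s,
                "context": e.context,
                "flags": ";".join(e.flags),
            }
            for e in events
        ],
        columns=["type", "sit_time_s", "stand_time_s", "mid_time_s", "duration_s",
                 "context", "flags"],
    )


def bouts_frame(bouts: list[ActivityBout]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"label": b.label, "start_s": b.start_s, "end_s": b.end_s} for b in bouts],
        columns=["label", "start_s", "end_s"],
    )


def read_bouts(path: str | Path) -> list[ActivityBout]:
    frame = pd.read_csv(path)
    return [
        ActivityBout(str(r.label), float(r.start_s), float(r.end_s))
        for r in frame.itertuples()
    ]


def write_report(results: pd.DataFrame, path: str | Path) -> None:
    """Screened-feature report CSV, sorted by adjusted AUC."""
    out = results.copy()
    if not out.empty and "auc_adjusted" in out.columns:
        out = out.sort_values("auc_adjusted", ascending=False, kind="mergesort")
    out.to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def dump_manifest(manifest, path: str | Path) -> None:
    data = dataclasses.asdict(manifest) if dataclasses.is_dataclass(manifest) else manifest
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")
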