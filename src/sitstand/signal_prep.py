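"""Calibration-based axis alignment and filtering / spectral utilities.

A 30-second quiet-standing recording gives the direction of gravity in
device axes.  During standing the cranial-caudal (CC) anatomical axis is
anti-parallel to gravity, so the measured gravity direction *is* the CC
axis; the rotation about it (sensor heading) is resolved using the nominal
mounting orientation of each site (sensor x approximately anterior for both
the thigh and the chest sensor).  Alignment is a pure rotation and is
therefore norm-preserving sample by sample.

Filtering uses 3rd-order Butterworth IIR designs.  The default is
forward-backward (zero-phase) application so that event indices are not
lag-shifted; note this squares the magnitude response (effective 6th-order
attenuation).  A causal mode is available behind ``zero_phase=False``.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import (
    AccelerometerRecording,
    AnatomicalSignal,
    CalibrationPose,
    CalibrationQualityError,
    NoDominantFrequencyError,
)

#: Nominal anterior direction of each sensor, in device axes.  Used only to
#: resolve the heading ambiguity (rotation about gravity); the CC axis itself
#: comes from the calibration.
NOMINAL_ANTERIOR = {
    "thigh": np.array([1.0, 0.0, 0.0]),
    "chest": np.array([1.0, 0.0, 0.0]),
}

MIN_CALIBRATION_S = 5.0
CALIBRATION_NORM_RANGE = (0.8, 1.2)


def estimate_gravity(calibration: AccelerometerRecording) -> CalibrationPose:
    """Estimate the gravity direction from a static standing trial.

    The gravity unit vector is the normalised mean of the triaxial samples;
    ``mean_norm_g`` is the norm of that mean vector and must fall within
    [0.8, 1.2] g or the calibration is rejected (sensor was moving, or the
    scale is off).
    """
    if calibration.duration_s < MIN_CALIBRATION_S:
        raise ValueError(
            f"calibration must cover at least {MIN_CALIBRATION_S:g} s, "
            f"got {calibration.duration_s:.2f} s"
        )
    mean_vec = calibration.samples.mean(axis=0)
    norm = float(np.linalg.norm(mean_vec))
    lo, hi = CALIBRATION_NORM_RANGE
    if not (lo <= norm <= hi):
        raise CalibrationQualityError(
            f"calibration mean norm {norm:.3f} g outside [{lo}, {hi}] g"
        )
    return CalibrationPose(mean_vec / norm, norm, site=calibration.site)


def _alignment_matrix(pose: CalibrationPose) -> np.ndarray:
    """Rows are the AP, ML, CC unit vectors expressed in device axes."""
    cc = pose.gravity_unit_vector
    if np.linalg.norm(cc) < 1e-12:
        raise ValueError("degenerate calibration pose (zero gravity vector)")
    anterior = NOMINAL_ANTERIOR[pose.site]
    ap = anterior - np.dot(anterior, cc) * cc
    if np.linalg.norm(ap) < 1e-9:
        # gravity happens to lie along the nominal anterior axis; fall back to
        # device y as the heading reference
        fallback = np.array([0.0, 1.0, 0.0])
        ap = fallback - np.dot(fallback, cc) * cc
    ap = ap / np.linalg.norm(ap)
    ml = np.cross(cc, ap)  # right-handed (AP, ML, CC) triad
    return np.vstack([ap, ml, cc])


def align_to_anatomical(
    rec: AccelerometerRecording, pose: CalibrationPose
) -> AnatomicalSignal:
    """Rotate a device-axis recording into anatomical (AP, ML, CC) axes.

    The CC axis is the calibration gravity direction, so a noiseless
    standing segment maps to CC = +1 g, AP = ML = 0 g.
    """
    if rec.site != pose.site:
        raise ValueError(
            f"recording site {rec.site!r} does not match calibration site {pose.site!r}"
        )
    rot = _alignment_matrix(pose)
    anat = rec.samples @ rot.T
    return AnatomicalSignal(
        ap=anat[:, 0], ml=anat[:, 1], cc=anat[:, 2], sampling_rate_hz=rec.sampling_rate_hz
    )


def butterworth_lowpass(
    x: np.ndarray,
    cutoff_hz: float,
    fs: float,
    order: int = 3,
    zero_phase: bool = True,
) -> np.ndarray:
    """3rd-order Butterworth low-pass, same length as the input."""
    x = np.asarray(x, dtype=float)
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={fs / 2}) Hz")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    if zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def butterworth_bandpass(
    x: np.ndarray,
    low_hz: float = 5.0,
    high_hz: float = 20.0,
    fs: float = 250.0,
    order: int = 3,
    zero_phase: bool = True,
) -> np.ndarray:
    """3rd-order Butterworth band-pass (default 5-20 Hz), same length.

    The default band keeps physiologically relevant transient content while
    rejecting DC and the slow orientation changes of the sensor, so features
    computed on the output are insensitive to constant offsets.
    """
    x = np.asarray(x, dtype=float)
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid at fs={fs} Hz (Nyquist {fs / 2} Hz)"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="band", fs=fs, output="sos")
    if zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def dominant_frequency(
    cc: np.ndarray,
    fs: float,
    band_hz: tuple[float, float] = (0.1, 1.5),
    min_band_fraction: float = 0.1,
) -> float:
    """Frequency of the largest spectral peak of ``cc`` within ``band_hz``.

    Used as the participant-specific low-pass cutoff for chair-stand
    delineation: the repetition rate of a 30-second chair stand test falls
    well inside 0.1-1.5 Hz.  The band must carry at least
    ``min_band_fraction`` of the total (mean-removed) power, otherwise the
    series has no meaningful repetition rate and
    :class:`NoDominantFrequencyError` is raised (e.g. pure noise, or a
    monotone drift whose power sits below the band).
    """
    cc = np.asarray(cc, dtype=float)
    if cc.size < 10 * fs:
        raise ValueError("dominant_frequency needs at least 10 s of signal")
    freqs, power = sps.periodogram(cc, fs=fs, detrend="constant")
    lo, hi = band_hz
    in_band = (freqs >= lo) & (freqs <= hi)
    total = float(power[freqs > 0].sum())
    band_power = float(power[in_band].sum())
    if total <= 0 or band_power / total < min_band_fraction or not np.any(in_band):
        raise NoDominantFrequencyError(
            f"no dominant spectral peak in {band_hz} Hz "
            f"(band fraction {band_power / total if total > 0 else 0:.3f})"
        )
    return float(freqs[in_band][np.argmax(power[in_band])])
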