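"""Shared fixtures: aligned synthetic signals and a trained activity classifier."""

from __future__ import annotations

import numpy as np
import pytest

from sitstand.activity import ClassifierConfig, train_classifier, window_stream
from sitstand.signal_prep import align_to_anatomical, estimate_gravity
from sitstand.synthetic import (
    SimulationConfig,
    generate_calibration,
    generate_cst_trial,
    generate_daily_stream,
    random_daily_schedule,
)


def aligned_sites(config, generator):
    """Generate recordings with ``generator`` and align them via calibration."""
    out = generator(config)
    recordings = out[0] if isinstance(out[0], dict) else {"thigh": out[0], "chest": out[1]}
    truth = out[-1]
    signals = {}
    for site, rec in recordings.items():
        pose = estimate_gravity(generate_calibration(config, site))
        signals[site] = align_to_anatomical(rec, pose)
    return signals, truth


@pytest.fixture(scope="session")
def cst_case():
    """Default noiseless 5-repetition chair-stand trial, aligned, with truth."""
    config = SimulationConfig(seed=1, n_repetitions=5, noise_sd_g=0.0)
    signals, truth = aligned_sites(config, generate_cst_trial)
    return config, signals, truth


def make_daily_case(seed, hours, **kwargs):
    schedule = random_daily_schedule(hours * 3600.0, np.random.default_rng(seed))
    config = SimulationConfig(
        seed=seed,
        sampling_rate_hz=62.5,
        activity_schedule=schedule,
        si_st_duration_s=kwargs.pop("si_st_duration_s", 2.0),
        st_si_duration_s=kwargs.pop("st_si_duration_s", 2.0),
        **kwargs,
    )
    signals, truth = aligned_sites(config, generate_daily_stream)
    return config, signals, truth


@pytest.fixture(scope="session")
def daily_classifier():
    """Activity classifier trained on one labelled synthetic hour."""
    _, signals, truth = make_daily_case(7, 1.0)
    labels = truth.per_sample_labels(62.5, signals["thigh"].n_samples)
    windows = window_stream(signals["thigh"], signals["chest"], labels=labels)
    return train_classifier(windows, ClassifierConfig(seed=0))
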