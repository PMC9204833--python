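"""Feature catalogs and aggregation statistics against brute-force oracles."""

import numpy as np
import pytest

from sitstand.core import AnatomicalSignal, CSTTrial, TransitionEvent
from sitstand.features import (
    bandpass_signal,
    daily_catalog,
    daily_life_features,
    peak_min_per_half,
    supervised_catalog,
    supervised_cst_features,
    unsupervised_catalog,
    unsupervised_cst_features,
)

FS = 250.0


def make_signal(cc=None, ap=None, ml=None, seconds=30.0, fs=FS):
    n = int(seconds * fs)
    z = np.zeros(n)
    return AnatomicalSignal(
        ap=z if ap is None else ap, ml=z if ml is None else ml,
        cc=z if cc is None else cc, sampling_rate_hz=fs,
    )


def make_event(kind, t_a, t_b, fs=FS, context="supervised_cst"):
    """Event between times t_a < t_b; sit/stand roles follow the kind."""
    lo, hi = int(t_a * fs), int(t_b * fs)
    mid = (lo + hi) // 2
    sit, stand = (lo, hi) if kind == "si_st" else (hi, lo)
    return TransitionEvent(kind, sit, stand, mid, (hi - lo) / fs,
                           (lo, mid), (mid, hi), context, fs)


def make_trial(si_st_durations, st_si_durations, signal=None):
    signal = signal or make_signal()
    events, cursor = [], 1.0
    for up, down in zip(si_st_durations, st_si_durations):
        events.append(make_event("si_st", cursor, cursor + up))
        cursor += up + 0.3
        events.append(make_event("st_si", cursor, cursor + down))
        cursor += down + 0.3
    return CSTTrial(events=events, repetition_count=len(si_st_durations),
                    thigh=signal, chest=signal)


class TestCatalogs:
    def test_catalog_sizes(self):
        sup = supervised_catalog()
        assert len(sup) == 153
        assert sum(1 for d in sup if d.family == "temporal") == 9
        assert sum(1 for d in sup if d.family == "acceleration") == 144
        assert sum(1 for d in sup if d.sensor == "thigh") == 72
        unsup = unsupervised_catalog()
        assert len(unsup) == 163
        assert sum(1 for d in unsup if d.family == "temporal") == 19
        daily = daily_catalog()
        assert sum(1 for d in daily if d.family == "temporal") == 10
        assert sum(1 for d in daily if d.family == "acceleration") == 192

    def test_descriptor_names_unique_within_context(self):
        for cat in (supervised_catalog(), unsupervised_catalog(), daily_catalog()):
            names = [d.name for d in cat]
            assert len(names) == len(set(names))

    def test_display_labels_match_reporting_convention(self):
        target = [d for d in supervised_catalog()
                  if d.sensor == "chest" and d.statistic == "avg_of_min"
                  and d.axis == "cc" and d.phase == "si_st" and d.half == 2]
        assert target[0].display == "Avg of (Chest) Min CC Accel Si-St (2) (g)"


class TestPeakMinPerHalf:
    def test_zero_signal_gives_zeros(self):
        sig = bandpass_signal(make_signal())
        event = make_event("si_st", 2.0, 3.5)
        out = peak_min_per_half(sig, event)
        assert len(out) == 6
        assert all(p == 0.0 and m == 0.0 for p, m in out.values())

    def test_in_band_burst_recovered_in_correct_cell(self):
        # a 10 Hz Gaussian-windowed burst of 0.3 g placed in half 2 of the
        # AP axis survives the 5-20 Hz band-pass within filter tolerance
        n = int(30 * FS)
        t = np.arange(n) / FS
        ap = 0.3 * np.exp(-0.5 * ((t - 3.2) / 0.15) ** 2) * np.sin(2 * np.pi * 10 * (t - 3.2))
        sig = bandpass_signal(make_signal(ap=ap))
        event = make_event("si_st", 2.0, 3.5)  # mid at 2.75: burst in half 2
        out = peak_min_per_half(sig, event)
        assert abs(out[("ap", 2)][0] - 0.3) <= 0.03
        assert abs(out[("ap", 1)][0]) < 0.02
        assert abs(out[("cc", 2)][0]) < 1e-9 and abs(out[("ml", 2)][0]) < 1e-9

    def test_sign_flip_swaps_and_negates(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.1, int(30 * FS))
        pos = peak_min_per_half(bandpass_signal(make_signal(ap=x)), make_event("si_st", 2, 4))
        neg = peak_min_per_half(bandpass_signal(make_signal(ap=-x)), make_event("si_st", 2, 4))
        for key in pos:
            assert np.isclose(neg[key][0], -pos[key][1], atol=1e-9)
            assert np.isclose(neg[key][1], -pos[key][0], atol=1e-9)

    def test_tiny_half_marked_missing(self):
        sig = bandpass_signal(make_signal())
        event = TransitionEvent("si_st", 500, 503, 501, 3 / FS,
                                (500, 501), (501, 503), "supervised_cst", FS)
        out = peak_min_per_half(sig, event)
        assert np.isnan(out[("ap", 1)][0])


class TestSupervisedFeatures:
    def test_temporal_hand_arithmetic(self):
        trial = make_trial([1.0, 1.2, 1.4], [0.9, 1.1, 1.0])
        vec = supervised_cst_features(trial)
        assert np.isclose(vec.values["avg_si_st"], 1.2)
        assert np.isclose(vec.values["med_si_st"], 1.2)
        assert np.isclose(vec.values["max_si_st"], 1.4)
        assert np.isclose(vec.values["min_si_st"], 1.0)
        assert vec.values["n_repetitions"] == 3.0
        assert len(vec.values) == 153

    def test_avg_of_peak_matches_bruteforce_mean(self):
        rng = np.random.default_rng(1)
        sig = make_signal(ap=rng.normal(0, 0.1, int(30 * FS)))
        trial = make_trial([1.0, 1.3, 1.1], [1.0, 1.0, 1.2], signal=sig)
        vec = supervised_cst_features(trial)
        bp = bandpass_signal(sig)
        peaks = [bp.ap[e.half2[0] : e.half2[1]].max()
                 for e in trial.events if e.type == "si_st"]
        assert abs(vec.values["thigh_avg_of_peak_ap_si_st_h2"] - np.mean(peaks)) < 1e-12

    def test_zero_repetitions_all_missing(self):
        trial = CSTTrial(events=[], repetition_count=0, thigh=make_signal())
        vec = supervised_cst_features(trial)
        assert vec.values["n_repetitions"] == 0.0
        assert "no_repetitions" in vec.flags
        others = [v for k, v in vec.values.items() if k != "n_repetitions"]
        assert all(np.isnan(v) for v in others)

    def test_event_order_permutation_invariant(self):
        rng = np.random.default_rng(2)
        sig = make_signal(ap=rng.normal(0, 0.1, int(30 * FS)))
        trial = make_trial([1.0, 1.3, 1.1], [1.0, 0.9, 1.2], signal=sig)
        shuffled = CSTTrial(events=list(reversed(trial.events)),
                            repetition_count=3, thigh=sig, chest=sig)
        a = supervised_cst_features(trial).values
        b = supervised_cst_features(shuffled).values
        assert all(np.isclose(a[k], b[k], equal_nan=True) for k in a)

    def test_constant_offset_leaves_acceleration_features_unchanged(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.1, int(30 * FS))
        base = make_trial([1.0, 1.2], [1.0, 1.1], signal=make_signal(ap=x))
        offset = make_trial([1.0, 1.2], [1.0, 1.1], signal=make_signal(ap=x + 0.25))
        a, b = supervised_cst_features(base).values, supervised_cst_features(offset).values
        for k in a:
            if "ap" in k:
                assert np.isclose(a[k], b[k], atol=1e-6)


class TestUnsupervisedFeatures:
    def test_catalog_and_hand_arithmetic(self):
        trials = [make_trial([d], [d]) for d in (1.0, 1.1, 1.2, 1.3)]
        vec = unsupervised_cst_features(trials, "P1")
        assert len(vec.values) == 163
        assert np.isclose(vec.values["avg_si_st"], 1.15)
        assert np.isclose(vec.values["med_of_avg_si_st"], 1.15)
        assert np.isclose(vec.values["med_of_min_time_si_st"], 1.15)
        assert np.isclose(vec.values["avg_repetitions"], 1.0)

    def test_three_trials_ineligible(self):
        trials = [make_trial([1.0], [1.0]) for _ in range(3)]
        vec = unsupervised_cst_features(trials, "P1")
        assert "ineligible" in vec.flags
        assert vec.values == {}

    def test_summary_statistics_ordering(self):
        rng = np.random.default_rng(4)
        trials = [make_trial(list(rng.uniform(0.8, 2.0, 5)), list(rng.uniform(0.8, 2.0, 5)))
                  for _ in range(6)]
        vec = unsupervised_cst_features(trials, "P1")
        for phase in ("si_st", "st_si"):
            assert vec.values[f"p5_{phase}"] <= vec.values[f"med_{phase}"] <= vec.values[f"p95_{phase}"]
            assert vec.values[f"avg_of_min_time_{phase}"] <= vec.values[f"avg_of_max_{phase}"]


class TestDailyFeatures:
    def test_temporal_hand_arithmetic_with_sample_sd_cv(self):
        events = [make_event("si_st", 1.0, 3.0, context="daily_life"),
                  make_event("si_st", 5.0, 7.5, context="daily_life"),
                  make_event("si_st", 9.0, 12.0, context="daily_life")]
        vec = daily_life_features(events, make_signal(), make_signal())
        assert np.isclose(vec.values["avg_si_st"], 2.5)
        # CV uses the sample standard deviation (n-1): 0.5 / 2.5
        assert np.isclose(vec.values["cv_si_st"], 0.2)
        temporal = [k for k in vec.values
                    if not any(s in k for s in ("thigh", "chest"))]
        assert len(temporal) == 10

    def test_single_event_cv_missing(self):
        events = [make_event("si_st", 1.0, 3.0, context="daily_life")]
        vec = daily_life_features(events, make_signal(), make_signal())
        assert np.isnan(vec.values["cv_si_st"])
        assert np.isclose(vec.values["avg_si_st"], 2.0)

    def test_p95_matches_bruteforce_order_statistic(self):
        rng = np.random.default_rng(5)
        sig = make_signal(cc=rng.normal(0, 0.2, int(30 * FS)))
        events = [make_event("si_st", 0.5 + 1.4 * i, 1.5 + 1.4 * i, context="daily_life")
                  for i in range(20)]
        vec = daily_life_features(events, sig, None)
        bp = bandpass_signal(sig)
        pooled = np.concatenate([bp.cc[e.half1[0] : e.half1[1]] for e in events])
        # brute-force linear-interpolation percentile
        srt = np.sort(pooled)
        pos = 0.95 * (srt.size - 1)
        lo = int(np.floor(pos))
        brute = srt[lo] + (pos - lo) * (srt[lo + 1] - srt[lo])
        assert abs(vec.values["thigh_p95_cc_si_st_h1"] - brute) < 1e-9

    def test_percentile_ordering_invariant(self):
        rng = np.random.default_rng(6)
        sig = make_signal(ap=rng.normal(0, 0.2, int(30 * FS)))
        events = [make_event("st_si", 0.5 + 1.4 * i, 1.6 + 1.4 * i, context="daily_life")
                  for i in range(15)]
        vec = daily_life_features(events, sig, None)
        mins = [bandpass_signal(sig).ap[e.half1[0] : e.half1[1]].min() for e in events]
        peaks = [bandpass_signal(sig).ap[e.half1[0] : e.half1[1]].max() for e in events]
        v = vec.values
        assert min(mins) <= v["thigh_p5_ap_st_si_h1"] <= v["thigh_p95_ap_st_si_h1"] <= max(peaks)

    def test_no_events_flagged(self):
        vec = daily_life_features([], make_signal(), make_signal())
        assert "no_transitions" in vec.flags
        assert all(np.isnan(v) for v in vec.values.values())
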