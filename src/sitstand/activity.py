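"""Activity classification of 4-second windows and bout merging.

Thigh and chest streams are cut into non-overlapping 4 s windows; each
window is summarised by orientation and dynamics features (per-axis mean
and SD, vector-norm SD, and mean absolute successive difference per
sensor) and classified into one of five classes: walk, stand, sit, lie and
"other" (the reject class for unclassifiable activity).  Consecutive
windows with the same label merge into activity bouts, the front end of
free-living sit<->stand transition detection.

The classifier behind :func:`train_classifier` is a seeded random forest
over these window features.  The published architecture this stage models
is a recurrent network (an LSTM layer of 215 hidden units with 30% dropout
feeding a BiLSTM layer of 125 units with 40% dropout, Adam optimisation,
trained on 97,000 labelled windows); those hyperparameters are carried on
:class:`ClassifierConfig` as the architecture descriptor, but the decision
surface shipped here is the feature-based model, which is what the rest of
the pipeline consumes.  Train/test hygiene is the caller's job:
:func:`split_by_participant` produces participant-disjoint splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .core import ACTIVITY_CLASSES, ActivityBout, AnatomicalSignal

WINDOW_S = 4.0

WINDOW_FEATURE_NAMES = tuple(
    f"{site}_{name}"
    for site in ("thigh", "chest")
    for name in (
        "mean_ap", "mean_ml", "mean_cc",
        "sd_ap", "sd_ml", "sd_cc",
        "sd_norm", "mean_abs_diff",
    )
)


@dataclass
class ObservationWindow:
    """One fixed-duration observation with features from both sensors."""

    start_s: float
    duration_s: float
    features: np.ndarray
    label: str | None = None
    participant_id: str | None = None


@dataclass
class ClassifierConfig:
    """Classifier settings; recurrent fields describe the reference design."""

    lstm_units: int = 215
    bilstm_units: int = 125
    dropout: tuple[float, float] = (0.3, 0.4)
    optimizer: str = "adam"
    epochs: int = 30
    seed: int = 0
    backend: str = "random_forest"
    n_estimators: int = 200


def _sensor_features(arr: np.ndarray) -> np.ndarray:
    """Features for windows of one sensor, ``arr`` shaped (n_win, len, 3)."""
    means = arr.mean(axis=1)
    sds = arr.std(axis=1, ddof=0)
    norm = np.linalg.norm(arr, axis=2)
    sd_norm = norm.std(axis=1, ddof=0)[:, None]
    mad = np.abs(np.diff(norm, axis=1)).mean(axis=1)[:, None]
    return np.hstack([means, sds, sd_norm, mad])


def window_stream(
    thigh: AnatomicalSignal,
    chest: AnatomicalSignal,
    window_s: float = WINDOW_S,
    hop_s: float | None = None,
    labels: np.ndarray | None = None,
    participant_id: str | None = None,
) -> list[ObservationWindow]:
    """Cut time-aligned thigh+chest streams into non-overlapping windows.

    The trailing remainder shorter than one window is dropped.  When a
    per-sample ``labels`` array is given, each window receives its
    majority label (training-corpus construction).
    """
    if hop_s is not None and hop_s != window_s:
        raise ValueError("only non-overlapping windows (hop == window) are supported")
    if thigh.sampling_rate_hz != chest.sampling_rate_hz:
        raise ValueError("thigh and chest must share one sampling rate")
    fs = thigh.sampling_rate_hz
    n = min(thigh.n_samples, chest.n_samples)
    win = int(round(window_s * fs))
    n_windows = n // win
    if n_windows == 0:
        return []
    t_arr = np.stack([thigh.ap, thigh.ml, thigh.cc], axis=1)[: n_windows * win]
    c_arr = np.stack([chest.ap, chest.ml, chest.cc], axis=1)[: n_windows * win]
    t_arr = t_arr.reshape(n_windows, win, 3)
    c_arr = c_arr.reshape(n_windows, win, 3)
    feats = np.hstack([_sensor_features(t_arr), _sensor_features(c_arr)])

    window_labels: list[str | None] = [None] * n_windows
    if labels is not None:
        lab = np.asarray(labels[: n_windows * win], dtype=object).reshape(n_windows, win)
        for i in range(n_windows):
            vals, counts = np.unique(lab[i].astype(str), return_counts=True)
            window_labels[i] = str(vals[np.argmax(counts)])

    return [
        ObservationWindow(
            start_s=i * window_s,
            duration_s=window_s,
            features=feats[i],
            label=window_labels[i],
            participant_id=participant_id,
        )
        for i in range(n_windows)
    ]


@dataclass
class ActivityClassifier:
    """Trained window classifier with a fixed five-class output space."""

    model: RandomForestClassifier
    config: ClassifierConfig
    classes: tuple[str, ...] = ACTIVITY_CLASSES
    missing_in_training: tuple[str, ...] = ()

    def predict(self, windows: list[ObservationWindow]) -> list[str]:
        if not windows:
            return []
        X = np.vstack([w.features for w in windows])
        return [str(lbl) for lbl in self.model.predict(X)]

    def predict_proba(self, windows: list[ObservationWindow]) -> pd.DataFrame:
        X = np.vstack([w.features for w in windows])
        proba = self.model.predict_proba(X)
        frame = pd.DataFrame(0.0, index=range(len(windows)), columns=list(self.classes))
        for j, cls in enumerate(self.model.classes_):
            frame[str(cls)] = proba[:, j]
        return frame


def train_classifier(
    windows: list[ObservationWindow],
    config: ClassifierConfig | None = None,
) -> ActivityClassifier:
    """Train the window classifier on labelled observations.

    Deterministic given ``config.seed`` (single-threaded fit).  A class
    absent from the training data is kept in the output space and reported
    via ``missing_in_training``.
    """
    config = config or ClassifierConfig()
    labelled = [w for w in windows if w.label is not None]
    if not labelled:
        raise ValueError("no labelled windows provided")
    y = np.array([w.label for w in labelled])
    present = set(y)
    if len(present) < 2:
        raise ValueError("training data must contain at least 2 classes")
    missing = tuple(c for c in ACTIVITY_CLASSES if c not in present)
    X = np.vstack([w.features for w in labelled])
    model = RandomForestClassifier(
        n_estimators=config.n_estimators,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return ActivityClassifier(model=model, config=config, missing_in_training=missing)


def classify_and_merge(
    classifier: ActivityClassifier, windows: list[ObservationWindow]
) -> list[ActivityBout]:
    """Predict per-window labels and merge identical runs into bouts."""
    labels = classifier.predict(windows)
    return merge_labels_to_bouts(labels, [w.start_s for w in windows],
                                 windows[0].duration_s if windows else WINDOW_S)


def merge_labels_to_bouts(
    labels: list[str], starts: list[float], window_s: float
) -> list[ActivityBout]:
    bouts: list[ActivityBout] = []
    for lbl, start in zip(labels, starts):
        if bouts and bouts[-1].label == lbl and np.isclose(bouts[-1].end_s, start):
            bouts[-1] = ActivityBout(lbl, bouts[-1].start_s, start + window_s)
        else:
            bouts.append(ActivityBout(lbl, start, start + window_s))
    return bouts


def bouts_to_labels(bouts: list[ActivityBout], window_s: float) -> list[str]:
    """Inverse of the run-length merge (used to check the merge is lossless)."""
    labels: list[str] = []
    for b in bouts:
        labels.extend([b.label] * int(round(b.duration_s / window_s)))
    return labels


def split_by_participant(
    participant_ids: list[str], test_fraction: float = 0.3, seed: int = 0
) -> tuple[set[str], set[str]]:
    """Participant-disjoint train/test id split."""
    unique = sorted(set(participant_ids))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(unique))
    n_test = max(1, int(round(test_fraction * len(unique))))
    test = {unique[i] for i in perm[:n_test]}
    train = set(unique) - test
    return train, test


def evaluate_classifier(
    predictions: list[str],
    truth: list[str],
    scores: pd.DataFrame | None = None,
) -> dict:
    """Accuracy, confusion matrix and per-class one-vs-rest AUC.

    ``scores`` (class-probability frame from ``predict_proba``) enables a
    proper ranking AUC; without it the AUC degrades to the one computable
    from hard labels.
    """
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have equal length")
    pred = np.asarray(predictions, dtype=object)
    true = np.asarray(truth, dtype=object)
    accuracy = float(np.mean(pred == true))
    confusion = pd.DataFrame(
        0, index=list(ACTIVITY_CLASSES), columns=list(ACTIVITY_CLASSES), dtype=int
    )
    for t, p in zip(true, pred):
        confusion.loc[str(t), str(p)] += 1
    auc: dict[str, float] = {}
    for cls in ACTIVITY_CLASSES:
        y = (true == cls).astype(int)
        if y.min() == y.max():
            auc[cls] = float("nan")
            continue
        s = scores[cls].to_numpy() if scores is not None else (pred == cls).astype(float)
        auc[cls] = float(roc_auc_score(y, s))
    return {"accuracy": accuracy, "confusion": confusion, "auc": auc}
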