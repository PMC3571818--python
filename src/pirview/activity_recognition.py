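"""Feature sets and the leave-one-subject-out recognition protocol.

Four feature sets are built from the pixel frames:

======  ==========================================  ====
set     contents                                    dim
======  ==========================================  ====
F1      the 20 pixel values p_ij(t)                 20
F2      their sum over the grid                     1
F3      F1 and F2 concatenated                      21
F4      pixel values at t-1, t and t+1              60
======  ==========================================  ====

Classification follows the leave-one-subject-out protocol: with one
dataset per subject, each fold trains on all other subjects and tests on
the held-out one, so no person's data leaks across the split.  The
classifier is an RBF-kernel support vector machine with the library's
default hyperparameters; it can be swapped via the ``classifier``
factory.  The reported recognition rate is the per-fold accuracy
averaged over folds, and the confusion matrix pools the per-frame
decisions of all folds (rows normalized to percent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "FEATURE_SETS",
    "ConfusionMatrix",
    "ProtocolResult",
    "extract_features",
    "run_protocol",
]

logger = logging.getLogger(__name__)

FEATURE_SETS = {"F1": 20, "F2": 1, "F3": 21, "F4": 60}


def extract_features(values: np.ndarray, set_id: str) -> tuple[np.ndarray, np.ndarray]:
    """Build feature vectors from a time-ordered pixel-value matrix.

    Parameters
    ----------
    values
        Pixel frames as a ``(T, 20)`` matrix (consecutive frames).
    set_id
        One of F1..F4.

    Returns
    -------
    X, idx
        Feature matrix and, for each row, the index of the frame it is
        centred on (F4 drops the first and last frame).
    """
    if set_id not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {set_id!r}; expected one of {sorted(FEATURE_SETS)}")
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("values must be a (T, n_sensors) matrix")
    T = v.shape[0]
    if set_id == "F1":
        return v.copy(), np.arange(T)
    if set_id == "F2":
        return v.sum(axis=1, keepdims=True), np.arange(T)
    if set_id == "F3":
        return np.hstack([v, v.sum(axis=1, keepdims=True)]), np.arange(T)
    # F4: three consecutive frames
    if T < 3:
        raise ValueError(f"feature set F4 needs at least 3 frames, got {T}")
    X = np.hstack([v[:-2], v[1:-1], v[2:]])
    return X, np.arange(1, T - 1)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-stochastic confusion matrix in percent.

    ``rates[a, b]`` is the percentage of frames of true activity
    ``labels[a]`` recognized as ``labels[b]``; each row with any support
    sums to 100 within 0.1.
    """

    labels: tuple[str, ...]
    rates: np.ndarray
    counts: np.ndarray

    def row_sums(self) -> np.ndarray:
        return self.rates.sum(axis=1)


@dataclass(frozen=True)
class ProtocolResult:
    recognition_rate: float          # mean per-fold accuracy, percent
    fold_rates: dict[str, float]     # subject -> fold accuracy (percent)
    confusion: ConfusionMatrix


def _default_classifier():
    # RBF kernel with the implementation's default hyperparameters
    return SVC(kernel="rbf")


def run_protocol(
    datasets: Mapping[str, tuple[np.ndarray, np.ndarray]],
    classifier: Callable[[], object] | None = None,
) -> ProtocolResult:
    """Leave-one-subject-out cross-validation over per-subject datasets.

    ``datasets`` maps subject id to ``(X, y)``.  A fold whose training
    partition lacks some class is logged as a warning but still run.
    """
    if len(datasets) < 2:
        raise ValueError("the protocol needs at least 2 subject partitions")
    subjects = list(datasets)
    all_labels = sorted({str(lab) for _, y in datasets.values() for lab in y})
    k = len(all_labels)
    lab_index = {lab: a for a, lab in enumerate(all_labels)}
    counts = np.zeros((k, k), dtype=int)
    fold_rates: dict[str, float] = {}

    for held_out in subjects:
        X_test, y_test = datasets[held_out]
        X_train = np.vstack([datasets[s][0] for s in subjects if s != held_out])
        y_train = np.concatenate([np.asarray(datasets[s][1]) for s in subjects if s != held_out])
        missing = set(all_labels) - set(map(str, y_train))
        if missing:
            logger.warning(
                "fold %s: training partition lacks class(es) %s; running anyway",
                held_out, ", ".join(sorted(missing)),
            )
        clf = (classifier or _default_classifier)()
        clf.fit(X_train, y_train)
        y_pred = clf.predict(X_test)
        acc = float(np.mean(np.asarray(y_pred) == np.asarray(y_test)))
        fold_rates[held_out] = 100.0 * acc
        for yt, yp in zip(y_test, y_pred):
            counts[lab_index[str(yt)], lab_index[str(yp)]] += 1

    rate = float(np.mean(list(fold_rates.values())))
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(row_tot > 0, 100.0 * counts / row_tot, 0.0)
    confusion = ConfusionMatrix(labels=tuple(all_labels), rates=rates, counts=counts)
    return ProtocolResult(recognition_rate=rate, fold_rates=fold_rates, confusion=confusion)
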