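"""Scoring fall detections against ground truth.

Event-level metrics: a detection is *correct* when its timestamp lies in
a true fall window extended by a matching tolerance (default 2 s); each
true fall can be credited at most once; surplus detections are false
alarms and uncredited falls are misses.  From the counts:

    Precision = correct / detections      Recall = correct / true falls
    FAR = 1 - Precision                   FRR = 1 - Recall
    F1  = 2 * Precision * Recall / (Precision + Recall)

Percentages are reported to two decimals.  ``roc_sweep`` re-runs the
detector across a list of thresholds lambda with a fixed seed, giving
the operating curve of the threshold test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import martingale

__all__ = [
    "MatchResult",
    "MetricsReport",
    "f1_score",
    "fall_windows_from_labels",
    "match_detections",
    "metrics",
    "roc_sweep",
    "score_events",
    "reports_to_frame",
]


@dataclass(frozen=True)
class MatchResult:
    correct: int
    false_alarms: int
    misses: int

    @property
    def detections(self) -> int:
        return self.correct + self.false_alarms

    @property
    def true_falls(self) -> int:
        return self.correct + self.misses


@dataclass(frozen=True)
class MetricsReport:
    """Precision/recall family for one detector operating point.

    All rates are percentages (rounded to 2 decimals on formatting, kept
    at full precision here); ``None`` marks an undefined rate (zero
    denominator).  Invariants: FAR = 100 - precision, FRR = 100 - recall,
    F1 is the harmonic mean of precision and recall.
    """

    lam: float | None
    correct: int
    detections: int
    true_falls: int
    precision: float | None
    recall: float | None
    far: float | None
    frr: float | None
    f1: float | None

    @property
    def undefined(self) -> bool:
        return self.precision is None or self.recall is None

    def as_row(self) -> dict:
        r2 = lambda v: None if v is None else round(v, 2)
        return {
            "lambda": self.lam,
            "correct": self.correct,
            "detections": self.detections,
            "true_falls": self.true_falls,
            "precision": r2(self.precision),
            "recall": r2(self.recall),
            "F1": r2(self.f1),
            "FAR": r2(self.far),
            "FRR": r2(self.frr),
        }


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if precision < 0 or recall < 0:
        raise ValueError("rates must be nonnegative")
    if precision + recall == 0:
        raise ValueError("F1 undefined when precision and recall are both 0")
    return 2.0 * precision * recall / (precision + recall)


def fall_windows_from_labels(labels, label: str = "fall") -> list[tuple[int, int]]:
    """Inclusive (start, end) sample-index windows of contiguous runs of
    ``label`` in a per-sample label sequence."""
    mask = np.asarray([lab == label for lab in labels], dtype=bool)
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    return list(zip(starts, ends))


def match_detections(
    event_times,
    truth_windows,
    tolerance: int = 0,
) -> MatchResult:
    """Match detection timestamps to true fall windows.

    ``truth_windows`` are inclusive, non-overlapping (start, end) pairs in
    sample units; ``tolerance`` (samples) extends each window on both
    sides.  A detection inside an extended window credits that window
    (each window at most once, earliest detection first); everything else
    is a false alarm, every uncredited window a miss.
    """
    windows = sorted((int(a), int(b)) for a, b in truth_windows)
    for (a, b) in windows:
        if b < a:
            raise ValueError(f"truth window ({a}, {b}) ends before it starts")
    for (a0, b0), (a1, _) in zip(windows, windows[1:]):
        if a1 <= b0:
            raise ValueError(f"truth windows ({a0}, {b0}) and starting at {a1} overlap")
    times = sorted(int(t) for t in event_times)
    credited = [False] * len(windows)
    correct = 0
    false_alarms = 0
    for t in times:
        hit = None
        for k, (a, b) in enumerate(windows):
            if a - tolerance <= t <= b + tolerance and not credited[k]:
                hit = k
                break
        if hit is None:
            false_alarms += 1
        else:
            credited[hit] = True
            correct += 1
    misses = credited.count(False)
    return MatchResult(correct=correct, false_alarms=false_alarms, misses=misses)


def metrics(
    correct: int,
    detections: int,
    true_falls: int,
    lam: float | None = None,
) -> MetricsReport:
    """Precision/recall/FAR/FRR/F1 from event counts (percentages)."""
    if min(correct, detections, true_falls) < 0:
        raise ValueError("counts must be nonnegative")
    if correct > detections or correct > true_falls:
        raise ValueError("correct detections cannot exceed detections or true falls")
    precision = 100.0 * correct / detections if detections > 0 else None
    recall = 100.0 * correct / true_falls if true_falls > 0 else None
    far = None if precision is None else 100.0 - precision
    frr = None if recall is None else 100.0 - recall
    if precision is None or recall is None or precision + recall == 0.0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricsReport(
        lam=lam, correct=correct, detections=detections, true_falls=true_falls,
        precision=precision, recall=recall, far=far, frr=frr, f1=f1,
    )


def score_events(
    event_times,
    truth_windows,
    tolerance: int,
    lam: float | None = None,
) -> MetricsReport:
    """Convenience: match then compute metrics."""
    m = match_detections(event_times, truth_windows, tolerance)
    return metrics(m.correct, m.detections, m.true_falls, lam=lam)


def roc_sweep(
    vectors: np.ndarray,
    truth_windows,
    lambdas,
    epsilon: float = martingale.DEFAULT_EPSILON,
    seed: int | None = None,
    tolerance: int = 0,
    t_index: np.ndarray | None = None,
    warmup: int = 0,
    holdoff: int = 0,
) -> list[MetricsReport]:
    """Run the martingale detector once per threshold and score each run.

    The same seed drives every run, so the theta draws are identical
    across thresholds and only lambda varies.  Reports are ordered by
    lambda.
    """
    lams = sorted(float(v) for v in lambdas)
    if len(lams) < 2:
        raise ValueError("roc_sweep needs at least two lambda values")
    reports = []
    for lam in lams:
        events, _ = martingale.detect(vectors, epsilon=epsilon, lam=lam,
                                      seed=seed, t_index=t_index, warmup=warmup,
                                      holdoff=holdoff)
        reports.append(score_events([e.t for e in events], truth_windows,
                                    tolerance, lam=lam))
    return reports


def reports_to_frame(reports) -> pd.DataFrame:
    """Tabulate a list of reports (one row per lambda)."""
    return pd.DataFrame([r.as_row() for r in reports])
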