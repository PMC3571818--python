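"""Online change detection with a randomized power martingale.

The detector watches the stream of 20-dimensional pixel vectors x(t).  At
each step it scores how *strange* the newest vector is relative to the
accumulated history (Euclidean distance to the mean of the history
including the current point), converts the strangeness into a randomized
conformal p-value

    qhat_t = (#{r <= t : s_r > s_t} + theta_t * #{r <= t : s_r = s_t}) / t

with theta_t ~ Uniform(0, 1], and multiplies the martingale

    M_n = prod_{t=1..n} eps * qhat_t^(eps - 1),    M_0 = 1.

Under exchangeability (no change) the qhat_t are uniform on (0, 1] and
M_n is a nonnegative martingale with E(M_n) = 1, so by Doob's maximal
inequality P(max_k M_k >= lambda) <= 1/lambda: the threshold lambda
directly bounds the false-alarm rate (lambda = 20 keeps it below 5%).  A
fall breaks exchangeability -- the sprawled body lights far more sensors
than walking -- which drives qhat_t small repeatedly and M_n through the
threshold within a couple of seconds.  On detection the martingale resets
to 1 and the history is cleared.

Scoring.  By default every history point is (re)scored against the
*current* center at each step (``freeze_scores=False``).  This is the
conformal construction: all points are ranked by the same function, the
p-values are exactly uniform under exchangeability, and the Doob bound is
honest.  The frozen variant -- keep each s_r as computed at its own time
r -- is also provided; it is cheaper but biases early scores low (the
early center sits close to the early points), which inflates the
martingale on perfectly normal streams.

Arming.  ``warmup`` withholds threshold testing (and martingale updates)
for the first ``warmup`` frames of the stream while the history
accumulates.  A rank among a handful of points is meaningless, and on
smooth motion streams the first seconds are otherwise guaranteed novelty;
a deployed monitor calibrates on the scene before arming.  The default
(0) is the bare reference algorithm.  ``holdoff`` similarly withholds
testing for a fixed number of frames after each detection while the
cleared history rebuilds, preventing alarm storms from back-to-back
cold starts.

The default power is eps = 0.92.  The martingale is tracked in log space
so long non-detecting runs cannot overflow.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right, insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_EPSILON",
    "DetectionEvent",
    "StepRecord",
    "MartingaleDetector",
    "strangeness",
    "phat",
    "martingale_update",
    "detect",
    "power_martingale_paths",
]

DEFAULT_EPSILON = 0.92


def strangeness(points: np.ndarray) -> float:
    """Strangeness of the last row of ``points`` w.r.t. the whole set.

    ``points`` is the history including the current vector (shape (t, d)).
    Returns the Euclidean distance of the current vector to the mean of
    all t vectors; an empty history yields 0 by convention.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return 0.0
    if pts.ndim == 1:
        pts = pts[None, :]
    c = pts.mean(axis=0)
    return float(np.linalg.norm(pts[-1] - c))


def phat(svals, theta: float) -> float:
    """Randomized conformal p-value of the last strangeness in ``svals``.

    ``svals`` holds s_1..s_t including the current s_t as its last entry;
    ``theta`` is the Uniform[0, 1] tie-breaking draw.
    """
    s = list(svals)
    if not s:
        raise ValueError("phat requires at least one strangeness value")
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    st = s[-1]
    greater = sum(1 for v in s if v > st)
    equal = sum(1 for v in s if v == st)
    return (greater + theta * equal) / len(s)


def martingale_update(M_prev: float, qhat: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """One multiplicative step of the randomized power martingale."""
    if M_prev < 0:
        raise ValueError("martingale value must be nonnegative")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    if not 0.0 < qhat <= 1.0:
        raise ValueError(
            f"qhat must lie in (0, 1], got {qhat}; qhat = 0 only arises from a "
            "user-supplied theta = 0 on a tie-free maximal strangeness"
        )
    return M_prev * epsilon * qhat ** (epsilon - 1.0)


@dataclass(frozen=True)
class DetectionEvent:
    """A martingale threshold crossing (fall alarm)."""

    t: int
    martingale_value: float


@dataclass(frozen=True)
class StepRecord:
    t: int
    strangeness: float
    qhat: float
    theta: float
    martingale: float
    detected: bool


@dataclass
class MartingaleDetector:
    """Stateful online martingale test over a vector stream.

    Parameters
    ----------
    epsilon
        Power of the martingale (default 0.92).
    lam
        Detection threshold lambda; 1/lam bounds the false-alarm rate
        under the no-change null.
    seed
        Seed of the dedicated theta RNG stream (one uniform draw per
        frame), making runs replayable.
    warmup
        Frames at the start of the stream during which the history
        accumulates but the martingale is not updated or tested.
    holdoff
        Frames after each detection during which the rebuilt history
        accumulates before testing resumes.
    freeze_scores
        Keep each strangeness value as computed at its own time instead
        of rescoring the history against the current center.
    history_cap
        Optional ring-buffer cap on the stored history.  Off by default:
        the reference algorithm lets the history grow without bound
        between detections; capping it is a deviation for long
        deployments only.
    """

    epsilon: float = DEFAULT_EPSILON
    lam: float = 15.0
    seed: int | None = None
    warmup: int = 0
    holdoff: int = 0
    freeze_scores: bool = False
    history_cap: int | None = None
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.warmup < 0 or self.holdoff < 0:
            raise ValueError("warmup and holdoff must be nonnegative")
        self._rng = np.random.default_rng(self.seed)
        self._t = 0
        self._armed_at = self.warmup
        self.reset()

    def reset(self) -> None:
        """Restart the test: M = 1, empty history.  The theta RNG stream
        keeps advancing so a full run stays replayable from the seed."""
        self._log_m = 0.0
        self._buf: np.ndarray | None = None   # preallocated history buffer
        self._n = 0                           # points in the buffer
        self._hist_sum: np.ndarray | None = None
        self._svals_sorted: list[float] = []  # frozen variant only

    @property
    def martingale(self) -> float:
        return math.exp(self._log_m) if self._log_m < 700 else math.inf

    def _qhat(self, x: np.ndarray, theta: float) -> tuple[float, float]:
        """Strangeness of ``x`` and its randomized p-value over the
        current history plus ``x``."""
        n_hist = self._n
        if n_hist == 0:
            s = 0.0
            greater, equal = 0, 1
        else:
            c = (self._hist_sum + x) / (n_hist + 1)
            s = float(np.linalg.norm(x - c))
            if self.freeze_scores:
                greater = n_hist - bisect_right(self._svals_sorted, s)
                equal = (bisect_right(self._svals_sorted, s)
                         - bisect_left(self._svals_sorted, s) + 1)
            else:
                ds = np.linalg.norm(self._buf[:n_hist] - c, axis=1)
                greater = int((ds > s).sum())
                equal = int((ds == s).sum()) + 1
        qhat = (greater + theta * equal) / (n_hist + 1)
        return s, qhat

    def step(self, x) -> StepRecord:
        """Consume one pixel vector; returns the step record (with the
        martingale value *at* this step, before any reset)."""
        x = np.asarray(x, dtype=float).ravel()
        self._t += 1
        theta = 1.0 - float(self._rng.random())  # Uniform(0, 1]
        s, qhat = self._qhat(x, theta)
        armed = self._t > self._armed_at
        if armed:
            self._log_m += math.log(self.epsilon) + (self.epsilon - 1.0) * math.log(qhat)
        m = self.martingale
        detected = armed and m > self.lam
        if detected:
            record = StepRecord(self._t, s, qhat, theta, m, True)
            self._armed_at = self._t + self.holdoff
            self.reset()
        else:
            self._append(x, s)
            record = StepRecord(self._t, s, qhat, theta, m, False)
        return record

    def _append(self, x: np.ndarray, s: float) -> None:
        if self._buf is None or self._n == len(self._buf):
            cap = 256 if self._buf is None else 2 * len(self._buf)
            new = np.empty((cap, x.size))
            if self._n:
                new[:self._n] = self._buf[:self._n]
            self._buf = new
        self._buf[self._n] = x
        self._n += 1
        self._hist_sum = x.copy() if self._hist_sum is None else self._hist_sum + x
        if self.freeze_scores:
            insort(self._svals_sorted, s)
        if self.history_cap is not None and self._n > self.history_cap:
            old = self._buf[0].copy()
            self._buf[:self._n - 1] = self._buf[1:self._n]
            self._n -= 1
            self._hist_sum = self._hist_sum - old
            if self.freeze_scores:
                # per-point score tracking is not kept; drop the smallest
                self._svals_sorted.pop(0)


def detect(
    vectors: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    lam: float = 15.0,
    seed: int | None = None,
    warmup: int = 0,
    holdoff: int = 0,
    t_index: np.ndarray | None = None,
    freeze_scores: bool = False,
    history_cap: int | None = None,
) -> tuple[list[DetectionEvent], pd.DataFrame]:
    """Run the martingale test over a whole series of pixel vectors.

    ``vectors`` has shape (T, d); ``t_index`` optionally maps rows to
    sample indices of the originating stream (default 1..T).  Returns the
    detection events and the full trace (t, s_t, qhat, M, detected).
    Deterministic given the seed.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim == 1:
        vectors = vectors[:, None]
    det = MartingaleDetector(epsilon=epsilon, lam=lam, seed=seed, warmup=warmup,
                             holdoff=holdoff, freeze_scores=freeze_scores,
                             history_cap=history_cap)
    if t_index is None:
        t_index = np.arange(1, len(vectors) + 1)
    events: list[DetectionEvent] = []
    rows = []
    for ti, x in zip(t_index, vectors):
        rec = det.step(x)
        rows.append((int(ti), rec.strangeness, rec.qhat, rec.martingale, rec.detected))
        if rec.detected:
            events.append(DetectionEvent(t=int(ti), martingale_value=rec.martingale))
    trace = pd.DataFrame(rows, columns=["t", "s_t", "qhat", "M", "detected"])
    return events, trace


def power_martingale_paths(
    n_runs: int,
    horizon: int,
    epsilon: float = DEFAULT_EPSILON,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Log-martingale paths driven by i.i.d. Uniform(0, 1] p-values.

    This is the exchangeable no-change null in closed form: under
    exchangeability the conformal p-values are uniform, so these paths
    have exactly the null distribution of log M_n.  Shape
    ``(n_runs, horizon)``; entry [r, k] is log M_{k+1}.
    """
    if rng is None:
        rng = np.random.default_rng()
    q = 1.0 - rng.random((n_runs, horizon))  # Uniform(0, 1]
    steps = math.log(epsilon) + (epsilon - 1.0) * np.log(q)
    return np.cumsum(steps, axis=1)
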