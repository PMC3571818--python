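"""Synthetic binary sensor streams for a ceiling PIR grid watching one person.

A pyroelectric infrared (PIR) sensor emits 1 while a warm body *moves*
inside its detection cone and, because of the element's latency, keeps
reporting 1 for a short hold window afterwards; a motionless person is
invisible.  The simulator reproduces the statistical regimes such a grid
exhibits with a single occupant:

* walking (100-150 cm/s) lights 2-4 sensors simultaneously,
* a fall sprawls the body over a much larger area and lights 5-8 sensors,
* a motionless person produces all-zero frames.

Model.  The person is a disc of body points (radius ``body_radius``) moving
along a trajectory; a sensor's floor footprint is a circle of radius
``footprint_radius`` around its position (the lens hood narrows the cone
well below the nominal detection distance).  A sensor is *in contact* at a
sample when a body point moving faster than ``motion_threshold`` lies in
its footprint.  A pyroelectric element in contact does not report
continuously: it *fires* in intermittent pulses as the thermal signal
retriggers it, modelled as an independent per-sample firing probability
(``fire_prob``) while in contact; the sensor then reads active while its
last firing is at most ``hold`` seconds old.  A fall replaces the disc by
an oriented head-to-toe sprawl -- a segment of length ``sprawl_length``
dilated by ``sprawl_halfwidth``, aligned with the walking direction at the
moment of the fall -- whose violent motion retriggers the elements at a
higher rate (``fall_fire_prob``).  Defaults are calibrated once so the
emergent active-sensor counts match the walking 2-4 / fall 5-8 regimes at
20 Hz.

All randomness flows from a single integer seed; identical inputs yield
bit-identical streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import DEFAULT_GRID, SensorGrid

__all__ = [
    "ADL_LABELS",
    "SPECIAL_LABELS",
    "KNOWN_LABELS",
    "DEFAULT_ANCHORS",
    "SimParams",
    "Segment",
    "ActivityScript",
    "SensorStream",
    "fall_event",
    "simulate_stream",
    "simulate_null",
    "walk_then_fall_script",
    "walk_only_script",
    "daily_round_script",
    "adl_session_script",
]

# The eight activities of daily living used for recognition, plus the
# special labels understood by the simulator.
ADL_LABELS = (
    "walking",
    "tidying",
    "watching_tv",
    "reading",
    "taking_drinks",
    "using_pc",
    "lying",
    "sweeping",
)
SPECIAL_LABELS = ("fall", "fall_like", "motionless")
KNOWN_LABELS = ADL_LABELS + SPECIAL_LABELS

# Ambulatory activities roam the room; everything else stays near an anchor.
_ROAMING = {"walking", "sweeping"}

# Default anchor (continuous grid-index coordinates) per stationary ADL,
# mimicking a furnished room: table, sofa, fridge, desk.
DEFAULT_ANCHORS: dict[str, tuple[float, float]] = {
    "tidying": (2.0, 2.0),
    "watching_tv": (3.4, 4.4),
    "reading": (1.6, 3.9),
    "taking_drinks": (1.2, 1.2),
    "using_pc": (3.4, 1.4),
    "lying": (2.9, 4.6),
}


@dataclass(frozen=True)
class SimParams:
    """Tunable physical parameters of the sensor-response model.

    All lengths in cm, times in seconds, speeds in cm/s.
    """

    body_radius: float = 25.0        # standing person as a disc of body points
    footprint_radius: float = 50.0   # sensor floor footprint (narrowed cone)
    hold: float = 0.3                # sensor latency after last firing
    motion_threshold: float = 5.0    # slower body points are invisible to PIR
    margin: float = 60.0             # person's center keeps this far from walls
    jitter_radius: float = 20.0      # wander radius of stationary activities
    jitter_speed: float = 30.0       # speed of the small stationary motions
    fire_prob: float = 0.25          # per-sample firing prob while in contact
    sprawl_length: float = 120.0     # head-to-toe extent of a fallen body
    sprawl_halfwidth: float = 30.0   # half-width of the sprawl (limbs out)
    fall_fire_prob: float = 0.8      # vigorous fall motion retriggers often
    fall_like_length: float = 90.0   # smaller sprawl: sitting fast / lying down
    fall_like_halfwidth: float = 25.0
    false_fire_prob: float = 0.0     # i.i.d. per-sensor-sample noise blips


@dataclass(frozen=True)
class Segment:
    """One scripted activity: label, anchor, duration and motion statistics.

    ``anchor`` is in continuous grid-index coordinates (``None`` lets the
    simulator pick or keep the current position).  ``motion_level`` is the
    fraction of time the person is actually moving; 0 means perfectly
    still.  ``speed`` is the movement speed while moving.  ``sprawl``
    optionally overrides the (length, half-width) of a fall-type sprawl.
    """

    label: str
    duration: float
    anchor: tuple[float, float] | None = None
    motion_level: float = 1.0
    speed: float = 125.0
    sprawl: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.label not in KNOWN_LABELS:
            raise ValueError(
                f"unknown activity label {self.label!r}; known labels: {', '.join(KNOWN_LABELS)}"
            )
        if self.duration <= 0:
            raise ValueError(f"segment duration must be positive, got {self.duration}")
        if not 0.0 <= self.motion_level <= 1.0:
            raise ValueError("motion_level must lie in [0, 1]")
        if self.speed < 0:
            raise ValueError("speed must be nonnegative")


@dataclass(frozen=True)
class ActivityScript:
    """Time-ordered sequence of activity segments."""

    segments: tuple[Segment, ...]

    def __init__(self, segments) -> None:
        segs = tuple(segments)
        if not segs:
            raise ValueError("ActivityScript requires at least one segment")
        object.__setattr__(self, "segments", segs)

    @property
    def duration(self) -> float:
        return sum(s.duration for s in self.segments)


@dataclass
class SensorStream:
    """Binary sensor responses s_ij(t) in {0,1} sampled at ``rate_H`` Hz.

    ``frames`` has shape ``(T, n_rows, n_cols)``; ``labels`` holds one
    activity label per sample; ``fall_times`` are the sample indices
    labelled ``"fall"``.
    """

    rate_H: float
    frames: np.ndarray
    labels: np.ndarray
    fall_times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    grid: SensorGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        if not 1.0 <= self.rate_H <= 80.0:
            raise ValueError(f"sampling rate must lie in [1, 80] Hz, got {self.rate_H}")
        self.frames = np.asarray(self.frames, dtype=np.uint8)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"frames must have shape (T, {self.grid.n_rows}, {self.grid.n_cols})"
            )
        if not np.isin(self.frames, (0, 1)).all():
            raise ValueError("sensor responses must be binary")
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape[0] != self.frames.shape[0]:
            raise ValueError("labels and frames must have equal length")

    @property
    def n_samples(self) -> int:
        return self.frames.shape[0]

    @property
    def flat(self) -> np.ndarray:
        """Frames flattened row-major to shape ``(T, n_sensors)``."""
        return self.frames.reshape(self.n_samples, -1)

    def active_counts(self) -> np.ndarray:
        """Number of simultaneously active sensors per sample."""
        return self.flat.sum(axis=1)


def fall_event(
    location: tuple[float, float],
    duration: float = 2.0,
    spread_radius: float = 60.0,
    *,
    grid: SensorGrid = DEFAULT_GRID,
    params: SimParams = SimParams(),
) -> Segment:
    """Build a fall segment anchored at ``location`` (grid-index coords).

    ``spread_radius`` is the half-length of the sprawl: the fallen body
    extends up to that far from the impact point along the fall direction.
    The location must lie inside the room and the sprawl must be able to
    cover at least 5 sensor cells for any orientation, so the fall is
    distinguishable from walking (which activates at most 4).
    """
    loc_cm = grid.index_to_cm(np.asarray(location, dtype=float))
    if not grid.contains(loc_cm):
        raise ValueError(f"fall location {tuple(location)} is outside the room")
    length = 2.0 * spread_radius
    halfwidth = params.sprawl_halfwidth
    reach = halfwidth + params.footprint_radius
    pos = grid.positions()
    min_cover = min(
        int(_stadium_mask(pos, loc_cm, theta, length, reach).sum())
        for theta in np.linspace(0.0, math.pi, 16, endpoint=False)
    )
    if min_cover < 5:
        raise ValueError(
            f"spread_radius {spread_radius} cm covers only {min_cover} sensor cells at "
            f"{tuple(location)}; a detectable fall needs at least 5"
        )
    return Segment(
        label="fall",
        duration=duration,
        anchor=tuple(float(v) for v in location),
        motion_level=1.0,
        speed=0.0,
        sprawl=(length, halfwidth),
    )


def _stadium_mask(points: np.ndarray, center: np.ndarray, theta: float,
                  length: float, reach: float) -> np.ndarray:
    """Points within ``reach`` of a segment of ``length`` through ``center``."""
    u = np.array([math.cos(theta), math.sin(theta)])
    d = points - center
    proj = np.clip(d @ u, -length / 2.0, length / 2.0)
    closest = center + proj[:, None] * u
    return np.linalg.norm(points - closest, axis=1) <= reach


# ---------------------------------------------------------------------------
# Trajectory synthesis
# ---------------------------------------------------------------------------

def _margin_box(grid: SensorGrid, margin: float) -> tuple[np.ndarray, np.ndarray]:
    ex, ey = grid.room_extent
    lo = np.array([min(margin, ex / 2), min(margin, ey / 2)])
    hi = np.array([ex, ey]) - lo
    return lo, hi


def _walk_path(start: np.ndarray, n: int, dt: float, speed: float,
               lo: np.ndarray, hi: np.ndarray, rng: np.random.Generator,
               first_target: np.ndarray | None = None) -> np.ndarray:
    """Random-waypoint wander: straight legs at constant speed."""
    path = np.empty((n, 2))
    pos = start.astype(float).copy()
    target = first_target if first_target is not None else rng.uniform(lo, hi)
    step = speed * dt
    for t in range(n):
        delta = target - pos
        dist = math.hypot(delta[0], delta[1])
        while dist < step:
            target = rng.uniform(lo, hi)
            delta = target - pos
            dist = math.hypot(delta[0], delta[1])
        pos = pos + delta / dist * step
        path[t] = pos
    return path


def _jitter_path(anchor: np.ndarray, n: int, dt: float, motion_level: float,
                 params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Small in-place motions around an anchor, moving a ``motion_level``
    fraction of the time (alternating moves to nearby jitter targets and
    pauses)."""
    path = np.empty((n, 2))
    if motion_level <= 0.0:
        path[:] = anchor
        return path
    pos = anchor.astype(float).copy()
    t = 0
    while t < n:
        # one jitter move
        target = anchor + rng.uniform(-1, 1, 2) * params.jitter_radius
        delta = target - pos
        dist = math.hypot(delta[0], delta[1])
        move_steps = max(1, int(math.ceil(dist / (params.jitter_speed * dt))))
        for _ in range(move_steps):
            if t >= n:
                return path
            step = min(params.jitter_speed * dt, math.hypot(*(target - pos)))
            d = target - pos
            nrm = math.hypot(d[0], d[1])
            if nrm > 1e-9:
                pos = pos + d / nrm * step
            path[t] = pos
            t += 1
        if motion_level < 1.0:
            pause = move_steps * (1.0 - motion_level) / motion_level
            pause_steps = int(round(pause * (0.5 + rng.random())))
            for _ in range(pause_steps):
                if t >= n:
                    return path
                path[t] = pos
                t += 1
    return path


def simulate_stream(
    grid: SensorGrid,
    script: ActivityScript,
    rate_H: float,
    seed: int,
    params: SimParams = SimParams(),
) -> SensorStream:
    """Simulate the binary responses of the grid for a scripted activity
    sequence.  Deterministic given identical arguments."""
    if not 1.0 <= rate_H <= 80.0:
        raise ValueError(f"sampling rate must lie in [1, 80] Hz, got {rate_H}")
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_H
    lo, hi = _margin_box(grid, params.margin)

    pos_chunks: list[np.ndarray] = []
    label_chunks: list[np.ndarray] = []
    # per-sample sprawl state: None for upright, (length, halfwidth, theta) lying
    sprawl_chunks: list[list] = []

    pos = rng.uniform(lo, hi)        # person enters at a random interior point
    heading = rng.uniform(0, 2 * math.pi)

    for seg in script.segments:
        n = max(1, int(round(seg.duration * rate_H)))
        anchor_cm = None if seg.anchor is None else grid.index_to_cm(np.asarray(seg.anchor))
        if seg.label in ("fall", "fall_like"):
            if anchor_cm is not None:
                pos = anchor_cm.astype(float)
            if seg.sprawl is not None:
                length, halfwidth = seg.sprawl
            elif seg.label == "fall":
                length, halfwidth = params.sprawl_length, params.sprawl_halfwidth
            else:
                length, halfwidth = params.fall_like_length, params.fall_like_halfwidth
            path = np.tile(pos, (n, 1))
            sprawl_chunks.append([(length, halfwidth, heading)] * n)
        elif seg.label == "motionless" or seg.motion_level <= 0.0:
            path = np.tile(pos, (n, 1))
            sprawl_chunks.append([None] * n)
        elif seg.label in _ROAMING:
            path = _walk_path(pos, n, dt, seg.speed, lo, hi, rng,
                              first_target=None if anchor_cm is None else anchor_cm)
            sprawl_chunks.append([None] * n)
        else:
            target = anchor_cm if anchor_cm is not None else rng.uniform(lo, hi)
            # walk over to the anchor, then fidget in place
            d0 = math.hypot(*(target - pos))
            walk_n = min(n, int(math.ceil(d0 / (max(seg.speed, 1e-6) * dt))))
            part = []
            if walk_n > 0 and d0 > 1.0:
                leg = np.empty((walk_n, 2))
                p = pos.copy()
                for k in range(walk_n):
                    d = target - p
                    nrm = math.hypot(d[0], d[1])
                    p = target if nrm <= seg.speed * dt else p + d / nrm * seg.speed * dt
                    leg[k] = p
                part.append(leg)
            rest = n - sum(len(a) for a in part)
            if rest > 0:
                part.append(_jitter_path(target, rest, dt, seg.motion_level, params, rng))
            path = np.vstack(part)
            sprawl_chunks.append([None] * n)
        # update heading from the path tail for a later fall orientation
        if len(path) >= 2:
            d = path[-1] - path[-2]
            if math.hypot(d[0], d[1]) > 1e-9:
                heading = math.atan2(d[1], d[0])
        pos = path[-1].copy()
        pos_chunks.append(path)
        label_chunks.append(np.full(n, seg.label, dtype=object))

    positions = np.vstack(pos_chunks)
    labels = np.concatenate(label_chunks)
    sprawls = [s for chunk in sprawl_chunks for s in chunk]
    T = positions.shape[0]
    sensors = grid.positions()

    # instantaneous speed of the person's center
    disp = np.vstack([np.zeros((1, 2)), np.diff(positions, axis=0)])
    speeds = np.linalg.norm(disp, axis=1) / dt
    moving = speeds > params.motion_threshold

    contact = np.zeros((T, grid.n_sensors), dtype=bool)
    fire_p = np.zeros(T)
    upright_reach = params.body_radius + params.footprint_radius
    for t in range(T):
        sp = sprawls[t]
        if sp is not None:
            length, halfwidth, theta = sp
            # the sprawl itself counts as moving (impact, limbs) for its duration
            contact[t] = _stadium_mask(sensors, positions[t], theta,
                                       length, halfwidth + params.footprint_radius)
            fire_p[t] = params.fall_fire_prob
        elif moving[t]:
            contact[t] = (
                np.linalg.norm(sensors - positions[t], axis=1) <= upright_reach
            )
            fire_p[t] = params.fire_prob

    # intermittent retriggering while in contact, then the hold window:
    # active while the last firing is at most `hold` old
    fired = contact & (rng.random((T, grid.n_sensors)) < fire_p[:, None])
    w = int(round(params.hold * rate_H))
    idx = np.arange(T)[:, None]
    last = np.maximum.accumulate(np.where(fired, idx, -(10 ** 9)), axis=0)
    active = (idx - last) <= w

    if params.false_fire_prob > 0.0:
        # momentary i.i.d. blips, injected after the hold so a pure-noise
        # motionless stream is exactly exchangeable
        active = active | (rng.random((T, grid.n_sensors)) < params.false_fire_prob)

    frames = active.astype(np.uint8).reshape(T, grid.n_rows, grid.n_cols)
    fall_times = np.flatnonzero(labels == "fall")
    return SensorStream(rate_H=rate_H, frames=frames, labels=labels,
                        fall_times=fall_times, grid=grid)


def simulate_null(
    grid: SensorGrid,
    n_samples: int,
    rate_H: float,
    p: float,
    seed: int,
) -> SensorStream:
    """I.i.d. Bernoulli(p) noise frames: an exactly exchangeable null stream
    (empty room / sensor false fires) for martingale calibration."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("false-fire probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    frames = (rng.random((n_samples, grid.n_rows, grid.n_cols)) < p).astype(np.uint8)
    labels = np.full(n_samples, "motionless", dtype=object)
    return SensorStream(rate_H=rate_H, frames=frames, labels=labels, grid=grid)


# ---------------------------------------------------------------------------
# Canned scripts
# ---------------------------------------------------------------------------

def walk_then_fall_script(
    walk_duration: float = 60.0,
    fall_duration: float = 2.0,
    rest_duration: float = 5.0,
    speed: float = 125.0,
) -> ActivityScript:
    """A one-minute round of walking ending in a fall, then lying
    motionless: the typical indoor fall scenario (most falls of elders
    happen during walking)."""
    return ActivityScript([
        Segment("walking", walk_duration, speed=speed),
        Segment("fall", fall_duration),
        Segment("motionless", rest_duration),
    ])


def walk_only_script(duration: float = 66.0, speed: float = 125.0) -> ActivityScript:
    return ActivityScript([Segment("walking", duration, speed=speed)])


def daily_round_script(
    seed: int,
    duration: float = 60.0,
    include_fall: bool = True,
    include_fall_like: bool = False,
) -> ActivityScript:
    """A one-minute round in the spirit of the fall-campaign protocol: the
    subject walks and performs a few random ADLs, optionally behaves
    fall-like, and (optionally) falls during the final stretch of walking."""
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    tail = (1.0 + 4.0) if include_fall else 0.0
    budget = duration - tail
    stationary = [a for a in ADL_LABELS if a not in _ROAMING]
    t = 0.0
    segments.append(Segment("walking", float(rng.uniform(4, 8))))
    t += segments[-1].duration
    while t < budget - 6.0:
        act = stationary[rng.integers(len(stationary))]
        seg = Segment(act, float(rng.uniform(4, 8)), anchor=DEFAULT_ANCHORS[act],
                      motion_level=float(rng.uniform(0.3, 0.8)))
        segments.append(seg)
        t += seg.duration
        if include_fall_like and rng.random() < 0.35:
            segments.append(Segment("fall_like", 0.8))
            t += 0.8
        walk = Segment("walking", float(rng.uniform(3, 6)))
        segments.append(walk)
        t += walk.duration
    if budget - t > 0.5:
        segments.append(Segment("walking", budget - t))
    if include_fall:
        segments.append(Segment("fall", 2.0))
        segments.append(Segment("motionless", 4.0))
    return ActivityScript(segments)


def adl_session_script(
    seed: int,
    segment_duration: float = 8.0,
    anchors: dict[str, tuple[float, float]] | None = None,
    activities: tuple[str, ...] = ADL_LABELS,
    motion_level: float = 1.0,
) -> ActivityScript:
    """One labelled segment per ADL, in random order, for building
    activity-recognition datasets.  ``motion_level=1`` keeps the person
    continuously fidgeting so every frame carries location information."""
    rng = np.random.default_rng(seed)
    anchors = dict(DEFAULT_ANCHORS if anchors is None else anchors)
    order = list(activities)
    rng.shuffle(order)
    segs = []
    for act in order:
        segs.append(Segment(
            act,
            segment_duration,
            anchor=anchors.get(act),
            motion_level=motion_level,
            speed=80.0 if act == "sweeping" else 125.0,
        ))
    return ActivityScript(segs)
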