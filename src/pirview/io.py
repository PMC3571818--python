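"""CSV and configuration round-tripping.

Fixed CSV dialect throughout: comma-separated, one header row, UNIX
newlines, '.' decimal point.  Every file written by the pipeline starts
with a comment line recording the package, the master seed and a hash of
the run configuration, so any output can be traced back to its run;
readers skip '#' comment lines.

Sensor log: ``t_index, s_1_1, ..., s_4_5`` (cells row-major, binary).
Label log:  ``t_index, activity_label``.
Pixel log:  ``t_index, p_1_1, ..., p_4_5`` (reals in [0, 1]).
Trace log:  ``t, s_t, qhat, M, detected``.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import SensorGrid
from .sensor_sim import KNOWN_LABELS, SensorStream
from .virtual_camera import PixelSeries

__all__ = [
    "RunConfig",
    "sensor_columns",
    "write_sensor_csv",
    "read_sensor_csv",
    "write_labels_csv",
    "read_labels_csv",
    "write_pixel_csv",
    "read_pixel_csv",
    "write_trace_csv",
    "read_trace_csv",
]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, in one serializable record."""

    n_rows: int = 4
    n_cols: int = 5
    spacing: float = 75.0
    detection_radius: float = 75.0
    rate_H: float = 20.0
    window_mode: str = "trailing"
    epsilon: float = 0.92
    lam: float = 15.0
    tolerance_s: float = 2.0
    warmup_s: float = 45.0
    holdoff_s: float = 2.0
    stride: int = 2
    seed: int = 0
    feature_set: str = "F4"

    @property
    def warmup_frames(self) -> int:
        """Warm-up length in detector frames at the configured cadence."""
        return int(round(self.warmup_s * self.rate_H / self.stride))

    @property
    def holdoff_frames(self) -> int:
        return int(round(self.holdoff_s * self.rate_H / self.stride))

    def grid(self) -> SensorGrid:
        return SensorGrid(self.n_rows, self.n_cols, self.spacing, self.detection_radius)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def header(self) -> str:
        return f"# pirview seed={self.seed} config={self.digest()}\n"

    def seed_streams(self) -> dict[str, np.random.Generator]:
        """Named child RNG streams derived from the master seed."""
        kids = np.random.SeedSequence(self.seed).spawn(3)
        names = ("simulator", "theta", "classifier")
        return {n: np.random.default_rng(s) for n, s in zip(names, kids)}

    def child_seed(self, name: str) -> int:
        """A reproducible integer sub-seed (< 2**31) for a named stage."""
        names = ("simulator", "theta", "classifier")
        if name not in names:
            raise ValueError(f"unknown seed stream {name!r}")
        kids = np.random.SeedSequence(self.seed).spawn(3)
        return int(kids[names.index(name)].generate_state(1)[0] % (2 ** 31))


def sensor_columns(grid: SensorGrid, prefix: str = "s") -> list[str]:
    return [
        f"{prefix}_{i}_{j}"
        for i in range(1, grid.n_rows + 1)
        for j in range(1, grid.n_cols + 1)
    ]


def _write_with_header(df: pd.DataFrame, path, config: RunConfig | None) -> None:
    with open(path, "w", newline="\n") as fh:
        if config is not None:
            fh.write(config.header())
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_sensor_csv(stream: SensorStream, path, config: RunConfig | None = None) -> None:
    df = pd.DataFrame(stream.flat, columns=sensor_columns(stream.grid))
    df.insert(0, "t_index", np.arange(stream.n_samples))
    _write_with_header(df, path, config)


def read_sensor_csv(path, rate_H: float, grid: SensorGrid = SensorGrid(),
                    labels=None) -> SensorStream:
    """Read a sensor log back into a stream, validating shape and values.

    Malformed rows are reported with their line number in the file.
    """
    expected = ["t_index"] + sensor_columns(grid)
    # manual pass for precise line diagnostics
    rows = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if header is None:
                header = parts
                if header != expected:
                    raise ValueError(
                        f"{path}: line {lineno}: expected columns {expected}, got {header}"
                    )
                continue
            if len(parts) != len(expected):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(expected)} columns, got {len(parts)}"
                )
            try:
                vals = [int(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer value ({exc})") from None
            if any(v not in (0, 1) for v in vals[1:]):
                raise ValueError(f"{path}: line {lineno}: sensor values must be 0 or 1")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=np.int64)
    frames = arr[:, 1:].astype(np.uint8).reshape(-1, grid.n_rows, grid.n_cols)
    if labels is None:
        labels = np.full(len(frames), "motionless", dtype=object)
    stream = SensorStream(rate_H=rate_H, frames=frames, labels=labels, grid=grid)
    stream.fall_times = np.flatnonzero(stream.labels == "fall")
    return stream


def write_labels_csv(stream: SensorStream, path, config: RunConfig | None = None) -> None:
    df = pd.DataFrame({"t_index": np.arange(stream.n_samples),
                       "activity_label": stream.labels})
    _write_with_header(df, path, config)


def read_labels_csv(path) -> np.ndarray:
    df = _read_table(path)
    if list(df.columns) != ["t_index", "activity_label"]:
        raise ValueError(f"{path}: expected columns t_index, activity_label")
    bad = set(df["activity_label"]) - set(KNOWN_LABELS)
    if bad:
        raise ValueError(f"{path}: unknown activity label(s): {', '.join(sorted(map(str, bad)))}")
    return df["activity_label"].to_numpy(dtype=object)


def write_pixel_csv(series: PixelSeries, path, config: RunConfig | None = None) -> None:
    grid = SensorGrid(*series.grid_shape)  # column naming only
    df = pd.DataFrame(series.values, columns=sensor_columns(grid, prefix="p"))
    df.insert(0, "t_index", series.t)
    _write_with_header(df, path, config)


def read_pixel_csv(path, rate_H: float, mode: str = "trailing",
                   grid_shape: tuple[int, int] = (4, 5)) -> PixelSeries:
    df = _read_table(path)
    grid = SensorGrid(*grid_shape)
    expected = ["t_index"] + sensor_columns(grid, prefix="p")
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}")
    vals = df[expected[1:]].to_numpy(dtype=float)
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError(f"{path}: pixel values must lie in [0, 1]")
    return PixelSeries(t=df["t_index"].to_numpy(dtype=int), values=vals,
                       H=rate_H, mode=mode, grid_shape=grid_shape)


def write_trace_csv(trace: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    out = trace.copy()
    out["detected"] = out["detected"].astype(int)
    _write_with_header(out, path, config)


def read_trace_csv(path) -> pd.DataFrame:
    df = _read_table(path)
    expected = ["t", "s_t", "qhat", "M", "detected"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}")
    df["detected"] = df["detected"].astype(bool)
    return df
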