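"""Geometry of the ceiling-mounted PIR sensor grid.

The reference installation is a 4 x 5 grid of pyroelectric infrared motion
sensors on the ceiling of a 300 cm x 375 cm room, one sensor per 75 cm x
75 cm cell.  Grid cells are indexed 1-based, ``i = 1..n_rows`` and
``j = 1..n_cols``; the sensor of cell ``(i, j)`` sits above the cell center
at ``((i - 1/2) * spacing, (j - 1/2) * spacing)`` in floor coordinates (cm,
origin at a room corner).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SensorGrid", "DEFAULT_GRID"]


@dataclass(frozen=True)
class SensorGrid:
    """Layout of the ceiling sensor array.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions (default 4 x 5 = 20 sensors).
    spacing
        Distance between neighbouring sensors in cm (default 75).
    detection_radius
        Nominal detection distance of one sensor in cm (default 75).  The
        grid must leave no dead space: every floor point has to lie within
        ``detection_radius`` of at least one sensor.
    """

    n_rows: int = 4
    n_cols: int = 5
    spacing: float = 75.0
    detection_radius: float = 75.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.spacing <= 0 or self.detection_radius <= 0:
            raise ValueError("spacing and detection_radius must be positive")

    @property
    def n_sensors(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def room_extent(self) -> tuple[float, float]:
        """Floor size (x, y) in cm covered by the grid."""
        return (self.n_rows * self.spacing, self.n_cols * self.spacing)

    def positions(self) -> np.ndarray:
        """Sensor floor positions, shape ``(n_sensors, 2)``, row-major.

        Row-major means cell (1,1), (1,2), ..., (1,n_cols), (2,1), ...
        """
        i = np.repeat(np.arange(1, self.n_rows + 1), self.n_cols)
        j = np.tile(np.arange(1, self.n_cols + 1), self.n_rows)
        return np.column_stack([(i - 0.5) * self.spacing, (j - 0.5) * self.spacing])

    def cell_position(self, i: int, j: int) -> tuple[float, float]:
        """Floor position (cm) of the sensor of 1-based cell ``(i, j)``."""
        if not (1 <= i <= self.n_rows and 1 <= j <= self.n_cols):
            raise ValueError(f"cell ({i}, {j}) outside the {self.n_rows}x{self.n_cols} grid")
        return ((i - 0.5) * self.spacing, (j - 0.5) * self.spacing)

    def index_to_cm(self, xy: np.ndarray) -> np.ndarray:
        """Convert continuous grid-index coordinates to floor cm."""
        return (np.asarray(xy, dtype=float) - 0.5) * self.spacing

    def cm_to_index(self, xy: np.ndarray) -> np.ndarray:
        """Convert floor cm to continuous grid-index coordinates."""
        return np.asarray(xy, dtype=float) / self.spacing + 0.5

    def contains(self, xy) -> bool:
        """Whether a floor point (cm) lies inside the room."""
        x, y = float(xy[0]), float(xy[1])
        ex, ey = self.room_extent
        return 0.0 <= x <= ex and 0.0 <= y <= ey

    def coverage_gap(self, resolution: float = 1.0) -> float:
        """Largest distance from any floor point to its nearest sensor.

        Evaluated on a square lattice with the given resolution (cm).  The
        grid has no dead space iff this gap does not exceed
        ``detection_radius``.
        """
        ex, ey = self.room_extent
        xs = np.arange(0.0, ex + resolution / 2, resolution)
        ys = np.arange(0.0, ey + resolution / 2, resolution)
        pos = self.positions()
        gap = 0.0
        # chunk over x to bound memory on fine lattices
        for x in xs:
            pts = np.column_stack([np.full_like(ys, x), ys])
            d = np.linalg.norm(pts[:, None, :] - pos[None, :, :], axis=2).min(axis=1)
            gap = max(gap, float(d.max()))
        return gap

    def covers_floor(self, resolution: float = 1.0) -> bool:
        """True if no floor point is farther than ``detection_radius`` from all sensors."""
        return self.coverage_gap(resolution) <= self.detection_radius


DEFAULT_GRID = SensorGrid()
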