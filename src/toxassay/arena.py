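"""Arena geometry, grid partition, and animal position tracks.

A behavioral trial takes place in a rectangular vessel with a focal sea
anemone at a fixed position. For scoring, a regular grid (15 cells by
default, 3 rows x 5 columns for the 27.5 x 8 cm vessel) is overlaid on the
arena and the predator's location is classified per scoring instant.

Coordinates are millimetres with the origin at one corner of the vessel:
x runs along the width (columns), y along the height (rows).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

__all__ = ["ArenaSpec", "Track", "cell_of"]


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry of the test vessel and the scoring protocol.

    Parameters
    ----------
    width, height
        Inner dimensions of the vessel in mm. Defaults match a
        27.5 cm x 8 cm container.
    grid_rows, grid_cols
        Grid partition used for proximity scoring (3 x 5 = 15 cells by
        default). Cells are equal rectangles.
    anemone_position
        (x, y) of the focal anemone in mm; must lie inside the arena.
    touch_radius
        Distance in mm below which the predator is considered to be
        touching the anemone (operationalizes the visual-contact
        criterion of manual scoring).
    scoring_interval
        Seconds between scored instants (10 s by default).
    duration
        Trial duration in seconds: 900 s (15 min) for shrimp assays,
        600 s (10 min) for fish assays.
    """

    width: float = 275.0
    height: float = 80.0
    grid_rows: int = 3
    grid_cols: int = 5
    anemone_position: tuple[float, float] = (137.5, 40.0)
    touch_radius: float = 5.0
    scoring_interval: float = 10.0
    duration: float = 900.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.grid_rows * self.grid_cols < 1:
            raise ValueError("grid must contain at least one cell")
        if self.touch_radius <= 0:
            raise ValueError("touch_radius must be positive")
        if self.scoring_interval <= 0:
            raise ValueError("scoring_interval must be positive")
        if not self.contains(self.anemone_position):
            raise ValueError("anemone_position must lie inside the arena")

    def contains(self, position: tuple[float, float]) -> bool:
        x, y = position
        return 0.0 <= x <= self.width and 0.0 <= y <= self.height

    @property
    def cell_width(self) -> float:
        return self.width / self.grid_cols

    @property
    def cell_height(self) -> float:
        return self.height / self.grid_rows

    @property
    def anemone_cell(self) -> tuple[int, int]:
        return cell_of(self.anemone_position, self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ArenaSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "anemone_position" in raw:
            raw["anemone_position"] = tuple(raw["anemone_position"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "width": self.width,
            "height": self.height,
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "anemone_position": list(self.anemone_position),
            "touch_radius": self.touch_radius,
            "scoring_interval": self.scoring_interval,
            "duration": self.duration,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def cell_of(position: tuple[float, float], arena: ArenaSpec) -> tuple[int, int]:
    """Grid cell (row, col) containing ``position``.

    Cells partition the arena into equal rectangles; points on the far
    boundary belong to the last row/column. Positions outside the arena
    are rejected.
    """
    x, y = position
    if not arena.contains(position):
        raise ValueError(f"position {position} lies outside the arena")
    col = min(int(x / arena.cell_width), arena.grid_cols - 1)
    row = min(int(y / arena.cell_height), arena.grid_rows - 1)
    return row, col


@dataclass(frozen=True)
class Track:
    """Time-ordered 2-D positions of one animal at a fixed sampling interval.

    ``times`` are seconds (strictly increasing, uniformly spaced to within
    1e-6 s), ``positions`` an (n, 2) array of x/y in mm.
    """

    times: np.ndarray
    positions: np.ndarray
    frame_dt: float = field(default=0.0)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if times.shape[0] != positions.shape[0]:
            raise ValueError("times and positions must have equal length")
        if times.shape[0] == 0:
            raise ValueError("empty track")
        if not np.all(np.isfinite(positions)) or not np.all(np.isfinite(times)):
            raise ValueError("track contains non-finite values")
        if times.shape[0] > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if dt.max() - dt.min() > 1e-6:
                raise ValueError("times must be uniformly spaced")
            inferred = float(dt.mean())
        else:
            inferred = float(self.frame_dt) or 1.0
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        if not self.frame_dt:
            object.__setattr__(self, "frame_dt", inferred)

    def __len__(self) -> int:
        return int(self.times.shape[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def position_at(self, t: float) -> tuple[float, float]:
        """Position at the frame nearest to instant ``t``.

        The nearest frame must lie within half a frame interval of ``t``
        (the track and the scoring clock need not be phase-aligned, but a
        scored instant must be covered by the recording).
        """
        idx = int(np.searchsorted(self.times, t))
        best = idx
        if idx >= len(self):
            best = len(self) - 1
        elif idx > 0 and abs(self.times[idx - 1] - t) <= abs(self.times[idx] - t):
            best = idx - 1
        if abs(self.times[best] - t) > self.frame_dt / 2 + 1e-9:
            raise ValueError(f"instant t={t} s is not covered by the track")
        return float(self.positions[best, 0]), float(self.positions[best, 1])

    def displacements(self) -> np.ndarray:
        """Euclidean step length (mm) between consecutive frames."""
        if len(self) < 2:
            raise ValueError("need at least 2 frames to compute displacements")
        return np.hypot(*np.diff(self.positions, axis=0).T)

    @classmethod
    def from_arrays(
        cls, positions: Iterable[tuple[float, float]], frame_dt: float, t0: float = 0.0
    ) -> "Track":
        pos = np.asarray(list(positions), dtype=float)
        times = t0 + np.arange(pos.shape[0]) * float(frame_dt)
        return cls(times=times, positions=pos, frame_dt=float(frame_dt))

    @classmethod
    def read_csv(cls, path: str | Path, frame_rate: float | None = None) -> "Track":
        """Read a track from CSV.

        Accepts the native dialect (``t_s, x_mm, y_mm``) or an
        exported-tracker dialect (``frame, x, y``) when ``frame_rate``
        (frames per second) is supplied.
        """
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "t_s" in cols:
            times = df[cols["t_s"]].to_numpy(float)
            pos = df[[cols["x_mm"], cols["y_mm"]]].to_numpy(float)
            return cls(times=times, positions=pos)
        if "frame" in cols:
            if frame_rate is None:
                raise ValueError("frame-indexed tracks need a declared frame_rate")
            times = df[cols["frame"]].to_numpy(float) / float(frame_rate)
            pos = df[[cols["x"], cols["y"]]].to_numpy(float)
            return cls(times=times, positions=pos, frame_dt=1.0 / float(frame_rate))
        raise ValueError(f"unrecognized track columns in {path}: {list(df.columns)}")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"t_s": self.times, "x_mm": self.positions[:, 0], "y_mm": self.positions[:, 1]}
        )
        df.to_csv(path, index=False, float_format="%.6f")

    def distance_to(self, point: tuple[float, float]) -> np.ndarray:
        return np.hypot(self.positions[:, 0] - point[0], self.positions[:, 1] - point[1])


def bearing(from_xy: tuple[float, float], to_xy: tuple[float, float]) -> float:
    """Angle (radians) of the vector from ``from_xy`` to ``to_xy``."""
    return math.atan2(to_xy[1] - from_xy[1], to_xy[0] - from_xy[0])
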