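"""Core in-memory containers shared across the pipeline.

Coordinates are pixel-centered, 0-based, row-major (y, x).  The axial
coordinate ``s`` of a cell runs from 0 at pole A to ``L`` (the cell length)
at pole B, so midcell sits at ``L / 2``.  All physical quantities carry
explicit units in their field names (``_um``, ``_min``, ``_px``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class ImageStack:
    """A calibrated multi-channel time-lapse image stack (axes T, C, Y, X)."""

    pixels: np.ndarray  # float array, T x C x Y x X
    pixel_size_um: float
    frame_interval_s: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be a T x C x Y x X array")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration must be positive")
        if len(self.channel_names) != self.pixels.shape[1]:
            raise ValueError("channel_names length must match channel axis")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return the T x Y x X sub-stack for one named channel."""
        return self.pixels[:, self.channel_names.index(name)]

    def frame_times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s / 60.0


@dataclass
class CellRecord:
    """One segmented cell in one frame, with medial-axis geometry.

    The pixel mask is stored as a local boolean array plus its bounding-box
    offset to keep large populations cheap; :meth:`full_mask` rebuilds the
    frame-sized mask on demand.  ``axis`` is the ordered medial-axis polyline
    in global (y, x) pixel coordinates, extended to the cell poles.
    """

    cell_id: int
    frame: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    mask: np.ndarray  # local boolean mask inside bbox
    axis: np.ndarray  # (n, 2) global (y, x) polyline, pole A -> pole B
    length_um: float
    width_um: float
    area_um2: float
    curvature: float  # mean unsigned axis curvature, 1/um
    sinuosity: float  # axis length / end-to-end distance, >= 1
    angularity: float  # mean absolute turning angle per axis step, rad
    centroid: tuple[float, float]  # (y, x) global px
    pixel_size_um: float
    track_id: Optional[int] = None
    parent_track_id: Optional[int] = None
    outline: Optional[np.ndarray] = None  # (m, 2) global (y, x) contour

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out

    def pixel_coords(self) -> np.ndarray:
        """Global (y, x) integer coordinates of all mask pixels, (n, 2)."""
        r0, c0, _, _ = self.bbox
        yy, xx = np.nonzero(self.mask)
        return np.column_stack([yy + r0, xx + c0])

    def contains(self, y: float, x: float) -> bool:
        r0, c0, r1, c1 = self.bbox
        yi, xi = int(round(y)), int(round(x))
        if not (r0 <= yi < r1 and c0 <= xi < c1):
            return False
        return bool(self.mask[yi - r0, xi - c0])

    def _axis_arclength_um(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.axis, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)]) * self.pixel_size_um

    def axial_coordinate_um(self, y: float, x: float) -> float:
        """Arc-length position (um from pole A) of the nearest axis point."""
        d2 = (self.axis[:, 0] - y) ** 2 + (self.axis[:, 1] - x) ** 2
        return float(self._axis_arclength_um()[int(np.argmin(d2))])


@dataclass
class FocusRecord:
    """A detected fluorescent spot: a single-pixel point maximum or an
    area-based region focus."""

    focus_id: int
    channel: str
    frame: int
    cell_id: int
    kind: str  # "point_maximum" | "region_focus"
    centroid: tuple[float, float]  # (y, x) px
    axial_s_um: float
    peak_intensity: float
    region_pixels: Optional[np.ndarray] = None  # (n, 2) global (y, x)
    area_um2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("point_maximum", "region_focus"):
            raise ValueError(f"unknown focus kind {self.kind!r}")
        if self.kind == "point_maximum" and self.region_pixels is not None:
            raise ValueError("point maxima carry no region")


@dataclass
class TrajectoryRecord:
    """A linked time course of one focus across frames."""

    trajectory_id: int
    channel: str
    frames: list[int]
    foci: list[FocusRecord]
    track_id: Optional[int] = None

    def __post_init__(self) -> None:
        if list(self.frames) != sorted(set(self.frames)):
            raise ValueError("trajectory frames must be strictly increasing")
        if len(self.frames) != len(self.foci):
            raise ValueError("frames and foci must align")

    @property
    def lifespan_frames(self) -> int:
        return len(self.frames)


PHENOTYPES = ("multifocal", "quarter", "midcell", "periseptal", "excluded")


@dataclass
class PhenotypeCall:
    """Per-cell, per-frame compaction phenotype with the counts behind it."""

    cell_id: int
    frame: int
    n_point_maxima: int
    n_region_foci: int
    phenotype: str

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")


@dataclass
class Track:
    """A consecutive-run cell track (no gap closing)."""

    track_id: int
    records: list[CellRecord] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return [r.frame for r in self.records]

    @property
    def n_frames(self) -> int:
        return len(self.records)


def records_to_dataframe(cells: Sequence[CellRecord]):
    """Tidy one-row-per-cell-per-frame table of geometric descriptors."""
    import pandas as pd

    rows = []
    for c in cells:
        rows.append(
            {
                "cell_id": c.cell_id,
                "frame": c.frame,
                "centroid_y": c.centroid[0],
                "centroid_x": c.centroid[1],
                "length_um": c.length_um,
                "width_um": c.width_um,
                "area_um2": c.area_um2,
                "curvature": c.curvature,
                "sinuosity": c.sinuosity,
                "angularity": c.angularity,
                "track_id": c.track_id,
                "parent_track_id": c.parent_track_id,
            }
        )
    return pd.DataFrame(rows)
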