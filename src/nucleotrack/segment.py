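"""Rod-cell segmentation with medial-axis geometry and division detection.

Cells are segmented from a preprocessed transmitted-light-like image by
automatic thresholding (Otsu by default; cells dark on a bright field).
Each connected component gets a medial axis — the skeleton pruned to its
longest path and extended to the poles — from which length, mean width,
curvature, sinuosity and angularity are measured.  A geometric-limits
filter rejects debris and mis-segmentations, and an axial width profile
flags constriction sites so dividing cells can be split into daughters.
"""

from __future__ import annotations

from collections import deque
from typing import Optional

import numpy as np
from pydantic import BaseModel, model_validator
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops
from skimage.morphology import skeletonize

from .records import CellRecord

_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)
]


class GeometryLimits(BaseModel):
    """Acceptance window for each geometric descriptor.

    Default profile (fully overridable): area 1-15 um^2, length 1.5-15 um,
    width 0.5-2 um, sinuosity <= 1.3, mean curvature <= 1 /um, angularity
    <= 0.5 rad.
    """

    area_um2: tuple[float, float] = (1.0, 15.0)
    length_um: tuple[float, float] = (1.5, 15.0)
    width_um: tuple[float, float] = (0.5, 2.0)
    sinuosity: tuple[float, float] = (1.0, 1.3)
    curvature: tuple[float, float] = (0.0, 1.0)
    angularity: tuple[float, float] = (0.0, 0.5)

    @model_validator(mode="after")
    def _ordered(self):
        for name in type(self).model_fields:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min must not exceed max")
        return self


# ---------------------------------------------------------------------------
# medial-axis machinery


def _longest_skeleton_path(skel: np.ndarray) -> list[tuple[int, int]]:
    """Order skeleton pixels along the longest path (double BFS)."""
    coords = list(zip(*np.nonzero(skel)))
    if not coords:
        return []
    pix = set(coords)

    def neighbors(p):
        y, x = p
        return [(y + dy, x + dx) for dy, dx in _NEIGHBOR_OFFSETS
                if (y + dy, x + dx) in pix]

    def bfs_farthest(start):
        seen = {start: None}
        queue = deque([start])
        last = start
        while queue:
            p = queue.popleft()
            last = p
            for q in neighbors(p):
                if q not in seen:
                    seen[q] = p
                    queue.append(q)
        return last, seen

    a, _ = bfs_farthest(coords[0])
    b, parents = bfs_farthest(a)
    path = [b]
    while parents[path[-1]] is not None:
        path.append(parents[path[-1]])
    return path[::-1]


def _resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample an ordered polyline at roughly uniform arc-length spacing."""
    if len(points) < 2:
        return points
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return points[:1]
    n = max(2, int(round(total / spacing)) + 1)
    grid = np.linspace(0.0, total, n)
    return np.column_stack(
        [np.interp(grid, s, points[:, 0]), np.interp(grid, s, points[:, 1])]
    )


def _extend_to_boundary(
    path: np.ndarray, mask: np.ndarray, max_steps: int = 80
) -> np.ndarray:
    """Extend both polyline ends along their tangents until leaving the mask.

    Skeletons stop about one half-width short of each pole; this extension
    recovers the full pole-to-pole length.
    """
    h, w = mask.shape

    def inside(p):
        y, x = int(round(p[0])), int(round(p[1]))
        return 0 <= y < h and 0 <= x < w and mask[y, x]

    out = [path]
    for end, ref in ((0, min(6, len(path) - 1)), (-1, max(-7, -len(path)))):
        direction = path[end] - path[ref]
        norm = np.linalg.norm(direction)
        if norm == 0:
            continue
        direction = direction / norm
        p = path[end].astype(float)
        tail = []
        for _ in range(max_steps):
            p = p + 0.5 * direction
            if not inside(p):
                break
            tail.append(p.copy())
        if tail:
            if end == 0:
                out.insert(0, np.array(tail[::-1]))
            else:
                out.append(np.array(tail))
    return np.vstack(out)


def _smooth_polyline(points: np.ndarray, window: int = 7) -> np.ndarray:
    """Moving-average smoothing with pinned endpoints (tames pixel jaggedness)."""
    if len(points) <= window:
        return points
    kernel = np.ones(window) / window
    sm = np.column_stack(
        [
            np.convolve(np.pad(points[:, d], window // 2, mode="edge"),
                        kernel, mode="valid")
            for d in range(2)
        ]
    )
    sm[0], sm[-1] = points[0], points[-1]
    return sm


def _axis_descriptors(axis_px: np.ndarray, pixel_size_um: float):
    """(length_um, sinuosity, curvature_per_um, angularity_rad) of a polyline.

    Turning angles are measured on a smoothed, 2-px-resampled version of
    the axis: raw skeleton polylines alternate between 0/45-degree steps
    and would otherwise register spurious curvature on perfectly straight
    cells.
    """
    smooth = _resample_polyline(
        _smooth_polyline(_resample_polyline(axis_px, spacing=1.0)), spacing=2.0
    )
    seg = np.diff(smooth, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    length_um = float(seglen.sum() * pixel_size_um)
    endtoend = float(np.linalg.norm(smooth[-1] - smooth[0]) * pixel_size_um)
    sinuosity = length_um / endtoend if endtoend > 0 else 1.0
    if len(seg) >= 2:
        ang = np.arctan2(seg[:, 0], seg[:, 1])
        dtheta = np.abs(np.angle(np.exp(1j * np.diff(ang))))
        angularity = float(dtheta.mean())
        ds_um = 0.5 * (seglen[:-1] + seglen[1:]) * pixel_size_um
        curvature = float(np.mean(dtheta / ds_um))
    else:
        angularity = 0.0
        curvature = 0.0
    return length_um, max(1.0, sinuosity), curvature, angularity


def cell_from_mask(
    mask_full: np.ndarray,
    cell_id: int,
    frame: int,
    pixel_size_um: float,
) -> Optional[CellRecord]:
    """Build a :class:`CellRecord` (geometry included) from a frame-sized mask.

    Returns None for degenerate components whose skeleton collapses to a
    point (below any sensible cell size).
    """
    ys, xs = np.nonzero(mask_full)
    if ys.size == 0:
        return None
    r0, r1 = int(ys.min()), int(ys.max()) + 1
    c0, c1 = int(xs.min()), int(xs.max()) + 1
    local = mask_full[r0:r1, c0:c1]
    padded = np.pad(local, 2)

    skel = skeletonize(padded)
    path = _longest_skeleton_path(skel)
    if len(path) < 2:
        # near-round component: the skeleton collapses to a point; seed the
        # axis with the inertia-tensor major axis through the centroid
        props = regionprops(padded.astype(np.uint8))
        if not props:
            return None
        theta = props[0].orientation  # angle of major axis vs vertical
        cy_l, cx_l = props[0].centroid
        d = np.array([np.cos(theta), np.sin(theta)])
        path = [
            (cy_l - 0.5 * d[0], cx_l - 0.5 * d[1]),
            (cy_l + 0.5 * d[0], cx_l + 0.5 * d[1]),
        ]
    # smooth before extending: staircase skeleton ends point off-axis and
    # would otherwise exit through the side of the rounded pole cap
    path_arr = _resample_polyline(
        _smooth_polyline(_resample_polyline(np.array(path, dtype=float), 1.0)),
        1.0,
    )
    axis_local = _extend_to_boundary(path_arr, padded)

    length_um, sinuosity, curvature, angularity = _axis_descriptors(
        axis_local, pixel_size_um
    )
    area_um2 = float(local.sum() * pixel_size_um**2)
    cy = float(ys.mean())
    cx = float(xs.mean())
    offset = np.array([r0 - 2, c0 - 2], dtype=float)
    contours = find_contours(padded.astype(float), 0.5)
    outline_local = max(contours, key=len) if contours else None
    outline = (outline_local + offset) if outline_local is not None else None

    # width: twice the mean distance from the (smoothed) axis core to the
    # smoothed sub-pixel outline; both smoothings remove the rasterization
    # zigzag that otherwise biases the estimate on diagonal cells
    if outline_local is not None and len(outline_local) > 3:
        n = len(path_arr)
        core = path_arr[n // 10 : -max(1, n // 10)]
        dense_outline = _resample_polyline(
            _smooth_polyline(outline_local, window=5), spacing=0.25
        )
        dists, _ = cKDTree(dense_outline).query(core)
        width_um = float(2.0 * dists.mean() * pixel_size_um)
    else:  # pragma: no cover - degenerate fallback
        edt = ndimage.distance_transform_edt(padded)
        skel_idx = np.array(path, dtype=int)
        width_um = float(
            2.0 * edt[skel_idx[:, 0], skel_idx[:, 1]].mean() * pixel_size_um
        )

    return CellRecord(
        cell_id=cell_id,
        frame=frame,
        bbox=(r0, c0, r1, c1),
        mask=local.copy(),
        axis=axis_local + offset,
        length_um=length_um,
        width_um=width_um,
        area_um2=area_um2,
        curvature=curvature,
        sinuosity=sinuosity,
        angularity=angularity,
        centroid=(cy, cx),
        pixel_size_um=pixel_size_um,
        outline=outline,
    )


# ---------------------------------------------------------------------------
# public operations


def segment_cells(
    tl_img: np.ndarray,
    pixel_size_um: float,
    frame: int = 0,
    dark_cells: bool = True,
    min_area_px: int = 20,
    threshold: Optional[float] = None,
) -> list[CellRecord]:
    """Segment rod cells from a preprocessed TL-like image.

    Foreground is below (``dark_cells``) or above an automatic Otsu
    threshold; connected components smaller than ``min_area_px`` are
    dropped.  A blank or constant image yields an empty list.
    """
    img = np.asarray(tl_img, dtype=float)
    if img.size == 0 or np.ptp(img) == 0:
        return []
    thr = threshold_otsu(img) if threshold is None else threshold
    fg = img < thr if dark_cells else img > thr
    labels = label(fg, connectivity=2)
    cells = []
    for region in regionprops(labels):
        if region.area < min_area_px:
            continue
        rec = cell_from_mask(
            labels == region.label, cell_id=region.label, frame=frame,
            pixel_size_um=pixel_size_um,
        )
        if rec is not None:
            cells.append(rec)
    return cells


def filter_cells(
    cells: list[CellRecord],
    limits: Optional[GeometryLimits] = None,
    return_reasons: bool = False,
):
    """Keep cells with every descriptor inside its [min, max] window."""
    lim = limits or GeometryLimits()
    kept, reasons = [], {}
    for c in cells:
        failed = [
            name
            for name, value in (
                ("area_um2", c.area_um2),
                ("length_um", c.length_um),
                ("width_um", c.width_um),
                ("sinuosity", c.sinuosity),
                ("curvature", c.curvature),
                ("angularity", c.angularity),
            )
            if not (getattr(lim, name)[0] <= value <= getattr(lim, name)[1])
        ]
        if failed:
            reasons[(c.frame, c.cell_id)] = failed
        else:
            kept.append(c)
    return (kept, reasons) if return_reasons else kept


def axial_width_profile(cell: CellRecord) -> tuple[np.ndarray, np.ndarray]:
    """(arc-length um, local width um) sampled along the medial axis."""
    r0, c0, _, _ = cell.bbox
    padded = np.pad(cell.mask, 2)
    edt = ndimage.distance_transform_edt(padded)
    local = cell.axis - np.array([r0 - 2, c0 - 2], dtype=float)
    yi = np.clip(np.round(local[:, 0]).astype(int), 0, padded.shape[0] - 1)
    xi = np.clip(np.round(local[:, 1]).astype(int), 0, padded.shape[1] - 1)
    widths = 2.0 * np.clip(edt[yi, xi] - 0.5, 0.0, None) * cell.pixel_size_um
    steps = np.linalg.norm(np.diff(cell.axis, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)]) * cell.pixel_size_um
    return s, widths


def detect_division_sites(
    cell: CellRecord,
    constriction_frac: float = 0.4,
    pole_margin_frac: float = 0.15,
) -> list[CellRecord]:
    """Split a constricted cell at its septum into two daughter records.

    A division site is an interior local minimum of the axial width profile
    below ``constriction_frac`` x the median width, located more than
    ``pole_margin_frac`` of the length from either pole (guards against
    pole artifacts).  Without a qualifying site the cell is returned
    unchanged.  Daughter masks partition the parent mask exactly and carry
    the parent's track id as ``parent_track_id``.
    """
    s, widths = axial_width_profile(cell)
    total = s[-1]
    if total == 0 or len(s) < 5:
        return [cell]
    interior = (s > pole_margin_frac * total) & (s < (1 - pole_margin_frac) * total)
    med = float(np.median(widths[interior])) if interior.any() else float(
        np.median(widths)
    )
    candidates = [
        i
        for i in range(1, len(widths) - 1)
        if interior[i]
        and widths[i] <= widths[i - 1]
        and widths[i] <= widths[i + 1]
        and widths[i] < constriction_frac * med
    ]
    if not candidates:
        return [cell]
    split = min(candidates, key=lambda i: widths[i])

    # assign each mask pixel to its nearest axis vertex; split by vertex index
    coords = cell.pixel_coords()
    d2 = (
        (coords[:, None, 0] - cell.axis[None, :, 0]) ** 2
        + (coords[:, None, 1] - cell.axis[None, :, 1]) ** 2
    )
    nearest = np.argmin(d2, axis=1)
    shape_full = (cell.bbox[2] + 4, cell.bbox[3] + 4)
    daughters = []
    for j, side in enumerate((nearest <= split, nearest > split)):
        mask = np.zeros(shape_full, dtype=bool)
        sel = coords[side]
        mask[sel[:, 0], sel[:, 1]] = True
        rec = cell_from_mask(
            mask, cell_id=cell.cell_id * 2 + 1 + j, frame=cell.frame,
            pixel_size_um=cell.pixel_size_um,
        )
        if rec is not None:
            rec.parent_track_id = cell.track_id
            daughters.append(rec)
    if len(daughters) != 2:
        return [cell]
    return daughters
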