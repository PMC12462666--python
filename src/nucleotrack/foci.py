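"""Two-tier fluorescent spot model: point maxima and area-based foci.

Point maxima are single-pixel local maxima of the (lightly smoothed)
in-cell fluorescence whose height above the in-cell minimum exceeds a
fraction of the cell's dynamic range — a rule invariant to constant
intensity offsets.  Region foci are connected components above an in-cell
``mean + k.SD`` threshold.  The two tiers are deliberately independent:
a merged periseptal nucleoid produces two point maxima inside a single
region focus, which is exactly the distinction the downstream phenotype
classifier needs.  Focus trajectories are nearest-neighbor links in
absolute image coordinates, and short-lived trajectories are discarded.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.measure import label as sklabel

from .records import CellRecord, FocusRecord, TrajectoryRecord

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _cell_crop(fluor_img: np.ndarray, cell: CellRecord, pad: int = 2):
    r0, c0, r1, c1 = cell.bbox
    h, w = fluor_img.shape
    R0, C0 = max(0, r0 - pad), max(0, c0 - pad)
    R1, C1 = min(h, r1 + pad), min(w, c1 + pad)
    crop = np.asarray(fluor_img[R0:R1, C0:C1], dtype=float)
    mask = np.zeros_like(crop, dtype=bool)
    mask[r0 - R0 : r1 - R0, c0 - C0 : c1 - C0] = cell.mask
    return crop, mask, (R0, C0)


def detect_point_maxima(
    fluor_img: np.ndarray,
    cell: CellRecord,
    smoothing_sigma: float = 1.0,
    prominence_frac: float = 0.2,
    min_separation_px: int = 3,
    channel: str = "dna",
) -> list[FocusRecord]:
    """Single-pixel local maxima of the smoothed in-cell fluorescence.

    A pixel qualifies when it is strictly greater than all 8-connected
    in-cell neighbors and its height over the in-cell minimum is at least
    ``prominence_frac`` of the in-cell dynamic range.  Of any pair closer
    than ``min_separation_px`` the higher peak is kept.  A flat cell yields
    no maxima.
    """
    crop, mask, (R0, C0) = _cell_crop(fluor_img, cell)
    if smoothing_sigma > 0:
        crop = ndimage.gaussian_filter(crop, smoothing_sigma)
    vals = crop[mask]
    if vals.size == 0:
        return []
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return []
    threshold = lo + prominence_frac * (hi - lo)

    work = np.where(mask, crop, -np.inf)
    h, w = work.shape
    peaks = []
    ys, xs = np.nonzero(mask)
    for y, x in zip(ys, xs):
        v = work[y, x]
        if v < threshold:
            continue
        is_max = True
        for dy, dx in _NEIGHBORS:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and work[ny, nx] >= v:
                is_max = False
                break
        if is_max:
            peaks.append((v, y, x))

    peaks.sort(key=lambda p: -p[0])
    kept: list[tuple[float, int, int]] = []
    for v, y, x in peaks:
        if all(
            (y - ky) ** 2 + (x - kx) ** 2 >= min_separation_px**2
            for _, ky, kx in kept
        ):
            kept.append((v, y, x))

    records = []
    for i, (v, y, x) in enumerate(kept):
        gy, gx = y + R0, x + C0
        records.append(
            FocusRecord(
                focus_id=i,
                channel=channel,
                frame=cell.frame,
                cell_id=cell.cell_id,
                kind="point_maximum",
                centroid=(float(gy), float(gx)),
                axial_s_um=cell.axial_coordinate_um(gy, gx),
                peak_intensity=float(v),
            )
        )
    return records


def detect_region_foci(
    fluor_img: np.ndarray,
    cell: CellRecord,
    k_sd: float = 2.0,
    min_area_px: int = 4,
    threshold_frac: Optional[float] = None,
    channel: str = "dna",
) -> list[FocusRecord]:
    """Area-based foci: connected in-cell regions above a statistical threshold.

    The default threshold is the in-cell ``mean + k_sd * SD``; pass
    ``threshold_frac`` to use a fraction of the in-cell maximum instead.
    Centroids are intensity-weighted; regions below ``min_area_px`` are
    dropped.
    """
    crop, mask, (R0, C0) = _cell_crop(fluor_img, cell)
    vals = crop[mask]
    if vals.size == 0 or np.ptp(vals) == 0:
        return []
    if threshold_frac is not None:
        thr = threshold_frac * float(vals.max())
    else:
        thr = float(vals.mean() + k_sd * vals.std())
    above = mask & (crop >= thr)
    labels = sklabel(above, connectivity=2)
    records = []
    for lab in range(1, labels.max() + 1):
        region = labels == lab
        if region.sum() < min_area_px:
            continue
        yy, xx = np.nonzero(region)
        weights = crop[yy, xx]
        cy = float(np.average(yy, weights=weights) + R0)
        cx = float(np.average(xx, weights=weights) + C0)
        records.append(
            FocusRecord(
                focus_id=len(records),
                channel=channel,
                frame=cell.frame,
                cell_id=cell.cell_id,
                kind="region_focus",
                centroid=(cy, cx),
                axial_s_um=cell.axial_coordinate_um(cy, cx),
                peak_intensity=float(weights.max()),
                region_pixels=np.column_stack([yy + R0, xx + C0]),
                area_um2=float(region.sum()) * cell.pixel_size_um**2,
            )
        )
    return records


def track_foci(
    foci_by_frame: list[list[FocusRecord]],
    min_lifespan: int = 5,
    max_disp_px: float = 5.0,
) -> list[TrajectoryRecord]:
    """Nearest-neighbor focus linking in absolute image coordinates.

    Links between consecutive frames are taken greedily in order of
    increasing displacement, capped at ``max_disp_px``; an unlinked focus
    starts a new trajectory.  Trajectories shorter than ``min_lifespan``
    frames are discarded.
    """
    open_traj: list[tuple[list[int], list[FocusRecord]]] = []
    finished: list[tuple[list[int], list[FocusRecord]]] = []

    for frame_idx, foci in enumerate(foci_by_frame):
        pairs = []
        for ti, (_, traj) in enumerate(open_traj):
            last = np.array(traj[-1].centroid)
            for fi, f in enumerate(foci):
                d = float(np.linalg.norm(np.array(f.centroid) - last))
                if d <= max_disp_px:
                    pairs.append((d, ti, fi))
        pairs.sort(key=lambda t: t[0])
        taken_t: set[int] = set()
        taken_f: set[int] = set()
        links: dict[int, int] = {}
        for d, ti, fi in pairs:
            if ti in taken_t or fi in taken_f:
                continue
            links[ti] = fi
            taken_t.add(ti)
            taken_f.add(fi)

        still = []
        for ti, (frames, traj) in enumerate(open_traj):
            if ti in links:
                frames.append(frame_idx)
                traj.append(foci[links[ti]])
                still.append((frames, traj))
            else:
                finished.append((frames, traj))
        for fi, f in enumerate(foci):
            if fi not in taken_f:
                still.append(([frame_idx], [f]))
        open_traj = still

    finished.extend(open_traj)
    out = []
    for frames, traj in finished:
        if len(frames) >= min_lifespan:
            out.append(
                TrajectoryRecord(
                    trajectory_id=len(out),
                    channel=traj[0].channel,
                    frames=frames,
                    foci=traj,
                )
            )
    return out


def relative_midcell_distance(focus: FocusRecord, cell: CellRecord) -> float:
    """|s - L/2| / L for a focus at axial position s in a cell of length L.

    Ranges from 0 (midcell) to 0.5 (pole)."""
    if cell.length_um <= 0:
        raise ValueError("cell length must be positive")
    if not cell.contains(*focus.centroid):
        raise ValueError("focus centroid lies outside the cell mask")
    d = abs(focus.axial_s_um - cell.length_um / 2.0) / cell.length_um
    return float(min(d, 0.5))
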