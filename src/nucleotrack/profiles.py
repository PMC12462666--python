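"""Axial fluorescence profiles, the 80%-of-maximum width statistic, and
kymograph heat maps.

Profiles average in-cell intensity per axial bin after projecting each
pixel onto the cell's medial axis.  The DNA-distribution statistic is the
distance between the *outer* bounds of a (usually symmetrized) profile at a
fraction of its maximum — a dip between two peaks does not terminate the
span.  Kymographs stack row-normalized profiles over time, either for one
tracked cell or averaged over a population in normalized-length
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import CellRecord


@dataclass
class AxialProfile:
    """Mean intensity along a cell's long axis.

    ``grid`` holds bin centers, in um from pole A or in normalized [0, 1]
    units; ``values`` is the mean intensity per bin (NaN-free: empty bins
    are filled by linear interpolation from their neighbors).
    """

    grid: np.ndarray
    values: np.ndarray
    cell_id: object = None
    frame: int | None = None
    normalized: bool = False


@dataclass
class KymographMatrix:
    """Time x normalized-axial-position intensity distribution.

    Every row is a relative distribution summing to one; ``n_cells`` counts
    the cells contributing to each time row.
    """

    matrix: np.ndarray  # (T, n_bins)
    times_min: np.ndarray
    n_cells: np.ndarray


def axial_profile(
    fluor_img: np.ndarray,
    cell: CellRecord,
    n_bins: int = 50,
    normalized: bool = True,
) -> AxialProfile:
    """Bin in-cell pixel intensities by axial position along the medial axis."""
    if cell.axis.shape[0] < 2:
        raise ValueError("degenerate medial axis")
    coords = cell.pixel_coords()
    # nearest axis vertex -> arc-length position
    d2 = (
        (coords[:, None, 0] - cell.axis[None, :, 0]) ** 2
        + (coords[:, None, 1] - cell.axis[None, :, 1]) ** 2
    )
    nearest = np.argmin(d2, axis=1)
    steps = np.linalg.norm(np.diff(cell.axis, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(steps)]) * cell.pixel_size_um
    s = arc[nearest]
    total = arc[-1] if arc[-1] > 0 else 1.0

    intens = np.asarray(fluor_img, dtype=float)[coords[:, 0], coords[:, 1]]
    x = s / total if normalized else s
    hi = 1.0 if normalized else total
    edges = np.linspace(0.0, hi, n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=intens, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    values = np.full(n_bins, np.nan)
    nz = counts > 0
    values[nz] = sums[nz] / counts[nz]
    if (~nz).any() and nz.any():
        values[~nz] = np.interp(centers[~nz], centers[nz], values[nz])
    return AxialProfile(
        grid=centers, values=values, cell_id=cell.cell_id, frame=cell.frame,
        normalized=normalized,
    )


def symmetrize(profile: AxialProfile) -> AxialProfile:
    """Average the profile with its mirror: out(x) = (in(x) + in(L-x)) / 2."""
    vals = 0.5 * (profile.values + profile.values[::-1])
    return AxialProfile(
        grid=profile.grid.copy(), values=vals, cell_id=profile.cell_id,
        frame=profile.frame, normalized=profile.normalized,
    )


def width_at_fraction(
    grid: np.ndarray | AxialProfile,
    values: np.ndarray | None = None,
    fraction: float = 0.8,
) -> float:
    """Outer-bounds width of a profile at ``fraction`` of its maximum.

    The left bound is the first grid position (interpolated between the
    bracketing samples) where the profile reaches the threshold from the
    left, the right bound the last from the right; the width is their
    separation.  Interior dips below the threshold are ignored.
    """
    if isinstance(grid, AxialProfile):
        values = grid.values
        grid = grid.grid
    g = np.asarray(grid, dtype=float)
    v = np.asarray(values, dtype=float)
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    vmax = np.nanmax(v)
    if not vmax > 0:
        raise ValueError("profile has no positive maximum")
    thr = fraction * vmax

    above = np.nonzero(v >= thr)[0]
    i, j = int(above[0]), int(above[-1])
    left = g[i]
    if i > 0 and v[i] != v[i - 1]:
        left = g[i - 1] + (thr - v[i - 1]) * (g[i] - g[i - 1]) / (v[i] - v[i - 1])
    right = g[j]
    if j < len(v) - 1 and v[j] != v[j + 1]:
        right = g[j] + (v[j] - thr) * (g[j + 1] - g[j]) / (v[j] - v[j + 1])
    return float(right - left)


def _row_normalize(rows: np.ndarray) -> np.ndarray:
    sums = rows.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return rows / sums


def cell_kymograph(
    track_records: Sequence[CellRecord],
    fluor_stack: np.ndarray,
    n_bins: int = 50,
    frame_interval_min: float = 1.0,
) -> KymographMatrix:
    """Single-cell kymograph: one row-normalized axial profile per frame."""
    if len(track_records) < 2:
        raise ValueError("a kymograph needs a track spanning at least 2 frames")
    rows, times = [], []
    for rec in sorted(track_records, key=lambda r: r.frame):
        prof = axial_profile(fluor_stack[rec.frame], rec, n_bins=n_bins)
        rows.append(prof.values)
        times.append(rec.frame * frame_interval_min)
    mat = _row_normalize(np.asarray(rows))
    return KymographMatrix(
        matrix=mat, times_min=np.asarray(times, float),
        n_cells=np.ones(len(rows), dtype=int),
    )


def population_kymograph(
    cells_by_frame: Sequence[Sequence[CellRecord]],
    fluor_stack: np.ndarray,
    n_bins: int = 50,
    frame_interval_min: float = 1.0,
) -> KymographMatrix:
    """Population kymograph in normalized-length coordinates.

    Per frame, each cell's profile is normalized to unit sum before
    averaging, so long and short cells contribute equally; rows are then
    renormalized.  Frames without cells produce all-NaN rows.
    """
    rows, times, counts = [], [], []
    for f, cells in enumerate(cells_by_frame):
        profs = []
        for rec in cells:
            p = axial_profile(fluor_stack[rec.frame], rec, n_bins=n_bins)
            s = np.nansum(p.values)
            if s > 0:
                profs.append(p.values / s)
        times.append(f * frame_interval_min)
        counts.append(len(profs))
        rows.append(
            np.mean(profs, axis=0) if profs else np.full(n_bins, np.nan)
        )
    mat = np.asarray(rows)
    good = ~np.isnan(mat).any(axis=1)
    mat[good] = _row_normalize(mat[good])
    return KymographMatrix(
        matrix=mat, times_min=np.asarray(times, float),
        n_cells=np.asarray(counts, int),
    )


def save_kymograph_png(
    kymo: KymographMatrix,
    path,
    title: str = "relative axial intensity",
    cmap: str = "viridis",
) -> None:
    """Render a kymograph matrix as a PNG heat map (time down, axis across)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.0, 3.0), constrained_layout=True)
    im = ax.imshow(
        kymo.matrix, aspect="auto", cmap=cmap, interpolation="nearest",
        extent=(0.0, 1.0, float(kymo.times_min[-1]), float(kymo.times_min[0])),
    )
    ax.set_xlabel("normalized cell length")
    ax.set_ylabel("time (min)")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="relative intensity")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def central_bin_mass(kymo: KymographMatrix, central_frac: float = 0.2) -> np.ndarray:
    """Per-row intensity mass within the central ``central_frac`` of the axis."""
    n = kymo.matrix.shape[1]
    half = max(1, int(round(central_frac * n / 2)))
    lo, hi = n // 2 - half, n // 2 + half
    return kymo.matrix[:, lo:hi].sum(axis=1)
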