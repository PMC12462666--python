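"""Synthetic time-lapse fluorescence microscopy of supercompacting rod cells.

The generator emulates the study conditions of a live-cell experiment on
ciprofloxacin-treated *E. coli*: static rod-shaped cells on a flat field,
imaged in a transmitted-light-like channel plus a DNA channel (an
HU-fluorescent-fusion proxy), optionally with two punctate focus channels
(a RecN-like and a RecA-like reporter).  Every cell carries a compaction
state from :mod:`nucleotrack.kinetics` and the DNA channel renders the
state's spatial template:

* multifocal — four axial Gaussian blobs (two nucleoids of two lobes each);
* quarter — two blobs at the +/- L/4 positions;
* midcell — one broad blob at the cell center (80%-of-max width ~25% of L);
* periseptal — two tight blobs flanking a small septum gap at midcell.

Templates conserve integrated intensity across states: compaction
redistributes signal, it does not create it.  Images are convolved with a
Gaussian PSF, then Poisson shot noise (``photon_scale`` photons per
intensity unit) and Gaussian read noise are applied on top of a planar
background.  Full ground truth (geometry, states, transition times, focus
positions) is exported alongside the stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.ndimage import gaussian_filter

from .kinetics import (
    ENDPOINT_STATES,
    MULTIFOCAL,
    STATE_NAMES,
    KineticsConfig,
    advance_states,
)
from .records import ImageStack


class PlacementError(RuntimeError):
    """Raised when the requested cells cannot be placed without overlap."""


class SceneConfig(BaseModel):
    """Geometry, optics and noise of one synthetic scene.

    Physical defaults follow a typical 100x-objective bacterial live-cell
    setup: 0.1 um pixels, 2-min frame interval, 2.5-4 um x ~0.9 um cells.
    Intensities are arbitrary units; ``photon_scale`` converts them to
    expected photon counts for the shot-noise model.
    """

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = Field(default=0.1, gt=0)
    frame_interval_s: float = Field(default=120.0, gt=0)
    n_frames: int = Field(default=16, ge=1)
    n_cells: int = Field(default=60, ge=1)
    cell_length_um: tuple[float, float] = (2.5, 4.0)
    cell_width_um: tuple[float, float] = (0.8, 1.0)
    psf_sigma_um: float = Field(default=0.10, gt=0)
    background_level: float = Field(default=20.0, ge=0)
    background_gradient: float = Field(default=0.1, ge=0)
    read_noise_sd: float = Field(default=1.0, ge=0)
    photon_scale: float = Field(default=20.0, gt=0)
    rng_seed: int = 0
    apply_noise: bool = True
    # DNA-template parameters
    dna_total_intensity: float = Field(default=600.0, gt=0)
    septum_gap_px: float = Field(default=2.0, gt=0)
    # optional punctate focus channels
    include_foci_channels: bool = False
    recn_foci_per_cell: float = Field(default=2.0, gt=0)
    p_focus_nucleoid: float = Field(default=0.5, ge=0, le=1)
    reca_foci_per_cell: float = Field(default=2.0, gt=0)
    p_reca_coloc: float = Field(default=0.5, ge=0, le=1)
    focus_intensity: float = Field(default=80.0, gt=0)
    focus_sigma_um: float = Field(default=0.12, gt=0)
    focus_jitter_px: float = Field(default=0.3, ge=0)

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.cell_length_um
        wlo, whi = self.cell_width_um
        if not (0 < lo <= hi) or not (0 < wlo <= whi):
            raise ValueError("cell size ranges must be positive and ordered")
        if whi >= lo:
            raise ValueError("cell width range must lie below cell length range")
        if min(lo, wlo) / self.pixel_size_um < 1.0:
            raise ValueError("physical sizes must resolve to >= 1 px")
        return self


@dataclass
class CellGeometry:
    """True geometry of one simulated (static) cell."""

    cell_id: int
    center_yx: tuple[float, float]  # px
    angle_rad: float  # axis angle w.r.t. +x
    length_um: float
    width_um: float

    def pole_positions_px(self, pixel_size_um: float) -> np.ndarray:
        half = self.length_um / pixel_size_um / 2.0
        dy, dx = np.sin(self.angle_rad), np.cos(self.angle_rad)
        cy, cx = self.center_yx
        return np.array(
            [[cy - half * dy, cx - half * dx], [cy + half * dy, cx + half * dx]]
        )


@dataclass
class GroundTruth:
    """Exported truth of a simulated scene.

    ``cells``: one row per cell (static geometry).  ``states``: one row per
    cell per frame with the true compaction state.  ``transitions``: per-cell
    first-passage times (min; NaN when the step never occurred within the
    movie).  ``foci``: one row per focus per frame (empty unless the focus
    channels were rendered).  ``labels`` is the static cell-id label image
    (cell_id + 1; background 0), valid for every frame because cells do not
    move.
    """

    cells: pd.DataFrame
    states: pd.DataFrame
    transitions: pd.DataFrame
    foci: pd.DataFrame
    labels: np.ndarray
    geometries: list[CellGeometry] = field(default_factory=list)

    def states_at(self, frame: int) -> pd.DataFrame:
        return self.states[self.states["frame"] == frame]


# ---------------------------------------------------------------------------
# DNA templates


def _dna_blobs(state: int, length_px: float, width_px: float, gap_px: float):
    """Axial blob layout for one state:
    (offsets_px, weights, sigma_ax_px, sigma_rad_px).

    Offsets are measured from the cell center along the axis; weights sum
    to one, so the integrated DNA signal is state-invariant.  The geometry
    is tuned so the downstream two-tier spot detectors recover the
    canonical per-state (point maxima, region foci) signature: multifocal
    cells carry two nucleoids of two lobes each with the outer lobes
    brighter, and the periseptal template adds a faint septum bridge that
    keeps its two tight lobes within a single thresholded region.
    """
    sigma_rad = max(1.2, width_px / 4.0)
    if state == MULTIFOCAL:
        off = np.array([-0.36, -0.12, 0.12, 0.36]) * length_px
        weights = np.array([0.3, 0.2, 0.2, 0.3])
        sigma_ax = max(1.3, 0.065 * length_px)
    elif state == 1:  # quarter
        off = np.array([-0.25, 0.25]) * length_px
        weights = np.array([0.5, 0.5])
        sigma_ax = max(1.5, 0.08 * length_px)
    elif state == 2:  # midcell
        off = np.array([0.0])
        weights = np.array([1.0])
        sigma_ax = 0.187 * length_px
    elif state == 3:  # periseptal
        half = gap_px / 2.0 + 2.5
        off = np.array([-half, 0.0, half])
        weights = np.array([0.35, 0.30, 0.35])
        sigma_ax = 1.2
    else:  # pragma: no cover
        raise ValueError(f"unknown state {state}")
    return off, weights, sigma_ax, sigma_rad


def _render_cell_channels(
    canvas_dna: np.ndarray,
    canvas_tl: np.ndarray,
    geom: CellGeometry,
    state: int,
    scene: SceneConfig,
) -> None:
    """Accumulate one cell's noise-free DNA and TL signal in place."""
    px = scene.pixel_size_um
    L = geom.length_um / px
    W = geom.width_um / px
    cy, cx = geom.center_yx
    H, Wi = canvas_dna.shape

    margin = L / 2 + W + 4
    r0 = max(0, int(np.floor(cy - margin)))
    r1 = min(H, int(np.ceil(cy + margin)) + 1)
    c0 = max(0, int(np.floor(cx - margin)))
    c1 = min(Wi, int(np.ceil(cx + margin)) + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - cy
    dx = xx - cx
    ca, sa = np.cos(geom.angle_rad), np.sin(geom.angle_rad)
    u = dx * ca + dy * sa  # axial
    v = -dx * sa + dy * ca  # radial

    # spherocylinder mask: distance to the axis segment of half-length (L-W)/2
    half_seg = max(0.0, (L - W) / 2.0)
    uc = np.clip(u, -half_seg, half_seg)
    dist = np.hypot(u - uc, v)
    inside = dist <= W / 2.0

    # TL-like channel: bright background, dark interior, darkest rim
    q = np.clip(dist / (W / 2.0), 0.0, 1.0)
    brightness = np.where(inside, 0.55 - 0.35 * q, 1.0)
    patch = canvas_tl[r0:r1, c0:c1]
    patch[:] = np.minimum(patch, brightness)

    # DNA channel: normalized Gaussian blobs, total mass state-invariant
    offsets, weights, s_ax, s_rad = _dna_blobs(state, L, W, scene.septum_gap_px)
    dna = np.zeros_like(u)
    for o, wt in zip(offsets, weights):
        amp = scene.dna_total_intensity * wt / (2.0 * np.pi * s_ax * s_rad)
        dna += amp * np.exp(
            -((u - o) ** 2) / (2 * s_ax**2) - (v**2) / (2 * s_rad**2)
        )
    canvas_dna[r0:r1, c0:c1] += dna


def _render_focus(canvas: np.ndarray, y: float, x: float, scene: SceneConfig) -> None:
    s = scene.focus_sigma_um / scene.pixel_size_um
    r = int(np.ceil(4 * s))
    H, W = canvas.shape
    r0, r1 = max(0, int(y) - r), min(H, int(y) + r + 1)
    c0, c1 = max(0, int(x) - r), min(W, int(x) + r + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    amp = scene.focus_intensity / (2 * np.pi * s**2)
    canvas[r0:r1, c0:c1] += amp * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2 * s**2)
    )


def _background_plane(scene: SceneConfig) -> np.ndarray:
    H, W = scene.image_size_px
    gy = (np.arange(H) / max(H - 1, 1) - 0.5)[:, None]
    gx = (np.arange(W) / max(W - 1, 1) - 0.5)[None, :]
    return scene.background_level * (1.0 + scene.background_gradient * (gy + gx))


def _apply_noise(signal: np.ndarray, scene: SceneConfig, rng: np.random.Generator):
    counts = rng.poisson(np.clip(signal, 0, None) * scene.photon_scale)
    img = counts / scene.photon_scale
    if scene.read_noise_sd > 0:
        img = img + rng.normal(0.0, scene.read_noise_sd, size=img.shape)
    return img.astype(np.float32)


def render_frame(
    geometries: list[CellGeometry],
    states: np.ndarray,
    scene: SceneConfig,
    rng: Optional[np.random.Generator] = None,
    foci_positions: Optional[dict[str, np.ndarray]] = None,
) -> np.ndarray:
    """Render one multi-channel frame (C x Y x X) from ground truth.

    Channel order is ``tl, dna`` plus one channel per key of
    ``foci_positions`` (each an (n, 2) array of (y, x) centers).  Noise is
    applied only when ``scene.apply_noise`` and an ``rng`` is given.
    """
    H, W = scene.image_size_px
    dna = np.zeros((H, W), dtype=float)
    tl = np.ones((H, W), dtype=float)
    for geom, state in zip(geometries, states):
        _render_cell_channels(dna, tl, geom, int(state), scene)

    psf_px = scene.psf_sigma_um / scene.pixel_size_um
    channels = [gaussian_filter(tl, psf_px) * scene.background_level]
    channels.append(gaussian_filter(dna, psf_px) + _background_plane(scene))
    if foci_positions:
        for name in foci_positions:
            ch = np.zeros((H, W), dtype=float)
            for y, x in foci_positions[name]:
                _render_focus(ch, y, x, scene)
            channels.append(gaussian_filter(ch, psf_px) + _background_plane(scene))

    out = np.stack(channels)
    if scene.apply_noise:
        if rng is None:
            raise ValueError("rng required when apply_noise is set")
        out = np.stack([_apply_noise(c, scene, rng) for c in out])
    return out.astype(np.float32)


# ---------------------------------------------------------------------------
# placement and simulation


def _place_cells(scene: SceneConfig, rng: np.random.Generator) -> list[CellGeometry]:
    H, W = scene.image_size_px
    px = scene.pixel_size_um
    occupied = np.zeros((H, W), dtype=bool)
    geoms: list[CellGeometry] = []
    attempts = 0
    max_attempts = 300 * scene.n_cells
    border = 3.0
    while len(geoms) < scene.n_cells:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {len(geoms)}/{scene.n_cells} cells after "
                f"{max_attempts} attempts; reduce n_cells or enlarge the image"
            )
        attempts += 1
        L = rng.uniform(*scene.cell_length_um) / px
        Wc = rng.uniform(*scene.cell_width_um) / px
        angle = rng.uniform(0.0, np.pi)
        half = L / 2 + Wc / 2 + border
        cy = rng.uniform(half, H - half)
        cx = rng.uniform(half, W - half)

        r0, r1 = max(0, int(cy - half)), min(H, int(np.ceil(cy + half)) + 1)
        c0, c1 = max(0, int(cx - half)), min(W, int(np.ceil(cx + half)) + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        ca, sa = np.cos(angle), np.sin(angle)
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        half_seg = max(0.0, (L - Wc) / 2.0)
        uc = np.clip(u, -half_seg, half_seg)
        # footprint dilated by a 2-px exclusion margin
        foot = np.hypot(u - uc, v) <= Wc / 2.0 + 2.0
        if occupied[r0:r1, c0:c1][foot].any():
            continue
        occupied[r0:r1, c0:c1] |= foot
        geoms.append(
            CellGeometry(
                cell_id=len(geoms),
                center_yx=(float(cy), float(cx)),
                angle_rad=float(angle),
                length_um=L * px,
                width_um=Wc * px,
            )
        )
    return geoms


def _label_image(geoms: list[CellGeometry], scene: SceneConfig) -> np.ndarray:
    H, W = scene.image_size_px
    labels = np.zeros((H, W), dtype=np.uint16)
    px = scene.pixel_size_um
    for g in geoms:
        L, Wc = g.length_um / px, g.width_um / px
        cy, cx = g.center_yx
        half = L / 2 + Wc / 2 + 2
        r0, r1 = max(0, int(cy - half)), min(H, int(np.ceil(cy + half)) + 1)
        c0, c1 = max(0, int(cx - half)), min(W, int(np.ceil(cx + half)) + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        ca, sa = np.cos(g.angle_rad), np.sin(g.angle_rad)
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        half_seg = max(0.0, (L - Wc) / 2.0)
        uc = np.clip(u, -half_seg, half_seg)
        inside = np.hypot(u - uc, v) <= Wc / 2.0
        labels[r0:r1, c0:c1][inside] = g.cell_id + 1
    return labels


def _axial_to_yx(geom: CellGeometry, s_off_px: float, v_px: float = 0.0):
    """Map an axial offset from the cell center (px) to global (y, x)."""
    ca, sa = np.cos(geom.angle_rad), np.sin(geom.angle_rad)
    cy, cx = geom.center_yx
    return (cy + s_off_px * sa - v_px * ca, cx + s_off_px * ca + v_px * sa)


def _sample_foci(
    geoms: list[CellGeometry],
    scene: SceneConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Static base positions of RecN-like and RecA-like foci (one row each)."""
    px = scene.pixel_size_um
    rows = []
    fid = 0
    for g in geoms:
        Lpx = g.length_um / px
        n_recn = max(1, rng.poisson(scene.recn_foci_per_cell))
        recn_pos = []
        for _ in range(n_recn):
            if rng.random() < scene.p_focus_nucleoid:
                s = rng.uniform(-0.15, 0.15) * Lpx  # nucleoid-proximal
            else:
                s = rng.choice([-1.0, 1.0]) * (Lpx / 2 - 0.4 / px)  # pole
            y, x = _axial_to_yx(g, s, rng.uniform(-0.5, 0.5))
            recn_pos.append((y, x, s))
            rows.append(
                dict(focus_id=fid, channel="recn", cell_id=g.cell_id,
                     y=y, x=x, s_off_px=s)
            )
            fid += 1
        n_reca = max(1, rng.poisson(scene.reca_foci_per_cell))
        for _ in range(n_reca):
            if recn_pos and rng.random() < scene.p_reca_coloc:
                y0, x0, s = recn_pos[rng.integers(len(recn_pos))]
                y, x = y0 + rng.uniform(-0.5, 0.5), x0 + rng.uniform(-0.5, 0.5)
            else:
                s = rng.uniform(-0.4, 0.4) * Lpx
                y, x = _axial_to_yx(g, s, rng.uniform(-0.5, 0.5))
            rows.append(
                dict(focus_id=fid, channel="reca", cell_id=g.cell_id,
                     y=y, x=x, s_off_px=s)
            )
            fid += 1
    return pd.DataFrame(rows)


def simulate_timelapse(
    scene: SceneConfig, kinetics: KineticsConfig
) -> tuple[ImageStack, GroundTruth]:
    """Simulate a full time-lapse and its ground truth.

    Identical configurations (including ``rng_seed``) produce bit-identical
    stacks and truth tables.
    """
    rng = np.random.default_rng(scene.rng_seed)
    geoms = _place_cells(scene, rng)
    labels = _label_image(geoms, scene)
    dt_min = scene.frame_interval_s / 60.0

    cells_df = pd.DataFrame(
        [
            dict(
                cell_id=g.cell_id,
                centroid_y=g.center_yx[0],
                centroid_x=g.center_yx[1],
                angle_rad=g.angle_rad,
                length_um=g.length_um,
                width_um=g.width_um,
            )
            for g in geoms
        ]
    )

    base_foci = (
        _sample_foci(geoms, scene, rng)
        if scene.include_foci_channels
        else pd.DataFrame(
            columns=["focus_id", "channel", "cell_id", "y", "x", "s_off_px"]
        )
    )

    n = len(geoms)
    states = np.full(n, MULTIFOCAL, dtype=np.int64)
    t_quarter = np.full(n, np.nan)
    t_end = np.full(n, np.nan)

    frames = []
    state_rows = []
    foci_rows = []
    channel_names = ["tl", "dna"]
    if scene.include_foci_channels:
        channel_names += ["recn", "reca"]

    for f in range(scene.n_frames):
        t_now = f * dt_min
        for cid in range(n):
            state_rows.append(
                dict(frame=f, time_min=t_now, cell_id=cid,
                     state=int(states[cid]),
                     state_name=STATE_NAMES[int(states[cid])])
            )
        foci_pos = None
        if scene.include_foci_channels:
            jit = rng.normal(0.0, scene.focus_jitter_px, size=(len(base_foci), 2)) \
                if scene.focus_jitter_px > 0 and len(base_foci) else 0.0
            ys = base_foci["y"].to_numpy() + (jit[:, 0] if np.ndim(jit) else 0.0)
            xs = base_foci["x"].to_numpy() + (jit[:, 1] if np.ndim(jit) else 0.0)
            foci_pos = {
                "recn": np.column_stack(
                    [ys[base_foci["channel"] == "recn"],
                     xs[base_foci["channel"] == "recn"]]
                ),
                "reca": np.column_stack(
                    [ys[base_foci["channel"] == "reca"],
                     xs[base_foci["channel"] == "reca"]]
                ),
            }
            for i, row in base_foci.reset_index(drop=True).iterrows():
                foci_rows.append(
                    dict(frame=f, focus_id=int(row["focus_id"]),
                         channel=row["channel"], cell_id=int(row["cell_id"]),
                         y=float(ys[i]), x=float(xs[i]))
                )
        frames.append(render_frame(geoms, states, scene, rng, foci_pos))

        new_states = advance_states(states, dt_min, kinetics, rng, t_min=t_now)
        t_next = t_now + dt_min
        just_quarter = (states == MULTIFOCAL) & (new_states != MULTIFOCAL)
        just_end = ~np.isin(states, ENDPOINT_STATES) & np.isin(
            new_states, ENDPOINT_STATES
        )
        t_quarter[just_quarter & np.isnan(t_quarter)] = t_next
        t_end[just_end] = t_next
        states = new_states

    transitions = pd.DataFrame(
        dict(
            cell_id=np.arange(n),
            t_quarter_min=t_quarter,
            t_end_min=t_end,
            end_state=[
                STATE_NAMES[int(s)] if s in ENDPOINT_STATES else ""
                for s in states
            ],
        )
    )
    stack = ImageStack(
        pixels=np.stack(frames),
        pixel_size_um=scene.pixel_size_um,
        frame_interval_s=scene.frame_interval_s,
        channel_names=channel_names,
    )
    truth = GroundTruth(
        cells=cells_df,
        states=pd.DataFrame(state_rows),
        transitions=transitions,
        foci=pd.DataFrame(foci_rows) if foci_rows else base_foci.iloc[0:0],
        labels=labels,
        geometries=geoms,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# noise calibration helpers


def estimate_snr(scene: SceneConfig) -> float:
    """Predicted SNR: dimmest state-template blob peak over background noise SD.

    The dimmest blobs belong to the multifocal template (total DNA intensity
    split four ways).  Noise SD combines shot noise at the background level
    and read noise in quadrature; the PSF widens the blob before the peak is
    measured.
    """
    px = scene.pixel_size_um
    L = np.mean(scene.cell_length_um) / px
    W = np.mean(scene.cell_width_um) / px
    _, weights, s_ax, s_rad = _dna_blobs(MULTIFOCAL, L, W, scene.septum_gap_px)
    psf = scene.psf_sigma_um / px
    s_ax_e = np.hypot(s_ax, psf)
    s_rad_e = np.hypot(s_rad, psf)
    peak = scene.dna_total_intensity * weights.min() / (2 * np.pi * s_ax_e * s_rad_e)
    noise_sd = np.sqrt(
        scene.background_level / scene.photon_scale + scene.read_noise_sd**2
    )
    return float(peak / noise_sd)


def read_noise_for_snr(scene: SceneConfig, snr: float) -> float:
    """Read-noise SD that hits a target SNR at the scene's other settings."""
    base = scene.model_copy(update={"read_noise_sd": 0.0})
    snr0 = estimate_snr(base)  # shot-noise-only SNR
    if snr0 <= snr:
        raise ValueError(
            f"target SNR {snr} unreachable: shot noise alone gives {snr0:.2f}"
        )
    px = scene.pixel_size_um
    L = np.mean(scene.cell_length_um) / px
    W = np.mean(scene.cell_width_um) / px
    _, weights, s_ax, s_rad = _dna_blobs(MULTIFOCAL, L, W, scene.septum_gap_px)
    psf = scene.psf_sigma_um / px
    peak = scene.dna_total_intensity * weights.min() / (
        2 * np.pi * np.hypot(s_ax, psf) * np.hypot(s_rad, psf)
    )
    var = (peak / snr) ** 2 - scene.background_level / scene.photon_scale
    return float(np.sqrt(var))
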