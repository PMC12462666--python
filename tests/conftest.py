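"""Shared fixtures: single-cell renders and full simulated replicates.

The heavy simulated datasets (three replicates per noise regime) are
session-scoped so the end-to-end recovery, segmentation-quality and
kymograph tests share one simulation each.
"""

from __future__ import annotations

import numpy as np
import pytest

from nucleotrack.kinetics import KineticsConfig
from nucleotrack.segment import cell_from_mask, segment_cells
from nucleotrack.synthetic import (
    CellGeometry,
    SceneConfig,
    read_noise_for_snr,
    render_frame,
    simulate_timelapse,
)

STATE_CODE = {"multifocal": 0, "quarter": 1, "midcell": 2, "periseptal": 3}


@pytest.fixture(scope="session")
def noise_free_scene() -> SceneConfig:
    return SceneConfig(image_size_px=(256, 256), apply_noise=False)


def render_single_cell(
    state: str,
    scene: SceneConfig,
    angle: float = 0.3,
    length_um: float = 3.2,
    width_um: float = 0.9,
):
    """Render one cell in a known state; return (tl, dna, CellRecord, geometry)."""
    geom = CellGeometry(
        cell_id=0, center_yx=(60.0, 128.0), angle_rad=angle,
        length_um=length_um, width_um=width_um,
    )
    img = render_frame([geom], np.array([STATE_CODE[state]]), scene)
    cells = segment_cells(img[0], scene.pixel_size_um)
    assert len(cells) == 1, "single-cell render must segment to one cell"
    return img[0], img[1], cells[0], geom


@pytest.fixture(scope="session")
def single_cell_by_state(noise_free_scene):
    return {
        state: render_single_cell(state, noise_free_scene)
        for state in STATE_CODE
    }


def rectangle_cell(height: int = 9, width: int = 40, pixel_size_um: float = 0.1):
    """A synthetic rectangular cell mask for detector unit tests."""
    mask = np.zeros((height + 10, width + 10), dtype=bool)
    mask[5 : 5 + height, 5 : 5 + width] = True
    rec = cell_from_mask(mask, cell_id=0, frame=0, pixel_size_um=pixel_size_um)
    assert rec is not None
    return rec


def spherocylinder_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    length_px: float,
    width_px: float,
    angle: float,
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - center[1]) * ca + (yy - center[0]) * sa
    v = -(xx - center[1]) * sa + (yy - center[0]) * ca
    half_seg = max(0.0, (length_px - width_px) / 2.0)
    uc = np.clip(u, -half_seg, half_seg)
    return np.hypot(u - uc, v) <= width_px / 2.0


# ---------------------------------------------------------------------------
# replicate-scale simulations (shared by the end-to-end tests)

_RECOVERY_KINETICS = KineticsConfig(
    k1_per_min=0.3, k2_per_min=0.3, lag_min=8.0, p_periseptal=0.15
)


def _replicate_scene(seed: int, noise: bool) -> SceneConfig:
    scene = SceneConfig(
        image_size_px=(1024, 1024),
        n_cells=300,
        n_frames=8,
        rng_seed=seed,
        apply_noise=noise,
        photon_scale=100.0,
    )
    if noise:
        scene = scene.model_copy(
            update={"read_noise_sd": read_noise_for_snr(scene, 5.0)}
        )
    return scene


@pytest.fixture(scope="session")
def replicates_noise_free():
    """Three noise-free 300-cell replicates of the supercompaction process."""
    return [
        simulate_timelapse(_replicate_scene(seed, noise=False), _RECOVERY_KINETICS)
        for seed in (11, 12, 13)
    ]


@pytest.fixture(scope="session")
def replicates_snr5():
    """Three SNR=5 300-cell replicates of the supercompaction process."""
    return [
        simulate_timelapse(_replicate_scene(seed, noise=True), _RECOVERY_KINETICS)
        for seed in (21, 22, 23)
    ]


def _classify_replicates(replicates):
    """Preprocess once, classify, and return the background-subtracted stack."""
    from nucleotrack.pipeline import classify_stack
    from nucleotrack.preprocess import preprocess_stack

    out = []
    for stack, truth in replicates:
        work = preprocess_stack(stack)
        cells_by_frame, calls = classify_stack(work, preprocess=False)
        out.append((work, truth, cells_by_frame, calls))
    return out


@pytest.fixture(scope="session")
def classified_noise_free(replicates_noise_free):
    """Noise-free replicates run through the full classification pipeline."""
    return _classify_replicates(replicates_noise_free)


@pytest.fixture(scope="session")
def classified_snr5(replicates_snr5):
    """SNR=5 replicates run through the full classification pipeline."""
    return _classify_replicates(replicates_snr5)
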