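"""Reading and writing stacks, truth tables and result tables.

Stacks go to multi-page TIFF with TCYX axes via :mod:`tifffile`; ground
truth and results are tidy CSV tables plus a JSON scene manifest embedding
the full configuration and seed, so any simulated dataset can be
regenerated exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .kinetics import KineticsConfig
from .records import ImageStack
from .synthetic import GroundTruth, SceneConfig


def write_stack(path: str | Path, stack: ImageStack) -> None:
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.pixels.astype(np.float32),
        metadata={
            "axes": "TCYX",
            "pixel_size_um": stack.pixel_size_um,
            "frame_interval_s": stack.frame_interval_s,
            "channel_names": stack.channel_names,
        },
    )


def read_stack(path: str | Path) -> ImageStack:
    with tifffile.TiffFile(str(path)) as tf:
        pixels = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if pixels.ndim == 3:  # single channel stored as TYX
        pixels = pixels[:, None]
    return ImageStack(
        pixels=pixels,
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        frame_interval_s=float(meta.get("frame_interval_s", 1.0)),
        channel_names=list(
            meta.get("channel_names", [f"ch{i}" for i in range(pixels.shape[1])])
        ),
    )


def write_simulation(
    outdir: str | Path,
    stack: ImageStack,
    truth: GroundTruth,
    scene: SceneConfig,
    kinetics: KineticsConfig,
) -> None:
    """Write a simulated dataset: TIFF stack, truth CSVs, scene manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_stack(outdir / "stack.tif", stack)
    truth.cells.to_csv(outdir / "cells.csv", index=False)
    truth.states.to_csv(outdir / "states.csv", index=False)
    truth.transitions.to_csv(outdir / "transitions.csv", index=False)
    truth.foci.to_csv(outdir / "foci.csv", index=False)
    tifffile.imwrite(outdir / "labels.tif", truth.labels)
    manifest = {
        "scene": scene.model_dump(),
        "kinetics": kinetics.model_dump(),
        "channel_names": stack.channel_names,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_manifest(outdir: str | Path) -> tuple[SceneConfig, KineticsConfig]:
    manifest = json.loads((Path(outdir) / "manifest.json").read_text())
    return (
        SceneConfig(**manifest["scene"]),
        KineticsConfig(**manifest["kinetics"]),
    )


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
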