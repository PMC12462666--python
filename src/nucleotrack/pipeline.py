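"""End-to-end convenience pipeline: stack -> cells -> phenotype calls.

These helpers wire the module-level operations together in the canonical
order (preprocess, segment the TL channel, filter by geometry, classify
from the DNA channel) and provide ground-truth matching for validation on
simulated data.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .kinetics import STATE_NAMES
from .phenotype import PhenotypeCall, classify_frame, phenotype_fractions
from .preprocess import PreprocessConfig, preprocess_stack
from .records import CellRecord, ImageStack
from .segment import GeometryLimits, filter_cells, segment_cells
from .synthetic import GroundTruth


def segment_stack(
    stack: ImageStack,
    limits: Optional[GeometryLimits] = None,
    tl_channel: str = "tl",
) -> list[list[CellRecord]]:
    """Segment and geometry-filter every frame of the TL channel."""
    tl = stack.channel(tl_channel)
    out = []
    for f in range(stack.n_frames):
        cells = segment_cells(tl[f], stack.pixel_size_um, frame=f)
        out.append(filter_cells(cells, limits))
    return out


def classify_stack(
    stack: ImageStack,
    cells_by_frame: Optional[list[list[CellRecord]]] = None,
    dna_channel: str = "dna",
    preprocess: bool = True,
    preprocess_config: Optional[PreprocessConfig] = None,
    limits: Optional[GeometryLimits] = None,
) -> tuple[list[list[CellRecord]], list[PhenotypeCall]]:
    """Run the full classification pipeline on a stack.

    Returns the per-frame cell records and the flat list of phenotype
    calls.  Segmentation is redone unless ``cells_by_frame`` is supplied.
    """
    work = preprocess_stack(stack, preprocess_config) if preprocess else stack
    if cells_by_frame is None:
        cells_by_frame = segment_stack(work, limits)
    dna = work.channel(dna_channel)
    calls: list[PhenotypeCall] = []
    for f, cells in enumerate(cells_by_frame):
        calls.extend(classify_frame(dna[f], cells))
    return cells_by_frame, calls


def match_cells_to_truth(
    cells_by_frame: list[list[CellRecord]], truth: GroundTruth
) -> pd.DataFrame:
    """Match segmented cells to ground-truth ids via the truth label image.

    A cell matches the truth id whose label covers the majority of its
    mask pixels (0 = unmatched/background).  One row per segmented cell
    per frame.
    """
    rows = []
    for f, cells in enumerate(cells_by_frame):
        for c in cells:
            coords = c.pixel_coords()
            labels = truth.labels[coords[:, 0], coords[:, 1]]
            vals, counts = np.unique(labels, return_counts=True)
            best = int(vals[np.argmax(counts)])
            rows.append(
                dict(
                    frame=f,
                    cell_id=c.cell_id,
                    true_id=best - 1 if best > 0 else -1,
                    overlap_frac=float(counts.max() / len(labels)),
                )
            )
    return pd.DataFrame(rows)


def classification_accuracy(
    calls: list[PhenotypeCall],
    cells_by_frame: list[list[CellRecord]],
    truth: GroundTruth,
) -> float:
    """Fraction of matched cell-frames whose call equals the true state."""
    match = match_cells_to_truth(cells_by_frame, truth).set_index(
        ["frame", "cell_id"]
    )
    true_states = truth.states.set_index(["frame", "cell_id"])["state"]
    n_ok = 0
    n = 0
    for call in calls:
        key = (call.frame, call.cell_id)
        if key not in match.index:
            continue
        tid = int(match.loc[key, "true_id"])
        if tid < 0:
            continue
        truth_name = STATE_NAMES[int(true_states.loc[(call.frame, tid)])]
        n += 1
        n_ok += int(call.phenotype == truth_name)
    return n_ok / n if n else float("nan")


def run_replicate(
    stack: ImageStack,
    replicate_id: str = "rep0",
    **kwargs,
):
    """Stack -> (cells, calls, phenotype fraction time series)."""
    cells_by_frame, calls = classify_stack(stack, **kwargs)
    times = {f: t for f, t in enumerate(stack.frame_times_min())}
    series = phenotype_fractions(calls, replicate_id, frame_times_min=times)
    return cells_by_frame, calls, series
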