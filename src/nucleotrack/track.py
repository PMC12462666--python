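"""Frame-to-frame cell tracking by greedy mask-overlap linking.

Antibiotic-arrested cells barely move, so maximal-IoU overlap linking with
a floor is reliable; ambiguous links (all IoU below the floor) terminate
tracks rather than risk identity swaps.  Tracks are consecutive runs — no
gap closing — and runs shorter than ``min_consecutive`` frames are
discarded, with their records left untagged.
"""

from __future__ import annotations

import numpy as np

from .records import CellRecord, Track


def mask_iou(a: CellRecord, b: CellRecord) -> float:
    """Intersection-over-union of two cells' pixel masks."""
    ar0, ac0, ar1, ac1 = a.bbox
    br0, bc0, br1, bc1 = b.bbox
    r0, c0 = max(ar0, br0), max(ac0, bc0)
    r1, c1 = min(ar1, br1), min(ac1, bc1)
    if r0 >= r1 or c0 >= c1:
        return 0.0
    sub_a = a.mask[r0 - ar0 : r1 - ar0, c0 - ac0 : c1 - ac0]
    sub_b = b.mask[r0 - br0 : r1 - br0, c0 - bc0 : c1 - bc0]
    inter = int(np.logical_and(sub_a, sub_b).sum())
    if inter == 0:
        return 0.0
    union = a.area_px + b.area_px - inter
    return inter / union


def track_cells(
    frames: list[list[CellRecord]],
    min_consecutive: int = 10,
    iou_min: float = 0.3,
) -> list[Track]:
    """Link cells across time-ordered frames into consecutive tracks.

    Candidate links between the previous frame's open tracks and the current
    frame's cells are taken greedily in order of descending IoU, subject to
    the ``iou_min`` floor; leftovers start new tracks.  Only tracks covering
    at least ``min_consecutive`` consecutive frames are returned, and each
    retained record is stamped with its ``track_id``.
    """
    next_id = 0
    open_tracks: list[Track] = []
    finished: list[Track] = []

    for cells in frames:
        candidates = []
        for ti, tr in enumerate(open_tracks):
            last = tr.records[-1]
            for ci, cell in enumerate(cells):
                iou = mask_iou(last, cell)
                if iou >= iou_min:
                    candidates.append((iou, ti, ci))
        candidates.sort(key=lambda t: -t[0])
        taken_tracks: set[int] = set()
        taken_cells: set[int] = set()
        assignments: dict[int, int] = {}
        for iou, ti, ci in candidates:
            if ti in taken_tracks or ci in taken_cells:
                continue
            assignments[ti] = ci
            taken_tracks.add(ti)
            taken_cells.add(ci)

        still_open = []
        for ti, tr in enumerate(open_tracks):
            if ti in assignments:
                tr.records.append(cells[assignments[ti]])
                still_open.append(tr)
            else:
                finished.append(tr)
        for ci, cell in enumerate(cells):
            if ci not in taken_cells:
                still_open.append(Track(track_id=next_id, records=[cell]))
                next_id += 1
        open_tracks = still_open

    finished.extend(open_tracks)
    kept = [t for t in finished if t.n_frames >= min_consecutive]
    for t in kept:
        for rec in t.records:
            rec.track_id = t.track_id
    return kept
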