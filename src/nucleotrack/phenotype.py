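"""Rule-based DNA-compaction phenotype classification and progression metrics.

Each cell in each frame is classified from the counts of DNA-channel point
maxima (``n_maxima``) and region foci (``n_foci``):

====================  =======================================
multifocal            n_maxima > 2
midcell               n_maxima == 1 (focus count immaterial)
quarter               n_maxima == 2 and n_foci > 1
periseptal            n_maxima == 2 and n_foci == 1
excluded              anything else (e.g. 0 maxima, or 2 maxima / 0 foci)
====================  =======================================

The rules partition all count pairs; every cell gets exactly one label.
Per-frame class fractions are normalized to the total cell count of the
replicate (excluded cells stay in the denominator by default).  The
progression-rate metric is the linearly interpolated time at which the
fraction of cells at a supercompaction endpoint (midcell or periseptal)
first crosses 10%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .foci import detect_point_maxima, detect_region_foci
from .records import CellRecord, PhenotypeCall

ENDPOINT_CLASSES = ("midcell", "periseptal")


def classify_cell(n_maxima: int, n_foci: int) -> str:
    """Map one cell's (point-maxima, region-foci) counts to a phenotype."""
    if n_maxima < 0 or n_foci < 0:
        raise ValueError("counts must be non-negative")
    if n_maxima > 2:
        return "multifocal"
    if n_maxima == 1:
        return "midcell"
    if n_maxima == 2:
        return "quarter" if n_foci > 1 else ("periseptal" if n_foci == 1 else "excluded")
    return "excluded"


def classify_frame(
    dna_img: np.ndarray,
    cells: Sequence[CellRecord],
    smoothing_sigma: float = 1.0,
    prominence_frac: float = 0.2,
    min_separation_px: int = 3,
    k_sd: float = 2.0,
    min_area_px: int = 4,
) -> list[PhenotypeCall]:
    """Detect both spot tiers on the DNA channel and classify every cell."""
    calls = []
    for cell in cells:
        maxima = detect_point_maxima(
            dna_img, cell, smoothing_sigma=smoothing_sigma,
            prominence_frac=prominence_frac, min_separation_px=min_separation_px,
        )
        foci = detect_region_foci(dna_img, cell, k_sd=k_sd, min_area_px=min_area_px)
        calls.append(
            PhenotypeCall(
                cell_id=cell.cell_id,
                frame=cell.frame,
                n_point_maxima=len(maxima),
                n_region_foci=len(foci),
                phenotype=classify_cell(len(maxima), len(foci)),
            )
        )
    return calls


@dataclass
class PhenotypeTimeSeries:
    """Per-frame phenotype fractions for one replicate.

    ``data`` has one row per frame: time_min, n_total, n_excluded, one
    ``frac_*`` column per class, and ``frac_endpoint`` (midcell +
    periseptal).  Frames with zero cells carry NaN fractions and are
    flagged in ``empty_frames``.
    """

    replicate_id: str
    data: pd.DataFrame
    empty_frames: list[int]

    def endpoint_fraction(self) -> pd.Series:
        return self.data.set_index("time_min")["frac_endpoint"]


def phenotype_fractions(
    calls: Sequence[PhenotypeCall],
    replicate_id: str = "rep0",
    frame_times_min: Optional[dict[int, float]] = None,
    denominator: str = "total",
) -> PhenotypeTimeSeries:
    """Per-frame phenotype fractions, normalized to the replicate cell count.

    ``denominator="total"`` (default) counts excluded cells in the
    denominator; ``"classified"`` restricts it to classified cells.
    """
    if denominator not in ("total", "classified"):
        raise ValueError("denominator must be 'total' or 'classified'")
    df = pd.DataFrame(
        [
            dict(frame=c.frame, phenotype=c.phenotype)
            for c in calls
        ]
    )
    rows, empty = [], []
    frames = sorted(df["frame"].unique()) if len(df) else []
    for f in frames:
        sub = df[df["frame"] == f]
        n_total = len(sub)
        n_excl = int((sub["phenotype"] == "excluded").sum())
        denom = n_total if denominator == "total" else n_total - n_excl
        t = frame_times_min[f] if frame_times_min else float(f)
        row = dict(frame=f, time_min=t, n_total=n_total, n_excluded=n_excl)
        if denom == 0:
            empty.append(f)
            for cls in ("multifocal", "quarter", "midcell", "periseptal"):
                row[f"frac_{cls}"] = np.nan
            row["frac_excluded"] = np.nan
            row["frac_endpoint"] = np.nan
        else:
            for cls in ("multifocal", "quarter", "midcell", "periseptal"):
                row[f"frac_{cls}"] = float((sub["phenotype"] == cls).sum()) / denom
            row["frac_excluded"] = n_excl / n_total if n_total else np.nan
            row["frac_endpoint"] = row["frac_midcell"] + row["frac_periseptal"]
        rows.append(row)
    return PhenotypeTimeSeries(
        replicate_id=replicate_id, data=pd.DataFrame(rows), empty_frames=empty
    )


@dataclass
class CrossingResult:
    time_min: Optional[float]
    left_censored: bool = False


def supercompaction_crossing_time(
    series: PhenotypeTimeSeries | tuple[np.ndarray, np.ndarray],
    threshold: float = 0.10,
) -> CrossingResult:
    """First time the endpoint fraction crosses ``threshold``.

    Linear interpolation between the bracketing samples gives the crossing
    time; if the first sampled fraction already exceeds the threshold the
    first time point is returned flagged as left-censored; if the threshold
    is never reached the result carries ``time_min=None``.
    """
    if isinstance(series, PhenotypeTimeSeries):
        t = series.data["time_min"].to_numpy(dtype=float)
        f = series.data["frac_endpoint"].to_numpy(dtype=float)
    else:
        t, f = np.asarray(series[0], float), np.asarray(series[1], float)
    good = ~np.isnan(f)
    t, f = t[good], f[good]
    if len(t) < 2:
        raise ValueError("need at least two sampled time points")
    if f[0] >= threshold:
        return CrossingResult(time_min=float(t[0]), left_censored=True)
    above = np.nonzero(f >= threshold)[0]
    if above.size == 0:
        return CrossingResult(time_min=None)
    i = int(above[0])
    t_star = t[i - 1] + (threshold - f[i - 1]) * (t[i] - t[i - 1]) / (f[i] - f[i - 1])
    return CrossingResult(time_min=float(t_star))
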