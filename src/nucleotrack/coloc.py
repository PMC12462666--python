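"""Object-based focus colocalization and the accompanying statistics.

A query focus colocalizes with a set of reference focus regions when its
centroid pixel falls inside any reference region dilated by an integer
pixel margin (8-connected dilation; margin 0 means strict containment).
This is the margin convention used for RecN-vs-DNA (margin 0) and
RecA-vs-RecN (margin 1) comparisons.  On top sit the replicate-level
statistics: colocalized-fraction time series with SEM, the
midcell-proximity contrast between colocalizing and non-colocalizing foci
tested with a one-sample t against zero, and Welch t-tests with
Holm-Sidak multiple-comparison adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .records import FocusRecord


def _regions_mask(
    reference_foci: Sequence[FocusRecord], shape: tuple[int, int]
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for ref in reference_foci:
        if ref.region_pixels is None:
            y, x = int(round(ref.centroid[0])), int(round(ref.centroid[1]))
            if 0 <= y < shape[0] and 0 <= x < shape[1]:
                mask[y, x] = True
        else:
            mask[ref.region_pixels[:, 0], ref.region_pixels[:, 1]] = True
    return mask


def colocalize(
    query_focus: FocusRecord,
    reference_foci: Sequence[FocusRecord],
    margin_px: int = 0,
    shape: Optional[tuple[int, int]] = None,
) -> bool:
    """True iff the query centroid lies within a margin-dilated reference region.

    Monotone in the margin: colocalization at margin m implies it at any
    larger margin.  Query and reference must come from the same frame.
    """
    if margin_px < 0:
        raise ValueError("margin must be a non-negative integer")
    refs = [r for r in reference_foci]
    for r in refs:
        if r.frame != query_focus.frame:
            raise ValueError("query and reference foci must share a frame")
    if not refs:
        return False
    if shape is None:
        ys = [query_focus.centroid[0]] + [
            float(r.region_pixels[:, 0].max() if r.region_pixels is not None
                  else r.centroid[0])
            for r in refs
        ]
        xs = [query_focus.centroid[1]] + [
            float(r.region_pixels[:, 1].max() if r.region_pixels is not None
                  else r.centroid[1])
            for r in refs
        ]
        shape = (int(max(ys)) + margin_px + 2, int(max(xs)) + margin_px + 2)
    mask = _regions_mask(refs, shape)
    if margin_px > 0:
        mask = ndimage.binary_dilation(
            mask, structure=np.ones((3, 3), bool), iterations=margin_px
        )
    y, x = int(round(query_focus.centroid[0])), int(round(query_focus.centroid[1]))
    if not (0 <= y < shape[0] and 0 <= x < shape[1]):
        return False
    return bool(mask[y, x])


def coloc_fraction_timeseries(records: pd.DataFrame) -> pd.DataFrame:
    """Per-frame colocalized fraction, averaged across replicates with SEM.

    ``records`` needs columns ``replicate``, ``frame``, ``colocalized``
    (bool).  Output has one row per frame: mean fraction, SEM over
    replicates, per-replicate focus counts; frames for which a replicate has
    zero query foci simply lack that replicate's contribution.
    """
    per_rep = (
        records.groupby(["frame", "replicate"])["colocalized"]
        .agg(["mean", "count"])
        .reset_index()
    )
    rows = []
    for f, sub in per_rep.groupby("frame"):
        vals = sub["mean"].to_numpy(dtype=float)
        rows.append(
            dict(
                frame=f,
                fraction=float(vals.mean()),
                sem=float(vals.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1 else np.nan,
                n_replicates=len(vals),
                n_foci=int(sub["count"].sum()),
            )
        )
    return pd.DataFrame(rows)


@dataclass
class ProximityContrast:
    """Replicate-level contrast in relative midcell distance.

    ``delta`` per replicate is mean(distance | colocalized) minus
    mean(distance | non-colocalized); negative values mean colocalizing
    foci sit closer to midcell.  The test is a one-sample t of the
    replicate deltas against zero, with the 95% CI on the replicate-mean
    scale.
    """

    per_replicate: pd.Series
    mean: float
    ci95: tuple[float, float]
    t: float
    p: float
    dropped_replicates: list


def midcell_proximity_contrast(records: pd.DataFrame) -> ProximityContrast:
    """One-sample t-test of per-replicate midcell-proximity deltas vs zero.

    ``records`` needs columns ``replicate``, ``colocalized`` (bool) and
    ``rel_midcell_distance``.  Replicates with an empty group are dropped
    with a warning entry; fewer than two usable replicates is an error.
    """
    deltas = {}
    dropped = []
    for rep, sub in records.groupby("replicate"):
        co = sub.loc[sub["colocalized"], "rel_midcell_distance"]
        nc = sub.loc[~sub["colocalized"], "rel_midcell_distance"]
        if len(co) == 0 or len(nc) == 0:
            dropped.append(rep)
            continue
        deltas[rep] = float(co.mean() - nc.mean())
    if len(deltas) < 2:
        raise ValueError("need at least two replicates with both groups populated")
    d = pd.Series(deltas)
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        # degenerate: all replicate deltas identical
        t_stat = 0.0 if mean == 0.0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0.0 else 0.0
        ci = (mean, mean)
    else:
        se = sd / np.sqrt(n)
        t_stat = mean / se
        p = float(2.0 * stats.t.sf(abs(t_stat), df=n - 1))
        tcrit = float(stats.t.ppf(0.975, df=n - 1))
        ci = (mean - tcrit * se, mean + tcrit * se)
    return ProximityContrast(
        per_replicate=d, mean=mean, ci95=ci, t=float(t_stat), p=float(p),
        dropped_replicates=dropped,
    )


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Satterthwaite df, two-tailed p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each arm needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), float(na + nb - 2), 0.0
    se2 = va / na + vb / nb
    t_stat = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2.0 * stats.t.sf(abs(t_stat), df=df))
    return float(t_stat), float(df), p


def welch_holm_sidak(
    groups_a: Sequence[np.ndarray], groups_b: Sequence[np.ndarray]
) -> pd.DataFrame:
    """Welch t per comparison with Holm-Sidak adjusted p-values.

    The step-down adjustment is p_adj(i) = max_{j<=i} 1 - (1 - p_(j))^(m-j+1)
    over ascending raw p-values, clipped at 1; adjusted values are never
    below raw ones and are monotone in rank.
    """
    if len(groups_a) != len(groups_b):
        raise ValueError("groups_a and groups_b must pair up")
    results = [welch_t(a, b) for a, b in zip(groups_a, groups_b)]
    p_raw = np.array([r[2] for r in results])
    with np.errstate(divide="ignore"):  # p_raw == 1 is a legitimate input
        _, p_adj, _, _ = multipletests(p_raw, method="holm-sidak")
    return pd.DataFrame(
        dict(
            t=[r[0] for r in results],
            df=[r[1] for r in results],
            p_raw=p_raw,
            p_adj=p_adj,
        )
    )


def foci_count_timeseries(
    foci_counts: pd.DataFrame, cell_counts: pd.DataFrame
) -> pd.DataFrame:
    """Mean foci per cell over time, with SEM across replicates.

    ``foci_counts``: columns ``replicate``, ``frame``, ``n_foci``;
    ``cell_counts``: columns ``replicate``, ``frame``, ``n_cells``.  Frames
    where a replicate has zero cells are flagged and excluded from that
    replicate's mean.
    """
    merged = foci_counts.merge(cell_counts, on=["replicate", "frame"], how="outer")
    merged["n_foci"] = merged["n_foci"].fillna(0)
    rows = []
    for f, sub in merged.groupby("frame"):
        ok = sub["n_cells"] > 0
        vals = (sub.loc[ok, "n_foci"] / sub.loc[ok, "n_cells"]).to_numpy(float)
        rows.append(
            dict(
                frame=f,
                mean_foci_per_cell=float(vals.mean()) if len(vals) else np.nan,
                sem=float(vals.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1 else np.nan,
                n_replicates=int(ok.sum()),
                flagged_zero_cells=int((~ok).sum()),
            )
        )
    return pd.DataFrame(rows)
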