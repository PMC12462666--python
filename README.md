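# nucleotrack

Single-cell quantification of antibiotic-induced **nucleoid
supercompaction** in rod-shaped bacteria from multi-channel time-lapse
fluorescence microscopy.

Severe DNA damage — for instance fluoroquinolone exposure in *E. coli* —
triggers an ordered condensation of the chromosome: the normally
multi-lobed nucleoid first fuses at the cell quarter positions and then
collapses into a single dense structure at midcell (or into two lobes
flanking a forming septum).  Quantifying this response requires a chain of
image-analysis steps: cell segmentation with medial-axis geometry, cell
and focus tracking, two-tier fluorescent-spot detection, rule-based
phenotype classification, axial intensity profiles and kymographs, and
object-based colocalization statistics for repair-protein reporters.
`nucleotrack` implements that chain as a tested, reusable library for
microscopists and image analysts, together with a synthetic-scene
generator that provides exact ground truth for validation.

## The model and the metrics

Cells progress irreversibly through compaction states

    multifocal  →  quarter-position  →  { midcell | periseptal }

after a lag *T*, with first-order step rates *k₁*, *k₂* (per minute) and
periseptal branching probability *p*.  The closed-form fraction of cells
at an endpoint state by time *t* (τ = t − T > 0) is

    P_end(t) = 1 − (k₂ e^{−k₁τ} − k₁ e^{−k₂τ}) / (k₂ − k₁),

with limit 1 − e^{−kτ}(1 + kτ) for k₁ = k₂ = k.  Dose maps to rate through
a Hill function, so higher doses progress faster by construction.

Per cell and frame, the classifier maps the counts of DNA-channel
single-pixel **point maxima** (m) and area-based **region foci** (f) to a
phenotype:

| phenotype   | rule                 |
|-------------|----------------------|
| multifocal  | m > 2                |
| midcell     | m = 1                |
| quarter     | m = 2 and f > 1      |
| periseptal  | m = 2 and f = 1      |
| excluded    | anything else        |

The headline progression metric is the **10%-crossing time**: the
linearly interpolated time at which the midcell + periseptal fraction
first reaches 10%.  The DNA-distribution statistic is the width between
the outer bounds of the (symmetrized) axial profile at 80% of its
maximum.  Colocalization is centroid-in-region with an integer pixel
margin (margin 0 for RecN-vs-DNA-style comparisons, margin 1 for
RecA-vs-RecN), with replicate-level one-sample *t* contrasts and Welch +
Holm–Šidák group tests.

## Worked example

Simulate a small movie, classify every cell in every frame, and estimate
the crossing time:

```python
import numpy as np
from nucleotrack import KineticsConfig, SceneConfig, simulate_timelapse
from nucleotrack.kinetics import crossing_time_analytic
from nucleotrack.pipeline import run_replicate

scene = SceneConfig(image_size_px=(512, 512), n_cells=60, n_frames=10,
                    rng_seed=7, apply_noise=False)
kin = KineticsConfig(k1_per_min=0.3, k2_per_min=0.3, lag_min=8.0)
stack, truth = simulate_timelapse(scene, kin)

cells, calls, series = run_replicate(stack)
print(series.data[["time_min", "frac_multifocal", "frac_quarter",
                   "frac_endpoint"]].round(3).to_string(index=False))

from nucleotrack.phenotype import supercompaction_crossing_time
est = supercompaction_crossing_time(series)
print(f"10%-crossing: {est.time_min:.2f} min "
      f"(closed form: {crossing_time_analytic(kin):.2f} min)")
```

Output:

```
 time_min  frac_multifocal  frac_quarter  frac_endpoint
      0.0            1.000         0.000          0.000
      2.0            1.000         0.000          0.000
      4.0            1.000         0.000          0.000
      6.0            1.000         0.000          0.000
      8.0            1.000         0.000          0.000
     10.0            0.683         0.317          0.000
     12.0            0.367         0.483          0.150
     14.0            0.167         0.483          0.350
     16.0            0.033         0.483          0.483
     18.0            0.017         0.333          0.650
10%-crossing: 11.33 min (closed form: 9.77 min)
```

Reading it: no cell leaves the multifocal state before the 8-min lag; the
quarter-position wave then sweeps through and endpoint states accumulate.
The interpolated time at which 10% of cells reached an endpoint
(11.33 min) sits within one 2-min frame interval of the closed-form root
of the kinetic model (9.77 min); at 60 cells the estimate carries visible
sampling noise, which shrinks at the 1000-cell sizes the validation suite
uses.

A command-line interface covers the two end-to-end paths:

```bash
nucleotrack simulate --config scene.yaml --out simdir/
nucleotrack analyze simdir/stack.tif --out results/
```

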