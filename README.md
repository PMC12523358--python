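# dungproxy

Quantifying livestock grazing intensity in free-ranging pastures is hard:
controlled experiments do not transfer, collars are expensive, and vegetation
indices are coarse. On alpine household pastures, however, yak dung pats are
countable from low-altitude UAV imagery, and repeated aerial snapshots of the
herd itself let grazing intensity be mapped directly. `dungproxy` implements
this dung-as-proxy workflow as a tested pipeline for rangeland scientists:

* **Adapted kernel density estimation** of grazing intensity. Each observed
  yak position contributes one yak·hour of occupancy spread by a unit-mass
  radially symmetric triangular kernel, `K(d) = 3/(πh²)·(1 − d/h)` for
  `d < h` with bandwidth `h = 300 m` (the hourly activity radius of yaks).
  Snapshots are weighted by the grazing hours they represent and scaled by an
  adjustment factor `A = days_in_month / monitored_days`, yielding monthly
  surfaces in yak·h·m⁻² at 1 m resolution.
* **UAV survey geometry**: footprint width `S_w·H/(f·1000)` (H in mm) and
  ground sampling distance from camera profiles, Rectangle (12 waypoints,
  20 m) and Belt (16 waypoints, 2 m) route layouts, fence/campsite exclusion
  buffers, and a riverbed-coverage image filter.
* **A virtual-pasture simulator**: a 113.64 ha pasture grazed by 278 yaks
  around a campsite concentrator with rotating night pens, hourly
  distance-decay movement, Poisson dung deposition, exponential decay with
  riverbed washout, and flight-height-dependent detection (1.0 at 2 m,
  0.9316 at 20 m) — so every downstream stage is testable without field data.
* **Calibration**: dung density (pats·m⁻²) regressed by OLS on cumulative
  grazing intensity over accumulation windows of k = 1..6 months, the
  R²-versus-k trend, flight-height accuracy comparison (Shapiro–Wilk →
  ANOVA / rank-sum), and inverse prediction of intensity from density.

## Worked example

```python
import numpy as np
from dungproxy import (SimConfig, run_virtual_study, fit_relationship,
                       sample_intensity_at)
from dungproxy.calibration import calibrate_study, r2_trend, results_from_table
from dungproxy.geometry import Footprint

ds = run_virtual_study(SimConfig(seed=0))          # full May–October study
fps = {int(r.waypoint_id): Footprint((r.x_m, r.y_m), r.width_m, r.length_m)
       for r in ds.waypoints.itertuples()}
table = calibrate_study(ds.counts, ds.monthly_estimate, fps)
print(table.groupby("k").R2.mean().round(2))
print(r2_trend(results_from_table(table)))
```

prints (seed 0)

```
k
1    0.71
2    0.82
3    0.85
4    0.86
5    0.87
6    0.88
Name: R2, dtype: float64
TrendResult(slope=0.03698635518827965, intercept=0.7101390640122235,
            r_squared=0.36521662130862764, p_value=0.003712472137047827,
            n_points=21, excluded_degenerate=0)
```

i.e. the mean coefficient of determination between waypoint dung density and
cumulative grazing intensity rises from 0.71 for same-month pairings to 0.88
for the full-season window, and the R²-on-k regression has a significantly
positive slope: the longer dung is allowed to accumulate, the better its
density indicates grazing intensity.

The same pipeline is scriptable from a shell:

```bash
dungproxy simulate  --seed 0 --outdir runs/demo
dungproxy intensity --snapshots runs/demo/snapshots.csv --outdir runs/demo/kde
dungproxy calibrate --counts runs/demo/counts_October.csv \
    --waypoints runs/demo/waypoints.csv --rasters-dir runs/demo \
    --outdir runs/demo/cal
dungproxy report --outdir runs/demo/cal --plot
```

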