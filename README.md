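# fptrack

First-passage-time analysis of GPS telemetry for movement ecology: detect
the spatial scale of area-restricted search, segment movement paths into
behavioural bouts, turn each bout into utilisation-distribution sampling
units, attach lagged environmental covariates, and rank candidate mixed
models of habitat use by AICc.

## The problem

Nomadic waterfowl in semi-arid landscapes (e.g. Egyptian Geese *Alopochen
aegyptiaca* and Red-billed Teal *Anas erythrorhyncha* in southern Africa)
track unpredictable resources — rain pulses, wetland filling, green-up of
shoreline vegetation. Whether their residence behaviour responds to
*current* conditions (reactive movement) or to *changes in the weeks before
arrival* (prescient movement) can be tested by modelling first-passage time
against environmental covariates at 16- and 32-day lags.

The analysis chain implemented here:

1. **Trajectories** — parse telemetry CSVs, split tracks at gaps > 1 week
   (suffixes `a`, `b`, `c` …), drop bouts shorter than 90 days, project to a
   local azimuthal-equidistant metre frame.
2. **First-passage time (FPT)** — for every fix and a radius sweep
   r = 100, 180, …, 9 940 m, the time to cross a circle of radius r centred
   on the fix: FPT(i, r) = (forward exit − tᵢ) + (tᵢ − backward exit), with
   exact segment–circle intersection and linear time interpolation. The
   radius r_max at which the population mean of Var[log FPT] peaks is the
   common analysis scale.
3. **Segmentation** — Lavielle-style penalised-contrast partitioning of
   each FPT series at r_max: dynamic programming minimises
   Σ n_seg·ln σ̂²_seg over breakpoints for each K; K_opt is the last K whose
   standardised-contrast second derivative exceeds S = 0.75.
4. **Utilisation distributions** — per-segment Gaussian-kernel density; the
   95% isopleth polygons are the sampling units, each carrying mFPT_Rmax
   (mean FPT at r_max over member fixes), area and occupancy window.
5. **Environment** — per polygon: current-window means and 16/32-day lagged
   differences of NDVI, mNDWI and precipitation, plus temperature,
   elevation and tagging site (12 predictors), averaging temporally over
   the occupancy window first, then spatially.
6. **Models** — 36 candidate linear mixed models
   (`log mFPT_Rmax ~ terms + (1|bird)`) fitted by ML, ranked by AICc with
   Akaike weights; marginal/conditional R², VIF/condition-number and
   residual-semivariogram diagnostics.

A synthetic-study generator (`fptrack.synthetic`) produces tracks and
raster time series with known ground truth — two-state correlated random
walks whose patch choice and dwell times follow a log-linear model in the
lagged covariates — so every stage, and the full coefficient-recovery loop,
is testable without any satellite data.

## Worked example

```python
import numpy as np
from fptrack import SimConfig, simulate_study, RunConfig, run_pipeline

bundle = simulate_study(SimConfig(seed=3))          # 3 sites x 4 birds x 120 d
report = run_pipeline(bundle["tracks"], bundle["env"],
                      bundle["elevation"], bundle["sites"], RunConfig())
print(f"r_max = {report.r_max_m:.0f} m")
print(report.selection.head(3)[["model_id", "K", "AICc", "dAICc", "weight"]])
```

prints (seed 3):

```
r_max = 2580 m
   model_id   K        AICc     dAICc    weight
0        16  10  739.089246  0.000000  0.619202
1        12   6  740.063474  0.974228  0.380436
2        18   9  754.535300 15.446054  0.000274
```

The detected scale sits near the 2 km patch radius planted by the
generator (the peak of the population Var[log FPT] curve is a grid member
by construction). The selection table ranks all 36 candidates; weights sum
to one. On this movement-level study current and lagged covariates are
intertwined (rain precedes greening precedes arrival), so the estimator-
level recovery experiment (`fptrack.synthetic.run_recovery_experiment`)
is the controlled check that the true lag-32 structure is recovered.

There is also a CLI: `fptrack simulate`, `fptrack tracks`,
`fptrack run-all --seed 3 --out out/`, `fptrack reference`.

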