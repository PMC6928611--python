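# grazetrack

Behavior classification for free-ranging livestock from GPS collars
and tri-axial accelerometers.

On fenced rangeland, grazing and nongrazing behaviors degrade pasture
in different ways, so managers and movement ecologists need to know
*which* behavior an animal was performing at each logged position —
without following the herd with a stopwatch. `grazetrack` reimplements
a complete desk pipeline for the binary problem (grazing = foraging,
head lowered; nongrazing = standing, lying, ruminating, or walking):

* **Movement metrics** from 50-s GPS fixes projected to UTM: backward/
  forward focal-lag linear distances, one-step segment distances,
  accumulative (path) distances and turning angles, at every window
  from 100 to 800 s (92 distance metrics at the full window).
* **Posture metrics** from nine accelerometer channels (neck/leg/tail ×
  three body axes): vector magnitudes M = √(ax²+ay²+az²), 7-sample
  windowed SDs, and ODBA — the sum of absolute *dynamic* accelerations,
  where dynamic = raw − running-mean static component.
* A **Random Forest** classifier with explicit mtry/ntree grid search,
  mean-decrease-in-Gini importance computed from the tree internals,
  and partial-dependence curves with plateau-threshold extraction.
* An **evaluation layer**: confusion matrices, overall and per-class
  accuracy, Cohen's κ = (p_o − p_e)/(1 − p_e), stratified 10-fold × 5
  cross-validation, and a 100–800-s interval sweep that selects the
  optimal window as the smallest T whose mean κ is within δ of the
  maximum.
* A **synthetic herd simulator** — a two-state renewal process driving
  both a state-dependent movement kernel and posture-dependent
  accelerations — so every stage is testable against known ground
  truth without field data.

## Worked example

```python
import grazetrack as gt
from grazetrack.accel import FEATURE_COLUMNS

# a labeled synthetic deployment: ~5.8 days of 50-s fixes
dep = gt.simulate_deployment(gt.SimConfig(seed=7, n_fixes=10_000))
accel = gt.build_accel_features(dep.accel)          # 24 posture model columns
gps = gt.build_gps_features(dep.trajectory)         # movement metrics, lags 1-16

cfg = gt.ModelConfig(seed=3, ntree=200, cv_folds=10, cv_repeats=5)
cv = gt.cross_validate(accel[FEATURE_COLUMNS], dep.labels, cfg)
print(f"tri-axial model: accuracy {cv.mean_accuracy:.3f}, kappa {cv.mean_kappa:.3f}")

model = gt.fit_forest(accel[FEATURE_COLUMNS], dep.labels, cfg)
print(gt.gini_importance(model).head(3))
```

prints

```
tri-axial model: accuracy 0.994, kappa 0.979
      feature  mean_decrease_gini  rank
0  raw_neck_y         2117.639274     1
1      M_neck          264.911376     2
2   SD_neck_y          211.205891     3
```

The posture model is nearly perfect because the generator's neck
anteroposterior channel separates the classes (head lowered while
grazing), and that channel tops the importance ranking — the same
structure the method is designed to exploit on real collars. The
movement-only model is interval-dependent: κ rises steeply from short
windows (where a grazing animal's drift is buried in positional
scatter) to a plateau once the window reaches the nongrazing bout
scale, and `gt.interval_sweep(...)` reports the resulting optimal
interval.

A CLI covers the same pipeline for shell use:

```sh
grazetrack simulate --config sim.yaml --out dep/ --seed 3
grazetrack featurize-gps --gps dep/gps.csv --out gps_features.csv
grazetrack featurize-accel --accel dep/accel.csv --out accel_features.csv
grazetrack evaluate --features accel_features.csv --labels dep/labels.csv \
    --config model.yaml --out eval/
grazetrack sweep --gps-features gps_features.csv --accel-features accel_features.csv \
    --labels dep/labels.csv --out sweep/
```

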