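# swarmkin

Swarm kinematics for 3D mosquito flight tracks: from raw trajectory
tables to swarm-level structure, trend models across operational sex
ratios, and an exploratory classifier of swarm composition.

Malaria-vector mosquitoes (*Anopheles*) mate in crepuscular swarms that
form over visual ground markers around sunset. Stereo-videography
devices emit tabular 3D detections at ~100 frames/s — one row per frame
per individual — and the scientific questions live at the swarm level:
how large is the aggregation, how dense, how fast do its members fly,
and does the ratio of males to females (the operational sex ratio, OSR)
leave a measurable signature in flight kinematics? `swarmkin` is a
library (plus a thin CLI) for researchers in vector behavioral ecology
who work with such track tables.

## What it computes

**Filtering.** Swarming tracks are isolated by four sequential filters:
a sunset-anchored time window; a spatial box of ±100 cm in X and Z
around the marker (height Y unconstrained); a minimum time-averaged
flight speed of 0.50 m/s (inclusive); and a flight time strictly
exceeding 25 s.

**Swarm structure.** All frame positions of one replicate's swarming
tracks are modelled as a single 3D Gaussian N(μ, Σ) (a one-component
Gaussian mixture with full covariance). The 90% confidence ellipsoid is

    E = { x : (x − μ)ᵀ Σ⁻¹ (x − μ) ≤ χ²₃(0.90) },   χ²₃(0.90) ≈ 6.2514

with semi-axes rᵢ = √(χ²₃(0.90)·λᵢ) along the eigenvectors of Σ and
volume V = (4/3)π·r₁r₂r₃. Frames inside E (by squared Mahalanobis
distance) are the swarm *core*; a track is core when at least half its
frames are. Swarm density is core tracks per cm³.

**Trend models.** Volume against the OSR code x ∈ {0, 50, 100, 150,
200} (male-only … female-only) via least squares on V(x) = ax² + bx + c;
penalized cubic smoothing splines S(x) = Σᵢ αᵢBᵢ(x); a Gaussian
random-intercept mixed model speed = β₀ + β₁·density + b_replicate with
Nakagawa marginal pseudo-R²; and an AIC ranking over linear, quadratic,
cubic, 4-parameter-logistic and spline candidates.

**Classification.** A 30-tree random forest predicts the OSR code from
per-frame core kinematics (speed, X, Y, Z, and the Euclidean distance
from the marker d = √(X²+Y²+Z²)), with an 80/20 stratified split and
SMOTE oversampling applied to the training split only. Reports include
the confusion matrix, per-class precision/recall/F1, one-vs-rest
ROC-AUC, and mean-decrease-in-impurity importances normalised to sum
to 1.

**Synthetic recordings.** Because raw recordings are large and often
unavailable, `swarmkin.simulate` generates trajectory datasets with the
structure the analysis assumes — Gaussian-distributed loop flight above
the marker, group-specific speeds and volumes, noise tracks that each
violate exactly one filter — together with a full ground-truth table,
so every stage can be validated by parameter recovery.

## Worked example

```python
import numpy as np
from swarmkin import fit_quadratic

osr     = np.array([0.0, 50.0, 100.0, 150.0, 200.0])
volumes = np.array([388.4, 305.0, 325.5, 536.3, 612.6])   # cm^3, group means
quad = fit_quadratic(osr, volumes)
print(f"V(x) = {quad.a:.4f} x^2 + {quad.b:.4f} x + {quad.c:.4f}  (R^2 = {quad.r2:.3f})")
```

prints

```
V(x) = 0.0146 x^2 + -1.5532 x + 370.4343  (R^2 = 0.889)
```

— swarm volume is smallest near the male-biased compositions
(minimum at x = −b/2a ≈ 53) and grows toward female-dominated groups,
with the quadratic explaining ~89% of the between-group variance.

The `examples/` directory holds one short script per capability
(simulation + filtering, ellipsoid structure, trend models, the OSR
classifier, the full pipeline); each prints the numbers it computes and
a line on what they mean. The full pipeline is also available from the
shell:

```sh
swarmkin run --out run --seed 1          # simulate -> filter -> structure -> trends -> classify
swarmkin report run                      # human-readable summary
```

or stage by stage (`simulate`, `filter`, `structure`, `trends`,
`classify`), which composes to byte-identical outputs under the same
seed.

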