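# Methods

## The cone model

Thumb abduction is treated as rotation of the thumb IP joint on a cone
whose axis is the second metacarpal. Writing the hand frame with the
first axis along the palm normal, the second along the base axis, and the
third in the palm plane perpendicular to it, the IP joint at rotational
displacement coordinates (r, θ) sits at (r sin θ, B, r cos θ): θ = 0°
in the palmar plane, θ = 90° a full radius out of it. The model assumes
the thumb CMC, MCP and IP joints are collinear and that r stays constant
through the movement — the reference measurement enforces r = 3 cm with a
guide device, and the simulator enforces it exactly. Two framings of the
frame origin exist (the rotation-centre second MP joint, or the CMC joint
with the second MP at (0, B, 0)); the formulas are identical, and
`SkeletonConfig.origin_joint` records which interpretation is intended.

Clinical radial and palmar abduction are computed as planar projections
of the IP position: radial = atan2(r cos θ, B) (projection onto the palm
plane, angle from the base axis) and palmar = atan2(r sin θ, B).
This projection definition was chosen over spherical angles because it is
the decomposition consistent with the (r sin θ, B, r cos θ) coordinates;
it makes θ → 90° − θ exactly swap the two abduction angles. The inverse
is closed-form (θ = atan2(tan palmar, tan radial),
r = B·hypot(tan radial, tan palmar)), so round-trips are exact to
floating-point precision. B is a free configuration parameter (no
standard value exists); the default 6 cm is an anthropometrically
plausible second-metacarpal offset. All public angles are degrees;
trigonometry is radians internally.

## The synthetic landmark generator

The simulator emulates the study design the method was validated with,
not the appearance of real video:

* **design** — 15 subjects × angles 0–90° in 10° steps × 30 fps for 2 s
  = 9000 frames (defaults of `DatasetSpec`);
* **hand template** — a flat canonical right hand (21 landmarks) with the
  palm in one plane; segment lengths are plausible round numbers (index
  MCP-to-tip 9.2 cm, palm width ~6 cm). Per-subject hand size is a single
  multiplicative factor drawn from uniform(0.85, 1.15), reproducing the
  inter-subject size variation that the normalized features exist to
  cancel;
* **posing** — the thumb chain is placed collinearly on the ray from the
  CMC through the cone position of the IP joint; the IP-to-index-MCP
  distance is r·scale exactly at every angle (the guide-device
  constraint);
* **camera** — a pinhole camera ~115 cm from the hand (50 cm above, ~1 m
  out, per the recording geometry), with the hand resting thumb-up so the
  palm is viewed obliquely. This orientation reproduces the direction of
  the empirically reported feature-angle relationships (projected thumb
  area and thumb-tip distance increase with θ). A weak-perspective mode
  (orthographic plus global scale) is provided as the analytically
  tractable limit used in projection tests;
* **noise** — isotropic Gaussian jitter added to the projected normalized
  coordinates, i.i.d. per frame and landmark. The default SD of 0.005
  normalized units (~3–5 px at 720p) is a realistic magnitude for
  detector keypoint jitter. Noise is the only stochastic element besides
  subject scale; both flow from one seed, and a given spec is
  byte-reproducible.

What the simulator does **not** model: detector bias fields (systematic
offsets that vary with pose), occlusion and mis-detection, soft-tissue
deviation of surface landmarks from joint centres, non-constant r during
real thumb motion, and left hands. Passing tests on synthetic data
therefore demonstrate that the geometric pipeline, the learners, and the
attribution machinery work as specified — not that any particular
accuracy will be achieved on real video. Headline metrics computed on
the synthetic sweep characterize the synthetic conditions only.

## Features

The nine predictors are the three interior angles at the thumb CMC
(to thumb tip/thumb MCP/pinky MCP vs the index MCP ray), three distances
from the index MCP to the thumb tip/IP/MCP normalized by the index-finger
length |(5)(8)|, and three parallelogram areas (thumb, thenar, palm)
normalized by |(5)(8)|². All are invariant under similarity transforms of
the image, which is verified property-style in the tests. Cross products
are reported as absolute areas by default; a `signed=True` flag exposes
the raw determinant, since orientation-aware variants are conceivable but
the quantities are defined as areas. When a frame carries pixel
dimensions, coordinates are de-normalized to isotropic units first —
angles computed in anisotropic normalized coordinates are distorted;
square pixels are assumed otherwise. Degenerate frames (zero-length
reference segment, coincident angle points) are skipped with a logged
warning and reported in the batch summary rather than failing the run,
because real detector streams glitch.

## Models and evaluation

The four families are fitted behind one Model/Results API. Tuning is
grid search by cross-validated RMSE on the training partition only
(5-fold by default, seeded and shuffled); the reference method does not
state its grids or kernel, so the package uses an RBF kernel for SVR and
modest library-default grids (ElasticNet α ∈ {0.01, 0.1, 1} ×
l1_ratio ∈ {0.2, 0.5, 0.8}; SVR C ∈ {1, 10, 100}; boosted trees
n_estimators ∈ {100, 300} × learning rate ∈ {0.05, 0.1}). ElasticNet and
SVR run behind a standard scaler. The 80/20 split is stratified by angle
level by default (plain random available); it splits frames, not
subjects, matching the reference protocol — frames of one subject can
appear in both partitions, so a stricter `group_by_subject` split is
offered for leakage-sensitive analyses.

Evaluation reports RMSE, MAE and Pearson r between actual and predicted
angles, with residuals defined as actual − predicted. Per-angle residual
tables group on the rounded true-angle level and use the sample (n − 1)
standard deviation; a single-frame group reports an undefined SD rather
than zero. A constant prediction leaves Pearson r undefined and is
reported as NaN with a warning. Every report asserts RMSE ≥ MAE ≥ 0.

## Attribution

Feature importance for the boosted-tree family is computed from per-split
gains: within each tree the gains are normalized to shares, and shares
are averaged across trees with at least one split, yielding a probability
vector. Shapley values are computed exactly: with nine features all 2⁹
coalitions are enumerated, absent features are marginalized over a
background sample (the training partition by default; capped in the
pipeline for speed), and contributions use the standard coalition
weights. Exactness is cheap at this dimensionality, so no approximation
is used in production; the tests cross-check the implementation against
an independently written enumeration and the permutation definition, and
verify the efficiency, dummy, symmetry and additive-model properties.

## Numerical choices and limitations

* Tolerances: geometric identities are asserted at 1e−9 (or exact);
  Shapley additivity at 1e−6 degrees.
* Reduced problem sizes: model-level tests and the noiseless recovery
  check use the full 15-subject × 10-angle grid at 10 frames per
  condition (1500 frames), which preserves the design while keeping the
  suite fast; the acceptance script runs the full 9000-frame sweep.
* Serialization: landmark and feature files are written with fixed
  9-significant-digit formatting, making identical data byte-identical on
  disk; pipeline runs record SHA-256 hashes of every artifact.
* Determinism: a single seed drives subject scales, jitter, splitting and
  model fitting; boosted trees run single-threaded for reproducibility.
* The per-angle residual tables and headline metrics on synthetic data
  follow the reference method's qualitative pattern (nonlinear families
  clearly ahead of linear ones, linear ≈ ElasticNet) but their absolute
  values describe the simulator's noise regime, not human video.
* The optional detector adapter defines the contract for a live
  pose-estimation backend (x, y used; z discarded) but ships no backend;
  without one the core package is fully functional on files and
  synthetic data.
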