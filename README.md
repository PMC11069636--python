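# thumbrot

Estimation of the thumb rotation angle from 2D hand-landmark coordinates.

Clinicians quantify thumb abduction — the movement that lets the thumb
oppose the fingers — with goniometers that require face-to-face contact.
When the carpometacarpal (CMC), metacarpophalangeal (MCP) and
interphalangeal (IP) joints of the thumb are approximately collinear, the
abduction arc can instead be modelled as motion on a **cone** around the
second metacarpal (the *base axis*): the thumb IP joint sits at rotational
displacement coordinates **(r, θ)**, where *r* is its distance from the
base axis (3 cm in the reference measurement setup) and *θ* the rotation
angle measured from the palmar plane (θ = 0° in the palm plane, θ = 90°
perpendicular to it). In a hand frame whose first axis is the palm normal
and second axis runs along the base axis, the IP joint is at

    (r sin θ,  B,  r cos θ)

with *B* the offset along the base axis. The same (r, θ) decomposes into
the two clinical angles as planar projections:

    radial abduction = atan2(r cos θ, B)      palmar abduction = atan2(r sin θ, B)

`thumbrot` estimates θ from the 21-point hand skeleton that pose-estimation
detectors emit for a single camera frame. Nine scale-free geometric
features (three angles at the thumb CMC, three distances from the index
MCP to the thumb joints normalized by the index-finger length, and three
normalized parallelogram areas, e.g. `norm_tip_size` =
|(1→4) × (1→5)| / |(5)(8)|²) are regressed onto θ with four model
families — linear regression, ElasticNet, RBF support-vector regression,
and gradient-boosted trees (LightGBM) — evaluated by RMSE, MAE and
Pearson r with per-angle residual tables, and interpreted with
gain-share feature importance and exact Shapley values.

Because the original video recordings behind the method are not publicly
deposited, the package ships a **synthetic landmark simulator** that
reproduces the study design end to end: 15 subjects × 10 angle levels
(0–90° in 10° steps) × 60 frames (30 fps for 2 s) = 9000 frames, a
perspective camera posed like the recording setup, per-subject hand-size
variation, and Gaussian landmark jitter emulating detector error.

## Worked example

```python
from thumbrot import (DatasetSpec, SplitSpec, generate_dataset,
                      feature_table, compare_models, feature_importance)

spec = DatasetSpec(n_subjects=15, fps=10.0, duration_s=1.0, seed=42)
frames = generate_dataset(spec)                  # 1500 labelled frames
table, _ = feature_table(frames)                 # 9 predictors + true_angle
cmp_ = compare_models(
    ["linear", "elastic_net", "svm_regression", "gradient_boosted_trees"],
    table, SplitSpec(seed=42), seed=42)
print(cmp_.summary())
```

prints

```
Model comparison (ranked by test RMSE)
========================================
1. gradient_boosted_trees   RMSE   9.20  MAE   6.49  r 0.948
2. svm_regression           RMSE   9.85  MAE   6.39  r 0.942
3. linear                   RMSE  10.64  MAE   8.24  r 0.929
4. elastic_net              RMSE  10.64  MAE   8.21  r 0.929
```

— the nonlinear families beat the linear ones because most features vary
nonlinearly with θ (the projected geometry follows sines and cosines of
the rotation). RMSE/MAE are in degrees on the held-out 20%; r is the
Pearson correlation between actual and predicted angles.
`feature_importance(cmp_.best).to_frame()` then ranks the predictors; on
this run the top features are

```
          feature    value  rank
    norm_tip_size 0.321958     1
        tip_angle 0.121582     2
norm_tip_distance 0.105018     3
```

i.e. the normalized thumb-parallelogram area carries the most signal about
the rotation angle. Converting an estimate to clinical angles:

```bash
$ thumbrot convert -r 3 -t 45 -b 6
radial abduction: 19.47 deg
palmar abduction: 19.47 deg
```

The CLI also exposes `simulate`, `features`, `train`, `evaluate`,
`explain`, and `run` (an end-to-end pipeline from a YAML config that
writes every artifact plus a SHA-256 manifest).

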