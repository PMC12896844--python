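# ccw — carcass segmentation and image-based weight estimation

`ccw` is a two-stage pipeline for estimating chicken carcass weight from
multi-view RGB images, aimed at poultry-processing and precision-livestock
researchers who want a fully testable, CPU-only reference implementation.

**Stage 1 — segmentation.** An attention-enhanced recurrent-residual U-Net
labels each pixel as background, torso, head, or leg. Encoder and decoder
units are recurrent-residual blocks (`y_s = relu(a + BN(conv_rec(y_{s-1})))`
for `t` refinement steps over `a = BN(conv_ff(x))`, plus a residual
shortcut). Selective-kernel attention after each encoder block fuses a 3×3
and a 5×5 branch with per-channel softmax weights `a + b = 1`
(`V = a·U1 + b·U2`), and CBAM gates each skip connection — channel gate
`σ(MLP(avgpool F) + MLP(maxpool F))`, then spatial gate
`σ(f7×7([mean; max]))`. Everything runs on a compact numpy reverse-mode
autodiff engine; every operator is cross-checked against independent
scalar-loop oracles and finite differences.

**Stage 2 — morphometry and regression.** Predicted masks are refined by
per-class morphological closing then opening, pixel counts are converted to
cm² via a known px/cm calibration, and per-view part areas are regressed
against weight (`R² = 1 − SSres/SStot`, RMSE in grams) with five model
families (MLP, RBF-SVR, Bayesian ridge, LightGBM, XGBoost), percentile
bootstrap 95% CIs, and ±2σ residual outlier flagging. Four feature groups
are supported: overall, torso, head, and leg areas (Mod1–Mod4), each with
one averaged area per view.

Because the kind of imagery this addresses is typically proprietary, the
package ships a synthetic carcass generator with exact analytic ground
truth (torso ellipse, head disc, splayed leg capsules, closed-form areas, a
noisy linear area→weight model). It defines the default study conditions —
301 carcasses × 3 views × 3 replicates, carcass-wise 8:1:1 split — and
makes every pipeline stage verifiable end to end. See `docs/methods.md`
for the full model description and its limitations.

## Worked example

```python
import numpy as np
from ccw.synthetic import generate_dataset, analytic_areas_table
from ccw.dataset_io import build_split
from ccw.regression import assemble_features, fit_and_evaluate

manifest = generate_dataset(n_carcasses=301, seed=7, canvas=320)
split = build_split(sorted(manifest.specs), ratios=(8, 1, 1), seed=7)

areas = analytic_areas_table(manifest)            # calibrated cm^2 per part/view
table = assemble_features(areas, manifest.weights, "Mod2")   # torso areas -> torso weight
result = fit_and_evaluate(table, "bayes", split, seed=7)
print(f"Mod2 / Bayesian ridge: R2 = {result.r2:.4f}, RMSE = {result.rmse:.2f} g")
print(f"95% CI for R2:   [{result.ci_r2[0]:.4f}, {result.ci_r2[1]:.4f}]")
```

prints

```
Mod2 / Bayesian ridge: R2 = 0.9601, RMSE = 35.60 g
95% CI for R2:   [0.9129, 0.9842]
```

i.e. on a fresh 301-carcass synthetic cohort (seed 7), torso areas from the
three views explain ~96% of the variance in torso weight on the 30 held-out
test carcasses, with a typical prediction error of ~36 g on ~700 g parts.
The confidence interval comes from 1000 paired bootstrap resamples of the
test set.

The same stages are available from the shell:

```bash
ccw synth --n-carcasses 60 --canvas 320 --seed 7 --out runs/demo
# synth: 540 image records, 60 carcasses -> runs/demo
ccw split --images-csv runs/demo/images.csv --ratios 8:1:1 --seed 7 \
    --out runs/demo/split.csv
# split: {'train': 48, 'val': 6, 'test': 6} -> runs/demo/split.csv
ccw run --config config.yaml --seed 7 --out runs/full   # end-to-end pipeline
```

Training a segmentation model at desk scale (the `train` subcommand or
`ccw.train.overfit_harness`) drives training mIoU above 0.95 on eight
synthetic 64×64 images in under two minutes on one CPU.

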