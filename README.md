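# stargardt-oct

Prediction of future Stargardt atrophy from a single baseline SD-OCT scan,
using en-face feature maps beyond mean intensity and an interpretable
ensemble of per-feature U-Nets.

Stargardt disease, the most common juvenile-onset macular dystrophy,
appears on OCT as disruption of the outer retinal layers (ellipsoid zone,
RPE).  Given a baseline OCT volume with segmented boundary surfaces (ELM,
EZ, inner/outer RPE, choroid–sclera junction), this package predicts the
binary atrophy mask expected at a 6- or 12-month follow-up, in the baseline
en-face frame.  It is aimed at researchers in retinal image analysis who
want a complete, reproducible, CPU-scale implementation of the approach —
including a synthetic OCT simulator, since clinical Stargardt cohorts are
not redistributable.

## Method

1. **En-face feature maps.**  For a slab between two boundary surfaces,
   each A-scan column yields one pixel per statistic: mean, median, max,
   min, standard deviation, skewness, kurtosis, gray-level entropy, and
   thickness.  Regions: ELM–EZ, EZ–IRPE, IRPE–ORPE, ORPE–CS, ELM–IRPE,
   EZ±5 px (thickness excluded for the last two).  Maps are OD-mirrored,
   resized (native → 512×512 for registration → 128×128 for the network),
   and min–max normalized.
2. **Registration.**  Follow-up FAF images and ground-truth masks are
   brought into the baseline frame by a least-squares affine fit to
   corresponding vessel landmarks, then warped (bilinear / nearest).
3. **Ensemble of component U-Nets.**  Each feature map feeds one U-Net
   (5×5 convs, batch norm, ReLU, max pool/unpool with indices, skip
   concatenations, 1×1 two-channel head, no per-component softmax).
   Outputs combine by pixelwise maximum,
   `g(E(Y)) = max(f1(x1), …, fn(xn))`, followed by a softmax — so each
   feature's contribution can be graded separately.
4. **Loss and training.**  `L = L_logloss + L_Dice + λ‖W‖²_F` with pixel
   weights 6 (regions) / 15 (boundary band), λ = 1e-4; SGD with batch 8,
   momentum 0.95, learning rate 1e-2 for 40 epochs then 1e-3 for 20.
   The network engine is pure numpy with hand-written backprop, validated
   against central-difference gradients.
5. **Evaluation.**  Dice `D = 2Σpg/(Σg²+Σp²)` and pixel accuracy per eye;
   cohort medians; per-component sigmoid grading; paired two-sided
   Wilcoxon signed-rank tests (exact null up to n = 25).

See `docs/methods.md` for every convention and the synthetic-data model.

## Worked example

Train an ensemble on a small synthetic cohort and score held-out eyes:

```python
from stargardt_oct import (AtrophyProgressionModel, ComponentUNetConfig,
                           SynthEyeParams, TrainConfig, generate_dataset)
from stargardt_oct.enface_features import build_feature_stack, prepare_mask
from stargardt_oct.evaluation import summarize
from stargardt_oct.synthetic_data import train_test_split

eyes = generate_dataset(24, SynthEyeParams(shape=(96, 128, 48)), seed=7)
train_eyes, test_eyes = train_test_split(eyes, seed=7)   # 3:1 split

features = ("mean", "std", "gray_level_entropy", "thickness")
model = AtrophyProgressionModel.from_eyes(
    train_eyes, region="EZ-IRPE", horizon="6mo", out_shape=(64, 64),
    features=features,
    unet_config=ComponentUNetConfig(input_shape=(64, 64), depth=3,
                                    widths=(8, 16, 32)))
result = model.fit(TrainConfig(lr_schedule=((8, 1e-2), (4, 1e-3)), seed=0))
print(result.summary())

stacks = [build_feature_stack(e.volume, e.surfaces, "EZ-IRPE", (64, 64), features)
          for e in test_eyes]
masks = [prepare_mask(e.mask_6mo, e.laterality, (64, 64)) for e in test_eyes]
print(summarize(result.evaluate(stacks, masks)).to_string(index=False))
```

This prints (about a minute on one CPU):

```
Atrophy progression ensemble
============================================================
Region:            EZ-IRPE
Horizon:           6mo
Features (n=4):  mean, std, gray_level_entropy, thickness
Component U-Net:   depth 3, widths (8, 16, 32), 5x5 kernels, input (64, 64)
Parameters:        309,512
Training eyes:     18
Epochs:            12 (schedule ((8, 0.01), (4, 0.001)))
Batch size:        8, momentum 0.95, weight decay 0.0001
Pixel weights:     region 6.0, boundary 15.0
Loss:              5.8844 (first epoch) -> 0.5782 (final)
Seed:              0

 region                configuration horizon  median_dice  median_pixel_accuracy  n_eyes
EZ-IRPE                     ensemble     6mo     0.949023               0.984741       6
EZ-IRPE               component:mean     6mo     0.285827               0.851929       6
EZ-IRPE                component:std     6mo     0.762569               0.929932       6
EZ-IRPE component:gray_level_entropy     6mo     0.878458               0.956299       6
EZ-IRPE          component:thickness     6mo     0.874364               0.984497       6
```

The ensemble predicts the held-out 6-month lesions with median Dice 0.95;
the per-component rows grade each feature's own contribution — mean
intensity is the weakest component here (vessel shadows confound it),
while distribution-shape and thickness features carry most of the signal.

A command-line interface wraps the same pipeline
(`stargardt-oct simulate | features | register | train | predict |
evaluate | compare | run`); `stargardt-oct run --config cfg.yaml --out run/`
executes everything end to end and writes a manifest sufficient to
reproduce the run bit-identically.

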