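# maefnet

In vivo prediction of broiler breast-muscle weight from radiographs.

Breast-muscle (pectoral) weight is a key phenotype in poultry breeding, but
measuring it directly requires dissection. This package implements a
nondestructive pipeline that estimates it from a single X-ray-style image plus
the bird's live weight:

1. **Segmentation** — MAEFNet, a lightweight encoder–decoder network
   (≤ 1.51 M trainable parameters), produces a binary pectoral-muscle mask.
   The encoder is MobileNetV3-Large truncated at output stride 16; the
   decoder refines encoder taps at strides 4/8/16 with an Attention
   Refinement Module (channel gating), a Coordinate Attention Module
   (directional spatial gating), and fuses them with Feature Fusion Modules
   before a two-class head at full resolution.
2. **Morphometrics** — 15 shape descriptors of the mask: √area (Ar), √convex
   area (Co), perimeter (P), moment-ellipse axes (Mal, Mil), bounding-box
   height/width (H, W), √(H·W) (Ra), ellipticity (El = Mal/Mil),
   circumscribed-circle diameter (D), equivalent diameter (Ed = 2√(A/π)),
   Heywood circularity factor (Hcf = P / 2√(πA)), aspect (As = H/W),
   curvature (Cu = 4A/(πD²)) and complexity (Cl = P²/A).
3. **Regression** — recursive feature elimination over live weight + the 15
   descriptors (linear-SVR coefficient ranking, subset size chosen by 5-fold
   cross-validated R²), then an ε-insensitive linear SVR (C = 10, ε = 0.3 g)
   mapping the selected features to grams.

Training follows the reference protocol: SGD (momentum 0.9, weight decay
1e-4), constant learning rate 0.01, batch size 8, per-pixel cross-entropy on
the training split, dice loss and precision/recall/IoU/DSC monitoring on the
validation split, best-validation-IoU checkpointing.

Real radiograph datasets of this kind are not publicly available, so the
package ships a **phantom generator**: synthetic radiographs with a bright
body silhouette, a perturbed-ellipse muscle blob with known pixel mask,
Gaussian sensor noise, and a known affine generative law
`weight = β₀ + β₁·live_weight + β₂·area + ε`. Every stage of the pipeline is
exercised and tested against these phantoms. The network itself runs on a
compact numpy reverse-mode autodiff engine (`maefnet.nn`) written for this
package — no deep-learning framework is required.

## Worked example

```python
import numpy as np
from maefnet.phantom import PhantomConfig, generate_dataset
from maefnet.shape_features import features_table
from maefnet import weight_prediction as wp

# 100 synthetic birds at 128x128, noise-free weight law
cfg = PhantomConfig.for_side(128, n_samples=100, weight_noise_sigma=0.0, seed=7)
ds = generate_dataset(cfg)

feats = features_table({s.sample_id: s.mask for s in ds.samples})
table = wp.build_predictor_table(feats, ds.manifest)

rfe = wp.rfe_select(table, wp.RFEConfig(cv_folds=5, seed=0))
folds, mean = wp.cross_validate(table, rfe.selected, k=5, seed=0)
print(rfe.selected)
print(f"mean CV: R2={mean.r2:.4f} RMSE={mean.rmse:.2f} g "
      f"MAE={mean.mae:.2f} g MRE={mean.mre:.3f}%")
```

prints

```
('live_weight', 'Ar', 'Co', 'Mal', 'El', 'Ed')
mean CV: R2=0.9993 RMSE=3.35 g MAE=2.43 g MRE=0.443%
```

RFE keeps live weight and the area-type descriptors (Ar, Co and Ed are all
monotone functions of mask area, which the generative law is affine in), and
five-fold cross-validation recovers the noise-free law almost exactly: the
mean coefficient of determination R² is 0.9993 and the root-mean-square error
is 3.35 g on targets of several hundred grams.

Segmentation, end to end:

```python
from maefnet.model import MAEFNet, MAEFNetConfig, predict_mask
from maefnet.training import TrainConfig, train, evaluate

model = MAEFNet(MAEFNetConfig(init_seed=0))
records = train(model, ds.subset("train"), ds.subset("val"),
                TrainConfig(epochs=40, seed=0))
print(evaluate(model, ds.subset("test"))["micro"])
mask = predict_mask(model, ds.samples[0].image)   # {0,1} array
```

A command-line interface mirrors these steps
(`maefnet phantom / prep / rasterize / train / evaluate / features / weights`);
run `maefnet --help`.

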