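# adstage

Handcrafted atrophy features for staging dementia in 2-D brain MRI
slices, built around an adaptive histogram multi-thresholding algorithm.

## The problem

As Alzheimer's disease progresses, grey matter — the outer cortical
tissue, which atrophies first — is replaced by dark void space in a
T1-like MRI slice, and overall tissue area shrinks. Quantifying that
loss needs grey/white matter segmentation, but fixed intensity cutoffs
fail across scanners and subjects. This package selects the cutoffs
*adaptively* from each slice's own intensity histogram, then derives an
interpretable 17-feature descriptor of atrophy that supports 4-stage
classification (0 = none, 1 = very mild, 2 = mild, 3 = moderate).

## The method

For a slice *I(m,n)* with *k*-bit intensities:

1. **Contrast stretch** — `I_C = (I − I_min)/(I_max − I_min) · (2^k − 1)`,
   an order-preserving map so tissue area ratios are unchanged.
2. **Histogram** — 256-bin counts `P(l)`, with `Σ_l P(l) = M·N`.
3. **Envelope smoothing** — `P_s = h_L * P`, a zero-phase minimum-order
   FIR lowpass (Kaiser design; passband edge 0.005 of Nyquist, stopband
   attenuation 60 dB), so valley/peak locations are unbiased.
4. **Thresholds** — `Th1 = x1`, `Th2 = x2`, the bins of interior local
   minima of `P_s` ("second and last" when a post-background notch
   precedes the tissue valleys); `(x3, y3)` is the absolute maximum.
5. **Geometry features** — slopes `α_i = (y3 − y_i)/(x3 − x_i)` and
   Euclidean distances `d1, d2, d3` between the three points.
6. **Segmentation** — grey: `Th1 < I_C < Th2`; white: `I_C > Th2`;
   per-tissue volume (pixel count), mean, standard deviation, skewness.
7. **Atrophy ratios** — `GWR = V_grey / V_white` and
   `shrinkage = (V_grey + V_white) / V_mask` over the brain mask.

The 17 features, in fixed order: `th1, th2, alpha1, alpha2, d1, d2, d3,
grey_volume, white_volume, grey_mean, white_mean, grey_std, white_std,
grey_skew, white_skew, gwr, shrinkage`. They feed MRMR and chi-square
feature ranking plus a seven-metric classifier harness (accuracy,
macro recall/specificity/precision/F1, multiclass Matthews correlation,
Cohen's kappa) under a repeated stratified 60/20/20 protocol.

A synthetic phantom generator provides brain-like slices (grey annulus,
white core, stage-dependent voids) with pixel-exact ground truth, so the
entire pipeline is testable without any external dataset.

## Worked example

```python
import numpy as np
from adstage import (PhantomSpec, generate_phantom, extract_features,
                     FEATURE_NAMES)

img, truth = generate_phantom(PhantomSpec(seed=1, void_fraction=0.18,
                                          noise_sigma=5.0, stage=2))
rec = extract_features(img)
print("truth: grey =", truth.grey_area, " white =", truth.white_area,
      " gwr = %.3f" % truth.gwr, " shrinkage = %.3f" % truth.shrinkage)
for name, value in zip(FEATURE_NAMES, rec.values):
    print(f"{name:>13s} = {value:10.3f}")
```

prints

```
truth: grey = 4598  white = 2451  gwr = 1.876  shrinkage = 0.819
          th1 =     56.000
          th2 =    174.000
       alpha1 =    -22.200
       alpha2 =     -7.145
           d1 =   1244.459
           d2 =   1255.316
           d3 =    118.000
  grey_volume =   4598.000
 white_volume =   2451.000
    grey_mean =    115.854
   white_mean =    231.989
     grey_std =      5.809
    white_std =      5.620
    grey_skew =      0.037
   white_skew =     -0.008
          gwr =      1.876
    shrinkage =      0.819
```

The thresholds 56/174 fall in the two valleys of the stretched trimodal
histogram; the segmented volumes equal the constructed tissue areas
exactly despite σ = 5 noise, so the recovered GWR (1.876) and shrinkage
(0.819, i.e. ~18% of the brain mask is void) match ground truth.

`AtrophyFeatureExtractor` is a scikit-learn transformer (images in,
`(n, 17)` features out) and `MRMRRanker`/`Chi2Ranker` are selectors, so
all of them compose with sklearn pipelines and model selection.

## Command line

```bash
adstage phantom  --n-per-stage 200 --out data/ --seed 0
adstage extract  --input data/ --output features.csv
adstage rank     --features features.csv --method mrmr --top 5
adstage classify --features features.csv --model svm --seed 0
adstage run-all  --workdir run/ --n-per-stage 100 --seed 0
```

Class labels come from the input subfolder names (`NonDemented`,
`VeryMildDemented`, `MildDemented`, `ModerateDemented` by default);
every pipeline default lives in a YAML config (`--config`).

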