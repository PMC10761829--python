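# Methods

## Model and assumptions

The pipeline assumes a T1-like 2-D slice in which three intensity
populations are separable: a dark background (plus intra-brain void),
mid-intensity grey matter, and bright white matter. Under that
assumption the smoothed intensity histogram is multimodal and the two
tissue boundaries appear as valleys of its envelope. Everything
downstream — segmentation, the atrophy ratios, the geometry features —
is a deterministic function of those two valleys, so the method's
robustness rests entirely on finding them stably.

## Contrast stretching

The linear stretch maps the slice minimum to 0 and maximum to
`2^k − 1` with round-half-up to the nearest integer (a fixed, documented
convention; "banker's" rounding would make the map depend on parity).
It is monotone and therefore preserves every area ratio. A constant
slice has no defined stretch; it returns all zeros with a warning rather
than raising, so batch runs survive blank slices.

## Envelope smoothing

The lowpass is a linear-phase FIR designed by the Kaiser-window method:
passband edge 0.005 (fraction of Nyquist on the 256-bin axis), stopband
attenuation 60 dB, transition width 0.15 by default. The transition
width is the one genuinely free knob: the filter order grows as the
inverse of the width, and widths much below ~0.05 produce kernels
longer than the histogram itself, which averages the three modes into a
single hump and destroys the valleys the method needs. 0.15 is the
conventional minimum-order lowpass default (≈85% steepness) and yields
a 51-tap kernel whose passband keeps the mode structure intact. The
Kaiser order formula is only an estimate, so the design loop grows the
order until the realized response actually meets the attenuation spec.

Zero-phase application: the histogram is padded symmetrically by half
the kernel length, convolved with the symmetric taps, and cropped —
exactly compensating the group delay, so extrema locations are
unbiased. Negative ringing is clamped to zero since the output
represents counts.

## Threshold selection

Local extrema are detected by a strict plateau-aware scan: a run of
equal values is one candidate at its midpoint, and it is a minimum
(maximum) when strictly below (above) its flanking values; sequence
endpoints are eligible.

Selection then applies three guards that the raw "take the second and
last minimum" rule needs in practice:

* **Occupied range.** Only the intensity range actually populated by
  the raw histogram is searched. Filter spill-over past the occupied
  range would otherwise create spurious valleys, and this also makes
  the geometry invariant to appending empty bins.
* **Interior minima only.** A valley whose plateau touches the range
  boundary (e.g. the decaying tail after the white-matter mode) cannot
  be a tissue boundary — selecting it would produce an empty tissue
  class — so endpoint minima are never thresholds. Interior-ness is
  judged by the plateau *extent*, not its midpoint, because a trailing
  plateau's midpoint can land inside the range.
* **Ripple floor.** Values below `10^(−A/20)` of the envelope peak
  (the filter's own stopband leakage, A = 60 dB) are zeroed before
  extrema detection, so ringing around the strong background spike
  does not masquerade as structure.

With ≥ 3 interior minima, `Th1` is the second and `Th2` the last — the
first minimum is the notch immediately after the empty-background
spike and is skipped. A clean trimodal histogram has exactly two
interior valleys and no such notch, so with exactly two minima they are
used directly. Fewer than two raises a `ThresholdingFailure` that
carries the extrema found. The alternative reading in which `Th1` sits
at the first interior peak is available as `th1_rule="first_maximum"`.

The absolute maximum breaks ties toward the smallest bin. Geometry
heights default to raw smoothed counts (so distances scale with image
size); `normalize_heights=True` switches to probability units.

## Brain mask

The mask is built from tissue pixels (`I > Th1`): 3×3 binary closing,
hole filling, largest connected component. Thresholding at zero — the
natural choice for pure-black backgrounds — breaks down on noisy
images, where roughly half the background pixels exceed zero and
percolate into the largest component; anchoring the mask at `Th1`
keeps it noise-robust while hole filling still recovers interior voids.
The zero-threshold variant remains available (`mask_mode="zero"`).

## Features

Fifteen features follow directly from the construction (2 thresholds,
2 slopes, 3 distances, 2 volumes, 2 means, 2 standard deviations, GWR,
shrinkage). The per-tissue *skewness* (third standardized moment)
completes the per-tissue moment set and brings the descriptor to the
fixed total of 17; it is a declared design choice and easy to swap.
Tissue statistics use the population convention (divide by n); the skew
of a zero-spread tissue is defined as 0. "Volume" is the 2-D pixel
count, since inputs are single slices. Extractions that fail (constant
slice, unimodal envelope, empty tissue class) produce per-image failure
records, never exceptions that abort a batch, and are excluded from the
feature table rather than imputed.

## Ranking

MRMR uses the greedy MID (difference) scheme — first pick maximises
mutual information with the label; each next pick maximises
`MI(f; y) − mean MI(f; selected)` — with equal-frequency 16-bin
discretization and base-2 logs; ties break by feature order, so the
ranking is fully deterministic. The reported score is the greedy
objective at selection time. The chi-square ranker scores each feature
by the Pearson statistic of its bin-by-class contingency table
(equal-width 10 bins by default; equal-frequency binning is available,
under which the statistic is invariant to monotone feature transforms).

## Evaluation protocol

The harness runs 10 repetitions of a stratified 60/20/20
train/validation/test split with seeds derived from one master seed —
honouring both a tenfold repetition count and those partition
fractions; a pure stratified 10-fold CV mode exists behind a flag. The
validation fifth is reserved for model selection and is never trained
on; the fixed hyperparameters used here need none, so reported metrics
come from the untouched test fifth, summarised as mean ± sd with a
pooled confusion matrix. Multiclass recall/specificity/precision/F1
are one-vs-rest macro averages (conservative under the heavy class
imbalance typical of dementia datasets); MCC is the multiclass R_K
statistic and kappa is Cohen's kappa, both computed directly from the
confusion matrix with a 0 fallback when the denominator vanishes.
Classifier families: fine decision tree, quadratic discriminant,
Gaussian naive Bayes (the closest library analogue of a kernel naive
Bayes), quadratic-kernel SVM (degree 2, coef0 = 1), 1-NN, subspace
discriminant ensemble (feature-subsampled bagging over LDA), and a
shallow network (one hidden layer of 10 units, ≤ 1000 iterations), each
behind a standardisation step.

## Phantom generator

Each phantom is an elliptical brain (semi-axes ≈ 0.44/0.37 of the
image size, ±3% jitter) with a grey annulus and a white core scaled so
the grey/white area ratio hits its target (default 1.5), rendered at
intensities 0/100/200 — well-separated modes that straddle plausible
threshold positions — with optional additive Gaussian noise clipped to
[0, 255]. Atrophy is modelled by carving voids at background level:
~85% ventricle-like interior blobs, the rest thin sulcus-like grooves,
all confined within 93% of the outline radius so every void is a closed
hole and mask recovery by hole filling is exact up to rasterisation.
Stages 0–3 use void fractions 0.02/0.08/0.18/0.30 (±15% per-sample
jitter) with the outline scaled by 1.00/0.97/0.94/0.90 — a monotone
schedule mimicking progressive atrophy. All randomness is
counter-derived from one seed, so any single phantom is reproducible in
isolation. An imbalanced mode mirrors the 3200:2240:897:64 class
proportions of the public 4-class dementia MRI set.

What the phantoms do *not* emulate: anatomy, partial-volume mixing,
bias fields, Rician noise, 3-D structure. Passing tests therefore show
that the algorithm recovers its own quantities correctly under the
stated intensity model — not that it reaches any particular accuracy on
clinical data.

## Problem sizes

The validation suite uses 1000 random images/histograms for the exact
bookkeeping and oracle checks, 50 noisy phantoms (σ = 5) for parameter
recovery, and a 200-per-stage (800-slice) phantom dataset for the
classification study — large enough that the stage classes are
represented across all splits while the whole suite stays quick on a
single CPU.

## Known limitations

* Strictly 2-D, 8-bit by default; no DICOM/NIfTI, registration, bias
  correction or skull stripping beyond the background mask.
* Threshold positions depend mildly on the filter's transition width;
  the defaults are tuned to 256-bin histograms.
* On histograms whose grey/white modes overlap heavily the valley
  between them disappears and extraction correctly reports failure
  rather than guessing.
* The evaluation harness reports phantom-data performance; accuracies
  on real MRI depend on the dataset and are out of scope here.
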