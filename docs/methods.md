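# Methods

## Scope and data model

`oralfluor` analyses paired multispectral autofluorescence endoscopic
images: for each patient, one cube over the suspicious lesion and one over a
clinically healthy-appearing contralateral site. A cube holds, per emission
band (390±20 nm, 452±22.5 nm, >500 nm), a stack of fluorescence decay traces
`y_λ(x, y, t)` on a shared uniform time axis. The unit of analysis is the
patient: each patient contributes exactly one lesion image with a single
histopathology grade (Benign, MoD, HiD, SCC), binarized as positive =
{MoD, HiD, SCC}. Coordinates are (row, col), 0-based, row-major.

Only intensity-derived features are used; decay-shape (lifetime) features
are out of scope, so the temporal axis matters solely through the integral
of each trace.

## Synthetic cohort generator

No clinical imaging data ship with the package; the generator produces
cohorts with exactly the statistical structure the analysis assumes, so that
every downstream stage is testable end to end.

Per pixel and band, the signal is a single-exponential decay after a
signal-free pre-pulse window, plus a constant background offset and
additive Gaussian noise on every time sample (Poisson noise is available but
off by default — no particular detector noise model is assumed):

    y_λ(t) = A · (f_λ / T_λ) · s_λ(t) + offset + ε,   ε ~ N(0, noise_sd²)

where `s_λ(t)` is a unit-peak exponential with per-band lifetime τ_λ
(defaults 5.0, 4.0, 4.5 ns — arbitrary but distinct; the features are
insensitive to decay shape) and `T_λ` is the trapezoidal integral of
`s_λ` on the simulation grid. Dividing by `T_λ` makes the numerically
integrated band intensity of a noise-free pixel equal `A · f_λ` exactly, so
the normalized intensities recover the configured class fractions to float
precision — the property the feature-extraction tests lean on.

The band-composition triples `f = (f390, f452, f500)` are class properties.
Defaults:

| class  | f390 | f452 | f500 | redox f452/f500 |
|--------|------|------|------|-----------------|
| Benign | 0.40 | 0.33 | 0.27 | 1.22 |
| MoD    | 0.30 | 0.350| 0.350| 1.00 |
| HiD    | 0.27 | 0.355| 0.375| 0.95 |
| SCC    | 0.24 | 0.360| 0.400| 0.90 |

These encode the reported trend directions for oral malignancy — collagen
share down, NADH share up, redox ratio down, graded with severity — at
effect sizes that make classes separable under the default noise
(`fraction_jitter_sd = 0.05` per-pixel compositional jitter, renormalized to
the simplex; `noise_sd = 2` intensity units against peak amplitudes of
~50–100). They are synthetic by construction and are **not** estimates of
clinical effect sizes; a real cohort's class overlap is far larger (field
inhomogeneity, anatomical site variation, partial-lesion fields of view,
biopsy label noise), which is why passing the recovery tests here says the
pipeline works, not that the clinical operating points would be reproduced.

Healthy cubes always draw from the Benign composition regardless of the
lesion's grade. Cohort labels follow `round(n_patients·positive_fraction)`
positives apportioned over grades by largest remainder (the default weights
1:3:29 reproduce the clinical cohort's 1 MoD / 3 HiD / 29 SCC at 33
positives) and are shuffled with a seed-derived RNG. Saturation artifacts:
a configured fraction of pixels has its amplitude boosted to twice the
clipping ceiling and every sample is hard-clipped at `saturation_level`, so
the preprocessing saturation mask has a planted ground truth. Each patient
is generated from an independent child seed of (cohort seed, patient
index), so streaming and materialized generation are bit-identical.

Defaults 64×64 pixels and 256 samples at 0.1 ns are a desk-scale stand-in
for the instrument's ~10 mm field at ~100 μm resolution; the 25.6 ns window
holds ≥99% of each exponential's area (validated), keeping integral
truncation negligible. The excitation pulse and instrument response are not
modelled — they act on the decay shape, which the features integrate out.

## Preprocessing

Five steps, in fixed order, independently on lesion and healthy cubes:

1. **Offset subtraction** — per pixel and band, the mean of the leading
   `baseline_samples` (default 16) pre-pulse samples is subtracted.
   Per-pixel estimation tolerates spatial background structure.
2. **Saturation mask** — a pixel is masked if its maximum amplitude in
   *any* band reaches the threshold. The threshold is an absolute amplitude
   if configured, else `saturation_fraction_of_max` (default 0.999) of the
   cube's global maximum. The fractional default assumes saturated pixels
   exist (clipped values tie at the maximum); on a cube with no saturation
   it may sacrifice the single brightest pixel, and on noise-free synthetic
   cubes (all pixels tied at the maximum) an absolute threshold must be
   used.
3. **Spatial smoothing** — 5×5 boxcar on every time sample, renormalized
   over in-image, unmasked neighbours: borders and masked pixels contribute
   nothing and no padding values leak in. Masked pixels are zeroed.
4. **SNR mask** — SNR(x,y,λ) = 20·log10(peak of the smoothed trace /
   σ_baseline), with σ_baseline the standard deviation of the smoothed
   trace's leading baseline samples; masked below 15 dB in any band. The
   dB definition on the amplitude ratio, the per-band rule and the
   smoothing-first order are package choices (recorded in the cleaned-file
   metadata); σ = 0 means a noise-free pixel and is kept. The "any band"
   rule reflects that all 18 features need all three bands.
5. **Manual mask** — an optional boolean image (file-based, e.g. teeth
   regions); never unmasks.

Masking is monotone across steps; each pixel's reason code is the first
cause encountered (SATURATED → LOW_SNR → MANUAL, plus NONPOS_INTENSITY from
feature extraction). A pair with zero valid pixels on either side raises an
error rather than propagating empty images.

## Feature extraction

Band intensities are composite-trapezoid integrals on the uniform grid.
Pixels where any band integral is ≤ 0 after offset subtraction (possible
under noise) are masked — every feature requires all three integrals
strictly positive; this rule is the package's resolution of an otherwise
undefined normalization. The 18 features and their canonical order are
fixed; that order is also the deterministic tie-break for feature ranking.
Relative features subtract the *median* of the paired healthy image's
corresponding absolute feature map (median for robustness to residual
artifacts); healthy stacks never receive relative features, being their own
baseline.

## Classification

Pixel-level training tables pool all valid pixels of the training lesions
(optionally capped at `pixel_cap` pixels per image — default 2000 — via a
seeded uniform subsample; `pixel_cap: null` reproduces the all-pixels
design). Each pixel inherits its image's binary label, a deliberate
label-noise source since the biopsy grades the lesion centre only.

Features are z-scored on training pixels (constant columns pass through
with unit scale). The L1 fit is liblinear's squared-hinge + L1
(`LinearSVC(penalty="l1", loss="squared_hinge", dual=False, C=1,
random_state=0)`) — the linear decision function and L1-sparse weights are
the contract; the solver variant is recorded in every serialized model, and
`random_state` pins liblinear's internal shuffling for bit-reproducibility.
Ranking uses |w| normalized to sum 1, descending, ties (including the
all-zero case, which is logged) broken canonically. The top-k refit uses
the same solver on the selected columns; if fewer than k features have
nonzero weight the remainder fills from canonical order with a warning.

Posterior probabilities come from a Platt-style logistic calibration,
`p = 1/(1+exp(a·d + b))`, fitted on the training decision values with a
weakly regularized 1-D logistic regression (C = 10⁶ caps the slope on
perfectly separated data). Any monotone calibrator leaves image rankings —
and hence ROC-derived thresholds — unchanged; logistic is the conventional
choice and the only one currently exposed.

## Evaluation

Image score = mean posterior over valid pixels. The operating threshold is
selected per fold on the *training* image scores: candidate thresholds are
the unique observed scores plus one value above the maximum (with the
`score ≥ θ` rule, intermediate candidates cannot enlarge the achievable
operating set, and the extra candidate guarantees feasibility at FPR = 0);
among candidates with FPR ≤ 30%, maximize sensitivity, break ties toward
lower FPR, then toward the larger threshold. An exhaustive-enumeration
oracle over a dense threshold grid verifies this rule property-wise in the
tests.

LOPOCV holds out one patient per fold (the healthy pair travels with its
patient, having already been consumed by the relative features). Held-out
data never touch training: a dedicated test permutes the held-out image's
pixels and checks the fold's model and threshold are bit-identical.
Reported: overall and per-grade confusion matrices, sensitivity TP/(TP+FN),
specificity TN/(TN+FP), accuracy (TP+TN)/N (integer-percent rounding in
reports), and each feature's selection frequency across folds. The
single-feature baseline (`I452,n+I500,n`, equal to `1 − I390,n` by the
normalization identity) runs the identical protocol with k = 1 and no
ranking step.

## Reproducibility and problem sizes

All randomness flows from one root seed, expanded per stage
(simulation, pixel subsampling) with a seed sequence; derived seeds are
logged in the run manifest together with a config hash, and every artifact
is reproducible from (config, seed) alone. Fold-wise runs share the one
subsample seed; it is recorded in `metrics.csv`.

Default study conditions — and the sizes used by the package's own
validation — are 40 patients, 64×64 pixels, 256 time samples and a
2000-pixel per-image cap: large enough for stable selection behaviour,
small enough that a full simulate-to-report cycle takes well under a minute
per cohort on a laptop core. Unit tests use smaller cohorts (8–12 patients,
12×24-pixel squares) chosen for speed.

## Known limitations

- Lesions are spatially homogeneous in the simulator; there is no partial
  lesion coverage, illumination inhomogeneity, motion blur or instrument
  response, and no registration between lesion and healthy images is
  performed (none is needed — the healthy image enters only via medians).
- Effect sizes, noise levels and the noise model are synthetic choices;
  performance numbers on synthetic cohorts characterize the pipeline, not
  the clinical problem.
- With heavily correlated features (all 9 absolute features are functions
  of the same compositional triple), L1 selection distributes weight among
  near-collinear proxies; selection frequencies should be read per group of
  correlated features rather than per single feature.
- The image score is the posterior-map mean; alternative summaries (median,
  mode, fraction of pixels above a probability cut) are deliberately not
  implemented.
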