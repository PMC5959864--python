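# Methods

## The calibration problem

The regression target is the moisture mass fraction *w* of a withering
tea-leaf sample (≈ 0.77 fresh to ≈ 0.40 fully withered). The predictors
are 15 first-order image statistics of the leaf surface. The workflow is
the standard chemometric one: standardize, reduce by PCA, partition with
Kennard–Stone, calibrate linear (PLS) and nonlinear (SVR, random-forest)
regressors, and report the usual indicator set on an external prediction
set.

## Feature definitions and numerical choices

* **Colour.** R, G, B are per-channel pixel means on the native integer
  scale (0–255 or 0–65535). H, S, V are means of the standard per-pixel
  RGB→HSV conversion on [0, 1]; the hue of achromatic pixels is defined
  as 0. L\*, a\*, b\* are means of a per-pixel sRGB→XYZ→Lab conversion
  (D65, 2° observer, standard sRGB linearization). The conversion is
  implemented in-package with the published sRGB→XYZ matrix and the
  reference white defined as that matrix's image of (1, 1, 1); with the
  rounded published coefficients this keeps the white anchor exact
  (pure white → L\* = 100, a\* = b\* = 0 to machine precision), which the
  test suite relies on.
* **Gray histogram.** Gray = 0.299 R + 0.587 G + 0.114 B on the native
  scale, mapped to 256 bins by affine rescaling to [0, 255] and rounding
  (a 16-bit image is therefore binned at 8-bit resolution). Binning by
  rescale-and-round rather than bit-shifting makes the 8→16-bit scale
  covariance exact: multiplying pixels by 257 leaves U, e, r, μ₃
  bit-identical while R, G, B, m, δ scale linearly.
* **Texture.** With bin probabilities p(zᵢ) and native-scale levels zᵢ:
  m = Σ zᵢ p(zᵢ); δ = √Σ (zᵢ − m)² p(zᵢ) (native scale);
  μ₃ = Σ ((zᵢ − m)/scale)³ p(zᵢ) and r = 1 − 1/(1 + (δ/scale)²) use gray
  rescaled to [0, 1] so both stay bounded; U = Σ p²; e = −Σ p log₂ p in
  bits with 0·log 0 ≡ 0. The six statistics are deliberately first-order
  (histogram) statistics; no co-occurrence offsets or angles enter.
* **ROI.** The analysis region defaults to a centered 1000 × 2000 crop;
  images smaller than the requested region are analysed whole with a
  warning. The synthetic frames are generated at ROI scale, so the
  pipeline skips cropping by default.

## Preparation

* **Z-score** uses the sample standard deviation (n − 1 denominator,
  configurable via `ddof`). Zero-variance features are rejected by name.
* **PCA** (full SVD) is fitted on standardized features; default output
  dimension 10 of 15, capped at the number of fit rows.
* **Leakage scope.** By default the standardizer and PCA are fitted on
  calibration rows only; `fit_scope="all"` reproduces the common
  whole-set-preprocessing variant for replication purposes.
* **Kennard–Stone** seeds the calibration set with the pair at maximal
  pairwise distance, then repeatedly adds the sample whose minimal
  distance to the selected set is maximal; ties break to the lowest
  index, making the split fully deterministic. The Mahalanobis metric
  whitens by the covariance of the full feature matrix; when its
  condition number exceeds 1e12 a ridge of 1e-8 · trace/p is added
  (or the split is refused with guidance if regularization is disabled).

## Models and tuning protocols

* **PLS** (NIPALS-type, via scikit-learn's `PLSRegression`, no internal
  scaling). The latent dimension is selected by cross-validated RMSE
  (shuffled K-fold, default 10 folds) over npc 1–10, ties to the
  smallest npc. Raw RMSEC is monotone non-increasing in npc and is kept
  only as a compatibility criterion.
* **ε-SVR** (libsvm via scikit-learn). Kernel set: linear, polynomial,
  rbf, sigmoid. ε defaults to 0.01 on the moisture-fraction scale — about
  half the replicate noise, so the tube absorbs measurement error without
  flattening the signal. (c, g) are searched exhaustively on the
  logarithmic grid 2⁻¹⁰ … 2¹⁰ under 5-fold CV; ties resolve to smaller c,
  then smaller g.
* **Random forest** (scikit-learn, seeded, single-threaded for
  reproducibility). The grid spans input PCs 1–10 × trees 50–1000 in
  steps of 50 (200 cells). The default selection criterion is out-of-bag
  RMSE; in-sample RMSEC is near zero for any large forest and is retained
  only as a compatibility mode. Ties resolve to fewer PCs, then fewer
  trees.

## Evaluation conventions

With prediction-set residuals rᵢ = ŷᵢ − yᵢ, n = |prediction set|:
Bias = mean r; RMSEP = √mean r²; SEP = √(Σ(rᵢ − Bias)²/(n − 1));
RPD = sd(y, n−1)/RMSEP; CV = sd(y)/mean(y); R is the Pearson correlation
of measured vs predicted. These standard definitions imply the identity
RMSEP² = Bias² + SEP²·(n − 1)/n, which the tests assert on random
residual vectors. Published tables in this area are not always mutually
consistent in their SEP/CV/RPD conventions, so the definitions above are
fixed and documented rather than reverse-engineered. A perfect prediction
set reports RPD = ∞; constant reference vectors are rejected because R
and RPD are undefined. Correlation significance stars use two-sided
t-tests at 0.05 (\*) and 0.01 (\*\*) without multiple-testing correction
(a Bonferroni option exists but is off by default, matching how such
tables are conventionally presented).

## The synthetic generator

The generator emulates the study design: 23 time points every 0.5 h, 6
replicates each (138 samples), moisture falling from 0.7718 to 0.3953
along w(t) = w_start − (w_start − w_end)(t/T)^shape with shape 1 by
default (only the endpoints and cadence of the real course are known;
a power law keeps curvature configurable). Replicate noise is Gaussian
with sd 0.01 — replicate-level variance is not reported anywhere, and
1 percentage point of water content is a realistic repeatability for
oven/halogen moisture analysis of 3 g subsamples.

**Image path.** The base colour at moisture w comes from piecewise-linear
Lab links — L\* rising linearly (34 → 53), a\* falling (−5 → −14, steeper
above the breakpoint), b\* rising and saturating — and a "wrinkle" field
(Gaussian-filtered seeded noise, σ = 6 px, unit variance) is added to L\*
(and, attenuated, to a\*/b\*) with amplitude following a piecewise-linear
link in w with breakpoint 0.60 (1.5 → 7 L\* units), plus per-pixel fine
noise (sd 0.5 L\* units). Frames default to 400 × 200 px, the 2:1 aspect
of the full-scale 2000 × 1000 analysis region. Link slopes were fixed
once so that the extracted features reproduce the observed sign pattern:
G, L\* strongly positive with moisture, U strongly negative, a\* negative,
S, b\*, e positive, with the texture statistics saturating below w = 0.60.

**Direct feature path.** For model-level work the 15 features are drawn
directly: each feature is a piecewise-linear link of the realized
moisture plus noise with a configurable covariance (default diagonal,
per-feature sds on each feature's natural scale). B, H and μ₃ carry no
moisture link, mirroring their non-significance in the observed
correlation structure.

**What the generator does not emulate:** illumination drift, specular
highlights, leaf/background segmentation, camera optics and demosaicing,
inter-feature noise correlation (default), and any biochemical dynamics.
Passing tests therefore demonstrate that the pipeline recovers structure
of this idealized kind, not field performance on real photographs.

All randomness flows through explicit per-call seeds; the pipeline
derives its stage seeds from one master seed via a seed sequence, so a
rerun with the same config is byte-identical in every CSV it writes.

## Problem sizes

The default desk-scale settings — 138 samples, 400 × 200 px frames,
441-cell SVR grid under 5-fold CV, 200-cell RF grid — run the full
pipeline in about two minutes on one CPU; unit tests use further reduced
designs (e.g. 8 × 3 samples, 64 × 32 px) chosen as the smallest sizes at
which each property is still meaningfully exercised.

## Known limitations

* The six texture statistics are first-order; spatially structured
  texture change with constant histogram is invisible to them.
* Kennard–Stone is applied to all 138 samples directly; no outlier
  screening precedes it.
* The PLS implementation delegates to scikit-learn; an independent
  NIPALS reference in the test suite guards the numerical contract.
* Serialized model bundles store the estimator state via joblib plus
  JSON/npz for metadata and preprocessing arrays; bundles are for
  round-tripping within the same environment, not long-term archival.
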