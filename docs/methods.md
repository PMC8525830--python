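# Methods

This note records the models, default parameters, numerical choices, and
known limitations of `fovealoc`, in the spirit of a package methods
appendix. Coordinates are master-image arcmin throughout, x rightward and
y downward; 1 deg = 60 arcmin exactly. Densities are cones/deg² and
spatial frequencies cycles/deg — those are the only places degrees appear.

## Cone density mapping

Cone centers are rasterized so that each cone occupies exactly one pixel
(default pixel scale 0.1 arcmin/px, well below a foveal cone diameter of
~0.5 arcmin, so the one-pixel rule is safe; a collision raises an error
naming the pair). The binary map is convolved with a circular window of
diameter 8 arcmin, discretized as the set of pixels whose centers lie
within the radius — the same definition a brute-force count uses, so the
two routes agree exactly. Counts are divided by the discretized window
area in deg². The density peak is the argmax restricted to pixels whose
window lies fully inside the image (margin = window/2); ties are broken
by the smallest row-major index with a warning. Whether to report raw
window counts or per-area densities is not dictated by the convolution
itself; we always normalize per deg² because the hexagonal-packing
sampling limit N_c = √(D/(2√3)) requires that unit.

FFT convolution is used for speed; because the exact result is an integer
count, the output is rounded to the nearest integer, which removes FFT
noise entirely rather than approximately.

## Fixation traces and the PRL

The PRL for a day is the mean of a maximum-likelihood 2D Gaussian over
the valid retinal target locations. The ML covariance is the (1/n)
scatter matrix — not the (1/(n−1)) unbiased estimate — because AIC
requires the likelihood at the ML point; the parameter count is k = 5.
The day-pair comparison fits m1 (pooled data, one Gaussian, k = 5) and
m2 (day-specific means, pooled within-day ML covariance, k = 7); both are
closed-form, and tests verify agreement with a generic numeric optimizer
to 1e−6 in log-likelihood. The m2 covariance is pooled after per-day mean
centering (the standard shared-covariance MLE); the alternative reading
(pooling before centering) collapses m2 into m1 and was not used. With
ΔAIC = AIC(m1) − AIC(m2), P(m1 best) = exp(−ΔAIC/2)/[1 + exp(−ΔAIC/2)]
and ER = P(m1)/P(m2) = exp(−ΔAIC/2); identical day data force
ΔAIC = −4 (Δk = 2 with identical likelihood) and ER = e².

The geometric median is computed by Weiszfeld iteration (tolerance 1e−8
arcmin, max 1000 iterations) with the Vardi–Zhang modified step when an
iterate lands on a data point.

Frame exclusion marks the first 20 frames (~667 ms at 30 Hz) of every
epoch invalid, covering the saccadic reaction to the target shift; the
operation is idempotent and never revalidates frames. For observers with
three days, the AIC/KS comparison uses the two days with the largest mean
difference — the most conservative choice for a stability claim.

## Two-sample 2D Kolmogorov–Smirnov test

The Fasano–Franceschini statistic: for every data point of each sample,
the fraction of each sample in each of the four open axis-aligned
quadrants around that point is compared; D is the average of the two
per-sample maxima of |F₁ − F₂|. Points falling exactly on a quadrant
boundary count in neither open quadrant. The asymptotic p-value uses
Z = D·√(n₁n₂/(n₁+n₂)) with the usual correlation correction
p = Q_KS(Z/(1 + √(1−r̄²)(0.25 − 0.75/√n))), r̄² the mean squared Pearson
correlation of the two samples. At the epoch-mean sample sizes this
pipeline produces (~25–35 per day) the asymptotic formula is rough, so a
label-permutation p-value is available and is the pipeline default.

The test is applied to per-epoch means, never raw 30-Hz frames: frames
within an epoch are strongly autocorrelated (drift), while epoch means
are approximately independent. The statistic is exactly invariant under
identical translations and isotropic scalings of both samples and under
argument exchange; it is **not** invariant under rotation (the quadrants
are axis-aligned), which the tests document.

## The SFL model

Densities over retinal stimulus location r, all sharing the center c:
"yes" ~ N(c, Σ_yes); "maybe" ~ N(c, Σ_maybe); "no" ~ a
difference-of-Gaussians constrained to be zero at the center,

    f(r) = C·[exp(−q/(2κ²)) − exp(−q/2)], q = (r−c)ᵀΣ_in⁻¹(r−c),
    Σ_out = κ²·Σ_in (shared orientation), κ > 1,
    C = 1/(2π√|Σ_in|(κ²−1)).

Equal unit peak amplitudes are the minimal construction that is
non-negative, exactly zero at the center, and smooth in its parameters;
free amplitudes with max(·, 0) clipping were rejected because the clip
makes the likelihood non-smooth. Each category is fitted as an
independent sample of its own normalized density (not as a mixture with
category priors), so category proportions do not influence c. Covariances
use a log-Cholesky parameterization and κ uses log(κ−1), giving an
unconstrained smooth search space; 8 multi-starts (BFGS, best result
polished by Nelder–Mead) are seeded from per-category moment estimates.
The "yes"/"maybe" Gaussians carry full covariance (elliptical, any
orientation). The 60.6% (= e^(−1/2), the 1-SD level of a single
Gaussian) level ellipses of the DoG are constant-q contours solved by
bracketed root finding on the radial profile, one on the inner slope
toward the central dip and one on the outer slope.

For isotropic Σ_in = σ²I the ring of maximal "no" density sits at
r* = σ·√(2·ln(κ²)·κ²/(κ²−1)), which the tests verify numerically.

## Comparative statistics

The normalized-distance t-test divides both |PRL−SFL| and |peak−SFL| by
|PRL−peak| per observer before the paired t-test, removing the trivial
dependence on how displaced the PRL is; an observer with PRL = peak is
excluded with a warning. The displacement-direction correlation
re-centers both angle sets so the circular mean of the PRL angles maps to
zero, wraps to (−π, π], and computes Pearson r with df = n−2 — one
reasonable handling of the wrap-around ambiguity, documented rather than
claimed unique.

The ordinal response model is a cumulative-logit regression (categories
yes < maybe < no) on stimulus distance from the raster center, distance
from the observer's PRL, and optionally their product, with observer as
fixed intercepts. A random observer effect would match the original
repeated-measures design more closely; fixed intercepts are a documented
approximation, and per-term likelihood-ratio chi-square tests (refitting
without the term) replace software-specific F statistics. Coefficients
are reported in the convention P(Y≤k) = σ(cut_k + xβ), so a negative
distance coefficient means "yes" becomes less likely with distance.

The ROI test centers one circle on the PRL and one displaced from the
mean retinal location of the raster center by the same vector in the
opposite direction (in retinal coordinates), both with diameter equal to
the separation — which bounds the overlap of the two regions; the 2×2
yes/not-yes × ROI table gets a Pearson chi-square without continuity
correction.

## The synthetic generator

The generator produces the statistical structure the analysis assumes,
with ground truth, at the experimental geometry of AOSLO foveal studies:

* **Mosaic**: hexagonal lattice, default spacing 0.5 arcmin at the peak,
  warped radially so local spacing grows as a0·(1 + R/falloff) with
  falloff 80 arcmin, Gaussian positional jitter (default SD 0.03 arcmin),
  over a 35-arcmin-diameter region. The warp stretches tangential spacing
  about half as fast as radial spacing; the functional form is a smooth
  monotone placeholder, not a claim about real foveas.
* **Fixation sessions**: 4 runs × 30 s at 30 Hz per day; the target
  shifts every 2–6 s by 5.5–15.6 arcmin within an 11×11-arcmin region.
  Recorded retinal target location = PRL + drift + i.i.d. scatter, plus,
  for a latency of 8 ± 2 frames after each shift, the old-target offset
  (the eye has not yet saccaded, so the stimulus sits a shift-distance
  away). Drift is a mean-reverting walk (stationary SD 0.5 arcmin,
  reversion 0.15/frame ≈ 200-ms correlation time); microsaccades are
  Poisson events at 1.2 Hz that reset the drift state with 0.3-arcmin
  landing scatter; blinks (0.1 Hz, 200 ms) invalidate frames. Frame
  scatter SD is 2 arcmin per axis ("a few arcmin" of fixational
  scatter). These oculomotor magnitudes are configurable placeholders —
  chosen once as plausible for foveal fixation, and so that a day of
  ~2700 valid frames determines the PRL to better than a tenth of an
  arcmin. Defaults yield ~2700–2950 valid frames and ~28–33 epochs per
  day after exclusion.
* **Judgment trials**: stimulus offset s uniform in a 22-arcmin square;
  raster-center retinal position e ~ N(alignment, eye_sd) with the
  alignment locus defaulting to the SFL and eye scatter SD 3 arcmin;
  r = e + s exactly. Responses come from a cumulative-logit model with
  linear predictor β_raster|s| + β_prl|r−SFL| (+ interaction), defaults
  β_raster = −0.25/arcmin, β_prl = −0.35/arcmin, cutpoints (2, 4) —
  giving a high "yes" rate at the center that decays over ~10 arcmin.
  Microsaccade flags are independent Bernoulli(0.1).

What the generator does **not** emulate: intra-frame retinal motion and
saccade main-sequence dynamics, torsion, optical blur and raster
distortion, response biases that depend on anything but the two
distances, and non-Gaussian heavy-tailed fixation scatter (real fixation
distributions show excess kurtosis). Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to every property of real recordings.

## Registration

Template localization is normalized cross-correlation with quadratic
3×3 sub-pixel refinement; scores below 0.5 flag the sample invalid.
Similarity registration estimates rotation/scale by phase correlation of
log-polar-warped Fourier magnitudes (band-passed and Hann-windowed) and
translation by phase correlation. Because the magnitude-spectrum stage is
biased for small rotations and can lock onto spurious peaks, both the
identity and the log-polar candidate are polished by a direct Powell
search on the normalized correlation of the warped overlap, and the
better final correlation wins; the correlation itself is returned as the
registration quality (failures below a configurable threshold raise).

## Problem sizes and runtime choices

The test suite and acceptance script use: 10 replicate days for PRL
recovery; 100 replicate day-pairs per condition for AIC model-selection
rates; 60 replicates for the ordinal type-I calibration; n = 1000–1500
trials for SFL and ordinal recovery (the scale of a real observer's
trial count); permutation KS with 2000 label permutations. These sizes
make each stochastic check reproducible and statistically meaningful
while keeping a full run to a few minutes on one CPU.

## Known limitations

* AIC model comparison on raw frames inherits their autocorrelation:
  with a genuinely shared PRL the shared-model preference rate is capped
  at P(χ²₂ < 4) = 86.5% for i.i.d. frames and drops further under
  drift autocorrelation (~73% at the default drift settings). The
  package reports the evidence ratio as defined; interpreting a single
  ER near 1 as decisive is not supported, which the stability analysis
  mitigates by pairing AIC with the KS test on epoch means.
* The fixed-intercept ordinal model understates between-observer
  variance relative to a random-effects fit.
* The 840-Hz strip-level eye-motion recovery of AOSLO processing is out
  of scope; all localization is frame-level at 30 Hz.
* Real deposited datasets can be analyzed by mapping them to the trace
  and trial CSV schemas (`fovealoc.io`); no download automation is
  provided.
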