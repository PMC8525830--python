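# fovealoc

Analysis tools for foveal fixation loci measured with adaptive-optics
scanning-laser ophthalmoscopy (AOSLO): from cone mosaics and per-frame
retinal stimulus traces to the cone-density peak, per-day estimates of the
**preferred retinal locus (PRL)** of fixation with day-to-day stability
tests, the **subjective fixation location (SFL)** inferred from
three-category ("yes"/"maybe"/"no") fixation judgments, and the
comparative statistics relating the three loci. A synthetic-data generator
with full ground truth stands in for AOSLO recordings, so every estimator
ships with parameter-recovery tests.

Intended users: vision scientists analyzing retinal-stabilized fixation
or stimulus-localization experiments, and anyone needing tested building
blocks for 2D Gaussian AIC model comparison, the two-sample 2D
Kolmogorov–Smirnov test, or constrained difference-of-Gaussians density
fits.

## The models

**Cone density and sampling limit.** Cone centers are rasterized to a
binary map and convolved with a circular window (diameter 8 arcmin); the
convolution maximum is the cone density peak. Assuming hexagonal packing,
density D (cones/deg²) implies spacing a with D = 2/(√3·a²) and a sampling
(Nyquist) limit N_c = 1/(√3·a) = √(D/(2√3)) cycles/deg.

**PRL and stability.** The PRL for a day is the mean μ of a 2D Gaussian
fitted by maximum likelihood to the valid retinal target locations (the
first 20 frames ≈ 667 ms after each target shift are excluded while the
corrective saccade completes; the assumption-free geometric median is
reported alongside). Two days are compared with AIC between m1 (one
Gaussian, shared μ and Σ, k = 5) and m2 (day-specific means, shared
covariance, k = 7):

    ΔAIC = AIC(m1) − AIC(m2),
    P(m1 best) = exp(−ΔAIC/2) / [1 + exp(−ΔAIC/2)],
    evidence ratio ER = P(m1 best) / P(m2 best),

plus a distribution-free two-sample 2D Kolmogorov–Smirnov test
(Fasano–Franceschini quadrant statistic) on per-epoch mean locations.

**SFL.** Over retinal stimulus location r, "yes" responses are modeled as
N(c, Σ_yes), "maybe" as N(c, Σ_maybe), and "no" as a
difference-of-Gaussians ring scaled to a minimum of 0 at the center:

    f(r) ∝ exp(−q/(2κ²)) − exp(−q/2),  q = (r−c)ᵀ Σ_in⁻¹ (r−c),  κ > 1,

all three sharing the center c, which — after maximizing the joint
likelihood — is the SFL.

**Comparisons.** Paired t-test on SFL distances to PRL vs cone peak
(normalized by the PRL–peak distance), Pearson correlation of displacement
directions, an ordinal (cumulative-logit) regression of the response on
stimulus distance from the raster center and from the PRL, and a
chi-square test of "yes" proportions in a PRL-side vs opposite-side
region of interest.

## Worked example

Run the full pipeline on synthetic inputs (default conditions: 2 days ×
4 runs × 30 s at 30 Hz; target shifts of 5.5–15.6 arcmin every 2–6 s;
1500 judgment trials):

```python
from fovealoc import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(out_dir="demo_out", seed=7,
                                     ks_method="permutation"))
```

which logs

```
INFO:fovealoc:cone mosaic: 4516 cones
INFO:fovealoc:density peak 16191.04 cones/deg^2 at (-0.38, -0.20) arcmin
INFO:fovealoc:day 0: 2909 valid samples
INFO:fovealoc:day 1: 2944 valid samples
INFO:fovealoc:report written to demo_out/report.json
```

and produces (abridged from `demo_out/report.json`):

| quantity | value | meaning |
|---|---|---|
| cone peak density | 16191 cones/deg² | → sampling limit 68.4 cpd |
| PRL day 0 / day 1 | (0.02, −0.03) / (−0.09, 0.06) arcmin | true PRL is (0, 0) |
| max day distance | 0.147 arcmin | sub-cone-diameter stability |
| KS on epoch means | D = 0.30, p = 0.204 (n = 33, 31) | no detectable day difference |
| SFL center | (0.94, −0.51) arcmin | generated at (1.0, −0.5) |
| "yes" ellipse QMR | 3.75 arcmin | larger than the fixation scatter |
| ordinal LR tests | raster p = 7.5e−5, PRL p = 1.7e−7, interaction p = 0.87 | both distances matter, no interaction |

The same stages are exposed on the command line:

```sh
fovealoc simulate mosaic --seed 1 --out demo
fovealoc conedensity --cones demo/cones.csv --out demo
fovealoc run --seed 7 --out demo_out
```

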