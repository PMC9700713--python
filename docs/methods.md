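# Methods

## Overview

`pwpe-eeg` implements a model-based single-trial analysis of the
auditory duration-oddball EEG paradigm. A three-level binary
hierarchical Gaussian filter (HGF) is run as a Bayes-optimal learner
over the standard/deviant tone sequence; its trial-wise
precision-weighted prediction errors (pwPEs) and uncertainty
trajectories are used as regressors in voxelwise GLMs over smoothed 2D
scalp x time volumes, followed by random-effects group inference with
permutation family-wise error (FWE) control and ANCOVA against symptom
severity (SIPS positive totals). Because the patient recordings the
design emulates are not publicly deposited, a first-class synthetic
module generates cohorts with planted, ground-truth effects; every
statistical claim the test suite makes is made against that ground
truth.

## The perceptual model

For tones u_k in {0 (standard, 50 ms), 1 (deviant, 100 ms)} the HGF
tracks three latent states: the stimulus category (level 1), the
tendency x2 toward deviants (level 2, Gaussian belief mu2, sigma2),
and the phasic log-volatility x3 of that tendency (level 3, belief
mu3, sigma3). Predictions before trial k:

    muhat1 = s(mu2),            sigma1 = muhat1 (1 - muhat1)
    v2     = exp(kappa mu3 + omega2)
    pihat2 = 1 / (sigma2 + v2), pihat3 = 1 / (sigma3 + exp(omega3))

with s the logistic sigmoid. After observing u_k:

    delta1 = u - muhat1
    pi2    = pihat2 + sigma1            (Bernoulli Fisher information)
    eps2   = delta1 / pi2,  mu2 <- mu2 + eps2,  sigma2 = 1/pi2
    delta2 = (sigma2 + eps2^2) / (sigma2_prev + v2) - 1
    w2     = v2 / (sigma2_prev + v2)
    r2     = (v2 - sigma2_prev) / (v2 + sigma2_prev)
    pi3    = pihat3 + (kappa^2/2) w2 (w2 + r2 delta2)
    eps3   = kappa/(2 pi3) w2 delta2,  mu3 <- mu3 + eps3

Every update has the generic form `delta_mu_i ∝ (pihat_{i-1}/pi_i)
delta_{i-1}`: the precision ratio is a dynamic learning rate. eps2 is
the low-level (sensory) pwPE, eps3 the high-level (volatility) pwPE;
sigma1/sigma2/sigma3 are the irreducible, informational and
environmental uncertainty trajectories. A non-positive pi3 marks the
parameter set inadmissible and raises (the fitter maps this to an
infinite objective). exp() overflow raises a domain error naming the
offending parameter, with the trial index attached by the sequence
filter.

Defaults (conventions of this package, all configurable): kappa = 1
fixed; starting beliefs mu2 = 0, sigma2 = 1, mu3 = 1, sigma3 = 1.

### Bayes-optimal fit

The oddball task is passive, so the model cannot be fitted to
behaviour. Instead (omega2, omega3) are chosen to minimise the
cumulative surprise S = -sum_k log p(u_k | prediction) plus Gaussian
prior penalties — a MAP estimate of the parameters an ideal observer
would use. Priors default to omega2 ~ N(-3, 16) and omega3 ~ N(-6, 16)
(weakly informative; the emulating study's exact priors are not
printed). Optimisation is Nelder-Mead from five fixed multi-starts;
inadmissible proposals receive +inf and are counted in the
diagnostics. Surprise is reported in nats (a bits option exists).
Trajectories are exported signed; an unsigned-magnitude variant is a
flag, since it is not documented whether the original regressors were
rectified.

## Synthetic data generator

The generator emulates the study conditions: 1830 tones, 10% deviants
placed i.i.d. Bernoulli (an optional `min_gap` enforces a minimum run
of standards between deviants; the original placement constraints are
unknown), ISI 500 ms, 32-channel modified 10-20 cap (Fp1...PO10)
sampled at 500 Hz plus a vertical EOG channel, epochs -100..400 ms,
and a cohort of 23 HC + 31 CHR with SIPS positive totals ~ N(10.5,
3.6^2) clipped at zero (other subscales likewise from the published
cohort table). Channel 2D positions come from the standard 10-20
template (azimuthal-equidistant projection, equatorial ring at 90 mm);
the exact cap geometry of the original recordings is unspecified.

Trial-wise EEG amplitude at the chosen channels/latencies varies
linearly with z-scored HGF regressors:

    amplitude(k, c, t) = drift + sum_e A_e * scale_subj * z(reg_e)_k
                         + AR(1)-in-time, Gaussian-in-space noise
                         (+ blink transients)

Defaults chosen once as study conditions: planted effect 5 uV per
z-unit of eps2 on six frontocentral channels (F3, Fz, F4, FC1, FC2,
Cz) in a 100-228 ms boxcar window — the window and topography of the
reported CHR sensory-pwPE cluster; noise sd 10 uV per sample
(single-trial EEG scale), AR(1) coefficient 0.95 at 500 Hz (smooth
band-limited background), spatial correlation length 40 mm (volume
conduction surrogate), blink rate 0.05/trial at 300 uV on the EOG with
fixed frontal leakage fractions, slow per-trial drift sd 2 uV. CHR
effect amplitude scales as 1 + 0.5 z(SIPS positive), making the
symptom-severity ANCOVA testable with a known positive link.

What the generator does *not* emulate: realistic EEG spectra, forward
head models/dipoles, non-stationary artifacts beyond blinks,
inter-subject montage variability. Passing tests therefore demonstrate
correctness and calibration of the statistical machinery under a known
generative model — not sensitivity or specificity on real recordings.

## Preprocessing

Fixed rule set, matching the emulated study where stated and filling
gaps with documented choices: zero-phase (forward-backward) 4th-order
Butterworth 0.5-30 Hz (order and zero-phase application were
unstated; forward-backward preserves latencies); blink detection as
supra-threshold excursions on the vertical EOG (default 250 uV,
padded +-100 ms; the original threshold is unstated) with overlapping
trials rejected rather than corrected; epoching to -100..400 ms (251
samples at 500 Hz) with -100..0 ms baseline subtraction; absolute
100 uV amplitude rejection (peak-to-peak vs absolute was unstated;
absolute chosen); channels artefactual in > 20% of trials flagged and
replaced by inverse-distance-weighted interpolation on the 2D montage
(the original software's spline default differs; inverse-distance is
dependency-free and exactly testable), after which the trial rule is
re-applied without them. Data stay in the recorded reference.
Rejection bookkeeping is conservative: kept + blink + amplitude +
edge-dropped = number of events, and re-running the cleaning on a
cleaned EpochSet is a no-op.

## Scalp x time GLM

Trial amplitudes are barycentrically (linearly) interpolated from the
electrode positions onto a regular lattice — voxel 4.25 mm x 5.38 mm
x 2 ms; the emulating study prints "4.25 ms x 5.38 ms" for the two
spatial axes, read here as a units typo for mm — restricted to the
100-400 ms analysis window and masked to the electrode hull. Spatial
smoothing uses a Gaussian kernel (FWHM 16 mm x 16 mm) renormalised
inside the mask, with an additive correction that preserves each
volume's masked mean exactly; no smoothing along time (only a spatial
FWHM is specified). Each voxel's trial series is fitted by OLS on
[1, z(regressor)], one regressor per GLM (separate GLMs per
computational quantity; a multi-regressor design is a config option,
off by default). Z-scoring per subject is applied by default so betas
are comparable across subjects at the group level.

## Group inference

Second level: one-sample t on subject betas, squared to F with df
(1, n-1); unpaired pooled-variance two-sample t for group differences
(the emulated study wrote "paired t-test", which is not computable for
23 vs 31 subjects; the implemented test and the verbatim wording are
both recorded in provenance); ANCOVA F on a covariate slope (SIPS
positive; optional age/sex nuisance) with the signed slope map
attached.

FWE control is permutation-based with max statistics: sign-flipping
for the one-sample design, Freedman-Lane residual permutation for
covariate designs. Clusters are 6-connected components above the F
value whose upper tail equals the cluster-defining threshold (default
p < 0.001); cluster-level p is the rank of the observed extent in the
permutation null of maximum extents, peak-level p likewise for the
maximum statistic; p = (1 + #{null >= obs}) / (n_perm + 1). 18- and
26-connectivity are config options. The original analysis used
random-field-theory corrections; permutation FWE was chosen because it
is self-contained and its calibration is directly testable. A
Gaussian-field peak correction is included only as a labelled
approximation. No correction is applied across the separate per-
regressor GLMs, matching per-quantity reporting.

Note on printed effect sizes: the standard conversion f^2 =
eta_p^2/(1-eta_p^2) with eta_p^2 = F df1/(F df1 + df2) gives f^2 = 1.0
for F(1,29) = 29.3, not the 0.338 printed in the emulated study; the
conversion used there is unknown, so printed f^2 values are not used
as references anywhere.

Report-level summaries: maximum-intensity projections collapsing the
left-right axis (retaining anterior-posterior x time), 15%/85%
quantile-split ERPs by regressor value (stable trial-order
tie-break), and the classical mismatch negativity difference wave
(standard minus deviant).

## Numerical choices and degenerate inputs

* exp() arguments are guarded at 700; saturated sigmoids raise rather
  than silently degenerate.
* Zero between-subject variance at a voxel yields an infinite
  statistic sentinel plus a log entry (never a silent NaN); 0/0 is
  defined as 0. Infinite sentinels are excluded from cluster forming.
* Quantile splits round q*n to the nearest integer and warn below 5
  trials per side.
* Permutation p-values are reproducible under a fixed seed; across
  seeds their standard error is sqrt(p(1-p)/n_perm).
* One master seed deterministically derives every per-subject,
  per-sequence and per-permutation seed (SeedSequence hierarchy, all
  below 2^31).

## Problem sizes in tests and the acceptance script

The calibration and recovery studies run scaled down, as this
package's own choice of affordable-but-informative sizes: FWER
calibration on a fully in-mask 8 x 8 x 30 lattice, 10 subjects, 500
sign-flips, 200 replicates; planted-effect recovery with 8 subjects x
200 trials per run on a coarsened lattice (12 x 12 mm x 8 ms) with 200
permutations, 50 runs; ANCOVA recovery with the full n = 31 CHR cohort
x 200 trials, 10 runs (8 in the acceptance script). The acceptance
script additionally reduces the FWER study to 100 replicates and
effect recovery to 20 runs. Full-size single-subject paths (1830
trials, 4.25 x 5.38 mm x 2 ms lattice) are exercised by the
deterministic tests.

## Known limitations

* The stationary oddball stream couples eps2 and eps3 strongly (the
  tone contingencies never switch), so volatility-level effects are
  hard to isolate — an inherent property of the paradigm, visible in
  the synthetic data too.
* Permutation FWE is not numerically interchangeable with
  random-field-theory corrections; cluster p-values agree in
  calibration, not value-for-value.
* The sign-flip permutation null assumes symmetric subject effects;
  with very few subjects the smallest achievable p is 2/2^n.
* Inverse-distance channel interpolation is a local scheme; it will
  differ from spherical-spline interpolation near the cap boundary.
* The blink model is stereotyped (fixed waveform and leakage); it
  exercises the detection/rejection path, not ICA-style separability.
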