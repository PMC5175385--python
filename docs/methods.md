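# Methods

## Scope

`erdentropy` implements a sensor-level analysis of movement-related
oscillatory power: baseline-relative spectral power on a 1-Hz grid from 8
to 25 Hz, the normalized spectral entropy of that relative-power
spectrum, and the group-level inferential layer (channel-wise two-sample
tests with FDR control, per-bin region-of-interest tests, random-intercept
mixed models pooling tasks, and post-hoc task contrasts). Because no
suitable public recordings exist for this design, the package ships a
synthetic-EEG generator whose spectral content is under exact analytic
control; it is first-class, tested code, not a fixture. Artifact
correction (ICA, muscle-artifact separation) and source localization are
out of scope: synthetic data is artifact-free, and only an optional
amplitude-threshold epoch-rejection utility is provided for imported
recordings.

## Signal model of the generator

Each epoch is an independent realization of a stationary Gaussian
process synthesized in the frequency domain: the rFFT coefficients are
drawn as independent complex normals scaled so that the expected
one-sided PSD equals

    S(ch, f) = noise_scale² / f^β
             + Σ_k bump_k(f) · (1 − d_k·𝟙[movement]) · 𝟙[ch ∈ channels_k]

with β the background slope (default 1) and each oscillatory component k
a Gaussian (center, FWHM) or boxcar bump. The desynchronization depth
d ∈ [0, 1) multiplies the component's *power* during movement (amplitude
by √(1−d)), so d is exactly the expected fractional power decrease at the
component bin — the quantity the percent-change measure estimates. DC and
Nyquist coefficients are zeroed.

Frequency-domain synthesis was chosen over band-pass-filtered time-domain
noise because it makes the expected Hann periodogram available in closed
form (`expected_epoch_power`): on the synthesis grid it is the target PSD
convolved with the periodic-Hann kernel (1/6, 2/3, 1/6); for analysis
windows shorter than the synthesis length (2-s baselines analyzed in 1-s
windows) the full quadratic-form kernel between the two grids is
evaluated. All Monte-Carlo fidelity tests compare against these exact
expectations.

Channels are synthesized independently; a common average reference is
applied as the final step (on by default), which attenuates a component
carried by m of M channels by (1−1/M)² and leaks (1/M²)·ΣS_j into every
other channel. The analytic expectation tracks both effects. Independence
across channels is a deliberate simplification — real EEG is spatially
correlated through volume conduction — so topographic *sharpness* on
synthetic data is optimistic relative to real recordings.

## Group and task presets

The presets encode the two qualitative response types the analysis is
meant to distinguish, with depths calibrated to the pattern, not to any
numeric effect size:

* **young** — deep narrowband decreases on the contralateral sensorimotor
  channels {FC3, C3, CP3}: 10 Hz (FWHM 1.5 Hz, peak PSD 24, d = 0.75) and
  a task-dependent beta response. The overlearned finger sequence drives a
  sharply tuned 20 Hz component (FWHM 1.5, PSD 12, d = 0.65); the pinch
  and whole-hand grip tasks drive a spectrally broader, band-centered
  low-beta response (16.5 Hz, FWHM 6, PSD 12, d = 0.5) and a shallower
  alpha depth (0.55). This spectral-shape difference is what makes the
  young group's 13–19 Hz entropy task-dependent.
* **elderly** — a flat 8–25 Hz boxcar component (PSD 14, d = 0.35) over a
  wide channel set (bilateral sensorimotor, frontal, Cz), identical in
  all tasks.

Both presets share a non-modulated broadband oscillatory floor (flat
8–25 Hz, PSD 2) on every channel and a posterior resting alpha on Oz.
The floor matters: without it, the Gaussian tails of a strong narrowband
component dominate the weak 1/f background several bins away, so a
"narrowband" response would register as broadband in percent change, and
common-average leakage would spread group differences to every channel of
a small montage.

Between-participant variability multiplies all of a participant's depths
by 1 + σ·z (σ = `between_subject_sd`, default 0.15), truncated so depths
stay in [0, 0.95]. Sub-seeds derive deterministically from the master
seed via `SeedSequence(entropy=master, spawn_key=(participant, stream))`,
so any participant can be regenerated independently of generation order
and identical configurations are bit-reproducible.

Default study conditions: two groups of 16 participants (the grip-task
subgroup scale), three tasks, 60 one-second movement epochs per task,
75 two-second baseline segments (~2.5 min of pooled rest), 1000 Hz
sampling.

## Spectral power

Power is the one-sided Hann-taper periodogram in density scaling,
P(f) = 2|X_w(f)|² / (fs·Σw²), restricted to the requested bins, which
must sit on the DFT grid of the window. This convention keeps white noise
flat and unbiased as a density and makes a unit-amplitude sinusoid at a
bin center of a 1-s epoch read 1/3 at any sampling rate. The absolute
convention is immaterial to the analysis — the percent-change ratio
cancels any fixed scale — but it makes absolute PSD checks meaningful.

Baseline segments (2 s) are split into non-overlapping 1-s sub-windows so
the frequency grid matches the movement epochs exactly (the bin-wise
ratio requires identical grids); power is averaged over all sub-windows
of all segments, and a zero anywhere in the average is an error since it
is the denominator of

    Pow_rel = 100 · (Pow_move − Pow_baseline) / Pow_baseline.

Percent change is computed per trial and then averaged across trials per
participant, in that order. Band summaries (default 8–25 Hz, 18 bins) are
arithmetic means over the bins inclusive of both endpoints.

## Spectral entropy

The band-restricted participant-level spectrum is magnitude-normalized,
p_i = |Pow_rel(i)| / Σ|Pow_rel(j)| (signs discarded), and summarized by
H = −(1/ln N)·Σ p_i ln p_i with 0·ln 0 := 0 and N the number of bins in
the band (18 for 8–25 Hz, 7 for 13–19 Hz). H is invariant to bin
permutation and to rescaling of the whole spectrum, and lies in [0, 1]
by construction. An all-zero band raises an error rather than returning
0 or NaN — the distribution is undefined and silence would propagate.
Entropy is computed on the trial-averaged spectrum (one H per participant
and channel); computing per-trial entropies and averaging is a different
estimator (strictly larger under noise, by concavity arguments) and is
not the default.

Estimation note: in bins whose true relative power is ~0, the estimate
fluctuates around zero and its magnitude still contributes mass after the
absolute value, so finite-trial H is biased upward for peaked spectra.
More trials shrink this bias; group comparisons are unaffected as long as
trial counts are comparable across groups.

## Inference

* **Two-sample tests.** Relative power uses the pooled-variance Student
  t-test (df = n₁+n₂−2; Welch available behind a flag is deliberately not
  the default). Entropy uses the Wilcoxon rank-sum with midranks for
  ties: exact two-sided p by complete enumeration of rank assignments
  when n₁+n₂ ≤ 12, else a normal approximation with tie and continuity
  correction.
* **FDR.** Benjamini–Hochberg step-up (via statsmodels), applied across
  channels for topographic maps and across the 18 bins for the ROI
  per-bin test. Adjusted p ≥ raw p and mask = (adjusted < α) are enforced
  structurally.
* **Mixed models.** Per channel, `value ~ group + task` with a
  participant random intercept, fitted by REML (statsmodels MixedLM) for
  estimates; the group-effect p-value comes from a likelihood-ratio test
  of ML refits with and without the group terms (χ², df = number of group
  terms), with a Wald z option. Boundary fits (participant variance → 0)
  are reported with the zero variance component, not hidden; the
  optimizer falls back through L-BFGS/Powell/Nelder–Mead before raising.
* **Post-hoc contrasts.** The group × task interaction model yields
  estimated marginal means per cell from the fixed effects (treatment
  coding; in balanced designs these equal raw cell means). All pairwise
  task differences within a group are tested with standard errors from
  the fixed-effect covariance and a normal reference, FDR-corrected over
  the group's whole contrast family (channels × task pairs). Correcting
  within channel instead would be less conservative; the family-wide
  choice matches how the maps are read.

## Numerical and design choices

* Analysis bands must lie on the 1-Hz grid; off-grid requests are errors
  naming the available resolution rather than silent rounding.
* The toy 16-channel montage is the default for desk-scale runs; the
  63-channel 10-10 preset mirrors the full recording setup. Channel
  coordinates come from the standard 10-05 positions (azimuthal
  projection) and are used only for plotting.
* EDF export uses a built-in 16-bit writer (one data record per epoch);
  import goes through MNE and re-segments continuous data (1-s movement
  epochs, 2-s baseline segments). A round trip is exact to one
  quantization step of the per-channel physical range. Recordings lacking
  the FC3/C3/CP3 ROI import with a warning and ROI-based stages are
  skipped.
* The pipeline writes TSVs with fixed float formatting and a JSON
  manifest (config hash, seed, library versions, output list); identical
  configurations reproduce identical bytes.

## What the tests show — and what they do not

Monte-Carlo tolerances in the test suite are derived from sampling
theory, not tuned: single-taper periodogram means over n epochs carry
~1/√n relative standard error per bin (chi-square with 2 df), so per-bin
5% checks are applied only where channel averaging over iid channels
makes them ≥3σ bounds, and looser bounds elsewhere are stated with their
sigma level. Calibration tests (type-I error of the mixed-model LRT,
null behavior of the FDR maps) and pattern-recovery tests (elderly-like
vs young-like topographies, per-bin profiles, young-only task contrasts)
run on reduced problem sizes: 200 null studies at 5 participants/group,
500 metric-level type-I replicates, and 20 pattern replicates at 15
participants/group with 60 trials — sizes chosen so each check retains
its statistical meaning at desk scale.

Passing these tests shows the estimators and inference behave correctly
under the generator's assumptions (independent channels, stationary
Gaussian oscillations, multiplicative subject variability, no artifacts).
They do not certify performance on real EEG, where spatial correlation,
non-stationarity, artifacts, and non-Gaussian amplitude dynamics are
present, and where preprocessing (artifact rejection, re-referencing
choices) interacts with the spectral estimates.

## Known limitations

* Per-participant trial counts are uniform; the strongly unbalanced
  retention patterns of real studies (60–260 trials) are not emulated.
* The generator's "tasks" differ only in their modulation profiles, not
  in timing structure or behavioral covariates.
* Only a single-taper Hann estimator is provided (no multitaper or
  wavelet time-frequency decompositions, no time-resolved ERD curves).
* The mixed model assumes a single random intercept; random slopes for
  task are not offered.
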