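# Methods

## The measurement being modelled

Non-invasive spinal structural health monitoring drives the spinous process
of T12 with an electromechanical shaker (5 N static contact preload) and
records the acceleration response at skin-mounted sensors over L1–L5.  The
excitation is a train of 10 one-second pulses of randomized frequencies
covering 1–2000 Hz, sampled at 5000 Hz, with the drive amplitude held
constant per frequency; three trains are collected per subject.  Holding the
per-frequency amplitude constant, small, and applied at a fixed site lets a
nonlinear biological system be treated as a *linear equivalent*, which is the
regime in which input–output spectral analysis (FRF, coherence) is valid.

## Excitation model

"Randomized frequencies" is realized as a **random-phase, flat-magnitude
multisine**: each pulse has unit spectral magnitude at every DFT bin of one
pulse inside [f_min, f_max] (1 Hz spacing for a 1 s pulse), zero outside,
with phases drawn uniformly from a seeded generator, then scaled so the
per-pulse RMS equals `force_rms` (default 1 N).  This makes the
per-frequency amplitude-constancy condition exact by construction, and each
pulse is periodic in its own window, so rectangular-window spectral analysis
is leakage-free.  Band-limited noise would be the main alternative reading
of the protocol; the multisine was chosen because it matches the
constant-voltage-per-frequency description and gives exactly flat in-band
spectra.  The 5 N preload has no dynamic role in a linear model and is
carried as metadata only.

One excitation program is generated per trial and shared by all subjects
(the shaker drive is the same program for every test), so identical models
produce identical noiseless responses — which is also what makes the
zero-variability twin-identity property exact.

## Spine model

The spine is a **lumped-parameter chain**: six point masses (T12, L1…L5)
joined by five spring–damper links, with T12 additionally tied to ground
through a spring–damper (the torso/rib-cage support).  The measured
acceleration at sensor s for unit force at T12 is

    H_s(f) = -(2*pi*f)^2 [ (K + i*2*pi*f*C - (2*pi*f)^2 M)^(-1) ]_{s,0}

multiplied by a per-sensor soft-tissue attenuation gain in (0, 1], plus
white Gaussian measurement noise.  Responses are synthesized pulse-by-pulse
in the frequency domain (each pulse is periodic, so this is the exact
steady-state response, with no transient leakage); linearity, superposition
and seeded determinism are exact by construction and asserted in tests.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| masses | T12 0.25 kg, L1–L5 0.15 kg | vertebra + immediately coupled tissue; the drive node also carries the indenter/load-cell contact mass |
| link stiffness | 8.0e6 N/m | places the internal chain modes at ~600–2200 Hz |
| ground stiffness | 1.6e6 N/m | a support distinctly softer than the links puts the fundamental (whole chain rocking on its support) at ≈178 Hz and makes it the dominant FRF peak at every sensor |
| damping | stiffness-proportional, c = 3.5e-5·k | ≈2% of critical for the fundamental; modal damping grows with mode frequency, so the fundamental peak is several 1-Hz bins wide (it survives median smoothing) while higher modes are progressively flattened |
| sensor attenuation | 1.0, 0.85, 0.70, 0.55, 0.007 | monotone decline with distance from the drive point, steep enough that attenuation (not biological variability) dominates the distance profile of twin FRF differences; the L5 value reflects the steep drop in transmitted signal at the most distal level |
| noise RMS | 0.6 m/s² | with the attenuation profile above, per-sensor mean coherence comes out ≈0.88/0.86/0.81/0.69 for L1–L4 and ≈0.10 for L5, reproducing the observed pattern of adequate proximal sensors and an inadequate most-distal sensor that QC must exclude |

The attenuation/noise pair was calibrated once against the target coherence
profile and then frozen; it is a property of the simulated study conditions,
not a per-experiment tuning knob.  The soft ground link and the
heavier drive mass were likewise chosen once so that the FRF's global
maximum sits on the *same* (fundamental) mode at all four proximal sensors
with a comfortable margin, even under between-pair parameter jitter —
without this, the argmax occasionally hops between modes at the
drive-adjacent sensor, which manifests as heavy-tailed PEAK differences.
With these defaults five undamped resonances lie inside the excited band
(178, 608, 1111, 1595, 1986 Hz), verified against direct generalized
eigenanalysis of (K, M).

### Alterations and cohorts

A structural alteration multiplies the node mass at one level and the
stiffness of the link on its T12 side (factors of 1 are the identity); the
default — stiffness × 0.5 at L1 — emulates a gross finding such as the
compression fracture at L1 in the study population.  Halving that link
lowers the fundamental by ≈8–10 Hz.

The twin-cohort generator draws, per pair, a base model by perturbing the
defaults with **between-pair biological variability** (lognormal,
CV = 10%), then gives each twin an independent **within-pair perturbation**
(CV = 2%; monozygotic twins are near-identical but not identical).  In
discordant pairs the second twin receives the alteration.  Per subject,
three trials are simulated (fresh noise per trial).  The default cohort is
5 concordant + 5 discordant pairs, matching the enrolled design.  Seeds are
split (numpy `SeedSequence`) between model perturbation, excitation phases
and measurement noise, so every layer is independently reproducible.

## Spectral estimation

One pulse is one estimation segment (no overlap; the protocol averages
pulses, not sliding windows).  Auto-spectra of force and acceleration and
the complex cross-spectra are averaged over the 10 pulses with a rectangular
window (leakage-free for the periodic multisine; a Hann option exists for
non-ideal inputs) and density scaling, and the grid is restricted to the
excited band.  The implementation is a direct vectorized periodogram
average; tests verify exact agreement with `scipy.signal.welch`/`csd` for
both windows.

* **FRF**: the primary convention is the **power ratio**
  P_aa(f)/P_ff(f), which behaves like |H(f)|²; a magnitude (|H|-like)
  convention — its square root — is available behind a flag.  PEAK is
  invariant to the choice (a strictly monotone transform cannot move an
  argmax); AUC and RMS are not, so reports should state the convention.
* **Coherence**: γ²(f) = |P̄_fa|² / (P̄_ff · P̄_aa) from the *averaged*
  spectra.  With one segment γ² ≡ 1 and is meaningless, so fewer than two
  pulses is an error.  Values are clipped to [0, 1] only within 1e-9
  numerical slack; anything worse raises.  The per-sensor mean coherence is
  taken over the excited band only (out-of-band bins carry no input power).
* **Smoothing**: a running median (default 5 bins; no kernel size is
  prescribed by the protocol, and 5 bins removes single-bin noise spikes
  without displacing the ≈7-bin-wide fundamental).  Edges shrink the window
  symmetrically, so endpoints are their own medians — no padding values are
  invented.  Kernel 1 is the identity.

## Outcomes, QC, aggregation

From each sensor's smoothed FRF: **PEAK** (frequency of the global maximum;
ties break to the lowest frequency), **AUC** (trapezoidal integral over the
band), **RMS** (root mean square across bins — no formula is prescribed for
RMS beyond being computed from the smoothed FRF, so the same curve feeds all
three outcomes).  A sensor is retained iff its mean coherence ≥ 0.5
(configurable; chosen midway between the observed adequate ≥0.71 and
inadequate 0.15 levels).  A subject's three trials are averaged per sensor;
a sensor failing QC in *any* trial is dropped for that subject — stricter
than per-trial exclusion, chosen for reproducibility.

## Twin comparison

Within a pair, the signed difference of each trial-averaged outcome is
computed per sensor (lower subject id minus higher — fixed so results do not
depend on argument order; swapping twins negates every difference and leaves
every p-value unchanged).  For each group (concordant / discordant) ×
outcome × sensor (L1–L4), H0: mean difference = 0 is tested two-sided.

* **paired-t** (default): one-sample t on the pair differences.  This is the
  test whose results the per-cell report mirrors.
* **ANCOVA**: OLS of the differences on an intercept plus centred pair-level
  covariates (default pair-mean BMI, the anthropometric factor most
  plausibly confounding a between-twin comparison), testing the intercept.

Zero-variance difference vectors report t = 0, p = 1 with a warning rather
than failing.  P-values are reported uncorrected, matching per-cell
reporting; a Bonferroni option exists but is off by default.  Group tests
require ≥ 2 pairs.

## What the synthetic cohorts show — and what they do not

With the defaults, the pipeline reproduces the expected pattern: the
discordant group's PEAK differences are significant at all four retained
sensors in essentially every replicate, concordant-group rejections sit near
the nominal 5% level, the most distal sensor is excluded by coherence QC,
and the mean |FRF difference| between twins declines monotonically from L1
to L4.

The generator emulates a *linear* chain with scalar attenuation, white
Gaussian noise, and multiplicative lognormal biological variability.  It
does not model: tissue nonlinearity, breathing or posture drift between
trials, sensor reattachment variability, frequency-dependent soft-tissue
filtering, distinct structural pathologies with distinct FRF "fingerprints",
or any coupling between BMI and the mechanical parameters.  Passing tests
therefore demonstrate that the estimation and inference machinery recovers
known structure from signals *of this class* — they are not evidence about
in-vivo effect sizes, and the simulated mean differences are not comparable
in magnitude to the human data.

## Numerical choices and degenerate inputs

Monte-Carlo sizes: detection power uses 50 replicates of 5+5-pair cohorts
(30 in the acceptance script) and false-positive control 200 concordant-only
replicates (100 in the script); these sizes bound the binomial standard
error on the reported rates at a few percent.  The frequency grid is the DFT
grid of one pulse (1 Hz for 1 s pulses); PEAK is therefore quantized to the
grid, and resonance-recovery checks are asserted to within one bin.
Configuration errors (Nyquist violations, degenerate bands, even kernels,
non-positive physical parameters) raise typed exceptions; estimation refuses
zero in-band input power naming the offending bin, and cohort analysis
raises when no sensor passes QC or no sensors overlap within a pair.

## Known limitations

* The chain is a deliberately coarse stand-in; its parameters are set for
  qualitative fidelity (resonances in-band, coherence profile, attenuation
  ordering), not fitted to human FRFs.
* PEAK's robustness here relies on one dominant resonance; structures whose
  FRF maxima sit on different modes at different sensors give heavy-tailed
  PEAK differences, and the paired t-test loses power (AUC/RMS are less
  affected).  This mirrors the real caveat that small or mode-localized
  alterations may escape PEAK-based detection.
* The ANCOVA covariate set is minimal (pair-mean BMI) and the simulated BMI
  is not linked to mechanics, so the ANCOVA path is exercised statistically
  rather than biologically.
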