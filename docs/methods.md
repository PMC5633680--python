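# Methods

`physioeval` evaluates how regressing out low-frequency physiological
signals — end-tidal CO2 (PETCO2), respiration volume per time (RVT), and
cardiac-rate variation (CRV) — changes the quality of resting-state fMRI
measures. Because suitable public datasets with simultaneous CO2, belt and
pulse recordings are scarce, the package ships a synthetic-study generator
with full ground truth; every downstream claim is validated against that
truth rather than against irreproducible acquisitions.

## The synthetic study

The generator emulates a test–retest design: `n_subjects = 8`, `n_runs = 2`,
8-minute runs sampled either at TR = 2 s (240 frames, "long TR") or
TR = 0.323 s (1,486 frames, "short TR"), plus a third condition obtained by
temporally decimating the short-TR runs to the 2-s grid. The brain is a
regular voxel grid (default 20×20×10 voxels of 3.44×3.44×4.6 mm; the shipped
analyses use 14×14×7 for speed) whose interior box is gray matter,
partitioned into seven axis-aligned block networks by recursive bisection;
the one-voxel rim is non-gray-matter tissue, which supplies true negatives
for specificity and a physiology-free reference population for the mixture
null.

Each gray-matter voxel's signal is the sum of

1. **a network component** — one band-limited (0.01–0.08 Hz) random signal
   per network, scaled by a subject-specific coupling (N(1, 0.15), persistent
   across runs) and a per-voxel weight. The realized series is normalized to
   exactly unit variance so that run-to-run (test–retest) variability comes
   only from the stated sources: fresh noise and fresh physiology;
2. **a physiological component** — the three regressors convolved with
   Gaussian impulse responses `h(t) = A·exp(−(t−μ)²/2σ²)` truncated at 40 s.
   Latency and width are subject-level draws (μ ~ N(10 s, 3 s),
   σ ~ N(5 s, 1 s)); amplitudes carry ±20% voxel-level jitter, a mild
   subject-level factor, and a per-network gain (0.6 for the motor analogue,
   network 1, up to 1.6 for the default-mode analogue, network 4), emulating
   the reported regional heterogeneity of physiological effects. PETCO2
   dominates the mix (weights 1.0 : 0.55 : 0.55 in amplitude);
3. **a time-locked quasi-periodic component** at the cardiac and respiratory
   phases (the part RETROICOR targets), scaled as 0.5 × the noise SD so that
   noise-free limits stay exact;
4. **white measurement noise** (SD 1 in baseline-100 units).

**Contamination calibration.** `contamination_scale` (default 0.15,
motivated by reports that up to ~15% of resting-state BOLD variance is
explained by end-tidal CO2) sets the gray-matter-average fraction of signal
variance contributed by the physiological terms. The scale is calibrated
exactly at each subject's *first* run and reused for the second: later
sessions then vary around the target because each run draws its own
physiological "state" (a lognormal scale with unit mean square on the
modulation depths of CO2, breathing and heart rate). This is deliberate —
between-session changes in physiological power are precisely what makes
physiological correction matter for test–retest reproducibility; normalizing
every run to the same share would erase the effect being studied.

**Waveforms.** Recordings start 6 s before the first frame (as physiological
monitoring does in practice), so every frame is covered by complete breaths
and beats. The pulse waveform is a raised-cosine train whose beat times
integrate an interval series (slow drift + respiratory sinus arrhythmia +
beat-scale variability); the belt and CO2 traces are phase-integrated
oscillators (period modulation never produces phase jumps), with
breath-to-breath variability in depth and end-tidal value. RVT and PETCO2
are breath-by-breath quantities *defined* by waveform geometry (peak minus
adjacent troughs over the breath period; per-breath maximum of the tracing),
so the ground truth is computed from the exact extrema of the noise-free
waveform on a 4× oversampled grid, and the frame-grid truth interpolates the
per-breath values. CRV truth is the windowed mean of the true inter-beat
intervals.

**What the generator does not emulate:** k-space/EPI physics, motion and
susceptibility artifacts, slice timing, spatially structured (vascular-tree)
noise, neural–physiological interactions, and between-subject anatomical
variability. Passing tests therefore demonstrate the *machinery* —
extraction, fitting, regression, metrics, statistics — not robustness to
real-world artifacts.

## Regressor extraction

Events are local extrema with a minimum separation, resolved greedily by
amplitude (scipy's peak finder) with a prominence floor relative to the
signal range (4% for the belt, where depth legitimately varies several-fold).
Extremum times and values are refined by a least-squares parabola over ±3
samples, which removes the positive bias of taking the noisiest sample.
CRV averages inter-beat intervals whose midpoints fall in a *centered* 4-s
window (centered for zero phase bias; the window is configurable); RVT uses
the peak minus the mean of both adjacent troughs and the centered peak
spacing, which cancels first-order drift in depth and period; breaths missing
a flanking trough (run edges) are dropped. Breath-wise series are linearly
interpolated onto frame times; frames outside the defined span take the
nearest defined value. Measured recovery on study waveforms: CRV max error
~0.03 s (exact on constant-rate input), RVT relative L2 error under 1%,
PETCO2 max error under 0.1 mmHg.

RETROICOR builds sin/cos of cardiac phase (linear between beats) and
respiratory phase (histogram-equalized amplitude with slope sign) for
harmonics 1..order (default 2 → 8 columns); the time-locked stage is
regressed out before response fitting, matching the standard ordering.

## Response model and correction

Responses to the three signals are estimated *simultaneously*: the design is
[intercept, linear drift, conv(PETCO2), conv(RVT), conv(CRV)], with each
convolution's Gaussian parameters searched on a grid (μ ∈ [0, 30] s, σ ∈
[1, 15] s, 1-s steps by default; the replicated-study analyses use 2-s steps).
The full three-signal grid is combinatorial, so the implementation uses
coordinate descent over signals — each sweep re-selects the best candidate
per voxel conditioned on the other two signals' current columns — iterated to
convergence (max 5 cycles). Voxels sharing candidate indices are processed as
single matrix-algebra batches, which keeps a whole-run fit in the seconds
range. Amplitudes come from least squares at the optimum; R² is reported
against the intercept+drift baseline.

An identifiability note that matters for interpretation: for smooth
regressors the convolution kernel acts largely through its DC gain, which is
proportional to σ, so the kernel-height amplitude A and the width σ are
strongly ridge-correlated. The *magnitude of the fitted response component*
(its temporal SD, in signal units) is the identifiable and physiologically
meaningful amplitude, and it is what the recovery analyses score (within 10%
of truth); latency and width are scored within one grid step. At 15%
per-signal contamination the pooled recovery rate is ~90–93%, close to the
Cramér–Rao limit for this SNR.

Correction regresses the convolved regressors of the chosen strategy
(8 combinations from "Base" = none to "All" = three signals) out of each
voxel, *without* orthogonalizing the signals against each other, and re-adds
the voxel mean. Residuals are exactly orthogonal to the included columns,
per-voxel variance is non-increasing, and nested strategies dominate:
residual variance under "All" is never above any single-signal strategy.

## Preprocessing

* Band-pass (0.01–0.1 Hz) is a zero-phase frequency-domain mask (Fourier
  coefficients outside the band zeroed), the convention of the standard
  resting-state toolchains; it is exactly idempotent, which a recursive
  filter of practical order is not when signal power sits at the band edges.
* Spatial smoothing is per-frame Gaussian (FWHM 10 mm by default) with masked
  normalization so gray matter is not diluted by the rim.
* Decimation to a coarser TR applies an anti-alias low-pass at the target
  Nyquist (toggleable, to reproduce naive decimation) and then samples at
  k·TR_target by linear interpolation, since 2.0/0.323 is not an integer
  ratio; 1,486 frames at 0.323 s become exactly 240 frames at 2 s.

## Measures

* **ALFF** is the mean one-sided Fourier amplitude in 0.01–0.1 Hz, computed
  on temporally unfiltered data (the pipeline structurally never feeds
  band-passed data into it). The mean (not the sum) over band bins keeps
  values comparable across TR conditions with different bin counts; the sum
  is available via an argument. Normalized ALFF subtracts the global in-mask
  mean and divides by the SD.
* **ReHo** is Kendall's W between each voxel and its 3×3×3 neighborhood
  restricted to the mask (voxels with fewer than 7 contributing series are
  missing), with the standard tie correction, on band-passed data.
* **Seed connectivity**: z = atanh(r)·√(n−3) against the mean signal of a
  4-mm-radius seed; |r| is capped just below 1. Maps are re-standardized
  against a fitted Gaussian(null) + Gamma(alternative) mixture
  ("mixture-model correction") before thresholding at corrected z > 0.5
  (strict). The EM fit initializes from median/MAD, updates the Gamma by
  weighted moment matching on the positive axis, and falls back to the
  robust null on non-convergence. The null is fitted over the whole in-brain
  map — the physiology-free rim anchors it — which is what makes globally
  shared physiological correlation visible to the separability index instead
  of being absorbed into the null mean.

## Quality battery and statistics

ICC is the one-way random-effects form (MS_b − MS_w)/(MS_b + (k−1)MS_w) with
k = 2 runs, exactly as printed in the reliability literature, with the usual
five categories (poor < 0.2 … excellent ≥ 0.8; negative values are "poor").
For regional summaries, ALFF/ReHo enter ICC as the network-mean value; for
connectivity, ICC is computed voxel-wise within the seed network and
averaged (the common "ICC map" practice), using the raw Fisher z values —
per-run mixture re-standardization adds run-specific scale noise that is a
property of the correction step, not of the connectivity values whose
reproducibility is being measured. Dice compares thresholded corrected maps
between runs (two empty maps count as agreement, with a warning). The
separability index is (WNC − BNC)/(WNC + BNC) on corrected z; sensitivity and
specificity are computed against the atlas with specificity restricted to
gray matter. Strategy and TR-condition effects are compared with a
two-factor within-subject ANOVA (statsmodels' repeated-measures ANOVA;
df = (7, 49) for Method and (2, 14) for TR at n = 8; no sphericity
correction by default) followed by uncorrected paired t-tests (a Holm column
is available).

## Problem sizes and replication

The shipped analyses and the acceptance script run on a 14×14×7 grid
(720 gray-matter voxels), 8 subjects × 2 runs, with 2-s search steps for the
response grid — sizes chosen so a full replicated-study comparison (10
studies) completes in minutes on one core while leaving every stage's
behaviour unchanged. The directional comparison uses the long-TR condition
and the Base vs PETCO2 strategies; the sampling-rate comparison uses the
short-TR runs and their decimated versions with one run per subject (the
quantities compared there do not need test–retest pairs).

## Known limitations

* Block-shaped networks make atlas overlap measures cleaner than real
  anatomy would; sensitivity in particular saturates near 1.
* The separability index is numerically high (~0.9) because between-network
  voxels carry no true shared neural signal; only its *changes* across
  strategies are meaningful in the synthetic setting.
* The mixture alternative is a single positive Gamma; negative tails are
  treated as null, consistent with thresholding only positive connectivity.
* Coordinate descent approximates the joint grid search; with three signals
  it can in principle stop in a local optimum, though sweeps conditioned on
  the other signals' best columns make this rare in practice.
* ICC at n = 8 subjects is intrinsically noisy (sampling SD ~0.3); the
  directional analyses therefore compare medians across replicated studies
  rather than single-study values.
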