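# Methods

This note records the models the package implements, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Phase-domain route (DBI)

### Model

Each oscillator pair (breathing vs cardiac-from-ECG, breathing vs
cardiac-from-perfusion, cardiac-from-ECG vs cardiac-from-perfusion) is
modelled by coupled Langevin phase equations

    dφᵢ/dt = Σₙ cᵢ,ₙ Φₙ(φ₁, φ₂) + εᵢ(t)

where the basis {1} ∪ {sin, cos}(n₁φ₁ + n₂φ₂) runs over de-duplicated index
pairs with |n₁|, |n₂| ≤ N (of (n₁,n₂) and (−n₁,−n₂) only one is kept — the
sign folds into the coefficients). At the default N = 2 this gives 25 terms
per equation. ε is white with a 2×2 intensity matrix E shared between the
two equations.

### Inference

Per window, targets are midpoint finite differences Δφ/Δt and design rows
evaluate the basis at midpoint phases. The window posterior is obtained by
alternating (a) noise re-estimation `E = (dt/T) RᵀR` from current residuals
and (b) the Gaussian posterior update of the stacked coefficients with
precision `Ξ_prior + dt·E⁻¹ ⊗ XᵀX`, iterated to a relative coefficient
change below 1e-6 (cap 100 iterations; non-convergence is flagged on the
result, not raised). The first window uses a flat prior (zero precision),
which makes the first update ordinary least squares per equation. Between
windows the posterior becomes the next prior with covariance inflated by
`p_w² diag(mean²)`, p_w = 0.2.

The update deliberately omits the Stratonovich midpoint Jacobian correction
term of the full stochastic-inference framework: the correction is of order
dt·E and does not affect the noise-free fixed point, while omitting it
preserves the exact identities the test-suite checks (zero targets → zero
posterior; invariance of the posterior under joint rescaling of dt). The
parameter-recovery, monotonicity and null-calibration properties were all
verified without it.

Directional strengths are Euclidean norms (the square root; a `squared`
switch exposes the plain sum of squares) over all coefficients of one
equation whose basis term carries the *other* oscillator's index — i.e. the
overall influence, direct and indirect. The directionality index
d = (s₁→₂ − s₂→₁)/(s₁→₂ + s₂→₁) is reported as missing (None/NaN), not 0,
when both strengths vanish.

### Surrogate validation

Thresholds are per-pair, per-direction medians over all windows of an
inter-subject surrogate ensemble (default 100 surrogates; with S subjects
there are S(S−1)(S−2) valid ordered triplets, sampled without replacement).
Because ridge extraction is a per-channel operation, the pipeline reuses
each subject's ridges when assembling surrogates — exactly equivalent to
re-extracting from recombined recordings. By construction the surrogate
median is the 50th percentile of the no-coupling distribution, so roughly
half of null windows pass per direction; directionality statistics use only
windows where *both* directions pass, which suppresses the null much more
strongly.

### A note on the heart–pulse pair

The two cardiac ridges (from ECG and from perfusion) track the *same*
oscillator, so their phases are nearly equal and the Fourier design becomes
close to collinear; the fitted cross-coefficients — and hence the strengths
s — blow up to values orders of magnitude above those of the lungs–heart
pair. This is a property of applying a bivariate phase model to two
measurements of one source, and shows up in real recordings of this kind as
well; interpret heart–pulse strengths only relative to each other.

## Preprocessing

Order fixed as resample → detrend → band-pass → CWT → ridge:

* resampling: polyphase anti-aliased decimation, 250 → 50 Hz;
* detrending: least-squares cubic (order 3) removal;
* band-pass: 4th-order Butterworth applied forward–backward (zero phase),
  cardiac band (0.6, 2.0) Hz, respiratory (0.145, 0.6) Hz;
* CWT: Morlet mother with central frequency f₀ = 1 *including* the
  admissibility correction term exp(−(2π)²/2), evaluated by FFT convolution
  on a logarithmic grid of 128 voices/octave (bin ratio 2^(1/128));
* ridge: two-pass dynamic programming. Pass one maximizes summed normalized
  amplitude with a quadratic penalty on the rate of (log-)frequency change;
  it fixes the component's mean log-frequency and mean rate, and pass two
  adds the quadratic deviation penalty around those references. Both
  penalty weights default to 1. Sub-bin frequency comes from parabolic
  interpolation of amplitude across adjacent bins; phase is the unwrapped
  argument of the complex coefficient along the ridge.

Samples within three wavelet standard deviations of either record edge are
flagged as inside the cone of influence; analysis windows overlapping
flagged samples by more than 50% carry a `boundary` flag downstream. The
phase convention (zero crossing) is arbitrary — only phase differences and
2π-periodic functions of phase are consumed.

The cardiac phase is taken from a wavelet ridge for the ECG as well as for
the perfusion signal (rather than from R-peak marking); this keeps the two
cardiac phase estimates methodologically identical.

## Spectral-domain route (DTF)

60-s non-overlapping windows at the native 250 Hz; each window is demeaned
and z-scored per channel (the channels carry incommensurate units), then
fitted by the Vieira–Morf multichannel lattice: forward/backward
prediction-error covariances updated through reflection matrices normalized
by the geometric mean (Cholesky factors) of the two error covariances. Two
numerical safeguards matter for strongly oversampled, nearly deterministic
windows: the normalized partial-correlation matrix is clipped to the closed
unit ball via its SVD, and Cholesky factorizations add an escalating
trace-scaled jitter. The fit warns and flags (never refuses) when
N·D < 100 × (M·D²).

The spectral transfer H(f) = B̄(f)⁻¹ is evaluated on the grid 0…2 Hz at
spacing 1/60 Hz; DTF is the row-normalized squared magnitude, so every sink
row sums to 1 by construction.

### Significance

Default: an asymptotic test of H₀: DTF_{j→i}(f) = 0. MVAR coefficient
estimates fluctuate as vec(Â) ~ N(vec(A), Γ⁻¹ ⊗ Σₑ / N) with Γ the lag
covariance; through dH = H dB̄ H the entry H_ij is asymptotically a complex
Gaussian whose 2×2 real covariance factorizes into a sink factor (row i of
H against Σₑ) and a source factor (column j against Γ⁻¹). |H_ij|² is then a
two-term weighted χ², whose tail is evaluated by common-random-number Monte
Carlo (≥ 2000 draws). Type-I error on independent white noise is calibrated
(verified ≤ α + 2√(α/50) per pair over 50 windows).

Time-shift surrogates (independent circular rotation ≥ 10 s per channel,
refit, recompute) are available via `method="timeshift"` but are *not* the
default: a circular shift of a narrowband signal is a linear filter of the
original, so such surrogates do not destroy linear cross-predictability
between oscillatory channels and the test loses essentially all power on
exactly the signal class this package targets.

Band averaging uses the half-open interval (0.05, 2] Hz and only bins whose
significance mask is true; a pair with no significant in-band bin is missing
(NaN), never zero, and missing pairs contribute nothing to group medians.
Trailing samples beyond the last full window are discarded.

## Group statistics

One-tailed Wilcoxon rank-sum tests, both alternatives reported per row
(H1a: control median greater; H1b: the reverse). For n_a + n_b ≤ 12 the
p-value is exact by full enumeration of rank assignments on midranks
(correct under ties); above that, the normal approximation with tie
correction. Pearson's χ² uses no continuity correction. Quartiles use
linear interpolation. Window-level pooling across subjects is the default
aggregation (matching how the connectivity tables are built); per-subject
medians are available via `level="subject"` — window-level pooling inflates
the effective n, which is a known limitation of this convention, not a bug.
No multiple-testing correction is applied by default across the 18
comparisons; a Benjamini–Hochberg option exists (`fdr=True`).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical regime the analysis assumes, with
cohort-level defaults chosen once: control heart rate 70.7 ± 7.2 bpm and
breathing rate 0.25 ± 0.06 Hz; the diabetic analog 74.1 ± 9.5 bpm and
0.28 ± 0.03 Hz; breathing→heart phase coupling 0.5 rad/s (control) vs 0.1
(analog) on sin(φ_breathing); a weak group-independent cardio-ventilatory
counter-coupling heart→breathing of 0.05 rad/s (an order of magnitude below
the forward drive — without it the reverse direction is a bare
estimation-noise floor, and tiny leakages of the forward effect through the
shared cardiac phase can masquerade as group differences); phase noise
0.1 rad/√s; 5-min records at 250 Hz. Euler–Maruyama integration at the acquisition step (1/250 s) with a
hard error if any phase increment reaches π/4.

Waveforms are phase-driven templates:

* **ECG** — a periodic von-Mises spike kernel exp(κ(cos φ_c − 1)), κ = 20.
  Respiratory presence in the channel (15% beat-amplitude modulation plus a
  respiratory baseline component at the default coupling) *scales with the
  breathing→heart coupling parameter*: the model treats the linear
  respiratory signature of the ECG as carried by the same autonomic pathway
  as the phase modulation. This is a deliberate simplification — in real
  recordings part of that signature is mechanical (electrode motion,
  thoracic impedance) and would not shrink with autonomic decline.
* **breathing** — cos φ_r plus a 5% cardiogenic oscillation (the mechanical
  cardiac artifact documented for chest-strap/impedance respiration
  signals), independent of the coupling.
* **perfusion** — a cardiac/respiratory cosine mixture with the cardiac
  share of band power set by `cardiac_power_fraction` (default 0.91, the
  cardiac share typical of laser-Doppler spectra), plus 1/f noise scaled by
  `noise_level` (default 0.2).
* all channels carry broadband sensor noise (5% of channel amplitude at the
  default noise level). Noise-free sinusoids are both physically
  unrealistic and numerically degenerate for MVAR estimation.

The generator makes no attempt at real ECG morphology (P/QRS/T), LDF
speckle statistics, device transfer functions, or the slower myogenic /
sympathetic / endothelial vasomotion bands (which a 5-min record cannot
resolve anyway). Consequently, passing tests demonstrate that the pipeline
recovers known couplings under the assumed model class and realistic rates,
bands and noise levels — not that it is robust to arrhythmias, motion
artifacts, or non-stationary rate drifts beyond the modelled phase
diffusion.

VAR ground truth uses exact stable recursions with Gaussian innovations and
a burn-in of 10·M samples. Inter-subject surrogates assemble the three
channels from three distinct subjects, sampling unique triplets without
replacement.

## Problem sizes used by the validation suite

The shipped test-suite and acceptance script use 5-min records, 10+10
subject cohorts, 100 DBI surrogates, 50-seed repetition for stochastic
properties, and n = 50,000 for the DTF fit-vs-truth comparison; these sizes
were chosen to make every stochastic criterion stable under reseeding on a
single CPU.

## Known limitations

* The bivariate phase model applied to two measurements of one oscillator
  (heart–pulse) yields collinearity-inflated strengths (see above).
* The DBI noise model assumes white phase noise; colored physiological
  variability (e.g. very-low-frequency rate drift) is absorbed into the
  window-to-window parameter diffusion rather than modelled.
* DTF is a linear measure: purely phase-modulatory (FM) coupling is visible
  to it only through weak rectification effects, which is why the generator
  gives the autonomic pathway an explicit linear component.
* In the linear route the forward and reverse lungs–heart strengths are not
  independent: the respiratory content the autonomic pathway imprints on the
  ECG channel is what makes the forward coupling linearly visible, and the
  same content weakly (but genuinely) improves prediction of the noisy
  breathing channel. The reverse ssDTF therefore inherits a small
  dependence on the forward coupling, which large pooled window counts
  resolve as a significant group difference. Only the phase-domain route
  yields a cleanly one-sided directional pattern; the spectral route's
  reverse direction should be interpreted with this in mind.
* The asymptotic DTF test treats the fitted coefficients' Gaussian
  fluctuation at the estimate as the H₀ fluctuation (standard delta-method
  practice); at extreme oversampling its effective α on strongly coherent
  narrowband *independent* channels can exceed the nominal level, which is
  the same caveat the estimator-variance approach carries in the
  literature.
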