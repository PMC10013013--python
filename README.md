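# cardionet

Directed-connectivity analysis of the cardio-respiratory–microvascular
oscillator network, for physiologists and biomedical-signal researchers who
record ECG, respiratory effort and laser-Doppler skin perfusion concurrently
(250 Hz, ~5 min) and want to quantify *who drives whom* among the heart,
lungs and microcirculation — e.g. to detect the weakening of respiratory
sinus arrhythmia in conditions such as type 1 diabetes.

Two complementary routes are implemented end to end:

**Nonlinear bivariate route — dynamical Bayesian inference (DBI).**
Each pair of oscillators is modelled by coupled stochastic phase equations

```
dφ₁/dt = ω₁ + q₁(φ₁, φ₂) + ε₁(t),      q₁ = Σₙ c₁,ₙ Φₙ(φ₁, φ₂)
```

with a Fourier basis Φₙ on the torus up to order N = 2 and white phase noise
ε. Instantaneous phases come from adaptive ridge curves of a Morlet wavelet
transform (f₀ = 1, 128 voices/octave) after downsampling to 50 Hz, cubic
detrending and zero-phase band-passing in the cardiac (0.6, 2.0) Hz or
respiratory (0.145, 0.6) Hz band. Coefficients are inferred in 25-s windows
(50% overlap, 23 windows per 5-min record) with sequential prior propagation
(diffusion constant p_w = 0.2). The Euclidean norm of the cross-oscillator
coefficients gives directional strengths s₁→₂ and s₂→₁, validated against
median thresholds from 100 inter-subject surrogates, and their asymmetry

```
d₁,₂ = (s₁→₂ − s₂→₁) / (s₁→₂ + s₂→₁) ∈ [−1, 1]
```

is the directionality index.

**Linear multivariate route — directed transfer function (DTF).**
Non-overlapping 60-s windows of the three channels are fitted by an MVAR
model `X(t) = Σ_τ A(τ) X(t−τ) + E(t)` (order M = 7, D = 3, Vieira–Morf
lattice estimation). With `B̄(f) = I − Σ_τ A(τ)e^(−i2πfτΔ)` and
`H(f) = B̄(f)⁻¹`, the DTF

```
DTF_{j→i}(f) = |H_ij(f)|² / Σ_k |H_ik(f)|²
```

measures the directed (direct + cascaded) influence of channel j on channel
i; per-frequency significance is assessed against the asymptotic estimator
distribution under H₀: DTF = 0, and significant values (ssDTF) are averaged
over (0.05, 2] Hz and summarized by the same directionality index.

A synthetic-data generator produces ground-truth coupled recordings (phase
oscillators with known coupling, phase-driven ECG/breathing/perfusion
waveforms, VAR processes, inter-subject surrogates), so every stage is
testable without clinical data. Group comparisons use one-tailed Wilcoxon
rank-sum tests (exact by enumeration for small samples) and Pearson's χ².

## Worked example

```python
import statistics
from cardionet.synthetic import simulate_physio_recording
from cardionet.preprocess import extract_component_phase
from cardionet.dbi import run_dbi

rec = simulate_physio_recording(heart_rate=70.7, breathing_rate=0.25,
                                coupling_breathing_to_heart=0.5, seed=7)
cardiac = extract_component_phase(rec.channel("ecg"), 250.0, (0.6, 2.0))
resp = extract_component_phase(rec.channel("breathing"), 250.0, (0.145, 0.6))
results = run_dbi(resp, cardiac)   # oscillator 1 = breathing, 2 = heart
print(f"windows analysed:            {len(results)}")
print(f"median s_breathing->heart:   {statistics.median(w.s_1to2 for w in results):.3f}")
print(f"median s_heart->breathing:   {statistics.median(w.s_2to1 for w in results):.3f}")
print(f"median directionality d:     {statistics.median(w.d for w in results):.3f}")
```

prints

```
windows analysed:            23
median s_breathing->heart:   0.211
median s_heart->breathing:   0.000
median directionality d:     0.996
```

The 5-min record yields 23 overlapping 25-s windows. The inferred
breathing→heart strength is large (the ground-truth coupling of 0.5 rad/s,
attenuated by ridge smoothing of the cardiac phase), the reverse strength
sits at the noise floor, and d ≈ +1 says breathing drives the heart —
respiratory sinus arrhythmia recovered from the waveforms alone.

The full cohort pipeline (simulate → phases → DBI + DTF → group tables)
runs from the shell:

```bash
cardionet run-all --seed 1 --out runs/demo
cardionet compare runs/demo --method dbi
```

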