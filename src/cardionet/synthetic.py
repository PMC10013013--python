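"""Ground-truth synthetic signals for validating the connectivity pipeline.

Three generator families mirror the statistical models the analysis assumes:

* coupled stochastic phase oscillators (the model class inferred by
  :mod:`cardionet.dbi`), integrated by Euler-Maruyama;
* phase-driven physiological waveforms — spike-like ECG, near-sinusoidal
  chest-effort breathing, and a perfusion signal dominated by the cardiac
  component with a respiratory component plus 1/f noise;
* stable vector-autoregressive processes with known coefficient matrices
  (the model class fitted by :mod:`cardionet.dtf`).

Inter-subject surrogates — pseudo-recordings whose three channels come from
three different subjects — destroy genuine within-subject coupling while
preserving marginal dynamics, and set the acceptance thresholds of the DBI
analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from cardionet.recording import CHANNELS, MultiChannelRecording

# Nominal physiological bands (Hz) of the perfusion spectrum; the two used here.
CARDIAC_BAND = (0.6, 2.0)
RESPIRATORY_BAND = (0.145, 0.6)


@dataclass
class OscillatorSpec:
    """One phase oscillator of a coupled pair.

    The phase obeys ``dphi_self/dt = 2*pi*natural_frequency + q(phi_self,
    phi_other) + noise`` where the coupling function ``q`` is a real Fourier
    series over the torus: ``coupling_coeffs`` maps ``(n_self, n_other,
    "sin"|"cos")`` to the coefficient of ``sin/cos(n_self*phi_self +
    n_other*phi_other)`` in rad/s.

    ``noise_sd`` is the intensity of the additive white phase noise in
    rad/sqrt(s): over a step ``dt`` the noise increment has standard
    deviation ``noise_sd * sqrt(dt)``.
    """

    natural_frequency: float  # Hz
    coupling_coeffs: dict[tuple[int, int, str], float] = field(default_factory=dict)
    noise_sd: float = 0.0
    initial_phase: float = 0.0
    max_order: int = 2

    def __post_init__(self) -> None:
        if self.natural_frequency <= 0:
            raise ValueError("natural_frequency must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for (n1, n2, parity) in self.coupling_coeffs:
            if parity not in ("sin", "cos"):
                raise ValueError(f"parity must be 'sin' or 'cos', got {parity!r}")
            if abs(n1) > self.max_order or abs(n2) > self.max_order:
                raise ValueError(
                    f"coupling index ({n1},{n2}) exceeds stated order {self.max_order}"
                )

    def drift(self, phi_self: np.ndarray, phi_other: np.ndarray) -> np.ndarray:
        """Deterministic part of dphi/dt in rad/s."""
        out = np.full_like(np.asarray(phi_self, dtype=float), 2.0 * np.pi * self.natural_frequency)
        for (n1, n2, parity), c in self.coupling_coeffs.items():
            arg = n1 * phi_self + n2 * phi_other
            out = out + c * (np.sin(arg) if parity == "sin" else np.cos(arg))
        return out


def simulate_coupled_phases(
    spec1: OscillatorSpec,
    spec2: OscillatorSpec,
    duration: float,
    dt: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a coupled pair of stochastic phase oscillators.

    Euler-Maruyama with step ``dt``; returns the two unwrapped phase series
    (rad), each of length ``round(duration/dt) + 1`` including t=0.
    Deterministic given ``seed``. Raises if any step would advance a phase by
    pi/4 or more (unstable step size).
    """
    n_steps = int(round(duration / dt))
    if n_steps < 2:
        raise ValueError("duration/dt must be at least 2")
    rng = np.random.default_rng(seed)
    phi1 = np.empty(n_steps + 1)
    phi2 = np.empty(n_steps + 1)
    phi1[0] = spec1.initial_phase
    phi2[0] = spec2.initial_phase
    sq = np.sqrt(dt)
    noise = rng.standard_normal((2, n_steps))
    for k in range(n_steps):
        d1 = spec1.drift(phi1[k], phi2[k]) * dt + spec1.noise_sd * sq * noise[0, k]
        d2 = spec2.drift(phi2[k], phi1[k]) * dt + spec2.noise_sd * sq * noise[1, k]
        if abs(d1) >= np.pi / 4 or abs(d2) >= np.pi / 4:
            raise RuntimeError(
                f"unstable integration step at step {k} (t={k * dt:.4f} s): "
                f"phase increment |{max(abs(d1), abs(d2)):.3f}| rad >= pi/4; reduce dt"
            )
        phi1[k + 1] = phi1[k] + d1
        phi2[k + 1] = phi2[k] + d2
    return phi1, phi2


def _one_over_f_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f (pink) noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid division by zero at DC
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    return out / out.std()


def simulate_physio_recording(
    heart_rate: float = 70.7,
    breathing_rate: float = 0.25,
    coupling_breathing_to_heart: float = 0.5,
    noise_level: float = 0.2,
    duration: float = 300.0,
    sampling_rate: float = 250.0,
    seed: int = 0,
    phase_noise_sd: float = 0.1,
    cardiac_power_fraction: float = 0.91,
    coupling_heart_to_breathing: float = 0.05,
    subject_id: str = "synthetic",
    group: str = "control",
) -> MultiChannelRecording:
    """Simulate one subject's ECG / breathing / perfusion recording.

    The cardiac phase obeys a stochastic phase-oscillator equation with
    respiratory drive ``coupling_breathing_to_heart * sin(phi_breathing)``
    (respiratory sinus arrhythmia); the breathing phase carries the much
    weaker cardio-ventilatory counter-coupling
    ``coupling_heart_to_breathing * sin(phi_cardiac)`` (default 0.05 rad/s,
    an order of magnitude below the forward drive). Waveforms are
    phase-driven templates: a periodic von-Mises spike kernel for ECG, a
    cosine for breathing, and for perfusion a cardiac/respiratory cosine
    mixture (cardiac power fraction ``cardiac_power_fraction``, default the
    ~91% cardiac share of LDF spectral power in the band of interest) plus
    1/f noise scaled by ``noise_level``.

    ``heart_rate`` is in beats/min and must lie in the nominal cardiac band
    (0.6, 2.0) Hz; ``breathing_rate`` (Hz) in the respiratory band
    (0.145, 0.6) Hz.
    """
    f_heart = heart_rate / 60.0
    if not (CARDIAC_BAND[0] < f_heart < CARDIAC_BAND[1]):
        raise ValueError(
            f"heart_rate/60 = {f_heart:.3f} Hz outside nominal cardiac band {CARDIAC_BAND}"
        )
    if not (RESPIRATORY_BAND[0] < breathing_rate < RESPIRATORY_BAND[1]):
        raise ValueError(
            f"breathing_rate = {breathing_rate} Hz outside nominal respiratory band "
            f"{RESPIRATORY_BAND}"
        )
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=3)

    cardiac = OscillatorSpec(
        natural_frequency=f_heart,
        coupling_coeffs=(
            {(0, 1, "sin"): coupling_breathing_to_heart}
            if coupling_breathing_to_heart != 0.0
            else {}
        ),
        noise_sd=phase_noise_sd if noise_level > 0 else 0.0,
        initial_phase=float(rng.uniform(0, 2 * np.pi)),
    )
    resp = OscillatorSpec(
        natural_frequency=breathing_rate,
        coupling_coeffs=(
            {(0, 1, "sin"): coupling_heart_to_breathing}
            if coupling_heart_to_breathing != 0.0
            else {}
        ),
        noise_sd=phase_noise_sd if noise_level > 0 else 0.0,
        initial_phase=float(rng.uniform(0, 2 * np.pi)),
    )
    dt = 1.0 / sampling_rate
    phi_c, phi_r = simulate_coupled_phases(cardiac, resp, duration, dt, seed=int(sub[0]))
    # keep exactly duration * sampling_rate samples so duration = n / fs
    n = int(round(duration * sampling_rate))
    phi_c, phi_r = phi_c[:n], phi_r[:n]

    # ECG: sharp periodic spike at phase 0 (von-Mises kernel). Respiratory
    # presence in the ECG channel (beat-amplitude modulation and baseline
    # shift) has a mechanical share (chest geometry / electrode motion,
    # independent of autonomic tone) plus an autonomic share scaling with the
    # breathing->heart coupling strength.
    kappa = 20.0
    c_bh = coupling_breathing_to_heart
    am_depth = 0.05 + 0.25 * c_bh
    baseline = 0.02 + 0.08 * c_bh
    ecg = np.exp(kappa * (np.cos(phi_c) - 1.0)) * (1.0 + am_depth * np.cos(phi_r))
    ecg = ecg + baseline * np.cos(phi_r)
    ecg -= ecg.mean()
    # chest-strap respiration with a cardiogenic oscillation (mechanical
    # cardiac artifact, independent of the autonomic coupling)
    breathing = np.cos(phi_r) + 0.1 * np.cos(phi_c - 1.0)
    w_card = np.sqrt(cardiac_power_fraction)
    w_resp = np.sqrt(1.0 - cardiac_power_fraction)
    perfusion = w_card * np.cos(phi_c - 0.4) + w_resp * np.cos(phi_r)
    if noise_level > 0:
        perfusion = perfusion + noise_level * _one_over_f_noise(n, np.random.default_rng(int(sub[1])))
        # broadband sensor noise on the electrode/strap channels (5% of the
        # channel's amplitude at the default noise_level of 0.2)
        sensor = np.random.default_rng(int(sub[2]))
        ecg = ecg + 0.25 * noise_level * ecg.std() * sensor.standard_normal(n)
        breathing = breathing + 0.25 * noise_level * breathing.std() * sensor.standard_normal(n)
    samples = np.vstack([ecg, breathing, perfusion])
    rec = MultiChannelRecording(
        samples=samples,
        channel_names=CHANNELS,
        sampling_rate=sampling_rate,
        subject_id=subject_id,
        group=group,
    )
    rec.meta.update(
        heart_rate_bpm=heart_rate,
        breathing_rate_hz=breathing_rate,
        coupling_breathing_to_heart=coupling_breathing_to_heart,
        cardiac_phase=phi_c,
        respiratory_phase=phi_r,
    )
    return rec


@dataclass
class VARSpec:
    """Specification of a stable vector-autoregressive process.

    ``coeff_matrices`` is the list of D x D matrices A(tau), tau = 1..M, in
    ``x(t) = sum_tau A(tau) x(t - tau) + e(t)`` with Gaussian innovations of
    covariance ``noise_cov``.
    """

    coeff_matrices: list[np.ndarray]
    noise_cov: np.ndarray
    n_samples: int
    sampling_rate: float = 250.0

    def __post_init__(self) -> None:
        self.coeff_matrices = [np.atleast_2d(np.asarray(a, dtype=float)) for a in self.coeff_matrices]
        self.noise_cov = np.atleast_2d(np.asarray(self.noise_cov, dtype=float))
        d = self.dim
        for a in self.coeff_matrices:
            if a.shape != (d, d):
                raise ValueError("all coefficient matrices must be D x D")
        if self.noise_cov.shape != (d, d):
            raise ValueError("noise_cov must be D x D")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        if np.any(np.linalg.eigvalsh(self.noise_cov) <= 0):
            raise ValueError("noise_cov must be positive definite")

    @property
    def dim(self) -> int:
        return self.coeff_matrices[0].shape[0]

    @property
    def order(self) -> int:
        return len(self.coeff_matrices)

    def companion_eigenvalues(self) -> np.ndarray:
        d, m = self.dim, self.order
        comp = np.zeros((d * m, d * m))
        comp[:d, :] = np.hstack(self.coeff_matrices)
        if m > 1:
            comp[d:, : d * (m - 1)] = np.eye(d * (m - 1))
        return np.linalg.eigvals(comp)

    @property
    def is_stable(self) -> bool:
        return bool(np.max(np.abs(self.companion_eigenvalues())) < 1.0)


def simulate_var(spec: VARSpec, seed: int) -> MultiChannelRecording:
    """Draw one realization of a stable VAR process.

    Iterates the recursion with Gaussian innovations, discarding a burn-in of
    ``10 * order`` samples started from zeros. Deterministic given ``seed``.
    """
    eig = np.max(np.abs(spec.companion_eigenvalues()))
    if eig >= 1.0:
        raise ValueError(f"unstable VAR spec: largest companion eigenvalue modulus {eig:.4f} >= 1")
    rng = np.random.default_rng(seed)
    d, m, n = spec.dim, spec.order, spec.n_samples
    burn = 10 * m
    total = n + burn
    chol = np.linalg.cholesky(spec.noise_cov)
    innov = rng.standard_normal((total, d)) @ chol.T
    x = np.zeros((total + m, d))
    a_stack = np.stack(spec.coeff_matrices)  # (M, D, D)
    for t in range(total):
        acc = innov[t].copy()
        for tau in range(m):
            acc += a_stack[tau] @ x[m + t - tau - 1]
        x[m + t] = acc
    out = x[m + burn :].T
    names = tuple(f"ch{i}" for i in range(d)) if d != 3 else CHANNELS
    return MultiChannelRecording(
        samples=out, channel_names=names, sampling_rate=spec.sampling_rate,
        subject_id="var-sim", group="control",
    )


def make_intersubject_surrogates(
    recordings: list[MultiChannelRecording],
    n_surrogates: int,
    seed: int,
) -> list[MultiChannelRecording]:
    """Assemble surrogate recordings mixing channels across subjects.

    Each surrogate takes its ECG, breathing and perfusion channels from three
    *different* subjects, so any genuine within-subject coupling is destroyed
    while each channel's marginal dynamics are preserved. Triplets are drawn
    without replacement from the enumerated set of valid assignments, so all
    surrogates are unique. Deterministic given ``seed``.
    """
    ids = [r.subject_id for r in recordings]
    if len(set(ids)) != len(ids):
        raise ValueError("recordings must have distinct subject_ids")
    if len(recordings) < 3:
        raise ValueError(
            "need at least 3 recordings from distinct subjects to build a "
            "3-distinct-subject surrogate"
        )
    n_min = min(r.n_samples for r in recordings)
    triplets = list(itertools.permutations(range(len(recordings)), 3))
    if n_surrogates > len(triplets):
        raise ValueError(
            f"requested {n_surrogates} surrogates but only {len(triplets)} "
            f"unique 3-distinct-subject triplets exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(triplets), size=n_surrogates, replace=False)
    out = []
    for k, idx in enumerate(chosen):
        ia, ib, ic = triplets[idx]
        samples = np.vstack(
            [
                recordings[ia].channel("ecg")[:n_min],
                recordings[ib].channel("breathing")[:n_min],
                recordings[ic].channel("perfusion")[:n_min],
            ]
        )
        sur = MultiChannelRecording(
            samples=samples,
            channel_names=CHANNELS,
            sampling_rate=recordings[ia].sampling_rate,
            subject_id=f"surrogate-{k:03d}",
            group="surrogate",
        )
        sur.meta["sources"] = (ids[ia], ids[ib], ids[ic])
        out.append(sur)
    return out


def simulate_cohort(
    n_subjects: int,
    group: str,
    seed: int,
    coupling: float | None = None,
    duration: float = 300.0,
    sampling_rate: float = 250.0,
) -> list[MultiChannelRecording]:
    """Simulate a cohort with the study's group-level signal regimes.

    Group presets follow the cohort summary statistics: controls with heart
    rate 70.7 +/- 7.2 bpm, breathing 0.25 +/- 0.06 Hz and breathing->heart
    coupling 0.5; the T1D analog with 74.1 +/- 9.5 bpm, 0.28 +/- 0.03 Hz and
    reduced coupling 0.1. Per-subject rates are drawn from those normals,
    clipped inside the nominal bands.
    """
    presets = {
        "control": dict(hr=70.7, hr_sd=7.2, br=0.25, br_sd=0.06, coupling=0.5),
        "t1d": dict(hr=74.1, hr_sd=9.5, br=0.28, br_sd=0.03, coupling=0.1),
    }
    if group not in presets:
        raise ValueError(f"group must be one of {sorted(presets)}")
    p = presets[group]
    if coupling is None:
        coupling = p["coupling"]
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n_subjects):
        hr = float(np.clip(rng.normal(p["hr"], p["hr_sd"]), 0.62 * 60, 1.95 * 60))
        br = float(np.clip(rng.normal(p["br"], p["br_sd"]), 0.16, 0.55))
        recs.append(
            simulate_physio_recording(
                heart_rate=hr,
                breathing_rate=br,
                coupling_breathing_to_heart=coupling,
                duration=duration,
                sampling_rate=sampling_rate,
                seed=int(rng.integers(0, 2**31 - 1)),
                subject_id=f"{group}-{i:02d}",
                group=group,
            )
        )
    return recs
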