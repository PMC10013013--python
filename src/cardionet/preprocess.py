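"""From raw signals to instantaneous phases.

The chain is: resample (anti-aliased, 250 -> 50 Hz by default) -> cubic
polynomial detrend -> zero-phase band-pass inside the physiological band of
interest -> Morlet continuous wavelet transform on a logarithmic frequency
grid (128 voices/octave) -> adaptive ridge extraction, whose complex argument
along the ridge gives the unwrapped instantaneous phase consumed by the
phase-coupling inference.

The mother wavelet (central frequency ``f0 = 1``) includes the admissibility
correction term that removes its DC response::

    gamma(t) = (1/sqrt(2*pi)) * (exp(i*2*pi*f0*t) - exp(-(2*pi*f0)**2 / 2)) * exp(-t**2/2)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps


def resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-alias filter and decimate from ``fs_in`` to ``fs_out`` Hz.

    Upsampling is unsupported. Output length is ``round(n * fs_out / fs_in)``.
    """
    if fs_out > fs_in:
        raise ValueError(f"upsampling unsupported (fs_out {fs_out} > fs_in {fs_in})")
    x = np.asarray(x, dtype=float)
    if fs_out == fs_in:
        return x.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10_000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def detrend_poly(x: np.ndarray, order: int = 3) -> np.ndarray:
    """Subtract the least-squares polynomial fit of the given order."""
    if order < 0:
        raise ValueError("order must be non-negative")
    x = np.asarray(x, dtype=float)
    if len(x) <= order + 1:
        raise ValueError(f"signal length {len(x)} too short for order {order}")
    t = np.linspace(-1.0, 1.0, len(x))
    coeffs = np.polynomial.polynomial.polyfit(t, x, order)
    return x - np.polynomial.polynomial.polyval(t, coeffs)


def bandpass(x: np.ndarray, fs: float, band: tuple[float, float], order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, no group delay)."""
    low, high = band
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band {band} must satisfy 0 < low < high < Nyquist ({fs / 2} Hz)")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


@dataclass
class TimeFrequencyMap:
    """Complex Morlet CWT coefficients on a log-spaced frequency grid."""

    coefficients: np.ndarray  # (n_freq, n_time) complex
    frequencies: np.ndarray  # Hz, strictly increasing, log-spaced
    times: np.ndarray  # s
    mother_central_frequency: float = 1.0
    voices_per_octave: int = 128

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")


def _morlet_ft(nu: np.ndarray, f0: float) -> np.ndarray:
    """Fourier transform of the corrected Morlet mother at frequency nu."""
    corr = np.exp(-((2 * np.pi * f0) ** 2) / 2.0)
    return np.exp(-2 * np.pi**2 * (nu - f0) ** 2) - corr * np.exp(-2 * np.pi**2 * nu**2)


def wavelet_tfr(
    x: np.ndarray,
    fs: float,
    fmin: float,
    fmax: float,
    voices: int = 128,
    f0: float = 1.0,
) -> TimeFrequencyMap:
    """Morlet continuous wavelet transform on a log frequency grid.

    Frequencies run from ``fmin`` upward in steps of ``2**(1/voices)`` up to
    ``fmax``. Computed by FFT convolution with zero padding (one wavelet
    support on each side) so the transform is linear in the input to machine
    precision.
    """
    if fmin >= fmax:
        raise ValueError("fmin must be < fmax")
    if fmin <= 0 or fmax >= fs / 2:
        raise ValueError(f"need 0 < fmin < fmax < Nyquist ({fs / 2} Hz)")
    x = np.asarray(x, dtype=float)
    n = len(x)
    k_max = int(np.floor(voices * np.log2(fmax / fmin)))
    freqs = fmin * 2.0 ** (np.arange(k_max + 1) / voices)
    # pad by the widest wavelet support (scale f0/fmin, ~4 sigma)
    pad = int(np.ceil(4.0 * (f0 / fmin) * fs))
    m = int(2 ** np.ceil(np.log2(n + 2 * pad)))
    xf = np.fft.fft(x, m)
    nu = np.fft.fftfreq(m, d=1.0 / fs)
    coeff = np.empty((len(freqs), n), dtype=complex)
    for i, f in enumerate(freqs):
        s = f0 / f
        # L1 scale normalization: unit-amplitude tone -> comparable |W| at every f
        kernel = _morlet_ft(s * nu, f0)
        coeff[i] = np.fft.ifft(xf * kernel)[:n]
    times = np.arange(n) / fs
    return TimeFrequencyMap(
        coefficients=coeff,
        frequencies=freqs,
        times=times,
        mother_central_frequency=f0,
        voices_per_octave=voices,
    )


@dataclass
class RidgeCurve:
    """Instantaneous frequency/amplitude/phase of one oscillatory component.

    ``phase`` is the unwrapped argument of the TFR coefficient along the
    ridge; ``valid`` flags samples outside the cone of influence (more than
    one wavelet support away from either record edge).
    """

    times: np.ndarray
    frequency: np.ndarray  # Hz
    amplitude: np.ndarray
    phase: np.ndarray  # rad, unwrapped
    band: tuple[float, float]
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(len(self.times), dtype=bool)
        if not (len(self.times) == len(self.frequency) == len(self.amplitude) == len(self.phase)):
            raise ValueError("ridge arrays must share one length")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


def _ridge_dp(
    amp: np.ndarray,
    dt: float,
    dq: float,
    rate_mean: float,
    freq_mean_bin: float | None,
    penalty_rate: float,
    penalty_deviation: float,
    max_jump: int,
) -> np.ndarray:
    """Dynamic-programming max-score path through an amplitude map.

    Score = sum over time of amplitude minus ``penalty_rate * (rate -
    rate_mean)^2 * dt`` (rate in octaves/s) minus, when ``freq_mean_bin`` is
    given, ``penalty_deviation * (q - q_mean)^2 * dt`` (q in octaves).
    """
    n_f, n_t = amp.shape
    offs = np.arange(-max_jump, max_jump + 1)
    trans = penalty_rate * (offs * dq / dt - rate_mean) ** 2 * dt
    node = amp.copy()
    if freq_mean_bin is not None:
        q_dev = (np.arange(n_f) - freq_mean_bin) * dq
        node -= penalty_deviation * (q_dev**2 * dt)[:, None]
    score = node[:, 0].copy()
    back = np.zeros((n_f, n_t), dtype=np.int32)
    idx = np.arange(n_f)
    for t in range(1, n_t):
        # candidate previous-bin scores for each offset
        best = np.full(n_f, -np.inf)
        best_prev = np.zeros(n_f, dtype=np.int32)
        for j, off in enumerate(offs):
            prev = idx - off
            ok = (prev >= 0) & (prev < n_f)
            cand = np.full(n_f, -np.inf)
            cand[ok] = score[prev[ok]] - trans[j]
            better = cand > best
            best[better] = cand[better]
            best_prev[better] = prev[better]
        score = best + node[:, t]
        back[:, t] = best_prev
    path = np.empty(n_t, dtype=np.int32)
    path[-1] = int(np.argmax(score))
    for t in range(n_t - 1, 0, -1):
        path[t - 1] = back[path[t], t]
    return path


def extract_ridge(
    tfr: TimeFrequencyMap,
    band: tuple[float, float],
    penalty_rate: float = 1.0,
    penalty_deviation: float = 1.0,
) -> RidgeCurve:
    """Extract a single continuous ridge from a TFR inside ``band``.

    Two-pass adaptive scheme: a first dynamic-programming pass with only the
    frequency-change penalty establishes the component's mean (log-)frequency
    and mean rate of frequency change; the second pass penalizes squared
    deviations from both running references, weighted by the two adjustable
    parameters (defaults 1). Sub-bin frequency is refined by parabolic
    interpolation of log-amplitude; phase is the unwrapped argument of the
    complex coefficient along the ridge.
    """
    low, high = band
    if low >= high:
        raise ValueError("empty band")
    sel = (tfr.frequencies >= low) & (tfr.frequencies <= high)
    if sel.sum() < 3:
        raise ValueError(f"band {band} covers fewer than 3 TFR frequency bins")
    freqs = tfr.frequencies[sel]
    w = tfr.coefficients[sel]
    amp = np.abs(w)
    amax = amp.max()
    if amax > 0:
        amp = amp / amax
    dt = float(np.median(np.diff(tfr.times)))
    dq = 1.0 / tfr.voices_per_octave  # octaves per bin
    max_jump = max(2, int(np.ceil(0.06 * tfr.voices_per_octave * dt)) + 1)

    path1 = _ridge_dp(amp, dt, dq, 0.0, None, penalty_rate, penalty_deviation, max_jump)
    rate_mean = float(np.mean(np.diff(path1)) * dq / dt)
    mean_bin = float(np.mean(path1))
    path = _ridge_dp(amp, dt, dq, rate_mean, mean_bin, penalty_rate, penalty_deviation, max_jump)

    # parabolic sub-bin refinement on log-amplitude
    n_f = len(freqs)
    logf = np.log2(freqs)
    ridge_logf = logf[path].astype(float)
    for t in range(len(path)):
        k = path[t]
        if 0 < k < n_f - 1:
            a0, a1, a2 = amp[k - 1, t], amp[k, t], amp[k + 1, t]
            denom = a0 - 2 * a1 + a2
            if denom < 0:  # strict local max
                delta = 0.5 * (a0 - a2) / denom
                ridge_logf[t] = logf[k] + np.clip(delta, -0.5, 0.5) * dq
    frequency = 2.0**ridge_logf
    amplitude = np.abs(w[path, np.arange(w.shape[1])]) * (amax if amax > 0 else 1.0)
    phase = np.unwrap(np.angle(w[path, np.arange(w.shape[1])]))

    # cone of influence: within ~3 wavelet standard deviations of either edge
    support = 3.0 * tfr.mother_central_frequency / np.maximum(frequency, 1e-12)
    t_rel = tfr.times - tfr.times[0]
    t_end = tfr.times[-1] - tfr.times
    valid = (t_rel >= support) & (t_end >= support)
    return RidgeCurve(
        times=tfr.times.copy(),
        frequency=frequency,
        amplitude=amplitude,
        phase=phase,
        band=band,
        valid=valid,
    )


def extract_component_phase(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    fs_analysis: float = 50.0,
    detrend_order: int = 3,
    voices: int = 128,
) -> RidgeCurve:
    """Full preprocessing chain for one channel and one physiological band.

    resample -> polynomial detrend -> zero-phase band-pass -> Morlet CWT ->
    adaptive ridge extraction. Returns the ridge whose ``phase`` feeds the
    coupling inference.
    """
    y = resample(x, fs, fs_analysis)
    y = detrend_poly(y, detrend_order)
    y = bandpass(y, fs_analysis, band)
    tfr = wavelet_tfr(y, fs_analysis, band[0], band[1], voices=voices)
    return extract_ridge(tfr, band)
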