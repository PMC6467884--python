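"""Synthetic single-channel occipital EEG with controllable SSVEP content.

The generator emulates what an Oz electrode records while a subject attends
a flickering LED: a sinusoid at the flicker frequency (15 or 17 Hz in the
two-choice design) riding on 1/f^alpha background activity.  Signal-to-noise
ratio is defined as the ratio of sinusoid power to background power inside
the 0-30 Hz band, i.e. the band the decision pipeline actually sees, so
decoder-accuracy-versus-SNR curves are directly interpretable.

Senders are sampled at 250 Hz; the Receiver's amplifier runs at 5000 Hz and
is decimated to 500 Hz before decoding, which :func:`downsample` reproduces
with proper anti-alias filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "EEGRecording",
    "SSVEPSpec",
    "generate_ssvep",
    "generate_idle",
    "downsample",
    "band_power",
]

#: Upper edge (Hz) of the analysis band used for the SNR definition.
ANALYSIS_BAND = (0.0, 30.0)


@dataclass(frozen=True)
class EEGRecording:
    """A single-channel EEG time series.

    Parameters
    ----------
    samples
        Amplitude series in microvolts.
    fs
        Sampling rate in Hz.
    label
        Channel name, e.g. ``"Oz"``.
    start_time
        Offset of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    label: str = "Oz"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("EEG samples must be finite")

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.fs


@dataclass(frozen=True)
class SSVEPSpec:
    """Parameters of a synthetic steady-state visually evoked response.

    ``snr`` is the ratio of sinusoid power to background-noise power within
    the 0-30 Hz band; ``math.inf`` yields a noise-free sinusoid and ``0``
    pure background.
    """

    target_freq: float
    amplitude: float = 1.0
    noise_exponent: float = 1.0
    snr: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_freq <= 0:
            raise ValueError(f"target_freq must be positive, got {self.target_freq}")
        if self.snr < 0:
            raise ValueError(f"snr must be nonnegative, got {self.snr}")
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")


def _n_samples(duration: float, fs: float) -> int:
    n = duration * fs
    n_int = round(n)
    if abs(n - n_int) > 1e-9 or n_int < 1:
        raise ValueError(
            f"duration ({duration} s) x fs ({fs} Hz) must be a whole, positive "
            f"number of samples, got {n}"
        )
    return n_int


def _colored_noise(n: int, fs: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f^alpha noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC: the decoder mean-removes anyway
    return np.fft.irfft(spectrum * shaping, n=n)


def band_power(samples: np.ndarray, fs: float, band: tuple[float, float] = ANALYSIS_BAND) -> float:
    """Mean power of ``samples`` within a frequency band (periodogram integral).

    Direct rfft evaluation of the boxcar, non-detrended periodogram,
    integrated over the band with the trapezoid rule.
    """
    n = len(samples)
    spectrum = np.fft.rfft(samples)
    psd = (np.abs(spectrum) ** 2) / (fs * n)
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[mask], freqs[mask]))


def generate_ssvep(spec: SSVEPSpec, duration: float, fs: float) -> EEGRecording:
    """Generate an SSVEP-bearing recording: target sinusoid + 1/f^alpha noise.

    The noise realization is rescaled so the realized sinusoid-to-noise power
    ratio in the 0-30 Hz band equals ``spec.snr`` exactly.  Identical
    ``spec`` (including seed), ``duration`` and ``fs`` give bitwise-identical
    samples.

    Raises
    ------
    ValueError
        If ``spec.target_freq`` is at or above the Nyquist frequency.
    """
    if spec.target_freq >= fs / 2:
        raise ValueError(
            f"target frequency {spec.target_freq} Hz is at/above Nyquist "
            f"({fs / 2} Hz) for sampling rate {fs} Hz"
        )
    n = _n_samples(duration, fs)
    t = np.arange(n) / fs
    sine = spec.amplitude * np.sin(2 * np.pi * spec.target_freq * t)

    if math.isinf(spec.snr):
        samples = sine
    else:
        rng = np.random.default_rng(spec.seed)
        noise = _colored_noise(n, fs, spec.noise_exponent, rng)
        noise_bp = band_power(noise, fs)
        if noise_bp <= 0:
            raise ValueError("degenerate noise realization (zero band power)")
        if spec.snr == 0:
            samples = noise * math.sqrt(band_power(sine, fs) / noise_bp)
        else:
            target_noise_power = band_power(sine, fs) / spec.snr
            samples = sine + noise * math.sqrt(target_noise_power / noise_bp)
    return EEGRecording(samples=samples, fs=fs)


def generate_idle(
    duration: float,
    fs: float,
    noise_exponent: float = 1.0,
    seed: int = 0,
    amplitude: float = 1.0,
) -> EEGRecording:
    """Background-only EEG: 1/f^alpha noise with no stimulus-locked component.

    Models the baseline epochs outside the SSVEP task, where spectral power
    at the two candidate frequencies is statistically indistinguishable.
    ``noise_exponent=0`` gives white (flat-spectrum) noise.
    """
    n = _n_samples(duration, fs)
    rng = np.random.default_rng(seed)
    noise = _colored_noise(n, fs, noise_exponent, rng)
    rms = np.sqrt(np.mean(noise**2))
    if rms > 0:
        noise = noise * (amplitude / rms)
    return EEGRecording(samples=noise, fs=fs)


def downsample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Reduce the sampling rate, anti-alias filtering before decimation.

    Integer decimation ratios use :func:`scipy.signal.decimate` with a
    zero-phase FIR low-pass; ``target_fs == rec.fs`` returns the recording
    unchanged.  Upsampling is rejected.
    """
    if target_fs > rec.fs:
        raise ValueError(
            f"target rate {target_fs} Hz exceeds recording rate {rec.fs} Hz; "
            "only downsampling is supported"
        )
    if target_fs == rec.fs:
        return rec
    ratio = rec.fs / target_fs
    if abs(ratio - round(ratio)) < 1e-9:
        out = signal.decimate(rec.samples, int(round(ratio)), ftype="fir", zero_phase=True)
    else:
        n_out = int(round(len(rec.samples) * target_fs / rec.fs))
        out = signal.resample_poly(
            rec.samples,
            up=int(round(target_fs)),
            down=int(round(rec.fs)),
        )[:n_out]
    return EEGRecording(samples=out, fs=target_fs, label=rec.label, start_time=rec.start_time)
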