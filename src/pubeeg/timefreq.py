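"""Morlet wavelet time-frequency decomposition.

Instantaneous power and phase are obtained by convolving each channel with a
family of complex Morlet wavelets

    w(t, f) = (sigma_t * sqrt(pi))**(-1/2)
              * exp(-t**2 / (2 * sigma_t**2)) * exp(i * 2 * pi * f * t),

where the temporal width follows from the constant frequency-to-bandwidth
ratio ``f / sigma_f`` (default 7) via ``sigma_f = 1 / (2 * pi * sigma_t)``,
i.e. ``sigma_t = ratio / (2 * pi * f)``.  Power is ``log10 |w * s|**2`` and
phase is ``arg(w * s)`` in (-pi, pi].

The kernel is truncated at +/- 4 sigma_t (a package choice; the Gaussian
envelope is below 3.4e-4 of its peak there).  Convolution uses zero padding;
samples within 2 sigma_t of either end of the signal are flagged unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._utils import wrap_phase
from .preprocess import EEGRecording

__all__ = [
    "WaveletConfig",
    "TFMaps",
    "EpochedPhase",
    "make_log_freqs",
    "wavelet_sigma_t",
    "wavelet_kernel",
    "tf_decompose",
    "epoch_phase",
    "EpochBoundsError",
]

# Kernel support half-width in units of sigma_t.
KERNEL_HALF_WIDTH_SIGMAS = 4.0
# Edge-mask half-width in units of sigma_t.
EDGE_SIGMAS = 2.0

DEFAULT_EPOCH_WINDOW = (-2.0, 1.5)
DEFAULT_EPOCH_RATE = 100.0


class EpochBoundsError(ValueError):
    pass


def make_log_freqs(fmin: float, fmax: float, n: int) -> np.ndarray:
    """Logarithmically spaced analysis frequencies from fmin to fmax (Hz)."""
    if not (0 < fmin < fmax):
        raise ValueError("need 0 < fmin < fmax")
    if n < 2:
        raise ValueError("need at least 2 frequencies")
    return np.geomspace(fmin, fmax, n)


@dataclass(frozen=True)
class WaveletConfig:
    """Morlet family: analysis frequencies, f/sigma_f ratio, sampling rate."""

    freqs: np.ndarray
    rate: float
    ratio: float = 7.0

    def __post_init__(self):
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        if self.freqs.ndim != 1 or np.any(self.freqs <= 0) or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing and positive")
        if self.ratio <= 0 or self.rate <= 0:
            raise ValueError("ratio and rate must be positive")

    @classmethod
    def default(cls, rate: float) -> "WaveletConfig":
        """50 log-spaced frequencies spanning 1-60 Hz at ratio 7."""
        return cls(freqs=make_log_freqs(1.0, 60.0, 50), rate=rate)


def wavelet_sigma_t(f: float, ratio: float = 7.0) -> float:
    """Temporal standard deviation ``sigma_t = ratio / (2 pi f)`` in seconds."""
    return ratio / (2.0 * np.pi * f)


def wavelet_kernel(f: float, config: WaveletConfig) -> np.ndarray:
    """Discretized complex Morlet wavelet at frequency ``f``.

    Support covers +/- 4 sigma_t; the center sample (t=0) is real and
    positive and |w| is symmetric in t.
    """
    sigma_t = wavelet_sigma_t(f, config.ratio)
    half = int(np.ceil(KERNEL_HALF_WIDTH_SIGMAS * sigma_t * config.rate))
    t = np.arange(-half, half + 1) / config.rate
    norm = (sigma_t * np.sqrt(np.pi)) ** (-0.5)
    return norm * np.exp(-t**2 / (2 * sigma_t**2)) * np.exp(2j * np.pi * f * t)


@dataclass
class TFMaps:
    """Per-channel instantaneous log-power and phase over a (freq, time) grid.

    ``power[c, f, t] = log10 |w * s|^2`` (``-inf`` where the convolution
    magnitude is exactly zero — those points are masked in ``valid``);
    ``phase`` in (-pi, pi].  ``reliable[f, t]`` is False within 2 sigma_t of
    either signal edge.
    """

    power: np.ndarray
    phase: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    channel_names: list[str]
    rate: float
    reliable: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.isfinite(self.power)


def tf_decompose(eeg: EEGRecording, config: WaveletConfig) -> TFMaps:
    """Morlet decomposition of every channel at every analysis frequency.

    FFT-based convolution, zero-padded, output aligned to the input samples
    (``mode='same'``).  Raises if the signal is shorter than the longest
    kernel (the lowest-frequency one).
    """
    if abs(eeg.rate - config.rate) > 1e-9:
        raise ValueError("config.rate must match the recording rate")
    n = eeg.n_samples
    C, F = eeg.n_channels, config.freqs.size
    longest = 2 * int(np.ceil(KERNEL_HALF_WIDTH_SIGMAS
                              * wavelet_sigma_t(config.freqs[0], config.ratio)
                              * config.rate)) + 1
    if n < longest:
        raise ValueError(
            f"signal ({n} samples) shorter than the longest wavelet ({longest})")

    power = np.empty((C, F, n))
    phase = np.empty((C, F, n))
    reliable = np.ones((F, n), dtype=bool)
    for j, f in enumerate(config.freqs):
        k = wavelet_kernel(f, config)
        conv = sps.fftconvolve(eeg.data, k[None, :], mode="same", axes=1)
        mag2 = np.abs(conv) ** 2
        with np.errstate(divide="ignore"):
            power[:, j] = np.log10(mag2)
        phase[:, j] = wrap_phase(np.angle(conv))
        edge = int(np.ceil(EDGE_SIGMAS * wavelet_sigma_t(f, config.ratio) * config.rate))
        if edge > 0:
            reliable[j, :edge] = False
            reliable[j, n - edge:] = False
    return TFMaps(power=power, phase=phase, times=np.arange(n) / eeg.rate,
                  freqs=config.freqs.copy(), channel_names=list(eeg.channel_names),
                  rate=eeg.rate, reliable=reliable)


@dataclass
class EpochedPhase:
    """Trial-locked phase: trials x channels x freqs x times.

    The time grid spans speech onset -2.0 s to +1.5 s inclusive at 100 Hz
    (351 points by default), the grid on which the PUB is computed.
    """

    phase: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    channel_names: list[str]

    @property
    def n_trials(self) -> int:
        return self.phase.shape[0]

    def grid_shape(self) -> tuple[int, int, int]:
        return self.phase.shape[1:]


def epoch_window_times(window=DEFAULT_EPOCH_WINDOW,
                       grid_rate: float = DEFAULT_EPOCH_RATE) -> np.ndarray:
    """Closed epoch time grid: k / grid_rate for window[0] <= k/rate <= window[1]."""
    k0 = int(np.round(window[0] * grid_rate))
    k1 = int(np.round(window[1] * grid_rate))
    return np.arange(k0, k1 + 1) / grid_rate


def epoch_phase(tf: TFMaps, trials: pd.DataFrame, window=DEFAULT_EPOCH_WINDOW,
                grid_rate: float = DEFAULT_EPOCH_RATE) -> EpochedPhase:
    """Extract trial-locked phase onto the analysis grid around speech onset.

    Nearest-sample extraction from the full-rate decomposition onto the
    ``grid_rate`` grid (the effective downsampling of phase for PUB).  Trials
    with null RT are *not* excluded here; the PUB stage handles that.
    """
    offsets = epoch_window_times(window, grid_rate)
    onsets = np.asarray(trials["speech_onset_s"], dtype=float)
    idx = np.round((onsets[:, None] + offsets[None, :]) * tf.rate).astype(int)
    if idx.min() < 0 or idx.max() >= tf.phase.shape[-1]:
        raise EpochBoundsError("epoch window extends outside the recording")
    # (trials, C, F, times)
    phase = tf.phase[:, :, idx].transpose(2, 0, 1, 3)
    return EpochedPhase(phase=phase, times=offsets, freqs=tf.freqs.copy(),
                        channel_names=list(tf.channel_names))
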