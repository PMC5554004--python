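"""Raw-EEG preprocessing: ocular regression correction, average re-reference,
event-locked artifact-template subtraction, and anti-aliased downsampling.

All operations are linear maps of the input signal and return a new
:class:`EEGRecording`; nothing is modified in place.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "EEGRecording",
    "correct_ocular",
    "rereference_average",
    "subtract_artifact_template",
    "downsample_signal",
    "downsample_recording",
    "DegenerateRegressorError",
    "WindowOverlapError",
]


class DegenerateRegressorError(ValueError):
    pass


class WindowOverlapError(ValueError):
    pass


@dataclass
class EEGRecording:
    """Multi-channel EEG signal: channels x samples matrix with metadata.

    ``data`` is in microvolts (channels along axis 0), ``rate`` in Hz.
    ``montage`` holds 2-D electrode positions aligned with ``channel_names``
    (may be None for position-free operations). ``reference`` records whether
    the data are as recorded or average-referenced.
    """

    data: np.ndarray
    rate: float
    channel_names: list[str]
    montage: np.ndarray | None = None
    reference: str = "as-recorded"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names must match data rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.montage is not None:
            self.montage = np.asarray(self.montage, dtype=float)
            if self.montage.shape != (self.data.shape[0], 2):
                raise ValueError("montage must be n_channels x 2")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate


def correct_ocular(eeg: EEGRecording, veog, heog) -> EEGRecording:
    """Remove ocular artifacts by joint two-regressor least squares.

    Each channel is regressed on the vertical and horizontal EOG series
    (with an intercept) and the fitted EOG contribution
    ``b_v * VEOG + b_h * HEOG`` is subtracted.  A channel orthogonal to the
    EOG span is left unchanged.
    """
    v = np.asarray(veog, dtype=float).ravel()
    h = np.asarray(heog, dtype=float).ravel()
    if v.size != eeg.n_samples or h.size != eeg.n_samples:
        raise ValueError("EOG series must match the recording length")
    X = np.column_stack([v, h, np.ones_like(v)])
    # Rank check on the demeaned EOG pair: identical or constant series give a
    # degenerate two-regressor problem.
    eog = np.column_stack([v - v.mean(), h - h.mean()])
    sv = np.linalg.svd(eog, compute_uv=False)
    if sv[-1] <= 1e-10 * max(sv[0], 1.0):
        raise DegenerateRegressorError("VEOG/HEOG pair is rank deficient")
    beta, *_ = np.linalg.lstsq(X, eeg.data.T, rcond=None)  # (3, n_channels)
    corrected = eeg.data - (X[:, :2] @ beta[:2]).T
    return replace(eeg, data=corrected)


def rereference_average(eeg: EEGRecording) -> EEGRecording:
    """Re-express every channel relative to the instantaneous channel mean.

    After the operation the per-sample mean across channels is zero; applying
    it twice is a no-op (it is a projection).
    """
    if eeg.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    mean = eeg.data.mean(axis=0, keepdims=True)
    return replace(eeg, data=eeg.data - mean, reference="average")


def subtract_artifact_template(eeg: EEGRecording, event_times, window: float) -> EEGRecording:
    """Subtract the mean event-locked epoch from every event window.

    For periodic artifacts (scanner gradients, cardiac pulse) the waveform is
    estimated per channel as the average over all event-locked windows of
    length ``window`` seconds starting at each event time, then subtracted
    from each window.  Requires at least two events; overlapping windows are
    rejected since averaging them would mix artifact instances.
    """
    times = np.sort(np.asarray(event_times, dtype=float).ravel())
    if times.size < 2:
        raise ValueError("need at least 2 events to form a template")
    win_n = int(round(window * eeg.rate))
    if win_n < 1:
        raise ValueError("window too short for the sampling rate")
    starts = np.round(times * eeg.rate).astype(int)
    if starts[0] < 0 or starts[-1] + win_n > eeg.n_samples:
        raise ValueError("event windows fall outside the recording")
    if np.any(np.diff(starts) < win_n):
        raise WindowOverlapError("artifact windows overlap")
    epochs = np.stack([eeg.data[:, s:s + win_n] for s in starts])  # (E, C, W)
    template = epochs.mean(axis=0)
    out = eeg.data.copy()
    for s in starts:
        out[:, s:s + win_n] -= template
    return replace(eeg, data=out)


def downsample_signal(x, from_rate: float, to_rate: float) -> np.ndarray:
    """Zero-phase anti-alias filter and decimate a sample series.

    ``from_rate`` must be an integer multiple of ``to_rate``.  A zero-phase
    FIR low-pass (applied forward-backward, so no phase distortion — phase
    integrity is essential for downstream phase analysis) precedes decimation.
    Output length is ``floor(n * to_rate / from_rate)``.
    """
    x = np.asarray(x, dtype=float)
    if to_rate > from_rate:
        raise ValueError("to_rate must not exceed from_rate")
    if to_rate == from_rate:
        return x.copy()
    q_f = from_rate / to_rate
    q = int(round(q_f))
    if abs(q_f - q) > 1e-9:
        raise ValueError("to_rate must divide from_rate")
    y = sps.decimate(x, q, ftype="fir", zero_phase=True, axis=-1)
    out_n = int(np.floor(x.shape[-1] * to_rate / from_rate))
    return y[..., :out_n]


def downsample_recording(eeg: EEGRecording, to_rate: float) -> EEGRecording:
    """Apply :func:`downsample_signal` to every channel of a recording."""
    data = downsample_signal(eeg.data, eeg.rate, to_rate)
    return replace(eeg, data=data, rate=float(to_rate))
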