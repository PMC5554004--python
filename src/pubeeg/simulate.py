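"""Synthetic-study generator: EEG, behavior and BOLD with known ground truth.

Every downstream stage of the package is exercisable on data from this module
with a known phase effect, so parameter recovery, null calibration and power
are all testable.  The generative behavioral model is exactly the cosine
model the PUB fits:

    log10(RT_ms) = B + A * cos(theta + tau) + Normal(0, sd),
    P(correct)   = clip(acc_base + acc_mod * cos(theta + tau), 0, 1),

with theta the oscillatory phase at a chosen (channel, frequency, time) locus
relative to speech onset, re-drawn uniformly on (-pi, pi] for every trial so
the PUB's phase-uniformity precondition holds by construction.  Responses
slower than 2 s are recorded as null and excluded downstream.

Trial timing mirrors a speech-in-noise recognition task: masking noise starts,
the spoken word starts 2.0 s later, the noise ends 1.5 s after speech onset,
a response probe follows, and the next trial starts after a gap drawn from a
fixed set of eight intervals between 1.167 and 1.833 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import rng_from, split_seed, wrap_phase
from .preprocess import EEGRecording
from .glm import build_eeg_regressor

__all__ = [
    "ChannelLayout",
    "EffectSpec",
    "StudyDataset",
    "TRIAL_GAPS_S",
    "gen_montage",
    "gen_trials",
    "gen_oscillatory_eeg",
    "gen_phase_dependent_behavior",
    "gen_study",
    "gen_phase_field",
    "gen_bold",
]

# Inter-trial gaps (s) between probe offset and the next noise onset.
TRIAL_GAPS_S = np.array([1.167, 1.262, 1.357, 1.452, 1.547, 1.642, 1.737, 1.833])

NOISE_TO_SPEECH_S = 2.0     # speech always starts 2 s after noise onset
NOISE_AFTER_SPEECH_S = 1.5  # masking noise ends 1.5 s after speech onset
SPEECH_DURATION_S = 1.0     # spoken word lasts about 1 s
RESPONSE_WINDOW_MS = 2000.0  # slower responses are recorded as null

# 10-20-ish electrode names used for layouts up to 32 channels.
_MONTAGE_NAMES = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "CP5", "CP1", "CP2", "CP6", "P7", "P3",
    "Pz", "P4", "P8", "O1", "Oz", "O2", "FC3", "FC4", "CP3", "CP4",
]


@dataclass(frozen=True)
class ChannelLayout:
    """Named electrodes with 2-D positions (flattened scalp projection)."""

    names: tuple[str, ...]
    positions: np.ndarray  # (n, 2)

    def __post_init__(self):
        object.__setattr__(self, "positions",
                           np.asarray(self.positions, dtype=float))
        if len(self.names) != self.positions.shape[0]:
            raise ValueError("names and positions must align")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def gen_montage(n_channels: int) -> ChannelLayout:
    """Deterministic scalp layout on the unit disc.

    Electrodes are placed by the sunflower (golden-angle) construction, which
    fills the disc with nearly uniform pairwise-distinct positions; n=4 is
    special-cased to a square.  Names follow 10-20 conventions up to 32
    channels, generic beyond.
    """
    if not (4 <= n_channels <= 64):
        raise ValueError("n_channels must be between 4 and 64")
    names = tuple(_MONTAGE_NAMES[i] if i < len(_MONTAGE_NAMES) else f"CH{i + 1}"
                  for i in range(n_channels))
    if n_channels == 4:
        pos = np.array([[-0.5, 0.5], [0.5, 0.5], [-0.5, -0.5], [0.5, -0.5]])
        return ChannelLayout(names=names, positions=pos)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_channels)
    r = np.sqrt((i + 0.5) / n_channels)
    ang = i * golden
    pos = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    return ChannelLayout(names=names, positions=pos)


def gen_trials(n_trials: int, seed: int, probe_duration_s: float = 1.2) -> pd.DataFrame:
    """Generate a trial table with task-realistic timing.

    Speech onset is always exactly 2.0 s after noise onset; the probe follows
    the ~1 s spoken word; inter-trial gaps are drawn uniformly from the eight
    fixed values in :data:`TRIAL_GAPS_S`.  ``probe_duration_s`` is the nominal
    probe display time used to lay out onsets (behavior is generated later
    and does not feed back into timing).

    Columns: trial, noise_onset_s, speech_onset_s, probe_onset_s,
    probe_duration_s, rt_ms (null), correct (null), word_id.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = rng_from(seed)
    gaps = rng.choice(TRIAL_GAPS_S, size=n_trials)
    word_id = rng.integers(0, 99, size=n_trials)

    noise_onset = np.empty(n_trials)
    t = 6.0  # leading pad so pre-speech epochs and wavelet edges fit
    for i in range(n_trials):
        noise_onset[i] = t
        probe_end = t + NOISE_TO_SPEECH_S + SPEECH_DURATION_S + probe_duration_s
        t = probe_end + gaps[i]
    speech_onset = noise_onset + NOISE_TO_SPEECH_S
    return pd.DataFrame({
        "trial": np.arange(n_trials),
        "noise_onset_s": noise_onset,
        "speech_onset_s": speech_onset,
        "probe_onset_s": speech_onset + SPEECH_DURATION_S,
        "probe_duration_s": probe_duration_s,
        "rt_ms": np.nan,
        "correct": pd.array([pd.NA] * n_trials, dtype="boolean"),
        "word_id": word_id,
    })


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth phase effect injected into a synthetic study.

    ``amplitude_A``, ``tau`` and ``baseline_B`` are the generative cosine
    parameters on the log10-ms scale; ``rt_noise_sd`` is the trial-to-trial
    log-RT noise.  Accuracy is ``accuracy_base + accuracy_mod*cos(theta+tau)``
    clipped to [0, 1].  ``osc_amplitude`` sets the locus oscillation strength
    in units of the 1/f background RMS; the default (None) resolves to 0 when
    ``amplitude_A == 0`` (null studies carry no distinguished channel) and to
    2.0 otherwise.
    """

    locus_channel: str = "CP1"
    locus_freq: float = 4.5
    locus_time: float = -0.5
    amplitude_A: float = 0.05
    tau: float = 1.0
    baseline_B: float = 3.05
    rt_noise_sd: float = 0.12
    accuracy_base: float = 0.75
    accuracy_mod: float = 0.0
    osc_amplitude: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.tau <= np.pi):
            raise ValueError("tau must lie in [0, pi]")
        if self.rt_noise_sd < 0:
            raise ValueError("rt_noise_sd must be >= 0")
        if not (0.0 <= self.accuracy_base <= 1.0):
            raise ValueError("accuracy_base must be a probability")

    @property
    def oscillation_amplitude(self) -> float:
        if self.osc_amplitude is not None:
            return self.osc_amplitude
        return 0.0 if self.amplitude_A == 0.0 else 2.0


def _powerlaw_noise(rng: np.random.Generator, n: int, rate: float,
                    exponent: float) -> np.ndarray:
    """Gaussian 1/f**exponent noise, unit RMS."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    return x / x.std()


def gen_oscillatory_eeg(layout: ChannelLayout, trials: pd.DataFrame,
                        effect: EffectSpec, rate: float = 500.0,
                        noise_exponent: float = 1.0, seed: int = 0,
                        spatial_spread: float = 0.6,
                        ) -> tuple[EEGRecording, np.ndarray]:
    """Synthesize scalp EEG: 1/f background plus a trial-phase-random locus
    oscillation.

    Every channel carries independent power-law noise.  The locus channel
    additionally carries, within each trial's epoch window, a sinusoid at the
    locus frequency whose phase at the locus time (relative to that trial's
    speech onset) is re-drawn uniformly on (-pi, pi] — decorrelating phase
    across trials so the PUB uniformity precondition holds.  As on the real
    scalp, where volume conduction makes any source visible at adjacent
    sensors, the montage neighbors of the locus channel receive the same
    oscillation attenuated by ``spatial_spread``.  The exact drawn phases are
    returned for recovery checks.
    """
    if rate < 4.0 * effect.locus_freq:
        raise ValueError("rate must be at least 4x the locus frequency")
    if effect.locus_channel not in layout.names:
        raise ValueError(f"locus channel {effect.locus_channel!r} not in layout")
    rng = rng_from(seed)
    speech = np.asarray(trials["speech_onset_s"], dtype=float)
    duration = float(trials["probe_onset_s"].iloc[-1]
                     + trials["probe_duration_s"].iloc[-1] + 6.0)
    n = int(np.ceil(duration * rate))
    data = np.empty((layout.n_channels, n))
    for c in range(layout.n_channels):
        data[c] = _powerlaw_noise(rng, n, rate, noise_exponent)

    true_phases = wrap_phase(rng.uniform(-np.pi, np.pi, size=speech.size))
    amp = effect.oscillation_amplitude
    t = np.arange(n) / rate
    ci = layout.index(effect.locus_channel)
    gains = {ci: 1.0}
    if amp > 0 and spatial_spread > 0:
        from .cluster import electrode_adjacency
        for c2 in electrode_adjacency(layout).neighbors[ci]:
            gains[c2] = spatial_spread
    # Oscillation confined to a window comfortably covering the epoch grid;
    # windows of consecutive trials never overlap under the task timing.
    w0, w1 = -2.5, 2.0
    for i, s in enumerate(speech):
        anchor = s + effect.locus_time
        i0 = max(0, int(np.round((s + w0) * rate)))
        i1 = min(n, int(np.round((s + w1) * rate)))
        seg_t = t[i0:i1]
        env = np.ones(seg_t.size)
        ramp = int(0.25 * rate)  # cosine ramps to limit spectral splatter
        if ramp > 0 and seg_t.size > 2 * ramp:
            hann = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
            env[:ramp] = hann
            env[-ramp:] = hann[::-1]
        if amp > 0:
            wave = env * np.cos(2 * np.pi * effect.locus_freq * (seg_t - anchor)
                                + true_phases[i])
            for c2, g in gains.items():
                data[c2, i0:i1] += amp * g * wave
    eeg = EEGRecording(data=data, rate=rate, channel_names=list(layout.names),
                       montage=layout.positions)
    return eeg, true_phases


def gen_phase_dependent_behavior(true_phases, effect: EffectSpec, seed: int,
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Draw reaction times and correctness from the generative cosine model.

    Returns ``(rt_ms, correct)``; RTs exceeding the 2 s response window are
    set to NaN (null — the trial is recorded but unusable downstream).
    """
    theta = np.asarray(true_phases, dtype=float).ravel()
    rng = rng_from(seed)
    mean_log = (effect.baseline_B
                + effect.amplitude_A * np.cos(theta + effect.tau))
    log_rt = mean_log + effect.rt_noise_sd * rng.standard_normal(theta.size)
    rt = 10.0 ** log_rt
    rt[rt > RESPONSE_WINDOW_MS] = np.nan
    p = np.clip(effect.accuracy_base
                + effect.accuracy_mod * np.cos(theta + effect.tau), 0.0, 1.0)
    correct = rng.random(theta.size) < p
    return rt, correct


@dataclass
class StudyDataset:
    """A synthetic cohort: per-participant recordings, trials and ground truth."""

    participants: list[tuple[EEGRecording, pd.DataFrame]]
    effect: EffectSpec
    seed: int
    true_phases: list[np.ndarray]
    layout: ChannelLayout = None  # type: ignore[assignment]

    @property
    def n_participants(self) -> int:
        return len(self.participants)


def gen_study(n_participants: int, n_trials: int, effect: EffectSpec,
              seed: int, rate: float = 500.0, n_channels: int = 30,
              noise_exponent: float = 1.0) -> StudyDataset:
    """Generate a full cohort with per-participant seeds split from ``seed``.

    Participant ``p`` uses child seeds derived by the documented arithmetic
    splitting rule, so any participant can be regenerated in isolation.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    layout = gen_montage(n_channels)
    participants = []
    phases_all = []
    for p in range(n_participants):
        s_trials = split_seed(seed, 3 * p)
        s_eeg = split_seed(seed, 3 * p + 1)
        s_beh = split_seed(seed, 3 * p + 2)
        trials = gen_trials(n_trials, seed=s_trials)
        eeg, phases = gen_oscillatory_eeg(layout, trials, effect, rate=rate,
                                          noise_exponent=noise_exponent,
                                          seed=s_eeg)
        rt, correct = gen_phase_dependent_behavior(phases, effect, seed=s_beh)
        trials = trials.assign(rt_ms=rt, correct=pd.array(correct, dtype="boolean"))
        participants.append((eeg, trials))
        phases_all.append(phases)
    return StudyDataset(participants=participants, effect=effect, seed=seed,
                        true_phases=phases_all, layout=layout)


def gen_phase_field(n_trials: int, n_channels: int, freqs, times, seed: int,
                    locus=None, true_phases=None,
                    anchor_time: float = 0.0) -> np.ndarray:
    """Directly simulate epoched phase on the analysis grid.

    Produces trials x channels x freqs x times phases as sampled oscillations
    ``theta = wrap(2 pi f (t - t0) + phi)`` with the offset ``phi`` drawn
    uniformly and independently per (trial, channel, frequency) — uniform
    across trials, temporally coherent within a trial, matching what the
    wavelet path yields for trial-random oscillators.  Used by large pipeline
    simulations where synthesizing and decomposing raw EEG for every study
    would be wasteful; the raw path is validated separately.

    When ``locus=(channels, freq_idx)`` and ``true_phases`` are given, the
    offsets of the listed channel(s) at that frequency are replaced so the
    phase at the grid time nearest 0 equals ``true_phases`` per trial;
    passing the locus channel together with its montage neighbors emulates
    the spatial spread of a volume-conducted scalp source.
    """
    freqs = np.asarray(freqs, dtype=float)
    times = np.asarray(times, dtype=float)
    rng = rng_from(seed)
    phi = rng.uniform(-np.pi, np.pi,
                      size=(n_trials, n_channels, freqs.size))
    if locus is not None:
        if true_phases is None:
            raise ValueError("true_phases required with locus")
        chans, fi = locus
        chans = [chans] if np.isscalar(chans) else list(chans)
        anchor = times[np.argmin(np.abs(times - anchor_time))]
        for ci in chans:
            phi[:, ci, fi] = (np.asarray(true_phases, dtype=float)
                              - 2 * np.pi * freqs[fi] * anchor)
    theta = (2 * np.pi * freqs[None, None, :, None] * times[None, None, None, :]
             + phi[..., None])
    return wrap_phase(theta)


def gen_bold(power_series, dt: float, beta_true: float, TR: float = 2.0,
             n_voxels: int = 100, noise_sd: float = 0.5,
             active_fraction: float = 0.5, seed: int = 0,
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthesize voxel x scan BOLD data driven by an EEG power series.

    Active voxels (the first ``round(active_fraction * n_voxels)``) respond
    as ``beta_true`` times the HRF-convolved z-scored power sampled at scan
    times ``0, TR, 2 TR, ...``; the rest are pure noise (beta 0).

    Returns ``(Y, active_mask, scan_times)``.
    """
    power = np.asarray(power_series, dtype=float).ravel()
    if TR <= 0:
        raise ValueError("TR must be positive")
    if power.size * dt <= TR:
        raise ValueError("power series must span more than one TR")
    rng = rng_from(seed)
    scan_times = np.arange(0.0, power.size * dt - 1e-9, TR)
    reg = build_eeg_regressor(power, scan_times, dt)
    n_active = int(round(active_fraction * n_voxels))
    active = np.zeros(n_voxels, dtype=bool)
    active[:n_active] = True
    Y = noise_sd * rng.standard_normal((n_voxels, scan_times.size))
    Y[active] += beta_true * reg[None, :]
    return Y, active, scan_times
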