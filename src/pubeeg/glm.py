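"""EEG-informed fMRI GLM: HRF-bridged power regressors and voxelwise OLS.

Band-limited EEG power is z-transformed, convolved with the canonical
hemodynamic response function to bridge the temporal gap between EEG and
BOLD, and subsampled at scan times to form a regressor.  The voxelwise model

    Y = X beta + eps

is fitted per participant by ordinary least squares (fixed effects), and
participant-level coefficients enter a random-effects group analysis as a
one-sample t-test.  The design matrix holds the EEG-power regressor(s), a
task regressor (probe boxcar convolved with the HRF), optional nuisance
columns (six head-motion parameters), and an intercept.

Spatial preprocessing and corrected inference are out of scope: the module
consumes already-shaped voxels x scans matrices and reports uncorrected
group t-maps (an optional Benjamini-Hochberg FDR helper is provided as a
convenience and is not part of the reference procedure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

__all__ = [
    "HRFParams",
    "GLMDesign",
    "GLMResult",
    "EEGInformedGLM",
    "canonical_hrf",
    "build_eeg_regressor",
    "build_task_regressor",
    "make_design",
    "glm_fit",
    "group_onesample_t",
    "band_power_series",
    "DegenerateRegressorError",
]


class DegenerateRegressorError(ValueError):
    pass


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF parameterized by its landmarks.

    Response gamma peaking at ``peak_s``, undershoot gamma peaking at
    ``undershoot_s``, peak-to-undershoot amplitude ratio ``ratio``, support
    truncated at ``length_s``.  Gamma shapes are ``peak/scale + 1`` so the
    modes land exactly on the stated landmarks (scale 1 s).
    """

    peak_s: float = 6.0
    undershoot_s: float = 16.0
    ratio: float = 6.0
    length_s: float = 32.0
    scale_s: float = 1.0


def canonical_hrf(dt: float, params: HRFParams = HRFParams()) -> np.ndarray:
    """Sampled canonical HRF kernel, peak-normalized to 1.

    ``kernel[0]`` (t=0) is 0 and the kernel is identically zero beyond the
    support length.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, params.length_s + dt / 2, dt)
    a1 = params.peak_s / params.scale_s + 1.0
    a2 = params.undershoot_s / params.scale_s + 1.0
    h = (spstats.gamma.pdf(t, a=a1, scale=params.scale_s)
         - spstats.gamma.pdf(t, a=a2, scale=params.scale_s) / params.ratio)
    h[t > params.length_s] = 0.0
    return h / h.max()


def _hrf_convolve(series: np.ndarray, dt: float, params: HRFParams) -> np.ndarray:
    kernel = canonical_hrf(dt, params)
    # Causal convolution, trimmed to the input length.
    return np.convolve(series, kernel)[:series.size]


def build_eeg_regressor(power_ts, scan_times, dt: float,
                        params: HRFParams = HRFParams()) -> np.ndarray:
    """EEG-power regressor: z-transform, HRF-convolve, sample at scan times."""
    power = np.asarray(power_ts, dtype=float).ravel()
    scan_times = np.asarray(scan_times, dtype=float).ravel()
    sd = power.std()
    if sd == 0:
        raise DegenerateRegressorError("power series has zero variance")
    z = (power - power.mean()) / sd
    conv = _hrf_convolve(z, dt, params)
    t = np.arange(power.size) * dt
    if scan_times.min() < t[0] - 1e-9 or scan_times.max() > t[-1] + 1e-9:
        raise ValueError("scan times fall outside the power series coverage")
    return np.interp(scan_times, t, conv)


def build_task_regressor(probe_onsets, probe_durations, scan_times, dt: float,
                         params: HRFParams = HRFParams()) -> np.ndarray:
    """Task regressor: probe-presentation boxcars convolved with the HRF."""
    onsets = np.atleast_1d(np.asarray(probe_onsets, dtype=float))
    durs = np.broadcast_to(np.asarray(probe_durations, dtype=float), onsets.shape)
    scan_times = np.asarray(scan_times, dtype=float).ravel()
    if np.any(durs < 0):
        raise ValueError("durations must be non-negative")
    t_end = max(scan_times.max(), (onsets + durs).max()) + dt
    n = int(np.ceil(t_end / dt)) + 1
    box = np.zeros(n)
    for o, d in zip(onsets, durs):
        i0 = int(np.round(o / dt))
        i1 = max(i0 + 1, int(np.round((o + d) / dt)))  # impulse for zero duration
        box[i0:i1] = 1.0
    conv = _hrf_convolve(box, dt, params)
    return np.interp(scan_times, np.arange(n) * dt, conv)


def band_power_series(tf_power: np.ndarray, freqs, channel_names,
                      electrodes, target_freq: float) -> np.ndarray:
    """Mean linear-scale power over an electrode set at the nearest grid
    frequency.

    ``tf_power`` is log10 power (channels x freqs x times); the electrode
    average is taken on the linear scale at the frequency bin closest to
    ``target_freq`` (log-grid bins do not land exactly on round frequencies).
    """
    freqs = np.asarray(freqs, dtype=float)
    fi = int(np.argmin(np.abs(freqs - target_freq)))
    idx = [list(channel_names).index(e) for e in electrodes]
    return (10.0 ** tf_power[idx, fi, :]).mean(axis=0)


@dataclass
class GLMDesign:
    """Design matrix with named columns; exactly one intercept column."""

    X: np.ndarray
    names: list[str]
    TR: float

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("X columns must match names")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("design matrix must be finite")
        if self.names.count("intercept") != 1:
            raise ValueError("design must contain exactly one intercept column")

    def column(self, name: str) -> int:
        return self.names.index(name)


def make_design(eeg_regressors: dict, task_regressor=None, motion=None,
                TR: float = 2.0) -> GLMDesign:
    """Assemble the standard design: EEG power, task, motion, intercept."""
    cols, names = [], []
    for name, reg in eeg_regressors.items():
        cols.append(np.asarray(reg, dtype=float).ravel())
        names.append(name)
    if task_regressor is not None:
        cols.append(np.asarray(task_regressor, dtype=float).ravel())
        names.append("task")
    if motion is not None:
        m = np.asarray(motion, dtype=float)
        if m.ndim != 2 or m.shape[1] != 6:
            raise ValueError("motion must be scans x 6")
        for j in range(6):
            cols.append(m[:, j])
            names.append(f"motion{j + 1}")
    n = cols[0].size
    cols.append(np.ones(n))
    names.append("intercept")
    return GLMDesign(X=np.column_stack(cols), names=names, TR=TR)


@dataclass
class GLMResult:
    """Voxelwise OLS estimates with residual variance and t-statistics."""

    beta: np.ndarray        # voxels x regressors
    sigma2: np.ndarray      # voxels
    df_resid: int
    design: GLMDesign

    def params(self, name: str) -> np.ndarray:
        return self.beta[:, self.design.column(name)]

    def tvalues(self, name: str) -> np.ndarray:
        j = self.design.column(name)
        XtX_inv = np.linalg.inv(self.design.X.T @ self.design.X)
        se = np.sqrt(self.sigma2 * XtX_inv[j, j])
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta[:, j] / se

    def summary(self) -> str:
        lines = ["Voxelwise GLM (OLS, fixed effects)",
                 "=" * 40,
                 f"{'voxels':<20}{self.beta.shape[0]:>10d}",
                 f"{'scans':<20}{self.design.X.shape[0]:>10d}",
                 f"{'residual df':<20}{self.df_resid:>10d}"]
        for name in self.design.names:
            b = self.params(name)
            lines.append(f"beta[{name:<10s}] mean={b.mean():+.5f}  sd={b.std():.5f}")
        return "\n".join(lines)


def glm_fit(Y, design: GLMDesign) -> GLMResult:
    """Ordinary least squares per voxel (``Y`` is voxels x scans)."""
    Y = np.asarray(Y, dtype=float)
    X = design.X
    if Y.shape[1] != X.shape[0]:
        raise ValueError("scan counts of Y and design differ")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Name the offending columns via near-zero diagonal of the R factor.
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [design.names[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (k, voxels)
    resid = Y.T - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / df
    return GLMResult(beta=beta.T, sigma2=sigma2, df_resid=df, design=design)


class EEGInformedGLM:
    """Model object: voxel x scan BOLD matrix plus a named design.

    ``fit()`` returns a :class:`GLMResult`; this is the per-participant
    fixed-effects stage of the two-level analysis.
    """

    def __init__(self, Y, design: GLMDesign):
        self.Y = np.asarray(Y, dtype=float)
        self.design = design

    def fit(self) -> GLMResult:
        return glm_fit(self.Y, self.design)


def group_onesample_t(betas) -> tuple[np.ndarray, int]:
    """Random-effects group stage: one-sample t against 0 per voxel.

    ``betas`` is participants x voxels.  Returns ``(t, df)`` with
    ``df = n - 1``.  Degenerate voxels (zero between-participant variance)
    get t = 0 when the mean is also 0 and +/-inf otherwise.
    """
    b = np.asarray(betas, dtype=float)
    if b.ndim != 2 or b.shape[0] < 2:
        raise ValueError("need a participants x voxels matrix with n >= 2")
    n = b.shape[0]
    mean = b.mean(axis=0)
    sd = b.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)),
                     np.where(mean == 0, 0.0, np.sign(mean) * np.inf))
    return t, n - 1


def fdr_bh(pvals, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg rejection mask (optional convenience)."""
    p = np.asarray(pvals, dtype=float).ravel()
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    k = np.max(np.where(passed)[0]) + 1 if np.any(passed) else 0
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    return mask
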