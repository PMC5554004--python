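"""Phase-utility on behavior (PUB): cosine regression of behavior on EEG phase.

The central statistic of the package.  Behavioral performance ``y`` (log10
reaction time per trial, or accuracy per phase bin) is regressed on the
instantaneous phase ``theta`` of an ongoing oscillation,

    y = A * cos(theta + tau) + B + noise,      0 <= tau <= pi,

and the PUB is the fitted amplitude ``|A|``.  A larger PUB means behavior
depends more strongly on the oscillatory phase.  The fit is solved in closed
form through the linearization

    A*cos(theta + tau) = a*cos(theta) + b*sin(theta),
    a = A*cos(tau),  b = -A*sin(tau),

so a single ordinary least-squares solve yields (a, b, B), from which
|A| = hypot(a, b) and tau follows, with the sign of A absorbing the mapping of
tau into [0, pi].

The estimate is only meaningful when the phases are approximately uniform
across trials: under phase locking the design matrix becomes ill conditioned.
Fits therefore carry a conditioning flag fed by a Rayleigh uniformity test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import wrap_phase

__all__ = [
    "CosineFit",
    "UniformityReport",
    "PhaseBehaviorModel",
    "PhaseBehaviorResult",
    "fit_cosine",
    "fit_cosine_grid",
    "optimal_phase",
    "pub_rt",
    "pub_accuracy",
    "circular_mean_index",
    "rayleigh_test",
    "rayleigh_p",
    "check_phase_uniformity",
]


class InsufficientDataError(ValueError):
    pass


class EmptyBinError(ValueError):
    pass


class UndefinedOptimumError(ValueError):
    pass


# Mean resultant length above which the three-column design is treated as
# ill conditioned regardless of sample size (phases nearly collapsed).
_LOCKING_RBAR = 0.9
# Rayleigh alpha used for the conditioning warning on larger samples.
_LOCKING_ALPHA = 0.01


@dataclass(frozen=True)
class CosineFit:
    """Closed-form least-squares fit of ``y = A cos(theta + tau) + B``.

    ``pub`` is always ``|A|``; the signed amplitude ``A`` together with
    ``tau`` in ``[0, pi]`` reproduces the fitted curve.
    """

    A: float
    tau: float
    B: float
    pub: float
    n: int
    rss: float
    ill_conditioned: bool = False

    def predict(self, phases):
        return self.A * np.cos(np.asarray(phases) + self.tau) + self.B


@dataclass(frozen=True)
class UniformityReport:
    n: int
    Z: float
    p: float
    flag: str  # "ok" | "phase-locked"


def _canonical_amplitude(a: float, b: float) -> tuple[float, float]:
    """Map linearized coefficients (a, b) to signed A and tau in [0, pi]."""
    amp = float(np.hypot(a, b))
    if amp == 0.0:
        return 0.0, 0.0
    tau_raw = float(np.arctan2(-b, a))  # in (-pi, pi]
    if tau_raw >= 0.0:
        return amp, tau_raw
    return -amp, tau_raw + np.pi


def fit_cosine(phases, y) -> CosineFit:
    """Fit the PUB cosine model to per-observation phases and behavior.

    Parameters
    ----------
    phases : array-like of float
        Instantaneous phases in radians, one per observation.
    y : array-like of float
        Behavioral measure per observation (same length).

    Returns
    -------
    CosineFit
        With ``pub = |A|``, ``tau`` in [0, pi], and a conditioning flag set
        when the phase sample is concentrated enough to make the linear
        system unreliable.
    """
    theta = np.asarray(phases, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if theta.shape != yv.shape:
        raise ValueError("phases and y must have the same length")
    n = theta.size
    if n < 3:
        raise InsufficientDataError(f"need at least 3 observations, got {n}")
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(yv))):
        raise ValueError("phases and y must be finite")

    X = np.column_stack([np.cos(theta), np.sin(theta), np.ones(n)])
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    a, b, intercept = (float(v) for v in beta)
    resid = yv - X @ beta
    rss = float(resid @ resid)

    A, tau = _canonical_amplitude(a, b)

    rbar = float(np.abs(np.mean(np.exp(1j * theta))))
    ill = rbar >= _LOCKING_RBAR
    if not ill and n >= 8:
        _, p = rayleigh_test(theta)
        ill = p < _LOCKING_ALPHA

    return CosineFit(A=A, tau=tau, B=intercept, pub=abs(A), n=n, rss=rss,
                     ill_conditioned=bool(ill))


def fit_cosine_grid(phases, y):
    """Vectorized cosine fits over a stack of grid points sharing one ``y``.

    Parameters
    ----------
    phases : ndarray, shape (n_trials, ...)
        Phases per trial at each grid point; trailing axes index the grid.
    y : ndarray, shape (n_trials,) or (n_trials, n_resamples)
        Behavior vector, or a matrix of resampled behavior vectors (used for
        surrogate construction — every column is fitted at every point).

    Returns
    -------
    pub, tau, B : ndarrays
        With shape ``grid_shape`` (or ``grid_shape + (n_resamples,)`` when
        ``y`` is 2-D).  ``tau`` follows the [0, pi] convention via the signed
        amplitude, but only ``pub = |A|`` and ``tau`` are returned here; use
        :func:`fit_cosine` for full single-point results.
    """
    theta = np.asarray(phases, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = theta.shape[0]
    grid_shape = theta.shape[1:]
    P = int(np.prod(grid_shape)) if grid_shape else 1
    th = theta.reshape(n, P)

    C = np.cos(th)
    S = np.sin(th)

    # Normal equations per grid point: M (P,3,3), rhs (P,3[,K]).
    M = np.empty((P, 3, 3))
    M[:, 0, 0] = np.einsum("ij,ij->j", C, C)
    M[:, 0, 1] = M[:, 1, 0] = np.einsum("ij,ij->j", C, S)
    M[:, 0, 2] = M[:, 2, 0] = C.sum(axis=0)
    M[:, 1, 1] = np.einsum("ij,ij->j", S, S)
    M[:, 1, 2] = M[:, 2, 1] = S.sum(axis=0)
    M[:, 2, 2] = n

    squeeze = yv.ndim == 1
    Y = yv[:, None] if squeeze else yv  # (n, K)
    rhs = np.stack([C.T @ Y, S.T @ Y, np.broadcast_to(Y.sum(axis=0), (P, Y.shape[1]))],
                   axis=1)  # (P, 3, K)
    try:
        beta = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        beta = np.linalg.pinv(M) @ rhs

    a, b, B = beta[:, 0], beta[:, 1], beta[:, 2]  # each (P, K)
    pub = np.hypot(a, b)
    tau_raw = np.arctan2(-b, a)
    tau = np.where(tau_raw >= 0.0, tau_raw, tau_raw + np.pi)

    if squeeze:
        pub, tau, B = pub[:, 0], tau[:, 0], B[:, 0]
        return pub.reshape(grid_shape), tau.reshape(grid_shape), B.reshape(grid_shape)
    K = Y.shape[1]
    return (pub.reshape(grid_shape + (K,)), tau.reshape(grid_shape + (K,)),
            B.reshape(grid_shape + (K,)))


def optimal_phase(fit: CosineFit, objective: str = "minimize") -> float:
    """Phase at which the fitted cosine predicts extremal behavior.

    For reaction times the optimum minimizes the curve: with a positive
    amplitude the optimal phase is ``pi - tau``; with a negative amplitude it
    is ``-tau``.  For accuracy pass ``objective="maximize"`` to get the
    antipode.  Result wrapped into (-pi, pi].
    """
    if objective not in ("minimize", "maximize"):
        raise ValueError("objective must be 'minimize' or 'maximize'")
    if fit.pub == 0.0:
        raise UndefinedOptimumError("flat fit has no optimal phase")
    phi = np.pi - fit.tau if fit.A > 0 else -fit.tau
    if objective == "maximize":
        phi = phi + np.pi
    return float(wrap_phase(phi))


def pub_rt(phases, rt_ms, correct=None, correct_only: bool = False) -> CosineFit:
    """PUB of reaction time: cosine fit of log10(RT in ms) on phase.

    All responded trials are used by default (incorrect trials included, which
    preserves trial count and statistical power); pass ``correct_only=True``
    with the ``correct`` flags to restrict the fit to correct trials.
    """
    theta = np.asarray(phases, dtype=float).ravel()
    rt = np.asarray(rt_ms, dtype=float).ravel()
    if np.any(~np.isfinite(rt)) or np.any(rt <= 0):
        raise ValueError("rt_ms must be positive and finite (drop null RTs first)")
    if correct_only:
        if correct is None:
            raise ValueError("correct flags required when correct_only=True")
        mask = np.asarray(correct, dtype=bool).ravel()
        theta, rt = theta[mask], rt[mask]
    return fit_cosine(theta, np.log10(rt))


def pub_accuracy(phases, correct, n_bins: int = 8) -> CosineFit:
    """PUB of accuracy: per-phase-bin accuracy fitted by the cosine model.

    The circle (-pi, pi] is split into ``n_bins`` equal-width bins; the
    accuracy within each bin is regressed on the bin-center phase.  An empty
    bin is an error — request fewer bins instead.
    """
    theta = wrap_phase(np.asarray(phases, dtype=float).ravel())
    corr = np.asarray(correct, dtype=bool).ravel()
    if theta.size != corr.size:
        raise ValueError("phases and correct must align")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    # (-pi, pi] half-open on the left: assign by right-closed bins.
    idx = np.clip(np.searchsorted(edges, theta, side="left") - 1, 0, n_bins - 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    acc = np.empty(n_bins)
    for k in range(n_bins):
        sel = idx == k
        if not np.any(sel):
            raise EmptyBinError(f"phase bin {k} is empty")
        acc[k] = corr[sel].mean()
    return fit_cosine(centers, acc)


def accuracy_pub_grid(phases, correct, n_bins: int = 8):
    """Vectorized binned-accuracy PUB over a grid of phase samples.

    ``phases``: trials x grid; ``correct``: per-trial flags.  At every grid
    point trials are assigned to ``n_bins`` equal-width phase bins and the
    per-bin accuracy is fitted by the cosine model on the bin centers.

    Returns ``(pub, tau)`` arrays with the grid shape.  Raises
    :class:`EmptyBinError` if any bin at any point is empty.
    """
    theta = wrap_phase(np.asarray(phases, dtype=float))
    corr = np.asarray(correct, dtype=float).ravel()
    n = theta.shape[0]
    grid_shape = theta.shape[1:]
    P = int(np.prod(grid_shape)) if grid_shape else 1
    th = theta.reshape(n, P)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, th, side="left") - 1, 0, n_bins - 1)
    comb = idx + n_bins * np.arange(P)[None, :]
    counts = np.bincount(comb.ravel(), minlength=n_bins * P)
    if np.any(counts == 0):
        raise EmptyBinError("empty phase bin at some grid point")
    hits = np.bincount(comb.ravel(),
                       weights=np.broadcast_to(corr[:, None], (n, P)).ravel(),
                       minlength=n_bins * P)
    acc = (hits / counts).reshape(P, n_bins).T  # (n_bins, P)
    centers = (edges[:-1] + edges[1:]) / 2.0
    X = np.column_stack([np.cos(centers), np.sin(centers), np.ones(n_bins)])
    beta, *_ = np.linalg.lstsq(X, acc, rcond=None)
    pub = np.hypot(beta[0], beta[1])
    tau_raw = np.arctan2(-beta[1], beta[0])
    tau = np.where(tau_raw >= 0.0, tau_raw, tau_raw + np.pi)
    return pub.reshape(grid_shape), tau.reshape(grid_shape)


def circular_mean_index(phases, rt_scaled) -> tuple[float, float]:
    """Weighted circular mean (1/N) * sum r_i * exp(i*theta_i).

    A comparison index for the PUB: with behavior min-max scaled to [0, 1] as
    weights, its modulus tracks phase dependence of behavior — but it also
    grows whenever the phases themselves are concentrated, regardless of
    behavior, which is the failure mode the PUB avoids.

    Returns ``(modulus, angle)``.
    """
    theta = np.asarray(phases, dtype=float).ravel()
    r = np.asarray(rt_scaled, dtype=float).ravel()
    if theta.size == 0:
        raise ValueError("empty input")
    if theta.shape != r.shape:
        raise ValueError("phases and weights must align")
    if np.any(r < -1e-12) or np.any(r > 1 + 1e-12):
        raise ValueError("weights must lie in [0, 1]")
    z = np.mean(r * np.exp(1j * theta))
    return float(np.abs(z)), float(np.angle(z))


def rayleigh_p(Z: float, n: int) -> float:
    """Rayleigh-test p-value by Zar's small-sample approximation.

    ``p = exp( sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n) )`` with ``R = sqrt(Z*n)``
    the resultant length.  Monotone decreasing in Z; clipped to [0, 1].
    """
    R2 = float(Z) * n
    p = np.exp(np.sqrt(1.0 + 4 * n + 4.0 * (n * n - R2)) - (1.0 + 2 * n))
    return float(min(max(p, 0.0), 1.0))


def rayleigh_test(angles) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns ``(Z, p)`` with ``Z = n * Rbar**2`` where ``Rbar`` is the mean
    resultant length, and the p-value from :func:`rayleigh_p`.
    """
    a = np.asarray(angles, dtype=float).ravel()
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 angles")
    rbar = float(np.abs(np.mean(np.exp(1j * a))))
    Z = n * rbar * rbar
    return float(Z), rayleigh_p(Z, n)


def check_phase_uniformity(phases, alpha: float = _LOCKING_ALPHA) -> UniformityReport:
    """Validity check for PUB: Rayleigh test of the trial-phase distribution.

    Flags ``"phase-locked"`` at the given alpha (default 0.01); the same
    criterion drives the ill-conditioning warning attached to fits.
    """
    theta = np.asarray(phases, dtype=float).ravel()
    if theta.size < 8:
        raise InsufficientDataError("need at least 8 phases for the uniformity check")
    Z, p = rayleigh_test(theta)
    flag = "ok" if p > alpha else "phase-locked"
    return UniformityReport(n=theta.size, Z=Z, p=p, flag=flag)


class PhaseBehaviorModel:
    """Cosine-regression model of behavioral performance on oscillatory phase.

    Parameters
    ----------
    phases : array-like
        Instantaneous phase per observation (radians).
    y : array-like
        Behavioral measure per observation.

    Examples
    --------
    >>> import numpy as np
    >>> theta = np.linspace(-np.pi, np.pi, 100, endpoint=False)
    >>> y = 3.0 + 0.05 * np.cos(theta + 1.0)
    >>> res = PhaseBehaviorModel(theta, y).fit()
    >>> round(res.pub, 6), round(res.tau, 6)
    (0.05, 1.0)
    """

    def __init__(self, phases, y):
        self.phases = np.asarray(phases, dtype=float).ravel()
        self.y = np.asarray(y, dtype=float).ravel()

    @classmethod
    def from_reaction_times(cls, phases, rt_ms, correct=None,
                            correct_only: bool = False) -> "PhaseBehaviorModel":
        """Build the model from reaction times in ms (log10-transformed).

        Trials with null (non-finite) RT are dropped; incorrect trials are
        kept unless ``correct_only``.
        """
        theta = np.asarray(phases, dtype=float).ravel()
        rt = np.asarray(rt_ms, dtype=float).ravel()
        keep = np.isfinite(rt)
        if correct_only:
            if correct is None:
                raise ValueError("correct flags required when correct_only=True")
            keep &= np.asarray(correct, dtype=bool).ravel()
        if np.any(rt[keep] <= 0):
            raise ValueError("reaction times must be positive")
        return cls(theta[keep], np.log10(rt[keep]))

    @classmethod
    def from_accuracy(cls, phases, correct, n_bins: int = 8) -> "PhaseBehaviorModel":
        """Build the model from correctness flags via equal-width phase bins."""
        theta = wrap_phase(np.asarray(phases, dtype=float).ravel())
        corr = np.asarray(correct, dtype=bool).ravel()
        edges = np.linspace(-np.pi, np.pi, n_bins + 1)
        idx = np.clip(np.searchsorted(edges, theta, side="left") - 1, 0, n_bins - 1)
        centers = (edges[:-1] + edges[1:]) / 2.0
        acc = np.empty(n_bins)
        for k in range(n_bins):
            sel = idx == k
            if not np.any(sel):
                raise EmptyBinError(f"phase bin {k} is empty")
            acc[k] = corr[sel].mean()
        return cls(centers, acc)

    def fit(self) -> "PhaseBehaviorResult":
        return PhaseBehaviorResult(self, fit_cosine(self.phases, self.y))


@dataclass
class PhaseBehaviorResult:
    """Fitted PUB model: estimates, diagnostics and summary."""

    model: PhaseBehaviorModel
    _fit: CosineFit
    uniformity: UniformityReport | None = field(default=None)

    def __post_init__(self):
        if self.uniformity is None and self.model.phases.size >= 8:
            self.uniformity = check_phase_uniformity(self.model.phases)

    @property
    def pub(self) -> float:
        return self._fit.pub

    @property
    def amplitude(self) -> float:
        return self._fit.A

    @property
    def tau(self) -> float:
        return self._fit.tau

    @property
    def intercept(self) -> float:
        return self._fit.B

    @property
    def rss(self) -> float:
        return self._fit.rss

    @property
    def nobs(self) -> int:
        return self._fit.n

    @property
    def ill_conditioned(self) -> bool:
        return self._fit.ill_conditioned

    def optimal_phase(self, objective: str = "minimize") -> float:
        return optimal_phase(self._fit, objective)

    def predict(self, phases):
        return self._fit.predict(phases)

    def summary(self) -> str:
        lines = [
            "Phase-Utility on Behavior (cosine regression)",
            "=" * 46,
            f"{'n obs':<22}{self.nobs:>12d}",
            f"{'PUB |A|':<22}{self.pub:>12.6f}",
            f"{'signed amplitude A':<22}{self.amplitude:>12.6f}",
            f"{'tau [rad, 0..pi]':<22}{self.tau:>12.6f}",
            f"{'intercept B':<22}{self.intercept:>12.6f}",
            f"{'residual SS':<22}{self.rss:>12.6f}",
        ]
        if self.pub > 0:
            lines.append(f"{'optimal phase (min y)':<22}{self.optimal_phase():>12.6f}")
        if self.uniformity is not None:
            lines.append(
                f"{'phase uniformity':<22}{self.uniformity.flag:>12s}"
                f"  (Rayleigh Z={self.uniformity.Z:.4f}, p={self.uniformity.p:.4f})"
            )
        if self.ill_conditioned:
            lines.append("warning: phase distribution concentrated; "
                         "estimate may be unreliable")
        return "\n".join(lines)
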