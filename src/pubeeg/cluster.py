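"""Group-level inference for PUB grids.

The chain implemented here:

1. Per participant, a surrogate PUB grid is built by permuting the behavior
   vector across trials (phases fixed) 200 times and taking the median PUB at
   every grid point — the median because the PUB is an absolute value, so its
   null distribution is asymmetric.
2. Pointwise two-sample t-maps compare original vs surrogate PUB across
   participants over the (channel, frequency, time) grid.
3. Suprathreshold points (one-sided positive by default; the hypothesis is
   that the PUB exceeds its surrogate) are grouped into clusters by
   adjacency: +/-1 time step, +/-1 frequency step, or neighboring electrode.
   Clusters spanning fewer than 2 distinct electrodes are excluded.
4. Cluster-level significance comes from a max-statistic permutation null:
   the 2N participant grids (original + surrogate) are pooled and randomly
   re-divided into two groups of N, the t-map and maximum cluster statistic
   recomputed each time.
5. Leave-one-participant-out (LOPO) selection picks, for each held-out
   participant, the maximum-t point of the matching cluster computed from the
   other N-1 participants — avoiding double dipping when that point's phase
   is used for the participant's own phase-binned reaction-time analysis
   (one-way repeated-measures ANOVA over six phase bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from ._utils import rng_from
from .pub import fit_cosine_grid

__all__ = [
    "AdjacencyGraph",
    "TMap",
    "Cluster",
    "ClusterSet",
    "SelectedPoint",
    "AnovaResult",
    "ClusterPermutationTest",
    "electrode_adjacency",
    "compute_pub_grid",
    "surrogate_pub",
    "surrogate_pub_grid",
    "pub_tmap",
    "t_threshold_from_p",
    "extract_clusters",
    "cluster_permutation_test",
    "lopo_select",
    "phase_bin_rt",
    "rm_anova",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric electrode neighbor structure; time/frequency adjacency is
    implicitly +/-1 grid step."""

    neighbors: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise ValueError("self-edges not allowed")
            for j in nb:
                if i not in self.neighbors[j]:
                    raise ValueError("adjacency must be symmetric")

    @property
    def n_electrodes(self) -> int:
        return len(self.neighbors)

    @classmethod
    def from_pairs(cls, n: int, pairs) -> "AdjacencyGraph":
        nb = [set() for _ in range(n)]
        for a, b in pairs:
            if a == b:
                continue
            nb[a].add(b)
            nb[b].add(a)
        return cls(tuple(tuple(sorted(s)) for s in nb))


def electrode_adjacency(layout, scale: float = 1.4) -> AdjacencyGraph:
    """Distance-based neighbor graph on the montage.

    Electrodes are neighbors when their distance is below ``scale`` times the
    median nearest-neighbor distance.  The default 1.4 keeps lattice diagonals
    (distance sqrt(2) on a unit grid) out of the neighborhood.  Template
    neighbor lists can be supplied instead via
    :meth:`AdjacencyGraph.from_pairs`.
    """
    pos = np.asarray(layout.positions, dtype=float)
    n = pos.shape[0]
    if n < 2:
        raise ValueError("need at least 2 electrodes")
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    med_nn = float(np.median(d.min(axis=1)))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
             if d[i, j] < scale * med_nn]
    return AdjacencyGraph.from_pairs(n, pairs)


@dataclass
class PUBGrid:
    """PUB and tau over the (channel, freq, time) grid for one participant."""

    pub: np.ndarray
    tau: np.ndarray
    participant: int = 0


def compute_pub_grid(phases, y, participant: int = 0) -> PUBGrid:
    """Vectorized PUB over the full grid for one participant.

    ``phases``: trials x channels x freqs x times; ``y``: behavior per trial
    (log10 RT), already restricted to responded trials.
    """
    pub, tau, _ = fit_cosine_grid(phases, np.asarray(y, dtype=float))
    return PUBGrid(pub=pub, tau=tau, participant=participant)


def surrogate_pub(phases, y, n_rep: int = 200, seed: int = 0,
                  bootstrap: bool = False) -> float:
    """Surrogate PUB at a single point: median PUB over behavior resamples.

    The behavior vector is permuted across trials (without replacement by
    default; ``bootstrap=True`` resamples with replacement) while the phases
    stay fixed, and the median of the ``n_rep`` resulting PUB values is the
    participant's surrogate.
    """
    grid = surrogate_pub_grid(np.asarray(phases, dtype=float)[:, None], y,
                              n_rep=n_rep, seed=seed, bootstrap=bootstrap)
    return float(grid[0])


def surrogate_pub_grid(phases, y, n_rep: int = 200, seed: int = 0,
                       bootstrap: bool = False) -> np.ndarray:
    """Surrogate PUB over a full grid (median across behavior resamples).

    Each of the ``n_rep`` resamples draws an independent permutation of the
    behavior vector; the same permutation is applied at every grid point (the
    behavior is one vector per participant — permuting it per point would
    break the map's spatial coherence).
    """
    theta = np.asarray(phases, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n = theta.shape[0]
    if yv.size != n:
        raise ValueError("y must align with trials")
    rng = rng_from(seed)
    if bootstrap:
        idx = rng.integers(0, n, size=(n_rep, n))
    else:
        idx = np.argsort(rng.random((n_rep, n)), axis=1)
    Y = yv[idx].T  # (n, n_rep)
    pub, _, _ = fit_cosine_grid(theta, Y)
    return np.median(pub, axis=-1)


@dataclass
class TMap:
    """Pointwise two-sample t statistics (original vs surrogate PUB)."""

    t: np.ndarray
    df: int
    n_orig: int
    n_surr: int
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.degenerate is None:
            self.degenerate = np.zeros_like(self.t, dtype=bool)
        if self.df != self.n_orig + self.n_surr - 2:
            raise ValueError("df must equal n_orig + n_surr - 2")


def _stack(grids) -> np.ndarray:
    arrs = [g.pub if isinstance(g, PUBGrid) else np.asarray(g, dtype=float)
            for g in grids]
    return np.stack(arrs)


def _two_sample_t(g1: np.ndarray, g2: np.ndarray):
    """Pooled-variance Student t along axis 0; zero pooled variance -> t=0."""
    n1, n2 = g1.shape[0], g2.shape[0]
    m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
    v1 = g1.var(axis=0, ddof=1)
    v2 = g2.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    degenerate = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, (m1 - m2) / np.where(degenerate, 1.0, denom))
    return t, degenerate


def pub_tmap(orig, surr) -> TMap:
    """Two-sample t-map of original vs surrogate PUB across participants.

    Positive t means the original PUB exceeds the surrogate.  Points with
    zero pooled variance get t = 0 and are flagged degenerate.
    """
    g1, g2 = _stack(orig), _stack(surr)
    if g1.shape != g2.shape:
        raise ValueError("original and surrogate stacks must share a shape")
    t, degenerate = _two_sample_t(g1, g2)
    return TMap(t=t, df=g1.shape[0] + g2.shape[0] - 2,
                n_orig=g1.shape[0], n_surr=g2.shape[0], degenerate=degenerate)


def t_threshold_from_p(p: float, df: int, sided: str = "one") -> float:
    """Student-t threshold for a tail probability (one-sided positive by
    default; the alternative is PUB > surrogate)."""
    if sided == "one":
        return float(spstats.t.ppf(1.0 - p, df))
    if sided == "two":
        return float(spstats.t.ppf(1.0 - p / 2.0, df))
    raise ValueError("sided must be 'one' or 'two'")


@dataclass
class Cluster:
    """Connected suprathreshold component in (channel, freq, time) space."""

    members: np.ndarray           # (k, 3) int array of (c, f, t) indices
    stat: float                   # sum of member t-values
    n_electrodes: int
    excluded: bool                # True when spanning < min_electrodes
    p_perm: float | None = None

    @property
    def size(self) -> int:
        return self.members.shape[0]

    def electrode_set(self) -> set[int]:
        return set(int(c) for c in np.unique(self.members[:, 0]))

    def bounds(self):
        """Bounding region: electrode set, (fmin, fmax), (tmin, tmax)."""
        f = self.members[:, 1]
        t = self.members[:, 2]
        return self.electrode_set(), (int(f.min()), int(f.max())), \
            (int(t.min()), int(t.max()))


@dataclass
class ClusterSet:
    """All clusters of a map plus the permutation null when available."""

    clusters: list[Cluster]
    t_threshold: float
    min_electrodes: int
    null_max_stats: np.ndarray | None = None
    alpha: float = 0.05

    def retained(self) -> list[Cluster]:
        return [c for c in self.clusters if not c.excluded]

    def significant(self) -> list[Cluster]:
        return [c for c in self.retained()
                if c.p_perm is not None and c.p_perm < self.alpha]

    def summary(self) -> str:
        lines = [
            "Cluster-level permutation test",
            "=" * 64,
            f"point threshold t > {self.t_threshold:.4f}; "
            f"min electrodes {self.min_electrodes}; alpha {self.alpha}",
            f"{'id':>3} {'size':>6} {'elec':>5} {'stat':>10} {'p':>8}  status",
        ]
        for i, c in enumerate(self.clusters):
            p = "---" if c.p_perm is None else f"{c.p_perm:.4f}"
            status = ("excluded (<2 electrodes)" if c.excluded else
                      ("significant" if c.p_perm is not None
                       and c.p_perm < self.alpha else "n.s."))
            lines.append(f"{i:>3} {c.size:>6} {c.n_electrodes:>5} "
                         f"{c.stat:>10.3f} {p:>8}  {status}")
        if not self.clusters:
            lines.append("  (no suprathreshold clusters)")
        return "\n".join(lines)


def _cluster_points(flat_points: np.ndarray, shape, neighbors) -> list[np.ndarray]:
    """Connected components of suprathreshold points via union-find.

    Adjacency: +/-1 time index, +/-1 frequency index, or neighboring
    electrode (one dimension at a time).
    """
    C, F, T = shape
    pos = {int(p): i for i, p in enumerate(flat_points)}
    parent = list(range(len(flat_points)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    FT = F * T
    for i, p in enumerate(flat_points):
        p = int(p)
        c, rem = divmod(p, FT)
        f, t = divmod(rem, T)
        if t + 1 < T and (q := p + 1) in pos:
            union(i, pos[q])
        if f + 1 < F and (q := p + T) in pos:
            union(i, pos[q])
        for c2 in neighbors[c]:
            if c2 > c and (q := p + (c2 - c) * FT) in pos:
                union(i, pos[q])
    groups: dict[int, list[int]] = {}
    for i in range(len(flat_points)):
        groups.setdefault(find(i), []).append(i)
    return [flat_points[np.array(g)] for g in groups.values()]


def extract_clusters(tmap: TMap, t_threshold: float, adjacency: AdjacencyGraph,
                     min_electrodes: int = 2) -> ClusterSet:
    """Connected suprathreshold components with summed-t statistics.

    Components spanning fewer than ``min_electrodes`` distinct electrodes are
    kept in the set but marked excluded (no spatial expansion).
    """
    t = tmap.t
    C, F, T = t.shape
    if adjacency.n_electrodes != C:
        raise ValueError("adjacency does not match the channel dimension")
    flat = np.flatnonzero(t.ravel() > t_threshold)
    clusters: list[Cluster] = []
    if flat.size:
        tf = t.ravel()
        for comp in _cluster_points(flat, (C, F, T), adjacency.neighbors):
            c_idx = comp // (F * T)
            rem = comp % (F * T)
            members = np.column_stack([c_idx, rem // T, rem % T]).astype(int)
            n_elec = int(np.unique(c_idx).size)
            clusters.append(Cluster(members=members,
                                    stat=float(tf[comp].sum()),
                                    n_electrodes=n_elec,
                                    excluded=n_elec < min_electrodes))
    clusters.sort(key=lambda c: -c.stat)
    return ClusterSet(clusters=clusters, t_threshold=t_threshold,
                      min_electrodes=min_electrodes)


def _max_retained_stat(t_flat: np.ndarray, threshold: float, shape,
                       neighbors, min_electrodes: int) -> float:
    """Maximum summed-t over retained clusters of one (flattened) t-map."""
    flat = np.flatnonzero(t_flat > threshold)
    if flat.size < min_electrodes:  # a retained cluster needs that many points
        return 0.0
    C, F, T = shape
    FT = F * T
    best = 0.0
    for comp in _cluster_points(flat, shape, neighbors):
        if np.unique(comp // FT).size >= min_electrodes:
            s = float(t_flat[comp].sum())
            if s > best:
                best = s
    return best


def cluster_permutation_test(orig, surr, adjacency: AdjacencyGraph,
                             n_perm: int = 10000, point_p: float = 0.001,
                             min_electrodes: int = 2, alpha: float = 0.05,
                             seed: int = 0, sided: str = "one",
                             scheme: str = "pooled") -> ClusterSet:
    """Max-statistic cluster permutation test of original vs surrogate PUB.

    ``scheme="pooled"`` pools the 2N participant grids and randomly divides
    them into two groups of N per permutation.  ``scheme="within"`` instead
    flips the original/surrogate labels within each participant (a paired
    sign-flip variant; not the reference procedure).  Cluster p-values use
    the +1-corrected convention ``(1 + #{null >= stat}) / (1 + n_perm)``.
    """
    import warnings
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives coarse p-values")
    g1, g2 = _stack(orig), _stack(surr)
    N = g1.shape[0]
    shape = g1.shape[1:]
    P = int(np.prod(shape))
    df = 2 * N - 2
    threshold = t_threshold_from_p(point_p, df, sided)

    observed = pub_tmap(g1, g2)
    cs = extract_clusters(observed, threshold, adjacency, min_electrodes)

    pooled = np.concatenate([g1, g2]).reshape(2 * N, P)
    pooled2 = pooled**2
    St, Qt = pooled.sum(axis=0), pooled2.sum(axis=0)
    rng = rng_from(seed)
    null_max = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(4e6 // max(N * P, 1)) or 1))
    done = 0
    neighbors = adjacency.neighbors
    while done < n_perm:
        B = min(chunk, n_perm - done)
        if scheme == "pooled":
            sel = np.argsort(rng.random((B, 2 * N)), axis=1)[:, :N]
        elif scheme == "within":
            flips = rng.integers(0, 2, size=(B, N))
            sel = np.where(flips == 0, np.arange(N), np.arange(N) + N)
        else:
            raise ValueError("scheme must be 'pooled' or 'within'")
        S1 = pooled[sel].sum(axis=1)   # (B, P)
        Q1 = pooled2[sel].sum(axis=1)
        S2, Q2 = St - S1, Qt - Q1
        v1 = (Q1 - S1**2 / N) / (N - 1)
        v2 = (Q2 - S2**2 / N) / (N - 1)
        sp2 = (v1 + v2) / 2.0
        denom = np.sqrt(sp2 * (2.0 / N))
        with np.errstate(divide="ignore", invalid="ignore"):
            tb = np.where(denom > 0, (S1 - S2) / (N * denom), 0.0)
        for b in range(B):
            null_max[done + b] = _max_retained_stat(tb[b], threshold, shape,
                                                    neighbors, min_electrodes)
        done += B

    for c in cs.clusters:
        if not c.excluded:
            c.p_perm = float((1 + np.sum(null_max >= c.stat)) / (1 + n_perm))
    cs.null_max_stats = null_max
    cs.alpha = alpha
    return cs


class ClusterPermutationTest:
    """Object interface to the cluster permutation pipeline.

    Parameters mirror :func:`cluster_permutation_test`; ``run()`` returns the
    :class:`ClusterSet` results object.
    """

    def __init__(self, orig, surr, adjacency: AdjacencyGraph,
                 point_p: float = 0.001, min_electrodes: int = 2,
                 alpha: float = 0.05, sided: str = "one",
                 scheme: str = "pooled"):
        self.orig, self.surr = orig, surr
        self.adjacency = adjacency
        self.point_p = point_p
        self.min_electrodes = min_electrodes
        self.alpha = alpha
        self.sided = sided
        self.scheme = scheme

    def run(self, n_perm: int = 10000, seed: int = 0) -> ClusterSet:
        return cluster_permutation_test(
            self.orig, self.surr, self.adjacency, n_perm=n_perm,
            point_p=self.point_p, min_electrodes=self.min_electrodes,
            alpha=self.alpha, seed=seed, sided=self.sided, scheme=self.scheme)


@dataclass(frozen=True)
class SelectedPoint:
    """A (channel, freq, time) grid point selected for one participant."""

    channel: int
    freq: int
    time: int
    t_value: float


def _overlap(a: Cluster, b: Cluster) -> int:
    sa = set(map(tuple, a.members))
    return sum(1 for m in map(tuple, b.members) if m in sa)


def lopo_select(orig, surr, group_clusters: ClusterSet,
                adjacency: AdjacencyGraph, point_p_cv: float = 0.01,
                sided: str = "one") -> list[dict[int, SelectedPoint | None]]:
    """Leave-one-participant-out point selection.

    For each held-out participant the t-map is recomputed from the remaining
    N-1 participants, clusters are formed at the cross-validation threshold
    (p < 0.01), and each retained group cluster is matched to the CV cluster
    with maximal member overlap (ties: larger overlap fraction, then larger
    stat).  Matched CV members are restricted to the group cluster's bounding
    region (its electrode set and time-frequency bounding box) before the
    maximum-t point is selected — an automated stand-in for by-eye cluster
    correspondence.  A participant with no overlapping CV cluster is flagged
    missing (None) for that cluster.

    Returns one dict per participant mapping the index of each retained group
    cluster to its selected point.  The selection never uses the held-out
    participant's own grids.
    """
    g1, g2 = _stack(orig), _stack(surr)
    N = g1.shape[0]
    if N < 3:
        raise ValueError("LOPO needs at least 3 participants")
    retained = group_clusters.retained()
    out: list[dict[int, SelectedPoint | None]] = []
    for i in range(N):
        keep = np.arange(N) != i
        tm = pub_tmap(g1[keep], g2[keep])
        thr = t_threshold_from_p(point_p_cv, tm.df, sided)
        # No electrode-extent exclusion at the CV stage: extent filtering is a
        # group-level decision, and dropping small CV clusters would only lose
        # matches.
        cv = extract_clusters(tm, thr, adjacency, min_electrodes=1).clusters
        sel: dict[int, SelectedPoint | None] = {}
        for gi, gc in enumerate(retained):
            best = None
            best_key = (0, 0.0, -np.inf)
            for cc in cv:
                ov = _overlap(gc, cc)
                if ov == 0:
                    continue
                key = (ov, ov / cc.size, cc.stat)
                if key > best_key:
                    best_key, best = key, cc
            if best is None:
                sel[gi] = None
                continue
            elec, (f0, f1), (t0, t1) = gc.bounds()
            m = best.members
            inside = (np.isin(m[:, 0], list(elec))
                      & (m[:, 1] >= f0) & (m[:, 1] <= f1)
                      & (m[:, 2] >= t0) & (m[:, 2] <= t1))
            m = m[inside] if np.any(inside) else best.members
            tv = tm.t[m[:, 0], m[:, 1], m[:, 2]]
            k = int(np.argmax(tv))
            sel[gi] = SelectedPoint(channel=int(m[k, 0]), freq=int(m[k, 1]),
                                    time=int(m[k, 2]), t_value=float(tv[k]))
        out.append(sel)
    return out


def phase_bin_rt(phases, log_rts, optimal_phase: float,
                 n_bins: int = 6) -> np.ndarray:
    """Mean log-RT in equal-width phase bins centered on the optimal phase.

    The circle is partitioned into ``n_bins`` sextants rotated so the optimal
    phase sits at the center of bin 0; empty bins yield NaN.
    """
    theta = np.asarray(phases, dtype=float).ravel()
    y = np.asarray(log_rts, dtype=float).ravel()
    if theta.shape != y.shape:
        raise ValueError("phases and log RTs must align")
    w = 2 * np.pi / n_bins
    u = np.mod(theta - optimal_phase + w / 2.0, 2 * np.pi)
    k = np.minimum((u / w).astype(int), n_bins - 1)
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = k == b
        if np.any(sel):
            means[b] = y[sel].mean()
    return means


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    degenerate: bool = False


def rm_anova(bin_means) -> AnovaResult:
    """One-way repeated-measures ANOVA across phase bins.

    ``bin_means`` is participants x bins; participants with any missing bin
    are dropped.  With 14 participants and 6 bins the design yields
    df = (5, 65).  A zero within-participant error term is flagged degenerate
    (F undefined).
    """
    m = np.asarray(bin_means, dtype=float)
    if m.ndim != 2:
        raise ValueError("bin_means must be participants x bins")
    m = m[~np.any(np.isnan(m), axis=1)]
    n, k = m.shape
    if n < 2:
        raise ValueError("need at least 2 complete participants")
    grand = m.mean()
    ss_cond = n * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((m - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_err = ss_err / df2
    if ms_err <= 0:
        return AnovaResult(F=np.nan, df1=df1, df2=df2, p=np.nan, degenerate=True)
    F = (ss_cond / df1) / ms_err
    p = float(spstats.f.sf(F, df1, df2))
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=p)
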