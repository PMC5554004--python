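"""Group statistics: surrogates, t-maps, cluster extraction (against a
flood-fill oracle), permutation testing, LOPO selection and the RM-ANOVA."""

import numpy as np
import pytest

import pubeeg as pe


def brute_force_clusters(mask, neighbors):
    """Independent flood-fill oracle: BFS over boolean (C, F, T) mask with
    +/-1 time, +/-1 freq, electrode-neighbor connectivity."""
    C, F, T = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for c in range(C):
        for f in range(F):
            for t in range(T):
                if not mask[c, f, t] or seen[c, f, t]:
                    continue
                comp = []
                stack = [(c, f, t)]
                seen[c, f, t] = True
                while stack:
                    cc, ff, tt = stack.pop()
                    comp.append((cc, ff, tt))
                    cands = [(cc, ff, tt - 1), (cc, ff, tt + 1),
                             (cc, ff - 1, tt), (cc, ff + 1, tt)]
                    cands += [(c2, ff, tt) for c2 in neighbors[cc]]
                    for c2, f2, t2 in cands:
                        if (0 <= c2 < C and 0 <= f2 < F and 0 <= t2 < T
                                and mask[c2, f2, t2] and not seen[c2, f2, t2]):
                            seen[c2, f2, t2] = True
                            stack.append((c2, f2, t2))
                comps.append(frozenset(comp))
    return set(comps)


def tmap_from(t_array, n=14):
    t_array = np.asarray(t_array, dtype=float)
    return pe.TMap(t=t_array, df=2 * n - 2, n_orig=n, n_surr=n)


class TestSurrogate:
    def test_constant_behavior_gives_zero(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(-np.pi, np.pi, 100)
        s = pe.surrogate_pub(theta, np.full(100, 3.0), n_rep=200, seed=1)
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_null_distribution_matches_original(self):
        """Under independence the original PUB and the surrogate PUB are
        draws whose medians agree (paired difference centered on 0)."""
        rng = np.random.default_rng(1)
        diffs = []
        for s in range(200):
            theta = rng.uniform(-np.pi, np.pi, 306)
            y = rng.standard_normal(306)
            orig = pe.fit_cosine(theta, y).pub
            surr = pe.surrogate_pub(theta, y, n_rep=50, seed=s)
            diffs.append(orig - surr)
        med = np.median(diffs)
        spread = np.std(diffs)
        assert abs(med) < 0.3 * spread

    def test_strong_effect_beats_surrogate(self):
        eff = pe.EffectSpec(amplitude_A=0.3, tau=1.0, rt_noise_sd=0.05)
        rng = np.random.default_rng(2)
        wins = 0
        for s in range(50):
            theta = rng.uniform(-np.pi, np.pi, 306)
            rt, _ = pe.gen_phase_dependent_behavior(theta, eff, seed=500 + s)
            keep = np.isfinite(rt)
            y = np.log10(rt[keep])
            orig = pe.fit_cosine(theta[keep], y).pub
            wins += orig > pe.surrogate_pub(theta[keep], y, n_rep=100, seed=s)
        assert wins >= 49

    def test_grid_median_matches_scalar_path(self):
        rng = np.random.default_rng(3)
        theta = rng.uniform(-np.pi, np.pi, (80, 2, 2))
        y = rng.standard_normal(80)
        g = pe.surrogate_pub_grid(theta, y, n_rep=64, seed=9)
        s = pe.surrogate_pub(theta[:, 1, 0], y, n_rep=64, seed=9)
        assert g[1, 0] == pytest.approx(s, abs=1e-12)


class TestTMap:
    def test_identical_groups_give_zero(self):
        rng = np.random.default_rng(4)
        g = rng.random((5, 3, 2, 4))
        tm = pe.pub_tmap(g, g)
        np.testing.assert_allclose(tm.t, 0.0, atol=1e-12)
        assert tm.df == 8

    def test_constant_shift_flagged_degenerate(self):
        g = np.ones((4, 2, 2, 2))
        tm = pe.pub_tmap(g + 1.0, g)
        assert tm.degenerate.all()
        np.testing.assert_array_equal(tm.t, 0.0)

    def test_null_pointwise_level(self):
        """Simulated null 14 vs 14: rate of t above the one-sided p<0.001
        threshold is within +/-50% of nominal over 1e5 points."""
        rng = np.random.default_rng(5)
        P = 100_000
        g1 = rng.standard_normal((14, P))
        g2 = rng.standard_normal((14, P))
        tm = pe.pub_tmap(g1, g2)
        thr = pe.t_threshold_from_p(0.001, tm.df)
        rate = np.mean(tm.t > thr)
        assert 0.0005 <= rate <= 0.0015


class TestAdjacency:
    def test_unit_square_edges_no_diagonals(self):
        lay = pe.ChannelLayout(names=("a", "b", "c", "d"),
                               positions=[[0, 0], [1, 0], [0, 1], [1, 1]])
        adj = pe.electrode_adjacency(lay)
        pairs = {(i, j) for i in range(4) for j in adj.neighbors[i] if i < j}
        assert pairs == {(0, 1), (0, 2), (1, 3), (2, 3)}

    def test_large_scale_complete_graph(self):
        lay = pe.gen_montage(6)
        adj = pe.electrode_adjacency(lay, scale=1e9)
        assert all(len(nb) == 5 for nb in adj.neighbors)

    def test_symmetry_enforced(self):
        with pytest.raises(ValueError):
            pe.AdjacencyGraph(neighbors=((1,), ()))
        with pytest.raises(ValueError):
            pe.AdjacencyGraph(neighbors=((0,),))


class TestExtractClusters:
    def small_adj(self):
        # chain 0-1-2-3
        return pe.AdjacencyGraph.from_pairs(4, [(0, 1), (1, 2), (2, 3)])

    def test_single_point_excluded(self):
        t = np.zeros((4, 3, 3))
        t[1, 1, 1] = 5.0
        cs = pe.extract_clusters(tmap_from(t), 3.0, self.small_adj())
        assert len(cs.clusters) == 1
        assert cs.clusters[0].excluded
        assert cs.retained() == []

    def test_three_point_chain_stat(self):
        t = np.zeros((4, 3, 3))
        t[0, 1, 1] = 5.0
        t[1, 1, 1] = 6.0
        t[1, 1, 2] = 7.0
        cs = pe.extract_clusters(tmap_from(t), 3.0, self.small_adj())
        assert len(cs.clusters) == 1
        c = cs.clusters[0]
        assert not c.excluded
        assert c.stat == pytest.approx(18.0)
        assert c.n_electrodes == 2

    def test_matches_flood_fill_oracle_on_random_grids(self):
        rng = np.random.default_rng(6)
        adj = self.small_adj()
        for _ in range(50):
            t = rng.normal(0, 1, (4, 4, 4))
            thr = 0.5
            cs = pe.extract_clusters(tmap_from(t), thr, adj, min_electrodes=2)
            got = {frozenset(map(tuple, c.members)) for c in cs.clusters}
            want = brute_force_clusters(t > thr, adj.neighbors)
            assert got == want

    def test_stat_additivity(self):
        rng = np.random.default_rng(7)
        t = rng.normal(0, 1.5, (4, 5, 6))
        thr = 1.0
        cs = pe.extract_clusters(tmap_from(t), thr, self.small_adj())
        total = sum(c.stat for c in cs.clusters)
        assert total == pytest.approx(t[t > thr].sum(), abs=1e-10)
        sizes = sum(c.size for c in cs.clusters)
        assert sizes == int((t > thr).sum())

    def test_gap_separates_clusters(self):
        t = np.zeros((4, 5, 5))
        t[0:2, 0, 0] = 5.0   # blob 1: electrodes 0,1 at (f0,t0)
        t[2:4, 4, 4] = 5.0   # blob 2: electrodes 2,3 at (f4,t4)
        cs = pe.extract_clusters(tmap_from(t), 3.0, self.small_adj())
        assert len(cs.clusters) == 2
        assert all(not c.excluded for c in cs.clusters)


class TestPermutationTest:
    def make_null(self, seed, N=8, shape=(4, 3, 5)):
        rng = np.random.default_rng(seed)
        orig = rng.standard_normal((N,) + shape)
        surr = rng.standard_normal((N,) + shape)
        return orig, surr

    def adj(self):
        return pe.AdjacencyGraph.from_pairs(4, [(0, 1), (1, 2), (2, 3)])

    def test_deterministic_given_seed(self):
        orig, surr = self.make_null(8)
        a = pe.cluster_permutation_test(orig, surr, self.adj(), n_perm=200,
                                        point_p=0.05, seed=3)
        b = pe.cluster_permutation_test(orig, surr, self.adj(), n_perm=200,
                                        point_p=0.05, seed=3)
        np.testing.assert_array_equal(a.null_max_stats, b.null_max_stats)
        assert [c.p_perm for c in a.clusters] == [c.p_perm for c in b.clusters]

    def test_p_monotone_in_stat(self):
        orig, surr = self.make_null(9)
        cs = pe.cluster_permutation_test(orig, surr, self.adj(), n_perm=300,
                                         point_p=0.10, seed=4)
        ret = cs.retained()
        for a, b in zip(ret, ret[1:]):  # sorted by decreasing stat
            assert a.p_perm <= b.p_perm

    def test_small_nperm_warns(self):
        orig, surr = self.make_null(10)
        with pytest.warns(UserWarning):
            pe.cluster_permutation_test(orig, surr, self.adj(), n_perm=50,
                                        point_p=0.05, seed=5)

    def test_object_interface_matches_function(self):
        orig, surr = self.make_null(11)
        cs1 = pe.ClusterPermutationTest(orig, surr, self.adj(),
                                        point_p=0.05).run(n_perm=100, seed=6)
        cs2 = pe.cluster_permutation_test(orig, surr, self.adj(), n_perm=100,
                                          point_p=0.05, seed=6)
        np.testing.assert_array_equal(cs1.null_max_stats, cs2.null_max_stats)

    def test_within_scheme_runs(self):
        orig, surr = self.make_null(12)
        cs = pe.cluster_permutation_test(orig, surr, self.adj(), n_perm=100,
                                         point_p=0.05, seed=7, scheme="within")
        assert cs.null_max_stats.size == 100


class TestLopo:
    def adj(self):
        return pe.AdjacencyGraph.from_pairs(4, [(0, 1), (1, 2), (2, 3)])

    def make_effect_grids(self, N=6, seed=0):
        rng = np.random.default_rng(seed)
        shape = (4, 3, 5)
        orig = 0.05 + 0.01 * rng.standard_normal((N,) + shape)
        surr = 0.05 + 0.01 * rng.standard_normal((N,) + shape)
        orig[:, 1:3, 1, 2] += 0.2  # strong effect, electrodes 1-2
        return orig, surr

    def test_identical_participants_select_group_argmax(self):
        orig, surr = self.make_effect_grids()
        orig = np.repeat(orig[:1], 6, axis=0) + 1e-9  # copies
        surr = np.repeat(surr[:1], 6, axis=0)
        tm = pe.pub_tmap(orig, surr)
        # degenerate within-group variance: use direct clusters at low threshold
        cs = pe.extract_clusters(tm, 0.0, self.adj())
        # all-copy groups give zero variance -> t=0; skip via jitter instead
        orig2, surr2 = self.make_effect_grids(seed=1)
        cs = pe.cluster_permutation_test(orig2, surr2, self.adj(), n_perm=100,
                                         point_p=0.01, seed=1)
        sel = pe.lopo_select(orig2, surr2, cs, self.adj())
        assert len(sel) == 6
        pts = [s[0] for s in sel if s.get(0) is not None]
        assert len(pts) == 6
        for p in pts:
            assert p.channel in (1, 2) and p.freq == 1 and p.time == 2

    def test_selection_independent_of_held_out_participant(self):
        orig, surr = self.make_effect_grids(seed=2)
        cs = pe.cluster_permutation_test(orig, surr, self.adj(), n_perm=100,
                                         point_p=0.01, seed=2)
        sel = pe.lopo_select(orig, surr, cs, self.adj())
        orig_pert = orig.copy()
        orig_pert[3] += 0.5  # perturb participant 3's own data wildly
        cs2 = pe.cluster_permutation_test(orig, surr, self.adj(), n_perm=100,
                                          point_p=0.01, seed=2)
        sel_pert = pe.lopo_select(orig_pert, surr, cs2, self.adj())
        assert sel[3][0] == sel_pert[3][0]

    def test_needs_three_participants(self):
        orig, surr = self.make_effect_grids()
        cs = pe.cluster_permutation_test(orig, surr, self.adj(), n_perm=100,
                                         point_p=0.01, seed=3)
        with pytest.raises(ValueError):
            pe.lopo_select(orig[:2], surr[:2], cs, self.adj())


class TestPhaseBinRT:
    def test_noiseless_cosine_minimum_in_first_bin(self):
        rng = np.random.default_rng(13)
        theta = rng.uniform(-np.pi, np.pi, 600)
        eff = pe.EffectSpec(amplitude_A=0.05, tau=1.0, rt_noise_sd=0.0)
        rt, _ = pe.gen_phase_dependent_behavior(theta, eff, seed=0)
        f = pe.pub_rt(theta, rt)
        opt = pe.optimal_phase(f)
        means = pe.phase_bin_rt(theta, np.log10(rt), opt)
        assert np.argmin(means) == 0
        # profile is a sampled cosine: antipodal bin is the maximum
        assert np.argmax(means) == 3

    def test_two_pi_shift_invariant(self):
        rng = np.random.default_rng(14)
        theta = rng.uniform(-np.pi, np.pi, 300)
        y = rng.standard_normal(300)
        a = pe.phase_bin_rt(theta, y, 0.7)
        b = pe.phase_bin_rt(theta, y, 0.7 + 2 * np.pi)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_uniform_phases_fill_all_bins(self):
        rng = np.random.default_rng(15)
        empty = 0
        for s in range(200):
            theta = rng.uniform(-np.pi, np.pi, 306)
            means = pe.phase_bin_rt(theta, np.zeros(306), 0.0)
            empty += np.any(np.isnan(means))
        assert empty <= 2  # all bins non-empty in >99% of draws


class TestRMAnova:
    def test_paper_scale_dfs(self):
        rng = np.random.default_rng(16)
        res = pe.rm_anova(rng.standard_normal((14, 6)))
        assert (res.df1, res.df2) == (5, 65)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(17)
        for seed in range(3):
            m = rng.standard_normal((10, 6)) + rng.standard_normal((10, 1))
            res = pe.rm_anova(m)
            d = pd.DataFrame({"y": m.ravel(),
                              "s": np.repeat(np.arange(10), 6),
                              "b": np.tile(np.arange(6), 10)})
            ref = pg.rm_anova(dv="y", within="b", subject="s", data=d)
            assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
            assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_degenerate_zero_error(self):
        m = np.tile(np.arange(6.0), (5, 1))  # identical rows, no error term
        res = pe.rm_anova(m)
        assert res.degenerate

    def test_cosine_profile_power(self):
        """14 participants with a shared cosine bin profile + noise: the main
        effect is detected in nearly every simulation at pilot amplitude."""
        rng = np.random.default_rng(18)
        profile = 0.02 * np.cos(np.linspace(0, 2 * np.pi, 6, endpoint=False))
        hits = 0
        sims = 100
        for _ in range(sims):
            m = profile[None, :] + 0.01 * rng.standard_normal((14, 6))
            hits += pe.rm_anova(m).p < 0.05
        assert hits >= 95

    def test_participants_with_missing_bins_dropped(self):
        rng = np.random.default_rng(19)
        m = rng.standard_normal((6, 6))
        m[2, 4] = np.nan
        res = pe.rm_anova(m)
        assert res.df2 == (6 - 1) * (5 - 1)
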