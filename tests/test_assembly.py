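from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from granuleco import assembly, synthetic
from granuleco.assembly import (
    _NullEngine,
    beta_mntd,
    bnti,
    env_optima,
    mantel_correlogram,
    null_assembly,
    nri_nti_series,
    raup_crick_bray,
    ses_phylo_alpha,
    turnover_series,
    weighted_mntd,
    weighted_mpd,
)
from granuleco.data_io import CountTable, EnvTable, PhyloTree
from granuleco.diversity import bray_curtis


def _table(counts, days=None):
    n, p = counts.shape
    return CountTable(
        [f"s{i:02d}" for i in range(n)], [f"x{j}" for j in range(p)],
        counts, days=days,
    )


class TestEnvOptima:
    def _env(self, values):
        n = len(values)
        return EnvTable(
            pd.DataFrame(
                {"day": np.arange(n, dtype=float), "nitrate": values},
                index=[f"s{i:02d}" for i in range(n)],
            )
        )

    def test_single_occurrence_takes_that_value(self):
        t = _table(np.array([[0, 5], [3, 0], [2, 0]]))
        opt = env_optima(t, self._env([4.0, 12.0, 6.0]), "nitrate")
        assert opt["x1"] == pytest.approx(4.0)

    def test_equal_counts_average_env(self):
        t = _table(np.array([[2, 1], [2, 1]]))
        opt = env_optima(t, self._env([4.0, 6.0]), "nitrate")
        assert opt["x0"] == pytest.approx(5.0)

    def test_matches_loop_oracle(self, rng):
        counts = rng.integers(0, 40, (10, 15))
        counts[:, 0] += 1
        counts[0] += 1
        e = rng.normal(10, 3, 10)
        t = _table(counts)
        opt = env_optima(t, self._env(e), "nitrate")
        for j, a in enumerate(t.asv_ids):
            tot = counts[:, j].sum()
            if tot == 0:
                assert a not in opt.index
            else:
                manual = sum(counts[i, j] * e[i] for i in range(10)) / tot
                assert opt[a] == pytest.approx(manual, abs=1e-12)


class TestMantelCorrelogram:
    def test_constructed_signal_detected_in_shortest_class(self, small_tree):
        # optima = smooth function of tree position: strong signal
        d = small_tree.cophenetic()
        optima = pd.Series(d[0], index=small_tree.tip_names())
        res = mantel_correlogram(optima, small_tree, n_perm=199, seed=3)
        first = res.classes.iloc[0]
        assert first["mantel_r"] > 0
        assert first["p_corrected"] <= 0.05

    def test_single_class_reduces_to_plain_mantel(self, small_tree):
        d = small_tree.cophenetic()
        optima = pd.Series(d[0], index=small_tree.tip_names())
        res = mantel_correlogram(optima, small_tree, n_classes=1, n_perm=99, seed=0)
        assert len(res.classes) == 1

    def test_constant_optima_rejected(self, small_tree):
        optima = pd.Series(1.0, index=small_tree.tip_names())
        with pytest.raises(ValueError, match="constant"):
            mantel_correlogram(optima, small_tree, seed=0)


def exhaustive_null_moments(stat_fn, abund, dist):
    """Exact null mean/sd of a dispersion statistic over all label
    permutations of the pool (pool small enough to enumerate)."""
    p = dist.shape[0]
    present = np.flatnonzero(abund > 0)
    vals = []
    for perm in permutations(range(p)):
        shuffled = np.zeros(p)
        shuffled[np.asarray(perm)[present]] = abund[present]
        vals.append(stat_fn(shuffled, dist))
    vals = np.array(vals)
    return vals.mean(), vals.std(ddof=1)


class TestSesPhyloAlpha:
    def test_monte_carlo_matches_exhaustive_enumeration(self):
        tree = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        d = tree.cophenetic(["a", "b", "c", "d"])
        abund = np.array([1.0, 1.0, 0.0, 0.0])  # two sister tips
        for stat, fn in (("mpd", weighted_mpd), ("mntd", weighted_mntd)):
            rec = ses_phylo_alpha(abund, d, stat, n_null=999, seed=4)
            mean, sd = exhaustive_null_moments(fn, abund, d)
            assert rec.null_mean == pytest.approx(mean, abs=3 * sd / np.sqrt(999))
            # MC sd within 3 standard errors of the sd estimate
            se_sd = sd / np.sqrt(2 * 998)
            assert rec.null_sd == pytest.approx(sd, abs=3 * se_sd)

    def test_star_tree_is_degenerate(self):
        tree = PhyloTree.from_newick("(a:1,b:1,c:1,d:1);")
        d = tree.cophenetic(["a", "b", "c", "d"])
        rec = ses_phylo_alpha(np.array([2.0, 1.0, 0, 0]), d, "mpd", n_null=99, seed=0)
        assert rec.degenerate and rec.ses == 0.0

    def test_full_pool_equal_abundance_is_degenerate(self, small_tree):
        d = small_tree.cophenetic()
        rec = ses_phylo_alpha(np.ones(d.shape[0]), d, "mntd", n_null=99, seed=0)
        assert rec.degenerate

    def test_sign_convention(self):
        """Mutually closest tips -> positive SES; distant tips -> negative."""
        tree = PhyloTree.from_newick(
            "(((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1):1.8,((e:0.1,f:0.1):0.1,(g:0.1,h:0.1):0.1):1.8);"
        )
        names = tree.tip_names()
        d = tree.cophenetic(names)
        clustered = np.zeros(8)
        clustered[[names.index(x) for x in "abcd"]] = 1.0
        spread = np.zeros(8)
        spread[[names.index(x) for x in "aceg"]] = 0.0
        spread[[names.index(x) for x in ("a", "e")]] = 1.0
        pos = ses_phylo_alpha(clustered, d, "mpd", n_null=499, seed=1)
        neg = ses_phylo_alpha(spread, d, "mpd", n_null=499, seed=1)
        assert pos.ses > 0 > neg.ses


class TestBetaMntd:
    def test_identical_compositions_give_zero(self, rng, small_tree):
        d = small_tree.cophenetic()
        a = np.zeros(40)
        a[rng.choice(40, 10, replace=False)] = rng.integers(1, 20, 10)
        assert beta_mntd(a, a, d) == 0.0

    def test_single_pair_cherry(self):
        tree = PhyloTree.from_newick("(a:1,b:1);")
        d = tree.cophenetic(["a", "b"])
        assert beta_mntd(np.array([1.0, 0]), np.array([0, 1.0]), d) == pytest.approx(2.0)

    def test_matches_double_loop_oracle(self, rng, small_tree):
        d = small_tree.cophenetic()
        a = rng.integers(0, 10, 40).astype(float)
        b = rng.integers(0, 10, 40).astype(float)
        a[0] += 1
        b[1] += 1
        ia, ib = np.flatnonzero(a > 0), np.flatnonzero(b > 0)
        fa, fb = a[ia] / a[ia].sum(), b[ib] / b[ib].sum()
        term_a = sum(
            f * min(d[i, j] for j in ib) for f, i in zip(fa, ia)
        )
        term_b = sum(
            f * min(d[i, j] for i in ia) for f, j in zip(fb, ib)
        )
        assert beta_mntd(a, b, d) == pytest.approx(0.5 * (term_a + term_b), abs=1e-12)


class TestBnti:
    def test_exhaustive_five_tip_oracle(self):
        tree = synthetic.simulate_tree(5, seed=2)
        d = tree.cophenetic()
        a = np.array([3.0, 1.0, 0, 0, 0])
        b = np.array([0, 2.0, 2.0, 0, 0])
        vals = []
        for perm in permutations(range(5)):
            perm = np.asarray(perm)
            sa, sb = np.zeros(5), np.zeros(5)
            sa[perm[[0, 1]]] = a[[0, 1]]
            sb[perm[[1, 2]]] = b[[1, 2]]
            vals.append(beta_mntd(sa, sb, d))
        vals = np.array(vals)
        rec = bnti(a, b, d, n_null=999, seed=8)
        assert rec.null_mean == pytest.approx(
            vals.mean(), abs=3 * vals.std(ddof=1) / np.sqrt(999)
        )
        se_sd = vals.std(ddof=1) / np.sqrt(2 * 998)
        assert rec.null_sd == pytest.approx(vals.std(ddof=1), abs=3 * se_sd)

    def test_shared_everything_is_nonpositive(self, rng, small_tree):
        d = small_tree.cophenetic()
        a = np.zeros(40)
        a[rng.choice(40, 12, replace=False)] = rng.integers(1, 9, 12)
        rec = bnti(a, a, d, n_null=199, seed=0)
        assert rec.observed == 0.0
        assert rec.ses <= 0.0

    def test_determinism(self, rng, small_tree):
        d = small_tree.cophenetic()
        a = rng.integers(0, 5, 40).astype(float)
        b = rng.integers(0, 5, 40).astype(float)
        a[0] += 1
        b[1] += 1
        r1 = bnti(a, b, d, n_null=99, seed=42)
        r2 = bnti(a, b, d, n_null=99, seed=42)
        assert r1 == r2


class TestFastEngineEquivalence:
    """The batched null engine must reproduce the per-draw reference
    implementations on random instances (property over 20 instances)."""

    def test_engine_matches_reference(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(8, 30))
            tree = synthetic.simulate_tree(n, seed=seed + 100)
            d = tree.cophenetic()
            k = int(rng.integers(2, n))
            ab = np.zeros(n)
            ab[rng.choice(n, k, replace=False)] = rng.integers(1, 30, k)
            engine = _NullEngine(d)
            perms = engine.permutations(np.random.default_rng(seed), 50)
            ia = np.flatnonzero(ab > 0)
            f = ab[ia] / ab[ia].sum()
            fast_mpd = engine.mpd_nulls(perms[:, : len(ia)], f)
            fast_mntd = engine.mntd_nulls(perms[:, : len(ia)], f)
            for b in range(0, 50, 17):
                shuffled = np.zeros(n)
                shuffled[perms[b, : len(ia)]] = ab[ia]
                assert fast_mpd[b] == pytest.approx(weighted_mpd(shuffled, d), abs=1e-5)
                assert fast_mntd[b] == pytest.approx(weighted_mntd(shuffled, d), abs=1e-9)


class TestRaupCrick:
    def test_bounds_and_determinism(self, rng):
        counts = rng.integers(0, 20, (6, 12))
        counts[:, 0] += 1
        occ = (counts > 0).sum(axis=0).astype(float)
        pool = counts.sum(axis=0) / counts.sum()
        r1 = raup_crick_bray(counts[0], counts[1], occ, pool, n_null=99, seed=5)
        r2 = raup_crick_bray(counts[0], counts[1], occ, pool, n_null=99, seed=5)
        assert r1 == r2
        assert -1.0 <= r1["rc"] <= 1.0

    def test_identical_samples_hit_lower_bound(self, rng):
        counts = rng.integers(0, 50, (8, 20))
        counts[:, :4] += 5
        occ = (counts > 0).sum(axis=0).astype(float)
        pool = counts.sum(axis=0) / counts.sum()
        rec = raup_crick_bray(counts[0], counts[0], occ, pool, n_null=999, seed=3)
        assert rec["rc"] <= -0.95  # observed BC = 0 is the attainable minimum

    def test_three_asv_richness_one_matches_exact_enumeration(self):
        """With richness-1 samples the null BC is 0 when both draws pick the
        same identity and 1 otherwise; enumerate the exact RC."""
        counts = np.array([[10, 0, 0], [0, 10, 0], [10, 0, 0], [0, 0, 10]])
        occ = (counts > 0).sum(axis=0).astype(float)  # (2, 1, 1)
        pool = counts.sum(axis=0) / counts.sum()
        pick = occ / occ.sum()
        p_same = float((pick**2).sum())
        obs = bray_curtis(counts[0], counts[2])  # identical -> 0
        # exact RC: null < obs never; ties (null == 0) with prob p_same
        exact = 2 * (0.5 * p_same) - 1
        rec = raup_crick_bray(counts[0], counts[2], occ, pool, n_null=4999, seed=9)
        assert obs == 0.0
        se = np.sqrt(p_same * (1 - p_same) / 4999)
        assert rec["rc"] == pytest.approx(exact, abs=3 * 2 * se)

    def test_richness_beyond_pool_rejected(self):
        with pytest.raises(ValueError):
            null_assembly(5, 10, np.ones(3), np.ones(3), np.random.default_rng(0))


class TestTurnoverSeries:
    def test_length_contract_and_determinism(self, rng, small_tree):
        counts = rng.integers(0, 30, (8, 40))
        counts[:, 0] += 1
        t = CountTable(
            [f"s{i:02d}" for i in range(8)], small_tree.tip_names(),
            counts, days=np.arange(8, dtype=float),
        )
        out1 = turnover_series(t, small_tree, n_null=99, seed=1)
        out2 = turnover_series(t, small_tree, n_null=99, seed=1)
        assert len(out1) == 7
        pd.testing.assert_frame_equal(out1, out2)


class TestNriNtiSeries:
    def test_columns_and_degenerate_handling(self, rng, small_tree):
        counts = rng.integers(0, 30, (5, 40))
        counts[:, 0] += 1
        counts[2] = 0
        counts[2, 0] = 7  # single present taxon -> flagged row
        t = CountTable([f"s{i:02d}" for i in range(5)], small_tree.tip_names(), counts)
        out = nri_nti_series(t, small_tree, n_null=99, seed=1)
        assert len(out) == 5
        assert bool(out.loc[2, "degenerate"])
        assert np.isnan(out.loc[2, "nri"])
        assert np.isfinite(out.loc[0, "nri"])
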