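import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from granuleco.ordination import (
    dbrda,
    forward_select_predictors,
    pcoa,
    variance_partition,
)


def euclid(points):
    return squareform(pdist(points))


class TestPcoa:
    def test_euclidean_distances_recovered(self, rng):
        pts = rng.normal(0, 1, (5, 2))
        d = euclid(pts)
        coords, eig = pcoa(d)
        assert np.allclose(euclid(coords), d, atol=1e-9)

    def test_equal_distances_give_equal_positive_eigenvalues(self):
        n = 6
        d = np.ones((n, n)) - np.eye(n)  # regular simplex geometry
        _, eig = pcoa(d)
        pos = eig[eig > 1e-10]
        assert len(pos) == n - 1
        assert np.allclose(pos, pos[0], atol=1e-10)

    def test_matches_skbio_oracle(self, rng):
        """Cross-check the Gower embedding against scikit-bio's PCoA."""
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from skbio import DistanceMatrix

        pts = rng.normal(0, 1, (8, 3))
        d = euclid(pts)
        coords, eig = pcoa(d)
        ref = skbio_pcoa(DistanceMatrix(d), number_of_dimensions=3)
        assert np.allclose(np.sort(eig[eig > 1e-9])[::-1][:3],
                           ref.eigvals.to_numpy()[:3], atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.zeros((1, 1)))
        with pytest.raises(ValueError):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric


class TestDbrda:
    def test_intercept_only_gives_zero_r2(self, rng):
        d = euclid(rng.normal(0, 1, (10, 2)))
        fit = dbrda(d, pd.DataFrame(index=range(10)), n_perm=9, seed=0)
        assert fit.r2 == 0.0

    def test_informative_gradient_is_significant(self):
        rng = np.random.default_rng(1)
        grad = np.linspace(0, 1, 20)
        y = np.column_stack([grad, 0.05 * rng.normal(size=20)])
        d = euclid(y)
        fit = dbrda(d, pd.DataFrame({"g": grad}), n_perm=999, seed=2)
        assert fit.p_value <= 0.005
        assert fit.adj_r2 > 0.8

    def test_orthogonal_predictor_is_null(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            d = euclid(rng.normal(0, 1, (15, 3)))
            noise = pd.DataFrame({"z": rng.normal(size=15)})
            fit = dbrda(d, noise, n_perm=99, seed=seed)
            if fit.p_value > 0.1 and abs(fit.adj_r2) < 0.15:
                hits += 1
        assert hits >= 40  # >= 80 % of seeds behave as a null

    def test_duplicated_predictor_rejected(self, rng):
        d = euclid(rng.normal(0, 1, (10, 2)))
        x = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0)})
        with pytest.raises(ValueError, match="aliased"):
            dbrda(d, x, n_perm=9, seed=0)

    def test_permutation_p_floor(self):
        rng = np.random.default_rng(3)
        grad = np.linspace(0, 1, 20)
        d = euclid(np.column_stack([grad, 0.01 * rng.normal(size=20)]))
        fit = dbrda(d, pd.DataFrame({"g": grad}), n_perm=199, seed=1)
        assert fit.p_value >= 1.0 / 200.0


class TestForwardSelection:
    def _setup(self, seed, n=30):
        rng = np.random.default_rng(seed)
        grad = rng.normal(0, 1, n)
        y = np.column_stack([2.0 * grad, 0.3 * rng.normal(size=n)])
        d = euclid(y)
        cands = pd.DataFrame(
            {
                "signal": grad,
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
                "noise3": rng.normal(size=n),
            }
        )
        return d, cands

    def test_informative_candidate_selected(self):
        hits = 0
        for seed in range(30):
            d, cands = self._setup(seed)
            sel = forward_select_predictors(d, cands, n_perm=99, seed=seed)
            if sel and sel[0] == "signal":
                hits += 1
        assert hits >= 27  # >= 90 % of seeds

    def test_all_noise_candidates_usually_give_empty_set(self):
        """Per-step alpha = 0.05 over 3 candidates bounds the family-wise
        entry rate near 1 - 0.95^3; most seeds select nothing."""
        empty = 0
        for seed in range(30):
            rng = np.random.default_rng(seed + 1000)
            d = euclid(rng.normal(0, 1, (25, 3)))
            cands = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
            sel = forward_select_predictors(d, cands, n_perm=99, seed=seed)
            if not sel:
                empty += 1
        assert empty >= 21  # ~70 % bound, consistent with 0.95^3

    def test_alpha_one_admits_everything(self):
        d, cands = self._setup(0, n=25)
        sel = forward_select_predictors(d, cands, alpha=1.0, n_perm=29, seed=0)
        assert set(sel) == set(cands.columns)


class TestVariancePartition:
    def test_duplicated_sets_share_everything(self, rng):
        n = 25
        grad = rng.normal(0, 1, n)
        d = euclid(np.column_stack([grad, 0.2 * rng.normal(size=n)]))
        a = pd.DataFrame({"x": grad})
        b = pd.DataFrame({"x2": grad * 2.0 + 1.0})  # same information
        c = pd.DataFrame({"z": rng.normal(size=n)})
        vp = variance_partition(d, a, b, c)
        assert abs(vp.fractions["abiotic"]) < 0.02
        assert abs(vp.fractions["biotic"]) < 0.02
        assert vp.fractions["abiotic|biotic"] > 0.5

    def test_orthogonal_gradients_recovered_within_tolerance(self):
        rng = np.random.default_rng(5)
        n = 120
        x1, x2, x3 = rng.normal(size=(3, n))
        v1, v2, v3, vn = 0.4, 0.3, 0.2, 0.1
        y = np.column_stack(
            [
                np.sqrt(v1) * (x1 - x1.mean()) / x1.std(),
                np.sqrt(v2) * (x2 - x2.mean()) / x2.std(),
                np.sqrt(v3) * (x3 - x3.mean()) / x3.std(),
                np.sqrt(vn) * rng.normal(size=n),
            ]
        )
        d = euclid(y)
        vp = variance_partition(
            d,
            pd.DataFrame({"a": x1}),
            pd.DataFrame({"b": x2}),
            pd.DataFrame({"c": x3}),
            labels=("abiotic", "biotic", "stage"),
        )
        assert vp.fractions["abiotic"] == pytest.approx(v1, abs=0.05)
        assert vp.fractions["biotic"] == pytest.approx(v2, abs=0.05)
        assert vp.fractions["stage"] == pytest.approx(v3, abs=0.05)
        assert vp.fractions["residual"] == pytest.approx(vn, abs=0.05)

    def test_fractions_sum_to_one_exactly(self, rng):
        n = 20
        d = euclid(rng.normal(0, 1, (n, 3)))
        vp = variance_partition(
            d,
            pd.DataFrame({"a": rng.normal(size=n)}),
            pd.DataFrame({"b": rng.normal(size=n)}),
            pd.DataFrame({"c": rng.normal(size=n)}),
        )
        assert sum(vp.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_under_relabeling(self, rng):
        n = 20
        d = euclid(rng.normal(0, 1, (n, 3)))
        a = pd.DataFrame({"a": rng.normal(size=n)})
        b = pd.DataFrame({"b": rng.normal(size=n)})
        c = pd.DataFrame({"c": rng.normal(size=n)})
        v1 = variance_partition(d, a, b, c)
        v2 = variance_partition(d, b, a, c)
        assert v1.fractions["abiotic"] == pytest.approx(v2.fractions["biotic"], abs=1e-10)
        assert v1.fractions["residual"] == pytest.approx(v2.fractions["residual"], abs=1e-10)
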