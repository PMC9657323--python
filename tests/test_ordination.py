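"""Bray-Curtis, PCoA, PERMANOVA, Mantel, nutrient distances, RDA and
forward selection, each against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from ruminant_ghg.ordination import (
    DistanceMatrix,
    bray_curtis,
    forward_select,
    mantel,
    nutrient_distance,
    pcoa,
    permanova,
    rda,
)


def dm(matrix, ids=None):
    matrix = np.asarray(matrix, float)
    ids = ids or [f"s{i}" for i in range(len(matrix))]
    return DistanceMatrix(ids, matrix)


def random_euclidean_dm(rng, n=8, p=3):
    x = rng.normal(size=(n, p))
    return dm(squareform(pdist(x))), x


class TestBrayCurtis:
    def test_identical_zero_disjoint_one(self):
        t = pd.DataFrame([[1, 2, 0, 0], [1, 2, 0, 0], [0, 0, 3, 4]],
                         index=["a", "b", "c"])
        d = bray_curtis(t)
        assert d.data[0, 1] == 0.0
        assert d.data[0, 2] == 1.0

    def test_direct_formula(self):
        t = pd.DataFrame([[1, 2, 3], [2, 1, 0]], index=["a", "b"])
        d = bray_curtis(t)
        assert d.data[0, 1] == pytest.approx(5 / 9)

    def test_matches_skbio(self, rng):
        import skbio

        t = pd.DataFrame(rng.integers(0, 50, (6, 10)).astype(float) + 1)
        ours = bray_curtis(t)
        ref = skbio.diversity.beta_diversity("braycurtis", t.to_numpy())
        np.testing.assert_allclose(ours.data, ref.data, atol=1e-12)

    def test_all_zero_sample_rejected(self):
        t = pd.DataFrame([[1, 2], [0, 0]], index=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            bray_curtis(t)


class TestPcoa:
    def test_two_samples_symmetric(self):
        res = pcoa(dm([[0, 2], [2, 0]]))
        assert res.coordinates[:, 0] == pytest.approx([1, -1]) or \
            res.coordinates[:, 0] == pytest.approx([-1, 1])

    def test_equilateral_triangle_equal_eigenvalues(self):
        d = dm(np.ones((3, 3)) - np.eye(3))
        res = pcoa(d)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], rel=1e-10)

    def test_euclidean_round_trip(self, rng):
        d, _ = random_euclidean_dm(rng)
        res = pcoa(d)
        recon = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(recon, d.data, atol=1e-8)
        assert res.n_negative == 0

    def test_matches_skbio(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        d, _ = random_euclidean_dm(rng, n=7)
        res = pcoa(d)
        ref = skbio_pcoa(d.data, number_of_dimensions=3)
        np.testing.assert_allclose(
            np.sort(res.eigenvalues[res.eigenvalues > 1e-8])[::-1][:3],
            ref.eigvals.to_numpy()[:3],
            rtol=1e-8,
        )

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            dm([[0, 1], [2, 0]])


class TestPermanova:
    def test_exhaustive_equals_brute_force(self, rng):
        """n = 6, two groups of 3: exhaustive p over all 20 assignments."""
        d, _ = random_euclidean_dm(rng, n=6)
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(d, groups, exhaustive=True)
        assert res.permutations == 20
        assert res.p_value * 20 == pytest.approx(round(res.p_value * 20))
        # brute force with an independent F implementation (skbio's)
        from skbio.stats.distance import permanova as sk_permanova
        from skbio import DistanceMatrix as SkDM

        ref = sk_permanova(SkDM(d.data, d.ids), groups, permutations=999)
        assert res.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_separated_clusters_minimal_p(self, rng):
        x = np.vstack([rng.normal(0, 0.01, (4, 2)), rng.normal(50, 0.01, (4, 2))])
        d = dm(squareform(pdist(x)))
        groups = np.repeat(["a", "b"], 4)
        # observed F is maximal: only the 2 cluster-aligned assignments (of
        # C(8,4) = 70) reach it, so the exact p is 2/70 and the sampled p is
        # bounded by the minimum achievable plus partition ties
        res = permanova(d, groups, exhaustive=True)
        assert res.p_value == pytest.approx(2 / 70)
        sampled = permanova(d, groups, permutations=99, rng=rng)
        assert 1 / 100 <= sampled.p_value <= 0.05

    def test_matches_skbio_f(self, rng):
        from skbio.stats.distance import permanova as sk_permanova
        from skbio import DistanceMatrix as SkDM

        d, _ = random_euclidean_dm(rng, n=9)
        groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        res = permanova(d, groups, permutations=99, rng=rng)
        ref = sk_permanova(SkDM(d.data, d.ids), groups, permutations=99)
        assert res.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_p_never_zero_and_reports_permutations(self, rng):
        d, _ = random_euclidean_dm(rng, n=8)
        res = permanova(d, np.repeat(["a", "b"], 4), permutations=49, rng=rng)
        assert res.permutations == 49
        assert 1 / 50 <= res.p_value <= 1.0

    def test_small_group_rejected(self, rng):
        d, _ = random_euclidean_dm(rng, n=4)
        with pytest.raises(ValueError):
            permanova(d, ["a", "a", "a", "b"], permutations=9)


class TestMantel:
    def test_self_correlation_one(self, rng):
        d, _ = random_euclidean_dm(rng)
        res = mantel(d, d, permutations=99, rng=rng)
        assert res.r == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        d, _ = random_euclidean_dm(rng)
        d2 = dm(3.0 * d.data + (1 - np.eye(d.n)), d.ids)
        res = mantel(d, d2, permutations=99, rng=rng)
        assert res.r == pytest.approx(1.0)

    def test_hand_vectorized_pearson(self, rng):
        d1, _ = random_euclidean_dm(rng, n=5)
        d2, _ = random_euclidean_dm(rng, n=5)
        res = mantel(d1, d2, permutations=9, rng=rng)
        iu = np.triu_indices(5, 1)
        oracle = pearsonr(d1.data[iu], d2.data[iu])[0]
        assert res.r == pytest.approx(oracle, rel=1e-12)

    def test_matches_skbio_statistic(self, rng):
        from skbio.stats.distance import mantel as sk_mantel

        d1, _ = random_euclidean_dm(rng, n=7)
        d2, _ = random_euclidean_dm(rng, n=7)
        r_ref, _, _ = sk_mantel(d1.data, d2.data, permutations=0)
        res = mantel(d1, d2, permutations=9, rng=rng)
        assert res.r == pytest.approx(r_ref, rel=1e-10)

    def test_size_mismatch_rejected(self, rng):
        d1, _ = random_euclidean_dm(rng, n=5)
        d2, _ = random_euclidean_dm(rng, n=6)
        with pytest.raises(ValueError):
            mantel(d1, d2)


class TestNutrientDistance:
    def _meta(self, groups):
        return pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(len(groups))], "group": groups}
        )

    def test_same_group_distance_zero(self):
        nut = pd.DataFrame({"DM": [90.0, 95.0], "CP": [5.0, 9.0]}, index=["YWG", "YCG"])
        d = nutrient_distance(nut, self._meta(["YWG", "YWG", "YCG"]))
        assert d.data[0, 1] == 0.0
        assert d.data[0, 2] > 0

    def test_one_standardized_unit(self):
        # two groups differing only in CP; z-scores are +/- 0.5 * ... scaled
        # so that the gap equals exactly 1 sd unit
        nut = pd.DataFrame({"CP": [4.0, 6.0], "DM": [90.0, 90.0]}, index=["YWG", "YCG"])
        meta = self._meta(["YWG", "YCG"])
        d = nutrient_distance(nut, meta)
        x = np.array([4.0, 6.0])
        gap = 2.0 / x.std(ddof=1)
        assert d.data[0, 1] == pytest.approx(gap)

    def test_hand_euclidean_oracle(self, rng):
        nut = pd.DataFrame(
            rng.uniform(5, 95, (3, 5)),
            index=["YWG", "YCG", "YCF"],
            columns=["DM", "CP", "NDF", "ADF", "OM"],
        )
        groups = ["YWG", "YCG", "YCF", "YWG"]
        meta = self._meta(groups)
        d = nutrient_distance(nut, meta)
        x = nut.loc[groups].to_numpy()
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        np.testing.assert_allclose(d.data, squareform(pdist(z)), atol=1e-10)

    def test_missing_group_rejected(self):
        nut = pd.DataFrame({"CP": [4.0]}, index=["YWG"])
        with pytest.raises(ValueError, match="YCG"):
            nutrient_distance(nut, self._meta(["YWG", "YCG"]))


class TestRda:
    def test_perfect_linear_community(self, rng):
        x = rng.normal(size=10)
        constraints = pd.DataFrame({"CP": x})
        community = pd.DataFrame(
            {"g1": 2 * x + 1, "g2": -x + 3, "g3": 0.5 * x},
        )
        res = rda(community, constraints)
        assert res.percent_variance[0] == pytest.approx(100.0, abs=1e-8)

    def test_orthogonal_constraint_no_variance(self, rng):
        n = 40
        x = np.tile([1.0, -1.0], n // 2)
        y = rng.normal(size=(n, 3))
        y -= np.outer(x, x @ y) / (x @ x)  # project community out of x
        res = rda(pd.DataFrame(y), pd.DataFrame({"v": x}))
        assert res.constrained_variance == pytest.approx(0.0, abs=1e-20)

    def test_regression_then_pca_oracle(self, rng):
        """Canonical eigenvalues equal PCA of the OLS fitted values."""
        community = pd.DataFrame(rng.normal(size=(10, 6)))
        constraints = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        res = rda(community, constraints)
        # independent two-step oracle: hat-matrix projection then eigh
        y = community.to_numpy() - community.to_numpy().mean(0)
        x = constraints.to_numpy()
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        hat = x @ np.linalg.inv(x.T @ x) @ x.T
        fitted = hat @ y
        eig = np.linalg.eigvalsh(fitted.T @ fitted / 9)[::-1]
        np.testing.assert_allclose(res.eigenvalues, eig[: len(res.eigenvalues)], atol=1e-8)
        assert res.percent_variance[0] == pytest.approx(
            eig[0] / (np.sum(y**2) / 9) * 100, rel=1e-8
        )

    def test_nested_models_monotone(self, rng):
        community = pd.DataFrame(rng.normal(size=(12, 5)))
        constraints = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        v1 = rda(community, constraints[["a"]]).constrained_variance
        v2 = rda(community, constraints[["a", "b"]]).constrained_variance
        v3 = rda(community, constraints).constrained_variance
        assert v1 <= v2 + 1e-12 <= v3 + 2e-12
        assert v3 <= rda(community, constraints).total_variance + 1e-12

    def test_collinear_constraints_rejected(self, rng):
        x = rng.normal(size=10)
        constraints = pd.DataFrame({"a": x, "b": 2 * x})
        community = pd.DataFrame(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError, match="collinear.*'b'"):
            rda(community, constraints)


class TestForwardSelect:
    def test_informative_variable_found(self, rng):
        n = 20
        signal = rng.normal(size=n)
        community = pd.DataFrame(
            {f"g{j}": 1.5 * signal + rng.normal(0, 0.5, n) for j in range(4)}
        )
        candidates = pd.DataFrame(
            {"signal": signal, "noise1": rng.normal(size=n), "noise2": rng.normal(size=n)}
        )
        selected = forward_select(community, candidates, alpha=0.05, permutations=199, rng=rng)
        assert selected[0] == "signal"

    def test_duplicate_never_admitted(self, rng):
        n = 15
        x = rng.normal(size=n)
        community = pd.DataFrame({f"g{j}": x + rng.normal(0, 0.3, n) for j in range(3)})
        candidates = pd.DataFrame({"a": x, "a_copy": x.copy()})
        selected = forward_select(community, candidates, alpha=0.05, permutations=199, rng=rng)
        assert len(selected) <= 1

    def test_pure_noise_rarely_selected(self):
        """Type-I rate of the first selection step is near alpha."""
        hits = 0
        reps = 100
        for i in range(reps):
            r = np.random.default_rng(1000 + i)
            community = pd.DataFrame(r.normal(size=(12, 4)))
            candidates = pd.DataFrame({"x": r.normal(size=12)})
            if forward_select(community, candidates, alpha=0.05, permutations=99, rng=r):
                hits += 1
        # binomial(100, 0.05): mean 5, accept up to ~3 sd
        assert hits <= 13
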