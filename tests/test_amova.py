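import numpy as np
import pandas as pd
import pytest

from epimsap import amova_two_group, pairwise_distance, pca, pcoa
from epimsap.amova import DistanceMatrix

from conftest import brute_force_amova


def _labels(ids, groups):
    return dict(zip(ids, groups))


class TestPairwiseDistance:
    def test_identical_rows_zero(self):
        X = pd.DataFrame([[0, 1, 1], [0, 1, 1]], index=["a", "b"])
        D = pairwise_distance(X, "hamming_sq")
        assert D.values[0, 1] == 0.0

    def test_complementary_rows(self):
        X = pd.DataFrame([[0] * 5, [1] * 5], index=["a", "b"])
        assert pairwise_distance(X, "hamming_sq").values[0, 1] == 5.0
        assert pairwise_distance(X, "gower").values[0, 1] == 1.0

    def test_mismatch_count_and_gower(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 10)
        b = a.copy(); b[:3] = 1 - b[:3]
        X = pd.DataFrame([a, b], index=["a", "b"])
        assert pairwise_distance(X, "hamming_sq").values[0, 1] == 3.0
        assert pairwise_distance(X, "gower").values[0, 1] == pytest.approx(0.3)

    def test_pairwise_complete_missing(self):
        X = pd.DataFrame([[1, np.nan, 0, 1], [0, 1, 0, np.nan]], index=["a", "b"])
        # jointly scored: L1 (mismatch), L3 (match) -> hamming 1, gower 0.5
        assert pairwise_distance(X, "hamming_sq").values[0, 1] == 1.0
        assert pairwise_distance(X, "gower").values[0, 1] == pytest.approx(0.5)

    def test_categorical_input(self):
        X = pd.DataFrame([["I", "II"], ["I", "IV"]], index=["a", "b"])
        assert pairwise_distance(X, "gower").values[0, 1] == pytest.approx(0.5)

    def test_no_shared_loci_is_error(self):
        X = pd.DataFrame([[1, np.nan], [np.nan, 1]], index=["a", "b"])
        with pytest.raises(ValueError, match="no scored loci"):
            pairwise_distance(X)


class TestAmovaTwoGroup:
    def test_no_structure_gives_phi_zero_p_one(self):
        X = pd.DataFrame(np.ones((6, 4)), index=[f"s{i}" for i in range(6)])
        D = pairwise_distance(X)
        res = amova_two_group(D, {f"s{i}": "AB"[i % 2] for i in range(6)}, n_perm=99, seed=0)
        assert res.phi == 0.0 and res.p_value == 1.0

    def test_fixed_difference_gives_phi_one(self):
        X = pd.DataFrame([[0] * 6] * 3 + [[1] * 6] * 3, index=[f"s{i}" for i in range(6)])
        D = pairwise_distance(X)
        groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        res = amova_two_group(D, groups, n_perm=0)
        assert res.phi == pytest.approx(1.0)

    def test_hand_derived_one_third_case(self):
        X = pd.DataFrame([[0, 0], [0, 1], [1, 1], [1, 0]], index=list("abcd"))
        D = pairwise_distance(X)
        res = amova_two_group(D, _labels("abcd", "AABB"), n_perm=0)
        assert res.phi == pytest.approx(1 / 3, abs=1e-12)
        assert res.ss_among + res.ss_within == pytest.approx(res.ss_total, abs=1e-9)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            L = int(rng.integers(2, 13))
            X = pd.DataFrame(rng.integers(0, 2, size=(n, L)).astype(float),
                             index=[f"s{i}" for i in range(n)])
            n_a = int(rng.integers(1, n))
            labels = np.array(["A"] * n_a + ["B"] * (n - n_a))
            rng.shuffle(labels)
            if len(set(labels)) < 2:
                continue
            D = pairwise_distance(X)
            res = amova_two_group(D, dict(zip(X.index, labels)), n_perm=0)
            ss_a, ss_w, s2a, s2w, phi = brute_force_amova(D.values, labels)
            assert res.ss_among == pytest.approx(ss_a, abs=1e-12)
            assert res.ss_within == pytest.approx(ss_w, abs=1e-12)
            assert res.sigma2_among_raw == pytest.approx(s2a, abs=1e-12)
            assert res.phi == pytest.approx(phi, abs=1e-12)

    def test_phi_invariant_to_distance_scaling(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.integers(0, 2, size=(8, 10)).astype(float),
                         index=[f"s{i}" for i in range(8)])
        D = pairwise_distance(X)
        groups = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        res1 = amova_two_group(D, groups, n_perm=0)
        D2 = DistanceMatrix(7.3 * D.values, D.ids, D.metric)
        res2 = amova_two_group(D2, groups, n_perm=0)
        assert res1.phi == pytest.approx(res2.phi, abs=1e-12)

    def test_fixed_seed_reproduces_p_exactly(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.integers(0, 2, size=(12, 20)).astype(float),
                         index=[f"s{i}" for i in range(12)])
        D = pairwise_distance(X)
        groups = {f"s{i}": ("A" if i < 6 else "B") for i in range(12)}
        p1 = amova_two_group(D, groups, n_perm=999, seed=77).p_value
        p2 = amova_two_group(D, groups, n_perm=999, seed=77).p_value
        assert p1 == p2

    def test_empty_group_is_error(self):
        X = pd.DataFrame(np.ones((3, 2)), index=list("abc"))
        D = pairwise_distance(X)
        with pytest.raises(ValueError):
            amova_two_group(D, {"a": "A", "b": "A", "c": "A"}, n_perm=0)


class TestPcoa:
    def test_collinear_points_single_axis(self):
        pts = np.array([0.0, 1.0, 3.0])
        d2 = (pts[:, None] - pts[None, :]) ** 2
        D = DistanceMatrix(d2, ["a", "b", "c"], "hamming_sq")
        ord_ = pcoa(D)
        assert len(ord_.eigenvalues) == 1
        coords = ord_.coordinates.to_numpy()
        rec = (coords[:, None, :] - coords[None, :, :]) ** 2
        assert np.allclose(rec.sum(-1), d2, atol=1e-9)

    def test_all_zero_distances_zero_coordinates(self):
        D = DistanceMatrix(np.zeros((4, 4)), list("abcd"), "hamming_sq")
        assert np.allclose(pcoa(D).coordinates.to_numpy(), 0.0)

    def test_planar_points_recovered(self):
        rng = np.random.default_rng(21)
        pts = rng.normal(size=(10, 2))
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        D = DistanceMatrix(d2, [f"s{i}" for i in range(10)], "hamming_sq")
        ord_ = pcoa(D)
        coords = ord_.coordinates.to_numpy()[:, :2]
        rec = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        assert np.allclose(rec, d2, atol=1e-9)
        assert ord_.percent_variance.sum() <= 100 + 1e-9

    def test_matches_skbio_eigenvalues(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(22)
        X = pd.DataFrame(rng.integers(0, 2, size=(8, 12)).astype(float),
                         index=[f"s{i}" for i in range(8)])
        D = pairwise_distance(X)
        ours = pcoa(D)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(np.sqrt(D.values), D.ids)
        )
        k = len(ours.eigenvalues)
        assert np.allclose(ours.eigenvalues, ref.eigvals.to_numpy()[:k], atol=1e-9)

    def test_nan_rejected(self):
        v = np.zeros((3, 3)); v[0, 1] = v[1, 0] = np.nan
        D = DistanceMatrix(v, list("abc"), "hamming_sq")
        with pytest.raises(ValueError):
            pcoa(D)


class TestPca:
    def test_two_samples_single_axis(self):
        X = pd.DataFrame([[0, 0, 0], [1, 1, 1]], index=["a", "b"])
        ord_ = pca(X)
        assert ord_.coordinates.shape[1] == 1
        assert ord_.percent_variance[0] == pytest.approx(100.0)

    def test_pca_scores_match_pcoa_of_hamming_distances(self):
        # classical MDS on squared Euclidean distances of complete binary
        # data is PCA of the centred indicator matrix (up to axis signs)
        rng = np.random.default_rng(23)
        X = pd.DataFrame(rng.integers(0, 2, size=(9, 14)).astype(float),
                         index=[f"s{i}" for i in range(9)])
        mds = pcoa(pairwise_distance(X, "hamming_sq")).coordinates.to_numpy()
        scr = pca(X).coordinates.to_numpy()
        k = min(mds.shape[1], scr.shape[1])
        for ax in range(k):
            assert (
                np.allclose(mds[:, ax], scr[:, ax], atol=1e-8)
                or np.allclose(mds[:, ax], -scr[:, ax], atol=1e-8)
            )

    def test_duplicated_rows_get_identical_scores(self):
        rng = np.random.default_rng(24)
        row = rng.integers(0, 2, 10).astype(float)
        X = pd.DataFrame([row, row, 1 - row], index=["a", "a2", "b"])
        coords = pca(X).coordinates
        assert np.allclose(coords.loc["a"], coords.loc["a2"])

    def test_zero_variance_matrix_warns_and_zeroes(self):
        X = pd.DataFrame(np.ones((4, 3)), index=list("abcd"))
        ord_ = pca(X)
        assert np.allclose(ord_.coordinates.to_numpy(), 0.0)
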