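import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from epimsap import bh_adjust, fisher_exact, upgma
from epimsap.diffmeth import test_all_msl as run_dm_tests
from epimsap.amova import DistanceMatrix, pairwise_distance
from epimsap.meth_states import MethylationStateMatrix, partition_loci


def exact_fisher_oracle(table) -> float:
    """Freeman-Halton p by exhaustive enumeration in exact rationals."""
    t = np.asarray(table, dtype=int)
    cols = t.sum(axis=0)
    r1 = int(t[0].sum())
    n = int(cols.sum())
    denom = math.comb(n, r1)

    def prob(a):
        num = 1
        for c, x in zip(cols, a):
            num *= math.comb(int(c), int(x))
        return Fraction(num, denom)

    p_obs = prob(t[0])
    total = Fraction(0)
    ranges = [range(int(c) + 1) for c in cols]
    for a in itertools.product(*ranges):
        if sum(a) != r1:
            continue
        p = prob(a)
        if p <= p_obs:
            total += p
    return float(total)


class TestFisherExact:
    def test_five_zero_diagonal(self):
        assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252, abs=1e-12)

    def test_mode_table_p_one(self):
        assert fisher_exact([[2, 2], [2, 2]]) == pytest.approx(1.0, abs=1e-9)

    def test_matches_rational_enumeration_2x3_2x4(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            k = int(rng.integers(3, 5))
            while True:
                t = rng.integers(0, 5, size=(2, k))
                if t.sum() <= 12 and (t.sum(axis=0) > 0).sum() >= 2 and (t.sum(axis=1) > 0).all():
                    break
            assert fisher_exact(t) == pytest.approx(exact_fisher_oracle(t), abs=1e-12)

    def test_2x2_matches_scipy_hypergeometric(self):
        from scipy import stats
        rng = np.random.default_rng(32)
        for _ in range(20):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            ref = stats.fisher_exact(t, alternative="two-sided")[1]
            assert fisher_exact(t) == pytest.approx(ref, abs=1e-10)

    def test_invariant_to_column_permutation_and_row_swap(self):
        t = np.array([[3, 1, 5], [0, 4, 2]])
        p = fisher_exact(t)
        assert fisher_exact(t[:, [2, 0, 1]]) == pytest.approx(p, abs=1e-12)
        assert fisher_exact(t[[1, 0]]) == pytest.approx(p, abs=1e-12)

    def test_zero_row_degenerate(self):
        assert fisher_exact([[0, 0, 0], [3, 2, 1]]) == 1.0


class TestBhAdjust:
    def test_step_up_hand_vector(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_empty_list(self):
        assert len(bh_adjust([])) == 0

    def test_second_hand_vector_with_order_restored(self):
        p = [0.03, 0.002, 0.04, 0.8]
        # ranked: 0.002*4/1=0.008, 0.03*4/2=0.06, 0.04*4/3=0.0533->min with
        # next, 0.8; step-up running minima from the top: 0.8, 0.0533, 0.0533, 0.008
        got = bh_adjust(p)
        assert np.allclose(got, [0.0533333333, 0.008, 0.0533333333, 0.8], atol=1e-9)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(33)
        p = rng.random(50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestTestAllMsl:
    def _states_from(self, field_cols, micro_cols):
        data = {k: field_cols[k] + micro_cols[k] for k in field_cols}
        idx = [f"f{i}" for i in range(len(next(iter(field_cols.values()))))] + [
            f"m{i}" for i in range(len(next(iter(micro_cols.values()))))
        ]
        df = pd.DataFrame(data, index=idx)
        groups = {s: ("field" if s.startswith("f") else "micro") for s in idx}
        return MethylationStateMatrix(df, "E"), groups

    def test_identical_distributions_nothing_significant(self):
        col = ["I", "II", "III", "IV"] * 3
        st, groups = self._states_from({"L1": col, "L2": col}, {"L1": col, "L2": col})
        part = partition_loci(st, 0.05)
        dm = run_dm_tests(st, part, groups)
        assert not dm.significant.any()

    def test_strong_shift_ranks_first(self):
        null_col = ["I", "II", "III", "IV"] * 6
        shift_f = ["I"] * 12 + ["II"] * 12
        shift_m = ["IV"] * 12 + ["II"] * 12
        st, groups = self._states_from(
            {"L1": null_col, "L2": shift_f}, {"L1": null_col, "L2": shift_m}
        )
        part = partition_loci(st, 0.05)
        dm = run_dm_tests(st, part, groups)
        assert dm.iloc[0]["locus_id"] == "L2" and dm.iloc[0]["significant"]

    def test_fdr_zero_never_significant(self):
        rng = np.random.default_rng(34)
        df = pd.DataFrame(
            rng.choice(["I", "II", "III", "IV"], size=(20, 10)),
            index=[f"s{i}" for i in range(20)],
        )
        groups = {f"s{i}": ("field" if i < 10 else "micro") for i in range(20)}
        st = MethylationStateMatrix(df, "E")
        part = partition_loci(st, 0.0)
        dm = run_dm_tests(st, part, groups, fdr=0.0)
        assert not dm.significant.any()

    def test_binary_mode_collapses_states(self):
        col_f = ["I"] * 10 + ["II"] * 2
        col_m = ["IV"] * 10 + ["III"] * 2
        st, groups = self._states_from({"L1": col_f}, {"L1": col_m})
        part = partition_loci(st, 0.05)
        dm = run_dm_tests(st, part, groups, binary=True)
        assert {"n_field_unmeth", "n_field_meth"} <= set(dm.columns)
        assert dm.iloc[0]["n_field_unmeth"] == 10


def naive_upgma_cophenetic(values: np.ndarray) -> np.ndarray:
    """Independent UPGMA oracle: recompute all cluster distances from the
    original matrix at every step (no Lance-Williams update)."""
    n = values.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([values[i, j] for i in clusters[a] for j in clusters[b]])
            key = (d, min(clusters[a] | clusters[b]), max(min(clusters[a]), min(clusters[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return coph


class TestUpgma:
    def test_hand_computed_two_step(self):
        v = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        D = DistanceMatrix(v, ["A", "B", "C"], "gower")
        dend = upgma(D)
        assert dend.merges[0][:3] == (0, 1, 1.0)
        assert dend.merges[1][2] == 2.0
        assert dend.leaf_order() == ["A", "B", "C"]

    def test_equal_distances_tie_break_deterministic(self):
        v = np.ones((4, 4)) - np.eye(4)
        D = DistanceMatrix(v, list("abcd"), "gower")
        dend = upgma(D)
        heights = [m[2] for m in dend.merges]
        assert all(h == pytest.approx(0.5) for h in heights)
        assert dend.merges[0][:2] == (0, 1)  # smallest leaf indices first

    def test_cophenetic_matches_naive_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            pts = rng.normal(size=(n, 3))
            v = ((pts[:, None] - pts[None, :]) ** 2).sum(-1)
            D = DistanceMatrix(v, [f"s{i}" for i in range(n)], "gower")
            got = upgma(D).cophenetic().to_numpy()
            ref = naive_upgma_cophenetic(v)
            assert np.allclose(got, ref, atol=1e-10)

    def test_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(8, 4))
        v = ((pts[:, None] - pts[None, :]) ** 2).sum(-1)
        D = DistanceMatrix(v, [f"s{i}" for i in range(8)], "gower")
        got = upgma(D).cophenetic().to_numpy()
        ref = squareform(cophenet(average(squareform(v))))
        assert np.allclose(got, ref, atol=1e-10)

    def test_ultrametric_heights_non_decreasing(self):
        rng = np.random.default_rng(43)
        v = rng.random((10, 10)); v = (v + v.T) / 2; np.fill_diagonal(v, 0)
        D = DistanceMatrix(v, [f"s{i}" for i in range(10)], "gower")
        dend = upgma(D)
        n = 10
        heights = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _) in enumerate(dend.merges):
            assert h >= heights[a] - 1e-12 and h >= heights[b] - 1e-12
            heights[n + k] = h

    def test_newick_parses_and_is_ultrametric(self):
        pytest.importorskip("Bio")
        import io
        from Bio import Phylo
        rng = np.random.default_rng(44)
        pts = rng.normal(size=(6, 2))
        v = ((pts[:, None] - pts[None, :]) ** 2).sum(-1)
        D = DistanceMatrix(v, [f"s{i}" for i in range(6)], "gower")
        dend = upgma(D)
        tree = Phylo.read(io.StringIO(dend.to_newick()), "newick")
        depths = tree.depths()
        leaf_depths = [d for c, d in depths.items() if c.is_terminal()]
        assert np.allclose(leaf_depths, leaf_depths[0], atol=1e-9)

    def test_single_sample_is_error(self):
        D = DistanceMatrix(np.zeros((1, 1)), ["a"], "gower")
        with pytest.raises(ValueError):
            upgma(D)


class TestHeatmapExport:
    def test_tsv_matches_state_subset_and_leaf_order(self, tmp_path):
        from epimsap.diffmeth import heatmap_export
        df = pd.DataFrame(
            {"L1": ["I", "II", "III", "IV"], "L2": ["IV", "IV", "I", "I"]},
            index=list("abcd"),
        )
        st = MethylationStateMatrix(df, "E")
        groups = {"a": "field", "b": "field", "c": "micro", "d": "micro"}
        D = pairwise_distance(df, "gower")
        dend = upgma(D)
        tsv = tmp_path / "h.tsv"
        png = tmp_path / "h.png"
        heatmap_export(st, ["L1", "L2"], groups, dend, tsv, png)
        assert png.exists()
        out = pd.read_csv(tsv, sep="\t").set_index("sample_id")
        assert list(out.index) == dend.leaf_order()
        for sid in out.index:
            assert out.loc[sid, "L1"] == df.loc[sid, "L1"]

    def test_zero_significant_loci_header_only(self, tmp_path):
        df = pd.DataFrame({"L1": ["I", "II"]}, index=["a", "b"])
        st = MethylationStateMatrix(df, "E")
        from epimsap.diffmeth import heatmap_export
        tsv = tmp_path / "h.tsv"
        out = heatmap_export(st, [], {"a": "field", "b": "micro"}, None, tsv, tmp_path / "h.png")
        assert out is None
        lines = tsv.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("sample_id")
        assert not (tmp_path / "h.png").exists()
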