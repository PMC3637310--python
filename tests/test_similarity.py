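"""Similarity scoring and UPGMA clustering against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

import estrofinger as ef


def brute_force_upgma_heights(dist: pd.DataFrame):
    """O(n^3) UPGMA oracle: average recomputed from the raw leaf distances."""
    clusters = {frozenset([n]) for n in dist.index}
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters, key=sorted), 2):
            d = np.mean([dist.loc[x, y] for x in a for y in b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters = (clusters - {a, b}) | {a | b}
    return heights


class TestSpearmanSimilarity:
    def test_self_correlation_is_one(self):
        fc = {f"p{i}": float(i) for i in range(5)}
        assert ef.spearman_similarity(fc, fc).rho == pytest.approx(1.0)

    def test_rank_reversal_is_minus_one(self):
        fc = {f"p{i}": float(i) for i in range(5)}
        rev = {f"p{i}": float(-i) for i in range(5)}
        assert ef.spearman_similarity(fc, rev).rho == pytest.approx(-1.0)

    def test_too_few_probes_rejected(self):
        with pytest.raises(ef.ValidationError):
            ef.spearman_similarity({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 0.0})

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        a = {f"p{i}": v for i, v in enumerate(rng.normal(size=30))}
        b = {f"p{i}": v for i, v in enumerate(rng.normal(size=30))}
        assert ef.spearman_similarity(a, b).rho == pytest.approx(
            ef.spearman_similarity(b, a).rho)

    @pytest.mark.parametrize("transform", [np.exp, lambda x: x**3, lambda x: 5 * x - 2])
    def test_invariant_under_monotone_transform(self, transform):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=25)
        a = {f"p{i}": v for i, v in enumerate(vals)}
        b = {f"p{i}": v for i, v in enumerate(rng.normal(size=25))}
        base = ef.spearman_similarity(a, b).rho
        warped = {k: float(transform(v)) for k, v in a.items()}
        assert ef.spearman_similarity(warped, b).rho == pytest.approx(base)

    def test_universe_restriction(self):
        rng = np.random.default_rng(2)
        a = {f"p{i}": v for i, v in enumerate(rng.normal(size=20))}
        b = {f"p{i}": v for i, v in enumerate(rng.normal(size=20))}
        sub = [f"p{i}" for i in range(8)]
        res = ef.spearman_similarity(a, b, universe=sub)
        assert res.n_probes == 8
        direct = ef.spearman_similarity(
            {k: a[k] for k in sub}, {k: b[k] for k in sub})
        assert res.rho == pytest.approx(direct.rho)


class TestSimilarityMatrix:
    def test_identical_contrasts_off_diagonal_one(self):
        fc = {f"p{i}": float(i) for i in range(6)}
        mat = ef.similarity_matrix({"a": fc, "b": dict(fc)})
        assert mat.loc["a", "b"] == pytest.approx(1.0)
        assert (np.diag(mat) == 1.0).all()

    def test_consistent_with_pairwise_calls(self):
        rng = np.random.default_rng(3)
        contrasts = {n: {f"p{i}": v for i, v in enumerate(rng.normal(size=15))}
                     for n in ("x", "y", "z")}
        mat = ef.similarity_matrix(contrasts)
        for a, b in itertools.combinations(contrasts, 2):
            assert mat.loc[a, b] == pytest.approx(
                ef.spearman_similarity(contrasts[a], contrasts[b]).rho)
            assert mat.loc[a, b] == mat.loc[b, a]


class TestAverageLinkage:
    def test_identical_profiles_merge_at_zero(self):
        x = np.array([1.0, 2.0, 3.0, 1.5])
        tree = ef.average_linkage_cluster({"a": x, "b": x.copy(), "c": -x})
        assert tree.merges[0][:3] == ("a", "b", pytest.approx(0.0))

    def test_three_item_hand_example(self):
        dist = pd.DataFrame(
            [[0.0, 0.1, 0.4], [0.1, 0.0, 0.5], [0.4, 0.5, 0.0]],
            index=list("ABC"), columns=list("ABC"))
        tree = ef.average_linkage_cluster(distance_matrix=dist)
        assert tree.merges[0] == ("A", "B", pytest.approx(0.1), 2)
        assert tree.merges[1][2] == pytest.approx(0.45)  # mean(0.4, 0.5)

    def test_lexicographic_tie_breaking(self):
        dist = pd.DataFrame(0.5, index=list("DCBA"), columns=list("DCBA"))
        np.fill_diagonal(dist.values, 0.0)
        tree = ef.average_linkage_cluster(distance_matrix=dist)
        assert tree.merges[0][:2] == ("A", "B")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        raw = rng.uniform(0.01, 2.0, size=(n, n))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        names = [f"i{k:02d}" for k in range(n)]
        dist = pd.DataFrame(d, index=names, columns=names)
        tree = ef.average_linkage_cluster(distance_matrix=dist)
        np.testing.assert_allclose(tree.heights, brute_force_upgma_heights(dist),
                                   rtol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_average_linkage_heights(self, seed):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(100 + seed)
        n = 10
        raw = rng.uniform(0.01, 2.0, size=(n, n))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        names = [f"i{k}" for k in range(n)]
        tree = ef.average_linkage_cluster(
            distance_matrix=pd.DataFrame(d, index=names, columns=names))
        scipy_heights = linkage(squareform(d), method="average")[:, 2]
        np.testing.assert_allclose(sorted(tree.heights), sorted(scipy_heights),
                                   rtol=1e-10)

    def test_heights_nondecreasing_and_leaves_preserved(self):
        rng = np.random.default_rng(42)
        profiles = {f"item{k}": rng.normal(size=20) for k in range(7)}
        tree = ef.average_linkage_cluster(profiles)
        assert np.all(np.diff(tree.heights) >= -1e-12)
        assert sorted(tree.leaf_order()) == sorted(profiles)

    def test_constant_profile_gets_unit_distance_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            dist = ef.correlation_distance_matrix(
                {"flat": np.ones(5), "x": np.arange(5.0), "y": -np.arange(5.0)})
        assert dist.loc["flat", "x"] == pytest.approx(1.0)
        assert any("constant" in r.message for r in caplog.records)

    def test_newick_parses_with_matching_tips(self):
        import skbio

        rng = np.random.default_rng(7)
        profiles = {f"t{k}": rng.normal(size=12) for k in range(5)}
        tree = ef.average_linkage_cluster(profiles)
        parsed = skbio.TreeNode.read([tree.to_newick()])
        assert sorted(t.name for t in parsed.tips()) == sorted(profiles)
        # ultrametric: every tip equidistant from the root (height/2)
        depths = {t.name: t.accumulate_to_ancestor(parsed) for t in parsed.tips()}
        np.testing.assert_allclose(list(depths.values()),
                                   tree.merges[-1][2] / 2, rtol=1e-4)

    def test_reference_and_top_dose_merge_first_on_signature_profiles(self):
        """Signature-restricted fold-change profiles put the reference next to
        the top-dose query before either joins a lower dose."""
        matrix, _ = ef.generate_experiment(ef.SimulationConfig(seed=1))
        contrasts = ef.compute_contrasts(matrix)
        sig = ef.derive_signature(contrasts)
        profiles = {"EM": contrasts.reference.log2_fc_map(sig.probe_ids).to_numpy()}
        for dose in contrasts.doses:
            t = contrasts.by_dose[dose]
            profiles[t.treatment_group] = t.log2_fc_map(sig.probe_ids).to_numpy()
        tree = ef.average_linkage_cluster(profiles)
        assert set(tree.merges[0][:2]) == {"EM", "SH"}


class TestMedianCenterRows:
    def test_simple_row(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p"], columns=list("abc"))
        centered, _, _ = ef.median_center_rows(df)
        np.testing.assert_allclose(centered.loc["p"], [-1.0, 0.0, 1.0])

    def test_constant_row_all_zero(self):
        df = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]],
                          index=["flat", "p"], columns=list("abc"))
        centered, _, _ = ef.median_center_rows(df)
        np.testing.assert_allclose(centered.loc["flat"], 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(6, 8)),
                          index=[f"p{i}" for i in range(6)],
                          columns=[f"s{i}" for i in range(8)])
        once, row_order, col_order = ef.median_center_rows(df)
        twice, row2, col2 = ef.median_center_rows(once)
        pd.testing.assert_frame_equal(once, twice)
        assert row_order == row2 and col_order == col2

    def test_empty_subset_rejected(self):
        df = pd.DataFrame([[1.0]], index=["p"], columns=["a"])
        with pytest.raises(ef.ValidationError):
            ef.median_center_rows(df, probes=[])
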