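"""Differential-expression statistics against hand and library oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import estrofinger as ef
from conftest import random_matrix


def brute_force_bh(p):
    """Step-up BH by direct definition: q_i = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q[order[rank - 1]] = min(running, 1.0)
    return q


class TestFoldChange:
    def test_equal_means_give_unit_fc(self):
        assert ef.fold_change([5, 5, 5], [5, 5, 5])[1] == pytest.approx(1.0)

    def test_two_log_units(self):
        log2_fc, fc = ef.fold_change([10.0], [8.0])
        assert log2_fc == pytest.approx(2.0)
        assert fc == pytest.approx(4.0)

    def test_hand_arithmetic(self):
        log2_fc, fc = ef.fold_change([9.0, 9.5, 10.0], [8.0, 8.2, 8.4])
        assert log2_fc == pytest.approx(1.3)
        assert fc == pytest.approx(2.4623, abs=1e-4)

    def test_empty_group_rejected(self):
        with pytest.raises(ef.ValidationError):
            ef.fold_change([], [1.0])


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = ef.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_hand_example(self):
        t, p = ef.two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742, abs=1e-4)
        assert p == pytest.approx(0.0213, abs=1e-4)

    def test_constant_unequal_groups_degenerate(self):
        with pytest.warns(UserWarning, match="zero"):
            t, p = ef.two_sample_t([5, 5, 5], [7, 7, 7])
        assert p == 0.0 and np.isinf(t)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n1=st.integers(2, 8), n2=st.integers(2, 8))
    def test_matches_scipy_pooled(self, seed, n1, n2):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=n1), rng.normal(size=n2)
        t, p = ef.two_sample_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=4), rng.normal(size=5)
        t_ab, p_ab = ef.two_sample_t(a, b)
        t_ba, p_ba = ef.two_sample_t(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)


class TestContrastTable:
    def test_vectorised_matches_scalar_ops(self):
        """Per-probe table agrees with the scalar fold_change/two_sample_t route."""
        matrix = random_matrix(seed=7, n_probes=10)
        table = ef.contrast_table(matrix, "EM", "C").table
        for probe in matrix.probe_ids:
            treat = matrix.group_values("EM").loc[probe]
            ctrl = matrix.group_values("C").loc[probe]
            log2_fc, fc = ef.fold_change(treat, ctrl)
            t, p = ef.two_sample_t(treat, ctrl)
            assert table.at[probe, "log2_fc"] == pytest.approx(log2_fc)
            assert table.at[probe, "fc"] == pytest.approx(fc)
            assert table.at[probe, "t_statistic"] == pytest.approx(t)
            assert table.at[probe, "p_value"] == pytest.approx(p)

    def test_fc_swap_reciprocal(self):
        matrix = random_matrix(seed=8, n_probes=6)
        fwd = ef.contrast_table(matrix, "EM", "C").table
        rev = ef.contrast_table(matrix, "C", "EM").table
        np.testing.assert_allclose(fwd["fc"] * rev["fc"], 1.0, rtol=1e-10)
        np.testing.assert_allclose(fwd["t_statistic"], -rev["t_statistic"], rtol=1e-10)

    def test_welch_differs_from_pooled_on_unequal_variance(self):
        matrix = random_matrix(seed=9, n_probes=40)
        pooled = ef.contrast_table(matrix, "EM", "C", welch=False).table
        welch = ef.contrast_table(matrix, "EM", "C", welch=True).table
        assert not np.allclose(pooled["p_value"], welch["p_value"])


class TestBHFDR:
    def test_single_p(self):
        assert ef.bh_fdr([0.05]) == pytest.approx([0.05])

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(ef.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_p_of_one(self):
        assert ef.bh_fdr([1.0]) == pytest.approx([1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ef.ValidationError):
            ef.bh_fdr([0.5, 1.5])

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 1000))
    def test_matches_brute_force_step_up(self, seed, n):
        p = np.random.default_rng(seed).uniform(size=n)
        np.testing.assert_allclose(ef.bh_fdr(p), brute_force_bh(p), rtol=1e-12)

    def test_monotone_in_p_ranked_order(self):
        p = np.random.default_rng(3).uniform(size=200)
        q = ef.bh_fdr(p)
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)


class TestInitialFilter:
    def test_examples(self):
        import pandas as pd
        table = ef.ContrastTable("x", pd.DataFrame(
            {
                "mean_log2_treatment": [1, 1, 1],
                "mean_log2_control": [0, 0, 0],
                "log2_fc": [1.0, -1.0, 2.32],
                "fc": [2.0, 0.5, 5.0],
                "t_statistic": [3.0, -3.0, 1.0],
                "p_value": [0.01, 0.01, 0.2],
            },
            index=["up_probe", "down_probe", "big_but_flat_p"],
        ))
        kept = ef.initial_filter(table)
        assert "up_probe" in kept           # p=0.01, fc=2.0
        assert "down_probe" in kept         # down-regulation, 1/0.5 = 2 > 1.5
        assert "big_but_flat_p" not in kept  # fc=5 but p=0.2

    def test_null_calibration(self):
        """On a no-effect simulation the p<0.05 fraction is 0.05 +/- 3 SE."""
        cfg = ef.SimulationConfig(
            n_probes=10_000, n_signature_up=0, n_signature_down=0,
            n_query_specific=0, seed=17)
        matrix, _ = ef.generate_experiment(cfg)
        table = ef.contrast_table(matrix, "EM", "C").table
        frac = (table["p_value"] < 0.05).mean()
        band = 3 * np.sqrt(0.05 * 0.95 / cfg.n_probes)
        assert abs(frac - 0.05) < band


class TestCollapseToGenes:
    def test_shared_symbol_counts_once(self):
        ann = ef.ProbeAnnotation.from_mapping(
            {"p1": ("GENE_A", ""), "p2": ("GENE_A", ""), "p3": ("GENE_B", "")})
        n, genes, unann = ef.collapse_to_genes(["p1", "p2", "p3"], ann)
        assert n == 2 and genes == ["GENE_A", "GENE_B"] and unann == []

    def test_empty_symbol_not_a_gene(self):
        ann = ef.ProbeAnnotation.from_mapping({"p1": ("", ""), "p2": ("GENE_A", "")})
        n, genes, unann = ef.collapse_to_genes(["p1", "p2"], ann)
        assert n == 1 and unann == ["p1"]

    def test_fixture_gene_count(self, table1, table1_ann):
        n, genes, unann = ef.collapse_to_genes(table1["E2"].probe_ids, table1_ann)
        assert n == 34
        assert sorted(unann) == ["1557277_a_at", "237334_at"]
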