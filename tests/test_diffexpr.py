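"""Rank-sum DEG testing, BH adjustment, Fisher combination and smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import avec
from avec.dataset import ValidationError
from avec.synthetic import ClusterProgram, SyntheticSpec
from conftest import cluster_cells, norm_dataset


class TestBH:
    def test_closed_form_example(self):
        np.testing.assert_allclose(
            avec.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert avec.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_reference_implementation(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(5):
            p = rng.uniform(size=rng.integers(1, 200))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(avec.bh_adjust(p), expected, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            avec.bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_monotone_in_sorted_order(self, p):
        adj = avec.bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all((adj >= np.asarray(p) - 1e-12) & (adj <= 1))


def two_group_dataset(norm1, norm2):
    norm = np.concatenate([norm1, norm2], axis=1)
    ds = norm_dataset(norm)
    g1 = ds.cells[: norm1.shape[1]]
    g2 = ds.cells[norm1.shape[1]:]
    return ds, g1, g2


class TestWilcoxonDEG:
    def test_low_expression_gene_not_tested(self):
        rng = np.random.default_rng(1)
        norm = rng.uniform(1, 2, size=(3, 40))
        norm[0] = 0.0
        norm[0, [0, 1, 20, 21]] = 1.0  # 10% expressing in both groups
        ds, g1, g2 = two_group_dataset(norm[:, :20], norm[:, 20:])
        table = avec.rank_test_table(ds, g1, g2, min_pct=0.25)
        assert "g0" not in set(table["gene"])

    def test_identical_groups_retain_nothing(self):
        rng = np.random.default_rng(2)
        half = rng.uniform(0.5, 2, size=(20, 15))
        ds, g1, g2 = two_group_dataset(half, half)
        assert avec.wilcoxon_deg(ds, g1, g2).empty

    def test_overlapping_groups_error(self):
        rng = np.random.default_rng(3)
        ds, g1, g2 = two_group_dataset(
            rng.uniform(1, 2, (5, 6)), rng.uniform(1, 2, (5, 6))
        )
        with pytest.raises(ValidationError, match="overlap"):
            avec.wilcoxon_deg(ds, g1, g1)

    def test_planted_contrast_recovery(self):
        spec = SyntheticSpec(
            n_genes=600,
            n_cells=200,
            cluster_profile=[
                ClusterProgram("hi", 0.5, {f"de_{i}": 2.0 for i in range(40)}),
                ClusterProgram("lo", 0.5, {}),
            ],
            seed=8,
        )
        ds, truth = avec.generate_vec_dataset(spec)
        degs = avec.wilcoxon_deg(
            ds, cluster_cells(truth, "hi"), cluster_cells(truth, "lo")
        )
        up = set(degs.loc[degs["direction"] == "up", "gene"])
        planted = truth.de_genes["hi"]
        assert len(up & planted) / len(planted) >= 0.9
        null_called = len(set(degs["gene"]) - planted)
        assert null_called <= 0.05 * (spec.n_genes - len(planted))

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(4)
        a = rng.gamma(2, 1, size=(30, 12))
        b = rng.gamma(2, 1.4, size=(30, 12))
        ds, g1, g2 = two_group_dataset(a, b)
        fwd = avec.rank_test_table(ds, g1, g2).set_index("gene")
        rev = avec.rank_test_table(ds, g2, g1).set_index("gene")
        np.testing.assert_allclose(fwd["p"], rev.loc[fwd.index, "p"], atol=1e-12)
        np.testing.assert_allclose(
            fwd["fold_change"], 1 / rev.loc[fwd.index, "fold_change"], rtol=1e-6
        )


class TestFisher:
    def test_two_p_closed_form(self):
        x = -2 * 2 * np.log(0.05)
        expected = stats.chi2.sf(x, df=4)
        assert avec.fisher_combine([0.05, 0.05]) == pytest.approx(expected)
        assert expected == pytest.approx(0.0175, abs=2e-4)

    def test_unit_p(self):
        assert avec.fisher_combine([1.0]) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(1e-12, 1.0))
    def test_single_p_identity(self, p):
        assert avec.fisher_combine([p]) == pytest.approx(p, rel=1e-9)

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = avec.fisher_combine([0.0, 0.5])
        assert 0 <= out < 1e-200


class TestSmooth:
    def test_constant_series_unchanged(self):
        out = avec.smooth_over_cells(np.full(30, 2.5), np.arange(30), window=20)
        np.testing.assert_allclose(out, 2.5)

    def test_window_one_is_identity(self):
        v = np.arange(10.0)
        np.testing.assert_allclose(
            avec.smooth_over_cells(v, np.arange(10), window=1), v
        )

    def test_matches_direct_loop(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=57)
        order = rng.permutation(57)
        out = avec.smooth_over_cells(v, order, window=20)
        ordered = v[order]
        for pos in range(57):
            lo = max(0, pos - 10)  # pandas centered window of 20: 10 left, 9 right
            hi = min(57, pos + 10)
            assert out[order[pos]] == pytest.approx(ordered[lo:hi].mean(), abs=1e-12)

    def test_invalid_window_and_order(self):
        with pytest.raises(ValidationError):
            avec.smooth_over_cells([1.0, 2.0], [0, 1], window=0)
        with pytest.raises(ValidationError):
            avec.smooth_over_cells([1.0, 2.0], [0, 0], window=2)


class TestPatternGenes:
    @pytest.fixture(scope="class")
    def staged(self):
        spec = SyntheticSpec(
            n_genes=300,
            n_cells=240,
            cluster_profile=[
                ClusterProgram("EP1", 1 / 3, {}),
                ClusterProgram("EP2", 1 / 3, {f"seg_{i}": 2.0 for i in range(10)}),
                ClusterProgram(
                    "EP3",
                    1 / 3,
                    {**{f"seg_{i}": 2.0 for i in range(10)},
                     **{f"str_{i}": 2.0 for i in range(10)}},
                ),
            ],
            seed=9,
        )
        ds, truth = avec.generate_vec_dataset(spec)
        table = avec.pattern_genes(
            ds,
            cluster_cells(truth, "EP1"),
            cluster_cells(truth, "EP2"),
            cluster_cells(truth, "EP3"),
        )
        return table.set_index("gene")

    def test_sustained_upregulation_is_segregation(self, staged):
        seg = [g for g in staged.index if g.startswith("seg_")]
        assert len(seg) >= 9
        assert (staged.loc[seg, "category"] == "arterial_segregation").all()

    def test_late_upregulation_is_strengthening(self, staged):
        stren = [g for g in staged.index if g.startswith("str_")]
        assert len(stren) >= 9
        assert (staged.loc[stren, "category"] == "arterial_strengthening").all()

    def test_flat_genes_absent(self, staged):
        flat = [g for g in staged.index if g.startswith("g0")]
        assert len(flat) <= 3
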