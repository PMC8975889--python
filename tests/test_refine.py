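"""Random-forest vote-probability cluster refinement."""

import numpy as np
import pandas as pd
import pytest

import avec
from avec.dataset import ValidationError
from avec.refine import RefinementConfig
from conftest import norm_dataset

FAST = RefinementConfig(n_folds=5, n_runs=5, n_trees=60, seed=0)


def block_dataset(n_per=10, n_genes=20, noise=0.0, seed=0):
    """Two cell blocks with anti-correlated profiles over the gene panel."""
    rng = np.random.default_rng(seed)
    shape = rng.normal(size=n_genes)
    a = np.tile(shape[:, None], (1, n_per))
    b = np.tile(-shape[:, None], (1, n_per))
    norm = np.concatenate([a, b], axis=1) + 5.0
    if noise:
        norm += rng.normal(scale=noise, size=norm.shape)
    return norm_dataset(norm)


class TestConfig:
    def test_vote_threshold_ordering_enforced(self):
        with pytest.raises(ValidationError):
            RefinementConfig(train_vote_min=0.5, keep_vote_min=0.6)
        with pytest.raises(ValidationError):
            RefinementConfig(keep_vote_min=0.4)


class TestInitialSplit:
    def test_anticorrelated_blocks_split_exactly(self):
        ds = block_dataset()
        labels = avec.initial_split(ds, ds.cells, ds.genes)
        first, second = labels.iloc[:10], labels.iloc[10:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_three_cells_split_one_vs_two(self):
        ds = block_dataset(n_per=3).subset_cells(["c0", "c1", "c5"])
        labels = avec.initial_split(ds, ds.cells, ds.genes)
        assert sorted(labels.value_counts()) == [1, 2]

    def test_constant_cell_assigned_by_neighbor(self):
        ds = block_dataset(noise=0.05)
        ds.norm[:, 0] = 7.0  # degenerate profile
        with pytest.warns(UserWarning, match="constant"):
            labels = avec.initial_split(ds, ds.cells, ds.genes)
        assert labels.iloc[0] in {"A", "B"}


class TestFeatureSelect:
    def test_planted_informative_genes_dominate_selection(self):
        rng = np.random.default_rng(1)
        n_cells = 100
        informative = np.repeat([0.0, 2.0], n_cells // 2)
        norm = rng.normal(2.0, 0.5, size=(120, n_cells))
        norm[:20] += informative[None, :]
        ds = norm_dataset(norm)
        labels = pd.Series(
            np.repeat(["A", "B"], n_cells // 2), index=ds.cells, name="cluster"
        )
        ranked = avec.rf_feature_select(ds, labels, ds.genes, FAST)
        selected = set(ranked.loc[ranked["selected"], "gene"])
        informative_names = {f"g{i}" for i in range(20)}
        assert len(selected & informative_names) / len(selected) >= 0.8
        assert ranked["gene"].iloc[0] in informative_names

    def test_permuted_labels_select_at_chance(self):
        rng = np.random.default_rng(2)
        n_cells = 100
        informative = np.repeat([0.0, 2.0], n_cells // 2)
        norm = rng.normal(2.0, 0.5, size=(120, n_cells))
        norm[:20] += informative[None, :]
        ds = norm_dataset(norm)
        labels = pd.Series(
            rng.permutation(np.repeat(["A", "B"], n_cells // 2)),
            index=ds.cells,
            name="cluster",
        )
        ranked = avec.rf_feature_select(ds, labels, ds.genes, FAST)
        selected = ranked.loc[ranked["selected"], "gene"]
        frac_informative = selected.isin([f"g{i}" for i in range(20)]).mean()
        assert frac_informative < 0.5  # no enrichment beyond chance + noise


class TestRefineLabels:
    @pytest.fixture(scope="class")
    def separable(self):
        rng = np.random.default_rng(3)
        n = 160
        truth = np.repeat(["A", "B"], n // 2)
        norm = rng.normal(2.0, 0.4, size=(30, n))
        norm[:15, truth == "A"] += 1.5
        ds = norm_dataset(norm)
        return ds, pd.Series(truth, index=ds.cells, name="cluster")

    def test_clean_labels_unchanged(self, separable):
        ds, labels = separable
        out = avec.refine_labels(ds, labels, ds.genes[:30], FAST)
        assert (out == labels).mean() >= 0.99

    def test_planted_flips_restored(self, separable):
        ds, labels = separable
        rng = np.random.default_rng(4)
        flipped = labels.copy()
        flip_idx = rng.choice(len(labels), size=16, replace=False)
        flipped.iloc[flip_idx] = np.where(
            flipped.iloc[flip_idx] == "A", "B", "A"
        )
        out = avec.refine_labels(ds, flipped, ds.genes[:30], FAST)
        restored = (out.iloc[flip_idx] == labels.iloc[flip_idx]).mean()
        assert restored >= 0.95

    def test_unseparable_data_aborts_with_warning(self):
        norm = np.ones((10, 40)) * 2.0
        ds = norm_dataset(norm)
        labels = pd.Series(
            np.repeat(["A", "B"], 20), index=ds.cells, name="cluster"
        )
        with pytest.warns(UserWarning, match="aborted"):
            out = avec.refine_labels(ds, labels, ds.genes, FAST)
        assert out.equals(labels)


class TestCVFilter:
    def test_conflicting_duplicate_discarded(self):
        rng = np.random.default_rng(5)
        n = 60
        truth = np.repeat(["A", "B"], n // 2)
        norm = rng.normal(2.0, 0.3, size=(20, n))
        norm[:10, truth == "A"] += 2.0
        # duplicate cell 0's profile into the other class
        norm = np.concatenate([norm, norm[:, [0]]], axis=1)
        ds = norm_dataset(norm)
        labels = pd.Series(
            list(truth) + ["B"], index=ds.cells, name="cluster"
        )
        res = avec.cv_filter(ds, labels, ds.genes, FAST)
        assert ds.cells[-1] in res.discarded  # the conflicted copy
        assert res.mean_vote.loc[ds.cells[-1]] < 0.55

    def test_well_separated_discards_nothing(self, refine_data):
        ds, truth = refine_data
        labels = truth.cells["true_cluster"].rename("cluster")
        sub = ds.subset_cells(ds.cells[:60] + ds.cells[150:210])
        res = avec.cv_filter(
            sub, labels.loc[sub.cells], [f"fa_{i}" for i in range(25)] + [f"fb_{i}" for i in range(25)], FAST
        )
        assert len(res.discarded) == 0

    def test_keep_vote_boundary_and_monotonicity(self, refine_data):
        ds, truth = refine_data
        sub = ds.subset_cells(ds.cells[:60] + ds.cells[150:210])
        labels = truth.cells["true_cluster"].loc[sub.cells].rename("cluster")
        feats = [f"fa_{i}" for i in range(25)] + [f"fb_{i}" for i in range(25)]
        loose = avec.cv_filter(sub, labels, feats, FAST)
        strict_cfg = RefinementConfig(
            n_folds=5, n_runs=5, n_trees=60, seed=0,
            train_vote_min=0.9, keep_vote_min=0.9,
        )
        strict = avec.cv_filter(sub, labels, feats, strict_cfg)
        assert set(loose.discarded) <= set(strict.discarded)
        # discard rule exactness from diagnostics
        for res, cfg in ((loose, FAST), (strict, strict_cfg)):
            expected = set(res.mean_vote.index[res.mean_vote < cfg.keep_vote_min])
            assert expected == set(res.discarded)


class TestFineTune:
    def test_flip_recovery_and_determinism(self, refine_data):
        ds, truth = refine_data
        sub_cells = ds.cells[:75] + ds.cells[150:225]
        sub = ds.subset_cells(sub_cells)
        labels = truth.cells["observed_cluster"].loc[sub_cells].rename("cluster")
        res = avec.fine_tune_clusters(sub, labels, FAST)
        retained = res.labels[res.labels != "discarded"]
        true = truth.cells.loc[retained.index, "true_cluster"]
        mapping = {
            lab: true[retained == lab].mode()[0] for lab in retained.unique()
        }
        acc = (retained.map(mapping) == true).mean()
        assert acc >= 0.95
        res2 = avec.fine_tune_clusters(sub, labels, FAST)
        assert res.labels.equals(res2.labels)
        np.testing.assert_allclose(res.mean_vote, res2.mean_vote)

    def test_identical_programs_negative_control(self):
        ds, truth = avec.generate_null_dataset(
            avec.null_spec(n_genes=300, n_cells=120, seed=10)
        )
        labels = truth.cells["true_cluster"].rename("cluster")
        with pytest.warns(UserWarning):
            res = avec.fine_tune_clusters(ds, labels, FAST)
        assert res.aborted or len(res.discarded) >= 0.3 * len(labels)
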