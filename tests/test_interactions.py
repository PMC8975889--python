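"""Ligand–receptor calling, threshold derivation and set algebra."""

import numpy as np
import pandas as pd
import pytest

import avec
from avec.dataset import ValidationError
from avec.interactions import MC_TO_VEC, VEC_TO_MC, REFERENCE_THRESHOLD
from conftest import norm_dataset


def pair_table(pairs):
    return pd.DataFrame(pairs, columns=["ligand", "receptor"])


class TestThreshold:
    def test_reference_constant(self):
        assert REFERENCE_THRESHOLD == 1.34

    def test_all_zero_matrix(self):
        ds = norm_dataset(np.zeros((4, 5)))
        assert avec.expression_threshold([ds]) == 0.0

    def test_percentile_convention_linear_interpolation(self):
        # per-gene means 0,1,2,3 -> 75th percentile 2.25
        norm = np.tile(np.array([0.0, 1.0, 2.0, 3.0])[:, None], (1, 6))
        ds = norm_dataset(norm)
        assert avec.expression_threshold([ds]) == pytest.approx(2.25)

    def test_empty_input_errors(self):
        with pytest.raises(ValidationError):
            avec.expression_threshold([])


class TestDetect:
    def test_uniform_expression_gives_single_directional_call(self):
        vec = norm_dataset(np.array([[0.0] * 6, [2.0] * 6]), genes=["L1", "R1"])
        mc = norm_dataset(np.array([[2.0] * 6, [0.0] * 6]), genes=["L1", "R1"])
        calls = avec.detect_interactions(vec, mc, pair_table([("L1", "R1")]), 1.34)
        assert len(calls) == 1
        assert calls[0].direction == MC_TO_VEC
        assert calls[0].ligand_frac == 1.0 and calls[0].receptor_frac == 1.0

    def test_exactly_half_expressing_is_not_called(self):
        vec = norm_dataset(np.array([[2.0] * 10]), genes=["R1"])
        mc_vals = np.array([[2.0] * 5 + [0.0] * 5])
        mc = norm_dataset(mc_vals, genes=["L1"])
        calls = avec.detect_interactions(vec, mc, pair_table([("L1", "R1")]), 1.34)
        assert calls == []

    def test_empty_pair_table_vacuous(self, mc_vec_data):
        vec, mc, _, _ = mc_vec_data
        assert avec.detect_interactions(vec, mc, pair_table([]), 1.0) == []

    def test_missing_gene_counts_as_silent(self):
        vec = norm_dataset(np.array([[2.0] * 4]), genes=["R1"])
        mc = norm_dataset(np.array([[2.0] * 4]), genes=["other"])
        assert avec.detect_interactions(vec, mc, pair_table([("L1", "R1")]), 1.0) == []

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(6)
        genes = [f"G{i}" for i in range(40)]
        vec = norm_dataset(rng.uniform(0, 3, size=(40, 25)), genes=genes)
        mc = norm_dataset(rng.uniform(0, 3, size=(40, 25)), genes=genes)
        pairs = pair_table(
            [
                (genes[rng.integers(40)], genes[rng.integers(40)])
                for _ in range(200)
            ]
        ).drop_duplicates()
        threshold, min_frac = 1.5, 0.5
        calls = avec.detect_interactions(vec, mc, pairs, threshold, min_frac)
        got = {(c.ligand, c.receptor, c.direction) for c in calls}

        def frac(ds, g):
            if g not in ds.genes:
                return 0.0
            return (ds.norm[ds.genes.index(g)] > threshold).mean()

        expected = set()
        for lig, rec in pairs.itertuples(index=False):
            if frac(mc, lig) > min_frac and frac(vec, rec) > min_frac:
                expected.add((lig, rec, MC_TO_VEC))
            if frac(vec, lig) > min_frac and frac(mc, rec) > min_frac:
                expected.add((lig, rec, VEC_TO_MC))
        assert got == expected

    def test_monotone_in_threshold_and_min_frac(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(20)]
        vec = norm_dataset(rng.uniform(0, 3, size=(20, 30)), genes=genes)
        mc = norm_dataset(rng.uniform(0, 3, size=(20, 30)), genes=genes)
        pairs = pair_table([(f"G{i}", f"G{19 - i}") for i in range(20)])

        def call_set(thr, mf):
            return {
                (c.ligand, c.receptor, c.direction)
                for c in avec.detect_interactions(vec, mc, pairs, thr, mf)
            }

        base = call_set(1.0, 0.5)
        assert call_set(1.5, 0.5) <= base
        assert call_set(1.0, 0.7) <= base

    def test_swapping_datasets_swaps_directions(self):
        rng = np.random.default_rng(8)
        genes = [f"G{i}" for i in range(15)]
        a = norm_dataset(rng.uniform(0, 3, size=(15, 20)), genes=genes)
        b = norm_dataset(rng.uniform(0, 3, size=(15, 20)), genes=genes)
        pairs = pair_table([(f"G{i}", f"G{(i + 3) % 15}") for i in range(15)])
        fwd = avec.detect_interactions(a, b, pairs, 1.2)
        rev = avec.detect_interactions(b, a, pairs, 1.2)
        flip = {MC_TO_VEC: VEC_TO_MC, VEC_TO_MC: MC_TO_VEC}
        assert {(c.ligand, c.receptor, flip[c.direction]) for c in fwd} == {
            (c.ligand, c.receptor, c.direction) for c in rev
        }

    def test_planted_pairs_called_perfectly(self, mc_vec_data):
        vec, mc, pairs, truth = mc_vec_data
        thr = avec.expression_threshold([vec, mc])
        calls = avec.detect_interactions(vec, mc, pairs, thr)
        got = {(c.ligand, c.receptor) for c in calls}
        assert got == set(truth.planted_pairs)
        assert all(c.direction == MC_TO_VEC for c in calls)
        assert all(
            c.ligand_frac > 0.5 and c.receptor_frac > 0.5 for c in calls
        )


class TestSetAlgebra:
    def test_venn_example(self):
        regions = avec.shared_distinct(
            {"s1": {("a", "x"), ("b", "y")}, "s2": {("b", "y"), ("c", "z")}, "s3": {("b", "y")}}
        )
        assert regions[frozenset({"s1", "s2", "s3"})] == {("b", "y")}
        assert regions[frozenset({"s1"})] == {("a", "x")}

    def test_disjoint_sets_have_no_shared_region(self):
        regions = avec.shared_distinct({"s1": {("a", "x")}, "s2": {("b", "y")}})
        assert frozenset({"s1", "s2"}) not in regions

    def test_counts_sum_to_union_on_random_sets(self):
        rng = np.random.default_rng(9)
        pool = [(f"L{i}", f"R{i}") for i in range(30)]
        sets = {
            f"s{k}": {pool[i] for i in rng.choice(30, size=12, replace=False)}
            for k in range(3)
        }
        regions = avec.shared_distinct(sets)
        union = set().union(*sets.values())
        assert sum(len(v) for v in regions.values()) == len(union)
        # brute-force region assignment
        for pair in union:
            key = frozenset(k for k, s in sets.items() if pair in s)
            assert pair in regions[key]


class TestNetwork:
    def _call(self, lig, rec, direction=MC_TO_VEC):
        return avec.InteractionCall(lig, rec, direction, 1.0, 1.0, 1.34)

    def test_single_edge_degrees(self):
        net = avec.interaction_network([self._call("L1", "R1")])
        edges = net[MC_TO_VEC]
        assert len(edges) == 1
        assert edges["ligand_degree"].iloc[0] == 1
        assert edges["receptor_degree"].iloc[0] == 1

    def test_hub_ligand_degree(self):
        calls = [self._call("L1", f"R{i}") for i in range(3)]
        edges = avec.interaction_network(calls)[MC_TO_VEC]
        assert (edges["ligand_degree"] == 3).all()

    def test_empty_calls_empty_network(self):
        net = avec.interaction_network([])
        assert net[MC_TO_VEC].empty and net[VEC_TO_MC].empty
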