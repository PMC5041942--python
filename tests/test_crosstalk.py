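import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mircross import crosstalk as ct
from mircross import diffexpr, regnet, synthdata
from mircross.config import SyntheticConfig
from mircross.errors import InputError
from mircross.io import ExpressionMatrix


def brute_force_pair_weight(set_i, set_j, diff_genes, ppi, expr, diff_p):
    """Naive double loop over all gene pairs, independent of the edge walk."""
    di = sorted(set_i & diff_genes)
    dj = sorted(set_j & diff_genes)
    total, count = 0.0, 0
    seen = set()
    for a in di:
        for b in dj:
            if a == b or not ppi.has_edge(a, b):
                continue
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            _, p_ab = regnet.correlate(expr.values.loc[a].to_numpy(),
                                       expr.values.loc[b].to_numpy())
            total += ct.edge_strength(diff_p[a], diff_p[b], p_ab)
            count += 1
    return total, count


def random_instance(rng, n_genes=14, n_samples=12):
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    expr = ExpressionMatrix(
        values=pd.DataFrame(rng.normal(size=(n_genes, n_samples)),
                            index=genes, columns=samples),
        feature_kind="gene")
    ppi = nx.Graph()
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < 0.3:
                ppi.add_edge(genes[i], genes[j])
    diff = set(rng.choice(genes, size=rng.integers(4, n_genes), replace=False))
    diff_p = {g: float(rng.uniform(1e-8, 1)) for g in genes}
    k_i = int(rng.integers(2, 8))
    k_j = int(rng.integers(2, 8))
    set_i = set(rng.choice(genes, size=k_i, replace=False))
    set_j = set(rng.choice(genes, size=k_j, replace=False))
    return genes, expr, ppi, diff, diff_p, set_i, set_j


class TestEdgeStrength:
    def test_unit_pvalues_give_zero(self):
        assert ct.edge_strength(1, 1, 1) == 0.0

    def test_analytic_value_exp_minus_one(self):
        assert ct.edge_strength(math.exp(-1), math.exp(-1), math.exp(-1)) == pytest.approx(6.0)

    def test_closed_form_at_five_percent(self):
        assert ct.edge_strength(0.05, 0.05, 0.05) == pytest.approx(-6 * math.log(0.05),
                                                                   abs=1e-10)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(InputError):
            ct.edge_strength(0.0, 0.5, 0.5)
        with pytest.raises(InputError):
            ct.edge_strength(-0.1, 0.5, 0.5)

    def test_monotone_in_each_argument(self, rng):
        for _ in range(50):
            p = rng.uniform(1e-6, 1, size=3)
            w = ct.edge_strength(*p)
            for k in range(3):
                q = p.copy()
                q[k] *= 0.5
                assert ct.edge_strength(*q) > w

    def test_floor_keeps_statistic_finite(self):
        assert np.isfinite(ct.edge_strength(1e-320, 1e-320, 1e-320))


class TestPairWeight:
    def test_no_qualifying_edges(self, rng):
        genes, expr, ppi, diff, diff_p, *_ = random_instance(rng)
        w, n = ct.pair_weight({"g0"}, {"g1"}, set(), ppi, expr, diff_p)
        assert (w, n) == (0.0, 0)

    def test_single_edge_equals_its_strength(self, rng):
        genes, expr, ppi, _, diff_p, *_ = random_instance(rng)
        a, b = next(iter(ppi.edges))
        w, n = ct.pair_weight({a}, {b}, {a, b}, ppi, expr, diff_p)
        _, p_ab = regnet.correlate(expr.values.loc[a].to_numpy(),
                                   expr.values.loc[b].to_numpy())
        assert n == 1
        assert w == pytest.approx(ct.edge_strength(diff_p[a], diff_p[b], p_ab))

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(25):
            genes, expr, ppi, diff, diff_p, set_i, set_j = random_instance(rng)
            w, n = ct.pair_weight(set_i, set_j, diff, ppi, expr, diff_p)
            w_ref, n_ref = brute_force_pair_weight(set_i, set_j, diff, ppi, expr, diff_p)
            assert n == n_ref
            assert w == pytest.approx(w_ref, rel=1e-10)

    def test_additive_over_disjoint_edge_sets(self, rng):
        genes, expr, ppi, _, diff_p, *_ = random_instance(rng, n_genes=16)
        diff = set(genes)
        set_i = {"g0", "g1"}
        set_j1, set_j2 = {"g2", "g3"}, {"g4", "g5"}
        w1, n1 = ct.pair_weight(set_i, set_j1, diff, ppi, expr, diff_p)
        w2, n2 = ct.pair_weight(set_i, set_j2, diff, ppi, expr, diff_p)
        w12, n12 = ct.pair_weight(set_i, set_j1 | set_j2, diff, ppi, expr, diff_p)
        assert n12 == n1 + n2
        assert w12 == pytest.approx(w1 + w2, rel=1e-10)

    def test_engine_agrees_with_direct_computation(self, rng):
        for _ in range(10):
            genes, expr, ppi, diff, diff_p, set_i, set_j = random_instance(rng)
            engine = ct.PermutationEngine(sorted(diff), ppi, expr, diff_p)
            w_fast, n_fast = engine.weight(engine.mask(set_i), engine.mask(set_j))
            w_ref, n_ref = ct.pair_weight(set_i, set_j, diff, ppi, expr, diff_p)
            assert n_fast == n_ref
            assert w_fast == pytest.approx(w_ref, rel=1e-10)


class TestPermutation:
    def test_pseudo_count_formula(self, rng):
        genes, expr, ppi, diff, diff_p, set_i, set_j = random_instance(rng)
        engine = ct.PermutationEngine(sorted(set(genes)), ppi, expr, diff_p)
        perm = engine.permuted_weights(3, 3, 99, np.random.default_rng(0))
        # an observed weight above every permuted one
        p = ct.permutation_p(perm.max() + 1.0, (3, 3), engine, 99,
                             np.random.default_rng(0))
        assert p == pytest.approx(1 / 100)

    def test_zero_weight_is_never_significant(self, rng):
        genes, expr, ppi, diff, diff_p, *_ = random_instance(rng)
        engine = ct.PermutationEngine(sorted(set(genes)), ppi, expr, diff_p)
        p = ct.permutation_p(0.0, (3, 3), engine, 49, np.random.default_rng(1))
        assert p == 1.0

    def test_pool_smaller_than_pathway_rejected(self, rng):
        genes, expr, ppi, diff, diff_p, *_ = random_instance(rng)
        engine = ct.PermutationEngine(sorted(set(genes))[:4], ppi, expr, diff_p)
        with pytest.raises(InputError):
            engine.permuted_weights(10, 2, 10, np.random.default_rng(0))


@pytest.fixture(scope="module")
def scored():
    ds = synthdata.generate_dataset(SyntheticConfig(seed=4))
    diff_g = diffexpr.call_all_contrasts(ds.gene_expr, ds.annotation)
    labels = pd.DataFrame({
        "pathway_id": sorted(ds.pathways.sets),
        "grade_association": "both", "direction": "up", "min_p": 0.0})
    graph, table = ct.build_crosstalk_network(
        labels, ds.pathways, ds.ppi, ds.gene_expr, diff_g,
        B=300, threshold=0.05, seed=7)
    return ds, graph, table


class TestNetworkBuild:

    def test_planted_pairs_detected(self, scored):
        ds, graph, _ = scored
        for a, b in ds.truth.planted_crosstalk_pairs:
            assert graph.has_edge(a, b)

    def test_false_positive_pairs_scarce(self, scored):
        ds, _, table = scored
        planted = {frozenset(p) for p in ds.truth.planted_crosstalk_pairs}
        nonplanted = table[[frozenset((a, b)) not in planted
                            for a, b in zip(table["pathway_i"], table["pathway_j"])]]
        assert (nonplanted["perm_p"] < 0.05).mean() <= 0.1

    def test_threshold_one_keeps_every_scored_pair_with_edges(self, scored):
        ds, _, _ = scored
        diff_g = diffexpr.call_all_contrasts(ds.gene_expr, ds.annotation)
        labels = pd.DataFrame({
            "pathway_id": sorted(ds.pathways.sets)[:6],
            "grade_association": "both", "direction": "up", "min_p": 0.0})
        graph, table = ct.build_crosstalk_network(
            labels, ds.pathways, ds.ppi, ds.gene_expr, diff_g,
            B=20, threshold=1.01, seed=7)
        with_edges = table[table["n_edges"] > 0]
        for row in with_edges.itertuples(index=False):
            assert graph.has_edge(row.pathway_i, row.pathway_j)

    def test_identical_seed_gives_identical_network(self, scored):
        ds, _, table1 = scored
        diff_g = diffexpr.call_all_contrasts(ds.gene_expr, ds.annotation)
        labels = pd.DataFrame({
            "pathway_id": sorted(ds.pathways.sets),
            "grade_association": "both", "direction": "up", "min_p": 0.0})
        _, table2 = ct.build_crosstalk_network(
            labels, ds.pathways, ds.ppi, ds.gene_expr, diff_g,
            B=300, threshold=0.05, seed=7)
        pd.testing.assert_frame_equal(table1, table2)
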