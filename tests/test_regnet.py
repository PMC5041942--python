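import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mircross import diffexpr, regnet, synthdata
from mircross.config import SyntheticConfig
from mircross.errors import InputError
from mircross.io import GeneSetCollection


def enumeration_hypergeom(N, M, n, m, tail="ge"):
    """Exhaustive oracle: enumerate all C(N, n) draws of n from an urn with
    M marked balls and count overlaps."""
    marked = set(range(M))
    total = 0
    hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        overlap = len(marked & set(draw))
        if (overlap >= m) if tail == "ge" else (overlap > m):
            hits += 1
    return hits / total


class TestCorrelate:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r, p = regnet.correlate(x, -x)
        assert r == pytest.approx(-1.0)
        assert p < 1e-6

    def test_positive_correlation_fails_negative_filter(self):
        x = np.arange(10.0)
        r, _ = regnet.correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_constant_vector_returns_null_result(self):
        r, p = regnet.correlate(np.ones(5), np.arange(5.0))
        assert (r, p) == (0.0, 1.0)

    def test_matches_scipy_pearsonr(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=30), rng.normal(size=30)
            r, p = regnet.correlate(x, y)
            r_ref, p_ref = stats.pearsonr(x, y)
            assert r == pytest.approx(r_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, rel=1e-9)

    def test_null_p_values_calibrated(self, rng):
        ps = []
        for _ in range(500):
            x, y = rng.normal(size=100), rng.normal(size=100)
            ps.append(regnet.correlate(x, y)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestHypergeomEnrich:
    def test_full_overlap_small_universe(self):
        res = regnet.hypergeom_enrich(set("abcde"), set("abcde"), set("abcdefghij"))
        assert res.p_value == pytest.approx(1 / 252, abs=1e-12)

    def test_partial_overlap_enumeration_value(self):
        res = regnet.hypergeom_enrich({"a", "b"}, {"a", "c"}, {"a", "b", "c", "d"})
        assert res.p_value == pytest.approx(5 / 6, abs=1e-12)

    def test_zero_overlap_is_certain(self):
        res = regnet.hypergeom_enrich(set(), {"a", "c"}, {"a", "b", "c", "d"})
        assert res.p_value == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(InputError):
            regnet.hypergeom_enrich({"a"}, {"a"}, set())

    @pytest.mark.parametrize("tail", ["ge", "gt"])
    def test_matches_enumeration_oracle_on_small_configs(self, tail):
        universe = [f"g{i}" for i in range(8)]
        for N in (4, 6, 8):
            for M in range(N + 1):
                for n in range(N + 1):
                    pathway = set(universe[:M])
                    targets = set(universe[:n])
                    res = regnet.hypergeom_enrich(targets, pathway, set(universe[:N]),
                                                  tail=tail)
                    m = len(pathway & targets)
                    expected = enumeration_hypergeom(N, M, n, m, tail=tail)
                    assert res.p_value == pytest.approx(expected, abs=1e-12)


@pytest.fixture(scope="module")
def small_study():
    cfg = SyntheticConfig(n_samples_per_grade=(30, 30, 30), seed=5)
    ds = synthdata.generate_dataset(cfg)
    diff_m = diffexpr.call_all_contrasts(ds.mirna_expr, ds.annotation)
    diff_g = diffexpr.call_all_contrasts(ds.gene_expr, ds.annotation)
    pairs = regnet.select_signature_pairs(
        diff_m, diff_g, ds.target_pairs, ds.mirna_expr, ds.gene_expr, ds.annotation)
    return ds, pairs


class TestSignaturePairs:

    def test_planted_pairs_recovered(self, small_study):
        ds, pairs = small_study
        for contrast, planted in ds.truth.planted_pairs.items():
            got = set(zip(pairs.loc[pairs["contrast"] == contrast, "mirna_id"],
                          pairs.loc[pairs["contrast"] == contrast, "gene_id"]))
            assert len(got & set(planted)) / len(planted) >= 0.8

    def test_decoy_pairs_mostly_rejected(self, small_study):
        ds, pairs = small_study
        selected = set(zip(pairs["mirna_id"], pairs["gene_id"]))
        decoys = set(ds.truth.decoy_pairs)
        assert len(selected & decoys) / len(decoys) <= 0.1

    def test_selected_pairs_satisfy_all_filters(self, small_study):
        ds, pairs = small_study
        assert (pairs["r"] <= -0.4).all()
        assert (pairs["r_p"] < 0.05).all()
        assert set(zip(pairs["mirna_id"], pairs["gene_id"])) <= ds.target_pairs

    def test_cutoff_is_strict_at_the_boundary(self):
        # engineered vectors with exact sample correlations -0.39 and -0.41:
        # project the noise orthogonal to m, then mix unit vectors
        rng = np.random.default_rng(0)
        n = 400
        m = rng.normal(size=n)
        noise = rng.normal(size=n)
        mc = (m - m.mean()) / np.linalg.norm(m - m.mean())
        e = noise - noise.mean()
        e -= (e @ mc) * mc
        ec = e / np.linalg.norm(e)

        def gene_with_exact_r(r):
            return r * mc + math.sqrt(1 - r * r) * ec

        g1 = gene_with_exact_r(-0.39)
        g2 = gene_with_exact_r(-0.41)
        assert np.corrcoef(m, g1)[0, 1] == pytest.approx(-0.39, abs=1e-9)
        assert np.corrcoef(m, g2)[0, 1] == pytest.approx(-0.41, abs=1e-9)
        samples = [f"S{i}" for i in range(n)]
        from mircross.io import ExpressionMatrix
        mirna = ExpressionMatrix(
            values=pd.DataFrame([m], index=["miR-a"], columns=samples),
            feature_kind="miRNA")
        genes = ExpressionMatrix(
            values=pd.DataFrame([g1, g2], index=["G1", "G2"], columns=samples),
            feature_kind="gene")
        ann = pd.DataFrame({
            "sample_id": samples,
            "grade": ["II"] * (n // 2) + ["III"] * (n // 2),
        }).set_index("sample_id", drop=False)
        diff_m = pd.DataFrame({
            "feature_id": ["miR-a"], "contrast": "III_vs_II", "direction": ["up"],
            "significant": [True]})
        diff_g = pd.DataFrame({
            "feature_id": ["G1", "G2"], "contrast": "III_vs_II",
            "direction": ["down", "down"], "significant": [True, True]})
        targets = {("miR-a", "G1"), ("miR-a", "G2")}
        pairs = regnet.select_signature_pairs(diff_m, diff_g, targets, mirna, genes, ann)
        assert set(pairs["gene_id"]) == {"G2"}

    def test_empty_targets_give_empty_result(self, small_study):
        ds, _ = small_study
        diff_m = diffexpr.call_all_contrasts(ds.mirna_expr, ds.annotation)
        diff_g = diffexpr.call_all_contrasts(ds.gene_expr, ds.annotation)
        pairs = regnet.select_signature_pairs(
            diff_m, diff_g, set(), ds.mirna_expr, ds.gene_expr, ds.annotation)
        assert pairs.empty

    def test_invariant_under_sample_column_permutation(self, small_study):
        ds, pairs = small_study
        rng = np.random.default_rng(3)
        perm = rng.permutation(ds.mirna_expr.values.shape[1])
        from mircross.io import ExpressionMatrix
        mirna = ExpressionMatrix(values=ds.mirna_expr.values.iloc[:, perm],
                                 feature_kind="miRNA")
        gene = ExpressionMatrix(values=ds.gene_expr.values.iloc[:, perm],
                                feature_kind="gene")
        diff_m = diffexpr.call_all_contrasts(mirna, ds.annotation)
        diff_g = diffexpr.call_all_contrasts(gene, ds.annotation)
        shuffled = regnet.select_signature_pairs(
            diff_m, diff_g, ds.target_pairs, mirna, gene, ds.annotation)
        key = ["contrast", "mirna_id", "gene_id"]
        assert set(map(tuple, shuffled[key].values)) == set(map(tuple, pairs[key].values))


class TestMirnaPathwayNetwork:
    def test_concentrated_targets_create_an_edge(self):
        universe = {f"g{i}" for i in range(30)}
        collection = GeneSetCollection(sets={
            "P1": ("d", {"g0", "g1", "g2"}),
            "P2": ("d", {f"g{i}" for i in range(10, 20)}),
        })
        pairs = pd.DataFrame({
            "contrast": ["III_vs_II"] * 3,
            "mirna_id": ["miR-x"] * 3,
            "gene_id": ["g0", "g1", "g2"],
            "direction_pattern": ["miR_up_gene_down"] * 3,
            "r": [-0.9] * 3, "r_p": [1e-6] * 3,
        })
        g = regnet.build_mirna_pathway_network(pairs, collection, universe)
        assert g.has_edge("miR-x", "P1")
        assert not g.has_edge("miR-x", "P2")
        assert g.nodes["P1"]["grade_association"] == "III"

    def test_zero_threshold_gives_empty_network(self, default_dataset):
        ds = default_dataset
        pairs = pd.DataFrame({
            "contrast": ["III_vs_II"], "mirna_id": ["miR-0001"],
            "gene_id": ["G0001"], "direction_pattern": ["miR_up_gene_down"],
            "r": [-0.9], "r_p": [1e-6]})
        g = regnet.build_mirna_pathway_network(
            pairs, ds.pathways, set(ds.gene_expr.feature_ids), threshold=0.0)
        assert g.number_of_edges() == 0

    def test_planted_enrichment_recovered(self, default_dataset):
        ds = default_dataset
        diff_m = diffexpr.call_all_contrasts(ds.mirna_expr, ds.annotation)
        diff_g = diffexpr.call_all_contrasts(ds.gene_expr, ds.annotation)
        pairs = regnet.select_signature_pairs(
            diff_m, diff_g, ds.target_pairs, ds.mirna_expr, ds.gene_expr, ds.annotation)
        universe = set(ds.gene_expr.feature_ids) & ds.pathways.all_genes()
        g = regnet.build_mirna_pathway_network(pairs, ds.pathways, universe)
        hits = 0
        total = 0
        for mirna, pws in ds.truth.planted_enriched_pathways.items():
            for pw in pws:
                total += 1
                if g.has_edge(mirna, pw):
                    hits += 1
        assert hits / total >= 0.8


class TestHubs:
    def _star_graph(self, degrees):
        g = nx.Graph()
        for i, d in enumerate(degrees):
            m = f"m{i:02d}"
            g.add_node(m, kind="miRNA")
            for j in range(d):
                p = f"p{i:02d}_{j}"
                g.add_node(p, kind="pathway")
                g.add_edge(m, p)
        return g

    def test_twenty_distinct_degrees_give_three_hubs(self):
        g = self._star_graph(range(1, 21))
        hubs = regnet.find_hubs(g)
        assert len(hubs) == 3
        assert hubs == ["m17", "m18", "m19"]

    def test_all_tied_means_all_hubs(self):
        g = self._star_graph([2] * 10)
        assert len(regnet.find_hubs(g)) == 10

    def test_sixty_untied_mirnas_give_nine_hubs(self):
        g = self._star_graph(range(1, 61))
        assert len(regnet.find_hubs(g)) == 9

    def test_ties_at_the_cut_are_included(self):
        g = self._star_graph([5, 4, 3, 3, 3, 2, 2, 1, 1, 1])  # ceil(1.5)=2, tie at 4? no
        hubs = regnet.find_hubs(g)  # ceil(0.15*10)=2 -> cut degree 4 -> {5,4}
        assert len(hubs) == 2
        g = self._star_graph([5, 4, 4, 4, 3, 2, 2, 1, 1, 1])
        hubs = regnet.find_hubs(g)  # cut degree 4, three miRNAs tied
        assert len(hubs) == 4
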