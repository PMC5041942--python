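"""Pathway-pathway crosstalk scored over PPI edges with a permutation null.

For two pathways i and j, every PPI edge (a, b) with a a differential gene
annotated in i and b a differential gene annotated in j contributes an
interaction strength combining three p-values by Fisher's method:

    w(a, b) = -2 * (ln P(a) + ln P(b) + ln P(a, b))

where P(a), P(b) are the genes' differential t-test p-values and P(a, b) is
the Pearson-correlation p-value of their expression profiles.  The pair's
crosstalk weight is the sum of w over qualifying edges (each unordered edge
counted once).  Significance comes from a resampling null: both pathways'
differential-gene sets are replaced by uniform same-size draws from the
pooled differential gene set, the weight is recomputed B times, and
perm_p = (r + 1) / (B + 1) with r the number of permuted weights >= the
observed one.  Pathway pairs with perm_p below a threshold form the
pathway crosstalk network.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from mircross.errors import InputError
from mircross.io import ExpressionMatrix, GeneSetCollection
from mircross.regnet import correlate, correlation_p_from_r, enrich_collection

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 1e-300


def edge_strength(p_a: float, p_b: float, p_ab: float, floor: float = DEFAULT_FLOOR) -> float:
    """Fisher's-method interaction strength -2(ln p_a + ln p_b + ln p_ab).

    Inputs must be positive p-values; values below ``floor`` are clipped to
    keep the statistic finite.
    """
    ps = (p_a, p_b, p_ab)
    if any((not np.isfinite(p)) or p <= 0 or p > 1 for p in ps):
        raise InputError(f"p-values must lie in (0, 1]: got {ps}")
    return float(-2.0 * sum(math.log(max(p, floor)) for p in ps))


def pair_weight(
    pathway_i_genes: Set[str],
    pathway_j_genes: Set[str],
    diff_genes: Set[str],
    ppi: nx.Graph,
    gene_expr: ExpressionMatrix,
    diff_p: Dict[str, float],
    sample_ids: Optional[Sequence[str]] = None,
    floor: float = DEFAULT_FLOOR,
) -> Tuple[float, int]:
    """Crosstalk weight of one pathway pair: sum of edge strengths.

    Qualifying edges are PPI edges (a, b), a != b, with a a differential
    gene in pathway i and b a differential gene in pathway j (or the
    reverse); each unordered edge counts once even when both genes belong
    to both pathways.  Returns ``(weight, n_edges)``.
    """
    set_i = pathway_i_genes & diff_genes
    set_j = pathway_j_genes & diff_genes
    expr = gene_expr.values if sample_ids is None else gene_expr.values.loc[:, list(sample_ids)]
    weight = 0.0
    n_edges = 0
    for a, b in ppi.edges:
        if not ((a in set_i and b in set_j) or (b in set_i and a in set_j)):
            continue
        if a not in diff_p or b not in diff_p:
            continue
        if a not in expr.index or b not in expr.index:
            continue
        _, p_ab = correlate(expr.loc[a].to_numpy(), expr.loc[b].to_numpy())
        weight += edge_strength(diff_p[a], diff_p[b], p_ab, floor=floor)
        n_edges += 1
    return weight, n_edges


class PermutationEngine:
    """Precomputed edge strengths over the differential gene pool.

    The pool is the union of differential genes available for resampling.
    All PPI edges internal to the pool are located once, and each edge's
    Fisher strength is precomputed from the genes' differential p-values
    and the correlation p of their expression.  Observed and permuted
    pathway-pair weights are then sums over boolean masks, which makes
    B ~ 10^3-10^6 randomizations tractable.
    """

    def __init__(
        self,
        pool_genes: Sequence[str],
        ppi: nx.Graph,
        gene_expr: ExpressionMatrix,
        diff_p: Dict[str, float],
        sample_ids: Optional[Sequence[str]] = None,
        floor: float = DEFAULT_FLOOR,
    ) -> None:
        self.pool = sorted(set(pool_genes) & set(gene_expr.feature_ids) & set(diff_p))
        self.index = {g: i for i, g in enumerate(self.pool)}
        expr = gene_expr.values if sample_ids is None else gene_expr.values.loc[:, list(sample_ids)]
        n_samples = expr.shape[1]
        if n_samples < 3:
            raise InputError("need at least three samples for correlation p-values")
        X = expr.loc[self.pool].to_numpy()

        ea, eb = [], []
        for a, b in ppi.edges:
            ia, ib = self.index.get(a), self.index.get(b)
            if ia is None or ib is None or ia == ib:
                continue
            ea.append(min(ia, ib))
            eb.append(max(ia, ib))
        self.edge_a = np.asarray(ea, dtype=np.intp)
        self.edge_b = np.asarray(eb, dtype=np.intp)

        if len(self.pool) >= 2 and self.edge_a.size:
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(X)
            r_edge = corr[self.edge_a, self.edge_b]
            r_edge = np.where(np.isfinite(r_edge), r_edge, 0.0)
            p_ab = correlation_p_from_r(r_edge, n_samples)
            log_p = np.log(np.maximum(
                np.array([diff_p[g] for g in self.pool], dtype=float), floor))
            self.edge_w = -2.0 * (log_p[self.edge_a] + log_p[self.edge_b]
                                  + np.log(np.maximum(p_ab, floor)))
        else:
            self.edge_w = np.zeros(0, dtype=float)

    def mask(self, genes: Iterable[str]) -> np.ndarray:
        m = np.zeros(len(self.pool), dtype=bool)
        for g in genes:
            i = self.index.get(g)
            if i is not None:
                m[i] = True
        return m

    def weight(self, mask_i: np.ndarray, mask_j: np.ndarray) -> Tuple[float, int]:
        if self.edge_w.size == 0:
            return 0.0, 0
        hit = (mask_i[self.edge_a] & mask_j[self.edge_b]) | \
              (mask_i[self.edge_b] & mask_j[self.edge_a])
        return float(self.edge_w[hit].sum()), int(hit.sum())

    def permuted_weights(
        self,
        size_i: int,
        size_j: int,
        B: int,
        rng: np.random.Generator,
        fixed_mask_j: Optional[np.ndarray] = None,
        mode: str = "joint",
    ) -> np.ndarray:
        """B resampled weights: pathway i's set is always redrawn; pathway
        j's is redrawn too in ``joint`` mode or held at ``fixed_mask_j`` in
        ``single`` mode."""
        n = len(self.pool)
        if size_i > n or size_j > n:
            raise InputError("pool smaller than a pathway's differential gene count")
        if B < 1:
            raise InputError("B must be >= 1")
        if mode not in ("joint", "single"):
            raise InputError(f"unknown randomization mode {mode!r}")
        if self.edge_w.size == 0:
            # draws still consumed so the RNG stream is stable across inputs
            rng.random((B, n))
            return np.zeros(B, dtype=float)
        order_i = np.argsort(rng.random((B, n)), axis=1)
        Mi = np.zeros((B, n), dtype=bool)
        np.put_along_axis(Mi, order_i[:, :size_i], True, axis=1)
        if mode == "joint":
            order_j = np.argsort(rng.random((B, n)), axis=1)
            Mj = np.zeros((B, n), dtype=bool)
            np.put_along_axis(Mj, order_j[:, :size_j], True, axis=1)
        else:
            if fixed_mask_j is None:
                raise InputError("single-side mode needs the fixed observed mask")
            Mj = np.broadcast_to(fixed_mask_j, (B, n))
        hit = (Mi[:, self.edge_a] & Mj[:, self.edge_b]) | \
              (Mi[:, self.edge_b] & Mj[:, self.edge_a])
        return hit @ self.edge_w


def permutation_p(
    observed_weight: float,
    sizes: Tuple[int, int],
    engine: PermutationEngine,
    B: int,
    rng: np.random.Generator,
    fixed_mask_j: Optional[np.ndarray] = None,
    mode: str = "joint",
) -> float:
    """Pseudo-count permutation p-value (r + 1) / (B + 1)."""
    size_i, size_j = sizes
    perm = engine.permuted_weights(size_i, size_j, B, rng,
                                   fixed_mask_j=fixed_mask_j, mode=mode)
    r = int(np.sum(perm >= observed_weight))
    return (r + 1) / (B + 1)


def select_dysregulated_pathways(
    pairs: pd.DataFrame,
    collection: GeneSetCollection,
    universe: Set[str],
    threshold: float = 0.05,
    tail: str = "ge",
) -> pd.DataFrame:
    """Pathways enriched by the grade- and direction-split target gene unions.

    The union of inversely correlated target genes is formed per contrast
    and split by gene direction (up / down); each group is tested against
    every pathway.  Returns one row per retained pathway with its grade
    association (III / IV / both) and the direction(s) of the enriching
    gene groups.
    """
    if pairs.empty:
        return pd.DataFrame(columns=["pathway_id", "grade_association", "direction", "min_p"])
    contrast_short = {"III_vs_II": "III", "IV_vs_II": "IV"}
    gene_dir = {"miR_up_gene_down": "down", "miR_down_gene_up": "up"}
    hits: Dict[str, Dict[str, object]] = {}
    for (contrast, pattern), grp in sorted(pairs.groupby(["contrast", "direction_pattern"])):
        short = contrast_short.get(contrast, contrast)
        direction = gene_dir[pattern]
        target_union = set(grp["gene_id"])
        for res in enrich_collection(target_union, collection, universe,
                                     subject_id=f"{short}:{direction}", tail=tail):
            if res.p_value < threshold:
                rec = hits.setdefault(
                    res.pathway_id, {"grades": set(), "directions": set(), "min_p": 1.0})
                rec["grades"].add(short)
                rec["directions"].add(direction)
                rec["min_p"] = min(rec["min_p"], res.p_value)
    rows = []
    for pid in sorted(hits):
        grades = hits[pid]["grades"]
        assoc = "both" if grades >= {"III", "IV"} else sorted(grades)[0]
        rows.append((pid, assoc, ";".join(sorted(hits[pid]["directions"])), hits[pid]["min_p"]))
    return pd.DataFrame(rows, columns=["pathway_id", "grade_association", "direction", "min_p"])


def differential_gene_pool(diff_genes: pd.DataFrame) -> Tuple[Set[str], Dict[str, float]]:
    """Significant genes (any contrast) and each gene's smallest contrast p."""
    sig = diff_genes[diff_genes["significant"]]
    pool = set(sig["feature_id"])
    p_map = sig.groupby("feature_id")["p"].min().to_dict()
    return pool, p_map


def build_crosstalk_network(
    pathway_labels: pd.DataFrame,
    collection: GeneSetCollection,
    ppi: nx.Graph,
    gene_expr: ExpressionMatrix,
    diff_genes: pd.DataFrame,
    B: int = 1000,
    threshold: float = 0.05,
    seed: int = 0,
    sample_ids: Optional[Sequence[str]] = None,
    floor: float = DEFAULT_FLOOR,
    mode: str = "joint",
) -> Tuple[nx.Graph, pd.DataFrame]:
    """Score all pathway pairs and keep edges with perm_p < ``threshold``.

    ``pathway_labels`` carries one row per candidate pathway (as produced
    by :func:`select_dysregulated_pathways`).  Returns the network and the
    full edge table (every scored pair, retained or not).

    Pairs with observed weight 0 are assigned perm_p = 1 without drawing:
    every permuted weight is >= 0, so the pseudo-count estimate is exactly 1.
    """
    pathways = sorted(pathway_labels["pathway_id"])
    if len(pathways) < 2:
        raise InputError("need at least two candidate pathways")
    labels = pathway_labels.set_index("pathway_id")
    pool, p_map = differential_gene_pool(diff_genes)
    engine = PermutationEngine(sorted(pool), ppi, gene_expr, diff_p=p_map,
                               sample_ids=sample_ids, floor=floor)
    masks = {pid: engine.mask(collection.genes(pid)) for pid in pathways}

    graph = nx.Graph()
    for pid in pathways:
        graph.add_node(pid,
                       grade_association=str(labels.loc[pid, "grade_association"]),
                       direction=str(labels.loc[pid, "direction"]))
    rows = []
    root = np.random.SeedSequence(seed)
    for idx_i in range(len(pathways)):
        for idx_j in range(idx_i + 1, len(pathways)):
            pi, pj = pathways[idx_i], pathways[idx_j]
            mi, mj = masks[pi], masks[pj]
            w_obs, n_edges = engine.weight(mi, mj)
            si, sj = int(mi.sum()), int(mj.sum())
            if w_obs == 0.0:
                perm_p = 1.0
            else:
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=root.entropy,
                                           spawn_key=(idx_i, idx_j)))
                perm_p = permutation_p(w_obs, (si, sj), engine, B, rng,
                                       fixed_mask_j=mj, mode=mode)
            rows.append((pi, pj, w_obs, n_edges, perm_p, B))
            if perm_p < threshold:
                graph.add_edge(pi, pj, weight=w_obs, n_edges=n_edges, perm_p=perm_p)
    table = pd.DataFrame(
        rows, columns=["pathway_i", "pathway_j", "weight", "n_edges", "perm_p",
                       "n_permutations"])
    logger.info("crosstalk network: %d pathways, %d significant of %d scored pairs",
                graph.number_of_nodes(), graph.number_of_edges(), len(table))
    return graph, table
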