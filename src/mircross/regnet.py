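"""Signature miRNA-target pairs and the miRNA-pathway enrichment network.

A signature pair is a predicted miRNA->gene couple in which both partners
are differentially expressed in the same grade contrast with opposite
directions and whose expression is inversely correlated past a cutoff
(Pearson r <= -0.4 at p < 0.05 by default).  Each miRNA's inversely
correlated target set is then tested for pathway enrichment with the
cumulative hypergeometric law

    p = P(X >= m),  X ~ Hypergeometric(N, M, n)

where N is the gene universe, M the pathway size, n the target-set size and
m their overlap.  Significant miRNA-pathway relations (p < 0.05) form a
bipartite network whose top-degree miRNAs (top 15%, ties included) are the
hub miRNAs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from mircross.diffexpr import CONTRAST_GRADES
from mircross.errors import InputError
from mircross.io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


def correlate(x, y) -> Tuple[float, float]:
    """Pearson correlation with its asymptotic two-sided p-value.

    The p-value comes from the t transform t = r * sqrt((n-2) / (1-r^2))
    with n-2 degrees of freedom.  Constant input yields (0, 1) with a
    warning since r is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("vectors must have equal length")
    if x.size < 3:
        raise InputError("need at least three paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("constant vector: correlation undefined, returning r=0, p=1")
        return 0.0, 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    n = x.size
    if abs(r) == 1.0:
        return r, float(np.nextafter(0.0, 1.0))
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(min(max(p, np.nextafter(0.0, 1.0)), 1.0))


def correlation_p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Vectorized two-sided p for Pearson r via the t transform."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def _contrast_samples(annotation: pd.DataFrame, contrast: str, mode: str) -> List[str]:
    if mode == "all":
        return list(annotation.index)
    case_grade, control_grade = CONTRAST_GRADES[contrast]
    mask = annotation["grade"].isin((case_grade, control_grade))
    return list(annotation.index[mask])


def select_signature_pairs(
    diff_mirnas: pd.DataFrame,
    diff_genes: pd.DataFrame,
    targets: Set[Tuple[str, str]],
    mirna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    cutoff: float = -0.4,
    p_max: float = 0.05,
    sample_mode: str = "per_contrast",
) -> pd.DataFrame:
    """Select miRNA->gene signature pairs per grade contrast.

    ``diff_mirnas`` / ``diff_genes`` are differential-result tables (as
    produced by :func:`mircross.diffexpr.call_all_contrasts`).  For each
    contrast, correlation is computed over the control (grade II) plus that
    contrast's case samples (``sample_mode="per_contrast"``, default) or
    over all samples (``sample_mode="all"``).

    Returns columns ``contrast, mirna_id, gene_id, direction_pattern, r, r_p``.
    """
    if sample_mode not in ("per_contrast", "all"):
        raise InputError(f"unknown sample_mode {sample_mode!r}")
    shared = [s for s in mirna_expr.sample_ids if s in set(gene_expr.sample_ids)]
    if not shared:
        raise InputError("expression matrices share no sample columns")
    ann = annotation.loc[annotation.index.intersection(shared)]

    rows = []
    contrasts = sorted(set(diff_mirnas["contrast"]) & set(diff_genes["contrast"]))
    for contrast in contrasts:
        dm = diff_mirnas[(diff_mirnas["contrast"] == contrast) & diff_mirnas["significant"]]
        dg = diff_genes[(diff_genes["contrast"] == contrast) & diff_genes["significant"]]
        mirna_dir = dict(zip(dm["feature_id"], dm["direction"]))
        gene_dir = dict(zip(dg["feature_id"], dg["direction"]))
        if not mirna_dir or not gene_dir:
            continue
        samples = _contrast_samples(ann, contrast, sample_mode)
        if len(samples) < 3:
            raise InputError(f"contrast {contrast}: fewer than 3 samples for correlation")
        mx = mirna_expr.values.loc[:, samples]
        gx = gene_expr.values.loc[:, samples]
        candidates = [
            (m, g) for (m, g) in targets
            if m in mirna_dir and g in gene_dir and mirna_dir[m] != gene_dir[g]
        ]
        for m, g in sorted(candidates):
            r, r_p = correlate(mx.loc[m].to_numpy(), gx.loc[g].to_numpy())
            if r <= cutoff and r_p < p_max:
                pattern = ("miR_up_gene_down" if mirna_dir[m] == "up"
                           else "miR_down_gene_up")
                rows.append((contrast, m, g, pattern, r, r_p))
    out = pd.DataFrame(
        rows, columns=["contrast", "mirna_id", "gene_id", "direction_pattern", "r", "r_p"]
    )
    logger.info("signature pairs: %d across %d contrasts", len(out), len(contrasts))
    return out


@dataclass
class EnrichmentResult:
    """One cumulative hypergeometric test of a gene set against a pathway."""

    subject_id: str
    pathway_id: str
    N: int
    M: int
    n: int
    m: int
    p_value: float


def hypergeom_enrich(
    target_genes: Set[str],
    pathway_genes: Set[str],
    universe: Set[str],
    subject_id: str = "",
    pathway_id: str = "",
    tail: str = "ge",
) -> EnrichmentResult:
    """Cumulative hypergeometric enrichment of ``target_genes`` in a pathway.

    ``tail="ge"`` (default) gives the standard upper tail P(X >= m);
    ``tail="gt"`` gives P(X > m).
    """
    if not universe:
        raise InputError("empty gene universe")
    if tail not in ("ge", "gt"):
        raise InputError(f"unknown tail {tail!r}")
    universe = set(universe)
    M_set = pathway_genes & universe
    n_set = target_genes & universe
    N, M, n = len(universe), len(M_set), len(n_set)
    m = len(M_set & n_set)
    k = m - 1 if tail == "ge" else m
    p = float(stats.hypergeom.sf(k, N, M, n))
    return EnrichmentResult(subject_id, pathway_id, N, M, n, m,
                            float(min(max(p, 0.0), 1.0)))


def enrich_collection(
    target_genes: Set[str],
    collection: GeneSetCollection,
    universe: Set[str],
    subject_id: str = "",
    tail: str = "ge",
) -> List[EnrichmentResult]:
    return [
        hypergeom_enrich(target_genes, collection.genes(pid), universe,
                         subject_id=subject_id, pathway_id=pid, tail=tail)
        for pid in sorted(collection.sets)
    ]


def build_mirna_pathway_network(
    pairs: pd.DataFrame,
    collection: GeneSetCollection,
    universe: Set[str],
    threshold: float = 0.05,
    tail: str = "ge",
) -> nx.Graph:
    """Build the bipartite miRNA-pathway network from signature pairs.

    For each (miRNA, contrast), the miRNA's inversely correlated target set
    is tested against every pathway; relations with p < ``threshold`` in at
    least one contrast become edges.  Node attributes carry the miRNA
    direction (per contrast) and each pathway's grade association
    (``III`` / ``IV`` / ``both``); edge attributes carry the per-contrast
    enrichment p-values.
    """
    if pairs.empty:
        raise InputError("no signature pairs: cannot build the network")
    graph = nx.Graph()
    contrast_short = {"III_vs_II": "III", "IV_vs_II": "IV"}

    for (contrast, mirna), grp in sorted(
        pairs.groupby(["contrast", "mirna_id"], sort=True), key=lambda kv: kv[0]
    ):
        short = contrast_short.get(contrast, contrast)
        target_set = set(grp["gene_id"])
        direction = "up" if (grp["direction_pattern"] == "miR_up_gene_down").all() else "down"
        for res in enrich_collection(target_set, collection, universe,
                                     subject_id=mirna, tail=tail):
            if res.p_value < threshold:
                if not graph.has_node(mirna):
                    graph.add_node(mirna, kind="miRNA")
                graph.nodes[mirna][f"direction_{short}"] = direction
                if not graph.has_node(res.pathway_id):
                    graph.add_node(res.pathway_id, kind="pathway")
                if graph.has_edge(mirna, res.pathway_id):
                    edge = graph.edges[mirna, res.pathway_id]
                else:
                    graph.add_edge(mirna, res.pathway_id)
                    edge = graph.edges[mirna, res.pathway_id]
                edge[f"p_{short}"] = res.p_value
                contrasts = set(edge.get("contrasts", "").split(";")) - {""}
                contrasts.add(short)
                edge["contrasts"] = ";".join(sorted(contrasts))

    for node, attrs in graph.nodes(data=True):
        if attrs.get("kind") != "pathway":
            continue
        seen = set()
        for _, _, eattrs in graph.edges(node, data=True):
            seen |= set(eattrs["contrasts"].split(";"))
        attrs["grade_association"] = "both" if seen >= {"III", "IV"} else sorted(seen)[0]
    logger.info(
        "miRNA-pathway network: %d miRNAs, %d pathways, %d edges",
        sum(1 for _, a in graph.nodes(data=True) if a.get("kind") == "miRNA"),
        sum(1 for _, a in graph.nodes(data=True) if a.get("kind") == "pathway"),
        graph.number_of_edges(),
    )
    return graph


def network_edge_table(graph: nx.Graph) -> pd.DataFrame:
    rows = []
    for a, b, attrs in graph.edges(data=True):
        mirna, pathway = (a, b) if graph.nodes[a].get("kind") == "miRNA" else (b, a)
        rows.append((mirna, pathway, attrs.get("contrasts", ""),
                     attrs.get("p_III", np.nan), attrs.get("p_IV", np.nan)))
    out = pd.DataFrame(rows, columns=["mirna_id", "pathway_id", "contrasts", "p_III", "p_IV"])
    return out.sort_values(["mirna_id", "pathway_id"], ignore_index=True)


def find_hubs(graph: nx.Graph, fraction: float = 0.15) -> List[str]:
    """Hub miRNAs: the inclusive top-``fraction`` of miRNAs by degree.

    Returns the ceil(fraction * n_mirnas) highest-degree miRNAs plus every
    miRNA tied with the last one included.
    """
    mirnas = sorted(n for n, a in graph.nodes(data=True) if a.get("kind") == "miRNA")
    if not mirnas:
        raise InputError("network contains no miRNAs")
    if not (0 < fraction <= 1):
        raise InputError("fraction must lie in (0, 1]")
    degrees = {m: graph.degree(m) for m in mirnas}
    k = math.ceil(fraction * len(mirnas))
    ranked = sorted(mirnas, key=lambda m: (-degrees[m], m))
    cut_degree = degrees[ranked[k - 1]]
    return sorted(m for m in mirnas if degrees[m] >= cut_degree)
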