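"""Stage orchestration: each stage reads the previous stage's tables from a
shared output directory, writes its own, and records a manifest.

Conventional filenames inside the output directory::

    mirna_expr.tsv gene_expr.tsv samples.tsv target_pairs.tsv
    ppi_edges.tsv pathways.gmt ground_truth.json        (simulate / inputs)
    differential.tsv                                    (diff)
    signature_pairs.tsv                                 (pairs)
    mirna_pathway_edges.tsv mirna_pathway.graphml hubs.tsv   (mirpath)
    crosstalk_pairs.tsv crosstalk_network.graphml
    crosstalk_pathways.tsv                              (crosstalk)
    biclique_modules.tsv clique_communities.tsv core_module.tsv (modules)
    survival_groups.tsv km_curve_short.tsv km_curve_long.tsv
    survival_summary.tsv                                (survive)

Every stage is a pure function of (inputs, config, seed); identical runs
produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import networkx as nx
import numpy as np
import pandas as pd

from mircross import __version__, io
from mircross.config import PipelineConfig
from mircross.errors import InputError
from mircross.io import FLOAT_FORMAT
from mircross import crosstalk as ct
from mircross import diffexpr, netmodules, regnet, survival, synthdata

logger = logging.getLogger(__name__)

STAGES = ("simulate", "diff", "pairs", "mirpath", "crosstalk", "modules", "survive")

FILES = {
    "mirna_expr": "mirna_expr.tsv",
    "gene_expr": "gene_expr.tsv",
    "annotation": "samples.tsv",
    "target_pairs": "target_pairs.tsv",
    "ppi": "ppi_edges.tsv",
    "pathways": "pathways.gmt",
    "ground_truth": "ground_truth.json",
    "differential": "differential.tsv",
    "signature_pairs": "signature_pairs.tsv",
    "mirna_pathway_edges": "mirna_pathway_edges.tsv",
    "mirna_pathway_graphml": "mirna_pathway.graphml",
    "hubs": "hubs.tsv",
    "crosstalk_pathways": "crosstalk_pathways.tsv",
    "crosstalk_pairs": "crosstalk_pairs.tsv",
    "crosstalk_graphml": "crosstalk_network.graphml",
    "biclique_modules": "biclique_modules.tsv",
    "clique_communities": "clique_communities.tsv",
    "core_module": "core_module.tsv",
    "survival_groups": "survival_groups.tsv",
    "km_short": "km_curve_short.tsv",
    "km_long": "km_curve_long.tsv",
    "survival_summary": "survival_summary.tsv",
}


def _path(config: PipelineConfig, key: str) -> Path:
    return Path(config.outdir) / FILES[key]


def _require(config: PipelineConfig, keys: List[str], stage: str, needed_stage: str) -> None:
    missing = [FILES[k] for k in keys if not _path(config, k).exists()]
    if missing:
        raise InputError(
            f"stage '{stage}' needs outputs of stage '{needed_stage}' "
            f"(missing: {', '.join(missing)}); run that stage first"
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(config: PipelineConfig, stage: str, inputs: List[str],
                    outputs: List[str]) -> None:
    outdir = Path(config.outdir)
    snapshot = config.to_dict()
    snapshot.pop("outdir", None)  # runs differing only in location stay comparable
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": config.seed,
        "config": snapshot,
        "input_checksums": {FILES[k]: _sha256(_path(config, k)) for k in inputs},
        "outputs": sorted(FILES[k] for k in outputs),
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _to_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------- stages

def run_simulate(config: PipelineConfig) -> None:
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    syn = config.synthetic
    dataset = synthdata.generate_dataset(syn)
    synthdata.write_dataset(dataset, config.outdir)
    _write_manifest(config, "simulate", [],
                    ["mirna_expr", "gene_expr", "annotation", "target_pairs",
                     "ppi", "pathways", "ground_truth"])
    logger.info("simulated dataset written to %s", config.outdir)


def _load_inputs(config: PipelineConfig):
    mirna = io.read_expression(_path(config, "mirna_expr"), "miRNA")
    gene = io.read_expression(_path(config, "gene_expr"), "gene")
    ann = io.read_annotation(_path(config, "annotation"))
    return mirna, gene, ann


def run_diff(config: PipelineConfig) -> None:
    _require(config, ["mirna_expr", "gene_expr", "annotation"], "diff", "simulate")
    mirna, gene, ann = _load_inputs(config)
    frames = [
        diffexpr.call_all_contrasts(mirna, ann, alpha=config.alpha, variant=config.t_variant),
        diffexpr.call_all_contrasts(gene, ann, alpha=config.alpha, variant=config.t_variant),
    ]
    result = pd.concat(frames, ignore_index=True)
    _to_tsv(result, _path(config, "differential"))
    _write_manifest(config, "diff",
                    ["mirna_expr", "gene_expr", "annotation"], ["differential"])


def _read_differential(config: PipelineConfig) -> pd.DataFrame:
    df = pd.read_csv(_path(config, "differential"), sep="\t")
    df["significant"] = df["significant"].astype(bool)
    return df


def run_pairs(config: PipelineConfig) -> None:
    _require(config, ["differential", "target_pairs"], "pairs", "diff")
    mirna, gene, ann = _load_inputs(config)
    diff = _read_differential(config)
    targets = io.read_target_pairs(_path(config, "target_pairs"))
    pairs = regnet.select_signature_pairs(
        diff[diff["kind"] == "miRNA"],
        diff[diff["kind"] == "gene"],
        targets, mirna, gene, ann,
        cutoff=config.correlation_cutoff,
        p_max=config.correlation_p_max,
        sample_mode=config.correlation_samples,
    )
    _to_tsv(pairs, _path(config, "signature_pairs"))
    _write_manifest(config, "pairs",
                    ["differential", "target_pairs"], ["signature_pairs"])


def _universe(config: PipelineConfig, gene_expr, collection) -> set:
    measured = set(gene_expr.feature_ids)
    if config.universe == "measured":
        return measured
    return measured & collection.all_genes()


def run_mirpath(config: PipelineConfig) -> None:
    _require(config, ["signature_pairs", "pathways"], "mirpath", "pairs")
    _, gene, _ = _load_inputs(config)
    pairs = pd.read_csv(_path(config, "signature_pairs"), sep="\t")
    collection = io.read_gmt(_path(config, "pathways"))
    universe = _universe(config, gene, collection)
    graph = regnet.build_mirna_pathway_network(
        pairs, collection, universe,
        threshold=config.enrichment_threshold, tail=config.enrichment_tail)
    _to_tsv(regnet.network_edge_table(graph), _path(config, "mirna_pathway_edges"))
    io.write_graphml(graph, _path(config, "mirna_pathway_graphml"))
    hubs = regnet.find_hubs(graph, fraction=config.hub_fraction)
    _to_tsv(pd.DataFrame({"mirna_id": hubs,
                          "degree": [graph.degree(m) for m in hubs]}),
            _path(config, "hubs"))
    _write_manifest(config, "mirpath", ["signature_pairs", "pathways"],
                    ["mirna_pathway_edges", "mirna_pathway_graphml", "hubs"])


def run_crosstalk(config: PipelineConfig) -> None:
    _require(config, ["signature_pairs", "differential", "pathways", "ppi"],
             "crosstalk", "pairs")
    _, gene, ann = _load_inputs(config)
    pairs = pd.read_csv(_path(config, "signature_pairs"), sep="\t")
    diff = _read_differential(config)
    collection = io.read_gmt(_path(config, "pathways"))
    ppi = io.read_ppi(_path(config, "ppi"), min_score=config.ppi_min_score)
    universe = _universe(config, gene, collection)
    labels = ct.select_dysregulated_pathways(
        pairs, collection, universe,
        threshold=config.enrichment_threshold, tail=config.enrichment_tail)
    _to_tsv(labels, _path(config, "crosstalk_pathways"))
    graph, table = ct.build_crosstalk_network(
        labels, collection, ppi, gene,
        diff[diff["kind"] == "gene"],
        B=config.permutations,
        threshold=config.crosstalk_threshold,
        seed=config.seed,
        floor=config.log_floor,
        mode=config.randomization,
    )
    _to_tsv(table, _path(config, "crosstalk_pairs"))
    io.write_graphml(graph, _path(config, "crosstalk_graphml"))
    _write_manifest(config, "crosstalk",
                    ["signature_pairs", "differential", "pathways", "ppi"],
                    ["crosstalk_pathways", "crosstalk_pairs", "crosstalk_graphml"])


def _load_crosstalk_network(config: PipelineConfig) -> nx.Graph:
    table = pd.read_csv(_path(config, "crosstalk_pairs"), sep="\t")
    labels = pd.read_csv(_path(config, "crosstalk_pathways"), sep="\t")
    graph = nx.Graph()
    for row in labels.itertuples(index=False):
        graph.add_node(row.pathway_id, grade_association=row.grade_association,
                       direction=row.direction)
    sig = table[table["perm_p"] < config.crosstalk_threshold]
    for row in sig.itertuples(index=False):
        graph.add_edge(row.pathway_i, row.pathway_j, weight=row.weight,
                       n_edges=row.n_edges, perm_p=row.perm_p)
    return graph


def _load_mirna_pathway_network(config: PipelineConfig) -> nx.Graph:
    edges = pd.read_csv(_path(config, "mirna_pathway_edges"), sep="\t")
    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        graph.add_node(row.mirna_id, kind="miRNA")
        graph.add_node(row.pathway_id, kind="pathway")
        graph.add_edge(row.mirna_id, row.pathway_id, contrasts=row.contrasts)
    return graph


def run_modules(config: PipelineConfig) -> None:
    _require(config, ["mirna_pathway_edges"], "modules", "mirpath")
    _require(config, ["crosstalk_pairs", "crosstalk_pathways"], "modules", "crosstalk")
    bipartite = _load_mirna_pathway_network(config)
    bicliques = netmodules.maximal_bicliques(
        bipartite, min_mirnas=config.min_biclique_mirnas,
        min_pathways=config.min_biclique_pathways)
    rows = []
    for mod in bicliques:
        for m in sorted(mod.mirna_set):
            rows.append((mod.id, "miRNA", m))
        for p in sorted(mod.pathway_set):
            rows.append((mod.id, "pathway", p))
    _to_tsv(pd.DataFrame(rows, columns=["module_id", "side", "member_id"]),
            _path(config, "biclique_modules"))

    crosstalk_net = _load_crosstalk_network(config)
    communities = netmodules.clique_percolation(crosstalk_net, k=config.clique_k)
    rows = [(c.id, p) for c in communities for p in sorted(c.pathway_set)]
    _to_tsv(pd.DataFrame(rows, columns=["community_id", "pathway_id"]),
            _path(config, "clique_communities"))

    core_rows = []
    if crosstalk_net.number_of_nodes():
        anchor = max(sorted(crosstalk_net.nodes), key=lambda n: crosstalk_net.degree(n))
        core = netmodules.extract_core_module(crosstalk_net, anchor, k=config.clique_k)
        for node in sorted(core.nodes):
            core_rows.append((anchor, node, bool(core.nodes[node]["in_community"])))
    _to_tsv(pd.DataFrame(core_rows, columns=["anchor", "pathway_id", "in_community"]),
            _path(config, "core_module"))
    _write_manifest(config, "modules",
                    ["mirna_pathway_edges", "crosstalk_pairs", "crosstalk_pathways"],
                    ["biclique_modules", "clique_communities", "core_module"])


def core_signature(config: PipelineConfig):
    """Signature genes/miRNAs of the core crosstalk module.

    Genes: signature-pair target genes annotated to a core-module pathway;
    miRNAs: signature miRNAs with a miRNA-pathway edge to a core pathway.
    """
    core = pd.read_csv(_path(config, "core_module"), sep="\t")
    if core.empty:
        raise InputError("core module is empty: cannot derive a survival signature")
    core_pathways = set(core["pathway_id"])
    collection = io.read_gmt(_path(config, "pathways"))
    pairs = pd.read_csv(_path(config, "signature_pairs"), sep="\t")
    edges = pd.read_csv(_path(config, "mirna_pathway_edges"), sep="\t")
    core_genes = set()
    for pid in core_pathways & set(collection.sets):
        core_genes |= set(pairs["gene_id"]) & collection.genes(pid)
    core_mirnas = set(edges.loc[edges["pathway_id"].isin(core_pathways), "mirna_id"])
    if not core_genes and not core_mirnas:
        raise InputError("core module yields an empty survival signature")
    return sorted(core_genes), sorted(core_mirnas)


def run_survive(config: PipelineConfig) -> None:
    _require(config, ["core_module", "signature_pairs", "mirna_pathway_edges",
                      "pathways"], "survive", "modules")
    mirna, gene, ann = _load_inputs(config)
    genes, mirnas = core_signature(config)
    table, curve_short, curve_long, chi2, p = survival.stratify_and_test(
        mirna, gene, ann, genes, mirnas,
        seed=config.seed, mode=config.survival_mode,
        n_restarts=config.kmeans_restarts)
    _to_tsv(table, _path(config, "survival_groups"))
    _to_tsv(curve_short.table(), _path(config, "km_short"))
    _to_tsv(curve_long.table(), _path(config, "km_long"))
    summary = pd.DataFrame([{
        "n_short": int((table["group"] == "short").sum()),
        "n_long": int((table["group"] == "long").sum()),
        "median_short": curve_short.median,
        "median_long": curve_long.median,
        "chi_square": chi2,
        "logrank_p": p,
        "n_signature_genes": len(genes),
        "n_signature_mirnas": len(mirnas),
        "mode": config.survival_mode,
    }])
    _to_tsv(summary, _path(config, "survival_summary"))
    _write_manifest(config, "survive",
                    ["core_module", "signature_pairs", "mirna_pathway_edges",
                     "pathways"],
                    ["survival_groups", "km_short", "km_long", "survival_summary"])


STAGE_FUNCS = {
    "simulate": run_simulate,
    "diff": run_diff,
    "pairs": run_pairs,
    "mirpath": run_mirpath,
    "crosstalk": run_crosstalk,
    "modules": run_modules,
    "survive": run_survive,
}


def run_stage(stage: str, config: PipelineConfig) -> None:
    if stage not in STAGE_FUNCS and stage != "all":
        raise InputError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    config.validate()
    if stage == "all":
        for s in STAGES:
            STAGE_FUNCS[s](config)
    else:
        STAGE_FUNCS[stage](config)
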