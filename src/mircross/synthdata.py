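"""Synthetic matched miRNA/gene expression with planted structure.

The generator emulates a three-grade tumor cohort and produces all five
pipeline inputs — two log-scale expression matrices, a sample annotation
table with survival, a predicted miRNA->target pair list, a scored PPI edge
list, and GMT pathway sets — together with the ground truth of what was
planted:

* per-contrast differential miRNAs and genes (mean shift ``effect_size`` in
  the case grade vs grade II, alternating directions);
* miRNA->target couples: each planted target's expression is its baseline
  plus ``coupling_beta`` times its miRNA's expression (negative slope, so
  the pair is inversely correlated and the gene shifts opposite to its
  miRNA) plus Normal(0, noise_sd) residuals;
* per-miRNA pathway enrichment: all of a planted miRNA's targets are
  annotated to one designated pathway;
* pathway crosstalk: designated pathway pairs receive inter-pathway PPI
  edges among planted differential genes at five times the baseline edge
  density;
* a two-group hazard difference: a latent risk factor loads on the planted
  miRNAs (and, through the coupling, their targets) and scales the
  exponential event-time hazard by ``hazard_ratio``.

Identical (config, seed) yields byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from mircross.config import SyntheticConfig
from mircross.errors import ConfigError
from mircross.io import (
    ExpressionMatrix,
    GeneSetCollection,
    write_annotation,
    write_expression,
    write_gmt,
    write_ppi,
    write_target_pairs,
)

import networkx as nx

CONTRASTS = ("III_vs_II", "IV_vs_II")


@dataclass
class GroundTruth:
    """What the generator planted, keyed the way downstream stages report."""

    #: contrast -> direction -> feature IDs
    planted_diff_mirnas: Dict[str, Dict[str, List[str]]]
    planted_diff_genes: Dict[str, Dict[str, List[str]]]
    #: contrast -> list of (mirna_id, gene_id)
    planted_pairs: Dict[str, List[Tuple[str, str]]]
    #: decoy (non-planted) predicted pairs included in the target list
    decoy_pairs: List[Tuple[str, str]]
    #: mirna_id -> pathway IDs its targets were concentrated in
    planted_enriched_pathways: Dict[str, List[str]]
    planted_crosstalk_pairs: List[Tuple[str, str]]
    #: sample_id -> "high" | "low"
    planted_risk_groups: Dict[str, str]

    def to_json(self, path) -> None:
        d = {
            "planted_diff_mirnas": self.planted_diff_mirnas,
            "planted_diff_genes": self.planted_diff_genes,
            "planted_pairs": {c: [list(p) for p in ps] for c, ps in self.planted_pairs.items()},
            "decoy_pairs": [list(p) for p in self.decoy_pairs],
            "planted_enriched_pathways": self.planted_enriched_pathways,
            "planted_crosstalk_pairs": [list(p) for p in self.planted_crosstalk_pairs],
            "planted_risk_groups": self.planted_risk_groups,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted_diff_mirnas=d["planted_diff_mirnas"],
            planted_diff_genes=d["planted_diff_genes"],
            planted_pairs={c: [tuple(p) for p in ps] for c, ps in d["planted_pairs"].items()},
            decoy_pairs=[tuple(p) for p in d["decoy_pairs"]],
            planted_enriched_pathways=d["planted_enriched_pathways"],
            planted_crosstalk_pairs=[tuple(p) for p in d["planted_crosstalk_pairs"]],
            planted_risk_groups=d["planted_risk_groups"],
        )

    def all_planted_pairs(self) -> Set[Tuple[str, str]]:
        out: Set[Tuple[str, str]] = set()
        for ps in self.planted_pairs.values():
            out |= set(ps)
        return out


@dataclass
class SyntheticDataset:
    mirna_expr: ExpressionMatrix
    gene_expr: ExpressionMatrix
    annotation: pd.DataFrame
    target_pairs: Set[Tuple[str, str]]
    ppi: nx.Graph
    pathways: GeneSetCollection
    truth: GroundTruth

    def write(self, outdir) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mirna_expr": outdir / "mirna_expr.tsv",
            "gene_expr": outdir / "gene_expr.tsv",
            "annotation": outdir / "samples.tsv",
            "target_pairs": outdir / "target_pairs.tsv",
            "ppi": outdir / "ppi_edges.tsv",
            "pathways": outdir / "pathways.gmt",
            "ground_truth": outdir / "ground_truth.json",
        }
        write_expression(self.mirna_expr, paths["mirna_expr"])
        write_expression(self.gene_expr, paths["gene_expr"])
        write_annotation(self.annotation, paths["annotation"])
        write_target_pairs(self.target_pairs, paths["target_pairs"])
        write_ppi(self.ppi, paths["ppi"])
        write_gmt(self.pathways, paths["pathways"])
        self.truth.to_json(paths["ground_truth"])
        return paths


def _censoring_horizon(rates: np.ndarray, censoring_rate: float) -> float:
    """Horizon h with censor times U(0, h) hitting the target censor rate.

    For T ~ Exp(rate) and C ~ U(0, h), P(censored) = (1 - e^{-rate h}) /
    (rate h), averaged over the group mix; monotone decreasing in h, so the
    root is bracketed and unique.
    """

    def mean_censor_prob(h: float) -> float:
        x = rates * h
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1e9
    target = censoring_rate
    if mean_censor_prob(hi) > target:
        return hi
    return float(brentq(lambda h: mean_censor_prob(h) - target, lo, hi, xtol=1e-9))


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the five pipeline inputs plus ground truth."""
    config.validate()
    c = config
    rng = np.random.default_rng(c.seed)

    n2, n3, n4 = c.n_samples_per_grade
    n_samples = n2 + n3 + n4
    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    grades = np.array(["II"] * n2 + ["III"] * n3 + ["IV"] * n4)
    mirna_ids = [f"miR-{i:04d}" for i in range(1, c.n_mirnas + 1)]
    gene_ids = [f"G{i:04d}" for i in range(1, c.n_genes + 1)]
    pathway_ids = [f"PW{i:03d}" for i in range(1, c.n_pathways + 1)]

    case_mask = {"III_vs_II": grades == "III", "IV_vs_II": grades == "IV"}

    # ---- planted feature allocation (index blocks, disjoint per contrast)
    mirna_blocks = {
        "III_vs_II": list(range(0, c.n_diff_mirnas)),
        "IV_vs_II": list(range(c.n_diff_mirnas, 2 * c.n_diff_mirnas)),
    }
    gene_blocks = {
        "III_vs_II": list(range(0, c.n_diff_genes)),
        "IV_vs_II": list(range(c.n_diff_genes, 2 * c.n_diff_genes)),
    }

    # ---- risk factor (independent of grade)
    risk = rng.integers(0, 2, size=n_samples)  # 1 = high risk
    z = np.where(risk == 1, 1.0, -1.0)

    # ---- miRNA matrix
    mirna_base = rng.normal(7.0, 1.0, size=c.n_mirnas)
    M = mirna_base[:, None] + rng.normal(0.0, c.noise_sd, size=(c.n_mirnas, n_samples))
    planted_diff_mirnas: Dict[str, Dict[str, List[str]]] = {}
    mirna_direction: Dict[int, Dict[str, str]] = {}
    for contrast in CONTRASTS:
        up: List[str] = []
        down: List[str] = []
        for j, idx in enumerate(mirna_blocks[contrast]):
            direction = "up" if j % 2 == 0 else "down"
            shift = c.effect_size if direction == "up" else -c.effect_size
            M[idx, case_mask[contrast]] += shift
            (up if direction == "up" else down).append(mirna_ids[idx])
            mirna_direction.setdefault(idx, {})[contrast] = direction
        planted_diff_mirnas[contrast] = {"up": sorted(up), "down": sorted(down)}
    # risk factor loads on every planted miRNA; targets inherit via coupling
    planted_mirna_idx = sorted(mirna_direction)
    if c.risk_factor_loading != 0 and planted_mirna_idx:
        M[np.array(planted_mirna_idx)[:, None], :] += c.risk_factor_loading * z[None, :]

    # ---- gene matrix
    gene_base = rng.normal(8.0, 1.2, size=c.n_genes)
    G = gene_base[:, None] + rng.normal(0.0, c.noise_sd, size=(c.n_genes, n_samples))
    planted_diff_genes: Dict[str, Dict[str, List[str]]] = {}
    planted_pairs: Dict[str, List[Tuple[str, str]]] = {}
    gene_of_mirna: Dict[int, List[int]] = {}
    for contrast in CONTRASTS:
        up: List[str] = []
        down: List[str] = []
        pairs: List[Tuple[str, str]] = []
        block = gene_blocks[contrast]
        coupled = c.n_targets_per_mirna * c.n_diff_mirnas
        pos = 0
        for midx in mirna_blocks[contrast]:
            for _ in range(c.n_targets_per_mirna):
                gidx = block[pos]
                pos += 1
                G[gidx, :] = (
                    gene_base[gidx]
                    + c.coupling_beta * (M[midx, :] - mirna_base[midx])
                    + rng.normal(0.0, c.noise_sd, size=n_samples)
                )
                gdir = "down" if mirna_direction[midx][contrast] == "up" else "up"
                (up if gdir == "up" else down).append(gene_ids[gidx])
                pairs.append((mirna_ids[midx], gene_ids[gidx]))
                gene_of_mirna.setdefault(midx, []).append(gidx)
        # remaining planted genes get a direct mean shift
        for j, gidx in enumerate(block[coupled:]):
            gdir = "up" if j % 2 == 0 else "down"
            shift = c.effect_size if gdir == "up" else -c.effect_size
            G[gidx, case_mask[contrast]] += shift
            (up if gdir == "up" else down).append(gene_ids[gidx])
        planted_diff_genes[contrast] = {"up": sorted(up), "down": sorted(down)}
        planted_pairs[contrast] = sorted(pairs)

    # ---- predicted target pair list: planted plus uniform decoys
    all_planted = set()
    for ps in planted_pairs.values():
        all_planted |= set(ps)
    null_mirnas = [mirna_ids[i] for i in range(2 * c.n_diff_mirnas, c.n_mirnas)]
    null_genes = [gene_ids[i] for i in range(2 * c.n_diff_genes, c.n_genes)]
    n_decoys = int(round(c.decoy_pair_ratio * len(all_planted)))
    decoys: Set[Tuple[str, str]] = set()
    if n_decoys and null_mirnas and null_genes:
        while len(decoys) < min(n_decoys, len(null_mirnas) * len(null_genes)):
            m = null_mirnas[rng.integers(len(null_mirnas))]
            g = null_genes[rng.integers(len(null_genes))]
            decoys.add((m, g))
    target_pairs = all_planted | decoys

    # ---- pathways: concentrate each planted miRNA's targets in one pathway
    all_diff_gene_set: Set[str] = set()
    for contrast in CONTRASTS:
        for d in ("up", "down"):
            all_diff_gene_set |= set(planted_diff_genes[contrast][d])
    memberships: Dict[str, Set[str]] = {pid: set() for pid in pathway_ids}
    planted_enriched: Dict[str, List[str]] = {}
    enrichment_home: Dict[str, str] = {}  # target gene -> its designated pathway
    # miRNAs sharing a pathway home come from the same (contrast, direction)
    # group, so the pathway is coherently enriched by one of the four union
    # target-gene groups the pathway-selection stage tests
    grouped_idx: List[int] = []
    for contrast in CONTRASTS:
        for direction in ("up", "down"):
            grouped_idx.extend(
                idx for idx in planted_mirna_idx
                if mirna_direction[idx].get(contrast) == direction)
    per_pathway = max(1, c.mirnas_per_pathway)
    for slot, midx in enumerate(grouped_idx):
        pid = pathway_ids[(slot // per_pathway) % c.n_pathways]
        targets = {gene_ids[g] for g in gene_of_mirna.get(midx, [])}
        if not targets:
            continue
        memberships[pid] |= targets
        for g in targets:
            enrichment_home[g] = pid
        planted_enriched[mirna_ids[midx]] = [pid]
    # pathways earmarked for planted crosstalk are filled first, and their
    # differential members become exclusive to them: without exclusivity the
    # dense inter-pathway blocks leak into unrelated pathway pairs through
    # membership overlap and break the permutation null's calibration
    crosstalk_pathway_ids = [pathway_ids[i] for i in range(2 * c.n_planted_crosstalk_pairs)]
    reserved: Set[str] = set()
    for pid in crosstalk_pathway_ids:
        room = c.pathway_size - len(memberships[pid])
        if room > 0:
            candidates = np.array(sorted(
                g for g in gene_ids
                if g not in memberships[pid] and enrichment_home.get(g, pid) == pid
            ))
            fill = rng.choice(candidates, size=min(room, len(candidates)), replace=False)
            memberships[pid] |= set(fill.tolist())
        reserved |= memberships[pid] & all_diff_gene_set
    for pid in pathway_ids:
        if pid in crosstalk_pathway_ids:
            continue
        room = c.pathway_size - len(memberships[pid])
        if room <= 0:
            continue
        candidates = np.array(sorted(
            g for g in gene_ids if g not in memberships[pid] and g not in reserved))
        fill = rng.choice(candidates, size=min(room, len(candidates)), replace=False)
        memberships[pid] |= set(fill.tolist())
    collection = GeneSetCollection(sets={
        pid: (f"synthetic pathway {pid}", memberships[pid]) for pid in pathway_ids
    })

    # ---- PPI network
    all_diff_genes: Set[str] = set()
    for d in planted_diff_genes.values():
        all_diff_genes |= set(d["up"]) | set(d["down"])
    ppi = nx.Graph()
    iu, ju = np.triu_indices(c.n_genes, k=1)
    background = rng.random(iu.size) < c.baseline_ppi_density
    scores = rng.integers(900, 1001, size=iu.size)
    for a, b, s in zip(iu[background], ju[background], scores[background]):
        ppi.add_edge(gene_ids[a], gene_ids[b], score=int(s))
    # low-confidence edges that a score>=900 reader must drop
    low_conf = rng.random(iu.size) < (c.baseline_ppi_density / 5.0)
    low_scores = rng.integers(150, 900, size=iu.size)
    low_edges: List[Tuple[str, str, int]] = []
    for a, b, s in zip(iu[low_conf], ju[low_conf], low_scores[low_conf]):
        if not ppi.has_edge(gene_ids[a], gene_ids[b]):
            low_edges.append((gene_ids[a], gene_ids[b], int(s)))
    # planted crosstalk: dense edges among differential genes of pathway pairs
    crosstalk_pairs: List[Tuple[str, str]] = []
    planted_density = min(1.0, 5.0 * c.baseline_ppi_density)
    for k in range(c.n_planted_crosstalk_pairs):
        pi, pj = pathway_ids[2 * k], pathway_ids[2 * k + 1]
        crosstalk_pairs.append((pi, pj))
        di = sorted(memberships[pi] & all_diff_genes)
        dj = sorted(memberships[pj] & all_diff_genes)
        for a in di:
            for b in dj:
                if a != b and rng.random() < planted_density:
                    ppi.add_edge(a, b, score=int(rng.integers(900, 1001)))

    # ---- survival
    truth_groups = {sid: ("high" if r == 1 else "low") for sid, r in zip(sample_ids, risk)}
    base_rate = math.log(2.0) / c.baseline_median_survival
    rates = np.where(risk == 1, base_rate * c.hazard_ratio, base_rate)
    event_times = rng.exponential(1.0 / rates)
    if c.censoring_rate > 0:
        horizon = _censoring_horizon(rates, c.censoring_rate)
        censor_times = rng.uniform(0.0, horizon, size=n_samples)
    else:
        censor_times = np.full(n_samples, np.inf)
    observed = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)

    annotation = pd.DataFrame({
        "sample_id": sample_ids,
        "grade": grades,
        "time_months": np.round(observed, 4),
        "event": event,
    }).set_index("sample_id", drop=False)

    mirna_expr = ExpressionMatrix(
        values=pd.DataFrame(np.round(M, 6), index=mirna_ids, columns=sample_ids),
        feature_kind="miRNA",
    )
    gene_expr = ExpressionMatrix(
        values=pd.DataFrame(np.round(G, 6), index=gene_ids, columns=sample_ids),
        feature_kind="gene",
    )

    truth = GroundTruth(
        planted_diff_mirnas=planted_diff_mirnas,
        planted_diff_genes=planted_diff_genes,
        planted_pairs=planted_pairs,
        decoy_pairs=sorted(decoys),
        planted_enriched_pathways=planted_enriched,
        planted_crosstalk_pairs=crosstalk_pairs,
        planted_risk_groups=truth_groups,
    )

    # every planted pair must join opposite-direction differential partners
    for contrast, ps in planted_pairs.items():
        mir_up = set(planted_diff_mirnas[contrast]["up"])
        gene_up = set(planted_diff_genes[contrast]["up"])
        for m, g in ps:
            if (m in mir_up) == (g in gene_up):
                raise ConfigError("internal: planted pair directions not opposite")

    # the low-confidence edges are appended to the written file only; the
    # in-memory graph stays at the analysis (score >= 900) level
    dataset = SyntheticDataset(
        mirna_expr=mirna_expr,
        gene_expr=gene_expr,
        annotation=annotation,
        target_pairs=target_pairs,
        ppi=ppi,
        pathways=collection,
        truth=truth,
    )
    dataset._low_confidence_edges = low_edges  # type: ignore[attr-defined]
    return dataset


def write_dataset(dataset: SyntheticDataset, outdir) -> Dict[str, Path]:
    """Write all inputs; includes sub-threshold PPI rows the reader filters."""
    paths = dataset.write(outdir)
    low = getattr(dataset, "_low_confidence_edges", [])
    if low:
        with open(paths["ppi"], "a") as fh:
            for a, b, s in sorted(low):
                fh.write(f"{a}\t{b}\t{s}\n")
    return paths
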