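"""Readers and writers for every file format the pipeline touches.

All tables are tab-separated text.  Expression matrices carry features in
rows and samples in columns; gene sets use the standard GMT dialect; PPI
edges are two- or three-column lists with an optional STRING-style combined
score (0-1000).  Readers are strict: ragged rows, non-numeric cells and
malformed lines raise :class:`~mircross.errors.FormatError` rather than
being coerced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from mircross.errors import FormatError, InputError

logger = logging.getLogger(__name__)

GRADES = ("II", "III", "IV")

# float format shared by all writers so identical runs are byte-identical
FLOAT_FORMAT = "%.10g"


@dataclass
class ExpressionMatrix:
    """A feature x sample log-expression matrix with its feature kind."""

    values: pd.DataFrame
    feature_kind: str  # "miRNA" or "gene"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("miRNA", "gene"):
            raise InputError(f"unknown feature kind {self.feature_kind!r}")
        if self.values.index.duplicated().any():
            raise InputError("duplicate feature IDs after load")
        if self.values.columns.duplicated().any():
            raise InputError("duplicate sample IDs")

    @property
    def feature_ids(self):
        return list(self.values.index)

    @property
    def sample_ids(self):
        return list(self.values.columns)


@dataclass
class GeneSetCollection:
    """Pathway membership: pathway_id -> (description, gene-ID set)."""

    sets: Dict[str, Tuple[str, Set[str]]] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)

    def genes(self, pathway_id: str) -> Set[str]:
        return self.sets[pathway_id][1]

    def description(self, pathway_id: str) -> str:
        return self.sets[pathway_id][0]

    def all_genes(self) -> Set[str]:
        out: Set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return out


def _check_rectangular(path: Path) -> None:
    widths = set()
    with open(path) as fh:
        for line in fh:
            widths.add(line.rstrip("\n").count("\t"))
            if len(widths) > 1:
                raise FormatError(f"{path}: ragged rows (inconsistent column counts)")
    if not widths:
        raise FormatError(f"{path}: empty file")


def read_expression(path, feature_kind: str, missing: str = "error") -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    Duplicate feature rows are collapsed by arithmetic mean, mirroring the
    upstream convention of averaging probes that map to the same feature.
    ``missing`` is ``"error"`` (default) or ``"impute_row_mean"``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    _check_rectangular(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at feature {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}: {raw.iat[r, c]!r}"
        )
    if values.isna().to_numpy().any():
        if missing == "impute_row_mean":
            values = values.apply(lambda row: row.fillna(row.mean()), axis=1)
            if values.isna().to_numpy().any():
                raise FormatError(f"{path}: feature with all values missing")
        else:
            n = int(values.isna().to_numpy().sum())
            raise FormatError(
                f"{path}: {n} missing values (pass missing='impute_row_mean' to impute)"
            )
    if values.index.duplicated().any():
        n_dup = int(values.index.duplicated().sum())
        logger.info("%s: averaging %d duplicate feature rows", path, n_dup)
        values = values.groupby(level=0, sort=False).mean()
    logger.info("%s: %d features x %d samples", path, *values.shape)
    return ExpressionMatrix(values=values, feature_kind=feature_kind)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id",
                         float_format=FLOAT_FORMAT)


def read_annotation(path) -> pd.DataFrame:
    """Read the sample annotation table (sample_id, grade[, time, event])."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "grade": str})
    required = {"sample_id", "grade"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    bad_grade = ~df["grade"].isin(GRADES)
    if bad_grade.any():
        raise FormatError(
            f"{path}: unknown grade {df.loc[bad_grade, 'grade'].iloc[0]!r}"
        )
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample IDs")
    if "time_months" in df.columns and (df["time_months"].dropna() < 0).any():
        raise FormatError(f"{path}: negative survival time")
    if "event" in df.columns and not df["event"].dropna().isin((0, 1)).all():
        raise FormatError(f"{path}: event indicator must be 0/1")
    return df.set_index("sample_id", drop=False)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_target_pairs(path) -> Set[Tuple[str, str]]:
    """Read predicted miRNA->gene pairs (two tab-separated columns)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    pairs: Set[Tuple[str, str]] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if i == 1 and fields[:2] == ["mirna_id", "gene_id"]:
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{i}: expected two tab-separated fields")
            m, g = fields[0], fields[1]
            if m == g:
                raise FormatError(f"{path}:{i}: self-referential pair {m!r}")
            pairs.add((m, g))
    return pairs


def write_target_pairs(pairs, path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_id\n")
        for m, g in sorted(pairs):
            fh.write(f"{m}\t{g}\n")


def read_ppi(path, min_score: Optional[int] = 900) -> nx.Graph:
    """Read a PPI edge list, keeping high-confidence interactions.

    Rows are ``gene_a<TAB>gene_b[<TAB>combined_score]``.  When scores are
    present, edges below ``min_score`` (default 900, the strict STRING
    combined-score cutoff) are discarded.  Self-loops are dropped with a
    warning; duplicate unordered edges are merged keeping the best score.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    graph = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if i == 1 and fields[0] == "gene_a":
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{i}: expected >=2 tab-separated fields")
            a, b = fields[0], fields[1]
            if a == b:
                n_loops += 1
                continue
            score: Optional[int] = None
            if len(fields) >= 3 and fields[2] != "":
                try:
                    score = int(fields[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{i}: non-integer score {fields[2]!r}") from exc
                if not (0 <= score <= 1000):
                    raise FormatError(f"{path}:{i}: score {score} outside 0-1000")
                if min_score is not None and score < min_score:
                    continue
            if graph.has_edge(a, b):
                old = graph.edges[a, b].get("score")
                if score is not None and (old is None or score > old):
                    graph.edges[a, b]["score"] = score
            else:
                if score is None:
                    graph.add_edge(a, b)
                else:
                    graph.add_edge(a, b, score=score)
    if n_loops:
        logger.warning("%s: dropped %d self-loop rows", path, n_loops)
    return graph


def write_ppi(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tcombined_score\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            score = graph.edges[a, b].get("score", "")
            fh.write(f"{a}\t{b}\t{score}\n")


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format (set_id, description, members...)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    sets: Dict[str, Tuple[str, Set[str]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{i}: GMT lines need >=3 tab-separated fields "
                    f"(got {len(fields)})"
                )
            set_id, desc = fields[0], fields[1]
            members = {g for g in fields[2:] if g}
            if not members:
                raise FormatError(f"{path}:{i}: gene set {set_id!r} has no members")
            if set_id in sets:
                raise FormatError(f"{path}:{i}: duplicate gene set {set_id!r}")
            sets[set_id] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(collection.sets):
            desc, members = collection.sets[set_id]
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


def write_graphml(graph: nx.Graph, path) -> None:
    """Export a network for inspection in standard graph viewers."""
    clean = nx.Graph()
    for node, attrs in sorted(graph.nodes(data=True)):
        clean.add_node(node, **{k: v for k, v in sorted(attrs.items()) if v is not None})
    for a, b, attrs in sorted(graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
        clean.add_edge(a, b, **{k: v for k, v in sorted(attrs.items()) if v is not None})
    nx.write_graphml(clean, path)
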