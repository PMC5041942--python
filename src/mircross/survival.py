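"""Survival stratification by module-signature expression.

Samples are split into two groups by K-means (k = 2) on per-feature
standardized signature expression; the group with the smaller Kaplan-Meier
median survival is labeled "short".  Group separation is tested with the
two-group log-rank test.  A helper produces the within-grade
complete-linkage orderings used for expression heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans

from mircross.errors import InputError
from mircross.io import ExpressionMatrix, GRADES

logger = logging.getLogger(__name__)


def standardize(matrix: np.ndarray) -> np.ndarray:
    """Z-score columns (features); constant features map to zero."""
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (matrix - mean) / sd


def two_group_cluster(
    feature_matrix: np.ndarray,
    seed: int = 0,
    n_restarts: int = 10,
) -> np.ndarray:
    """K-means (k = 2) labels for a sample x feature matrix.

    Features are standardized before clustering so layers on different
    scales (genes vs miRNAs) contribute comparably to Euclidean distance.
    Best of ``n_restarts`` seeded initializations; deterministic given seed.
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("need a 2-D matrix with at least two samples")
    X = standardize(X)
    if np.allclose(X, X[0]):
        raise InputError("all samples identical: two-group clustering is degenerate")
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    return km.fit_predict(X)


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    event_times: np.ndarray  # ordered distinct observed times
    survival: np.ndarray     # S(t) at each time
    at_risk: np.ndarray      # subjects at risk just before each time
    median: float            # smallest t with S(t) <= 0.5; inf if never

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "survival": self.survival,
            "at_risk": self.at_risk,
        })


def km_fit(times, events) -> KMCurve:
    """Kaplan-Meier estimate with the grouped product-limit tie handling."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise InputError("empty survival input")
    if times.size != events.size:
        raise InputError("times and events must have equal length")
    if (times < 0).any():
        raise InputError("negative survival time")
    if not np.isin(events, (0, 1)).all():
        raise InputError("event indicators must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_.iloc[:, 0]
    at_risk = kmf.event_table["at_risk"]
    # drop lifelines' t=0 baseline row unless an observation sits at 0
    keep = sf.index > 0 if (times > 0).all() else np.ones(len(sf), dtype=bool)
    grid = sf.index[keep].to_numpy(dtype=float)
    surv = sf[keep].to_numpy(dtype=float)
    below = surv <= 0.5
    median = float(grid[below][0]) if below.any() else float("inf")
    return KMCurve(
        event_times=grid,
        survival=surv,
        at_risk=at_risk[keep].to_numpy(dtype=float),
        median=median,
    )


def logrank(times_a, events_a, times_b, events_b) -> Tuple[float, float]:
    """Two-group log-rank statistic and its 1-df chi-square p-value."""
    ta, tb = np.asarray(times_a, dtype=float), np.asarray(times_b, dtype=float)
    ea, eb = np.asarray(events_a, dtype=int), np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise InputError("both groups must be nonempty")
    if ea.sum() == 0 and eb.sum() == 0:
        logger.warning("no events in either group: log-rank undefined, p set to 1")
        return 0.0, 1.0
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def stratify_and_test(
    mirna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    signature_genes: Sequence[str],
    signature_mirnas: Sequence[str],
    seed: int = 0,
    mode: str = "combined",
    n_restarts: int = 10,
) -> Tuple[pd.DataFrame, KMCurve, KMCurve, float, float]:
    """Cluster samples on signature expression and test survival separation.

    ``mode`` selects the feature layers: ``combined`` (default) stacks
    signature gene and miRNA expression, ``genes`` / ``mirnas`` use one
    layer.  Returns ``(table, curve_short, curve_long, chi_square, p)``
    where ``table`` has columns sample_id, group, time, event.
    """
    if mode not in ("combined", "genes", "mirnas"):
        raise InputError(f"unknown mode {mode!r}")
    ann = annotation.dropna(subset=["time_months", "event"])
    samples = [s for s in ann.index
               if s in set(mirna_expr.sample_ids) and s in set(gene_expr.sample_ids)]
    if len(samples) < 4:
        raise InputError("need at least four samples with survival data")

    blocks = []
    genes = [g for g in sorted(set(signature_genes)) if g in gene_expr.values.index]
    mirnas = [m for m in sorted(set(signature_mirnas)) if m in mirna_expr.values.index]
    if mode in ("combined", "genes"):
        if not genes and mode == "genes":
            raise InputError("no signature genes found in the expression matrix")
        if genes:
            blocks.append(gene_expr.values.loc[genes, samples].to_numpy().T)
    if mode in ("combined", "mirnas"):
        if not mirnas and mode == "mirnas":
            raise InputError("no signature miRNAs found in the expression matrix")
        if mirnas:
            blocks.append(mirna_expr.values.loc[mirnas, samples].to_numpy().T)
    if not blocks:
        raise InputError("empty survival signature")
    X = np.hstack(blocks)
    labels = two_group_cluster(X, seed=seed, n_restarts=n_restarts)
    if labels.min() == labels.max():
        raise InputError("clustering produced a single group")

    times = ann.loc[samples, "time_months"].to_numpy(dtype=float)
    events = ann.loc[samples, "event"].to_numpy(dtype=int)
    curves = {lab: km_fit(times[labels == lab], events[labels == lab]) for lab in (0, 1)}
    # tie-break equal medians by mean observed time so labeling is total
    order = sorted((0, 1), key=lambda lab: (curves[lab].median,
                                            times[labels == lab].mean()))
    short_lab, long_lab = order
    group = np.where(labels == short_lab, "short", "long")
    chi2, p = logrank(times[labels == short_lab], events[labels == short_lab],
                      times[labels == long_lab], events[labels == long_lab])
    table = pd.DataFrame({
        "sample_id": samples,
        "group": group,
        "time": times,
        "event": events,
    })
    logger.info("survival split: %d short / %d long, log-rank chi2=%.3f p=%.3g",
                (group == "short").sum(), (group == "long").sum(), chi2, p)
    return table, curves[short_lab], curves[long_lab], chi2, p


def heatmap_order(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
) -> Tuple[List[str], List[str]]:
    """Heatmap sample and feature orderings via complete-linkage clustering.

    Samples are clustered within each grade (Euclidean distance, complete
    linkage) and grades kept contiguous in II -> III -> IV order; features
    are clustered across all samples.  Dendrogram ties break toward the
    lower-index leaf, making the order deterministic.
    """
    ann = annotation.loc[annotation.index.intersection(matrix.values.columns)]
    sample_order: List[str] = []
    for grade in GRADES:
        ids = [s for s in matrix.sample_ids if s in set(ann.index[ann["grade"] == grade])]
        if not ids:
            continue
        if len(ids) < 2:
            sample_order.extend(ids)
            continue
        X = matrix.values[ids].to_numpy().T
        order = leaves_list(linkage(X, method="complete", metric="euclidean"))
        sample_order.extend(ids[i] for i in order)
    feats = matrix.feature_ids
    if len(feats) >= 2:
        cols = [s for s in sample_order if s in set(matrix.sample_ids)] or matrix.sample_ids
        F = matrix.values.loc[:, cols].to_numpy()
        forder = leaves_list(linkage(F, method="complete", metric="euclidean"))
        feature_order = [feats[i] for i in forder]
    else:
        feature_order = list(feats)
    return sample_order, feature_order
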