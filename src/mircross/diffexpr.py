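"""Differential expression calling across tumor-grade contrasts.

Grade II samples serve as controls; grade III and grade IV cases are each
compared against them with an unpaired t-test (pooled-variance Student's
test by default, Welch optional).  Benjamini-Hochberg adjustment is applied
separately within each (feature kind, contrast) family and features are
called significant at FDR < alpha (default 5%).
"""

from __future__ import annotations

import logging
from typing import Iterable, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mircross.errors import InputError
from mircross.io import ExpressionMatrix

logger = logging.getLogger(__name__)

CONTRASTS = ("III_vs_II", "IV_vs_II")
#: contrast -> (case grade, control grade)
CONTRAST_GRADES = {"III_vs_II": ("III", "II"), "IV_vs_II": ("IV", "II")}


def t_test_feature(case_values, control_values, variant: str = "student") -> Tuple[float, float]:
    """Two-sided unpaired t-test for one feature.

    Returns ``(t, p)``.  A feature constant and equal in both groups has an
    undefined statistic and is reported as ``(0.0, 1.0)`` with a warning so
    the feature universe stays stable downstream.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size < 2 or control.size < 2:
        raise InputError("each group needs at least two values")
    if variant not in ("student", "welch"):
        raise InputError(f"unknown t-test variant {variant!r}")
    if case.std() == 0 and control.std() == 0 and case.mean() == control.mean():
        logger.warning("feature constant and identical in both groups; p set to 1")
        return 0.0, 1.0
    t, p = stats.ttest_ind(case, control, equal_var=(variant == "student"))
    if not np.isfinite(t):  # zero pooled variance with distinct means
        t = np.sign(case.mean() - control.mean()) * np.inf
        return float(t), np.nextafter(0.0, 1.0)
    return float(t), float(max(p, np.nextafter(0.0, 1.0)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    contrast: str,
    alpha: float = 0.05,
    variant: str = "student",
) -> pd.DataFrame:
    """Call differential features for one grade contrast.

    Returns one row per feature with columns ``feature_id, kind, contrast,
    t, p, fdr, direction, significant``.  Direction is ``up`` iff the case
    mean exceeds the control mean.
    """
    if contrast not in CONTRAST_GRADES:
        raise InputError(f"unknown contrast {contrast!r}")
    case_grade, control_grade = CONTRAST_GRADES[contrast]
    in_matrix = annotation.index.intersection(matrix.values.columns)
    ann = annotation.loc[in_matrix]
    case_ids = ann.index[ann["grade"] == case_grade]
    control_ids = ann.index[ann["grade"] == control_grade]
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise InputError(
            f"contrast {contrast}: need >=2 samples per grade "
            f"(got {len(case_ids)} case, {len(control_ids)} control)"
        )
    if variant not in ("student", "welch"):
        raise InputError(f"unknown t-test variant {variant!r}")
    case = matrix.values[case_ids].to_numpy()
    control = matrix.values[control_ids].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(case, control, axis=1, equal_var=(variant == "student"))
    mean_diff = case.mean(axis=1) - control.mean(axis=1)
    # constant-and-equal features: undefined statistic -> non-significant
    degenerate = ~np.isfinite(t)
    both_flat = degenerate & (mean_diff == 0)
    t = np.where(both_flat, 0.0, t)
    p = np.where(both_flat, 1.0, p)
    # zero pooled variance with distinct means -> maximally significant
    split_flat = degenerate & (mean_diff != 0)
    t = np.where(split_flat, np.sign(mean_diff) * np.inf, t)
    p = np.where(split_flat, np.nextafter(0.0, 1.0), p)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    if both_flat.any():
        logger.warning("%d features constant and identical in both groups", both_flat.sum())

    fdr = bh_adjust(p)
    result = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "kind": matrix.feature_kind,
            "contrast": contrast,
            "t": t,
            "p": p,
            "fdr": fdr,
            "direction": np.where(mean_diff > 0, "up", "down"),
            "significant": fdr < alpha,
        }
    )
    logger.info(
        "%s %s: %d/%d significant at FDR < %g",
        matrix.feature_kind, contrast, int(result["significant"].sum()), len(result), alpha,
    )
    return result


def call_all_contrasts(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    contrasts: Iterable[str] = CONTRASTS,
    alpha: float = 0.05,
    variant: str = "student",
) -> pd.DataFrame:
    """BH families are per (kind, contrast): each contrast adjusted alone."""
    frames = [call_differential(matrix, annotation, c, alpha, variant) for c in contrasts]
    return pd.concat(frames, ignore_index=True)
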