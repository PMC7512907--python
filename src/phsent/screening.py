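"""Group-difference screening of entropy measures with an age-confounder filter.

Each of the 33 entropy measures is tested for a patient-vs-control location
difference with the two-sided Mann–Whitney U test (nonparametric; entropy
measures are not Gaussian).  Because the two groups may differ strongly in
age, a measure could separate the groups merely by tracking age; measures
whose Pearson correlation with age exceeds ``cc_max`` in magnitude are
therefore discarded.  A measure is *selected* when it passes both gates:

    selected  <=>  p < alpha  and  |corr(measure, age)| <= cc_max

Bonferroni correction is then applied to the selected set: the corrected
threshold is ``alpha / n_selected`` and selected measures beating it are
additionally flagged ``strongly_significant``.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UndefinedCorrelationError

logger = logging.getLogger(__name__)

__all__ = [
    "mann_whitney_u",
    "pearson_cc",
    "select_measures",
    "screen_matrix",
    "load_reference_screen",
    "SelectionResult",
]


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns ``(U, p)``.

    Exact enumeration when both samples have at most 8 values and no ties
    span the groups; otherwise the normal approximation with midrank tie
    correction and continuity correction.  Two identical constant samples
    give p = 1 (no evidence of a shift).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return len(a) * len(b) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(a) <= 8 and len(b) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pearson_cc(values: np.ndarray, ages: np.ndarray) -> float:
    """Pearson product-moment correlation between a measure and age."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(values) != len(ages) or len(values) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(values) == 0 or np.std(ages) == 0:
        raise UndefinedCorrelationError("zero variance in correlation input")
    return float(stats.pearsonr(values, ages).statistic)


@dataclass(frozen=True)
class SelectionResult:
    report: pd.DataFrame           # measure, p_value, age_cc, selected, strongly_significant
    selected: tuple[str, ...]
    alpha: float
    cc_max: float
    corrected_threshold: float | None


def select_measures(
    report: pd.DataFrame, alpha: float = 0.05, cc_max: float = 0.30
) -> SelectionResult:
    """Apply the significance + confounder filter to a screening report.

    ``report`` needs columns ``measure``, ``p_value``, ``age_cc``.  The CC
    gate is inclusive (``|cc| <= cc_max``): a measure whose correlation sits
    exactly on the threshold is still considered weakly age-related.
    Bonferroni correction divides alpha by the number of *selected*
    measures, and ``strongly_significant`` marks those also beating the
    corrected threshold.  The selection itself is idempotent and independent
    of row order.
    """
    required = {"measure", "p_value", "age_cc"}
    missing = required - set(report.columns)
    if missing:
        raise ValueError(f"report missing columns: {sorted(missing)}")
    out = report.loc[:, ["measure", "p_value", "age_cc"]].copy()
    finite = np.isfinite(out["p_value"]) & np.isfinite(out["age_cc"])
    if not finite.all():
        logger.warning("excluding %d measures with non-finite screening values",
                       int((~finite).sum()))
    out["selected"] = (
        finite
        & (out["p_value"] < alpha)
        & (out["age_cc"].abs() <= cc_max + 1e-12)
    )
    selected = tuple(out.loc[out["selected"], "measure"])
    if selected:
        corrected = alpha / len(selected)
    else:
        logger.warning("no measures passed the significance + confounder filter")
        corrected = None
    out["strongly_significant"] = out["selected"] & (
        out["p_value"] < (corrected if corrected is not None else np.nan)
    )
    return SelectionResult(report=out, selected=selected, alpha=alpha,
                           cc_max=cc_max, corrected_threshold=corrected)


def screen_matrix(
    matrix: pd.DataFrame, alpha: float = 0.05, cc_max: float = 0.30
) -> SelectionResult:
    """Screen every measure column of an entropy matrix.

    ``matrix`` is the subjects-by-measures table from
    :func:`phsent.entropy.entropy_matrix` (columns ``group``, ``age``, then
    measures).  Subjects carrying an infinite sentinel in a measure are
    excluded from that measure's test with a logged warning; measures with
    zero variance against age are skipped entirely.
    """
    measures = [c for c in matrix.columns if c not in ("group", "age")]
    is_patient = matrix["group"] == "patient"
    rows = []
    for name in measures:
        col = matrix[name].to_numpy(dtype=float)
        ok = np.isfinite(col)
        if not ok.all():
            logger.warning("measure %s: excluding %d subjects with sentinel values",
                           name, int((~ok).sum()))
        a = col[ok & is_patient.to_numpy()]
        b = col[ok & ~is_patient.to_numpy()]
        if len(a) < 2 or len(b) < 2 or ok.sum() < 3:
            logger.warning("measure %s: too few finite values, skipping", name)
            rows.append({"measure": name, "p_value": np.nan, "age_cc": np.nan})
            continue
        _, p = mann_whitney_u(a, b)
        try:
            cc = pearson_cc(col[ok], matrix.loc[ok, "age"].to_numpy(dtype=float))
        except UndefinedCorrelationError:
            logger.warning("measure %s: zero variance, skipping", name)
            p, cc = np.nan, np.nan
        rows.append({"measure": name, "p_value": p, "age_cc": cc})
    return select_measures(pd.DataFrame(rows), alpha=alpha, cc_max=cc_max)


def load_reference_screen() -> pd.DataFrame:
    """Published per-measure significance levels and age correlations.

    A 33-row table of Mann–Whitney p-values and age correlation
    coefficients reported for a real pulmonary-hypertension heart-sound
    cohort, shipped as package data.  Used to validate the selection rule
    against its published outcome (nine selected measures).
    """
    with importlib.resources.files("phsent.data").joinpath(
        "reference_screen.csv"
    ).open() as fh:
        return pd.read_csv(fh)
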