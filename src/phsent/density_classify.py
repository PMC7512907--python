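"""KDE-based Bayes classification of subjects from entropy measures.

For a chosen subset of measures, the patient and control groups each get a
nonparametric density estimate: a product-Gaussian kernel density estimator
with one Silverman rule-of-thumb bandwidth per dimension,

    f(e) = (1/n) sum_i prod_j  phi((e_j - e_ij) / h_j) / h_j

with ``h = 1.06 * sd * n**(-1/5)`` in one dimension and
``h_j = (4 / (d + 2))**(1/(d+4)) * n**(-1/(d+4)) * sd_j`` for joint
densities.  An unknown subject with measure vector ``e_u`` is labelled
*patient* iff ``f_patient(e_u) > f_control(e_u)`` (equal-prior Bayes rule;
ties go to *healthy*, which favors specificity in a screening setting).

Performance is estimated by leave-one-out cross-validation: each subject is
classified by densities trained on all the others, bandwidths refit within
every fold.  Sensitivity, specificity and accuracy come from the confusion
counts; the ROC curve sweeps a threshold over the held-out log density
ratios ``log f_p - log f_h`` (threshold 0 recovers the Bayes rule), with
AUC by trapezoid.  :func:`search_combinations` scores every subset of the
candidate measures up to a maximum dimension and ranks by accuracy, then
AUC.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateBandwidthError

logger = logging.getLogger(__name__)

__all__ = [
    "FittedDensity",
    "EvaluationResult",
    "silverman_bandwidth",
    "kde_fit",
    "bayes_classify",
    "loocv_evaluate",
    "search_combinations",
    "roc_curve",
]


def silverman_bandwidth(sd: float, n: int, d: int = 1) -> float:
    """Silverman rule-of-thumb bandwidth for one KDE dimension.

    ``d = 1``: ``1.06 * sd * n**(-1/5)``.  ``d > 1``:
    ``(4/(d+2))**(1/(d+4)) * n**(-1/(d+4)) * sd``.
    """
    if n < 2:
        raise ValueError("need at least 2 training samples")
    if not (sd > 0):
        raise DegenerateBandwidthError(f"non-positive spread sd={sd}")
    if d < 1:
        raise ValueError("dimension must be >= 1")
    if d == 1:
        return 1.06 * sd * n ** (-0.2)
    return (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) * n ** (-1.0 / (d + 4.0)) * sd


@dataclass(frozen=True)
class FittedDensity:
    """Product-Gaussian KDE with per-dimension Silverman bandwidths."""

    points: np.ndarray      # (n, d) training vectors
    bandwidths: np.ndarray  # (d,) positive

    @property
    def dimension(self) -> int:
        return self.points.shape[1]

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def __call__(self, e: np.ndarray) -> np.ndarray:
        """Density at one d-vector or a batch of shape (k, d)."""
        e = np.atleast_2d(np.asarray(e, dtype=float))
        if e.shape[1] != self.dimension:
            raise ValueError(
                f"query dimension {e.shape[1]} != density dimension {self.dimension}"
            )
        z = (e[:, None, :] - self.points[None, :, :]) / self.bandwidths
        kernels = np.exp(-0.5 * np.sum(z**2, axis=-1))
        norm = (2.0 * math.pi) ** (self.dimension / 2.0) * np.prod(self.bandwidths)
        out = kernels.sum(axis=1) / (self.n * norm)
        return out if out.size > 1 else out


def kde_fit(samples: np.ndarray) -> FittedDensity:
    """Fit the product-Gaussian KDE to an (n, d) sample matrix.

    At d = 1 this is exactly the classic single-variable Gaussian KDE with
    the 1.06 Silverman bandwidth; for d > 1 each dimension gets its own
    multivariate-Silverman bandwidth (diagonal bandwidth matrix).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    n, d = samples.shape
    if n < 2:
        raise ValueError("need at least 2 training samples")
    sds = samples.std(axis=0, ddof=1)
    bandwidths = np.array([silverman_bandwidth(float(s), n, d) for s in sds])
    return FittedDensity(points=samples, bandwidths=bandwidths)


def bayes_classify(
    e_u: np.ndarray, f_patient: FittedDensity, f_healthy: FittedDensity
) -> str:
    """Equal-prior Bayes rule: 'patient' iff f_patient(e_u) > f_healthy(e_u)."""
    if f_patient.dimension != f_healthy.dimension:
        raise ValueError("density dimensions differ")
    return "patient" if float(f_patient(e_u)[0]) > float(f_healthy(e_u)[0]) else "healthy"


@dataclass(frozen=True)
class EvaluationResult:
    measures: tuple[str, ...]
    num_tp: int
    num_fn: int
    num_tn: int
    num_fp: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    roc_points: np.ndarray = field(repr=False)  # (k, 2) of (FPR, TPR)
    scores: np.ndarray = field(repr=False)      # held-out log density ratios
    labels: np.ndarray = field(repr=False)      # true labels, 1 = patient


def _confusion(labels: np.ndarray, predicted_patient: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum(predicted_patient & (labels == 1)))
    fn = int(np.sum(~predicted_patient & (labels == 1)))
    tn = int(np.sum(~predicted_patient & (labels == 0)))
    fp = int(np.sum(predicted_patient & (labels == 0)))
    return tp, fn, tn, fp


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and trapezoid AUC from scores (higher => more patient-like).

    The decision ``score > tau`` sweeps tau from above the maximum score
    (operating point (0, 0)) down to below the minimum ((1, 1)).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(1 - sorted_labels)
    # collapse ties so each distinct score contributes a single point
    distinct = np.flatnonzero(sorted_scores[1:] != sorted_scores[:-1])
    keep = np.r_[distinct, len(sorted_scores) - 1]
    tpr = np.r_[0.0, tps[keep] / max(n_pos, 1)]
    fpr = np.r_[0.0, fps[keep] / max(n_neg, 1)]
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def loocv_evaluate(
    matrix: pd.DataFrame,
    measures: list[str] | tuple[str, ...],
) -> EvaluationResult:
    """Leave-one-out evaluation of the KDE-Bayes classifier.

    ``matrix`` is the subjects-by-measures table (columns ``group``, ``age``
    and measure columns).  For each subject the two group densities are
    refit (including Silverman bandwidths) on the remaining subjects and the
    held-out vector is scored by ``log f_p - log f_h``.  A training fold
    whose group has zero spread in a measure is rescued by an infinitesimal
    deterministic jitter (1e-9 of the grand SD), logged.
    """
    measures = tuple(measures)
    if not measures:
        raise ValueError("need at least one measure")
    missing = [m for m in measures if m not in matrix.columns]
    if missing:
        raise ValueError(f"matrix lacks measures: {missing}")
    labels = (matrix["group"] == "patient").to_numpy(dtype=int)
    if labels.sum() < 3 or (len(labels) - labels.sum()) < 3:
        raise ValueError("need at least 3 subjects per group")
    data = matrix.loc[:, list(measures)].to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite measure values; screen sentinels out first")
    grand_sd = data.std(axis=0, ddof=1)

    n = len(labels)
    scores = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        train, lab = data[keep], labels[keep]
        folds = []
        for cls in (1, 0):
            pts = train[lab == cls]
            sds = pts.std(axis=0, ddof=1)
            if np.any(sds == 0):
                logger.warning("fold %d: zero-variance measure jittered", i)
                jitter = 1e-9 * np.where(grand_sd > 0, grand_sd, 1.0)
                offsets = np.linspace(-1, 1, len(pts))[:, None] * jitter
                pts = pts + np.where(sds == 0, 1.0, 0.0) * offsets
            folds.append(kde_fit(pts))
        f_p, f_h = folds
        with np.errstate(divide="ignore"):
            log_p = float(np.log(f_p(data[i])[0]))
            log_h = float(np.log(f_h(data[i])[0]))
        if math.isinf(log_p) and math.isinf(log_h):
            scores[i] = 0.0  # both densities underflowed: tie -> healthy
        else:
            scores[i] = log_p - log_h

    predicted = scores > 0.0  # ties -> healthy
    tp, fn, tn, fp = _confusion(labels, predicted)
    sen = tp / (tp + fn) if tp + fn else float("nan")
    spe = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / n
    points, auc = roc_curve(scores, labels)
    return EvaluationResult(
        measures=measures, num_tp=tp, num_fn=fn, num_tn=tn, num_fp=fp,
        sensitivity=sen, specificity=spe, accuracy=acc, auc=auc,
        roc_points=points, scores=scores, labels=labels,
    )


def search_combinations(
    matrix: pd.DataFrame,
    candidates: list[str] | tuple[str, ...],
    d_max: int,
    sizes: tuple[int, ...] | None = None,
) -> list[EvaluationResult]:
    """Evaluate measure subsets and rank by accuracy (AUC as tiebreak).

    By default all subsets of size 1..d_max are scored; ``sizes`` restricts
    to specific subset sizes (e.g., ``(2,)`` for the pairwise search).
    """
    candidates = tuple(candidates)
    if not candidates:
        raise ValueError("candidate set is empty")
    if d_max > len(candidates):
        raise ValueError("d_max exceeds the number of candidates")
    wanted = sizes if sizes is not None else tuple(range(1, d_max + 1))
    results = [
        loocv_evaluate(matrix, combo)
        for size in wanted
        for combo in itertools.combinations(candidates, size)
    ]
    results.sort(key=lambda r: (-r.accuracy, -r.auc, r.measures))
    return results


def results_table(results: list[EvaluationResult]) -> pd.DataFrame:
    """Ranking table of a combination search (one row per subset)."""
    return pd.DataFrame(
        {
            "measures": ["/".join(r.measures) for r in results],
            "n_measures": [len(r.measures) for r in results],
            "sensitivity": [r.sensitivity for r in results],
            "specificity": [r.specificity for r in results],
            "accuracy": [r.accuracy for r in results],
            "auc": [r.auc for r in results],
        }
    )
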