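"""Regularity statistics of per-cycle feature sequences.

Three related entropy estimators quantify how unpredictable a short
physiological sequence is:

* **Sample entropy (SampEn)** — the negative log of the conditional
  probability that two windows of ``m`` consecutive values that match within
  a tolerance ``r`` (Chebyshev distance) still match when extended to
  ``m + 1`` values.  Self-matches are excluded, so the estimator is unbiased
  for perfectly regular input (a constant sequence scores 0).
* **Fuzzy entropy (FuzzyEn)** — SampEn with the hard match indicator replaced
  by a smooth membership function of the window distance, which stabilizes
  the estimate on short sequences.
* **Fuzzy measure entropy (FuzzyMEn)** — the sum of a *local* fuzzy entropy
  computed on windows with their own mean removed and a *global* fuzzy
  entropy computed on windows with the grand mean removed, capturing both
  fast local irregularity and slow global fluctuation.

All three use the tolerance ``r = r_frac * SD(x)`` (population SD).  With a
relative tolerance SampEn and FuzzyEn are invariant under affine maps of the
data; FuzzyMEn, whose similarity kernel is ``exp(-d**n / r)``, is invariant
under translation but not under rescaling — its value depends on the units
of the sequence, which is inherent to the definition.

Applied to the 11 heart-sound feature sequences this yields 33 named
measures per subject (``SampEn_Ener_s1`` ... ``FMEn_Int_s1``), assembled
into a subjects-by-measures table by :func:`entropy_matrix`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, MissingFeatureError

logger = logging.getLogger(__name__)

#: canonical order of the 11 per-cycle heart-sound features
FEATURE_NAMES = (
    "Int_s1",
    "Int_s2",
    "Car_cycle",
    "Max_pow_s1",
    "Max_f_s1",
    "Max_pow_s2",
    "Max_f_s2",
    "Ener_s1",
    "Ener_s2",
    "ShanEner_s1",
    "ShanEner_s2",
)

#: short names of the three entropy estimators, used as column prefixes
ENTROPY_PREFIXES = ("SampEn", "FuzzyEn", "FMEn")

MembershipKind = Literal["gauss", "literal"]


@dataclass(frozen=True)
class EntropyParams:
    """Shared parameters of the three entropy estimators.

    Parameters
    ----------
    m : int
        Embedding dimension (window length of the template vectors).
    r_frac : float
        Match tolerance as a fraction of the sequence standard deviation.
    n_local, n_global : float
        Exponents of the local and global fuzzy similarity kernels used by
        fuzzy measure entropy.
    membership : {"gauss", "literal"}
        Fuzzy entropy membership function.  ``"gauss"`` (default) is
        ``exp(-ln(2) * (d/r)**2)``: 1 at zero distance and 0.5 at ``d = r``.
        ``"literal"`` is ``exp(-(ln(d/r))**2)``, kept only for comparison;
        it is 0 at zero distance and is not a meaningful similarity.
    standardize : bool
        Standardize each sequence to zero mean / unit SD before computing
        the measures (default True).  SampEn and FuzzyEn are affine
        invariant, so this only affects fuzzy measure entropy, whose
        ``exp(-d**n / r)`` kernel is scale-dependent and degenerates
        (underflows to an infinite sentinel, or saturates at 0) when the
        sequence units put distances far from unit scale — e.g. cycle
        durations in milliseconds.  Standardization makes the 33-measure
        table unit-free.
    """

    m: int = 2
    r_frac: float = 0.2
    n_local: float = 3.0
    n_global: float = 2.0
    membership: MembershipKind = "gauss"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if not (self.r_frac > 0):
            raise ValueError(f"r_frac must be > 0, got {self.r_frac}")
        if self.n_local < 1 or self.n_global < 1:
            raise ValueError("similarity exponents must be >= 1")


def _templates(x: np.ndarray, length: int, count: int) -> np.ndarray:
    """First `count` sliding windows of `length` consecutive samples."""
    windows = np.lib.stride_tricks.sliding_window_view(x, length)
    return windows[:count]


def _chebyshev_pairs(templates: np.ndarray) -> np.ndarray:
    """Pairwise Chebyshev distance matrix between template vectors."""
    diff = templates[:, None, :] - templates[None, :, :]
    return np.abs(diff).max(axis=-1)


def _mean_offdiag(values: np.ndarray) -> float:
    """Mean over i of the mean over j != i of a square matrix."""
    n = values.shape[0]
    row_sums = values.sum(axis=1) - np.diag(values)
    return float(np.mean(row_sums / (n - 1)))


def _validate_sequence(x: np.ndarray, m: int) -> None:
    if x.ndim != 1:
        raise ValueError("expected a 1-D sequence")
    if len(x) < m + 2:
        raise InsufficientDataError(
            f"sequence of length {len(x)} too short for m={m} (need >= {m + 2})"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("sequence contains non-finite values")


def sample_entropy(x: Sequence[float], params: EntropyParams = EntropyParams()) -> float:
    """Sample entropy of a sequence.

    Returns 0 for a zero-variance sequence (maximally regular) and ``inf``
    when no window pair still matches at length ``m + 1`` (the conditional
    probability is 0 and its log undefined); callers treat ``inf`` as a
    flagged sentinel, not a value.
    """
    x = np.asarray(x, dtype=float)
    _validate_sequence(x, params.m)
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = params.r_frac * sd
    n_vec = len(x) - params.m  # same template count at both lengths
    means = []
    for length in (params.m, params.m + 1):
        d = _chebyshev_pairs(_templates(x, length, n_vec))
        means.append(_mean_offdiag((d <= r).astype(float)))
    b_m, b_m1 = means
    if b_m1 == 0.0 or b_m == 0.0:
        return math.inf
    return math.log(b_m) - math.log(b_m1)


def _fuzzy_membership(d: np.ndarray, r: float, kind: MembershipKind) -> np.ndarray:
    if kind == "gauss":
        return np.exp(-math.log(2.0) * (d / r) ** 2)
    if kind == "literal":
        with np.errstate(divide="ignore"):
            logs = np.log(d / r)
        out = np.exp(-np.square(logs))
        return np.where(d == 0.0, 0.0, out)
    raise ValueError(f"unknown membership kind: {kind!r}")


def fuzzy_entropy(x: Sequence[float], params: EntropyParams = EntropyParams()) -> float:
    """Fuzzy entropy: SampEn with a smooth membership in place of the hard match."""
    x = np.asarray(x, dtype=float)
    _validate_sequence(x, params.m)
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = params.r_frac * sd
    n_vec = len(x) - params.m
    phis = []
    for length in (params.m, params.m + 1):
        d = _chebyshev_pairs(_templates(x, length, n_vec))
        phis.append(_mean_offdiag(_fuzzy_membership(d, r, params.membership)))
    if phis[0] <= 0.0 or phis[1] <= 0.0:
        return math.inf
    return math.log(phis[0]) - math.log(phis[1])


def fuzzy_measure_entropy(
    x: Sequence[float], params: EntropyParams = EntropyParams()
) -> tuple[float, float, float]:
    """Fuzzy measure entropy and its local/global components.

    Returns ``(total, local, global)`` where ``total = local + global``
    exactly.  Local windows have their own mean removed; global windows the
    grand mean.  Similarity kernels are ``exp(-d**n_local / r)`` and
    ``exp(-d**n_global / r)`` with ``r = r_frac * SD(x)`` for both.
    """
    x = np.asarray(x, dtype=float)
    _validate_sequence(x, params.m)
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0, 0.0, 0.0
    r = params.r_frac * sd
    n_vec = len(x) - params.m
    grand_mean = float(np.mean(x))

    phi_local: list[float] = []
    phi_global: list[float] = []
    for length in (params.m, params.m + 1):
        w = _templates(x, length, n_vec)
        local = w - w.mean(axis=1, keepdims=True)
        glob = w - grand_mean
        d_local = _chebyshev_pairs(local)
        d_global = _chebyshev_pairs(glob)
        phi_local.append(_mean_offdiag(np.exp(-(d_local**params.n_local) / r)))
        phi_global.append(_mean_offdiag(np.exp(-(d_global**params.n_global) / r)))

    local_en = math.log(phi_local[0]) - math.log(phi_local[1])
    global_en = math.log(phi_global[0]) - math.log(phi_global[1])
    return local_en + global_en, local_en, global_en


def measure_name(prefix: str, feature: str) -> str:
    """Canonical measure column name, e.g. ``SampEn_Max_pow_s2``."""
    return f"{prefix}_{feature}"


def all_measure_names() -> list[str]:
    """The 33 measure names in canonical (estimator-major) order."""
    return [measure_name(p, f) for p in ENTROPY_PREFIXES for f in FEATURE_NAMES]


def entropy_matrix(
    cohort: Iterable,
    params: EntropyParams = EntropyParams(),
) -> pd.DataFrame:
    """Compute the 33 entropy measures for every subject of a cohort.

    Parameters
    ----------
    cohort : iterable of FeatureSequenceSet
        Each element must expose ``sequences`` (mapping of the 11 feature
        names to equal-length arrays) and ``subject_meta`` (with ``id``,
        ``group`` and ``age`` attributes).

    Returns
    -------
    pandas.DataFrame
        Indexed by subject id with columns ``group``, ``age`` and the 33
        measures.  Sequences with no surviving template match produce an
        ``inf`` sentinel, which is logged; screening excludes them.
    """
    rows = []
    for subject in cohort:
        meta = subject.subject_meta
        row: dict[str, object] = {"id": meta.id, "group": meta.group, "age": meta.age}
        for feature in FEATURE_NAMES:
            if feature not in subject.sequences:
                raise MissingFeatureError(
                    f"subject {meta.id!r} is missing feature {feature!r}"
                )
            seq = np.asarray(subject.sequences[feature], dtype=float)
            if params.standardize and np.std(seq) > 0:
                seq = (seq - np.mean(seq)) / np.std(seq)
            samp = sample_entropy(seq, params)
            fuzz = fuzzy_entropy(seq, params)
            fmen, _, _ = fuzzy_measure_entropy(seq, params)
            row[measure_name("SampEn", feature)] = samp
            row[measure_name("FuzzyEn", feature)] = fuzz
            row[measure_name("FMEn", feature)] = fmen
            for prefix, value in (("SampEn", samp), ("FuzzyEn", fuzz), ("FMEn", fmen)):
                if math.isinf(value):
                    logger.warning(
                        "infinite %s sentinel for subject %s feature %s",
                        prefix, meta.id, feature,
                    )
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("id")
    return frame[["group", "age"] + all_measure_names()]
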