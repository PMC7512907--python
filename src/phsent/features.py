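"""Per-cycle heart-sound features.

Eleven features are computed for every retained cardiac cycle:

========== =====================================================
Int_s1     S1 duration, ms
Int_s2     S2 duration, ms
Car_cycle  cycle duration (S1 onset to next S1 onset), ms
Max_pow_s1 peak of the Burg AR(4) power spectral density of S1
Max_f_s1   frequency of that peak, Hz
Max_pow_s2 / Max_f_s2   same for S2
Ener_s1    average energy of S1, mean(s^2)
Ener_s2    average energy of S2
ShanEner_s1  average Shannon energy of S1, -mean(s^2 ln s^2)
ShanEner_s2  average Shannon energy of S2
========== =====================================================

Energy features assume the recording was globally normalized to
``max |s| = 1`` (so ``s^2 <= 1`` and Shannon energy is nonnegative);
spectral features use a fourth-order autoregressive fit (Burg method, which
stays stable and smooth on the short S1/S2 segments) evaluated on a 1 Hz
grid up to the Nyquist frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.regression.linear_model import burg as _sm_burg

from .entropy import FEATURE_NAMES
from .exceptions import InsufficientCyclesError, InsufficientDataError
from .segmentation import CycleSegmentation, normalize_amplitude
from .synthcohort import FeatureSequenceSet, SubjectMeta

__all__ = [
    "ArModel",
    "interval_features",
    "burg_ar",
    "ar_psd",
    "spectral_peak_features",
    "energy_features",
    "build_feature_sequences",
]

AR_ORDER = 4
MIN_CYCLES = 11


@dataclass(frozen=True)
class ArModel:
    """Autoregressive model x_t = sum_k a_k x_{t-k} + e_t (predictor form)."""

    order: int
    coefficients: np.ndarray  # a_1 .. a_p
    noise_variance: float

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.order:
            raise ValueError("order must equal the number of coefficients")
        if self.noise_variance < 0:
            raise ValueError("noise variance must be nonnegative")


def interval_features(
    seg: CycleSegmentation, next_s1_start: int, fs: float
) -> tuple[float, float, float]:
    """(Int_s1, Int_s2, Car_cycle) in ms for one cycle.

    The cycle duration runs from this cycle's S1 onset to the next cycle's
    S1 onset, so the caller must supply the successor's ``s1_start``.
    """
    to_ms = 1000.0 / fs
    int_s1 = (seg.s1_end - seg.s1_start) * to_ms
    int_s2 = (seg.s2_end - seg.s2_start) * to_ms
    car_cycle = (next_s1_start - seg.s1_start) * to_ms
    return int_s1, int_s2, car_cycle


def burg_ar(x: np.ndarray, order: int = AR_ORDER) -> ArModel:
    """Fit an AR model by the Burg method (forward+backward prediction error).

    The segment is de-meaned before fitting.  Coefficients are returned in
    the predictor convention (an AR(1) with dependence 0.9 on its past
    yields a first coefficient near +0.9).
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= order:
        raise InsufficientDataError(
            f"segment of length {len(x)} too short for AR order {order}"
        )
    x = x - np.mean(x)
    coeffs, sigma2 = _sm_burg(x, order=order, demean=False)
    return ArModel(order=order, coefficients=np.asarray(coeffs, dtype=float),
                   noise_variance=float(sigma2))


def ar_psd(
    model: ArModel, fs: float, n_freq: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Power spectral density of an AR model on a grid over (0, fs/2].

    ``PSD(f) = sigma^2 / |1 - sum_k a_k exp(-i 2 pi f k / fs)|^2``; with the
    default ``n_freq = fs/2`` points the grid spacing is 1 Hz at 2 kHz.
    Returns ``(freqs, psd)``.
    """
    freqs = np.linspace(0.0, fs / 2.0, n_freq + 1)[1:]
    k = np.arange(1, model.order + 1)
    phases = np.exp(-2j * np.pi * np.outer(freqs, k) / fs)
    denom = np.abs(1.0 - phases @ model.coefficients) ** 2
    psd = model.noise_variance / denom
    return freqs, psd


def spectral_peak_features(
    segment: np.ndarray, fs: float, order: int = AR_ORDER, n_freq: int = 1000
) -> tuple[float, float]:
    """(Max_pow, Max_f): height and location of the AR(4) PSD maximum."""
    model = burg_ar(segment, order)
    freqs, psd = ar_psd(model, fs, n_freq)
    peak = int(np.argmax(psd))
    return float(psd[peak]), float(freqs[peak])


def energy_features(segment: np.ndarray) -> tuple[float, float]:
    """(Ener, ShanEner): average energy and average Shannon energy.

    ``Ener = mean(s^2)``; ``ShanEner = -mean(s^2 * ln(s^2))`` with natural
    log and the ``0 * ln 0 = 0`` convention.  Nonnegative whenever the
    segment comes from a max-|s|-normalized recording.
    """
    segment = np.asarray(segment, dtype=float)
    if len(segment) == 0:
        raise InsufficientDataError("empty segment")
    sq = segment**2
    ener = float(np.mean(sq))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(sq > 0, sq * np.log(sq), 0.0)
    shan = float(-np.mean(terms))
    return ener, shan


def build_feature_sequences(
    pcg: np.ndarray,
    fs: float,
    segmentations: list[CycleSegmentation],
    subject_meta: SubjectMeta,
    ar_order: int = AR_ORDER,
    max_car_cycle_ms: float = 2000.0,
) -> FeatureSequenceSet:
    """Assemble the 11 equal-length feature sequences of one subject.

    The PCG is globally normalized to ``max |s| = 1`` first.  A cycle
    contributes one value per feature only when the next retained cycle
    directly follows it (cycle duration needs the successor's S1 onset and
    must stay below ``max_car_cycle_ms``, so QC gaps do not fabricate long
    cycles); the final cycle is therefore always dropped.

    Raises
    ------
    InsufficientCyclesError
        If fewer than 11 usable cycles remain (downstream entropy needs a
        workable sequence length).
    """
    pcg = normalize_amplitude(pcg)
    ordered = sorted(segmentations, key=lambda s: s.r_index)

    values: dict[str, list[float]] = {name: [] for name in FEATURE_NAMES}
    for seg, nxt in zip(ordered[:-1], ordered[1:]):
        int_s1, int_s2, car = interval_features(seg, nxt.s1_start, fs)
        if car > max_car_cycle_ms:
            continue
        s1 = pcg[seg.s1_start:seg.s1_end]
        s2 = pcg[seg.s2_start:seg.s2_end]
        try:
            pow_s1, f_s1 = spectral_peak_features(s1, fs, ar_order)
            pow_s2, f_s2 = spectral_peak_features(s2, fs, ar_order)
        except InsufficientDataError:
            continue
        ener_s1, shan_s1 = energy_features(s1)
        ener_s2, shan_s2 = energy_features(s2)
        for name, val in (
            ("Int_s1", int_s1), ("Int_s2", int_s2), ("Car_cycle", car),
            ("Max_pow_s1", pow_s1), ("Max_f_s1", f_s1),
            ("Max_pow_s2", pow_s2), ("Max_f_s2", f_s2),
            ("Ener_s1", ener_s1), ("Ener_s2", ener_s2),
            ("ShanEner_s1", shan_s1), ("ShanEner_s2", shan_s2),
        ):
            values[name].append(val)

    n = len(values["Int_s1"])
    if n < MIN_CYCLES:
        raise InsufficientCyclesError(
            f"subject {subject_meta.id!r}: only {n} usable cycles (need >= {MIN_CYCLES})"
        )
    sequences = {name: np.asarray(v, dtype=float) for name, v in values.items()}
    return FeatureSequenceSet(sequences=sequences, subject_meta=subject_meta)
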