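"""ECG-gated S1/S2 segmentation of phonocardiograms.

R peaks detected from the simultaneously recorded ECG (Pan–Tompkins) mark
the start of each cardiac cycle; within a cycle the first and second heart
sounds are located as supra-threshold lobes of the average Shannon energy
envelope of the amplitude-normalized PCG.  Manual verification of failed
cycles is replaced by per-cycle QC flags plus plausibility limits on the
derived intervals.

Conventions: sample indices are 0-based; segment windows are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .exceptions import InvalidFrameError, NoPeaksError

__all__ = [
    "CycleSegmentation",
    "SegmentationParams",
    "detect_r_peaks",
    "shannon_envelope",
    "segment_sounds",
    "qc_cycles",
    "segment_recording",
    "normalize_amplitude",
]


@dataclass(frozen=True)
class CycleSegmentation:
    """S1/S2 boundaries of one cardiac cycle (sample indices, half-open)."""

    r_index: int
    s1_start: int
    s1_end: int
    s2_start: int
    s2_end: int
    qc_pass: bool = True

    def ordered(self) -> bool:
        return (
            self.r_index <= self.s1_start < self.s1_end
            < self.s2_start < self.s2_end
        )


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable stage parameters (defaults suit 2 kHz PCG/ECG)."""

    frame_ms: float = 20.0
    overlap_frac: float = 0.5
    smooth_frames: int = 3
    threshold_frac: float = 0.2      # of the per-cycle envelope excursion
    s1_search_ms: float = 200.0      # S1 must start within this window after R
    int_s1_limits_ms: tuple[float, float] = (30.0, 250.0)
    int_s2_limits_ms: tuple[float, float] = (30.0, 250.0)
    car_cycle_limits_ms: tuple[float, float] = (400.0, 2000.0)


# ---------------------------------------------------------------------------
# R-peak detection (Pan-Tompkins)
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Pan–Tompkins QRS detection.

    Stages: 5–15 Hz band-pass (zero-phase), five-point derivative, squaring,
    150 ms moving-window integration, then adaptive dual thresholds on the
    integrated signal with a 200 ms refractory period.  Detected fiducials
    are snapped to the largest absolute band-passed deflection within
    ±100 ms, so reported indices align with the R wave itself.

    Raises
    ------
    NoPeaksError
        If the ECG is constant or no beat exceeds the adaptive threshold.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.ndim != 1 or len(ecg) < int(2 * fs):
        raise ValueError("need a 1-D ECG of at least 2 s")
    if np.ptp(ecg) == 0:
        raise NoPeaksError("constant ECG: no R peaks")

    nyq = fs / 2.0
    b, a = butter(2, [5.0 / nyq, 15.0 / nyq], btype="band")
    filtered = filtfilt(b, a, ecg)

    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * fs / 8.0
    deriv = np.convolve(filtered, kernel[::-1], mode="same")
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    # candidate local maxima of the integrated signal
    from scipy.signal import find_peaks

    candidates, _ = find_peaks(integrated, distance=refractory)
    if len(candidates) == 0:
        raise NoPeaksError("no candidate peaks in integrated ECG")

    # adaptive dual thresholds (signal / noise running estimates)
    spki = float(np.max(integrated[: int(2 * fs)])) * 0.5
    npki = float(np.mean(integrated[: int(2 * fs)])) * 0.5
    peaks: list[int] = []
    for idx in candidates:
        peaki = integrated[idx]
        threshold1 = npki + 0.25 * (spki - npki)
        if peaki > threshold1:
            if peaks and idx - peaks[-1] < refractory:
                continue
            peaks.append(int(idx))
            spki = 0.125 * peaki + 0.875 * spki
        else:
            npki = 0.125 * peaki + 0.875 * npki
    if not peaks:
        raise NoPeaksError("no beats exceeded the adaptive threshold")

    # snap to the R wave in the band-passed signal
    half = int(round(0.100 * fs))
    snapped = []
    for idx in peaks:
        lo, hi = max(0, idx - half), min(len(ecg), idx + half + 1)
        snapped.append(lo + int(np.argmax(np.abs(filtered[lo:hi]))))
    snapped = np.unique(snapped)
    return snapped.astype(int)


# ---------------------------------------------------------------------------
# Shannon energy envelope
# ---------------------------------------------------------------------------

def normalize_amplitude(pcg: np.ndarray) -> np.ndarray:
    """Scale to max |s| = 1 so s**2 <= 1 and Shannon energy is nonnegative."""
    pcg = np.asarray(pcg, dtype=float)
    peak = np.max(np.abs(pcg))
    return pcg if peak == 0 else pcg / peak


def _frame_grid(n: int, frame_len: int, hop: int) -> int:
    return 1 + (n - frame_len) // hop


def shannon_envelope(
    pcg: np.ndarray,
    fs: float,
    frame_ms: float = 20.0,
    overlap_frac: float = 0.5,
    smooth_frames: int = 3,
) -> tuple[np.ndarray, int, int]:
    """Per-frame average Shannon energy of an amplitude-normalized PCG.

    Each frame of ``frame_ms`` (hop ``frame_ms * (1 - overlap_frac)``)
    contributes ``-mean(s^2 * ln(s^2))`` with the ``0 * ln 0 = 0``
    convention.  The envelope is standardized to zero mean / unit variance
    and smoothed with a short moving average.

    Returns ``(envelope, frame_len, hop)`` in samples, so callers can map
    frame indices back to sample indices.
    """
    pcg = np.asarray(pcg, dtype=float)
    frame_len = int(round(frame_ms / 1000.0 * fs))
    hop = max(1, int(round(frame_len * (1.0 - overlap_frac))))
    if frame_len <= 0 or frame_len > len(pcg):
        raise InvalidFrameError(
            f"frame of {frame_len} samples incompatible with signal length {len(pcg)}"
        )
    n_frames = _frame_grid(len(pcg), frame_len, hop)
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = pcg[idx]
    sq = frames**2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(sq > 0, sq * np.log(sq), 0.0)
    energy = -np.mean(terms, axis=1)

    sd = np.std(energy)
    env = (energy - np.mean(energy)) / sd if sd > 0 else energy - np.mean(energy)
    if smooth_frames > 1:
        k = np.ones(smooth_frames) / smooth_frames
        env = np.convolve(env, k, mode="same")
    return env, frame_len, hop


# ---------------------------------------------------------------------------
# lobe-based S1/S2 segmentation
# ---------------------------------------------------------------------------

def _lobes(env: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of frames with env >= threshold, as [start, end) pairs."""
    above = env >= threshold
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(env))
    return list(zip(starts, ends))


def _refine_boundaries(
    pcg: np.ndarray, start: int, end: int, fs: float,
    floor_frac: float = 3e-4, max_extend_ms: float = 50.0,
) -> tuple[int, int]:
    """Snap coarse frame-level lobe boundaries to the sound's actual extent.

    The squared signal is smoothed over ~5 ms; boundaries move outward (up
    to ``max_extend_ms``) until the smoothed energy drops below
    ``floor_frac`` of the lobe peak, then inward past any leading/trailing
    sub-floor samples.  Removes the inward bias of frame-resolution
    threshold crossings.
    """
    k = max(1, int(round(0.005 * fs)))
    kernel = np.ones(k) / k
    energy = np.convolve(pcg**2, kernel, mode="same")
    peak = energy[start:end].max() if end > start else 0.0
    if peak <= 0:
        return start, end
    floor = floor_frac * peak
    ext = int(round(max_extend_ms / 1000.0 * fs))
    lo = start
    while lo > max(0, start - ext) and energy[lo - 1] >= floor:
        lo -= 1
    while lo < end - 1 and energy[lo] < floor:
        lo += 1
    hi = end
    while hi < min(len(pcg), end + ext) and energy[hi] >= floor:
        hi += 1
    while hi > lo + 1 and energy[hi - 1] < floor:
        hi -= 1
    return lo, hi


def segment_sounds(
    envelope: np.ndarray,
    r_peaks: np.ndarray,
    fs: float,
    frame_len: int,
    hop: int,
    threshold_frac: float = 0.2,
    s1_search_ms: float = 200.0,
    pcg: np.ndarray | None = None,
) -> list[CycleSegmentation]:
    """Locate S1 and S2 lobes within each R-to-R cycle.

    The per-cycle threshold sits at ``threshold_frac`` of the envelope
    excursion (min to max) inside the cycle.  S1 is the first lobe starting
    within ``s1_search_ms`` after the R peak; S2 is the next lobe after S1.
    When the normalized ``pcg`` is supplied, lobe boundaries are refined to
    sample resolution against the smoothed signal energy.  Cycles where
    either lobe is missing are returned with ``qc_pass=False`` (boundaries
    fall back to the R index) rather than raising.
    """
    envelope = np.asarray(envelope, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(r_peaks) < 2:
        return []
    centers = frame_len / 2.0 + hop * np.arange(len(envelope))

    out: list[CycleSegmentation] = []
    for r0, r1 in zip(r_peaks[:-1], r_peaks[1:]):
        in_cycle = np.flatnonzero((centers >= r0) & (centers < r1))
        if len(in_cycle) < 3:
            out.append(CycleSegmentation(int(r0), int(r0), int(r0) + 1,
                                         int(r0) + 2, int(r0) + 3, qc_pass=False))
            continue
        cyc = envelope[in_cycle]
        thr = cyc.min() + threshold_frac * (cyc.max() - cyc.min())
        lobes = _lobes(cyc, thr)

        def to_samples(lobe: tuple[int, int]) -> tuple[int, int]:
            f0, f1 = in_cycle[lobe[0]], in_cycle[lobe[1] - 1]
            return int(f0 * hop), int(f1 * hop + frame_len)

        s1 = next(
            (lb for lb in lobes
             if 0 <= to_samples(lb)[0] - r0 <= s1_search_ms / 1000.0 * fs),
            None,
        )
        s2 = None
        if s1 is not None:
            later = [lb for lb in lobes if lb[0] > s1[1]]
            # skip directly-adjacent lobes split by a single dip? keep first
            if later:
                s2 = later[0]
        if s1 is None or s2 is None:
            out.append(CycleSegmentation(int(r0), int(r0), int(r0) + 1,
                                         int(r0) + 2, int(r0) + 3, qc_pass=False))
            continue
        s1s, s1e = to_samples(s1)
        s2s, s2e = to_samples(s2)
        if pcg is not None:
            s1s, s1e = _refine_boundaries(pcg, s1s, s1e, fs)
            s2s, s2e = _refine_boundaries(pcg, s2s, s2e, fs)
            s1s = max(s1s, int(r0))
            s1e = min(s1e, s2s) if s1e > s2s else s1e
        seg = CycleSegmentation(int(r0), s1s, s1e, s2s, s2e,
                                qc_pass=(r0 <= s1s < s1e < s2s < s2e))
        out.append(seg)
    return out


def qc_cycles(
    segmentations: list[CycleSegmentation],
    fs: float,
    params: SegmentationParams = SegmentationParams(),
) -> list[CycleSegmentation]:
    """Drop cycles failing QC flags or plausibility limits on intervals.

    Limits default to Int_s1, Int_s2 in [30, 250] ms and the R-to-R cycle in
    [400, 2000] ms, a permissive envelope around resting adult physiology.
    """
    kept: list[CycleSegmentation] = []
    for k, seg in enumerate(segmentations):
        if not seg.qc_pass or not seg.ordered():
            continue
        int_s1 = (seg.s1_end - seg.s1_start) / fs * 1000.0
        int_s2 = (seg.s2_end - seg.s2_start) / fs * 1000.0
        lo1, hi1 = params.int_s1_limits_ms
        lo2, hi2 = params.int_s2_limits_ms
        if not (lo1 <= int_s1 <= hi1 and lo2 <= int_s2 <= hi2):
            continue
        if k + 1 < len(segmentations):
            cycle_ms = (segmentations[k + 1].r_index - seg.r_index) / fs * 1000.0
            loc, hic = params.car_cycle_limits_ms
            if not (loc <= cycle_ms <= hic):
                continue
        kept.append(seg)
    return kept


def segment_recording(
    pcg: np.ndarray,
    ecg: np.ndarray,
    fs: float,
    params: SegmentationParams = SegmentationParams(),
) -> list[CycleSegmentation]:
    """Full segmentation chain: normalize, detect R peaks, envelope, lobes."""
    normalized = normalize_amplitude(pcg)
    r_peaks = detect_r_peaks(ecg, fs)
    env, frame_len, hop = shannon_envelope(
        normalized, fs, params.frame_ms, params.overlap_frac, params.smooth_frames
    )
    return segment_sounds(
        env, r_peaks, fs, frame_len, hop,
        params.threshold_frac, params.s1_search_ms, pcg=normalized,
    )
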