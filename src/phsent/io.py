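"""Reading and writing of the pipeline's file contracts.

Recordings travel as 16-bit PCM WAV (one file per channel) or two-column
CSV (``time,value``; the time column is ignored, sample order is
authoritative).  Annotations, features and entropy matrices are plain CSV
with fixed headers so every stage can be re-run from its persisted inputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .exceptions import StageContractError
from .segmentation import CycleSegmentation

TRUTH_COLUMNS = ["cycle", "r_index", "s1_start", "s1_end", "s2_start", "s2_end"]
SEGMENTATION_COLUMNS = TRUTH_COLUMNS + ["qc_pass"]
META_COLUMNS = ["id", "group", "age"]


def write_wav(path: str | Path, waveform: np.ndarray, fs: float) -> None:
    """Write a waveform as 16-bit PCM, scaled to the full integer range."""
    waveform = np.asarray(waveform, dtype=float)
    peak = np.max(np.abs(waveform))
    scaled = waveform / peak if peak > 0 else waveform
    wavfile.write(str(path), int(fs), (scaled * 32767).astype(np.int16))


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    fs, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        data = data.astype(float) / 32767.0
    return np.asarray(data, dtype=float), float(fs)


def write_waveform_csv(path: str | Path, waveform: np.ndarray, fs: float) -> None:
    t = np.arange(len(waveform)) / fs
    pd.DataFrame({"time": t, "value": waveform}).to_csv(path, index=False)


def read_waveform_csv(path: str | Path) -> np.ndarray:
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise StageContractError(f"{path}: expected two columns (time,value)")
    return frame.iloc[:, 1].to_numpy(dtype=float)


def write_truth_csv(path: str | Path, truth: list[dict]) -> None:
    pd.DataFrame(truth)[TRUTH_COLUMNS].to_csv(path, index=False)


def write_segmentation_csv(path: str | Path, segs: list[CycleSegmentation]) -> None:
    rows = [
        dict(cycle=k, r_index=s.r_index, s1_start=s.s1_start, s1_end=s.s1_end,
             s2_start=s.s2_start, s2_end=s.s2_end, qc_pass=s.qc_pass)
        for k, s in enumerate(segs)
    ]
    pd.DataFrame(rows, columns=SEGMENTATION_COLUMNS).to_csv(path, index=False)


def read_segmentation_csv(path: str | Path) -> list[CycleSegmentation]:
    frame = pd.read_csv(path)
    missing = set(SEGMENTATION_COLUMNS) - set(frame.columns)
    if missing:
        raise StageContractError(f"{path}: missing columns {sorted(missing)}")
    return [
        CycleSegmentation(
            r_index=int(r.r_index), s1_start=int(r.s1_start), s1_end=int(r.s1_end),
            s2_start=int(r.s2_start), s2_end=int(r.s2_end), qc_pass=bool(r.qc_pass),
        )
        for r in frame.itertuples()
    ]


def require_columns(frame: pd.DataFrame, columns: list[str], origin: str) -> None:
    missing = set(columns) - set(frame.columns)
    if missing:
        raise StageContractError(f"{origin}: missing columns {sorted(missing)}")
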