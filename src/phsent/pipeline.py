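"""End-to-end orchestration: simulate -> segment -> features -> entropy ->
screen -> classify, with CSV/JSON artifacts per stage.

Every stage writes its output under the run directory and reads only the
previous stage's file contract, so any stage can be re-run in isolation.
All randomness derives from the single cohort seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .density_classify import results_table, search_combinations
from .entropy import FEATURE_NAMES, EntropyParams, entropy_matrix
from .exceptions import InsufficientCyclesError, StageContractError
from .features import build_feature_sequences
from .screening import screen_matrix
from .segmentation import SegmentationParams, qc_cycles, segment_recording
from .synthcohort import (
    CohortConfig,
    FeatureSequenceSet,
    generate_feature_sequences,
    generate_recording_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run (defaults follow the study design:
    m=2, r=0.2 SD, fuzzy exponents 3/2, AR order 4, alpha=0.05, |CC|<=0.30,
    fs=2000)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    entropy: EntropyParams = field(default_factory=EntropyParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    alpha: float = 0.05
    cc_max: float = 0.30
    d_max: int = 3
    use_waveforms: bool = False
    write_waveforms: bool = False


def _features_frame(cohort: list[FeatureSequenceSet]) -> pd.DataFrame:
    rows = []
    for subject in cohort:
        meta = subject.subject_meta
        n = len(next(iter(subject.sequences.values())))
        for k in range(n):
            row = {"id": meta.id, "group": meta.group, "age": meta.age, "cycle": k}
            row.update({f: float(subject.sequences[f][k]) for f in FEATURE_NAMES})
            rows.append(row)
    return pd.DataFrame(rows)


def _simulate(config: RunConfig, out: Path) -> list[FeatureSequenceSet]:
    if not config.use_waveforms:
        return generate_feature_sequences(config.cohort)
    cohort = []
    recordings = generate_recording_cohort(config.cohort)
    for rec in recordings:
        if config.write_waveforms:
            pio.write_wav(out / f"{rec.subject_meta.id}_pcg.wav", rec.pcg, rec.fs)
            pio.write_wav(out / f"{rec.subject_meta.id}_ecg.wav", rec.ecg, rec.fs)
            pio.write_truth_csv(out / f"{rec.subject_meta.id}_truth.csv", rec.truth)
        segs = segment_recording(rec.pcg, rec.ecg, rec.fs, config.segmentation)
        kept = qc_cycles(segs, rec.fs, config.segmentation)
        try:
            cohort.append(
                build_feature_sequences(rec.pcg, rec.fs, kept, rec.subject_meta)
            )
        except InsufficientCyclesError as err:
            logger.warning("dropping subject: %s", err)
    return cohort


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages and write per-stage artifacts.

    Writes ``features.csv``, ``entropy_matrix.csv``, ``screening.csv``,
    ``ranking.csv`` and ``summary.json`` under ``out_dir`` and returns the
    summary dictionary (selected measures; best single / pairwise /
    multi-measure LOOCV performance).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = _simulate(config, out)
    if len(cohort) < 6:
        raise StageContractError("fewer than 6 subjects survived simulation/QC")
    features = _features_frame(cohort)
    features.to_csv(out / "features.csv", index=False)

    matrix = entropy_matrix(cohort, config.entropy)
    matrix.to_csv(out / "entropy_matrix.csv")

    selection = screen_matrix(matrix, alpha=config.alpha, cc_max=config.cc_max)
    selection.report.to_csv(out / "screening.csv", index=False)

    def fully_finite(name: str) -> bool:
        return bool(np.isfinite(matrix[name].to_numpy(dtype=float)).all())

    # classification needs every subject's value, so measures with sentinel
    # (infinite-entropy) subjects are dropped here even if they screened in
    candidates = [c for c in selection.selected if fully_finite(c)]
    if len(candidates) < len(selection.selected):
        logger.warning(
            "dropping %d selected measures with sentinel values before LOOCV",
            len(selection.selected) - len(candidates),
        )
    if not candidates:
        logger.warning("empty selection; falling back to all finite measures")
        candidates = [
            c for c in matrix.columns if c not in ("group", "age") and fully_finite(c)
        ]

    d_max = min(config.d_max, len(candidates))
    results = search_combinations(matrix, candidates, d_max)
    table = results_table(results)
    table.to_csv(out / "ranking.csv", index=False)

    def best(size_filter) -> dict | None:
        rows = [r for r in results if size_filter(len(r.measures))]
        if not rows:
            return None
        r = rows[0]
        return {
            "measures": list(r.measures),
            "num_TP": r.num_tp, "num_FN": r.num_fn,
            "num_TN": r.num_tn, "num_FP": r.num_fp,
            "Sen": round(r.sensitivity, 6), "Spe": round(r.specificity, 6),
            "Acc": round(r.accuracy, 6), "AUC": round(r.auc, 6),
        }

    summary = {
        "seed": config.cohort.seed,
        "n_subjects": len(cohort),
        "alpha": config.alpha,
        "cc_max": config.cc_max,
        "selected_measures": candidates,
        "corrected_threshold": selection.corrected_threshold,
        "best_single": best(lambda k: k == 1),
        "best_pair": best(lambda k: k == 2) if d_max >= 2 else None,
        "best_multi": best(lambda k: True),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
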