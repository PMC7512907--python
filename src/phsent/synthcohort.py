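"""Synthetic two-group heart-sound cohorts with known ground truth.

No public recording set exists for the pulmonary-hypertension (PH) heart
sound study design this package targets, so validation runs on synthetic
cohorts generated at two levels:

* **feature level** — the 11 per-cycle feature sequences are drawn directly
  from a MIX-type stochastic process whose irregularity is tunable, skipping
  the waveform entirely.  This isolates the entropy / screening /
  classification stages from segmentation.
* **waveform level** — paired PCG + ECG waveforms are synthesized from a
  per-cycle plan (cycle length, S1/S2 durations, frequencies, amplitudes)
  with exact sample-index truth annotations, exercising R-peak detection,
  envelope segmentation and feature extraction end to end.

The irregularity knob is the classic MIX(p) process: a unit-variance
sinusoid in which each sample is independently replaced by uniform noise
with probability ``p``.  Entropy of MIX(p) increases monotonically with
``p``, giving a controllable ground-truth group separation.  The two group
probabilities are placed symmetrically around 0.5 by ``regularity_shift``:
``p_patient = 0.5 * (1 - shift)``, ``p_control = 0.5 * (1 + shift)``, so
``shift = 0`` makes the groups statistically identical and ``shift = 0.8``
gives the strongly separated MIX(0.1) vs MIX(0.9) pair.  Patients are the
*more regular* group here, mirroring the reduced beat-to-beat variability
reported in pulmonary hypertension.

Group ages default to the study-like means/SDs of 69.4 ± 12.3 (patients)
vs 32.6 ± 14.9 (controls) years.  Age confounding is off by default; with
``confound_age=True`` each subject's mixing probability is additionally
pulled by its standardized age, so entropy measures correlate with age and
the confounder filter has something to reject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .exceptions import InvalidConfigError, PlanInfeasibleError
from .entropy import FEATURE_NAMES

__all__ = [
    "CohortConfig",
    "SubjectMeta",
    "FeatureSequenceSet",
    "CyclePlan",
    "SyntheticRecording",
    "generate_feature_sequences",
    "generate_waveform",
    "generate_recording_cohort",
    "mix_sequence",
    "plan_cycles",
]

#: physiologically plausible (center, scale) used to map unit-variance MIX
#: output onto each feature's natural range and units
FEATURE_RANGES: Mapping[str, tuple[float, float]] = {
    "Int_s1": (100.0, 10.0),        # ms
    "Int_s2": (80.0, 8.0),          # ms
    "Car_cycle": (800.0, 40.0),     # ms  (~75 bpm)
    "Max_pow_s1": (0.020, 0.004),   # normalized PSD units
    "Max_f_s1": (50.0, 5.0),        # Hz
    "Max_pow_s2": (0.030, 0.006),
    "Max_f_s2": (70.0, 6.0),        # Hz
    "Ener_s1": (0.010, 0.002),
    "Ener_s2": (0.012, 0.0024),
    "ShanEner_s1": (0.050, 0.010),
    "ShanEner_s2": (0.060, 0.012),
}


@dataclass(frozen=True)
class SubjectMeta:
    id: str
    group: str  # "patient" | "control"
    age: float


@dataclass
class FeatureSequenceSet:
    """The 11 named per-cycle feature sequences of one subject."""

    sequences: dict[str, np.ndarray]
    subject_meta: SubjectMeta

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a synthetic cohort.

    ``regularity_shift`` may be a scalar applied to every feature or a
    mapping from feature name to a per-feature shift in [0, 1].
    """

    n_patient: int = 50
    n_control: int = 54
    n_cycles: int = 300          # ~5 min of recording at ~75 bpm
    seed: int = 0
    regularity_shift: float | Mapping[str, float] = 0.8
    age_means: tuple[float, float] = (69.4, 32.6)   # (patient, control) years
    age_sds: tuple[float, float] = (12.3, 14.9)
    murmur_level: float = 0.0
    fs: float = 2000.0
    confound_age: bool = False
    age_coupling: float = 0.3    # strength of age -> irregularity coupling

    def __post_init__(self) -> None:
        scalars = [
            self.n_patient, self.n_control, self.n_cycles, self.seed,
            *self.age_means, *self.age_sds, self.murmur_level, self.fs,
            self.age_coupling,
        ]
        shifts = (
            list(self.regularity_shift.values())
            if isinstance(self.regularity_shift, Mapping)
            else [self.regularity_shift]
        )
        if not all(math.isfinite(float(v)) for v in scalars + shifts):
            raise InvalidConfigError("non-finite value in cohort config")
        if self.n_patient < 2 or self.n_control < 2:
            raise InvalidConfigError("need at least 2 subjects per group")
        if self.n_cycles < 10:
            raise InvalidConfigError("need at least 10 cycles per subject")
        if any(not (0.0 <= s <= 1.0) for s in shifts):
            raise InvalidConfigError("regularity_shift must lie in [0, 1]")
        if self.murmur_level < 0:
            raise InvalidConfigError("murmur_level must be >= 0")
        if self.fs <= 0:
            raise InvalidConfigError("fs must be positive")

    def shift_for(self, feature: str) -> float:
        if isinstance(self.regularity_shift, Mapping):
            return float(self.regularity_shift.get(feature, 0.0))
        return float(self.regularity_shift)


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    # counter-based fan-out: adding subjects never reshuffles existing ones
    return np.random.default_rng([seed & 0x7FFFFFFF, subject_index])


def mix_sequence(
    n: int, p: float, rng: np.random.Generator, period: int = 12
) -> np.ndarray:
    """MIX(p) process: unit-variance sinusoid with noise substitution.

    ``x(i) = (1 - z_i) * sqrt(2) * sin(2*pi*i/period) + z_i * e_i`` with
    ``z_i ~ Bernoulli(p)`` and ``e_i ~ Uniform(-sqrt(3), sqrt(3))``; both
    components have unit variance, so p tunes irregularity at roughly
    constant amplitude.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"mixing probability must be in [0, 1], got {p}")
    i = np.arange(n)
    s = math.sqrt(2.0) * np.sin(2.0 * math.pi * i / period)
    z = rng.random(n) < p
    e = rng.uniform(-math.sqrt(3.0), math.sqrt(3.0), size=n)
    return np.where(z, e, s)


def group_mix_probability(shift: float, group: str) -> float:
    """Per-group Bernoulli substitution probability for a regularity shift."""
    half = 0.5 * shift
    return 0.5 - half if group == "patient" else 0.5 + half


def _draw_ages(config: CohortConfig, rng: np.random.Generator, group: str) -> float:
    idx = 0 if group == "patient" else 1
    return float(rng.normal(config.age_means[idx], config.age_sds[idx]))


def generate_feature_sequences(config: CohortConfig) -> list[FeatureSequenceSet]:
    """Generate a labelled cohort of feature-sequence sets.

    Patient subjects use the lower MIX probability (more regular sequences,
    lower entropy).  With ``confound_age=True`` a subject's probability is
    shifted by ``age_coupling * (age - pooled_mean) / pooled_sd`` (clipped to
    [0.01, 0.99]), tying irregularity to age across the whole cohort.
    """
    cohort: list[FeatureSequenceSet] = []
    pooled_mean = float(np.mean(config.age_means))
    pooled_sd = float(np.mean(config.age_sds)) + abs(
        config.age_means[0] - config.age_means[1]
    ) / 2.0

    groups = ["patient"] * config.n_patient + ["control"] * config.n_control
    for idx, group in enumerate(groups):
        rng = _subject_rng(config.seed, idx)
        age = _draw_ages(config, rng, group)
        sequences: dict[str, np.ndarray] = {}
        for feature in FEATURE_NAMES:
            p = group_mix_probability(config.shift_for(feature), group)
            if config.confound_age:
                p += config.age_coupling * (age - pooled_mean) / pooled_sd
                p = float(np.clip(p, 0.01, 0.99))
            center, scale = FEATURE_RANGES[feature]
            raw = mix_sequence(config.n_cycles, p, rng)
            sequences[feature] = center + scale * raw
        label = "p" if group == "patient" else "c"
        meta = SubjectMeta(id=f"{label}{idx:03d}", group=group, age=age)
        cohort.append(FeatureSequenceSet(sequences=sequences, subject_meta=meta))
    return cohort


# ---------------------------------------------------------------------------
# waveform level
# ---------------------------------------------------------------------------

#: fraction of the cycle (from S1 onset) at which S2 begins; a typical
#: systolic interval for resting adult cycles
SYSTOLIC_FRACTION = 0.35

#: delay from the ECG R peak to S1 onset, seconds (electromechanical delay)
R_TO_S1_DELAY_S = 0.04


@dataclass
class CyclePlan:
    """Per-cycle layout of a synthetic recording (all arrays same length)."""

    car_cycle_ms: np.ndarray
    int_s1_ms: np.ndarray
    int_s2_ms: np.ndarray
    f_s1_hz: np.ndarray
    f_s2_hz: np.ndarray
    amp_s1: np.ndarray
    amp_s2: np.ndarray

    def __post_init__(self) -> None:
        arrays = [
            self.car_cycle_ms, self.int_s1_ms, self.int_s2_ms,
            self.f_s1_hz, self.f_s2_hz, self.amp_s1, self.amp_s2,
        ]
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1:
            raise ValueError("cycle plan arrays must have equal length")

    def __len__(self) -> int:
        return len(self.car_cycle_ms)


@dataclass
class SyntheticRecording:
    pcg: np.ndarray
    ecg: np.ndarray
    fs: float
    truth: list[dict]  # per-cycle r_index, s1_start, s1_end, s2_start, s2_end
    subject_meta: SubjectMeta


def plan_cycles(
    config: CohortConfig, group: str, rng: np.random.Generator
) -> CyclePlan:
    """Draw a per-cycle plan from group-specific MIX processes."""

    def seq(feature: str) -> np.ndarray:
        p = group_mix_probability(config.shift_for(feature), group)
        center, scale = FEATURE_RANGES[feature]
        return center + scale * mix_sequence(config.n_cycles, p, rng)

    return CyclePlan(
        car_cycle_ms=seq("Car_cycle"),
        int_s1_ms=seq("Int_s1"),
        int_s2_ms=seq("Int_s2"),
        f_s1_hz=seq("Max_f_s1"),
        f_s2_hz=seq("Max_f_s2"),
        amp_s1=np.full(config.n_cycles, 0.8),
        amp_s2=np.full(config.n_cycles, 0.6),
    )


def _tone_burst(length: int, freq_hz: float, fs: float, amp: float,
                phase: float = 0.0) -> np.ndarray:
    """Windowed sinusoid occupying exactly `length` samples.

    A Tukey window (15% cosine taper each side) keeps the burst tonal — the
    fourth-order autoregressive spectrum of the segment peaks at the planned
    frequency — while the amplitude still falls to zero exactly at the
    annotated boundaries.
    """
    from scipy.signal.windows import tukey

    t = np.arange(length) / fs
    window = tukey(length, 0.3)
    return amp * window * np.sin(2.0 * math.pi * freq_hz * t + phase)


def _r_wave(fs: float) -> np.ndarray:
    """Narrow biphasic QRS-like template with energy in the 5-15 Hz band."""
    width = int(round(0.12 * fs))
    t = np.arange(width) / fs
    center = (width - 1) / 2.0 / fs
    sigma = 0.018
    g = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return g * np.cos(2.0 * math.pi * 9.0 * (t - center))


def generate_waveform(
    subject_meta: SubjectMeta,
    cycle_plan: CyclePlan,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticRecording:
    """Render a PCG/ECG pair from a cycle plan, with exact truth annotations.

    Each cycle places an ECG R wave at its start; S1 begins a fixed
    electromechanical delay after R, S2 at the systolic fraction of the
    cycle.  Both sounds are Gaussian-windowed sinusoids whose support equals
    the annotated window exactly.  The patient group receives band-limited
    murmur noise scaled by ``config.murmur_level``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.fs
    max_freq = float(max(cycle_plan.f_s1_hz.max(), cycle_plan.f_s2_hz.max()))
    if fs <= 2.0 * max_freq:
        raise InvalidConfigError(
            f"fs={fs} must exceed twice the highest planned frequency {max_freq}"
        )

    cycle_samples = np.round(np.asarray(cycle_plan.car_cycle_ms) * fs / 1000.0).astype(int)
    total = int(cycle_samples.sum()) + int(fs)  # 1 s tail margin
    pcg = np.zeros(total)
    ecg = np.zeros(total)
    r_template = _r_wave(fs)
    truth: list[dict] = []

    cursor = int(round(0.2 * fs))  # lead-in
    for k in range(len(cycle_plan)):
        r_index = cursor
        n_cycle = cycle_samples[k]
        s1_len = int(round(cycle_plan.int_s1_ms[k] * fs / 1000.0))
        s2_len = int(round(cycle_plan.int_s2_ms[k] * fs / 1000.0))
        s1_start = r_index + int(round(R_TO_S1_DELAY_S * fs))
        s1_end = s1_start + s1_len
        s2_start = s1_start + int(round(SYSTOLIC_FRACTION * n_cycle))
        s2_end = s2_start + s2_len
        if s1_end >= s2_start or s2_end >= r_index + n_cycle:
            raise PlanInfeasibleError(
                f"cycle {k}: planned events overlap or exceed the cycle "
                f"(s1 [{s1_start},{s1_end}), s2 [{s2_start},{s2_end}), "
                f"cycle end {r_index + n_cycle})"
            )
        half = len(r_template) // 2
        lo = r_index - half
        ecg[lo:lo + len(r_template)] += r_template
        pcg[s1_start:s1_end] += _tone_burst(
            s1_len, cycle_plan.f_s1_hz[k], fs, cycle_plan.amp_s1[k]
        )
        pcg[s2_start:s2_end] += _tone_burst(
            s2_len, cycle_plan.f_s2_hz[k], fs, cycle_plan.amp_s2[k]
        )
        truth.append(
            dict(cycle=k, r_index=r_index, s1_start=s1_start, s1_end=s1_end,
                 s2_start=s2_start, s2_end=s2_end)
        )
        cursor += n_cycle

    ecg += 0.01 * rng.standard_normal(total)
    if subject_meta.group == "patient" and config.murmur_level > 0:
        from scipy.signal import butter, filtfilt

        noise = rng.standard_normal(total)
        b, a = butter(2, [100.0 / (fs / 2), 400.0 / (fs / 2)], btype="band")
        pcg += config.murmur_level * filtfilt(b, a, noise)
    return SyntheticRecording(pcg=pcg, ecg=ecg, fs=fs, truth=truth,
                              subject_meta=subject_meta)


def generate_recording_cohort(config: CohortConfig) -> list[SyntheticRecording]:
    """Waveform-level cohort: one recording per subject, truth included."""
    recordings: list[SyntheticRecording] = []
    groups = ["patient"] * config.n_patient + ["control"] * config.n_control
    for idx, group in enumerate(groups):
        rng = _subject_rng(config.seed, idx)
        age = _draw_ages(config, rng, group)
        label = "p" if group == "patient" else "c"
        meta = SubjectMeta(id=f"{label}{idx:03d}", group=group, age=age)
        plan = plan_cycles(config, group, rng)
        recordings.append(generate_waveform(meta, plan, config, rng))
    return recordings


def truth_feature_sequences(recording: SyntheticRecording) -> dict[str, np.ndarray]:
    """Interval feature sequences implied by a recording's truth annotations.

    Only the three interval features are derivable from annotations alone;
    spectral and energy features require the waveform.  Used by tests to
    compare detected boundaries against planted truth.
    """
    fs = recording.fs
    t = recording.truth
    n = len(t) - 1  # last cycle has no successor S1
    sequences = {
        "Int_s1": np.array(
            [(c["s1_end"] - c["s1_start"]) / fs * 1000.0 for c in t[:n]]
        ),
        "Int_s2": np.array(
            [(c["s2_end"] - c["s2_start"]) / fs * 1000.0 for c in t[:n]]
        ),
        "Car_cycle": np.array(
            [(t[k + 1]["s1_start"] - t[k]["s1_start"]) / fs * 1000.0 for k in range(n)]
        ),
    }
    return sequences  # plain dict: not a full 11-feature set
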