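# Methods

## Signal model and segmentation

Recordings are paired single-channel PCG and lead-II ECG at fs = 2000 Hz.
R peaks anchor the cardiac cycles; the implementation follows the classic
Pan–Tompkins stages — 5–15 Hz band-pass (2nd-order Butterworth, zero-phase),
five-point derivative, squaring, 150 ms moving-window integration, adaptive
dual thresholds with a 200 ms refractory period — and then snaps each
fiducial to the largest band-passed deflection within ±100 ms so the
reported index sits on the R wave itself. A constant or empty ECG raises a
no-peaks error rather than returning an empty list silently.

S1/S2 segmentation works on the average Shannon energy envelope,
−mean(s²·ln s²) per 20 ms frame with 50 % overlap, computed after global
normalization of the PCG to max |s| = 1 (this keeps s² ≤ 1 so the Shannon
energy is nonnegative; it also makes the energy features dimensionless).
The envelope is standardized and smoothed over 3 frames. Within each R-to-R
interval the threshold sits at 20 % of the envelope excursion; S1 is the
first supra-threshold lobe starting within 200 ms of the R peak and S2 the
next lobe. Frame-resolution boundaries are then refined at sample
resolution: the squared signal is smoothed over 5 ms and each boundary moves
outward until the smoothed energy falls below 3×10⁻⁴ of the lobe peak
(≈ 1.7 % in amplitude, i.e. where a tapered burst genuinely ends), limited
to 50 ms. On noiseless synthetic waveforms this places boundaries within a
few milliseconds of the planted truth; the tests enforce ≤ 20 ms.

Manual review of failed cycles is replaced by automated QC: cycles missing
either lobe are flagged, and flagged or implausible cycles (S1 or S2 outside
30–250 ms, cycle outside 400–2000 ms) are dropped. All frame lengths,
thresholds and limits are exposed in `SegmentationParams`.

## Features

`Int_s1`, `Int_s2` are the S1/S2 durations; `Car_cycle` runs from one S1
onset to the next, so the final cycle contributes no value and a cycle
contributes at all only when its immediate successor was retained (gaps
created by QC would otherwise fabricate double-length cycles). All 11
sequences are truncated to this common length.

Spectral features fit a 4th-order autoregressive model to the de-meaned
segment by the Burg method (`statsmodels.regression.linear_model.burg`) and
evaluate PSD(f) = σ²/|1 − Σ aₖe^(−i2πfk/fs)|² on a 1 Hz grid over
(0, 1000] Hz; `Max_pow` and `Max_f` are the grid maximum and its frequency.
Coefficients use the predictor convention (an AR(1) with dependence 0.9
yields a₁ ≈ +0.9). Energy features use natural log and the 0·ln 0 = 0
convention.

## Entropy measures

All three estimators share the embedding dimension m = 2 and tolerance
r = 0.2·SD(x) (population SD, the convention of the reference SampEn
implementations). Template vectors are counted as N − m at both window
lengths m and m + 1, and self-matches are excluded. Sample entropy returns
0 for a zero-variance sequence (a constant sequence is maximally regular;
aborting on degenerate QC-passed subjects would be worse) and a flagged
+inf sentinel when no window pair survives to length m + 1 — downstream
screening excludes sentinel subjects per measure with a warning, and the
classifier refuses sentinel columns outright.

Fuzzy entropy uses the membership exp(−ln2·(d/r)²), which is 1 at zero
distance and 0.5 at d = r. A `membership="literal"` switch evaluates
exp(−(ln(d/r))²) instead — a form that appears in print but is 0 at zero
distance and is not a meaningful similarity — for comparison only.

Fuzzy measure entropy uses local windows (own mean removed) with kernel
exp(−d^nL/rL), nL = 3, and global windows (grand mean removed) with
exp(−d^nG/rG), nG = 2; the measure is the sum of the local and global
entropies. Because the kernel divides d^n by r (not by r^n), the measure is
translation- but **not** scale-invariant: distances far from unit scale
saturate the kernel at 0 or 1 and the estimate degenerates (for cycle
durations in milliseconds, d³/r ~ 10³ and every similarity underflows).
The measure table therefore standardizes each sequence to zero mean and
unit SD before scoring (`EntropyParams.standardize`, on by default); sample
entropy and fuzzy entropy are affine-invariant, so only fuzzy measure
entropy is affected, and the resulting 33-measure table is unit-free.

## Screening

Each measure gets a two-sided Mann–Whitney U test (exact enumeration when
both groups have ≤ 8 finite values and no ties; otherwise the normal
approximation with midrank tie correction and continuity correction) and a
Pearson correlation with age. Selection requires p < α (= 0.05) **and**
|cc| ≤ 0.30; the correlation gate is inclusive so a measure printed exactly
at the threshold is retained. Bonferroni correction divides α by the number
of selected measures and flags those also beating the corrected threshold
as strongly significant. Replayed on the packaged reference table of 33
published p-values and age correlations, this rule reproduces the published
selection of exactly nine measures, eight of them strongly significant.

A structural caveat the synthetic cohorts make explicit: when the groups
differ in age *and* the group difference drives every measure, each
informative measure correlates with age through group membership alone
(|cc| ≈ 0.75 with the default 69.4- vs 32.6-year groups), and the filter
rightly rejects everything. Runs that need a non-empty selection should use
age-matched groups; the pipeline otherwise falls back, with a logged
warning, to all fully-finite measures.

## Density estimation and classification

Group densities are product-Gaussian KDEs with one Silverman bandwidth per
dimension: h = 1.06·σ·n^(−1/5) at d = 1 and
hᵢ = (4/(d+2))^(1/(d+4))·n^(−1/(d+4))·σᵢ for joint densities (a diagonal
bandwidth matrix; this is the only reading of the multivariate rule that
reduces exactly to the 1-D form, and the tests verify both the reduction
and ∫f = 1 to 10⁻³). Sample SDs use ddof = 1. An unknown subject is a
patient iff f_p(e) > f_h(e); exact ties go to healthy, which favors
specificity in a screening context (configurable at the decision-score
level, where the rule is score = log f_p − log f_h > τ with τ = 0).

Leave-one-out cross-validation refits both densities — including
bandwidths — inside every fold, so no information about the held-out
subject leaks into training. A fold whose group has zero spread in a
measure is rescued with a deterministic jitter of 10⁻⁹ of the grand SD
(logged). ROC curves sweep τ over the held-out scores; AUC is the
trapezoid integral and equals the rank-sum (probability-of-correct-ordering)
form exactly, which the tests assert. Combination search scores every
subset of the candidate measures up to `d_max` and ranks by accuracy, then
AUC.

Known property: under the null (identical groups, n = 30 + 30), LOOCV
accuracy centers near 0.42 rather than 0.50 — the held-out subject's own
group trains on one fewer point, so the opposite density is slightly
favored. This leave-one-out pessimism is inherent to equal-prior density
comparison, is most visible at small n, and disappears as separation grows;
it is reported as-is rather than corrected.

## Synthetic cohorts

The generator defines the study conditions. Defaults: 50 patients and 54
controls; 300 cycles per subject (≈ 5 minutes at a typical resting rate);
ages 69.4 ± 12.3 years (patients) vs 32.6 ± 14.9 (controls); fs = 2000 Hz.
Feature sequences come from MIX(p) processes — x(i) = √2·sin(2πi/12) with
each sample independently replaced by Uniform(−√3, √3) noise with
probability p — whose entropy rises monotonically in p, giving tunable
ground-truth separation. `regularity_shift` s places the groups at
p = 0.5 ∓ s/2, so s = 0 is an exact null and s = 0.8 the strongly separated
MIX(0.1)-vs-MIX(0.9) pair; patients are the more regular group. Unit-scale
MIX output is mapped affinely onto plausible physiological ranges (cycle
800 ± 40 ms, S1 100 ± 10 ms, S2 80 ± 8 ms, S1 peak ~50 Hz, S2 peak ~70 Hz).
Age confounding is an explicit switch (off by default) that shifts each
subject's p by 0.3 standardized-age units, for testing the screening filter
in both regimes.

Waveform-level cohorts render, per cycle, an ECG R-wave template at the
cycle start and two Tukey-windowed (15 % taper) sinusoid bursts: S1 starting
40 ms after R (electromechanical delay) and S2 at 35 % of the cycle (a
typical systolic fraction; the source design never models systole length).
The taper keeps the bursts tonal — the Burg AR(4) spectrum peaks at the
planned frequency within a couple of Hz — while the amplitude reaches zero
exactly at the annotated boundaries, so truth annotations are sample-exact.
Patient recordings optionally add 100–400 Hz band-limited murmur noise
scaled by `murmur_level`. Per-subject RNG streams derive from
(seed, subject-index), so enlarging a cohort never reshuffles existing
subjects.

What the generator does **not** emulate: real S1/S2 morphology and A2–P2
splitting, respiratory modulation, sensor and ambient noise spectra,
arrhythmias, and any physiologic coupling between features (each of the 11
sequences is drawn independently). Passing tests therefore demonstrate that
the chain recovers known structure under controlled conditions, not
clinical performance; the published cohort's headline numbers (best single
measure Sen 0.720/Spe 0.648; best joint measures Sen 0.740/Spe 0.870) are
not reproducible without the original recordings, which were never
deposited.

## Problem sizes and numerical choices

Test and acceptance runs use scaled-down cohorts chosen as the smallest
sizes at which each property is statistically decidable: 100
oracle-comparison sequences of N ≤ 80; 2000 null Mann–Whitney pairs at
n = 30 per group; 200 subjects per group for the Bayes-consistency check
(accuracy within 0.05 of Φ(1) ≈ 0.8413); 30 + 30 null and 15 + 15
strong-separation cohorts with 100–150 cycles per subject; four 30-cycle
subjects for waveform segmentation. KDE integrals are trapezoid sums over
±6 SD grids. Entropy estimators build the full pairwise distance matrix
(O(N²) memory, N ≤ a few hundred cycles in practice). All randomness flows
from explicit integer seeds; identical configuration and seed reproduce
every artifact byte-for-byte.
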