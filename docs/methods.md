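# Methods

This note documents the models, numerical choices and known limitations of
the `distexp` pipeline, in the order data flow through it.

## Design generator

Locations are indexed 0–5 clockwise from the top of an imaginary circle, at
polar angles 90°, 30°, −30°, −90°, −150°, 150°. This is the unique 6-point
layout in which two locations sit on the vertical midline (0, 3) and two
lateralized locations lie below the horizontal midline (2, 4) — the latter
are the only admissible high-probability distractor locations in
Experiment 2, so that anticipatory lateralized activity can be measured.

Experiment 1 produces 18 blocks (6 per condition, cycling block-by-block) of
50 distractor-present trials; Experiment 2 produces 2 sessions × 54 blocks
of 56 trials with 18 consecutive blocks per condition. Within every block
exactly 70% of distractor-present trials (35 of 50) place the distractor at
the high-probability location; the remaining 15 are spread evenly (3 each)
over the other five locations, and the target location is drawn uniformly
from the five locations not occupied by the distractor. Each Experiment-2
block also contains 6 randomly interleaved distractor-absent trials with the
target once at every location. Blocked spatial frequencies rotate
deterministically across blocks so that every frequency serves in every
target/distractor pairing equally often. Condition order, the
high-probability side, and its mirroring between condition runs are
counterbalanced across subjects by subject index. The exact-70% allocation
(rather than Bernoulli sampling) matches counterbalanced practice and makes
the design structure testable exactly.

All randomness flows through `numpy` SeedSequence streams keyed by
(seed, subject, purpose), so every artifact is reproducible bit-for-bit from
one integer.

## Reaction-time model

RT = µ + σ·N(0,1) + Exp(τ) + additive effects. Defaults: µ = 450 ms,
σ = 60 ms, τ = 60 ms — a moderately skewed ex-Gaussian whose draws exceed
the 1000 ms response window (a non-response, dropped as incorrect) in well
under 0.1% of trials. Additive effects: a 40 ms distractor-present cost; a
condition-specific benefit when the distractor occupies the high-probability
location (defaults 50.9 / 30.6 / 41.7 ms for DpTp identical / DpTp unique /
DpTv unique, with between-subject SDs 24.4 / 10.7 / 20.1 ms — each simulated
subject draws its benefit once per condition); a 15 ms cost when the target
occupies the high-probability location. Accuracy is i.i.d. Bernoulli at 0.92.

### RT filtering and the trimming-scope choice

Filtering order is fixed: drop incorrect/non-response trials, drop
RT < 200 ms, then trim outside mean ± 2.5 SD. The order matters (a slow
outlier can survive if the SD is computed while anticipation responses are
still present); a regression test pins it.

The trim statistics are computed **within design cells** (condition ×
distractor location × target-at-high-probability), not pooled per
participant. Pooled bounds over cells whose true means differ by b attenuate
every between-cell difference by ≈ 2·k·φ(k) ≈ 8.8% at k = 2.5 — the slower
cell loses more of its upper tail and less of its lower tail — a bias that
is independent of the noise scale and distribution shape (we verified this
both analytically and by Monte Carlo). Cell-wise bounds remove the bias
while trimming a comparable fraction (~1.5–2%, matching published rates for
this cutoff). `filter_rts(..., trim_within_cells=False)` restores the
pooled variant for comparison.

Location-tuned analyses exclude co-occurrence confounds: distractor-tuned
cell means drop trials with the target at the high-probability location (and
distractor-absent trials); target-tuned means use only distractor-absent
trials in Experiment 2. The intertrial-priming control drops trials whose
distractor location repeats the immediately preceding trial's within a
block.

## EEG generator

Epochs span −1250…1050 ms around search onset (the −750…550 ms analysis
window extended by 500 ms so filters and wavelets have padding) at 512 Hz by
default; µV units; 64 scalp channels in a standard 10-10 montage plus VEOG,
HEOG and two earlobe references. The montage's 2D unit-disc positions are a
frozen projection of the standard 10-10 coordinate set; mirror pairs are
derived from the odd/even label convention.

Baseline activity is 1/f^α-shaped noise (spectral shaping of white noise,
α = 1, unit-variance normalized per trace) plus white noise, both 1 µV by
default. Ground-truth components, all zero-amplitude unless configured:

* **alpha lateralization** — a 10 Hz oscillation under a Hann envelope over
  −750…0 ms on the posterior pools, with amplitude base + a contralateral
  and base ipsilateral to the high-probability location;
* **N2pc / Pd** — Gaussian-windowed deflections (SD 30 ms) at 154 ms
  (negative, contralateral to the lateral target or distractor) and 283 ms
  (positive, contralateral to the distractor), the Pd scaled by 0.2 at the
  high-probability location to emulate learned suppression;
* **spatial-frequency codes** — one fixed unit-norm random 64-channel
  topography per (role, frequency class), drawn from a dedicated seed so
  target and distractor codes are independent. Evoked copies appear under a
  Hann window from 80 ms; anticipatory copies (Hann over −750…0 ms) appear
  only where foreknowledge exists: the target code in DpTp unique, the
  distractor code in DpTv unique. Because blocked frequencies are
  anti-associated in DpTp unique (target ≠ distractor within a block),
  cross-class decoding there generalizes *below* chance — the same
  signature the real paradigm shows — whereas independent codes give
  cross-class AUC ≈ 0.5;
* **artifacts** — 100 ms bursts of 110–140 Hz band-limited noise at a
  configurable multiple (default 10×) of the white-noise SD, and HEOG step
  artifacts (default 40 µV) at random latencies, each with per-trial
  probabilities.

The generator does **not** model volume-conducted dipolar topographies,
channel covariance of real EEG, eye-movement potentials beyond HEOG steps,
blinks, or non-stationary noise. Passing tests therefore demonstrate the
*analysis chain* is correct and calibrated, not that it would be this
sensitive on real recordings.

## Preprocessing

Chain: earlobe-average re-reference → 0.1 Hz high-pass → EMG rejection →
ocular regression → bad-channel interpolation → HEOG step rejection, each
logged with parameters in the epoch provenance.

Filters are linear-phase Hamming windowed-sinc FIR kernels (transition band
max(0.25·f_c, 0.1 Hz)), applied zero-phase via symmetric 'same' convolution.
Kernels are capped at half the epoch length so the central half of every
epoch sees full kernel overlap (this is what the 500 ms padding is for);
high-pass kernels are built by spectral inversion of the complementary
low-pass, which pins the DC gain to exactly zero even when capped.

EMG detection band-passes 110–140 Hz, takes the Hilbert envelope averaged
over scalp channels, z-scores it across all trials and timepoints, and
summarizes each trial by its max z. The cutoff adapts per subject: starting
at z = 4 it rises in 0.5 steps until the flagged set stops changing (cap
12). This replaces an inspect-then-reject workflow with a deterministic
rule; trials with no between-trial variance are never flagged. The HEOG
step detector slides two adjacent 100 ms half-windows in 10 ms steps and
flags any trial whose half-window mean difference exceeds 20 µV. Bad
channels are rebuilt by inverse-distance-squared weighting of the good
scalp channels on the 2D montage — a deliberately simple smooth spatial
fill. Blink handling regresses the VEOG channel out of every scalp channel
(least squares over all timepoints).

## Time–frequency analysis

Complex Morlet wavelets e^(i2πft)·e^(−t²/2s²) with s = δ/(2πf), for 25
log-spaced frequencies 1–40 Hz and 25 log-spaced cycle counts δ from 3 to
12; support ±5s, L2-normalized; convolution via FFT products (verified
against direct convolution to 1e-9 relative error); power = squared
magnitude, decimated ×4 in time. Power stays in raw µV² — the
lateralization index (P_contra − P_ipsi)/(P_contra + P_ipsi) is
self-normalizing, which is precisely its advantage: no pre-stimulus
baseline window is needed. Power is pooled over trials and then over the
channels of each pool before the ratio (ratio of means, stabilizing the
denominator); frequency bins belong to the 8–12 Hz alpha band when their
center lies in the closed interval. The statistical pools are PO7/8 and
O1/2.

## Decoding

Epochs are baseline-corrected (−750…−550 ms) and polyphase-resampled to
128 Hz; features are the 64 scalp channels at a single timepoint. The
classifier is a linear discriminant with the pooled within-class covariance
shrunk toward its diagonal, Σ̂ = (1−λ)S + λ·diag(S); λ defaults to the
analytic Schäfer–Strimmer estimate (off-diagonal variance over off-diagonal
energy, clipped to [0,1]), appropriate for 64 features and small per-fold
counts. Cross-validation is 10-fold with equal class counts per fold
(excess trials dropped under the seed); performance is macro one-vs-rest
AUC via the rank (Mann–Whitney) formulation with 0.5 tie credit.

Decoding runs within condition. Distractor-frequency decoding uses
distractor-present trials; target-frequency decoding also uses
distractor-present trials, reserving target-only (distractor-absent) trials
as the held-out test set for cross-class generalization — the only
leakage-safe split. Cross-class decoding fits one classifier per timepoint
on the class-balanced training trials and scores the disjoint test set (an
overlap raises an error); no CV is needed.

## ERP analysis

Distractor-tuned trials have the distractor at a lateral below-midline
location and the target on the vertical midline; target-tuned trials the
mirror criterion (distractor-absent trials with a lateral target count as
target-tuned). Cells are tagged high/low by whether the lateral stimulus
occupies the high-probability location. Epochs are 30 Hz low-pass filtered
and baselined on −450…−250 ms (the 200 ms preceding placeholder onset,
which sits at −250 ms). Contralateral/ipsilateral waveforms average trials
then the three-channel hemisphere pool; the component window is the most
negative (N2pc) or positive (Pd) sample of the condition-averaged
difference wave within 100–400 ms, ± 40 ms (width exactly 80 ms). Peaks are
found on the native sample grid, window endpoints inclusive, ties broken to
the earliest sample, boundary peaks warned about. N2pc window selection
pools target- and distractor-tuned waves over all cells; the Pd uses
distractor-tuned waves only.

## Statistics

`rm_anova` handles any fully-crossed within-subject design via the balanced
complete-layout decomposition (inclusion–exclusion over marginal means)
with subject as the random factor; each effect is tested against its
subject interaction. Greenhouse–Geisser ε comes from the covariance of the
orthonormalized effect contrasts (Kronecker products across factors),
clipped to [1/df, 1]; partial η² = SS_effect/(SS_effect+SS_error). A
zero-SS effect reports F = 0, p = 1. The implementation matches pingouin's
two-factor results to print precision and reduces to F = t² for one
two-level factor.

Cluster tests form clusters from samples exceeding the two-sided parametric
t threshold at p < .05 (df = n−1), with 4-neighborhood connectivity in
time×frequency; cluster mass is the summed t. The null is the maximal
absolute cluster mass over sign-flips of the subject-level deviations
(paired contrasts are reduced to one-sample difference scores first, which
is exactly the sign-flip exchangeability condition), with the observed
statistic included (+1), so p ≥ 1/(n_perm+1). Cluster masses match MNE's
implementation exactly on shared fixtures; empirical FWER on i.i.d. null
data is 0.04–0.06 at 500 datasets.

## Problem sizes in tests and calibration

The calibration studies use 300-epoch decoding null sets averaged over 20
repetitions, 24 simulated subjects × 100 replications for RT recovery, and
500 null datasets × 1024 permutations for the FWER study; EEG-based tests
use 1–3 blocks per condition at 128–512 Hz. These sizes give Monte-Carlo
standard errors comfortably below the tolerances being checked while
keeping the full suite fast.

## Known limitations

* Channel interpolation is inverse-distance weighting, not spherical
  splines; fine for smooth topographies, it underestimates sharply dipolar
  ones.
* The ocular correction is a single-channel regression, not a component
  decomposition; it removes only activity linearly predictable from VEOG.
* The adaptive EMG cutoff is a deterministic surrogate for a
  visual-inspection step; its flag rate on real data would need re-checking.
* The generator's noise is spatially white across channels; real EEG's
  strong channel correlations would lower decoding SNR and alter shrinkage
  behavior.
* `rm_anova` requires complete balanced data (no missing cells).
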