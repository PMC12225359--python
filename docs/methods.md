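# Methods

## Model

Each RR interval x_k (ms) is mapped to a state in S = {A, N}: N when
lower ≤ x_k ≤ upper for a closed reference band α = [lower, upper], A
otherwise. Both bounds are inclusive and comparison happens at full
float precision; A covers deviation on *either* side of the band (the
model does not distinguish tachycardic from bradycardic excursions).
Two presets are built in: [800, 1000] ms (arachnophobia cohort) and
[900, 1100] ms (blood-pressure cohorts), both centred near the typical
resting RR interval of ~900 ms. The label sequence X_0, X_1, … is
treated as a realization of a first-order, two-state Markov chain.

A window of W consecutive intervals (default W = 10, i.e. roughly
6–12 s of recording at resting heart rates) slides along the sequence
with step s (default 1, maximally overlapping). Within each window the
transition matrix is estimated by maximum likelihood from adjacent-pair
counts: P_ij = n_ij / (n_iA + n_iN). Defined rows are exactly
row-stochastic; a row with zero outgoing transitions inside a window is
*undefined* for that window and is excluded from downstream pooling
rather than imputed as 0 or 0.5 — imputation would both break the
conservation identity and bias pooled means.

Window-level probabilities from all records of a group are pooled into
one sample per transition type. The pooled samples of a row pair
(P_AA/P_AN, and P_NA/P_NN) are pointwise complements defined on exactly
the same windows, so every group report necessarily satisfies
mean(P_iA) + mean(P_iN) = 1, sd(P_iA) = sd(P_iN), and a shared p-value
per row pair. This is a structural identity of the method, useful as a
self-check on any report the package emits.

## Group comparison

Two groups are compared per transition with a two-sided Mann–Whitney U
rank-sum test; reported summaries are the arithmetic mean and the
sample SD (denominator n − 1). Pooled samples are dominated by exact 0s
and 1s (a 10-beat window rarely contains many transitions), so tie
handling is explicit:

* **Exact mode** — the full null distribution is enumerated over all
  C(n_x + n_y, n_x) assignments of the pooled midranks, counting
  assignments whose U deviates from the null mean n_x·n_y/2 at least as
  much as the observed U. This remains valid under ties. Auto mode
  selects it when min(n_x, n_y) ≤ 8 *and* the enumeration stays below
  200,000 assignments; the cap exists because a tiny sample against a
  large pooled group would otherwise make C(n, min) astronomically
  large. `mode="exact"` forces enumeration regardless.
* **Normal approximation** — z = (|U − μ| − ½) / σ with the standard
  tie-corrected variance σ² = n_x·n_y/12 · [(n+1) − Σ(t³ − t)/(n(n−1))]
  over tie-group sizes t, and a continuity correction of ½. If every
  pooled value is identical, σ = 0 and p = 1. The approximation was
  verified to agree bitwise with scipy's asymptotic implementation.

No multiple-testing correction is applied across the four transitions:
the four rows are two complementary pairs, so only two distinct
p-values exist per report, and they are presented raw.

### Known limitation: overlapping windows and p-value calibration

With the default step of 1, adjacent windows share W − 2 of their W − 1
pairs, so pooled window-level samples are strongly autocorrelated. The
rank test treats them as independent — deliberately, because the
procedure being implemented is defined that way. The practical
consequence, measured by simulation in this package (see
`tests/test_acceptance.py` and `scripts/acceptance.py`): under the null
(both groups drawn from the same chain, 5 records × 300 intervals per
group) p(A→A) exceeds 0.01 in only ~60–65% of replicates instead of the
≥ 99% a calibrated test would give. The identical machinery with
non-overlapping windows (step = W) is well calibrated (~99.5%), which
isolates the overlap as the cause. Absolute p-values from overlapping
windows should therefore be read as ranking/ordering evidence, not as
calibrated error rates; power to detect a true difference of 0.2 in
P_AA at these sample sizes is effectively 100%.

## Synthetic generators

The generators define the study conditions under which the pipeline is
validated; all are parameterized by a seed and bit-reproducible.

* **Hidden two-state chain** (`simulate_markov_rr`). The chain starts
  from the stationary distribution of the true matrix (forceable for
  degenerate cases such as an identity matrix). State N emits uniformly
  inside the band; state A emits uniformly in a 200 ms strip above the
  band by default (below, or mixed 50/50, configurable). Optional
  Gaussian jitter is added and clipped to the correct side of the band
  edge, so classification provably recovers the hidden states — the
  property every recovery test relies on. Default validation truth is
  P_AA = 0.8, P_NN = 0.7 with 300-interval records, five records per
  group — short resting recordings at realistic scale; large-n checks
  use 100,000 intervals.
* **RSA-like series** (`simulate_rsa_rr`). RR_k = mean + amplitude ·
  sin(2πf·t_k) + Gaussian noise, with t_k the cumulative elapsed time
  (so the modulation is sampled where beats actually fall). Defaults:
  mean 900 ms, amplitude 80 ms, f = 0.25 Hz (15 breaths/min), noise SD
  10 ms — a resting adult with pronounced RSA. The config requires
  mean > amplitude + 3·noise so emissions stay positive; anything lower
  is clipped at 1 ms. This is a fixture generator, not an
  integral-pulse-frequency-modulation cardiac model: it reproduces the
  sinusoidal shape of respiratory modulation, not baroreflex dynamics,
  ectopy, or measurement artefacts.
* **EKG pulse train** (`simulate_ekg_pulsetrain`). Unit triangular
  pulses (default width 80 ms) centred at cumulative beat times rounded
  to the nearest sample, plus optional Gaussian noise; the planted peak
  indices are returned as ground truth. Rendering fails loudly if the
  sampling rate cannot separate the closest pair of peaks by at least
  two samples.

What passing tests on these generators does *not* show: robustness to
real-EKG morphology (P/T waves, baseline wander beyond a slow trend,
ectopic beats, electrode noise) or to annotation conventions of human
scorers. The peak detector is an automatic stand-in for careful manual
annotation and is validated only for exact recovery on clean pulse
trains and for its refractory/threshold contracts.

## Peak detection

Moving-average detrend (centred, ~1 s) → squared central-difference
derivative, reflect-padded so a peak on the very first or last sample
is not penalized → ~80 ms smoothing (mirrored at the edges for the same
reason) → adaptive threshold = factor × rolling 2 s maximum of the
emphasis (default factor 0.5) → each supra-threshold region, expanded
by the smoothing support, is refined to the local maximum of the
detrended trace → refractory enforcement (default 250 ms) keeping the
larger-amplitude peak, the earlier one on ties. A flat signal produces
no peaks because the threshold comparison is strict.

## Numerical and interface choices

* RR files: one millisecond value per line; blank lines and `#`
  comments ignored; commas tolerated. No unit auto-detection — values
  below 10 ms trigger a loud warning instead of a silent rescale.
* Peak indices are 0-based sample offsets; RR derivation is
  (index difference) / rate × 1000 ms.
* Window count follows floor((L − W)/s) + 1 for L ≥ W, else zero with a
  warning rather than an error (an over-short record is valid input).
* Undefined probabilities serialize as empty CSV cells, never 0.
* Conservation of defined rows holds to 1e-12 (in practice exactly, as
  counts are small integers).
* Config precedence: CLI flags > YAML config file > cohort preset;
  unknown config keys fail loudly. Every run logs band, window, step
  and any seed, sufficient to reproduce its output.

## Validation problem sizes

Randomized-window property checks use ≥ 1000 windows; estimator-vs-
oracle checks use 1000 windows of lengths 2–50; exact-test checks
enumerate every split with n_x + n_y ≤ 12; parameter recovery uses one
100,000-interval series against a different-seed Monte-Carlo oracle;
calibration and power use 200 replicates of 5 records × 300 intervals
per group. These sizes make the stochastic checks stable across seeds
while keeping a full validation run in the tens of seconds.
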