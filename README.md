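# rrmarkov

Markov-chain analysis of RR-interval (heart rate variability) series.

Respiratory sinus arrhythmia and related heart-rate dynamics can be
summarized by a simple discrete-time, two-state Markov chain: each
inter-beat (RR) interval is labelled **N** (normal) when its duration
falls inside a closed reference band α = [lower, upper] in milliseconds,
and **A** (arrhythmic) otherwise. Over the state space S = {A, N} the
chain is described by a row-stochastic transition matrix

```
        P = | P_AA  P_AN |        P_AA + P_AN = 1
            | P_NA  P_NN |        P_NA + P_NN = 1
```

whose entries are estimated per *moving window* of W consecutive RR
intervals (default W = 10, advancing one interval at a time) by counting
adjacent ordered pairs: `P_ij = n_ij / (n_iA + n_iN)`. A row with no
outgoing transitions in a window is *undefined* for that window, never
imputed. Window-level probabilities from all subjects of a group are
pooled into one sample per transition type; two groups (e.g.
hypertensive vs normotensive, or spider-fearful individuals with vs
without coping techniques) are compared per transition with a two-sided
Mann–Whitney U rank-sum test (exact enumeration for small samples;
tie-corrected, continuity-corrected normal approximation otherwise).

The package is aimed at researchers analyzing HRV recordings stored as
plain-text IBI/RR files, and includes an automatic R-peak detector for
raw single-channel EKG traces plus fully seeded synthetic generators
(hidden two-state chain, sinusoidal RSA-like modulation, EKG pulse
trains) so the entire pipeline is testable with known ground truth.

## Worked example

Simulate two groups of five 300-beat records from known chains — an
"arrhythmia-prone" group (true P_AA = 0.7, P_NN = 0.6) and a "stable"
group (P_AA = 0.45, P_NN = 0.8) — with the [900, 1100] ms band, then
compare them:

```sh
for s in 1 2 3 4 5; do
  rrmarkov simulate markov --p-aa 0.7 --p-nn 0.6 --alpha-low 900 \
      --alpha-high 1100 --n 300 --seed $s --out groupA/rec$s.txt
done
for s in 6 7 8 9 10; do
  rrmarkov simulate markov --p-aa 0.45 --p-nn 0.8 --alpha-low 900 \
      --alpha-high 1100 --n 300 --seed $s --out groupB/rec$s.txt
done
rrmarkov compare --group-a groupA --group-b groupB \
    --cohort blood_pressure --window 10 --step 1 --out report.csv
```

`report.csv` (columns abridged):

```
transition  p_value     mean_a  mean_b  sd_a    sd_b    n_a   n_b
A to N      7.25e-108   0.366   0.612   0.241   0.297   1454  1313
A to A      7.25e-108   0.634   0.388   0.241   0.297   1454  1313
N to A      8.05e-147   0.482   0.241   0.275   0.179   1396  1455
N to N      8.05e-147   0.518   0.759   0.275   0.179   1396  1455
```

Reading the table: group A stays arrhythmic (mean P_AA ≈ 0.63) far more
often than group B (≈ 0.39), and group B holds the normal state (mean
P_NN ≈ 0.76 vs 0.52); `n` counts pooled windows in which the row was
defined. Row pairs are pointwise complements, so means sum to 1, SDs
coincide, and each pair shares one p-value — the same structure a group
report of this kind always shows. The p-values treat overlapping-window
samples as independent and are therefore optimistic in absolute terms
(see `docs/methods.md`); the group ordering and effect sizes are the
interpretable output.

A single record can be inspected window by window:

```sh
rrmarkov analyze --rr groupA/rec1.txt --cohort blood_pressure --out windows.csv
```

which writes per-window probabilities (`start_index, p_aa, p_an, p_na,
p_nn`, undefined rows as empty cells) and a JSON summary — for this
record: 300 intervals read, 291 windows, A row defined in 290 of them.
`rrmarkov peaks` and `rrmarkov analyze --ekg trace.txt --fs 100` run the
same analysis from a raw plain-text EKG trace via automatic R-peak
detection.

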