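# timefactor

Latent-factor decomposition of trial-to-trial timing variability in
repeated action sequences.

## The problem

When an animal repeats a stereotyped motor sequence — the motivating case
is adult zebra finch song, a fixed string of syllables and silent gaps —
each rendition reproduces the same K interval durations with
millisecond-scale deviations.  Those deviations are not interchangeable
noise: part of the trial's deviation is a shared **tempo** change that
stretches or compresses the whole sequence, part is **boundary jitter**
that lengthens one interval exactly as much as it shortens its neighbour,
and part is **independent noise** confined to single intervals.  These
three sources have different biological interpretations and different
covariance signatures (tempo: positive covariance everywhere; jitter:
negative covariance between adjacent intervals; independent: diagonal
only), so they can be separated from an N × K table of interval durations
alone.

`timefactor` is for researchers with such a table (trials × intervals, in
msec) who want the decomposition, trial-by-trial estimates of the latent
timing variables, and an honest account of how reliable those estimates
are.

## The model

For rendition *n*,

    y_n = mu + z_n W' + x_n T' + e_n,

where `z_n` holds M unit-variance global factors with weight matrix `W`
(msec per unit latent), `x_n ~ N(0, diag(psi_x))` is jitter at the K−1
internal boundaries, `T` is the ±1 differencing matrix mapping boundary
shifts to interval-length changes (column sums zero: jitter conserves
total length), and `e_n ~ N(0, diag(psi_e))` is independent noise.  The
implied covariance

    S = W W' + T diag(psi_x) T' + diag(psi_e)

is fitted to the sample covariance by maximum likelihood via a constrained
EM algorithm (a confirmatory factor analysis: `T` and the unit latent
variance are fixed, `W`, `psi_x`, `psi_e` are free), with a 100-restart,
two-stage convergence protocol.  The number of global factors is chosen by
BIC; for M > 1 the weights are rotated so factor 1 is the tempo
(sequence-length) axis and the remaining, length-neutral factors are
ordered by residual variance.  Goodness of fit is scored by SRMR, and a
Monte Carlo harness quantifies parameter and latent recovery under known
truths, including skewed (Weibull / exponential) latent distributions.
See `docs/methods.md` for the full treatment.

## Worked example

Generate a song-scale synthetic dataset (K=11 alternating syllables and
gaps, N=600 renditions), fit, and diagnose:

```sh
timefactor fixture --preset zf_song --seed 7 --n 600 \
    --out-model truth.json --out-data song.csv
# wrote truth.json and song.csv (N=600, K=11)

timefactor fit --data song.csv --m 1 --restarts 20 --keep 5 --seed 3 \
    --out fit.json --latents-out latents.csv
# loglik -13098.513, SRMR 0.0231 -> fit.json
```

The fitted tempo weights track the generating ones (msec per unit tempo
deviation; truth in parentheses): 1.08 (1.10), 0.70 (0.75), 1.40 (1.30),
0.78 (0.85), 0.86 (0.90), 0.74 (0.70), 1.32 (1.40), 0.84 (0.80), 0.89
(1.05), 1.07 (1.00), 1.08 (1.10).  `latents.csv` holds one row per
rendition with the posterior tempo (`z1`), boundary-jitter (`x1..x10`,
msec) and residual (`e1..e11`, msec) estimates, ready to join against
time-of-day or recording-day metadata.

```sh
timefactor diagnose --data song.csv --model fit.json \
    --out diag.json --summary-out summary.csv
# SRMR 0.0231 -> diag.json
```

`diag.json` reports, among other things:

* `sequence_length`: `{global_var: 115.8, independent_var: 15.1,
  global_fraction: 0.884}` — tempo accounts for 88% of motif-length
  variance even though its per-interval weights (~1 msec) are comparable
  to the independent SDs, because a shared factor is amplified ~K-fold at
  the sequence level (jitter contributes nothing to sequence length).
* tempo elasticity (weight / mean duration, a partial CV) by interval
  type: gaps median 0.017 vs syllables 0.0095 — gaps stretch about twice
  as much as syllables per unit tempo change (Wilcoxon rank-sum p = 0.02
  on this single synthetic song).
* An SRMR of 0.023, far below the 0.05 "excellent fit" rule of thumb, as
  expected when the generating model is in the fitted class.

Library use mirrors the CLI: `timefactor.fit(dataset, n_global, config)`,
`timefactor.select_global_dimension(...)`,
`timefactor.recovery_experiment(...)`, etc.

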