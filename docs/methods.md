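# Methods

This note documents the models, estimators and numerical conventions behind
`rqaboot`, the choices that were genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Model and procedure

The package treats a scalar observable U_i sampled at a fixed interval dt as
a projection of an underlying dynamical system. The analysis assumes the
system has a *baseline* recurrence structure over the observation period;
statistically significant departures of windowed recurrence measures from
that baseline are reported as transitions in the dynamics. The method makes
no assumption of linearity or stationarity inside a window beyond what the
delay embedding itself requires, but it does assume windows are long enough
that their line-length distributions are statistically meaningful — short
windows are the method's main practical limitation.

Pipeline order: embedding parameter selection (once, on the full series) →
sliding-window normalization and embedding → per-window adaptive
thresholding → line-length extraction → pooling → bootstrap band →
transition flagging.

## Embedding (delay d, dimension m)

- **Auto-mutual information.** I(τ) is estimated with an equal-width
  histogram over the full series range (default 16 bins, shared edges for
  all lags), in bits. The delay is the first local minimum: the smallest
  τ ≥ 1 with I(τ) < I(τ−1) and I(τ) ≤ I(τ+1); a plateau counts at its first
  lag. If no interior minimum exists, the largest lag is returned flagged
  unconverged. Known estimator limitation: for a *noiseless* periodic signal
  the binned joint distribution has deterministic non-monotonic wiggles that
  can create a local minimum well before the quarter period; with even mild
  observation noise (σ ≳ 0.05 of the amplitude) the first minimum lands
  where theory expects it. Real observables are noisy, so this rarely
  matters in practice, but it is why the estimator is validated against a
  brute-force oracle rather than against the quarter-period rule alone.
- **False nearest neighbors.** For each candidate m the nearest neighbor of
  every embedded point (maximum norm, KD-tree) is lifted to m+1; it is false
  if the extra-coordinate separation exceeds rtol (default 10) times the
  m-dimensional distance or the lifted distance exceeds atol (default 2)
  standard deviations of the series. The chosen m is the first with FNN
  fraction ≤ 0.01. The defaults are standard toolbox conventions; all three
  are configurable. i.i.d. noise never converges and is flagged as such.
- **Global-then-window policy.** m and d are estimated once on the whole
  series and reused for every window, keeping windows comparable; per-window
  re-estimation would confound the transition statistics with estimator
  variance.

## Windowed RQA

- Defaults mirror the standard protocol for a 10 ps-sampled RMSD trace:
  window 1000 samples, step 100, target RR 5% (1% as a sensitivity check),
  l_min = v_min = 2, maximum norm. A 1000-sample window at m = 6, d = 24
  embeds to 880 states.
- **Normalization.** Each window is z-scored before embedding, so ε is
  chosen on normalized data and windows with different local amplitude are
  comparable. Constant windows raise an error naming the window.
- **Adaptive threshold.** ε is the k-th order statistic of the unmasked
  pairwise distances with k = round(target · n_unmasked / 2) per triangle
  (cells recur in symmetric pairs). For generic data the achieved RR — always
  reported next to ε — is within one cell of the target. Delay-embedded
  states can tie exactly under the maximum norm (shifted pairs share m−1
  coordinate differences), in which case the count moves in tie-block steps
  and the implementation lands on the side of the block closest to the
  target: the achieved RR is the closest achievable value.
- **Theiler window.** Default half-width 1: the line of identity is excluded
  from RR, the line counts and ε selection, because a trivially recurrent
  main diagonal inflates DET. Setting 0 reproduces the literal definition
  including the LOI. The same unmasked region is used consistently for RR
  and both distributions, so Σ l·counts(l) conserves the recurrence-point
  count of that region (per triangle for diagonals).
- **Distributions.** Length-1 structures are kept in all distributions —
  the DET/LAM denominators run from l = 1, so singletons are needed both for
  the measures and for the bootstrap to be well defined. Zero-recurrence
  matrices yield RR = DET = LAM = 0 with a warning rather than NaN.
- **Fixed-ε mode.** Supported for comparison, with the caveat that the
  per-window structure count then fluctuates (it is logged): the bootstrap
  band assumes a constant per-window statistical sample, which is exactly
  what the adaptive-RR mode provides.

## Bootstrap band and flagging

- The per-window distributions are pooled by summation. Each of the
  n_boot = 1000 replicates draws round(mean structures per window)
  individual line lengths with replacement, with probability proportional to
  pooled counts, and evaluates Σ_{l≥l_min} l / Σ l on the drawn multiset.
- Quantiles are type-1 (inverse empirical CDF), deterministic; the band is
  the central pair at (1−α)/2 and 1−(1−α)/2 with α = 0.95. A central band
  was chosen over a one-sided 5/95 pair because both directions of departure
  are interpreted; both levels are configurable. By construction the band
  contains a fraction α of the replicates up to quantile discreteness
  (≤ 2/n_boot).
- Windows are flagged by strict inequality (value > upper or < lower);
  maximal consecutive runs are reported as [first, last] window start time.
  DET and LAM are banded and reported independently. Window values are *not*
  bootstrap replicates — overlapping windows are strongly correlated — so
  the expected flag rate on stationary data is not 1−α; empirically it
  averages ≈ 0.19 on stationary AR(1) controls with per-run fluctuation
  from 0.06 to 0.45. The method is a heuristic detector, not a calibrated
  hypothesis test, and no multiplicity correction across windows is applied.
- All resampling uses a seeded generator; the seed is mandatory in the API
  and recorded in every report, making runs byte-reproducible.

## Synthetic benchmark

The frozen two-regime benchmark concatenates 6000 samples of a noisy sine
(period 50 samples, amplitude 1, noise σ = 0.05 — high-DET regime) and 6000
samples of stationary AR(1) noise (φ = 0.3, σ = 1 — low-DET regime), change
point at sample 6000. It is analysed with window 500, step 50, RR 5%,
500 bootstrap replicates and a frozen embedding m = 3, d = 12 (delay ≈ a
quarter of the oscillation period; auto-selection is deliberately not used
here because FNN need not converge on a mixed periodic/noise series, and a
frozen embedding keeps benchmark runs comparable). Across 20 seeded runs the
flagged regions cover the change point's neighborhood in every run.

What the benchmark emulates: two regimes with strongly different recurrence
character and an abrupt switch. What it does not: the slow drifts,
multi-scale correlations and regime *gradations* of real protein dynamics,
observation noise correlated with the signal, or thermostat artifacts.
Passing the benchmark shows the machinery detects a clear recurrence change
at realistic window statistics; it does not certify sensitivity to subtle
conformational transitions, whose detectability depends on window length and
on how strongly the transition alters the line-length distributions.

## Numerical and problem-size choices

- Distance matrices are computed exactly (no neighbor truncation); windows
  of ~500–1000 samples give 400–900 states, well within memory for dense
  N×N matrices.
- Line counting concatenates all diagonals (per triangle) or columns with
  separators and run-length encodes once; verified exactly against naive
  double-loop oracles up to N = 100.
- Test and acceptance runs use the benchmark sizes above (12,000 samples,
  231 windows, 500–1000 bootstrap replicates), sized so a full suite run
  completes in a couple of minutes on one CPU while keeping ≥ 400 states per
  window, the regime where the order-statistic discreteness (~1/n²) is
  negligible.
- RMSD extraction superposes each model onto the reference by the standard
  SVD (Kabsch) least-squares rotation via Biopython's `Superimposer`; only
  multi-model PDB input with consistent Cα ordering is supported.

## Known limitations

- The bootstrap treats pooled structures as exchangeable; heavy serial
  correlation between windows (large overlap) makes the band anti-
  conservative for flag-rate interpretation, as noted above.
- The band is only as meaningful as the pooled baseline: if most of the
  series is "in transition", the baseline itself is a mixture.
- The histogram AMI estimator's noiseless-periodic artifact (above).
- The constant-ε mode is provided for completeness but is statistically
  inferior to the adaptive-RR mode for this bootstrap, and says so in its
  log output.
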