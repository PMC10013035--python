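# Methods

This note documents the models implemented in `physiocausal`, the parameter
choices that matter, the numerical conventions, and what the synthetic
benchmarks do and do not establish about real recordings.

## Granger causality

The detector fits nested lagged least-squares models with **no intercept**:
inputs are assumed standardized to zero mean (the network pipeline
standardizes every patch; the benchmark generators produce zero-mean
signals), and the model equations carry no constant term. Both members of a
nested pair are fitted on the identical observation rows t = p..n−1, so
their residual sums of squares are directly comparable and the effective
sample size is `n_obs = n − p` for every model regardless of how many
regressor blocks enter.

Residual STDs use the `σ = sqrt(RSS / n_obs)` normalization, not
`1/(n_obs − k)`. With this convention the nesting property holds exactly —
the unrestricted RSS can never exceed the restricted RSS on the same rows —
so `G = ln(σ_r/σ_u) ≥ 0` always. The price is a small positive bias under
the null, `E[G] ≈ p/(2 n_obs)`, which matters when averaging G-values over
many patches (see *Surrogate baselines* below).

The F-statistic is `((RSS_r − RSS_u)/p) / (RSS_u/(n_obs − k_u))` with p
numerator degrees of freedom and `k_u` the unrestricted parameter count (2p
pairwise, 3p with one conditioning signal). The chi-squared variant uses
`p·F` with p degrees of freedom and is slightly anticonservative at small
n; the F-test is the default. Lag-0 (instantaneous) terms are never
included and not configurable: physiological sampling rates exceed the
delay of the couplings of interest, so instantaneous causality is excluded
by design.

Degenerate inputs are handled explicitly: a numerically perfect
unrestricted fit (RSS_u ≤ 10⁻²⁰·RSS_r) reports G = +inf with p-value 0; a
constant target reports G = 0 with p-value 1; rank-deficient designs are
solved minimum-norm and flagged `collinear` rather than raised.

Default model order **p = 5** for the benchmark experiments: the built-in
system lags are 3 (two-node) and 2/4 (common-driver), so five past terms
cover every true dependency. A caveat discovered during calibration: with
1/f^0.5 noise (long memory), order-5 truncation leaves structure in the
residuals that the conditional test can mistake for a direct link once the
common-driver couplings are strong (majority conditional rejection from
q ≈ 0.26 on the diagonal at n = 2^15; at order 10, or with white noise, the
effect disappears). This is a genuine property of truncated AR modelling of
long-memory processes, not a defect of the implementation; the Region-3
regime simply begins at lower couplings than a white-noise intuition
suggests.

## BPRSA

Trigger events default to rising positions of the trigger signal
(`z_t > z_{t−1}`); any boolean criterion over the sample values can be
plugged in. Windows of width 2L are centred on each anchor, windows
crossing either boundary are discarded *before* averaging, and the curve is
the point-wise mean over the m surviving windows. Default half-width
**L = 15** (2L = 30 curve values), the window used throughout the
benchmark experiments. For 64-sample series the boundary discard consumes
most of the data, which is why no BPRSA test detects anything there.

Significance tests on the 2L curve values:

- **ks1** — one-sample Kolmogorov–Smirnov of the curve values,
  standardized by **their own sample mean and STD (ddof = 1)**, against
  N(0, 1). The naive null scale `s_x/√m` is badly miscalibrated here:
  trigger windows overlap heavily and the target is autocorrelated, so the
  curve values are far more dispersed than independent m-averages and share
  a common random offset — standardizing by `√m/s_x` rejects ~54% of true
  nulls at the 5% level. Self-standardization absorbs the common offset;
  the cost is Lilliefors-type conservatism (parameters estimated from the
  sample), measured at ~0% null rejection, which is precisely why ks1 ends
  up the weakest of the normality-based tests — it needs roughly twice the
  coupling strength of Anderson–Darling at fixed length.
- **ks2** — two-sample KS between the real curve values and a curve
  recomputed at m uniformly random trigger positions (one surrogate curve
  by default; pooling k surrogates is a parameter). With only 30-value
  samples on each side this test has almost no power and serves as the
  negative control of the comparison.
- **ad** — Anderson–Darling composite normality test. scipy exposes no
  p-value for this test, so the statistic and the D'Agostino–Stephens
  case-4 approximation (the formulas behind R's `nortest::ad.test`) are
  implemented directly; agreement with the R implementation is exact to
  ten digits on frozen samples.
- **sw** — Shapiro–Wilk via scipy.

ad and sw are location-scale invariant, so they are applied to the raw
curve values. Their null calibration on uncoupled 1/f^0.5 systems measures
at 0.05 ± 0.01 despite the mild dependence between neighbouring curve
values.

## Benchmark systems

`fourier_filtered_noise` builds 1/f^α noise by scaling white-noise spectral
amplitudes with f^(−α/2), zeroing the DC component, inverse-transforming
and standardizing to exactly zero mean and unit sample variance. The
ensemble-averaged periodogram slope reproduces −α within ±0.05 over 50
seeds. Default α = 0.5 everywhere.

The two-node system mixes `x_t = q·z_{t−lag} + (1−q)·o2_t` (lag 3 by
default, exposed as a parameter); the common-driver system couples a hidden
driver y into z at lag 2 and into x at lag 4, with no direct z→x term, so
any pairwise z→x detection is indirect by construction. Generators draw
each noise component from an independent child of the master seed
(`numpy` SeedSequence spawning), making every configuration bit-reproducible.
After applying lags, the leading max-lag samples are trimmed so returned
series share one grid at the requested length.

## Experiments

The **isoline study** estimates, per series length N, the smallest coupling
q at which a detector's mean p-value over 20 realizations drops below
0.05, on a 24-point log grid q ∈ [0.005, 0.95] with the crossing
interpolated linearly in log q. Mean-p aggregation is the default
(rejection-fraction ≥ 0.5 would be the alternative); confidence bands are
the 5th/95th percentiles over 100 bootstrap resamples of the realizations.
Per-(N, q, realization) seeds derive deterministically from the master
seed, so any cell can be recomputed in isolation. Measured behaviour at
these settings: Granger needs ~2–3× weaker coupling than ad/sw, ks1 ~2×
more than ad, ks2 detects essentially nothing, and the Granger critical
coupling falls roughly as N^−0.5 over N = 2^8..2^16 (fitted log–log slope
≈ −0.43 at one master seed).

The **region map** classifies each (q_yz, q_yx) cell of the common-driver
system by the majority outcome over 20 realizations of the pairwise and
conditional F-tests at level 0.05: neither rejects (Region 1), pairwise
only (Region 2 — the correct "indirect" answer), both (Region 3). On the
diagonal at N = 2^15 the Region-1→2 boundary sits near coupling product
0.012–0.02; Region 3 begins near q ≈ 0.26 (see the truncation caveat
above).

## Stationarity segmentation

ADF regression includes a constant but no trend term: patches are
standardized to zero mean, and a deterministic trend should cause rejection
rather than be absorbed. Significance level 0.05. A patch is accepted at
the first model order in {5, 4, 3} at which **all three** channels reject
the unit root; that order is reused as the AR order of the subsequent
G-fit, keeping the stationarity screen and the causality model in the same
framework. Failures split the patch in half — the left half receives the
extra sample of an odd split — and pieces shorter than six samples are
discarded (90 s at 15 s resolution). Six samples cannot in fact determine
an order-5 model; the floor is a data-sufficiency cut-off inherited from
the segmentation rule, and in practice the ADF test itself rejects patches
much shorter than ~50 samples, so accepted patches are comfortably longer
than the floor. Series too short or too degenerate for the test regression
count as non-stationary rather than raising.

## Synthetic sleeper and network pipeline

The sleeper fixture emulates the three 1 Hz node series of a
polysomnography-derived triple — heart rate H, breathing rate B, EEG alpha
amplitude E — as stage-labelled segments of 1/f^α noise coupled by the same
lagged mixing form as the two-node benchmark (not an AR recursion), with
piecewise-constant per-stage coupling strengths and per-stage mean/scale
shifts that make segment boundaries non-stationary. Defaults: 120 epochs
(1 h) per subject in the sequence LS×40, DS×20, REM×20, LS×40; α = 0.5 per
channel. What it does **not** emulate: realistic ECG/EEG waveforms,
within-stage drifts, artifacts, apnea events, or circadian structure —
passing pipeline tests therefore demonstrate correctness of the machinery
and recoverability of planted couplings at these noise levels, not
performance on clinical recordings.

The pipeline per subject and resolution: block-average the 1 Hz triple,
cut it into maximal same-stage runs (wake excluded), standardize each
patch, split into stationary sub-patches, and compute the conditional
G-value of all six ordered channel pairs per accepted sub-patch,
conditioning on the third channel. Patches shorter than 2p + 2 samples are
skipped with a log entry. Group edges average patch G-values weighted by
patch length; standard errors bootstrap the **unweighted** mean over
patches (100 resamples), exactly the printed procedure, with a
`weighted=True` flag for a consistent alternative. Edges with no surviving
patch are absent, not zero. No multiple-testing correction is applied
across the 6 edges × stages × resolutions — significance is judged against
surrogate networks instead.

**Surrogate baselines.** Pseudo-subject i keeps its own H channel and
hypnogram and takes B and E from the next subjects cyclically (a
derangement requiring ≥ 3 subjects), so no genuine coupling can survive;
channels are truncated to the shortest donor. On cohorts with a planted
coupling of strength 0.5 the planted edge's mean G (~0.34) exceeds every
surrogate edge (~0.002–0.007) by two orders of magnitude. Note, however,
that surrogate means are *not* statistically compatible with exactly zero:
G is non-negative with null bias ≈ p/(2 n_obs), so the mean over K patches
sits ~√(K·p/2) bootstrap SEs above zero no matter how long the patches
are. Surrogate networks are a baseline *level* to compare real edges
against, not a quantity that vanishes.

## Preprocessing conventions

Event-rate series assign each inter-event rate 1/Δt to the interval's
closing event time and interpolate linearly onto the integer-second grid
(zero-order hold available). EEG alpha amplitude band-passes 7.8–15.6 Hz
with a 4th-order zero-phase Butterworth filter, takes the analytic-signal
envelope (rectified mean × π/2 as the selectable alternative — both equal
the amplitude for an in-band sinusoid) and averages non-overlapping 1 s
windows; the first/last seconds carry filter edge effects. Coarse-graining
is non-overlapping block means with the trailing remainder dropped. All
indices are 0-based half-open; times are seconds.

## Known limitations

- Linear, fixed-coefficient AR models only: no spectral, wavelet or
  time-varying Granger variants, and no nonlinear couplings.
- Conditional analysis conditions on observed signals; unobserved common
  drivers remain undetectable in principle.
- Long-memory noise plus truncated AR orders can fake direct links at
  strong couplings (Region 3); raise the order when this regime matters.
- BPRSA offers no conditional variant, so it cannot separate direct from
  indirect links.
- The six-sample patch floor is far below what an order-5 fit can support;
  it is the segmentation rule's stopping condition, not a sufficiency
  guarantee.
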