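# Methods

This note documents the model, the numerical choices, and the synthetic
data on which the package is validated — including what passing tests do
and do not show about real recordings.

## Signal model

Heart period (ms, the interval between successive R peaks, assigned to the
*following* beat) is treated as the output of a small set of linear
time-invariant systems driven by brief autonomic inputs at stimulus
onsets. Each system's impulse response — a response function, RF — is a
single Gaussian `a·exp(−(t−μ)²/2σ²)` on a support of −5 to +30 s around
the event; the 5 s prestimulus interval absorbs apparent response onsets
before the stimulus that IBI interpolation can produce. Within the GLM
every RF enters as its unit-peak signed shape, so a coefficient reads
directly as the peak deflection in milliseconds along that component's
direction (decelerations positive, accelerations negative).

The LTI assumptions (identical response to identical input; superposition
of overlapping responses) are approximations: the physiological range of
heart period is bounded and the system saturates when responses crowd
together. The package therefore does not attempt to deconvolve heavily
overlapping responses; instead it warns (`OverlapWarning`) whenever an
RF's effective support (μ + 2σ) exceeds the minimum intertrial interval,
and ships `validation_basis()` — the canonical basis truncated to its
first four RFs — for short-ITI designs.

## Pipeline constants

| Stage | Constant | Value | Why |
|---|---|---|---|
| Antialias | Butterworth low-pass | order 2, 100 Hz | half the 200 Hz working rate |
| Working rate | ECG | 200 Hz | 5 ms beat-time resolution |
| QRS detector | band-pass | 5–15 Hz | QRS energy band |
| | moving-window integration | 150 ms | QRS complex width |
| | refractory period | 200 ms | physiological minimum |
| | search-back window | 360 ms | missed-beat recovery |
| IBI screening | outlier bound | mean ± 2 SD | record-wide, ddof = 1 |
| Heart period | sampling rate | 10 Hz | resolves the 0.01–2 Hz band |
| | band-pass | order 2, 0.01–2 Hz | drift removal, interpolation smoothing |
| Epochs | window | −2 to +29 s | covers the full response |
| Peak scoring | B / D1 / A / D2 | −1–0 / 0–2 / 2–5 / 5–8 s | classic protocol windows |
| Validity | decisive |ΔAIC| | 3 | evidence ratio exp(−3) ≈ 0.0498 |

All filters are applied zero-phase (forward–backward with
`scipy.signal.sosfiltfilt`). Zero-phase processing is chosen throughout
because the GLM basis encodes component *timing*: a causal filter's group
delay would systematically shift amplitude between neighbouring RFs. The
cost is that each filter's amplitude response is squared; tests that check
attenuation use the squared, bilinear-warped Butterworth magnitude.

GLM regressors are passed through the identical band-pass as the data
(default on): fitting filtered data with unfiltered regressors biases
amplitudes. Onsets are rasterized to the nearest heart-period sample
(±50 ms at 10 Hz). An intercept column is always included — the band-pass
removes DC, but finite-record leakage remains.

## Offline QRS detection

The detector keeps the classic Pan–Tompkins chain (band-pass,
differentiate, square, moving-window integrate, adaptive dual thresholds
with search-back) and adds three offline modifications: zero-phase
filtering, a second pass over the record with thresholds initialized from
the estimates the first pass converged to, and refinement of each
detection to the R-peak of the raw 200 Hz trace (which assumes a dominant
positive R spike, true of the synthetic template and of a well-chosen
lead). On simulated ECG (noise SD 10 % of the R amplitude) the detector
reaches 100 % sensitivity and PPV with ~1.4 ms median timing error; real
ECG with muscle artifact, baseline wander, or ectopy will do worse, which
is why the mean ± 2 SD IBI screen and the programmatic correction API
(`delete` / `interpolate`) sit behind it.

## Basis development

Epochs ([−2, +29] s, 311 samples at 10 Hz) are mean-centred per epoch; the
PCA is the SVD of that row-centred matrix (no column centring — the model
defines centring per epoch, which is why `numpy` SVD is used rather than
a column-centring PCA implementation). Component signs are fixed so the
largest-magnitude sample is positive. The scree decision is exposed as an
explicit `n_keep` parameter (default 3) with a largest-drop elbow rule
(`elbow_n_keep`) replacing visual inspection.

Every local extremum of a retained component above 10 % prominence (of
the waveform's maximum absolute value — a floor is needed for noisy
inputs) is fitted with a Gaussian on a neighbourhood bounded by adjacent
zero crossings and extrema; minima get negative amplitudes.

Candidate RFs are then selected stepwise. Step 1 fits each candidate
alone, per participant, and keeps it if its amplitude estimates show a
stable direction pooled across experiments (one-sample t test) or
separate the experiments (one-way between-subjects ANOVA), at α = 0.05.
The basis then grows chronologically: the next untested survivor — plus
any survivor whose μ ± 2σ interval overlaps it, since overlap is not
defined numerically anywhere else — competes to join; candidate sets are
orthogonalized in temporal order (sequential Gram–Schmidt, norms restored
by rescaling), refitted, and the added RF with the lowest ANOVA p-value
joins if significant. "Alone" fits legitimately absorb experiment-
dependent projections of the true signal, so step 1 is permissive by
construction; the growth phase is the real filter. Because growth runs
one test per remaining survivor, testing at α would admit a spurious
component in roughly `1−(1−α)^m` of runs; the growth threshold therefore
defaults to the Bonferroni share α / (number of candidates), keeping the
family-wise false-inclusion rate of the whole selection at α
(`growth_alpha=α` restores the uncorrected variant). Participant loadings
and estimates for multi-condition experiments are reduced by averaging
over conditions.

## Predictive validity

Each analysis parameter is judged by how well it alone predicts the
experimental condition across participants: a univariate logistic model
(intercept + one slope on the standardized parameter, k = 2) is fitted by
bounded maximum likelihood and summarized as AIC = −2 log L + 2k. Since k
is constant across parameters, ranking by AIC is ranking by likelihood.
Under perfect separation the standardized slope is capped at magnitude 10
and flagged so AIC stays finite and comparable. An uninformative
predictor costs exactly +2 against the intercept-only null. Three-class
designs are handled as pairwise two-class contrasts, mirroring how
planned linear contrasts are reported. Classic statistics (one-way ANOVA
with Tukey HSD post hocs between subjects; paired t tests within) are
provided without multiple-comparison correction, on the assumption that
contrasts are pre-specified.

## Synthetic data: what it does and does not emulate

The simulator is the forward version of the model the analysis inverts,
plus the dominant nuisance processes in minimal form:

* **Event-related signal** — planted amplitude × RF unit shape, placed on
  the same sampled grid as the design matrix, so noiseless simulations
  are exactly representable (noiseless GLM recovery ~1e−11 ms).
* **Respiratory sinus arrhythmia** — a single sinusoid, 30 ms at 0.25 Hz
  by default (random phase). Real RSA is broadband and
  breathing-coupled; a sinusoid is the minimal structure that exercises
  the band-pass and averaging.
* **Drift** — a 50 ms sinusoid at 0.005 Hz, below the 0.01 Hz high-pass
  corner, so its removal is demonstrable.
* **Noise** — white Gaussian, 5 ms SD by default. No published noise
  magnitudes exist for this decomposition; these defaults were chosen
  once for test discriminability, not fidelity.
* **Beats** — integral pulse frequency modulation: a beat fires when the
  running integral of the instantaneous rate (1000 / heart period)
  crosses successive integers, with a seeded initial phase. No ectopy.
* **ECG** — a fixed Gaussian-bump P-QRS-T template with unit R spike;
  single-lead, no morphology variability.

Four schedule designs mirror the study paradigms: long discrete ITIs of
{29, 34, 39} s (`exp1`, and `exp2_oddball` for the modelled oddball
events), {43, 45, 47} s with three picture conditions (`exp3`), and a
short-ITI validation design uniform on [4, 16] s with four conditions
(`exp4`). Stimulus duration is fixed at 1 s.

The packaged development study plants two true RFs (an early deceleration,
μ = 2 s, and a mid-latency acceleration, μ = 7 s) with
experiment-specific amplitudes (between-participant SD 10 ms) in three
simulated experiments of 10 participants × 15 events, alongside two
spurious late candidates with zero planted amplitude. Stepwise selection
recovers exactly the planted pair in ≥ 95 % of runs.

Passing these tests shows the implementation inverts its own forward
model correctly and that the statistical machinery behaves as designed.
It does not certify performance on real recordings, whose artifact
structure, RSA spectrum, and violation of linearity at short ITIs are all
richer than the simulation.

## Known limitations and numerical notes

* The end-to-end ECG route (IPFM beats → detection → interpolation)
  attenuates and redistributes amplitude between neighbouring RFs,
  because assigning each IBI to its following beat delays the observed
  response by a fraction of a beat. Condition *ordering* — the quantity
  the method is optimized for — is preserved; absolute amplitudes from
  full round trips are conservative. Fitting the simulated heart period
  directly recovers planted amplitudes to within a few percent (mean
  error < 2.5 % over 50 noisy runs at the default nuisance levels).
* `flag_outlier_ibis` uses a strict inequality, so a zero-variance record
  is never flagged; with Gaussian IBI jitter the 2 SD rule flags ~5 % of
  beats by construction — it is a screen, not a classifier.
* Gram–Schmidt raises on (numerically) dependent shapes (residual norm
  < 1e−12 of the input norm) naming the offending RF; orthogonalized
  pairwise inner products are below 1e−8 of the norm product, and GLM
  fitted values are invariant under orthogonalization (same column
  space).
* Problem sizes in the test-suite simulations (participants, events,
  seed counts) are chosen to make every statistical check decisive at
  desk scale; the acceptance script reports the size used alongside each
  number.
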