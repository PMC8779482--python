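# Methods

This note documents the models, parameter choices and numerical decisions
behind `tacitload`, and what the synthetic benchmark does and does not show
about real data.

## The measurement model

A session has three conditions in fixed order — resting state, picking,
coordination — so that the rest block yields a task-free baseline. The
rest block (60 s) is segmented into 60 one-second epochs; each of the 12
picking and 12 coordination games contributes one 1-s epoch aligned to game
onset. Per epoch and channel, band energies are the summed squared
coefficients of a 3-level discrete wavelet transform at 64 Hz, which maps
dyadically onto the classical EEG bands (δ 0–4, θ 4–8, α 8–16, β 16–32 Hz).
The theta/beta ratio `TBR = E_θ/E_β` is scale-invariant, so it is identical
whether computed from raw or relative (sum-normalised) band powers; both
are emitted for transparency. The ratio is computed per epoch and then
aggregated (ratio-then-aggregate), never the reverse; `0/0` epochs yield an
undefined sentinel that every aggregate drops with a logged count, and
`E_β = 0` with positive theta yields `+inf`, likewise excluded.

**Wavelet choice.** Daubechies-4 with periodised boundary handling: db4 is
the most common EEG band-power wavelet, and the periodised orthogonal
transform conserves energy exactly (Parseval), which the test suite asserts
to 1e−6 relative. Band assignment is validated against an independent FFT
band-power oracle for tones at 5/6/7 Hz (θ) and 18/22/28 Hz (β).

## Preprocessing chain

Fixed order, asserted in code: band-pass → notch → ICA → average reference
→ downsample → baseline-corrected epoching.

* **Band-pass 1–32 Hz**, zero-phase 4th-order Butterworth
  (forward–backward). The upper edge matches the highest DWT band at the
  64 Hz working rate; zero-phase filtering preserves epoch timing.
* **Notch** 50 Hz, second-order IIR, quality factor 30, zero-phase.
* **ICA blink removal**: FastICA (fixed-point negentropy maximisation,
  deflation, logcosh contrast). A component is removed when the absolute
  loading on Fp1+Fp2 exceeds 0.4 of its total loading *and* more than 0.6
  of its source power lies below 4 Hz — the stereotyped signature of
  blinks. The unmixing matrix is estimated on a 6× decimated copy of the
  filtered signal (alias-free, since the signal is band-limited to 32 Hz)
  and applied at full rate; this changes nothing statistically and keeps
  repeated pipeline runs cheap. On data whose background is largely
  Gaussian, some noise components never meet the fixed-point convergence
  tolerance; since reconstruction from all components is exact regardless,
  the iteration count and a convergence flag are reported in the
  `IcaReport` rather than aborting, and only a non-finite decomposition
  raises an error.
* **Average reference**: instantaneous across-channel mean subtraction.
* **Downsampling** to 64 Hz by polyphase anti-aliased resampling
  (`resample_poly`); event onsets are rounded to the nearest output sample.
* **Baseline correction** subtracts each epoch's own per-channel mean (no
  pre-stimulus interval exists in this design, so the epoch mean is the
  only available baseline).

Everything except ICA component flagging is linear, and the chain commutes
with scalar amplitude scaling — a property test.

## Behavioural metrics

`CI = Σ_l n_l(n_l−1)/(N(N−1))` is the collision probability of two distinct
players' choices. `iCA_i = Σ_g m_i(g)/(G(N−1))` counts agreements of player
i with each other player, normalised to [0, 1]. These are linked by an
exact identity: the population mean of per-game agreement rates equals that
game's CI, hence mean iCA = mean CI. The iCA normalisation adopted here is
the unique pairwise-match form with the documented [0, 1] range that scores
a player "against the entire population"; alternative historical variants
(e.g. counting only modal-label matches) exist, which is why the formula is
stated prominently. Printed CI values use round-half-even to three
decimals; all internal comparisons use full precision. Minimum-CI games are
reported as the hardest, with exact ties reported as a tie set. For N = 10
and four labels the attainable minimum is 16/90 at the (3,3,2,2) split,
verified by brute force over all compositions.

## Inference

* **ANOVA**: pooled one-way fixed-effects decomposition over per-epoch TBR
  values from the six frontal/prefrontal electrodes, F on (k−1, N−k) df.
  The pooled form is used because epoch-level pooling is the only reading
  consistent with condition-level df in the hundreds; the per-epoch
  observations within a trial are correlated across electrodes, so the
  reported df overstate independent information — the ANOVA is a
  descriptive screen here, with the planted-effect tests carrying the
  inferential weight in the synthetic setting. Degenerate inputs return
  sentinels rather than erroring: identical groups → F = 0, p = 1; zero
  within-variance with differing means → F = +inf, p = 0.
* **Tukey HSD** (Tukey–Kramer for unequal n) from the studentized-range
  distribution with pooled within-group MS; α = 0.05 throughout.
* **RANSAC** (line model): each of 2000 iterations fits the exact line
  through two random points and counts points within the residual
  threshold; the largest consensus set wins, ties resolved toward the
  earliest iteration, and a seeded generator makes runs reproducible. The
  default threshold is 2.5 × 1.4826 × MAD of the residuals of an initial
  all-points fit, i.e. ≈2.5σ under Gaussian noise. The 2.5σ scaling
  matters on small datasets: a ~1σ threshold classifies a third of
  *genuine* points as outliers and can excise exactly the extreme-x points
  that carry the slope information. A best consensus no larger than the
  minimal sample raises a degenerate-fit error.
* **Polynomial regression** (degree 1 or 2) by least squares on the
  (optionally masked) points, reporting intercept-first coefficients, R²,
  the regression F on (d, n−d−1) df, its p-value, unbiased residual
  variance and coefficient standard errors.
* **Response-time model**: the RT relationship is exposed generically —
  the pipeline fits RT on per-trial TBR (quadratic, plus a linear fit for
  the sign) but `fit_polynomial` accepts any pairing, since which variables
  carry the quadratic relationship is a modelling choice the user may
  revisit.

The regressions use channel F4 only (the electrode with the strongest load
effect in this literature); the condition-level summaries pool the six
frontal/prefrontal electrodes.

## Synthetic-data generator

The generator is the package's benchmark instrument, not a head model. Each
subject's recording is 1/f Gaussian noise (per-channel, RMS 4 µV over the
band) plus, in each 1-s event window, one shared theta and one shared beta
sinusoid (carriers jittered within 4.5–7.5 / 17–30 Hz, random phase, Tukey
taper) projected to the channels with a frontal-weighted gain (1.0 on the
six frontal electrodes, 0.45 elsewhere, ±10 % per-subject jitter).
Artifacts are injected separately: 50 Hz line noise (2 µV) on all channels
and ~12/min raised-cosine blinks (400 ms, 200 µV) with a frontal topography
peaking at Fp1/Fp2 — exactly the signature the ICA stage is built to
remove.

Condition-level oscillation amplitudes anchor the planted TBR medians:

| condition    | θ (µV) | β (µV) | planted TBR ≈ (θ/β)² |
|--------------|--------|--------|----------------------|
| rest         | 22.0   | 9.6    | 5.3                  |
| picking      | 20.0   | 10.0   | 4.0                  |
| coordination | 17.0   | 10.3   | 2.7                  |

Per-trial log-amplitude jitter (σ = 0.2 per band) gives a per-epoch
log-TBR spread of ≈ 0.57, i.e. an interquartile ratio around 2 — the same
order as empirical frontal TBR distributions.

A single latent **depth of reasoning** `d_i`, evenly spaced over [0, 1]
across subjects, drives both sides of the planted correlation structure:

* **Choices**: subject i picks from `softmax(s_i · w_g)` with sharpening
  `s_i = 5.0 · (0.15 + 0.85 d_i)` over per-game salience weights `w_g`.
  The baseline floor keeps even the shallowest player weakly responsive to
  salience (needed for unanimity in one-hot games); depth scales the rest,
  spreading iCA across the population widely enough that iCA tracks depth
  despite its 12-game sampling noise. The twelve default salience vectors
  range from near-uniform (no focal point, CI near chance) to strongly
  focal.
* **Load**: a dimensionless per-trial load
  `z = 0.4 (d_i − ½) + 0.5 (c̄ − c_g)` (coordination trials only), where
  `c_g` is the softmax collision probability of game g at average
  sharpening — a difficulty proxy. Theta is multiplied by `e^(−z)` and beta
  by `e^(+z)`, so planted log-TBR shifts by −4z: deeper reasoners and
  harder games yield lower TBR.
* **Response time**: `RT = base_cond + 0.8 z + ε`, ε ~ N(0, 0.3 s),
  truncated at 0.3 s, with bases 1.2 s (picking) and 2.2 s (coordination).

A subject-level log-TBR offset (σ = 0.15) not tied to depth adds realistic
between-subject variance. All randomness flows from one seed through named
substreams (`pink`, `trial`, `choice`, `order`, `blink`, `line`, `ica`,
`ransac`, …), so the recording events and the behavioural table carry
identical response times and any stage can be regenerated in isolation;
identical (config, seed) is bit-identical end to end.

**What passing tests show — and don't.** The benchmark demonstrates that
the pipeline recovers known structure: the condition ordering of median
TBR, the positive CI→TBR and negative iCA→TBR slopes and the negative
RT–TBR relationship are each recovered in ≥ 95 % of seeded replicates at
default effect sizes, and a null configuration (all couplings zero) leaves
the CI→TBR slope confidence interval covering zero. It does not show that
real EEG satisfies the generator's assumptions: real data have
volume-conducted broadband sources, non-stationary artifacts, heavier
channel correlation and unknown effect sizes. The generator also makes no
attempt to model the semantic content of word stimuli — labels are opaque
indices with numeric salience.

## Problem sizes and runtimes

Default sessions are 10 subjects × (60 rest + 12 + 12 game epochs) × 16
channels at 512 Hz (~132 s each). A full simulate→report run takes a few
seconds on one core; the replicate-based recovery tests use 50 seeded runs
at the default size, and the scaled-down Monte-Carlo checks in the module
tests use 2–4 subjects, chosen so the whole suite stays in the minutes
range.

## Known limitations

* The iCA definition is one defensible member of a family; see above.
* ANOVA df treat pooled epochs as independent (see Inference).
* ICA quality is validated only against the generator's blink model;
  muscle, cardiac and movement artifacts are out of scope.
* EDF export is not implemented (no writer dependency); EDF ingestion is
  available via the optional `mne` extra, text I/O is the primary format.
* No mixed-effects/random-intercept models and no channel interpolation,
  impedance handling or streaming filtering.
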