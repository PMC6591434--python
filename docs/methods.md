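# Methods

This note records the analysis model, the choices made where the
methodology was genuinely open, and what the synthetic data do and do
not establish.

## Input model and units

A recording is a per-animal, per-condition sequence of beat times
(seconds) or RR intervals (milliseconds); beat tables are differenced to
RR series (`rr[i] = 1000·(t[i+1] − t[i])`). Tables carry either a time
column or an interval column, never both — supplying both is ambiguous
and raises. An optional `epoch` label lets callers distinguish
sub-windows (e.g. 90-min pre/post drug periods) without committing the
loader to either convention.

## Segment selection

HRV metrics are only meaningful on stationary, artifact-light stretches,
so analysis operates on non-overlapping candidate windows scanned
left-to-right (non-overlap avoids pseudo-replication in the downstream
mixed model). A window qualifies when:

- **Stationarity.** An OLS line of RR against beat index must not show a
  trend that is both statistically significant (two-sided slope test,
  α = 0.05) and practically large (fitted drift across the window
  > 5% of mean RR). Requiring both avoids rejecting long windows for
  microscopic but "significant" slopes, and avoids accepting short noisy
  ramps.
- **Usable length.** At least `min_intervals` (default 2048, the
  spectral transform length) non-ectopic intervals.

**Ectopic rule.** An interval is ectopic when it deviates from the
window mean by more than 2 sample SD. Statistics are computed once on
the raw window — no iterative re-masking; the rule as stated is a single
pass, and iteration would make the flagged set depend on evaluation
order. A constant window (SD = 0 up to float rounding) flags nothing.
Note the rule's intrinsic behaviour on broadband-noise data: a Gaussian
series always has ≈ 4.5% of points beyond 2 SD, so "ectopic-free" test
data must use bounded noise (uniform noise peaks at ~1.73 SD).

**Cleaning modes.** `remove` drops flagged intervals (time-domain and
nonlinear metrics); `zero_replace` writes literal zeros at flagged
positions (spectral analysis, which needs a fixed-length beat grid).
Kept windows are truncated to exactly `min_intervals` usable intervals
(remove) or positions (zero_replace) from the window start, so every
segment has identical analysis length. At the default window size
(= `min_intervals`) a qualifying window must be ectopic-free; the
pipeline driver scans windows 10% longer so occasional ectopics — and
the 2-SD tail of Gaussian noise — can be absorbed and truncated away.

## Time-domain metrics

Mean RR, range (max − min), SDRR and CV = SDRR/mean on removal-cleaned
segments. Sample (n−1) variance is used everywhere in the package — the
convention is arbitrary at n = 2048 but a single convention is required
for the Poincaré identity (below) to hold at the stated tolerance.
Zero-replaced segments are rejected by these functions: embedded zeros
would corrupt every statistic.

## Spectral analysis

The spectrum is taken directly on the beat-indexed RR sequence
(tachogram) of exactly 2048 intervals:

1. mean over nonzero entries, T̄ (converted to seconds);
2. mean-centre the nonzero entries (zeros untouched) — without
   centring, the DC term dwarfs every band; the DC bin is reported but
   excluded from all bands and from total power;
3. FFT, length 2048, rectangular window by default (a Hann taper is
   available behind a flag but is not the reference configuration);
4. per-bin power |X_k|²/T̄, folded one-sided (interior bins doubled; DC
   and Nyquist not);
5. bin k labels frequency f = (k/2048)/T̄ Hz — cycles-per-beat divided
   by the mean beat period. This mapping is what makes 0–0.4 / 0.4–1.5 /
   1.5–5.0 Hz sensible band edges for a mouse: at T̄ ≈ 0.1 s the
   per-beat Nyquist (0.5 cycles/beat) lands at ≈ 5 Hz, the HF top edge.
6. band powers over half-open [low, high) Hz bins, the top band closed;
   total power sums every non-DC bin up to the top edge.

The divisor T̄ is taken in seconds; this fixes the absolute scale only
and cancels in all genotype/drug ratios. Zeroed ectopic positions enter
the FFT literally; linear interpolation across them is available
(`interpolate_ectopics=True`) and recovers band power better when
dropouts are isolated, but zeros are the default behaviour.

Numerical anchors: Parseval (Σ folded |X_k|² = N·Σx² for the centred
vector) holds to 1e-9 relative; a sinusoidal modulation at c cycles/beat
appears at bin c·2048 regardless of T̄, and doubling its amplitude
quadruples its band power.

## Nonlinear metrics

**Poincaré.** SD1 = √(var(d)/2) with d the successive differences,
SD2 = √(var(s)/2) with s the successive sums (sample variance). This is
the universal convention — SD1 the short-axis, beat-to-beat statistic;
the swapped assignment is available behind `literal_sums_for_sd1` for
compatibility with sources that word the formula the other way. The
identity SD1² + SD2² = 2·SDRR² is exact on circularly-closed series
under population variance and holds within 1% at n = 2048.

**Sample entropy.** SampEn(m, r) = −ln(A/B), B the count of ordered
pairs of distinct m-length templates within Chebyshev distance r, A the
same at length m+1; both counts run over the same N−m template start
positions so A ≤ B always. Defaults m = 2, r = 0.2× the segment's
sample SD, recomputed per segment, which makes the statistic invariant
under affine transforms of the series. A constant series yields r = 0
yet all templates still match at distance 0, so A = B and E1 = 0; when
either count is zero the value is flagged undefined rather than ±∞. The
implementation builds the pairwise distance matrix incrementally
(O(n²) memory, ~34 MB at n = 2048) and is verified bit-exactly against
an exhaustive pair-enumeration oracle.

**Multiscale E1.** Coarse-grain by non-overlapping means of length
`scale`, then SampEn with r held fixed at its scale-1 value (0.2× the
*original* series SD). Holding r fixed is the standard multiscale
convention and is what gives white noise its signature declining curve;
recomputing r per scale would flatten it. Scale 1 is bit-identical to
plain SampEn. "E1" is the scale-1 value of this curve.

## Genotype × drug statistics

Tidy metric rows (one per segment × metric) are modelled per metric as

    value ~ genotype + drug + genotype:drug,   random intercept ~ animal

by REML. The random-intercept-only structure is the minimal one
supporting repeated pre/post measures per animal; each drug session is
analyzed against its own same-day baseline, and every animal must have
both rows (unpaired animals raise, listing the offenders). Fitting
delegates to statsmodels `MixedLM`; everything test-related is built on
top of the fitted variance components (σ²_animal, σ²_resid):

- effects are cell-mean contrasts on the treatment-coded coefficients:
  genotype and drug main effects at the average over the other factor
  (LS-mean style), interaction = difference of within-animal drug
  responses between genotypes; each has one numerator df, so F = t²;
- denominator df use the Satterthwaite approximation
  df = 2·f²/(∇f′ A ∇f), where f(θ) = Var(c′β̂) from the GLS covariance,
  ∇f is a central finite difference in θ = (σ²_animal, σ²_resid), and A
  is the inverse observed REML information (numerical Hessian of the
  REML log-likelihood). df is clamped to [1, n−p]; degenerate geometry
  (boundary variances, non-PD information) falls back to the residual
  df. In the balanced 6 + 6 pre/post design this reproduces the exact
  paired-t reference (p-values agree to ~1e-5).
- flags: ‡ genotype main effect p < 0.05, T drug main effect p < 0.05,
  * a pairwise LS-mean difference p < 0.05 when the interaction is also
  significant.

Zero-residual (exactly identified) inputs skip the mixed fit — the
variance components are not estimable — and use OLS with a variance
floor, recovering the generating constants exactly. A singular mixed fit
falls back to paired-difference t tests and is flagged `fallback=True`.
Metrics are analyzed independently with no multiplicity correction,
matching per-metric reporting practice in this design. Per-hour average
heart rate uses a one-way genotype ANOVA per bin.

## Synthetic generator

The generator is additive in the beat domain:

    rr_i = mean_rr + lf_amp·sin(2π·lf_freq·i) + hf_amp·sin(2π·hf_freq·i + φ)
           + trend_slope·i + ε_i,    ε_i ~ N(0, noise_sd²),

then each beat independently becomes `ectopic_scale·rr_i` with
probability `ectopic_rate`. The additive-sinusoid form was chosen over
integral-pulse-frequency-modulation because it has closed-form targets —
E[SDRR] = √(lf² /2 + hf²/2 + noise²) and exact band locations — that the
test suite verifies directly; IPFM is a possible extension. Randomness
is `numpy.random.default_rng` (PCG64), exactly reproducible by seed
across platforms.

Preset values live in `data/presets.yaml`, versioned with the package:
WT at 100 ms mean RR (~600 bpm) with LF/HF/noise of 4/5/3 ms
(SDRR ≈ 5.4 ms); TG^AC8 at 85 ms (~706 bpm, higher heart rate) with
1.6/2/1.2 ms (SDRR ≈ 2.2 ms), a ≈ 2.5-fold basal variability contrast —
inside the two- to threefold range that characterizes the phenotype.
Beat-domain frequencies 0.08 and 0.30 cycles/beat land at ≈ 0.8–0.94 Hz
(LF band) and ≈ 3.0–3.5 Hz (HF band) for both presets. Drug transforms
are per-(drug, genotype) multipliers on mean RR and the fluctuation
amplitudes, encoding the observed directions: atropine and dobutamine
shorten RR and cut modulation much more in WT than TG^AC8; propranolol
lengthens RR modestly, more in the transgene; dual blockade converges
both genotypes toward a low-modulation intrinsic state.

**What the generator does not emulate:** circadian structure,
respiratory sinus arrhythmia as a coupled (rather than fixed-frequency)
oscillation, 1/f fractal scaling, activity-driven nonstationarity, and
physiologically shaped ectopy (compensatory pauses). Passing tests
therefore demonstrate correctness of the *computations* and calibration
of the *statistical machinery* under the assumed structure — not that
the metrics discriminate genotypes in real telemetry.

## Problem sizes and numerical conventions

Analysis segments are 2048 intervals throughout. Generator-calibration
checks use 50 000-beat series (SDRR closed form holds within 3%);
mixed-model calibration uses 200 replicates for CI coverage and 500 for
the null interaction rejection rate, at 6 + 6 animals — the design's
native size. Ties at band edges go to the upper band (half-open bins);
the HF top edge is closed. Entropy match comparisons use ≤ (not <) r,
following the standard template-matching definition. Constant series
are handled explicitly everywhere (no ectopics, zero variability
metrics, E1 = 0, zero spectral power).

## Known limitations

- The spectral power scale depends on the seconds-vs-ms choice for the
  T̄ divisor; only ratios across groups are scale-free.
- Satterthwaite df rely on numerical derivatives of the REML surface;
  for severely unbalanced designs the finite-difference steps may need
  tuning (they are relative to θ̂).
- The stationarity test targets linear trends only; slow oscillatory
  nonstationarity within a window passes.
- `select_segments` at the default window size requires ectopic-free
  windows; callers with broadband-noise data should pass a larger
  `window_size` (the pipeline driver does).
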