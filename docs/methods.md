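# Methods

## Scope and data model

The package analyses two phenotypes of short-day duckweed strains and the
relationship between them:

1. **Circadian rhythm phenotypes** from bioluminescence reporter traces:
   the free-running period (FRP, `tau`) under constant light, the relative
   amplitude error (RAE) as a rhythm-quality index, and the timing of the
   first peak after release into constant light (the phase phenotype).
2. **Photoperiodic flowering phenotypes**: the critical day length (CDL),
   the day length at which the flowering response falls to half its
   maximum (Fmax).

A trace is a uniformly sampled signal (default 20-min sampling) covering
two days of 15 h light / 9 h dark entrainment followed by constant light
(LL).  Release into LL is modelled as the lights simply staying on at the
end of the last photoperiod, so LL begins 15 h after the final dawn; peak
times are reported relative to that final dawn.  Flowering assays are
frond counts (flowering / total) over a grid of day lengths, by default
{9, 11, 11.5, 12, 12.5, 13, 13.5, 14, 14.5, 15} h with two replicate wells.

## Preprocessing

Traces are detrended by subtracting a centered 24-h moving average and
amplitude-normalized by dividing by the centered 24-h moving standard
deviation.  Numerical choices, fixed for bit-reproducibility:

- The window is the largest odd sample count spanning at most 24 h with
  inclusive endpoints — 73 samples at 20-min sampling.  Because both
  endpoints of a full cycle enter the window, a pure 24-h cosine is not
  left exactly invariant (the window mean of `cos` over the 73-point grid
  is `-cos/73`); the tests pin this against a directly evaluated window
  oracle rather than the idealized continuum limit.
- Full-window-only evaluation: `(n-1)/2` samples are trimmed at each edge
  per pass (no padding).  The period analysis uses the interior 60–132 h
  window, so edge handling never influences results.
- The moving SD uses the population (N) denominator; it is a normalization
  constant, not an inferential estimate.
- A zero moving SD (locally constant signal) is an error naming the time
  point; gap imputation is out of scope — readers require complete grids.

The composed transform is invariant to affine rescaling `y -> a*y + b`
(a > 0), so period estimates cannot depend on reporter brightness.

## Peak detection

Candidate peaks are local maxima of a 2-h moving-average-smoothed copy of
the (by default detrended) trace; each candidate is refined by an ordinary
least-squares quadratic on the raw samples within ±2 h, taking the vertex
as the peak time.  Fits with non-negative curvature or a vertex outside
the window are dropped; peaks closer than 12 h are resolved by keeping the
higher fitted peak.  The 2-h smoothing and fit half-width cover roughly a
sixth of a cycle, where a cosine is near-quadratic: on a noiseless 24-h
cosine the vertex bias is below 0.05 h (verified in the tests).  Under
heavy noise a candidate can split into two shoulders whose vertices fall
outside the fit window, occasionally losing one cycle's peak; replicate
averaging absorbs this.

The first-LL-peak phenotype is the earliest fitted peak at or after LL
onset, in hours since the final dawn.  The dawn reference and the
detrended-vs-raw choice are configurable.

## Period estimation (FFT-seeded nonlinear least squares)

The normalized 60–132 h window is fit with

    y(t) = c0 + sum_k A_k cos(2*pi*(t - phi_k)/tau_k)

Components are added one at a time.  Each new component is seeded from the
largest non-zero-frequency line of the discrete Fourier periodogram of the
current residuals (period, amplitude `2|X|/N`, and phase from the DFT
angle), then all parameters are refit jointly by damped least squares
(Levenberg–Marquardt, relative tolerance 1e-10).  Amplitudes are kept
non-negative by sign-flip reparameterization (a negative `A` becomes a
half-period phase shift) and periods enter through `|tau|` since the
cosine is even.  Addition stops when the newest component's amplitude is
not significantly positive, at four components, or when the residual sum
of squares reaches round-off; a non-significant component is discarded and
RSS is non-increasing across accepted additions.

Significance and the RAE both use the linearized covariance at the
optimum: `sigma^2 (J^T J)^{-1}` with `sigma^2 = RSS/(n - p)` and the
Student-t quantile on `n - p` degrees of freedom.  RAE = (95 % CI
half-width of the amplitude) / amplitude, capped at 1; a singular normal
matrix gives RAE 1 with a warning.  Classic implementations of this
method use joint confidence regions; the linearized t-interval is adopted
here as the fully reproducible choice, which can differ for rhythms close
to the significance boundary.

The reported FRP is the fitted component with period inside the circadian
selection range [15, 35] h having the largest amplitude — the range
brackets plausible free-running periods (20–28 h) with margin while
rejecting the 12-h harmonic.  If no component lands in range the estimate
carries a missing period and RAE 1.

Replicates (typically three) are aggregated per strain: mean and sample SD
of the period, mean RAE, mean first-peak time.  A strain is excluded when
mean RAE > 0.1 **or** SD of FRP > 1.5 h (each criterion can be toggled
off) or when any replicate lacks a circadian component.  The mean RAE
across replicates, not the maximum, is compared to the threshold.

## CDL estimation

Counts are pooled across replicate wells per day length (weighting wells
by frond number; averaging replicate percentages is available as an
option) into rates `100 * sum(k)/sum(n)`.  The flowering response is the
piecewise-linear interpolation of the pooled rates over the sorted day
lengths — a parameter-free construction, not a fitted breakpoint model.
CDL is the day length of the first downward crossing of Fmax/2 at or
after the day length attaining Fmax; the descending limb is used because
in a short-day plant that limb is the photoperiodic boundary, even when a
noisy response dips below half-maximum earlier.  A response that never
falls to Fmax/2 inside the grid is right-censored; Fmax = 0 is undefined.
Censored CDLs are excluded from correlations and regressions, never
imputed at the grid boundary.  Critical night length is the trivial
complement `24 - CDL`.

## Association statistics

- **Pearson correlation** with the two-sided t-test p-value (n − 2 df).
- **Deming regression** with error-variance ratio `delta`; `delta = 1`
  (orthogonal regression) is the default because FRP and CDL are both
  measured in hours with comparable-scale error.  The closed-form slope
  `(s_yy - d*s_xx + sqrt((s_yy - d*s_xx)^2 + 4*d*s_xy^2))/(2*s_xy)` shares
  the sign of `s_xy`; `s_xy = 0` is flagged degenerate.
- **Pairwise Wilcoxon rank-sum tests**: exact by the rank-sum distribution
  (subset-sum recurrence) when the combined sample is ≤ 12 and tie-free,
  with the two-sided p `min(1, 2*min(P(W<=w), P(W>=w)))`; otherwise a
  normal approximation with tie-corrected variance and 0.5 continuity
  correction.  The switch point and tie rule are fixed here for
  reproducibility.
- **Holm adjustment** (delegated to statsmodels) and a **compact letter
  display** built by insert-and-absorb: groups share a letter iff their
  adjusted p is at or above alpha, deterministic given input order.

Analyses involving FRP drop strains flagged by the exclusion rule; the
peak-time vs CDL analysis keeps all strains with both phenotypes.

## External-coincidence gate model

A deliberately minimal rendering of the coincidence hypothesis: floral
induction is clock-gated and permitted only in darkness, with the gate
opening `d0 + k*(tau - 24)` hours after dusk.  Flowering then requires
night length to exceed the gate delay, so the predicted CDL is
`24 - (d0 + k*(tau - 24))`, strictly decreasing in `tau` for `k > 0` with
slope exactly `-k`.  Fitting the model to a panel is the exact
reparameterization of the Deming line of CDL on FRP (`k = -slope`,
`d0 = 24 - intercept - 24*slope`); a positive panel slope yields `k < 0`
and is flagged as inconsistent with the gate direction rather than
hidden.  The gate is anchored to dusk; linearity in `(tau - 24)` is the
simplest form consistent with the hypothesis.  This is a toy model for
prediction and parameter bookkeeping, not a mechanistic inference.

## Synthetic data generator

Traces follow `y(t) = exp(g*t) * [M + A*D(t)*cos(theta(t))] + eps` with
phase advancing at `2*pi/24` per hour during entrainment (peak anchored
2 h after each dawn — a morning-phased reporter) and at `2*pi/tau` after
release, continuous at the transition; `D(t)` decays exponentially in LL.
Defaults, chosen once as a realistic reporter regime: mesor 100 and
amplitude 50 signal units, noise SD 10 (amplitude/noise = 5), growth
0.005 h⁻¹ (signal roughly +65 % over the recording as the fronds grow),
damping 0.005 h⁻¹.  Flowering assays draw binomial counts from a
symmetric linear ramp of width 1 h centred on the programmed CDL, so the
half-Fmax point equals the programmed CDL by construction; the ramp width
is a simulation convenience, not a claim about the plant.  Panels draw
`tau ~ N(24.5 h, 1.5 h)` and `CDL = 25.25 - 0.5*tau (+ noise)`, and can
add independent measurement noise to both phenotypes to create the
errors-in-both-variables regime Deming regression addresses.

What the generator does **not** emulate: autocorrelated noise, stochastic
limit-cycle dynamics, light-intensity or temperature effects, non-ramp
flowering response shapes, and replicate-to-replicate phase scatter beyond
independent noise.  Passing tests therefore demonstrate correctness of the
estimators under this model, not robustness to every feature of real
reporter data.

## Problem sizes and determinism

The recovery studies use 100 traces for period recovery and RAE
discrimination (SNR 5, periods uniform on 20–28 h), 200 assays for CDL
recovery (40 fronds per day length), and 200 panels of 72 strains for the
regression comparison; the worked example panel is 24 strains × 3
replicates.  All randomness flows through `numpy.random.default_rng`
seeds carried in the simulation specs, so every table and figure input is
exactly reproducible from a single integer seed.

## Known limitations

- The FRP estimate has a small negative bias at high damping because the
  moving-SD normalization does not perfectly whiten a decaying envelope.
- Peak detection can miss a cycle under heavy noise (vertex-outside-window
  rejection); the first-LL-peak phenotype is the mean over replicates and
  occasionally inherits an outlier.
- The exact Wilcoxon path requires tie-free data; tied small samples fall
  back to the corrected normal approximation.
- The exclusion rule's OR-combination of the RAE and period-SD criteria is
  configurable because either criterion alone is defensible; results for
  borderline strains depend on the choice.
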