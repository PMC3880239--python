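# Methods

## Signal model and assumptions

The pipeline assumes a scalar signal sampled at fixed, uniform intervals
dt (default 5 s, 360 points ≈ 30 min) representing a continuous underlying
phenomenon: a slowly varying baseline (possibly drifting linearly),
superposed transient spikes with fast rise and slower decay, and additive
measurement noise. Two recordings are required per run: a *treatment* set
and a matched *control* set in which only background noise (no evoked
spiking) is present. The control is not optional — it calibrates both the
detection thresholds and the significance cut-off, which is what makes the
analysis transferable across instruments and imaging conditions.

## Savitzky–Golay filtering with derivatives

Smoothing fits a degree-k polynomial by least squares to each sliding
window of w = 2n + 1 samples and evaluates the fit (and its first and
second derivatives) at the window centre. The weights are obtained from
the pseudo-inverse of the window Vandermonde matrix (an orthogonal
decomposition, exact to floating-point precision for any polynomial of
degree ≤ k), so any admissible (w, k) pair works without coefficient
tables. The first and last n points are produced by evaluating the fit of
the nearest *full* window at the corresponding off-centre offset: output
length equals input length, there are no padding artifacts, and these edge
points are excluded from peak candidacy anyway. Derivatives are rescaled
to per-second units (÷dt, ÷dt²).

Defaults w = 9, k = 5: at dt = 5 s the window spans 45 s, comparable to
one spike's visible duration, and an odd degree captures the rise/decay
asymmetry. For symmetric peaks k = 2 is a reasonable alternative. The
trade-off is standard: wider windows and lower degrees suppress more noise
but flatten narrow spikes.

## Peak detection

Candidates are points where the estimated f′ crosses from positive to
non-positive between neighbouring samples with f″ < 0 at the assigned
index (the crossing is attributed to whichever neighbour has the larger
smoothed value; plateau ties resolve to the left edge). Slopes smaller
than 1e-8·max|f|/dt are treated as zero so exactly flat stretches generate
no spurious crossings from floating-point round-off. Note that the
polynomial fit can ring slightly at sharp onset corners, producing genuine
low-amplitude candidates; these are pruned by the merit threshold, not by
candidacy.

Each candidate i is scored with the continuous merit

    peak_c(i) = max(f_i − δ, 0)
              · max(1 − |f′_i|·(1/ξ + 1/γ)/2, 0)
              · max(−f″_i · dt², 0)

and accepted iff peak_c(i) > τ. Each factor vanishes exactly where the
corresponding logical peak condition (f_i > δ; −ξ < f′_i < γ; f″_i < 0)
fails, and the score is 1 at the reference point f_i = δ + 1, f′_i = 0,
f″_i·dt² = −1. Two unit choices matter:

* the curvature factor uses −f″·dt² (per sampling interval squared) rather
  than per-second curvature. Spikes lasting minutes have |f″| of order
  1e-2 s⁻², which would push all merits far below any O(1) threshold; in
  per-sample units a spike a few samples wide has curvature of order its
  amplitude, so merits are O(1) and the useful range of τ is roughly 1–2
  (the default is τ = 1; raising it toward 2 prunes the weakest peaks
  first). The same convention governs w, which is also specified in
  samples. The cost is that the merit scale is tied to the sampling rate;
  δ, ξ, γ remain acquisition-rate independent.
* the slope factor averages the reciprocal tolerances 1/ξ and 1/γ so an
  asymmetric tolerance pair still yields a single penalty per candidate.

Start/end delimitation: t_s is the nearest derivative trough (a
non-positive→positive crossing of f′, assigned to the smaller-f neighbour)
left of the apex, t_e the nearest trough to its right; a peak truncated by
the record boundary keeps the first/last interior index. Two adjacent
peaks that share a trough receive the same boundary index.

Amplitude and intensity are measured above the straight chord joining
(t_s, f(t_s)) and (t_e, f(t_e)); intensity is the trapezoidal integral of
the smoothed trace minus the chord, clamped at zero. Chord subtraction
makes both measures invariant to constant offsets and linear drift, which
is what sloped-baseline records require. Integration uses the smoothed
trace — the same curve on which the peak was defined.

## Control calibration

Three quantities are estimated from the control set when not supplied:

* **δ** (height threshold, signal units): the control median plus the 90th
  percentile of |f − rolling median(f)| (window w). This sits just above
  the control noise band, wherever the baseline happens to be.
* **ξ = γ** (slope tolerances, signal units/s): 3 robust standard
  deviations (1.4826·MAD) of the control's f′ estimate, floored at
  0.5 s⁻¹. The floor is a discretization allowance: a true apex falling
  between two samples leaves |f′| up to |f″|·dt/2 at the nearest sample,
  which is orders of magnitude above the control-noise derivative scale;
  without the floor the trend factor would veto every real peak. The
  control term takes over only for very noisy acquisitions.
* **Significance threshold**: detection is rerun on every control trace
  with τ = 0 and the intensities of all resulting "false peaks" are
  pooled; the threshold is their q-quantile (linear interpolation between
  order statistics, default q = 0.9; q = 0 gives the minimum, an empty
  harvest gives 0). A treatment peak is validated iff its intensity is
  *strictly* greater. Strictness yields the self-consistency property that
  a control analyzed as its own treatment at q = 1 validates nothing.

Validation is performed on intensity (the explicit ∫f dt formulation);
amplitude is recorded alongside for reporting.

## Spiking statistics

Waiting times are maximum-to-maximum intervals between consecutive
validated peaks, in seconds. The regularity summary is the lag-1
autocorrelation with a single global mean and full-series denominator,

    r₁ = Σ_{j<m−1} (x_j − x̄)(x_{j+1} − x̄) / Σ_j (x_j − x̄)²,

undefined (reported NA, excluded from class counts) for fewer than 3
intervals or zero variance; the estimator is scale- and shift-invariant.
With the short records typical here (≈10 intervals) r₁ is biased toward
zero by roughly −1/m, so iid cohorts show a mild negative tilt — the
±0.2 classification band absorbs most of it, and the band is a fixed,
configurable cutoff, not a significance bound. Cells are *active* at ≥ 3
validated peaks (configurable); cohort means (peak number, waiting time)
are taken over active cells only, waiting-time means as the mean of
per-cell means so long-spiking cells do not dominate.

## Group comparisons

* Responding fractions (one value per biological replicate): Shapiro–Wilk
  screen at α = 0.05 on each group (groups too small or degenerate to
  screen route to the rank test); Student t if both pass, otherwise
  two-sided Wilcoxon–Mann–Whitney. The chosen test is named in the output.
* Peak counts (≥ 3 groups): Kruskal–Wallis, then Dunn's pairwise rank z
  tests with tie correction and Bonferroni adjustment (implemented here;
  the adjustment is capped at 1 and named in the output). Two groups are
  redirected to the two-sample path.
* Autocorrelation classes: classic Pearson χ² on the 2×3 table without
  continuity correction; classes empty in both groups are dropped first,
  and expected counts below 5 raise a logged warning.

## Synthetic cohorts

The generator emulates the acquisition regime the pipeline targets:
360 points at dt = 5 s, ratio baseline 1.0 with mild linear drift
(5e-5 s⁻¹ ≈ +0.09 over the record), Gaussian noise (SD 0.02), and spikes
shaped as normalized double exponentials e^(−t/decay) − e^(−t/rise) with
rise 5 s, decay 20 s (apex ≈ 9.2 s after onset, visible duration ≈ 45 s)
and apex amplitude 3.0 — a strong but realistic ratiometric response, and
one for which the default detection parameters sit comfortably inside
their working range (merit ≈ 2 at τ = 1). Event times follow one of three
regimes: iid exponential (mean 150 s, shifted above the refractory floor
so the configured mean is exact), strict short/long alternation
(80 s / 220 s with 8 s jitter; anti-persistent, r₁ near −1 in truth), or
AR(1) (mean 150 s, φ = 0.8, innovation SD 50 s; persistent). All intervals
respect a refractory floor, default 45 s ≈ one peak duration, so planted
peaks never merge ambiguously; events whose apex would fall within 8
samples of the record end are not planted, so the planted truth is fully
recoverable. Controls share baseline, drift and noise but carry no events.
A seed fully determines every cohort.

What the generator does **not** emulate: photobleaching and non-linear
baseline trends, saturated or dropped frames, cell-to-cell amplitude and
shape heterogeneity, bursting/refractory dynamics beyond the fixed floor,
and spike-shape variability within a cell. Passing the recovery and
discrimination suites therefore demonstrates correctness of the machinery
under the stated signal model, not performance bounds on arbitrary real
recordings — on real data the δ/ξ/γ/τ/q calibration knobs exist precisely
because those features vary.

## Numerical and design choices

* Quantile convention: linear interpolation between order statistics
  (e.g. intensities {1…10} at q = 0.9 give 9.1).
* Ties: plateau apices resolve to the leftmost index; trough assignment
  prefers the smaller-f neighbour, left on ties.
* Degenerate inputs fail fast: non-finite values, ragged columns, empty
  sample sets, too-short series and ill-posed (w, k) pairs are errors, not
  warnings. Undefined statistics (r₁, empty-active means) are values (NA),
  not errors.
* Candidates are restricted to strictly interior indices so every reported
  peak satisfies t_s < i_max < t_e even at record boundaries.
* Exclusion of samples is by ID; bare 1-based positions are accepted and
  resolved to IDs in the log (positions are fragile across re-orderings).
* Reports are deterministic byte-for-byte (full-precision `repr` floats,
  `.` decimal separator, no timestamps); PNG output suppresses software
  metadata.
* Problem sizes in the verification suites (cohorts of 5–40 cells, 100
  seeded signature runs, 2,000 null simulations, 10,000-interval estimator
  checks) were chosen as the smallest sizes at which the targeted rates
  are statistically stable.

## Known limitations

* The merit scale depends on dt (by design, see above); comparing τ across
  acquisitions with different sampling rates requires rescaling.
* Overlapping spikes closer than about one filter window merge into a
  single detected peak; narrow windows recover them at the cost of noise.
* The χ² class comparison is asymptotic; with small cohorts expected
  counts below 5 occur and are only warned about.
* The lag-1 statistic summarizes interval structure at one lag; longer
  range periodicity is out of scope.
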