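# Methods

## The paradigm and its time axis

Each trial of the urgent flanker task starts with a fixation stimulus
(350/400/500 ms); its offset is the Go-signal opening a 1,000-ms response
window. After a gap of 0–950 ms (11 levels) the target and its four
flankers appear; in the SOA variant the flankers appear first and the
target follows 120 ms later. The analysis variable is the raw processing
time, rPT = RT − gap − SOA, the time the target was visible before the
response. Accuracy as a function of rPT (the tachometric function) is flat
at the guessing level for negative/short rPTs, rises to a near-perfect
asymptote once the target can be processed, and — when the task-irrelevant
flankers are processed ahead of the target and conflict with it — dips
below chance in an intermediate window.

## Design generation

`build_design` lays out balanced blocks: the full factorial of
gap × congruency × target × SOA × fixation duration fits the block sizes
exactly (11·2·2·3 = 132 for experiments 1–2; ×2 SOA levels = 264 for
experiment 3), each combination occurring equally often, order randomized
independently per block. Totals per participant are 5 sessions × 9 × 132 =
5,940 (experiments 1–2) and 5 × 4 × 264 = 5,280 (experiment 3); the first
block of session 1 is flagged practice and excluded from analysis (leaving
5,808 / 5,016 analyzable trials per participant). If a block size is
divisible by the base factorial but not by the fixation-extended one,
fixation levels are cycled instead; indivisible block sizes are rejected.

## The observer model

Simulated accuracy follows

p(correct | rPT) = clip( p_floor + (p_asym − p_floor)·σ((rPT − μ − δ·I)/s)
− A·exp(−(rPT − c)² / 2w²)·D − λ·max(0, rPT − t₀), 0.001, 0.999 )

with σ the logistic function, I the incongruency indicator and D the dip
indicator (incongruent trials; when `dip_soa_gated` is set, additionally
SOA > 0, i.e. the dip requires the flankers to lead the target — the exp3
preset uses this to confine the below-chance episode to the 120-ms-SOA
condition). Defaults: p_floor = 0.5, p_asym = 0.97, rise midpoint
μ = 250 ms, scale s = 40 ms, incongruent delay δ = 50 ms (the flanker
effect as a rightward shift), dip center c = 400 ms and width w = 80 ms,
late decline λ = 0 (off, onset t₀ = 800 ms). The dip amplitude A is not
set directly in the exp3 preset: `calibrate_dip_depth` solves (bisection)
for the A at which the generative curve's minimum over rPT > 0 equals a
stated target, 0.16 for the asymmetry scenario.

Response times are truncated normal (mean 800 ms, SD 150 ms, bounds
[100, 1,300] ms), independent of gap and rounded to integer ms; these
values make realized rPTs span the full −200…1,000-ms analysis window
across the 11 gap levels. Responses at rPT below 0 are pre-stimulus: they
are drawn from a guessing rule with an optional hand bias (probability of
choosing the right-hand response), so their accuracy follows from the
balanced target assignment — a hand bias shifts responses, not accuracy.
Stimulus-driven responses are Bernoulli draws from p(correct | rPT).

What the generator does *not* emulate: sequential effects, learning or
fatigue across sessions, participant heterogeneity (all simulated
participants share one observer), gap-dependent RT strategies, and eye
movements. Passing tests therefore show that the *pipeline* recovers known
generative structure at realistic trial counts, not that real data are
this well behaved.

## Curve estimation

Trials are filtered (practice out; −200 ≤ rPT ≤ 1,000 ms kept, both
boundaries closed; every exclusion counted and reported), assigned to
1-ms bins by nearest integer, and the per-bin proportions correct are
locally regressed onto the full 1-ms grid. The smoother is a tricube
local polynomial with nearest-neighbour bandwidth: at grid point x₀ the
window reaches its q-th nearest nonempty bin, q = max(⌊span·n⌋, degree+2),
span 0.2, degree 2 (the conventional default of the local-regression
procedure this follows; degree is configurable). Empty bins are dropped —
they carry no accuracy information — and bins are unweighted by default,
with an optional count-weighted mode. Fitted values are clipped to [0, 1].
A public curve requires at least max(10, ⌈2/span⌉) nonempty bins; inside
resampling loops the weaker algebraic requirement (enough bins for the
local polynomial) applies, so tiny enumeration instances remain testable.
The smoother is linear in the binned proportions; its hat matrix is
exposed and tested against a per-grid-point weighted-least-squares oracle
(agreement to 1e-8; an external check against R's `loess` on identical
bins agreed to |Δ| ≤ 0.007, attributable to R's interpolation surface).

`n_local`, the trial count behind each grid point, is the number of trials
whose bins fall within that point's bandwidth window; it feeds the chance
band.

## Inference

**Restricted minimum.** Minima are taken over grid points with rPT
strictly greater than 0 (pre-stimulus responses cannot be
stimulus-driven); ties break to the smallest rPT.

**Minima difference test.** Observed statistic min_A − min_B, each through
the full bin → smooth → minimum pipeline. Null: pool the two groups'
trials, relabel randomly preserving group sizes (per trial, on the
aggregated table — the analysis is aggregate by design), recompute.
Two-sided, B = 1,000 by default, p = (1 + #{|null| ≥ |obs|})/(1 + B) so
p > 0 always; an exhaustive mode enumerates all relabellings on toy
instances. Replicates whose groups cannot be smoothed are redrawn and
counted.

**Minimum vs chance.** The test statistic is the restricted minimum; the
null regenerates every trial's correctness as an independent fair coin
while keeping all rPTs, and is lower-sided (the question is whether the
curve drops *below* what guessing produces). Because bin occupancy is
fixed under this null, re-running the pipeline per replicate is exactly
the fixed hat matrix applied to the regenerated bin proportions, which is
how it is computed (the identity is asserted in a test). Calibration on
pure-guessing data: rejection rate 0.065 at α = 0.05 over 200 datasets of
2,000 trials (95% binomial interval [0.020, 0.080]).

**Bootstrap SE.** Trials resampled with replacement within condition,
full pipeline per resample, SD of the resampled minima.

**Chance band.** Half-width 1.96·√(p₀(1−p₀)/n_local) around p₀ = 0.5,
undefined (flagged) where n_local = 0. `classify_dip` turns the band into
a dip/no-dip call: a meaningful drop must stay below the lower limit for
≥ 50 consecutive ms *and* reach at least one half-width below it somewhere
in that run. Both conditions target smoothing noise — correlation across
the bandwidth can stretch a marginal wander past any duration cutoff, but
only a real dip goes deep (generative dips reach ~20 half-widths below the
limit, noise excursions well under one).

**Bayes factors.** Per 100-ms bin (half-open, last bin closed, partitioning
[−200, 1,000]), the marginal likelihood of k successes in n under a
logistic prior on the log-odds ω (location logit(0.5) = 0, scale 0.5,
truncated to ω < 0 for the below-chance factor and ω > 0 for above) is
divided by the point-null likelihood at p = 0.5. The integrand is maximized
on a coarse grid, shifted by its peak, and integrated by adaptive
quadrature, so very large factors stay finite in log space; results are
decadal logs with ±∞ and empty-bin sentinels retained. Validated against a
10⁶-point trapezoid oracle to 1e-6 in log₁₀.

## Orchestration and reproducibility

`run_analysis` executes the whole scheme per condition — and per SOA level
when the data contain several, with the SOA entering the rPT computation —
and emits a JSON report (statistics, seeds, config hash, exclusion
accounting), curve and Bayes-factor tables, and one figure per group
(curve, chance band, SOA onset markers, log₁₀-BF strip). One master seed
expands into per-stage seeds via CRC32(stage name) mixed through a
SeedSequence, so adding stages never perturbs existing ones and identical
config + seed gives byte-identical reports.

## Problem sizes

The bundled analyses run the experiments at their designed sizes (35,640 /
31,680 trials) with 1,000 permutations and 1,000 bootstrap resamples. The
calibration study uses 200 datasets of 2,000 trials with 400 permutations
each; with B = 400 the rejection event p ≤ 0.05 corresponds to at most 19
null exceedances, a valid test of size 20/401 ≈ 0.0499.

## Known limitations

- Where the rPT grid is sparsely covered (notably near +1,000 ms in the
  120-ms-SOA condition, whose rPT axis is shifted left), local fits rest on
  bins holding very few trials, so both observed and null curves have
  inflated variance at the edge. This makes the minimum-vs-chance test
  conservative there: in the exp3 preset the 120-ms-SOA incongruent group
  shows a deep dip (minimum ≈ 0.19) with contrast tests at p ≈ 0.001, yet
  its min-vs-chance p is only ≈ 0.05 because fair-coin null curves
  occasionally dive at the thin edge. The behavior is shared by R's loess
  and is a property of evaluating minima over weakly supported grid
  regions, not of this implementation.
- The fitted curve is evaluated on the fixed −200…1,000-ms grid even where
  it extrapolates beyond the outermost nonempty bins.
- No per-participant random effects: all inference is on aggregated data,
  which is appropriate for the small-N, many-trials design it mirrors but
  does not generalize across observers.
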