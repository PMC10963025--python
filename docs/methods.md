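# Methods

## The models

`docksim` simulates release at a small active zone with `N` independent
release units ("docking sites") driven by a train of `n_stim` action
potentials (APs). Two site architectures are implemented.

**RS/DS (two-slot sequential).** Each unit has a distal *replacement site*
(RS) and a proximal *docking site* (DS) that can be occupied simultaneously.
Initial occupancies are Bernoulli with probabilities ρ (RS) and δ (DS),
drawn independently per site and per train. Each AP cycle applies, in order:

1. **release** — an occupied DS fuses with probability `p_r`;
2. **docking** — a unit with occupied RS and empty DS promotes the RS
   vesicle with probability `r`;
3. **replenishment** — an empty RS refills with probability `s` from the
   upstream pool (optionally a finite intermediate pool, IP);
4. **IP refill** — each IP vacancy refills with probability `r_ip` from an
   effectively infinite recycling pool.

Because both slots can be full at once, a unit can emit two vesicles in two
APs without any upstream supply: the maximum readily releasable pool (RRP)
per site is 2.

**LS/TS (single-slot).** One slot per unit, whose vesicle is loosely or
tightly docked (`loose → tight` with probability `r`; only tight vesicles
fuse; an empty slot refills as loose with probability `s`). The slot never
holds two vesicles, so the RRP per site is 1. This architectural difference —
2 versus 1 — is the discriminating prediction the estimators are designed to
probe.

Transition probabilities are defined **per inter-AP interval** and are not
rescaled when the stimulation frequency changes; an explicit rate-based
conversion (`p = 1 − exp(−λΔt)`) can be applied by the caller if desired.
`p_r` is constant across the train. Trains are independent (inter-train
intervals in the emulated experiments are seconds long).

### Intra-interval scheduling

The default `blocked` order (release → docking → replenishment) lets a
vesicle take at most one transition per interval: an SV arriving at the RS
cannot dock until the next interval, and a newly docked SV cannot fuse until
the next AP. Two variants are provided because the literature's occupancy
bookkeeping at the second AP is under-determined: `chained` gives
just-replenished SVs one extra docking draw in the same interval, and
`split_interval` applies docking and replenishment twice per interval with
half-interval probabilities `1 − sqrt(1 − p)`.

The diagnostic `rs_occupancy_components` reports the RS occupancy just
before a chosen AP, split into SVs present at train onset versus SVs that
arrived through `s`. Under the blocked order with the potentiated parameter
set (δ = 0.9, ρ = 1, p_r = 0.9, r = 0.7, s = 0.35) it gives a total RS
occupancy of ≈ 0.59 at the second AP, of which ≈ 0.22 is replenishment;
published figures for the same quantities (0.460 and 0.097) evidently follow
a different intra-interval bookkeeping that none of the three variants
reproduces exactly. The replenishment-contribution calculus therefore takes
the occupancy components as explicit inputs rather than deriving them.

### Closed forms

For a single site the model is a small Markov chain, so expected counts are
exact: `P1 = δ·p_r`, and for RS/DS
`P2 = p_r·[δ(1−p_r) + (1−δ(1−p_r))·ρ·r]` (the high-`p_r` shorthand
`ρ·r·p_r` is exposed as a variant). `analytic_mean_si` iterates the
occupancy distribution for any train length, model kind and scheduling; it
broadcasts over parameter arrays and is the default fitting loss. The finite
IP couples sites, so IP conditions always use the Monte Carlo path.

## Estimators

All variances and covariances use population normalisation (divide by `n`),
matching the moment definition of the covariance statistic; `ddof=1` is
available where it matters.

**Docking-site number.** Two methods, as used in counting studies:

* *binomial*: for each candidate `N`, the release probability `P` minimises
  the summed squared deviation between empirical count frequencies
  (`k = 0..N`) and the binomial pmf; the best integer `N` wins, ties to the
  smaller. Candidates below the largest observed count are impossible.
  A multinomial-likelihood objective (`objective="likelihood"`) is provided;
  it separates adjacent `N` more sharply on small samples (at exactly 60
  trains and `P ≈ 0.7` the squared-frequency objective confuses `N = 6` with
  `N = 7` in ~14% of replicates; the likelihood objective essentially never
  does). The default remains the squared-frequency objective. Fitting the
  first two stimuli jointly (pass `[s1, s2]`) follows the protocol of
  counting studies and is markedly more robust.
* *variance–mean*: unweighted least squares of `var = m − m²/N` over the
  per-stimulus (mean, variance) points — a parabola with initial slope 1 and
  zero intercept whose positive x-intercept is the maximal mean output,
  i.e. `N`. The single free parameter is initialised at the maximum observed
  count + 1; the standard error comes from the fit curvature. Degenerate
  inputs (zero variances, non-positive `N`) return flagged estimates.

Both methods recover the generating `N ∈ {2..6}` on simulated synapses and
agree with each other under high-P conditions; N estimates are invariant to
the release-probability regime of the same synapse.

**Covariance profile.** `cov(S_i, s_{i+1})` between cumulative release
through stimulus `i` and the next count. Pure depletion makes every entry
non-positive; under partially occupied initial conditions the magnitude
peaks at `i = 2` for the two-slot model (first-AP releases are partly
backfilled from the RS, so anticorrelation builds after the second AP),
whereas a single-slot model peaks at `i = 1` — a shape diagnostic between
the architectures.

**SMN back-extrapolation.** Cumulative mean synchronous counts are placed at
`t_i = stimulus time + 5 ms` (when the synchronous window closes); a
regression line through the late-train points (default stimuli 5–8) is
extrapolated back to the first measurement time `t_1`. The intercept
`P_back` estimates the pool consumed by the train above steady-state
replenishment; the slope, converted to SVs per AP, estimates that
replenishment. When depression is incomplete the method underestimates the
true pool (`P_back ≤ ρ + δ` per site), and stronger depression (higher
`p_r`, δ) moves the estimate toward the architectural ceiling — the ordering
control < 4-AP < PTP on simulated conditions.

**Depression metrics.** Paired-pulse ratio `⟨s_2⟩/⟨s_1⟩`; steady-state
release per AP (late-train regression slope) over `⟨s_1⟩`; and the
exponential fall-off of `⟨s_i⟩` for `i > 2` with asymptote fixed at zero,
fitted in stimulus-index space and converted to ms with the inter-AP
interval (1.66 intervals at 200 Hz ↔ 8.3 ms). Constant tails report an
infinite time constant with a flag rather than a fake fit.

**Latencies.** Release latencies after each AP follow a biphasic density:
fast direct release of docked SVs (τ_f, default 0.47 ms) plus slow two-step
release via the RS (τ_s, default 4.0 ms). `fit_latency_biexp` fits the
two-exponential mixture by maximum likelihood on the unbinned sample, with a
fixed onset delay. A lone exponential leaves the mixture likelihood flat
along a ridge of arbitrary splits, so the fit is compared against the
single-exponential MLE and collapsed (flagged `degenerate`) when the mixture
does not improve the log-likelihood by at least 3.

**Replenishment contribution.** Replacement-site SVs reach the synchronous
window only through two-step release, whose captured share is
`amp·(1 − exp(−window/τ))` (= 0.14 for amp 0.2, window 5 ms, τ 4 ms). The
fraction of `P2` from upstream replenishment is that share times the
replenishment fraction of the RS occupancy at AP 2, and the percentage of
`P1 + P2` follows by weighting with `P2/(P1 + P2)` (the `P1` share is zero:
no two-step release occurs at the first AP).

## Model fitting

The fitting target is the vector of mean counts over a stimulus window
(default 1..5), loss is summed squared deviation, ρ is fixed at 1, and
(δ, p_r, r, s) are free. Search is a coarse grid (step 0.05 on [0,1], fully
vectorised through the broadcasting recursion) followed by Nelder–Mead on
the analytic loss, or a shrinking compass search on the Monte Carlo loss
with common random numbers (each evaluation re-seeds the same generator, so
the stochastic loss is locally smooth and fits are reproducible). If
refinement fails to improve on the grid, the best grid point is returned
with `converged=False`.

δ and p_r trade off through `P1 = δ·p_r`: the product is recovered within
±0.03 on 5000-train data even when the factors drift. Recovery experiments
fit the full 8-stimulus train: synthetic data follow the model exactly over
the whole train, and the extra stimuli condition the δ–p_r–r ridge (with the
5-stimulus window the noise-displaced minimum drifts beyond 0.1 in a
substantial fraction of seeds — verifiably a genuine minimum shift, since
the fitted loss is below the loss at the generating parameters). The default
window remains 1..5 for real data, whose late-train responses deviate from
the bare model through IP depletion and asynchronous release.

The IP extension freezes the base parameters and searches the integer IP
size and `r_ip` on a grid against the full-train means (the IP only matters
once the replacement sites have drained); with coupling on, `s` is scaled by
the IP filling fraction. Monte Carlo repetition defaults to 5000 per
condition.

## Synthetic data

`generate_condition_dataset` emulates single-synapse vesicle-count
recordings: `N ∈ {2..6}` sites, 8-AP trains at 100–200 Hz, ≥ 20 trains per
condition, counts from the simulators (so first-stimulus counts are exactly
binomial(`N`, δ·p_r), and depletion structure propagates to variances and
covariances), and per-SV latencies from the fast/slow mixture with the slow
share ramping 0 → 0.5 across the train. Latencies are attached post hoc —
the discrete-time model has no within-interval dynamics — and truncated at
the inter-AP interval. Three named parameter sets (`CONDITION_PARAMS`)
represent the control (δ=0.65, p_r=0.6, r=0.7, s=0.35), potassium-channel-
blocker (δ=0.8, p_r=0.9) and post-tetanic-potentiation (δ=0.9, p_r=0.9)
regimes, all with ρ=1.

Traces are sums of a miniature-EPSC template (rise-filtered double
exponential, five parameters, peak-normalised) at the event times, with
multiplicative amplitude depression `1 − d·exp(−Δt/τ_rec)` (defaults d=0.3,
τ_rec=5 ms — synthetic stand-ins for a receptor saturation/desensitisation
correction whose constants are instrument-specific, config-exposed) and
white Gaussian noise. Not emulated: receptor kinetics, coloured noise,
across-train drift, site heterogeneity. Passing round-trip tests therefore
demonstrate the counting pipeline's self-consistency at realistic rates and
noise, not robustness to every artefact of recorded data.

## Event counting

Traces are deconvolved by the template with a Tikhonov-regularised inverse
filter (regularisation 1e-3 of peak spectral power), which turns each event
into a narrow spike; the spike train is calibrated so a unit-amplitude
template deconvolves to height 1, making thresholds commensurate with event
amplitudes. Spikes above threshold (default 4× the MAD-based robust noise of
the deconvolved trace) are picked with a minimum separation of 0.2 ms — the
effective time resolution — and the amplitudes of the picked onsets are then
jointly refit by least squares against shifted templates, dropping
sub-threshold amplitudes and re-solving. Amplitudes are divided by the
recovery-rule factor for the preceding-event interval and reported in
mean-mEPSC units. Events ≥ 1.7 mEPSC units are split into two (a pair fused
below the resolution), and per-stimulus synchronous counts use 5-ms post-AP
windows, with later events reported separately as asynchronous.

The split percentage is an undercount audit, not a fixed constant: under the
potentiated 200-Hz condition ~33% of true first-stimulus events fall in
sub-0.2-ms pairs, and the detected split share fluctuates around ~16%
(10–22% across seeds at 20 trains) — the depression rule keeps many merged
pairs below the 1.7 threshold. The test suite bounds the diagnostic at 30%.

## Problem sizes and numerical choices

Test and acceptance runs use 5000-train simulations for moment-level checks
(SE of a per-stimulus mean ≈ 0.014 at N = 4), 1e5 single-site trials for
closed-form cross-checks (3-SE agreement), 20 000 trains for the covariance
peak, 60-train replicates for the N-recovery experiments, and 10–20 trains
for trace round trips. Stochastic assertions use 3–4 Monte-Carlo standard
errors. Ties in integer-N selection go to the smaller N; all probability
parameters are validated on construction; degenerate estimator inputs
return flagged results instead of raising wherever a flag is scientifically
meaningful (all-zero counts, zero variances, constant tails).

## Limitations

No continuous-time calcium dynamics, no intra-interval fusion (asynchronous
release exists only in the synthetic latency mixture), no receptor-level
biophysics, no across-train nonstationarity. The LS/TS "labile tight state"
(a transiently elevated `r` after an AP) is not modelled as a distinct
state. Group-mean fitting is the default; per-experiment fitting is a
caller-side loop.
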