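# docksim

Stochastic docking-site models and train-response estimators for
single-synapse vesicle counting.

At small central synapses, release is organised around a handful of docking
sites (`N` per active zone). A central question of short-term plasticity is
how many vesicles each site can hold ready — the readily releasable pool
(RRP) per site. Two architectures make opposite predictions:

* the **RS/DS model** — each site is a two-slot sequence of a distal
  *replacement site* (RS) and a proximal *docking site* (DS) that can be
  occupied simultaneously, so the RRP per site can reach **2**;
* the **LS/TS model** — one slot per site whose vesicle is either loosely or
  tightly docked, capping the RRP per site at **1**.

`docksim` implements both as discrete-time Monte Carlo simulators driven by
AP trains, with transition probabilities δ, ρ (initial DS/RS occupancies),
`p_r` (release per AP), `r` (RS→DS per interval) and `s` (RS replenishment
per interval), plus an optional finite intermediate pool feeding the RS. On
top of the simulators it provides the complete estimator toolbox used with
counted-vesicle train data:

- per-stimulus statistics `⟨s_i⟩`, `var(s_i)`, `S_i`, `P_i = ⟨s_i⟩/N`;
- docking-site counting by binomial fitting of count frequencies and by the
  variance–mean parabola `var = m − m²/N`;
- covariance profiles `cov(S_i, s_{i+1})`, whose peak position separates the
  two architectures;
- RRP estimation by back-extrapolation of cumulative synchronous release
  (SMN method), with its documented underestimation property;
- depression metrics (paired-pulse ratio, steady-state release per AP,
  exponential fall-off constant);
- biexponential release-latency fitting and synchronous/asynchronous
  classification in 5-ms windows;
- least-squares recovery of (δ, p_r, r, s) — and the intermediate-pool
  parameters — from observed train means;
- a synthetic-data generator (counts, latency rasters, current traces) and a
  deconvolution-based event counter that closes the loop from traces back to
  counts.

## Worked example

Simulate a strongly potentiated synapse (δ = 0.9, ρ = 1, p_r = 0.9,
r = 0.7, s = 0.35, N = 4), then count its docking sites and size its RRP
from the simulated data alone:

```python
import docksim as dk

params = dk.CONDITION_PARAMS["ptp"]          # delta=0.9, p_r=0.9, r=0.7, s=0.35
proto = dk.TrainProtocol(n_stim=8, freq_hz=100.0, n_trains=5000, seed=7)
cm = dk.simulate_trains(params, proto)
stats = dk.summarize(cm)

est = dk.fit_binomial_N([cm.counts[:, 0], cm.counts[:, 1]])
print(f"binomial N estimate: {est.n_int} (P_hat = {est.p_hat:.2f})")

vm = dk.fit_variance_mean(stats)
print(f"variance-mean N estimate: {vm.n_real:.2f} -> N = {vm.n_int}")

print(f"P_1 = {stats.mean_si[0] / est.n_int:.2f}, P_2 = {stats.mean_si[1] / est.n_int:.2f}")

per_site = dk.summarize(cm.per_site(est.n_int))
back = dk.smn_backextrapolate(per_site, protocol=proto, fit_range=(5, 8))
print(f"SMN back-extrapolated RRP: {back.p_back:.2f} SVs per docking site")

prof = dk.covariance_profile(cm)
print(f"covariance peak at i = {prof.argmax_magnitude()}")
```

prints

```
binomial N estimate: 4 (P_hat = 0.73)
variance-mean N estimate: 4.00 -> N = 4
P_1 = 0.81, P_2 = 0.66
SMN back-extrapolated RRP: 1.31 SVs per docking site
covariance peak at i = 2
```

Both counting methods recover the generating `N = 4`. The first two
per-site release probabilities sum to 1.47 — already above the one-vesicle
ceiling of a single-slot site — and the SMN estimate of 1.31 SVs per site
exceeds 1 as well, while remaining an underestimate of the true initial
pool ρ + δ = 1.9 because steady-state replenishment (the late-train slope)
is not zero. The covariance magnitude peaking at the second stimulus is the
two-slot signature: first-AP releases are partly backfilled from the RS
before the second AP.

The same analyses run from the shell:

```sh
docksim simulate counts.csv --delta 0.9 --p-r 0.9 --n-trains 5000 --seed 7
docksim estimate-n counts.csv
docksim smn counts.csv --per-site
docksim fit counts.csv
docksim run config.yaml --outdir out/   # full multi-condition pipeline
```

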