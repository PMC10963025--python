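"""Synthetic single-synapse datasets: count matrices, latency rasters, traces.

This module is the forward model for the whole analysis chain.  It emulates
vesicle-count recordings from a "simple synapse" (one granule-cell to
interneuron contact with N = 2..6 docking sites driven by 8-AP trains at
100–200 Hz, >= 20 independent trains per condition):

* released-SV counts come from the stochastic docking-site simulators, so
  their per-stimulus means, variances and covariances carry the depletion
  structure the estimators assume;
* each released SV receives a latency from a fast/slow exponential mixture —
  the fast component is direct release of docked SVs, the slow component
  emulates two-step release, whose share grows along the train (0% at the
  first AP to 50% at the eighth by default).  Latencies beyond the 5-ms
  window make asynchronous release;
* optionally, events are convolved with a miniature-EPSC template, with
  amplitude depression of closely spaced events and white Gaussian noise, to
  produce current traces for the event-counting pipeline.

What this generator does not emulate: receptor kinetics beyond the simple
amplitude-recovery rule, non-white recording noise, across-train drift, and
heterogeneity of release probability across sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .core_model import (
    CountMatrix,
    EventRaster,
    IPParams,
    ModelParams,
    Scheduling,
    TrainProtocol,
    simulate_trains,
)
from .errors import DataError, ParameterError

__all__ = [
    "LatencyModel",
    "TraceModel",
    "generate_condition_dataset",
    "synthesize_trace",
]


@dataclass(frozen=True)
class LatencyModel:
    """Fast/slow exponential latency mixture for release events.

    ``tau_fast_ms`` is the time constant of direct docked-SV release and
    ``tau_slow_ms`` that of two-step release (defaults 0.47 and 4.0 ms, the
    3 mM Ca values).  ``slow_fraction_by_stimulus`` maps the stimulus index
    to the slow-pathway weight; when omitted, the weight ramps linearly from
    0 at the first AP to 0.5 at the eighth.  ``onset_delay_ms`` shifts the
    whole distribution rightward (0.2 ms emulates the 4-AP condition).
    """

    tau_fast_ms: float = 0.47
    tau_slow_ms: float = 4.0
    slow_fraction_by_stimulus: Optional[Mapping[int, float]] = None
    onset_delay_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_fast_ms < 0 or self.tau_slow_ms < 0:
            raise ParameterError("latency time constants must be >= 0")
        if self.onset_delay_ms < 0:
            raise ParameterError("onset_delay_ms must be >= 0")
        if self.slow_fraction_by_stimulus is not None:
            for i, f in self.slow_fraction_by_stimulus.items():
                if not (0.0 <= f <= 1.0):
                    raise ParameterError(f"slow fraction for stimulus {i} outside [0, 1]")

    def slow_fraction(self, stimulus: int, n_stim: int = 8) -> float:
        """Slow-pathway weight at a (1-based) stimulus index."""
        if self.slow_fraction_by_stimulus is not None:
            return float(self.slow_fraction_by_stimulus.get(stimulus, 0.0))
        if n_stim <= 1:
            return 0.0
        return 0.5 * (stimulus - 1) / (n_stim - 1)


def _truncated_exp(rng: np.random.Generator, tau: float, upper: float, n: int) -> np.ndarray:
    """Exponential(tau) conditioned on [0, upper], by inverse CDF."""
    if n == 0:
        return np.zeros(0)
    if tau <= 0:
        return np.zeros(n)
    u = rng.random(n)
    mass = -math.expm1(-upper / tau)  # 1 - exp(-upper/tau)
    return -tau * np.log1p(-u * mass)


def generate_condition_dataset(
    params: ModelParams,
    protocol: TrainProtocol,
    latency: LatencyModel = LatencyModel(),
    ip: Optional[IPParams] = None,
    scheduling: Scheduling | str = Scheduling.BLOCKED,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[CountMatrix, EventRaster]:
    """Simulate one experimental condition: counts plus a latency raster.

    Counts come from :func:`docksim.core_model.simulate_trains`; every
    released SV then draws a pathway (slow with the per-stimulus mixture
    weight) and a latency from the corresponding exponential, truncated at
    the inter-AP interval so events stay inside their stimulus window.  A
    fixed seed on the protocol makes the whole dataset reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(protocol.seed)
    cm = simulate_trains(params, protocol, ip=ip, scheduling=scheduling, rng=rng)

    trains, stims = np.nonzero(cm.counts)
    reps = cm.counts[trains, stims]
    train_idx = np.repeat(trains, reps).astype(np.int64)
    stim_idx = (np.repeat(stims, reps) + 1).astype(np.int64)
    n_ev = int(reps.sum())

    upper = protocol.interval_ms - latency.onset_delay_ms
    if upper <= 0:
        raise ParameterError("onset delay leaves no room inside the inter-AP interval")
    frac = np.array([latency.slow_fraction(i, protocol.n_stim) for i in stim_idx])
    slow = rng.random(n_ev) < frac
    lat = np.empty(n_ev)
    lat[~slow] = _truncated_exp(rng, latency.tau_fast_ms, upper, int((~slow).sum()))
    lat[slow] = _truncated_exp(rng, latency.tau_slow_ms, upper, int(slow.sum()))
    lat += latency.onset_delay_ms

    events = pd.DataFrame(
        {
            "train": train_idx,
            "stimulus": stim_idx,
            "latency_ms": lat,
            "pathway": np.where(slow, "slow", "fast"),
        }
    )
    raster = EventRaster(events=events, protocol=protocol)
    return cm, raster


@dataclass(frozen=True)
class TraceModel:
    """Miniature-EPSC template and recording model for trace synthesis.

    The template is a rise-filtered double-exponential decay (five
    parameters: rise time, peak amplitude, fast and slow decay constants,
    slow-decay fraction), normalised so its maximum equals ``peak_pA``.
    Closely spaced events are depressed multiplicatively,
    ``a = peak * (1 - depression * exp(-dt / tau_recovery))`` with ``dt`` the
    time since the preceding event, emulating receptor saturation and
    desensitisation.  The template constants are synthetic defaults shaped
    like a fast glutamatergic mEPSC and are all configuration-exposed.
    """

    rise_ms: float = 0.15
    peak_pA: float = 50.0
    decay_fast_ms: float = 1.2
    decay_slow_ms: float = 6.0
    slow_fraction: float = 0.2
    sample_rate_khz: float = 50.0
    noise_sd_pA: float = 2.0
    depression: float = 0.3
    tau_recovery_ms: float = 5.0

    def __post_init__(self) -> None:
        for name in ("rise_ms", "peak_pA", "decay_fast_ms", "decay_slow_ms", "sample_rate_khz"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        if not (0.0 <= self.slow_fraction <= 1.0):
            raise ParameterError("slow_fraction must be in [0, 1]")
        if self.noise_sd_pA < 0:
            raise ParameterError("noise_sd_pA must be >= 0")
        if not (0.0 <= self.depression < 1.0):
            raise ParameterError("depression must be in [0, 1)")

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sample_rate_khz

    def kernel(self, duration_ms: Optional[float] = None) -> np.ndarray:
        """Sampled unit template (peak 1) starting at t = 0."""
        if duration_ms is None:
            duration_ms = self.rise_ms + 8.0 * self.decay_slow_ms
        t = np.arange(0.0, duration_ms, self.dt_ms)
        shape = (1.0 - np.exp(-t / self.rise_ms)) * (
            (1.0 - self.slow_fraction) * np.exp(-t / self.decay_fast_ms)
            + self.slow_fraction * np.exp(-t / self.decay_slow_ms)
        )
        return shape / shape.max()

    def amplitude_factor(self, dt_since_prev_ms: np.ndarray) -> np.ndarray:
        """Recovery-rule amplitude factor for inter-event intervals in ms."""
        return 1.0 - self.depression * np.exp(-np.asarray(dt_since_prev_ms) / self.tau_recovery_ms)


def synthesize_trace(
    raster: EventRaster,
    trace: TraceModel = TraceModel(),
    duration_ms: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render a current trace per train from an event raster.

    Returns ``(times_ms, currents)`` with ``currents`` of shape
    ``(n_trains, n_samples)``: a sum of amplitude-scaled template instances
    at the event times (depressed by the recovery rule for short inter-event
    intervals within a train) plus white Gaussian noise.
    """
    if trace.dt_ms > trace.rise_ms / 2.0:
        raise ParameterError(
            f"sampling interval {trace.dt_ms} ms too coarse for rise time {trace.rise_ms} ms"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    protocol = raster.protocol
    if duration_ms is None:
        duration_ms = protocol.n_stim * protocol.interval_ms + 20.0
    n_samples = int(round(duration_ms / trace.dt_ms))
    times = np.arange(n_samples) * trace.dt_ms
    kernel = trace.kernel() * trace.peak_pA

    currents = np.zeros((protocol.n_trains, n_samples))
    ev = raster.events
    abs_t = raster.absolute_times_ms()
    if np.any(abs_t > duration_ms):
        raise DataError("event times exceed the trace duration")
    for train in range(protocol.n_trains):
        mask = ev["train"].to_numpy() == train
        t_ev = np.sort(abs_t[mask])
        if t_ev.size == 0:
            continue
        dt_prev = np.diff(t_ev, prepend=-np.inf)
        amps = trace.amplitude_factor(dt_prev)
        for t0, a in zip(t_ev, amps):
            i0 = int(round(t0 / trace.dt_ms))
            seg = min(kernel.size, n_samples - i0)
            if seg > 0:
                currents[train, i0 : i0 + seg] += a * kernel[:seg]
    if trace.noise_sd_pA > 0:
        currents += rng.normal(0.0, trace.noise_sd_pA, size=currents.shape)
    return times, currents
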