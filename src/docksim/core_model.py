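"""Discrete-time stochastic simulators of sequential vesicle docking and release.

Two site architectures are implemented for a synapse with ``N`` independent
release units ("docking sites"):

* **RS/DS** — each unit carries a distal *replacement site* (RS) and a proximal
  *docking site* (DS) that can be occupied simultaneously, so a unit holds up
  to two vesicles and the readily releasable pool (RRP) per unit is at most 2.
* **LS/TS** — each unit is a single slot whose vesicle is either *loosely* or
  *tightly* docked; the slot holds at most one vesicle, so the RRP per unit is
  at most 1.

Time is discretised by the stimulus train: each action potential (AP) triggers
release, and the inter-AP interval carries the docking (``r``) and
replenishment (``s``) transitions.  Per AP cycle the update order is

1. *release* — every occupied DS (RS/DS) or tight slot (LS/TS) fuses with
   probability ``p_r`` and increments the per-stimulus count;
2. *docking* — every unit with an empty DS and an occupied RS promotes the RS
   vesicle with probability ``r`` (LS/TS: loose -> tight);
3. *replenishment* — every empty RS (LS/TS: empty slot) refills with
   probability ``s``, optionally drawing from a finite intermediate pool (IP);
4. *IP refill* — each IP vacancy refills from an effectively infinite
   recycling pool with probability ``r_ip``.

Under the default ``blocked`` scheduling a vesicle takes at most one transition
per interval: an SV arriving at the RS in step 3 cannot dock until the next
interval, and an SV docked in step 2 cannot fuse until the next AP.  The
``chained`` and ``split_interval`` variants relax the first constraint (see
:func:`simulate_trains`).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

__all__ = [
    "ModelKind",
    "Scheduling",
    "ModelParams",
    "IPParams",
    "TrainProtocol",
    "CountMatrix",
    "EventRaster",
    "simulate_trains",
    "simulate_events",
    "analytic_P1",
    "analytic_P2_rsds",
    "analytic_mean_si",
    "max_rrp_per_site",
    "rs_occupancy_components",
]


class ModelKind(str, enum.Enum):
    """Site architecture: two-slot sequential (RSDS) or single-slot (LSTS)."""

    RSDS = "rsds"
    LSTS = "lsts"


class Scheduling(str, enum.Enum):
    """Intra-interval ordering of the docking and replenishment transitions.

    ``BLOCKED``
        release -> docking -> replenishment; a vesicle takes at most one
        transition per inter-AP interval (default).
    ``CHAINED``
        as blocked, but a vesicle that entered the RS during the interval gets
        an additional docking draw in the same interval.
    ``SPLIT_INTERVAL``
        the interval is split into two sub-steps, each applying docking then
        replenishment with sub-step probability ``1 - sqrt(1 - p)``; vesicles
        replenished in the first sub-step may dock in the second.
    """

    BLOCKED = "blocked"
    CHAINED = "chained"
    SPLIT_INTERVAL = "split_interval"


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ParameterError(f"{name} must be a probability in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class ModelParams:
    """Transition-probability parameter set of a docking-site model.

    Parameters
    ----------
    model_kind:
        ``RSDS`` or ``LSTS``.
    n_sites:
        Number of independent docking sites per synapse, ``N >= 1``.
    delta:
        Initial occupancy probability of the proximal site (DS; LS/TS: the
        probability that a slot starts in the tight state).
    rho:
        Initial occupancy probability of the distal site (RS; LS/TS: the
        probability that a slot *not* in the tight state holds a loose SV).
    p_r:
        Release probability of a docked (DS / tight) vesicle per AP.
    r:
        Per-interval RS->DS (loose->tight) transition probability.
    s:
        Per-interval replenishment probability of an empty RS (empty slot).
    """

    model_kind: ModelKind = ModelKind.RSDS
    n_sites: int = 4
    delta: float = 0.65
    rho: float = 1.0
    p_r: float = 0.6
    r: float = 0.7
    s: float = 0.35

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_kind", ModelKind(self.model_kind))
        if int(self.n_sites) != self.n_sites or self.n_sites < 1:
            raise ParameterError(f"n_sites must be a positive integer, got {self.n_sites!r}")
        object.__setattr__(self, "n_sites", int(self.n_sites))
        for name in ("delta", "rho", "p_r", "r", "s"):
            object.__setattr__(self, name, _check_prob(name, getattr(self, name)))


#: Fitted parameter sets for the three experimental conditions
#: (3 mM Ca control, 4-AP, and post-tetanic potentiation), all with rho = 1.
CONDITION_PARAMS: Mapping[str, ModelParams] = {
    "control": ModelParams(delta=0.65, rho=1.0, p_r=0.6, r=0.7, s=0.35),
    "4ap": ModelParams(delta=0.8, rho=1.0, p_r=0.9, r=0.7, s=0.35),
    "ptp": ModelParams(delta=0.9, rho=1.0, p_r=0.9, r=0.7, s=0.35),
}


@dataclass(frozen=True)
class IPParams:
    """Finite intermediate pool (IP) feeding the replacement sites.

    ``ip_size0`` vesicles per synapse at train onset; each vacancy refills from
    an infinite recycling pool with per-interval probability ``r_ip``.  When
    ``couple_s_to_ip`` is set, the replenishment probability ``s`` is scaled by
    the IP filling fraction (current size / initial size).
    """

    ip_size0: int = 12
    r_ip: float = 0.2
    couple_s_to_ip: bool = True

    def __post_init__(self) -> None:
        if int(self.ip_size0) != self.ip_size0 or self.ip_size0 < 0:
            raise ParameterError(f"ip_size0 must be a non-negative integer, got {self.ip_size0!r}")
        object.__setattr__(self, "ip_size0", int(self.ip_size0))
        _check_prob("r_ip", self.r_ip)


@dataclass(frozen=True)
class TrainProtocol:
    """Stimulation protocol: ``n_stim`` APs at ``freq_hz``, ``n_trains`` repeats."""

    n_stim: int = 8
    freq_hz: float = 100.0
    n_trains: int = 5000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_stim < 1:
            raise ParameterError(f"n_stim must be >= 1, got {self.n_stim!r}")
        if self.n_trains < 1:
            raise ParameterError(f"n_trains must be >= 1, got {self.n_trains!r}")
        if not self.freq_hz > 0:
            raise ParameterError(f"freq_hz must be positive, got {self.freq_hz!r}")

    @property
    def interval_ms(self) -> float:
        """Inter-AP interval in milliseconds."""
        return 1000.0 / self.freq_hz

    def stimulus_times_ms(self) -> np.ndarray:
        """Absolute AP times within a train, first AP at t = 0."""
        return np.arange(self.n_stim) * self.interval_ms


@dataclass(frozen=True)
class CountMatrix:
    """Per-train, per-stimulus released-SV counts (the central observable).

    ``counts[t, i]`` is the number of vesicles released synchronously with
    stimulus ``i + 1`` in train ``t``.  Counts are stored per synapse;
    per-site values are a view obtained by dividing by the site number.
    """

    counts: np.ndarray
    protocol: TrainProtocol
    normalization: str = "per_synapse"
    params: Optional[ModelParams] = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise DataError(f"counts must be 2-D (trains x stimuli), got shape {counts.shape}")
        if counts.shape != (self.protocol.n_trains, self.protocol.n_stim):
            raise DataError(
                f"counts shape {counts.shape} does not match protocol "
                f"({self.protocol.n_trains} trains x {self.protocol.n_stim} stimuli)"
            )
        if np.any(counts < 0):
            raise DataError("counts must be non-negative")
        if self.normalization not in ("per_synapse", "per_site"):
            raise DataError(f"unknown normalization {self.normalization!r}")
        object.__setattr__(self, "counts", counts)

    @property
    def n_trains(self) -> int:
        return self.counts.shape[0]

    @property
    def n_stim(self) -> int:
        return self.counts.shape[1]

    def per_site(self, n_sites: Optional[int] = None) -> np.ndarray:
        """Counts divided by the docking-site number (a float view)."""
        if n_sites is None:
            if self.params is None:
                raise DataError("n_sites required when the matrix carries no model params")
            n_sites = self.params.n_sites
        return self.counts / float(n_sites)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"stim_{i + 1}" for i in range(self.n_stim)]
        return pd.DataFrame(self.counts, columns=cols)


@dataclass(frozen=True)
class EventRaster:
    """Per-release-event records: train index, stimulus index, latency, pathway.

    Latencies are measured from the onset of the triggering stimulus, in ms.
    ``pathway`` tags the generating latency component (``fast`` for direct
    docked-SV release, ``slow`` for two-step release).
    """

    events: pd.DataFrame
    protocol: TrainProtocol

    _COLUMNS = ("train", "stimulus", "latency_ms", "pathway")

    def __post_init__(self) -> None:
        missing = [c for c in self._COLUMNS if c not in self.events.columns]
        if missing:
            raise DataError(f"event raster missing columns {missing}")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def absolute_times_ms(self) -> np.ndarray:
        """Event times from train onset (stimulus time + latency)."""
        stim_t = (self.events["stimulus"].to_numpy() - 1) * self.protocol.interval_ms
        return stim_t + self.events["latency_ms"].to_numpy()


def _substep_prob(p: float) -> float:
    # probability per half-interval such that two independent chances compose to p
    return 1.0 - math.sqrt(1.0 - p)


def _dock_replenish_rsds(
    rs: np.ndarray,
    ds: np.ndarray,
    ip_count: Optional[np.ndarray],
    params: ModelParams,
    ip: Optional[IPParams],
    scheduling: Scheduling,
    rng: np.random.Generator,
    rs_origin: Optional[np.ndarray] = None,
) -> None:
    """Apply the inter-AP transitions in place for the RS/DS model.

    ``rs_origin`` (optional int8 array, 0 = initial-pool SV, 1 = replenished
    SV) is kept in sync when provided; used by the occupancy diagnostic.
    """
    shape = rs.shape

    def dock(prob: float, eligible: np.ndarray) -> None:
        move = eligible & rs & ~ds & (rng.random(shape) < prob)
        ds[move] = True
        rs[move] = False

    def replenish(prob: float) -> np.ndarray:
        if ip is not None and ip.couple_s_to_ip and ip.ip_size0 > 0:
            frac = ip_count / float(ip.ip_size0)
            eff = prob * frac[:, None]
        else:
            eff = np.full((shape[0], 1), prob)
        want = ~rs & (rng.random(shape) < eff)
        if ip is not None:
            # exchangeable sites: grant refills in site order up to the IP stock
            allowed = np.cumsum(want, axis=1) <= ip_count[:, None]
            want &= allowed
            ip_count[:] -= want.sum(axis=1)
        rs[want] = True
        if rs_origin is not None:
            rs_origin[want] = 1
        return want

    everywhere = np.ones(shape, dtype=bool)
    if scheduling is Scheduling.SPLIT_INTERVAL:
        r_h, s_h = _substep_prob(params.r), _substep_prob(params.s)
        dock(r_h, everywhere)
        replenish(s_h)
        dock(r_h, everywhere)
        replenish(s_h)
    else:
        dock(params.r, everywhere)
        arrived = replenish(params.s)
        if scheduling is Scheduling.CHAINED:
            dock(params.r, arrived)


def _simulate_rsds(
    params: ModelParams,
    protocol: TrainProtocol,
    ip: Optional[IPParams],
    scheduling: Scheduling,
    rng: np.random.Generator,
) -> np.ndarray:
    shape = (protocol.n_trains, params.n_sites)
    ds = rng.random(shape) < params.delta
    rs = rng.random(shape) < params.rho
    ip_count = np.full(protocol.n_trains, ip.ip_size0) if ip is not None else None

    counts = np.zeros((protocol.n_trains, protocol.n_stim), dtype=np.int64)
    for i in range(protocol.n_stim):
        fuse = ds & (rng.random(shape) < params.p_r)
        counts[:, i] = fuse.sum(axis=1)
        ds &= ~fuse
        _dock_replenish_rsds(rs, ds, ip_count, params, ip, scheduling, rng)
        if ip is not None and ip.ip_size0 > 0:
            vacancies = ip.ip_size0 - ip_count
            ip_count += rng.binomial(vacancies, ip.r_ip)
    return counts


def _simulate_lsts(
    params: ModelParams,
    protocol: TrainProtocol,
    ip: Optional[IPParams],
    scheduling: Scheduling,
    rng: np.random.Generator,
) -> np.ndarray:
    # slot state: 0 empty, 1 loose, 2 tight; at most one SV per slot
    shape = (protocol.n_trains, params.n_sites)
    state = np.zeros(shape, dtype=np.int8)
    tight0 = rng.random(shape) < params.delta
    loose0 = ~tight0 & (rng.random(shape) < params.rho)
    state[tight0] = 2
    state[loose0] = 1
    ip_count = np.full(protocol.n_trains, ip.ip_size0) if ip is not None else None

    def dock(prob: float, eligible: np.ndarray) -> None:
        move = eligible & (state == 1) & (rng.random(shape) < prob)
        state[move] = 2

    def replenish(prob: float) -> np.ndarray:
        if ip is not None and ip.couple_s_to_ip and ip.ip_size0 > 0:
            eff = prob * (ip_count / float(ip.ip_size0))[:, None]
        else:
            eff = np.full((shape[0], 1), prob)
        want = (state == 0) & (rng.random(shape) < eff)
        if ip is not None:
            allowed = np.cumsum(want, axis=1) <= ip_count[:, None]
            want &= allowed
            ip_count[:] -= want.sum(axis=1)
        state[want] = 1
        return want

    counts = np.zeros((protocol.n_trains, protocol.n_stim), dtype=np.int64)
    everywhere = np.ones(shape, dtype=bool)
    for i in range(protocol.n_stim):
        fuse = (state == 2) & (rng.random(shape) < params.p_r)
        counts[:, i] = fuse.sum(axis=1)
        state[fuse] = 0
        if scheduling is Scheduling.SPLIT_INTERVAL:
            r_h, s_h = _substep_prob(params.r), _substep_prob(params.s)
            dock(r_h, everywhere)
            replenish(s_h)
            dock(r_h, everywhere)
            replenish(s_h)
        else:
            dock(params.r, everywhere)
            arrived = replenish(params.s)
            if scheduling is Scheduling.CHAINED:
                dock(params.r, arrived)
        if ip is not None and ip.ip_size0 > 0:
            vacancies = ip.ip_size0 - ip_count
            ip_count += rng.binomial(vacancies, ip.r_ip)
    return counts


def simulate_trains(
    params: ModelParams,
    protocol: TrainProtocol,
    ip: Optional[IPParams] = None,
    scheduling: Scheduling | str = Scheduling.BLOCKED,
    rng: Optional[np.random.Generator] = None,
) -> CountMatrix:
    """Monte Carlo simulation of released-SV counts for a train protocol.

    Sites are independent within and across trains; trains are independent
    repetitions with freshly drawn initial occupancies (no carryover).  One
    seeded generator drives the whole call; uniform draws are consumed in the
    fixed order (initial DS, initial RS, then per stimulus: release, docking,
    replenishment[, chained docking], IP refill), so a given seed reproduces
    the counts bit for bit.

    Returns a :class:`CountMatrix` of per-synapse counts.
    """
    scheduling = Scheduling(scheduling)
    if rng is None:
        rng = np.random.default_rng(protocol.seed)
    if params.model_kind is ModelKind.RSDS:
        counts = _simulate_rsds(params, protocol, ip, scheduling, rng)
    else:
        counts = _simulate_lsts(params, protocol, ip, scheduling, rng)
    return CountMatrix(counts=counts, protocol=protocol, params=params)


def simulate_events(
    params: ModelParams,
    protocol: TrainProtocol,
    latency,
    ip: Optional[IPParams] = None,
    scheduling: Scheduling | str = Scheduling.BLOCKED,
    rng: Optional[np.random.Generator] = None,
) -> EventRaster:
    """Simulate a train and attach release latencies to every counted SV.

    The discrete-time model has no intra-interval fusion, so every simulated
    release is a direct docked-SV event and draws from the *fast* latency
    component only (exponential with ``latency.tau_fast_ms`` plus
    ``latency.onset_delay_ms``).  Mixture rasters with a slow (two-step)
    component are produced by :func:`docksim.synthetic_data.generate_condition_dataset`.
    """
    if rng is None:
        rng = np.random.default_rng(protocol.seed)
    cm = simulate_trains(params, protocol, ip=ip, scheduling=scheduling, rng=rng)
    counts = cm.counts
    trains, stims = np.nonzero(counts)
    reps = counts[trains, stims]
    train_idx = np.repeat(trains, reps)
    stim_idx = np.repeat(stims, reps) + 1
    n_ev = int(reps.sum())
    tau = float(latency.tau_fast_ms)
    onset = float(getattr(latency, "onset_delay_ms", 0.0))
    lat = onset + (rng.exponential(tau, size=n_ev) if tau > 0 else np.zeros(n_ev))
    events = pd.DataFrame(
        {
            "train": train_idx.astype(np.int64),
            "stimulus": stim_idx.astype(np.int64),
            "latency_ms": lat,
            "pathway": "fast",
        }
    )
    return EventRaster(events=events, protocol=protocol)


def analytic_P1(params: ModelParams) -> float:
    """Closed-form per-site release probability at the first AP: ``delta * p_r``."""
    return params.delta * params.p_r


def analytic_P2_rsds(params: ModelParams, method: str = "exact") -> float:
    """Per-site release probability at the second AP of the RS/DS model.

    ``method="exact"`` evaluates the one-step recursion under the blocked
    update order,

        P2 = p_r * [delta (1 - p_r) + (1 - delta (1 - p_r)) * rho * r],

    i.e. the DS is still occupied after AP 1 (survived release) or was refilled
    from an initially occupied RS during the interval.  ``method="approx"``
    returns the high-``p_r`` shorthand ``rho * r * p_r`` (exact when the first
    AP empties every DS).
    """
    if params.model_kind is not ModelKind.RSDS:
        raise ParameterError("analytic_P2_rsds requires RSDS params")
    if method == "approx":
        return params.rho * params.r * params.p_r
    if method != "exact":
        raise ParameterError(f"unknown method {method!r}")
    survive = params.delta * (1.0 - params.p_r)
    refill = (1.0 - survive) * params.rho * params.r
    return params.p_r * (survive + refill)


def analytic_mean_si(
    params: ModelParams,
    n_stim: int = 8,
    scheduling: Scheduling | str = Scheduling.BLOCKED,
) -> np.ndarray:
    """Exact per-site mean released-SV counts ``E[s_i]/N`` for i = 1..n_stim.

    Sites evolve as independent Markov chains, so per-site means follow from
    iterating the single-site occupancy distribution; multiply by ``n_sites``
    for per-synapse means.  Supports both model kinds and all scheduling
    variants; the (finite) intermediate pool breaks site independence and is
    not covered here — use the simulator for IP conditions.
    """
    return _mean_si_markov(
        params.model_kind,
        params.delta,
        params.rho,
        params.p_r,
        params.r,
        params.s,
        n_stim,
        Scheduling(scheduling),
    )


def _mean_si_markov(model_kind, d, rho, p, r, s, n_stim, scheduling):
    """Single-site occupancy recursion; broadcasts over parameter arrays.

    Returns an array of shape ``broadcast(params).shape + (n_stim,)`` (or a
    length-``n_stim`` vector for scalar inputs).
    """
    d, rho, p, r, s = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (d, rho, p, r, s))
    )
    means = np.empty(d.shape + (n_stim,))

    sub = lambda x: 1.0 - np.sqrt(1.0 - x)  # noqa: E731 - half-interval probability

    if model_kind is ModelKind.RSDS:
        # joint occupancy (rs, ds): probabilities p00, p01, p10, p11
        p11 = rho * d
        p10 = rho * (1 - d)
        p01 = (1 - rho) * d
        p00 = (1 - rho) * (1 - d)

        def dock(p00, p01, p10, p11, prob):
            move = p10 * prob
            return p00, p01 + move, p10 - move, p11

        def replenish(p00, p01, p10, p11, prob):
            up0, up1 = p00 * prob, p01 * prob
            # returns the newly-replenished mass split by ds state
            return (p00 - up0, p01 - up1, p10 + up0, p11 + up1), (up0, up1)

        for i in range(n_stim):
            docked = p01 + p11
            means[..., i] = docked * p
            rel0, rel1 = p01 * p, p11 * p
            p00, p01 = p00 + rel0, p01 - rel0
            p10, p11 = p10 + rel1, p11 - rel1
            if scheduling is Scheduling.SPLIT_INTERVAL:
                r_h, s_h = sub(r), sub(s)
                p00, p01, p10, p11 = dock(p00, p01, p10, p11, r_h)
                (p00, p01, p10, p11), _ = replenish(p00, p01, p10, p11, s_h)
                p00, p01, p10, p11 = dock(p00, p01, p10, p11, r_h)
                (p00, p01, p10, p11), _ = replenish(p00, p01, p10, p11, s_h)
            else:
                p00, p01, p10, p11 = dock(p00, p01, p10, p11, r)
                (p00, p01, p10, p11), (up0, _) = replenish(p00, p01, p10, p11, s)
                if scheduling is Scheduling.CHAINED:
                    move = up0 * r  # fresh RS mass with empty DS docks in-interval
                    p10, p01 = p10 - move, p01 + move
        return means

    # LSTS: slot state distribution (empty, loose, tight)
    pt = d * np.ones_like(d)
    pl = (1 - d) * rho
    pe = 1 - pt - pl

    for i in range(n_stim):
        means[..., i] = pt * p
        rel = pt * p
        pt, pe = pt - rel, pe + rel
        if scheduling is Scheduling.SPLIT_INTERVAL:
            r_h, s_h = sub(r), sub(s)
            for _ in range(2):
                move = pl * r_h
                pl, pt = pl - move, pt + move
                up = pe * s_h
                pe, pl = pe - up, pl + up
        else:
            move = pl * r
            pl, pt = pl - move, pt + move
            up = pe * s
            pe, pl = pe - up, pl + up
            if scheduling is Scheduling.CHAINED:
                move = up * r
                pl, pt = pl - move, pt + move
    return means


def max_rrp_per_site(
    model_kind: ModelKind | str,
    delta: float = 1.0,
    rho: float = 1.0,
    n_stim: int = 8,
) -> int:
    """Total SVs released per site over a train in the deterministic limit.

    Runs the simulator at full transition probabilities (``p_r = r = 1``) with
    no replenishment (``s = 0``); with ``delta = rho = 1`` this realises the
    maximum readily releasable pool per docking site: 2 for RS/DS (the docked
    SV plus the replacement SV that docks during the first interval), 1 for
    LS/TS (the single slot can never hold a second SV).
    """
    params = ModelParams(
        model_kind=ModelKind(model_kind), n_sites=1, delta=delta, rho=rho, p_r=1.0, r=1.0, s=0.0
    )
    protocol = TrainProtocol(n_stim=n_stim, freq_hz=100.0, n_trains=1, seed=0)
    cm = simulate_trains(params, protocol)
    total = int(cm.counts.sum())
    assert total % params.n_sites == 0
    return total // params.n_sites


def rs_occupancy_components(
    params: ModelParams,
    stimulus: int = 2,
    scheduling: Scheduling | str = Scheduling.BLOCKED,
    n_trains: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Replacement-site occupancy just before a given AP, split by SV origin.

    Returns ``(total, from_replenishment)`` — the mean probability that the RS
    is occupied at the time of AP ``stimulus`` and the part of that occupancy
    carried by SVs that entered via the ``s`` transition (rather than being
    present at train onset).  Estimated by tagged Monte Carlo; used to audit
    how much of the second-AP response can come from upstream replenishment.
    """
    if params.model_kind is not ModelKind.RSDS:
        raise ParameterError("occupancy diagnostic is defined for the RSDS model")
    if stimulus < 1:
        raise ParameterError("stimulus must be >= 1")
    scheduling = Scheduling(scheduling)
    rng = np.random.default_rng(seed)
    shape = (n_trains, params.n_sites)
    ds = rng.random(shape) < params.delta
    rs = rng.random(shape) < params.rho
    origin = np.zeros(shape, dtype=np.int8)

    for i in range(stimulus - 1):
        fuse = ds & (rng.random(shape) < params.p_r)
        ds &= ~fuse
        _dock_replenish_rsds(rs, ds, None, params, None, scheduling, rng, rs_origin=origin)
    total = float(rs.mean())
    repl = float((rs & (origin == 1)).mean())
    return total, repl
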