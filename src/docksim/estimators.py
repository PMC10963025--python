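"""Statistics computed from release-count matrices and event rasters.

Covers the full train-response toolbox: per-stimulus summaries, docking-site
number estimation (binomial fit and variance–mean parabola), covariance
profiling of successive release counts, cumulative-release back-extrapolation
of the readily releasable pool (SMN method), depression and paired-pulse
metrics, biexponential latency fitting, and the arithmetic that bounds the
contribution of upstream replenishment to early-train release.

Variances and covariances use population normalisation (divide by ``n``) by
default, matching the moment definition of the covariance statistic
``cov(S_i, s_{i+1}) = <(S_i - <S_i>)(s_{i+1} - <s_{i+1}>)>``; pass ``ddof=1``
where offered for sample normalisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_model import CountMatrix, EventRaster, TrainProtocol
from .errors import DataError, FitError, ParameterError

__all__ = [
    "StimulusStats",
    "NEstimate",
    "CovarianceProfile",
    "BackExtrapolationResult",
    "DepressionMetrics",
    "LatencyFit",
    "ReplenishmentBreakdown",
    "summarize",
    "fit_binomial_N",
    "fit_variance_mean",
    "covariance_profile",
    "smn_backextrapolate",
    "depression_metrics",
    "classify_sync_async",
    "fit_latency_biexp",
    "two_step_ratio",
    "replenishment_contribution",
]


@dataclass(frozen=True)
class StimulusStats:
    """Per-stimulus moments of a count matrix.

    ``mean_si[i]``, ``var_si[i]`` and ``cum_Si[i]`` are the mean, variance and
    mean cumulative count for stimulus ``i + 1``; ``n_sites``, when known,
    allows per-site release probabilities ``P_i = <s_i> / N``.
    """

    mean_si: np.ndarray
    var_si: np.ndarray
    cum_Si: np.ndarray
    n_trains: int
    n_sites: Optional[int] = None
    protocol: Optional[TrainProtocol] = None

    @property
    def n_stim(self) -> int:
        return len(self.mean_si)

    @property
    def p_i(self) -> np.ndarray:
        """Per-site release probability ``<s_i> / N`` (requires ``n_sites``)."""
        if self.n_sites is None:
            raise DataError("P_i requires a docking-site number; set n_sites")
        return self.mean_si / float(self.n_sites)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "i": np.arange(1, self.n_stim + 1),
                "mean": self.mean_si,
                "var": self.var_si,
                "cum": self.cum_Si,
            }
        )
        if self.n_sites is not None:
            out["P_i"] = self.p_i
        return out


@dataclass(frozen=True)
class NEstimate:
    """Docking-site number estimate from one of the two counting methods."""

    method: str
    n_real: float
    n_int: Optional[int]
    fit_error: float
    stderr: Optional[float] = None
    p_hat: Optional[float] = None
    indeterminate: bool = False
    failed: bool = False


@dataclass(frozen=True)
class CovarianceProfile:
    """``cov(S_i, s_{i+1})`` for i = 1..n_stim-1 (population normalisation)."""

    cov: np.ndarray
    n_trains: int

    def argmax_magnitude(self) -> int:
        """1-based stimulus index i at which |cov(S_i, s_{i+1})| is largest."""
        return int(np.argmax(np.abs(self.cov))) + 1


@dataclass(frozen=True)
class BackExtrapolationResult:
    """Back-extrapolated RRP estimate from late-train cumulative release."""

    p_back: float
    slope_per_ap: float
    slope_per_ms: float
    fit_stim_range: Tuple[int, int]
    times_ms: np.ndarray
    cum_means: np.ndarray


@dataclass(frozen=True)
class DepressionMetrics:
    """Paired-pulse ratio, steady-state depression ratio, and decay constant."""

    ppr: float
    depression_ratio: float
    decay_tau_intervals: float
    decay_tau_ms: float
    decay_amplitude: float = math.nan
    flagged: bool = False


@dataclass(frozen=True)
class LatencyFit:
    """Two-component exponential mixture fit of release latencies."""

    tau_fast_ms: float
    tau_slow_ms: float
    slow_fraction: float
    extra_delay_ms: float = 0.0
    log_likelihood: float = math.nan
    degenerate: bool = False


@dataclass(frozen=True)
class ReplenishmentBreakdown:
    """Inputs of the replenishment-contribution calculus.

    ``rho2_total`` is the replacement-site occupancy at the second AP and
    ``rho2_replenishment`` the part of it contributed by SVs recruited from
    upstream pools during the first interval.  Replacement-site SVs can only
    release via the two-step pathway, whose share of the synchronous
    measurement window is ``twostep_amp * (1 - exp(-window/tau))``.
    """

    rho2_total: float
    rho2_replenishment: float
    twostep_amp: float = 0.2
    window_ms: float = 5.0
    tau_twostep_ms: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho2_replenishment <= self.rho2_total <= 1.0):
            raise ParameterError(
                "require 0 <= rho2_replenishment <= rho2_total <= 1, got "
                f"{self.rho2_replenishment!r}, {self.rho2_total!r}"
            )

    @property
    def twostep_ratio(self) -> float:
        return two_step_ratio(self.twostep_amp, self.window_ms, self.tau_twostep_ms)


def summarize(
    counts: Union[CountMatrix, np.ndarray],
    n_sites: Optional[int] = None,
    ddof: int = 0,
) -> StimulusStats:
    """Per-stimulus mean, variance and cumulative mean of a count matrix."""
    protocol = None
    if isinstance(counts, CountMatrix):
        protocol = counts.protocol
        if n_sites is None and counts.params is not None:
            n_sites = counts.params.n_sites
        counts = counts.counts
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise DataError("counts must be 2-D (trains x stimuli)")
    if counts.shape[0] < 2:
        raise DataError("variance undefined: need at least 2 trains")
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=ddof)
    cum = np.cumsum(mean)
    return StimulusStats(
        mean_si=mean,
        var_si=var,
        cum_Si=cum,
        n_trains=counts.shape[0],
        n_sites=n_sites,
        protocol=protocol,
    )


def _binomial_fit_one(counts: np.ndarray, n: int, objective: str) -> Tuple[float, float]:
    """Best-fit P and its objective value for candidate N."""
    if objective == "sse":
        freqs = np.bincount(counts, minlength=n + 1).astype(float)
        freqs /= counts.size
        k = np.arange(n + 1)

        def fun(p: float) -> float:
            return float(np.sum((freqs - stats.binom.pmf(k, n, p)) ** 2))
    else:  # negative multinomial log-likelihood

        def fun(p: float) -> float:
            return -float(stats.binom.logpmf(counts, n, min(max(p, 1e-9), 1 - 1e-9)).sum())

    res = optimize.minimize_scalar(fun, bounds=(0.0, 1.0), method="bounded")
    return float(res.x), float(res.fun)


def fit_binomial_N(
    counts: Union[np.ndarray, Sequence[np.ndarray]],
    n_range: Sequence[int] = range(1, 11),
    objective: str = "sse",
) -> NEstimate:
    """Estimate the docking-site number by fitting binomial count frequencies.

    ``counts`` holds integer per-train release counts at one stimulus, or a
    sequence of such arrays (e.g. ``[s_1, s_2]``) fitted jointly by summing
    the per-stimulus squared deviations.  For every candidate ``N`` the
    release probability ``P`` minimises the summed squared deviation between
    the empirical relative frequencies of ``k = 0..N`` and the binomial pmf
    ``C(N, k) P^k (1 - P)^(N-k)``; the returned ``N`` minimises that error
    (ties broken toward the smaller ``N``).  ``objective="likelihood"``
    selects ``N`` by multinomial maximum likelihood instead, which separates
    adjacent ``N`` candidates more sharply on small samples; the selected
    ``N`` may differ from the squared-deviation choice.

    All-zero counts leave ``N`` unidentified and return an estimate flagged
    ``indeterminate``.  Candidates below the largest observed count are
    impossible and excluded; if the whole range is excluded a
    :class:`~docksim.errors.DataError` is raised.
    """
    if isinstance(counts, np.ndarray) and counts.ndim == 1:
        arrays = [counts]
    elif isinstance(counts, np.ndarray):
        raise DataError("counts must be 1-D per stimulus")
    else:
        arrays = list(counts)
    arrays = [np.asarray(a) for a in arrays]
    for a in arrays:
        if a.size == 0:
            raise DataError("empty count array")
        if not np.issubdtype(a.dtype, np.integer):
            if not np.all(a == np.floor(a)):
                raise DataError("counts must be integers")
            a = a.astype(np.int64)
        if np.any(a < 0):
            raise DataError("counts must be non-negative")
    arrays = [a.astype(np.int64) for a in arrays]

    max_count = max(int(a.max()) for a in arrays)
    if max_count == 0:
        return NEstimate(
            method="binomial",
            n_real=math.nan,
            n_int=None,
            fit_error=0.0,
            p_hat=0.0,
            indeterminate=True,
        )
    candidates = [n for n in n_range if n >= max(max_count, 1)]
    if not candidates:
        raise DataError(
            f"no candidate N can support the data: max observed count {max_count} "
            f"exceeds the candidate range"
        )

    if objective not in ("sse", "likelihood"):
        raise ParameterError(f"unknown objective {objective!r}")
    best = None
    for n in candidates:
        p_tot, err_tot = 0.0, 0.0
        for a in arrays:
            p, err = _binomial_fit_one(a, n, objective)
            p_tot += p
            err_tot += err
        if best is None or err_tot < best[1] - 1e-15:
            best = (n, err_tot, p_tot / len(arrays))
    n_best, err_best, p_best = best
    return NEstimate(
        method="binomial", n_real=float(n_best), n_int=n_best, fit_error=err_best, p_hat=p_best
    )


def fit_variance_mean(stats_: StimulusStats) -> NEstimate:
    """Estimate the docking-site number from the variance–mean parabola.

    Fits ``var = m - m^2 / N`` (initial slope fixed at 1, zero intercept) to
    the per-stimulus (mean, variance) points by unweighted least squares with
    ``N`` the single free parameter; the parabola's positive x-intercept is
    the maximal mean output and hence the site number.  ``N_int`` is the
    nearest integer; the standard error comes from the fit curvature.

    Degenerate inputs (all variances zero, or a non-positive fitted ``N``)
    return an estimate flagged ``failed`` with ``n_real`` at the maximal
    observed mean.
    """
    m = np.asarray(stats_.mean_si, dtype=float)
    v = np.asarray(stats_.var_si, dtype=float)
    keep = m > 0
    m, v = m[keep], v[keep]
    if len(np.unique(m)) < 3:
        raise DataError("variance-mean fit needs >= 3 stimulus points with distinct means")
    m_max = float(m.max())
    if np.allclose(v, 0.0):
        return NEstimate(
            method="variance_mean",
            n_real=m_max,
            n_int=max(1, round(m_max)),
            fit_error=0.0,
            failed=True,
        )

    def model(mm: np.ndarray, n: float) -> np.ndarray:
        return mm - mm**2 / n

    p0 = m_max + 1.0
    try:
        popt, pcov = optimize.curve_fit(model, m, v, p0=[p0], maxfev=10_000)
    except RuntimeError as exc:  # pragma: no cover - curve_fit rarely fails here
        raise FitError(f"variance-mean fit did not converge: {exc}") from exc
    n_real = float(popt[0])
    resid = v - model(m, n_real)
    fit_error = float(np.sum(resid**2))
    stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else None
    if n_real <= 0:
        return NEstimate(
            method="variance_mean", n_real=n_real, n_int=None, fit_error=fit_error, failed=True
        )
    return NEstimate(
        method="variance_mean",
        n_real=n_real,
        n_int=max(1, round(n_real)),
        fit_error=fit_error,
        stderr=stderr,
    )


def covariance_profile(counts: Union[CountMatrix, np.ndarray]) -> CovarianceProfile:
    """Covariance between cumulative release ``S_i`` and the next count ``s_{i+1}``.

    Uses the population moment ``<(S_i - <S_i>)(s_{i+1} - <s_{i+1}>)>``.
    Depletion without replenishment makes every entry non-positive in
    expectation: trains that have already released much have less left.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise DataError("need a 2-D count matrix with >= 2 stimuli")
    if counts.shape[0] < 2:
        raise DataError("covariance undefined for a single train")
    S = np.cumsum(counts, axis=1)
    dS = S - S.mean(axis=0)
    ds = counts - counts.mean(axis=0)
    cov = np.array([np.mean(dS[:, i] * ds[:, i + 1]) for i in range(counts.shape[1] - 1)])
    return CovarianceProfile(cov=cov, n_trains=counts.shape[0])


def smn_backextrapolate(
    data: Union[CountMatrix, StimulusStats, np.ndarray],
    protocol: Optional[TrainProtocol] = None,
    fit_range: Tuple[int, int] = (5, 8),
    window_ms: float = 5.0,
) -> BackExtrapolationResult:
    """RRP estimate by back-extrapolation of cumulative synchronous release.

    Cumulative mean counts are plotted against time at ``t_i = stimulus time +
    window_ms`` (measurements are complete 5 ms after each AP); a regression
    line through the late-train points (stimulus indices ``fit_range``,
    inclusive, 1-based) is extrapolated back to the first measurement time
    ``t_1``.  The intercept ``P_back`` estimates the pool released by the
    train over and above steady-state replenishment, and the slope (converted
    to SVs per AP) estimates that replenishment rate.

    When the synapse does not depress completely, early release still rides on
    replenishment and ``P_back`` underestimates the true pool.
    """
    if isinstance(data, StimulusStats):
        cum = np.asarray(data.cum_Si, dtype=float)
        protocol = protocol or data.protocol
    else:
        stats_ = summarize(data)
        cum = stats_.cum_Si
        protocol = protocol or stats_.protocol
    if protocol is None:
        raise DataError("a TrainProtocol is required to place points in time")
    lo, hi = fit_range
    if not (1 <= lo < hi <= len(cum)):
        raise DataError(f"fit_range {fit_range} needs >= 2 points inside the train")
    times = protocol.stimulus_times_ms() + window_ms
    idx = np.arange(lo - 1, hi)
    slope, intercept = np.polyfit(times[idx], cum[idx], 1)
    p_back = float(slope * times[0] + intercept)
    return BackExtrapolationResult(
        p_back=p_back,
        slope_per_ap=float(slope * protocol.interval_ms),
        slope_per_ms=float(slope),
        fit_stim_range=(lo, hi),
        times_ms=times,
        cum_means=cum,
    )


def depression_metrics(
    stats_: StimulusStats,
    protocol: Optional[TrainProtocol] = None,
    fit_range: Optional[Tuple[int, int]] = None,
) -> DepressionMetrics:
    """Paired-pulse ratio, steady-state depression ratio, and decay constant.

    * ``ppr`` = ``<s_2> / <s_1>``;
    * ``depression_ratio`` = steady-state synchronous release per AP (slope of
      the regression line through late-train cumulative release, default the
      last four stimuli) divided by ``<s_1>``;
    * exponential fall-off of ``<s_i>`` for ``i > 2`` with the asymptote fixed
      at zero, fitted in stimulus-index space and converted to ms with the
      inter-AP interval.

    A constant tail (no decay) is reported as an infinite time constant with
    the ``flagged`` bit set, as is an undefined ratio when ``<s_1> = 0``.
    """
    protocol = protocol or stats_.protocol
    if protocol is None:
        raise DataError("a TrainProtocol is required for time conversion")
    m = np.asarray(stats_.mean_si, dtype=float)
    if len(m) < 2:
        raise DataError("need >= 2 stimuli")
    flagged = False
    if m[0] == 0:
        ppr = math.nan
        dep_ratio = math.nan
        flagged = True
    else:
        ppr = float(m[1] / m[0])
        if fit_range is None:
            fit_range = (max(2, len(m) - 3), len(m))
        back = smn_backextrapolate(stats_, protocol=protocol, fit_range=fit_range)
        dep_ratio = float(back.slope_per_ap / m[0])

    tau_iv, amp = math.nan, math.nan
    tail = m[2:]
    if len(tail) >= 2 and np.any(tail > 0):
        i_rel = np.arange(len(tail), dtype=float)  # 0 at i = 3
        if np.ptp(tail) < 1e-12 * max(1.0, tail.max()):
            tau_iv = math.inf
            amp = float(tail[0])
            flagged = True
        else:
            try:
                popt, _ = optimize.curve_fit(
                    lambda x, a, tau: a * np.exp(-x / tau),
                    i_rel,
                    tail,
                    p0=[float(tail[0]), 1.5],
                    bounds=([0.0, 1e-6], [np.inf, np.inf]),
                    maxfev=10_000,
                )
                amp, tau_iv = float(popt[0]), float(popt[1])
            except RuntimeError:
                flagged = True
    tau_ms = tau_iv * protocol.interval_ms if math.isfinite(tau_iv) else tau_iv
    return DepressionMetrics(
        ppr=ppr,
        depression_ratio=dep_ratio,
        decay_tau_intervals=tau_iv,
        decay_tau_ms=tau_ms,
        decay_amplitude=amp,
        flagged=flagged,
    )


def classify_sync_async(raster: EventRaster, window_ms: float = 5.0) -> EventRaster:
    """Tag every event synchronous (latency <= window) or asynchronous.

    Latencies are measured from the triggering stimulus onset; events later
    than the window (but before the next stimulus) count as asynchronous
    release.  Negative latencies are rejected.
    """
    lat = raster.events["latency_ms"].to_numpy()
    if np.any(lat < 0):
        raise DataError("negative latencies are not allowed")
    events = raster.events.copy()
    events["synchronous"] = lat <= window_ms
    return EventRaster(events=events, protocol=raster.protocol)


def fit_latency_biexp(
    latencies: np.ndarray,
    onset_delay_ms: float = 0.0,
    min_events: int = 100,
) -> LatencyFit:
    """Maximum-likelihood biexponential mixture fit of release latencies.

    Latency histograms after an AP are biphasic: a fast component (direct
    release of docked SVs, time constant ``tau_f``) and a slow component
    (two-step release via the replacement site, ``tau_s``).  The density is

        f(t) = (1-w)/tau_f exp(-(t-d)/tau_f) + w/tau_s exp(-(t-d)/tau_s)

    for ``t >= d`` with fixed onset delay ``d``.  Parameters are optimised on
    the unbinned sample; components are ordered so ``tau_fast < tau_slow``.
    Fits with nearly equal time constants are flagged ``degenerate``.
    """
    lat = np.asarray(latencies, dtype=float)
    if lat.size == 0:
        raise DataError("cannot fit an empty latency sample")
    t = lat - onset_delay_ms
    if np.any(t < 0):
        raise DataError("latencies below the onset delay")
    t = np.maximum(t, 1e-9)
    if lat.size < min_events:
        raise DataError(f"need >= {min_events} latencies for a stable fit, got {lat.size}")

    mean_t = float(t.mean())

    def nll(theta: np.ndarray) -> float:
        ltf, lts, logit_w = theta
        tf, ts = math.exp(ltf), math.exp(lts)
        w = 1.0 / (1.0 + math.exp(-logit_w))
        dens = (1 - w) / tf * np.exp(-t / tf) + w / ts * np.exp(-t / ts)
        return -float(np.sum(np.log(np.maximum(dens, 1e-300))))

    x0 = np.array([math.log(max(0.3 * mean_t, 1e-3)), math.log(3.0 * mean_t), 0.0])
    res = optimize.minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 5000})
    tf, ts = math.exp(res.x[0]), math.exp(res.x[1])
    w = 1.0 / (1.0 + math.exp(-res.x[2]))
    if tf > ts:
        tf, ts, w = ts, tf, 1.0 - w
    # single-exponential MLE as the degeneracy reference: a lone exponential
    # leaves the mixture likelihood flat along a ridge of arbitrary splits
    nll_single = t.size * (math.log(mean_t) + 1.0)
    if ts < 1.5 * tf or nll_single - float(res.fun) < 3.0:
        return LatencyFit(
            tau_fast_ms=mean_t,
            tau_slow_ms=mean_t,
            slow_fraction=0.0,
            extra_delay_ms=onset_delay_ms,
            log_likelihood=-nll_single,
            degenerate=True,
        )
    degenerate = False
    return LatencyFit(
        tau_fast_ms=tf,
        tau_slow_ms=ts,
        slow_fraction=w,
        extra_delay_ms=onset_delay_ms,
        log_likelihood=-float(res.fun),
        degenerate=degenerate,
    )


def two_step_ratio(amp: float, window_ms: float = 5.0, tau_ms: float = 4.0) -> float:
    """Share of synchronous release contributed by the two-step pathway.

    The two-step release rate decays exponentially with time constant
    ``tau_ms`` and asymptotic amplitude ``amp`` (fraction of total synchronous
    release); within a measurement window of ``window_ms`` after the AP the
    captured share is ``amp * (1 - exp(-window/tau))``.
    """
    if not (0.0 <= amp <= 1.0):
        raise ParameterError(f"amp must be in [0, 1], got {amp!r}")
    if window_ms < 0:
        raise ParameterError(f"window_ms must be >= 0, got {window_ms!r}")
    if not tau_ms > 0:
        raise ParameterError(f"tau_ms must be positive, got {tau_ms!r}")
    return amp * (1.0 - math.exp(-window_ms / tau_ms))


def replenishment_contribution(
    breakdown: ReplenishmentBreakdown,
    P1: float,
    P2: float,
) -> Tuple[float, float]:
    """Fraction of early-train release attributable to upstream replenishment.

    Replenishment SVs sit in replacement sites at the second AP, so they
    reach the measurement window only through two-step release:

        P2_replenishment / P2_total
            = (rho2_replenishment / rho2_total) * twostep_ratio.

    Returns ``(p2_share, percent_of_sum)`` where ``percent_of_sum`` is the
    percentage of ``P1 + P2`` carried by replenishment SVs (the first-AP
    share is zero because no two-step release occurs at the first AP).
    """
    for name, v in (("P1", P1), ("P2", P2)):
        if not (0.0 <= v <= 1.0):
            raise ParameterError(f"{name} must be in [0, 1], got {v!r}")
    if breakdown.rho2_total == 0:
        raise ParameterError("rho2_total = 0: replenishment share undefined")
    p2_share = (breakdown.rho2_replenishment / breakdown.rho2_total) * breakdown.twostep_ratio
    if P1 + P2 == 0:
        raise ParameterError("P1 + P2 = 0: percentage undefined")
    percent = 100.0 * p2_share * P2 / (P1 + P2)
    return p2_share, percent
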