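"""Recover docking-model transition probabilities from observed train means.

The fitting target is the vector of mean released-SV counts over the early
train (default stimuli 1..5), and the loss is the summed squared deviation
between model and observed means.  Free parameters among (delta, p_r, r, s)
are searched on a coarse probability grid (step 0.05) and then refined
locally; the initial replacement-site occupancy rho is fixed at 1 by default.

Two loss backends exist:

* ``analytic`` (default) — the exact single-site Markov recursion for the
  expected counts, deterministic and fast; valid for both model kinds
  without an intermediate pool.
* ``mc`` — Monte Carlo means from the simulator with common random numbers
  (every evaluation re-seeds the same generator), which keeps the stochastic
  loss locally smooth and the fit reproducible; required for the
  intermediate-pool extension, where the finite pool couples sites.

Note the identifiability caveat: within the early train, ``delta`` and
``p_r`` trade off strongly through the first-stimulus mean
``P_1 = delta * p_r``; the product is much better determined than either
factor alone.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .core_model import (
    IPParams,
    ModelKind,
    ModelParams,
    Scheduling,
    TrainProtocol,
    _mean_si_markov,
    simulate_trains,
)
from .errors import DataError, ParameterError
from .estimators import StimulusStats

__all__ = ["FitSpec", "FitResult", "fit_model", "fit_ip_extension"]

_FREE_NAMES = ("delta", "rho", "p_r", "r", "s")


@dataclass(frozen=True)
class FitSpec:
    """Target statistics and settings for a model fit.

    ``fixed`` maps parameter names to frozen values; by default ``rho`` is
    pinned at 1 (a fully occupied replacement site at train onset) and the
    remaining four transition probabilities are free.
    """

    target_stats: StimulusStats
    fit_stim_range: Tuple[int, int] = (1, 5)
    fixed: Dict[str, float] = field(default_factory=lambda: {"rho": 1.0})
    mc_reps: int = 5000
    loss: str = "sse"
    n_sites: Optional[int] = None
    protocol: Optional[TrainProtocol] = None

    def __post_init__(self) -> None:
        lo, hi = self.fit_stim_range
        if not (1 <= lo <= hi <= self.target_stats.n_stim):
            raise ParameterError(f"fit_stim_range {self.fit_stim_range} outside the train")
        if self.mc_reps < 100:
            raise ParameterError("mc_reps must be >= 100")
        if self.loss != "sse":
            raise ParameterError(f"unsupported loss {self.loss!r}")
        unknown = set(self.fixed) - set(_FREE_NAMES)
        if unknown:
            raise ParameterError(f"unknown fixed parameters {sorted(unknown)}")

    def resolved_n_sites(self) -> int:
        n = self.n_sites if self.n_sites is not None else self.target_stats.n_sites
        if n is None:
            raise DataError("n_sites unknown: set it on the FitSpec or the StimulusStats")
        return n

    def resolved_protocol(self) -> TrainProtocol:
        proto = self.protocol or self.target_stats.protocol
        if proto is None:
            raise DataError("a TrainProtocol is required (FitSpec.protocol or stats.protocol)")
        return proto


@dataclass(frozen=True)
class FitResult:
    """Best parameters, loss, and bookkeeping of a fit."""

    params_hat: ModelParams
    loss_value: float
    n_evaluations: int
    seed: Optional[int] = None
    ip_hat: Optional[IPParams] = None
    converged: bool = True


def _target_slice(spec: FitSpec) -> Tuple[np.ndarray, slice]:
    lo, hi = spec.fit_stim_range
    sl = slice(lo - 1, hi)
    return np.asarray(spec.target_stats.mean_si, dtype=float)[sl], sl


def _mc_means(
    params: ModelParams,
    protocol: TrainProtocol,
    ip: Optional[IPParams],
    scheduling: Scheduling,
    seed: int,
    mc_reps: int,
) -> np.ndarray:
    proto = replace(protocol, n_trains=mc_reps, seed=None)
    rng = np.random.default_rng(seed)  # common random numbers: same seed every call
    cm = simulate_trains(params, proto, ip=ip, scheduling=scheduling, rng=rng)
    return cm.counts.mean(axis=0)


def fit_model(
    spec: FitSpec,
    model_kind: ModelKind | str = ModelKind.RSDS,
    scheduling: Scheduling | str = Scheduling.BLOCKED,
    method: str = "analytic",
    grid_step: float = 0.05,
    seed: int = 0,
) -> FitResult:
    """Least-squares fit of the free transition probabilities to train means.

    Coarse grid search (``grid_step`` over the [0, 1] box of free parameters)
    followed by local refinement: Nelder–Mead on the exact analytic loss, or
    a shrinking pattern search on the common-random-number Monte Carlo loss
    when ``method="mc"``.  If refinement does not improve on the grid, the
    best grid point is returned with ``converged=False``.
    """
    model_kind = ModelKind(model_kind)
    scheduling = Scheduling(scheduling)
    if method not in ("analytic", "mc"):
        raise ParameterError(f"unknown method {method!r}")
    target, sl = _target_slice(spec)
    n_sites = spec.resolved_n_sites()
    protocol = spec.resolved_protocol()
    n_stim = spec.fit_stim_range[1]
    free = [n for n in _FREE_NAMES if n not in spec.fixed]
    if not free:
        raise ParameterError("no free parameters to fit")

    def make_params(values: Dict[str, float]) -> ModelParams:
        kw = dict(spec.fixed)
        kw.update(values)
        return ModelParams(model_kind=model_kind, n_sites=n_sites, **kw)

    n_evals = 0

    def loss_scalar(values: Dict[str, float]) -> float:
        nonlocal n_evals
        n_evals += 1
        params = make_params(values)
        if method == "analytic":
            means = _mean_si_markov(
                model_kind, params.delta, params.rho, params.p_r, params.r, params.s,
                n_stim, scheduling,
            ) * n_sites
            means = means[sl]
        else:
            means = _mc_means(params, protocol, None, scheduling, seed, spec.mc_reps)[sl]
        return float(np.sum((means - target) ** 2))

    # --- coarse grid, vectorised through the broadcasting Markov recursion
    axis = np.arange(0.0, 1.0 + 1e-9, grid_step)
    grids = np.meshgrid(*[axis] * len(free), indexing="ij")
    flat = {name: g.ravel() for name, g in zip(free, grids)}
    full = {name: flat.get(name, np.full(flat[free[0]].shape, spec.fixed.get(name, 0.0)))
            for name in _FREE_NAMES}
    if method == "analytic":
        means = _mean_si_markov(
            model_kind, full["delta"], full["rho"], full["p_r"], full["r"], full["s"],
            n_stim, scheduling,
        ) * n_sites
        losses = np.sum((means[:, sl] - target) ** 2, axis=1)
        n_evals += losses.size
        best_idx = int(np.argmin(losses))
        best_grid = {name: float(flat[name][best_idx]) for name in free}
        best_grid_loss = float(losses[best_idx])
    else:
        # stochastic loss: thin the grid to keep evaluation counts sane
        coarse = np.arange(0.0, 1.0 + 1e-9, max(grid_step, 0.1))
        best_grid, best_grid_loss = None, math.inf
        for combo in itertools.product(coarse, repeat=len(free)):
            values = dict(zip(free, map(float, combo)))
            l = loss_scalar(values)
            if l < best_grid_loss:
                best_grid, best_grid_loss = values, l

    # --- local refinement
    x0 = np.array([best_grid[n] for n in free])
    if method == "analytic":
        def fun(x: np.ndarray) -> float:
            x = np.clip(x, 0.0, 1.0)
            return loss_scalar(dict(zip(free, x)))

        res = optimize.minimize(
            fun, x0, method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-12, "maxiter": 4000},
        )
        x_best, loss_best = np.clip(res.x, 0.0, 1.0), float(res.fun)
    else:
        x_best, loss_best = _pattern_search(
            lambda x: loss_scalar(dict(zip(free, x))), x0, step0=0.05, tol=0.005
        )

    converged = loss_best <= best_grid_loss + 1e-12
    if not converged:
        x_best, loss_best = x0, best_grid_loss
    params_hat = make_params(dict(zip(free, map(float, x_best))))
    return FitResult(
        params_hat=params_hat,
        loss_value=loss_best,
        n_evaluations=n_evals,
        seed=seed,
        converged=converged,
    )


def _pattern_search(fun, x0: np.ndarray, step0: float, tol: float) -> Tuple[np.ndarray, float]:
    """Box-constrained compass search with shrinking step on [0, 1]^d."""
    x = np.clip(np.asarray(x0, dtype=float), 0.0, 1.0)
    fx = fun(x)
    step = step0
    while step >= tol:
        improved = False
        for j in range(x.size):
            for sign in (+1.0, -1.0):
                cand = x.copy()
                cand[j] = min(1.0, max(0.0, cand[j] + sign * step))
                if cand[j] == x[j]:
                    continue
                fc = fun(cand)
                if fc < fx:
                    x, fx = cand, fc
                    improved = True
        if not improved:
            step /= 2.0
    return x, fx


def fit_ip_extension(
    spec: FitSpec,
    base_params: ModelParams,
    ip_sizes: Iterable[int] = range(0, 31),
    r_ip_step: float = 0.05,
    couple_s_to_ip: bool = True,
    scheduling: Scheduling | str = Scheduling.BLOCKED,
    seed: int = 0,
) -> FitResult:
    """Fit the intermediate-pool parameters with the base model frozen.

    The base transition probabilities stay at their fitted values; only the
    initial IP size (integer grid) and the IP refill probability ``r_ip``
    are searched.  The loss runs over the full train (the IP only matters
    once the replacement sites have drained, i.e. late stimuli), using the
    Monte Carlo simulator with common random numbers.
    """
    scheduling = Scheduling(scheduling)
    protocol = spec.resolved_protocol()
    target = np.asarray(spec.target_stats.mean_si, dtype=float)
    n_stim = spec.target_stats.n_stim
    proto = replace(protocol, n_stim=n_stim)

    n_evals = 0
    best = None
    r_ip_axis = np.arange(0.0, 1.0 + 1e-9, r_ip_step)
    for size in ip_sizes:
        for r_ip in r_ip_axis:
            ip = IPParams(ip_size0=int(size), r_ip=float(r_ip), couple_s_to_ip=couple_s_to_ip)
            means = _mc_means(base_params, proto, ip, scheduling, seed, spec.mc_reps)
            loss = float(np.sum((means - target) ** 2))
            n_evals += 1
            if best is None or loss < best[1]:
                best = (ip, loss)
    ip_best, loss_best = best
    return FitResult(
        params_hat=base_params,
        loss_value=loss_best,
        n_evaluations=n_evals,
        seed=seed,
        ip_hat=ip_best,
    )
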