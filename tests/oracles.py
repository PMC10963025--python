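"""Brute-force oracles: exhaustive state-tree enumeration of single-site models.

Independent of the package's simulators: enumerates every branch of the
release/docking/replenishment probability tree for one site over a short
train (blocked intra-interval order) and returns the exact joint
distribution of the per-stimulus release counts.
"""

from __future__ import annotations

import itertools
from typing import Dict, Tuple

import numpy as np

Joint = Dict[Tuple[int, ...], float]


def _branches(possible: bool, p: float):
    if not possible:
        return [(False, 1.0)]
    out = []
    if p > 0:
        out.append((True, p))
    if p < 1:
        out.append((False, 1.0 - p))
    return out


def enumerate_rsds(delta, rho, p_r, r, s, n_stim) -> Joint:
    """Exact joint law of (s_1..s_n) for one RS/DS site, blocked scheduling."""
    dist: Joint = {}

    def step(i, rs, ds, prob, counts):
        if i == n_stim:
            dist[counts] = dist.get(counts, 0.0) + prob
            return
        for fuse, pf in _branches(ds, p_r):
            ds1 = ds and not fuse
            c = counts + ((1,) if fuse else (0,))
            for mv, pm in _branches(rs and not ds1, r):
                rs2, ds2 = (False, True) if mv else (rs, ds1)
                for fill, pr_ in _branches(not rs2, s):
                    step(i + 1, rs2 or fill, ds2, prob * pf * pm * pr_, c)

    for ds0, pd in _branches(True, delta):
        for rs0, pr0 in _branches(True, rho):
            step(0, rs0, ds0, pd * pr0, ())
    return dist


def enumerate_lsts(delta, rho, p_r, r, s, n_stim) -> Joint:
    """Exact joint law of (s_1..s_n) for one LS/TS slot, blocked scheduling."""
    dist: Joint = {}

    def step(i, state, prob, counts):  # state: 0 empty, 1 loose, 2 tight
        if i == n_stim:
            dist[counts] = dist.get(counts, 0.0) + prob
            return
        for fuse, pf in _branches(state == 2, p_r):
            st1 = 0 if fuse else state
            c = counts + ((1,) if fuse else (0,))
            for mv, pm in _branches(st1 == 1, r):
                st2 = 2 if mv else st1
                for fill, pr_ in _branches(st2 == 0, s):
                    step(i + 1, 1 if fill else st2, prob * pf * pm * pr_, c)

    for tight, pt in _branches(True, delta):
        if tight:
            step(0, 2, pt, ())
        else:
            for loose, pl in _branches(True, rho):
                step(0, 1 if loose else 0, pt * pl, ())
    return dist


def joint_means(dist: Joint) -> np.ndarray:
    """E[s_i] per stimulus from a joint law."""
    n = len(next(iter(dist)))
    means = np.zeros(n)
    for counts, p in dist.items():
        means += p * np.asarray(counts)
    return means


def joint_cov_profile(dist: Joint) -> np.ndarray:
    """Exact cov(S_i, s_{i+1}) per i from a joint law."""
    n = len(next(iter(dist)))
    means = joint_means(dist)
    cum_means = np.cumsum(means)
    cov = np.zeros(n - 1)
    for counts, p in dist.items():
        S = np.cumsum(counts)
        for i in range(n - 1):
            cov[i] += p * (S[i] - cum_means[i]) * (counts[i + 1] - means[i + 1])
    return cov


def binomial_sample_from_pmf(n: int, p: float, size: int = 10_000) -> np.ndarray:
    """Integer sample whose relative frequencies match the binomial pmf to ~1/size."""
    from scipy import stats

    k = np.arange(n + 1)
    reps = np.round(stats.binom.pmf(k, n, p) * size).astype(int)
    return np.repeat(k, reps)
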