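"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own recursions: path enumeration for
HMM likelihoods, per-bp scanning for interval overlap, and direct counting
for transitions. They are only feasible at tiny sizes, which is the point.
"""

from __future__ import annotations

import itertools

import numpy as np

from epigene.hmm import HMMParameters, ObservationSequence, emission_loglik


def enumerate_paths(params: HMMParameters, obs: ObservationSequence):
    """(log total probability, best path log-probability, best path) by
    exhaustive enumeration over all k^T state paths."""
    T, k = obs.T, params.k
    ll_em = emission_loglik(params, obs)
    with np.errstate(divide="ignore"):
        log_init = np.where(params.initial > 0, np.log(np.clip(params.initial, 1e-300, None)), -np.inf)
        log_A = np.where(params.transition > 0, np.log(np.clip(params.transition, 1e-300, None)), -np.inf)
    total = 0.0
    best = -np.inf
    best_path = None
    for path in itertools.product(range(k), repeat=T):
        lp = log_init[path[0]] + ll_em[0, path[0]]
        for t in range(1, T):
            lp += log_A[path[t - 1], path[t]] + ll_em[t, path[t]]
            if lp == -np.inf:
                break
        if np.isfinite(lp):
            total += np.exp(lp)
        if lp > best:
            best, best_path = lp, path
    log_total = np.log(total) if total > 0 else -np.inf
    return log_total, best, best_path


def random_params(k: int, n: int, rng: np.random.Generator) -> HMMParameters:
    """Unconstrained random parameter set (everything free, no zeros)."""
    A = rng.random((k, k)) + 0.05
    A /= A.sum(axis=1, keepdims=True)
    init = rng.random(k) + 0.05
    init /= init.sum()
    return HMMParameters(
        emission=rng.random((k, n)),
        transition=A,
        initial=init,
        structural_zero=np.zeros((k, k), dtype=bool),
        free_transition=np.ones((k, k), dtype=bool),
        free_emission=np.ones((k, n), dtype=bool),
        free_initial=np.ones(k, dtype=bool),
    )


def random_obs(T: int, n: int, rng: np.random.Generator) -> ObservationSequence:
    return ObservationSequence((rng.random((T, n)) < 0.5).astype(np.uint8))


def bp_overlap_mask(intervals, grid) -> np.ndarray:
    """Per-bin overlap mask by scanning every base pair (tiny grids only)."""
    mask = np.zeros(grid.n_bins, dtype=np.uint8)
    for iv in intervals:
        length = grid.contig_length(iv.contig)
        for bp in range(max(0, iv.start), min(length, iv.end)):
            mask[grid.bin_index(iv.contig, bp)] = 1
    return mask
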