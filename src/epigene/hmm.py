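"""Multivariate Bernoulli-emission HMM with constrained (semi-supervised) EM.

Each hidden state emits an n-vector of independent Bernoulli variables (one
per histone mark), so the per-bin observation likelihood is a product of
Bernoulli terms. Three constraint mechanisms distinguish this from a vanilla
HMM:

* **structural zeros** — transitions forbidden by the model topology are
  exactly 0 and never receive probability mass;
* **clamped parameters** — entries whose free mask is False are bit-identical
  before and after EM (used for supervised transition/emission rows);
* **partial-row renormalization** — in rows mixing clamped and free
  transition entries, the clamped entries keep their values and the free
  entries share the remaining mass in proportion to their EM expected counts,
  so every row still sums to 1.

Forward/backward uses per-position scaling (no underflow for sequences of
10^6 bins); Viterbi runs in log space with deterministic tie-breaking
(lowest state index wins).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "EPS",
    "HMMError",
    "InfeasiblePathError",
    "StateMeta",
    "HMMParameters",
    "ObservationSequence",
    "emission_loglik",
    "forward_backward",
    "baum_welch",
    "viterbi",
    "save_model",
    "load_model",
]

EPS = 1e-6  # emission clipping; supervision may still install exact 0/1
_ROW_TOL = 1e-9

MODEL_FORMAT_VERSION = 1


class HMMError(ValueError):
    pass


class InfeasiblePathError(RuntimeError):
    """Every state path has probability zero; names the first infeasible bin."""


class StateMeta(NamedTuple):
    name: str
    role: str  # TSS, TTS, exon1, intron1, exonI, intronI, exonL, intronL, background
    strand: str  # '+', '-', or 'na'


@dataclass
class ObservationSequence:
    """One contig's slice of a class matrix: T bins × n marks, binary."""

    values: np.ndarray
    contig: str = ""
    start_bin: int = 0

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise HMMError("observation sequence must be a T x n matrix with T >= 1")
        if not np.isin(self.values, (0, 1)).all():
            raise HMMError("observations must be binary")

    @property
    def T(self) -> int:
        return self.values.shape[0]


@dataclass
class HMMParameters:
    """Full parameter set with structural-zero and trainability masks."""

    emission: np.ndarray  # (k, n) Bernoulli success probabilities
    transition: np.ndarray  # (k, k) row-stochastic
    initial: np.ndarray  # (k,)
    structural_zero: np.ndarray  # (k, k) bool, True = forced exact 0
    free_transition: np.ndarray  # (k, k) bool, True = EM-updated
    free_emission: np.ndarray  # (k, n) bool
    free_initial: np.ndarray  # (k,) bool
    state_meta: list[StateMeta] = field(default_factory=list)
    marks: list[str] | None = None

    def __post_init__(self) -> None:
        self.emission = np.asarray(self.emission, dtype=np.float64)
        self.transition = np.asarray(self.transition, dtype=np.float64)
        self.initial = np.asarray(self.initial, dtype=np.float64)
        self.structural_zero = np.asarray(self.structural_zero, dtype=bool)
        self.free_transition = np.asarray(self.free_transition, dtype=bool)
        self.free_emission = np.asarray(self.free_emission, dtype=bool)
        self.free_initial = np.asarray(self.free_initial, dtype=bool)
        k, n = self.emission.shape
        if not self.state_meta:
            self.state_meta = [StateMeta(f"state{i}", "background", "na") for i in range(k)]
        self._validate(k, n)

    def _validate(self, k: int, n: int) -> None:
        if self.transition.shape != (k, k) or self.initial.shape != (k,):
            raise HMMError("parameter shape mismatch")
        for name, arr, shape in (
            ("structural_zero", self.structural_zero, (k, k)),
            ("free_transition", self.free_transition, (k, k)),
            ("free_emission", self.free_emission, (k, n)),
            ("free_initial", self.free_initial, (k,)),
        ):
            if arr.shape != shape:
                raise HMMError(f"{name} shape {arr.shape} != {shape}")
        if len(self.state_meta) != k:
            raise HMMError("state_meta length mismatch")
        if (self.emission < 0).any() or (self.emission > 1).any():
            raise HMMError("emission probabilities outside [0, 1]")
        if (self.transition < 0).any() or (self.initial < 0).any():
            raise HMMError("negative probabilities")
        if np.abs(self.transition.sum(axis=1) - 1).max() > _ROW_TOL:
            raise HMMError("transition rows must sum to 1 within 1e-9")
        if abs(self.initial.sum() - 1) > _ROW_TOL:
            raise HMMError("initial distribution must sum to 1 within 1e-9")
        if (self.transition[self.structural_zero] != 0).any():
            raise HMMError("structural zeros must be exactly 0")
        if (self.structural_zero & self.free_transition).any():
            raise HMMError("structural zeros can never be free")
        # a row whose clamped mass is already >= 1 cannot give its free
        # entries any mass: reject at construction
        clamped = np.where(self.free_transition, 0.0, self.transition)
        bad = (clamped.sum(axis=1) >= 1 - 1e-12) & self.free_transition.any(axis=1)
        if bad.any():
            raise HMMError(
                f"transition rows {np.flatnonzero(bad).tolist()} have clamped "
                "mass >= 1 but contain free entries"
            )
        if self.free_initial.any() and not self.free_initial.all():
            clamped_mass = self.initial[~self.free_initial].sum()
            if clamped_mass >= 1 - 1e-12:
                raise HMMError("initial distribution: clamped mass >= 1 with free entries")

    @property
    def k(self) -> int:
        return self.emission.shape[0]

    @property
    def n(self) -> int:
        return self.emission.shape[1]

    def copy(self) -> "HMMParameters":
        return replace(
            self,
            emission=self.emission.copy(),
            transition=self.transition.copy(),
            initial=self.initial.copy(),
            structural_zero=self.structural_zero.copy(),
            free_transition=self.free_transition.copy(),
            free_emission=self.free_emission.copy(),
            free_initial=self.free_initial.copy(),
            state_meta=list(self.state_meta),
            marks=None if self.marks is None else list(self.marks),
        )

    def state_indices(self, role: str | None = None, strand: str | None = None) -> np.ndarray:
        out = [
            i
            for i, m in enumerate(self.state_meta)
            if (role is None or m.role == role) and (strand is None or m.strand == strand)
        ]
        return np.asarray(out, dtype=np.int64)

    @property
    def tu_states(self) -> np.ndarray:
        return np.asarray(
            [i for i, m in enumerate(self.state_meta) if m.role != "background"],
            dtype=np.int64,
        )


# ---------------------------------------------------------------------------
# likelihoods


def emission_loglik(params: HMMParameters, obs: ObservationSequence) -> np.ndarray:
    """T × k matrix: log P(o_t | state) = sum_j o·log e + (1−o)·log(1−e).

    Emission entries of exactly 0/1 (installed by supervision) are floored at
    1e-300 inside the log, keeping values finite while leaving mismatches
    effectively impossible.
    """
    if obs.values.shape[1] != params.n:
        raise HMMError(
            f"observation has {obs.values.shape[1]} marks, model expects {params.n}"
        )
    e = params.emission
    loge = np.log(np.clip(e, 1e-300, None))
    log1me = np.log(np.clip(1.0 - e, 1e-300, None))
    o = obs.values.astype(np.float64)
    return o @ loge.T + (1.0 - o) @ log1me.T


class _FBResult(NamedTuple):
    loglik: float
    alpha: np.ndarray  # (T, k) scaled forward
    beta: np.ndarray  # (T, k) scaled backward
    b: np.ndarray  # (T, k) shifted emission likelihoods
    c: np.ndarray  # (T,) per-position scale factors


def _forward_backward_scaled(params: HMMParameters, obs: ObservationSequence) -> _FBResult:
    A = params.transition
    ll_em = emission_loglik(params, obs)
    shift = ll_em.max(axis=1)
    b = np.exp(ll_em - shift[:, None])
    T, k = b.shape
    alpha = np.empty((T, k))
    c = np.empty(T)
    a = params.initial * b[0]
    c[0] = a.sum()
    if c[0] <= 0:
        raise InfeasiblePathError("no feasible state at bin 0")
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * b[t]
        c[t] = a.sum()
        if c[t] <= 0:
            raise InfeasiblePathError(f"no feasible state path at bin {t}")
        alpha[t] = a / c[t]
    beta = np.empty((T, k))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (b[t + 1] * beta[t + 1])) / c[t + 1]
    loglik = float(np.log(c).sum() + shift.sum())
    return _FBResult(loglik, alpha, beta, b, c)


def forward_backward(
    params: HMMParameters, obs: ObservationSequence
) -> tuple[float, np.ndarray]:
    """Log-likelihood of the sequence and T × k posterior state probabilities."""
    res = _forward_backward_scaled(params, obs)
    post = res.alpha * res.beta
    post /= post.sum(axis=1, keepdims=True)
    return res.loglik, post


# ---------------------------------------------------------------------------
# constrained Baum–Welch


def baum_welch(
    params: HMMParameters,
    sequences: Sequence[ObservationSequence],
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[HMMParameters, list[float]]:
    """Constrained EM: fit free parameters, keep clamped ones bit-identical.

    Sufficient statistics are pooled across sequences (each sequence starts
    from the initial distribution). The returned trace holds the total
    log-likelihood at the *start* of each iteration and is asserted
    non-decreasing within 1e-8; training stops when the improvement drops
    below *tol* or after *max_iter* iterations.
    """
    if not sequences:
        raise HMMError("baum_welch needs at least one observation sequence")
    params = params.copy()
    k, n = params.k, params.n
    trace: list[float] = []
    for _ in range(max_iter):
        A = params.transition
        A_num = np.zeros((k, k))
        e_num = np.zeros((k, n))
        e_den = np.zeros(k)
        init_num = np.zeros(k)
        total_ll = 0.0
        for obs in sequences:
            res = _forward_backward_scaled(params, obs)
            total_ll += res.loglik
            gamma = res.alpha * res.beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            init_num += gamma[0]
            e_den += gamma.sum(axis=0)
            e_num += gamma.T @ obs.values
            if obs.T > 1:
                w = (res.b[1:] * res.beta[1:]) / res.c[1:, None]
                A_num += A * (res.alpha[:-1].T @ w)
        if trace and total_ll < trace[-1] - 1e-8:
            raise RuntimeError(
                f"EM log-likelihood decreased: {trace[-1]:.10g} -> {total_ll:.10g}"
            )
        converged = bool(trace) and total_ll - trace[-1] < tol
        trace.append(total_ll)
        if converged:
            break
        # M-step — transitions: clamped entries keep their values, free
        # entries share the remaining row mass proportionally to counts
        newA = params.transition.copy()
        for i in range(k):
            free = params.free_transition[i]
            if not free.any():
                continue
            free_mass = 1.0 - params.transition[i, ~free].sum()
            counts = A_num[i, free]
            if counts.sum() > 0:
                newA[i, free] = free_mass * counts / counts.sum()
        params.transition = newA
        new_init = params.initial.copy()
        free = params.free_initial
        if free.any():
            free_mass = 1.0 - params.initial[~free].sum()
            counts = init_num[free]
            if counts.sum() > 0:
                new_init[free] = free_mass * counts / counts.sum()
        params.initial = new_init
        new_e = params.emission.copy()
        upd = params.free_emission & (e_den[:, None] > 0)
        est = np.clip(
            e_num / np.where(e_den[:, None] > 0, e_den[:, None], 1.0), EPS, 1 - EPS
        )
        new_e[upd] = est[upd]
        params.emission = new_e
    return params, trace


# ---------------------------------------------------------------------------
# Viterbi


def viterbi(params: HMMParameters, obs: ObservationSequence) -> tuple[np.ndarray, float]:
    """Most probable state path and its log-probability.

    Structural zeros are respected exactly (log 0 = −inf); ties resolve to
    the lowest state index. Raises :class:`InfeasiblePathError` naming the
    first bin at which every path has probability zero.
    """
    A = params.transition
    with np.errstate(divide="ignore"):
        logA = np.where(A > 0, np.log(np.where(A > 0, A, 1.0)), -np.inf)
        loginit = np.where(
            params.initial > 0, np.log(np.where(params.initial > 0, params.initial, 1.0)), -np.inf
        )
    ll_em = emission_loglik(params, obs)
    T, k = ll_em.shape
    psi = np.zeros((T, k), dtype=np.int64)
    delta = loginit + ll_em[0]
    if not np.isfinite(delta).any():
        raise InfeasiblePathError("no feasible state at bin 0")
    for t in range(1, T):
        scores = delta[:, None] + logA
        psi[t] = np.argmax(scores, axis=0)  # first max = lowest state index
        delta = scores[psi[t], np.arange(k)] + ll_em[t]
        if not np.isfinite(delta).any():
            raise InfeasiblePathError(f"no feasible state path at bin {t}")
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path, float(delta.max())


# ---------------------------------------------------------------------------
# serialization


def save_model(params: HMMParameters, path: str | Path) -> None:
    """Write the model as a versioned JSON document."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "k": params.k,
        "n": params.n,
        "marks": params.marks,
        "states": [m._asdict() for m in params.state_meta],
        "emission": params.emission.tolist(),
        "transition": params.transition.tolist(),
        "initial": params.initial.tolist(),
        "structural_zero": params.structural_zero.astype(int).tolist(),
        "free_transition": params.free_transition.astype(int).tolist(),
        "free_emission": params.free_emission.astype(int).tolist(),
        "free_initial": params.free_initial.astype(int).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_model(path: str | Path) -> HMMParameters:
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise HMMError(f"unsupported model format version {version!r}")
    return HMMParameters(
        emission=np.array(doc["emission"]),
        transition=np.array(doc["transition"]),
        initial=np.array(doc["initial"]),
        structural_zero=np.array(doc["structural_zero"], dtype=bool),
        free_transition=np.array(doc["free_transition"], dtype=bool),
        free_emission=np.array(doc["free_emission"], dtype=bool),
        free_initial=np.array(doc["free_initial"], dtype=bool),
        state_meta=[StateMeta(**m) for m in doc["states"]],
        marks=doc.get("marks"),
    )
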