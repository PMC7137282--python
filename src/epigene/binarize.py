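"""ChIP-seq enrichment calling and binarization.

Per bin, the ChIP count ``s`` out of ``t = chip + control`` trials is modelled
as a mixture of binomials: a background component in which reads fall on ChIP
and control at comparable rates, and an enriched component with a higher ChIP
success probability. The mixture is fitted by EM on all bins with ``t > 0``
(bins with no reads in either track carry no information and are excluded —
they are never called). Bins are then ranked by their posterior probability
of enrichment and assigned q-values as the running mean of (1 − posterior)
down the ranking; a bin is called enriched iff its q-value is at or below
the target FDR (default 0.2).

Stacking the per-mark call vectors column-wise yields the m × n binary class
matrix observed by the HMM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .grid import BinGrid, CountTrack

__all__ = [
    "BinarizationError",
    "EnrichmentResult",
    "ClassMatrix",
    "fit_enrichment",
    "call_enriched",
    "binarize",
    "build_class_matrix",
]

DEFAULT_FDR = 0.2


class BinarizationError(ValueError):
    pass


@dataclass
class EnrichmentResult:
    """Fitted enrichment mixture plus per-bin posteriors and q-values.

    ``posterior`` and ``qvalue`` are NaN for bins excluded from the fit
    (chip + control == 0); such bins are never called.
    """

    grid: BinGrid
    posterior: np.ndarray
    qvalue: np.ndarray
    fitted: np.ndarray  # bool: bin participated in the fit
    weights: np.ndarray  # mixture proportions, one per component
    success_probs: np.ndarray  # chip/(chip+control) success prob per component
    enriched_component: int
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True


def _sort_by_posterior(posterior: np.ndarray, fitted: np.ndarray) -> np.ndarray:
    """Fitted bin indices by decreasing posterior, ties broken by bin index."""
    idx = np.flatnonzero(fitted)
    order = np.lexsort((idx, -posterior[idx]))
    return idx[order]


def fit_enrichment(
    chip: CountTrack,
    control: CountTrack,
    n_components: int = 2,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> EnrichmentResult:
    """Fit the binomial-mixture enrichment model to a (ChIP, control) pair.

    Initialization is deterministic: the background component starts at the
    median per-bin ChIP fraction and the enriched component at the 90th
    percentile (intermediate components are spread between); weights start
    uniform. The EM log-likelihood is non-decreasing across iterations; if
    it has not converged within *max_iter*, the best fit is returned with
    ``converged=False`` and a warning.
    """
    if chip.grid != control.grid:
        raise BinarizationError("chip and control tracks are on different grids")
    if n_components < 2:
        raise BinarizationError("n_components must be >= 2")
    s = chip.values.astype(np.float64)
    t = s + control.values.astype(np.float64)
    fitted = t > 0
    if not fitted.any():
        raise BinarizationError("all bins have zero chip + control counts")
    sf, tf = s[fitted], t[fitted]
    frac = sf / tf

    qs = np.linspace(50, 90, n_components)
    p = np.clip(np.percentile(frac, qs), 1e-3, 1 - 1e-3)
    p = np.maximum.accumulate(p + np.arange(n_components) * 1e-6)  # strictly increasing
    w = np.full(n_components, 1.0 / n_components)

    logcoef = gammaln(tf + 1) - gammaln(sf + 1) - gammaln(tf - sf + 1)
    trace: list[float] = []
    converged = False
    resp = None
    for _ in range(max_iter):
        logp = np.log(np.clip(p, 1e-12, None))
        log1mp = np.log(np.clip(1 - p, 1e-12, None))
        # (bins, components) complete-data log-likelihood
        ll_bc = logcoef[:, None] + sf[:, None] * logp + (tf - sf)[:, None] * log1mp
        ll_bc = ll_bc + np.log(w)
        norm = logsumexp(ll_bc, axis=1)
        ll = float(norm.sum())
        resp = np.exp(ll_bc - norm[:, None])
        if trace and ll < trace[-1] - 1e-9:
            raise RuntimeError("EM log-likelihood decreased")
        done = bool(trace) and ll - trace[-1] < tol
        trace.append(ll)
        if done:
            converged = True
            break
        w = resp.mean(axis=0)
        denom = resp.T @ tf
        p = np.where(denom > 0, (resp.T @ sf) / np.where(denom > 0, denom, 1.0), p)
        p = np.clip(p, 1e-9, 1 - 1e-9)
    if not converged:
        warnings.warn(f"enrichment EM did not converge in {max_iter} iterations")

    enriched = int(np.argmax(p))
    posterior = np.full(len(t), np.nan)
    posterior[fitted] = resp[:, enriched]
    qvalue = np.full(len(t), np.nan)
    order = _sort_by_posterior(posterior, fitted)
    running = np.cumsum(1.0 - posterior[order]) / np.arange(1, len(order) + 1)
    qvalue[order] = running
    return EnrichmentResult(
        grid=chip.grid,
        posterior=posterior,
        qvalue=qvalue,
        fitted=fitted,
        weights=w,
        success_probs=p,
        enriched_component=enriched,
        loglik_trace=trace,
        converged=converged,
    )


def call_enriched(result: EnrichmentResult, fdr: float = DEFAULT_FDR) -> np.ndarray:
    """Binary enrichment calls at the target FDR.

    A fitted bin is called iff its q-value (running mean of 1 − posterior
    over bins sorted by decreasing posterior) is <= *fdr*. Excluded bins
    are always 0.
    """
    if not 0 < fdr < 1:
        raise BinarizationError(f"fdr must be in (0, 1), got {fdr}")
    calls = np.zeros(result.grid.n_bins, dtype=np.uint8)
    ok = result.fitted & (result.qvalue <= fdr)
    calls[ok] = 1
    return calls


def binarize(
    chip: CountTrack,
    control: CountTrack,
    fdr: float = DEFAULT_FDR,
    **fit_kwargs,
) -> tuple[np.ndarray, EnrichmentResult]:
    """Convenience: fit the enrichment model and call at *fdr*."""
    result = fit_enrichment(chip, control, **fit_kwargs)
    return call_enriched(result, fdr=fdr), result


@dataclass
class ClassMatrix:
    """m bins × n marks binary matrix of enrichment calls (HMM observations)."""

    grid: BinGrid
    marks: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2 or self.values.shape != (self.grid.n_bins, len(self.marks)):
            raise BinarizationError(
                f"class matrix shape {self.values.shape} does not match "
                f"({self.grid.n_bins} bins, {len(self.marks)} marks)"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise BinarizationError("class matrix entries must be 0/1")

    @property
    def n_marks(self) -> int:
        return len(self.marks)

    def contig_blocks(self):
        """Yield (contig, start_bin_offset, submatrix) per contig."""
        for name, _ in self.grid.contigs:
            sl = self.grid.contig_slice(name)
            yield name, sl.start, self.values[sl]


def build_class_matrix(
    calls: Mapping[str, np.ndarray],
    grid: BinGrid,
    mark_order: Sequence[str] | None = None,
) -> ClassMatrix:
    """Assemble per-mark binary call vectors into a class matrix.

    *mark_order* fixes the column order (it must cover exactly the provided
    marks); the recorded order is enforced against the model at prediction
    time. A single-mark matrix is permitted with a warning.
    """
    if mark_order is None:
        mark_order = list(calls)
    if set(mark_order) != set(calls) or len(set(mark_order)) != len(mark_order):
        raise BinarizationError(
            f"mark_order {list(mark_order)} does not cover provided marks {sorted(calls)}"
        )
    if len(mark_order) == 1:
        warnings.warn("building a class matrix with a single mark")
    cols = []
    for mark in mark_order:
        v = np.asarray(calls[mark])
        if v.shape != (grid.n_bins,):
            raise BinarizationError(f"call vector for {mark!r} has length {v.shape}, expected {grid.n_bins}")
        cols.append(v.astype(np.uint8))
    return ClassMatrix(grid, list(mark_order), np.column_stack(cols))
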