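"""Bin-level evaluation against a Pol-II/nascent-RNA gold standard.

The gold standard marks a bin as actively transcribed (AT = 1) iff both the
binarized RNA Polymerase II ChIP-seq call and the nascent-RNA call are 1 in
that bin; prediction sets are reduced to per-bin masks (PT = 1 iff >= 1 bp
overlap with a prediction). Metrics are the standard bin-level contingency
quantities, ROC/PRC curves with trapezoidal AUCs and, because active bins
are vastly outnumbered by inactive ones, a subsampled AUC estimator::

    AUC = mean(L_AUC) − stdDev(L_AUC) / sqrt(n)

where L_AUC collects per-iteration AUCs on balanced subsamples (all positive
bins plus an equal number of randomly drawn negative bins) and stdDev uses
the n−1 denominator. Evaluation resolution is configurable (50/100/200/500
bp); masks at a new resolution are recomputed from intervals, not resampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .grid import BinGrid, GenomicInterval, intervals_to_bin_mask

__all__ = [
    "EvaluationError",
    "GoldStandard",
    "PredictionMask",
    "AUCEstimate",
    "build_gold_standard",
    "prediction_mask",
    "contingency",
    "roc_prc",
    "combine_auc_samples",
    "sampled_auc",
    "rebin",
]


class EvaluationError(ValueError):
    pass


@dataclass
class GoldStandard:
    """Per-bin actual-transcription vector AT plus the evaluated-bin mask."""

    grid: BinGrid
    at: np.ndarray  # uint8, AT(bin)
    mask: np.ndarray  # bool, False = excluded from evaluation

    @property
    def n_evaluated(self) -> int:
        return int(self.mask.sum())


@dataclass
class PredictionMask:
    """A method's per-bin binary predictions, with an optional ranking score."""

    name: str
    pt: np.ndarray
    scores: np.ndarray | None = None


def build_gold_standard(
    polII_calls: np.ndarray,
    nascent_calls: np.ndarray,
    grid: BinGrid,
    exclusion: Iterable[GenomicInterval] | None = None,
) -> GoldStandard:
    """AT = elementwise AND of the two evidence tracks.

    Bins overlapping *exclusion* intervals (e.g. assembly gaps) are removed
    from all downstream tallies. An entirely excluded grid is an error.
    """
    polII_calls = np.asarray(polII_calls)
    nascent_calls = np.asarray(nascent_calls)
    if polII_calls.shape != (grid.n_bins,) or nascent_calls.shape != (grid.n_bins,):
        raise EvaluationError("evidence vectors do not match the grid")
    at = ((polII_calls > 0) & (nascent_calls > 0)).astype(np.uint8)
    mask = np.ones(grid.n_bins, dtype=bool)
    if exclusion is not None:
        mask &= intervals_to_bin_mask(exclusion, grid) == 0
    if not mask.any():
        raise EvaluationError("every bin is excluded; empty evaluation set")
    return GoldStandard(grid=grid, at=at, mask=mask)


def prediction_mask(
    intervals: Iterable[GenomicInterval],
    grid: BinGrid,
    name: str = "predictions",
    scores: np.ndarray | None = None,
) -> PredictionMask:
    """PT(bin) = 1 iff >= 1 bp of any prediction interval overlaps the bin."""
    return PredictionMask(name=name, pt=intervals_to_bin_mask(intervals, grid), scores=scores)


def contingency(gold: GoldStandard, pred: PredictionMask | np.ndarray) -> dict:
    """Bin-level TP/FP/FN/TN with precision, recall, and specificity."""
    pt = pred.pt if isinstance(pred, PredictionMask) else np.asarray(pred)
    if pt.shape != gold.at.shape:
        raise EvaluationError("prediction vector does not match the gold standard grid")
    at = gold.at[gold.mask].astype(bool)
    pt = pt[gold.mask].astype(bool)
    tp = int((at & pt).sum())
    fp = int((~at & pt).sum())
    fn = int((at & ~pt).sum())
    tn = int((~at & ~pt).sum())
    return {
        "TP": tp,
        "FP": fp,
        "FN": fn,
        "TN": tn,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
    }


def _curves(y: np.ndarray, scores: np.ndarray, curve: str) -> tuple[np.ndarray, np.ndarray, float]:
    from sklearn.metrics import precision_recall_curve, roc_curve

    if curve == "roc":
        fpr, tpr, _ = roc_curve(y, scores)
        return fpr, tpr, float(np.trapezoid(tpr, fpr))
    precision, recall, _ = precision_recall_curve(y, scores)
    # integrate in threshold order (recall descending): tied-recall points
    # form zero-width segments instead of spurious trapezoids
    return recall, precision, float(abs(np.trapezoid(precision, recall)))


def roc_prc(gold: GoldStandard, scores: np.ndarray) -> dict:
    """ROC and PRC curves with trapezoidal AUCs from a per-bin ranking score.

    Thresholds descend through the score values with ties grouped. For a
    score-less binary method, pass its 0/1 calls: the curves degenerate to
    the single operating point plus endpoints. A gold standard that is all
    positive or all negative cannot support a ROC curve (error); for the
    PRC it yields a warning from the underlying curve computation.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != gold.at.shape:
        raise EvaluationError("score vector does not match the gold standard grid")
    if not np.isfinite(scores[gold.mask]).all():
        raise EvaluationError("scores must be finite on evaluated bins")
    y = gold.at[gold.mask]
    s = scores[gold.mask]
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise EvaluationError("gold standard is single-class; ROC undefined")
    fpr, tpr, auc_roc = _curves(y, s, "roc")
    recall, precision, auc_prc = _curves(y, s, "prc")
    return {
        "roc": {"fpr": fpr, "tpr": tpr, "auc": auc_roc},
        "prc": {"recall": recall, "precision": precision, "auc": auc_prc},
    }


@dataclass
class AUCEstimate:
    """Subsampled AUC: estimate = mean(L_AUC) − stdDev(L_AUC)/sqrt(n)."""

    estimate: float
    l_auc: np.ndarray
    n: int
    curve: str = "prc"

    def __post_init__(self) -> None:
        self.l_auc = np.asarray(self.l_auc, dtype=np.float64)
        if ((self.l_auc < 0) | (self.l_auc > 1)).any():
            raise EvaluationError("per-sample AUCs must lie in [0, 1]")


def combine_auc_samples(l_auc: Sequence[float]) -> float:
    """mean(L_AUC) − stdDev(L_AUC)/sqrt(n), with sample (n−1) stdDev."""
    l = np.asarray(l_auc, dtype=np.float64)
    if l.size < 2:
        raise EvaluationError("need n >= 2 sampled AUCs for a defined stdDev")
    return float(l.mean() - l.std(ddof=1) / np.sqrt(l.size))


def sampled_auc(
    gold: GoldStandard,
    scores: np.ndarray,
    sample_size: int | None = None,
    n_iterations: int = 100,
    seed: int = 0,
    curve: str = "prc",
) -> AUCEstimate:
    """Class-imbalance-robust AUC via balanced subsampling of bins.

    Each iteration takes *sample_size* positive bins (default: all of them)
    plus an equal number of negative bins drawn without replacement, computes
    the requested curve's AUC on the subsample, and the estimates are
    combined as mean − stdDev/sqrt(n).
    """
    if curve not in ("roc", "prc"):
        raise EvaluationError(f"curve must be 'roc' or 'prc', got {curve!r}")
    if n_iterations < 2:
        raise EvaluationError("need n_iterations >= 2 for a defined stdDev")
    scores = np.asarray(scores, dtype=np.float64)
    y = gold.at[gold.mask]
    s = scores[gold.mask]
    pos = np.flatnonzero(y > 0)
    neg = np.flatnonzero(y == 0)
    if sample_size is None:
        sample_size = len(pos)
    if sample_size < 1 or sample_size > len(pos):
        raise EvaluationError(
            f"sample_size {sample_size} exceeds the {len(pos)} positive bins"
        )
    if len(neg) < sample_size:
        raise EvaluationError("fewer negative bins than the balanced sample needs")
    rng = np.random.default_rng(seed)
    l_auc = np.empty(n_iterations)
    for it in range(n_iterations):
        p = pos if sample_size == len(pos) else rng.choice(pos, sample_size, replace=False)
        m = rng.choice(neg, sample_size, replace=False)
        idx = np.concatenate([p, m])
        _, _, l_auc[it] = _curves(y[idx], s[idx], curve)
    return AUCEstimate(
        estimate=combine_auc_samples(l_auc), l_auc=l_auc, n=n_iterations, curve=curve
    )


def rebin(
    grid: BinGrid,
    to_width: int,
    intervals: Iterable[GenomicInterval] | None = None,
    vector: np.ndarray | None = None,
) -> tuple[BinGrid, np.ndarray]:
    """Recompute a per-bin mask at a new resolution (50/100/200/500 bp ...).

    With *intervals*, the mask is re-derived on a fresh grid at *to_width*
    (the preferred route: refinement and coarsening are both exact). With
    only *vector*, coarsening to a multiple of the current width takes the
    logical OR of child bins; any other width is an error directing the
    caller to interval input.
    """
    if to_width <= 0:
        raise EvaluationError("to_width must be positive")
    new_grid = BinGrid(grid.contigs, bin_width=to_width)
    if intervals is not None:
        return new_grid, intervals_to_bin_mask(intervals, new_grid)
    if vector is None:
        raise EvaluationError("rebin needs intervals or a vector")
    vector = np.asarray(vector)
    if vector.shape != (grid.n_bins,):
        raise EvaluationError("vector length does not match the source grid")
    if to_width == grid.bin_width:
        return new_grid, vector.astype(np.uint8)
    if to_width % grid.bin_width != 0:
        raise EvaluationError(
            f"cannot refine a {grid.bin_width}-bp vector to {to_width} bp; "
            "supply the underlying intervals instead"
        )
    out = np.zeros(new_grid.n_bins, dtype=np.uint8)
    for name, _ in grid.contigs:
        src = vector[grid.contig_slice(name)]
        dst_off = new_grid.contig_offset(name)
        factor = to_width // grid.bin_width
        for local, val in enumerate(src):
            if val:
                out[dst_off + local // factor] = 1
    return new_grid, out
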