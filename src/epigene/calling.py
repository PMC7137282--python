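"""Genome decoding and refinement of the state path into TU records.

The trained model is decoded per contig with Viterbi; the per-bin posterior
mass on the 14 TU states (from forward/backward) serves as a ranking score.
Maximal runs of TU states are refined into transcription-unit records: a run
is emitted iff, in genome order, it starts at a TSS-role bin and ends at a
TTS-role bin with forward-chain body states between them ('+' strand), or
starts at TTS and ends at TSS with reverse-chain body states ('−' strand).
Runs violating this boundary rule — possible only at sequence edges, since
the topology's structural zeros enforce the grammar elsewhere — are dropped
and logged. Adjacent TUs sharing a boundary (a TTS immediately followed by a
TSS) are split at the state change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .binarize import ClassMatrix
from .grid import BinGrid
from .hmm import HMMError, HMMParameters, ObservationSequence, forward_backward, viterbi
from .topology import ROLE_BACKGROUND, ROLE_TSS, ROLE_TTS

__all__ = ["TURecord", "decode_genome", "refine_to_tus", "write_tu_bed", "call_tus"]

logger = logging.getLogger(__name__)


@dataclass
class TURecord:
    """A called transcription unit (bin-aligned, 0-based half-open)."""

    id: str
    contig: str
    start: int
    end: int
    strand: str
    states: list[str]  # member-bin state names in genome order
    score: float  # mean TU-state posterior over member bins

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"TU strand must be + or -, got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("TU end must exceed start")


def decode_genome(
    model: HMMParameters, class_matrix: ClassMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Viterbi state path and per-bin TU posterior for the whole grid.

    One Viterbi and one forward/backward run per contig; the TU posterior of
    a bin is the summed posterior over all non-background states. The class
    matrix's mark order must match the model's.
    """
    if model.marks is not None and list(class_matrix.marks) != list(model.marks):
        raise HMMError(
            f"mark order mismatch: model {model.marks}, class matrix {class_matrix.marks}"
        )
    states = np.zeros(class_matrix.grid.n_bins, dtype=np.int64)
    tu_post = np.zeros(class_matrix.grid.n_bins, dtype=np.float64)
    tu_idx = model.tu_states
    for contig, start, block in class_matrix.contig_blocks():
        if block.shape[0] < 1:
            continue
        obs = ObservationSequence(values=block, contig=contig, start_bin=start)
        path, _ = viterbi(model, obs)
        _, post = forward_backward(model, obs)
        sl = slice(start, start + block.shape[0])
        states[sl] = path
        tu_post[sl] = post[:, tu_idx].sum(axis=1)
    return states, tu_post


def refine_to_tus(
    state_path: np.ndarray,
    tu_posterior: np.ndarray,
    grid: BinGrid,
    model: HMMParameters,
) -> list[TURecord]:
    """Extract strand-assigned TU records from a decoded state path."""
    meta = model.state_meta
    is_tu = np.array([m.role != ROLE_BACKGROUND for m in meta])
    tus: list[TURecord] = []
    dropped = 0
    n = len(state_path)
    i = 0
    serial = 0
    while i < n:
        if not is_tu[state_path[i]]:
            i += 1
            continue
        # maximal run of TU states
        j = i
        while j + 1 < n and is_tu[state_path[j + 1]]:
            j += 1
        # split the run into boundary-delimited segments; a prefix of body
        # states without an opening boundary (possible at sequence edges)
        # is dropped up to the next TSS/TTS bin
        seg_start = i
        while seg_start <= j:
            opening = meta[state_path[seg_start]].role
            if opening not in (ROLE_TSS, ROLE_TTS):
                nxt = seg_start
                while nxt <= j and meta[state_path[nxt]].role not in (ROLE_TSS, ROLE_TTS):
                    nxt += 1
                dropped += 1
                seg_start = nxt
                continue
            closing = ROLE_TTS if opening == ROLE_TSS else ROLE_TSS
            t = seg_start + 1
            while t <= j and meta[state_path[t]].role != closing:
                t += 1
            if t > j:  # no closing boundary before the run ends
                dropped += 1
                break
            rec = _make_record(state_path, tu_posterior, grid, model, seg_start, t, serial)
            if rec is None:
                dropped += 1
                seg_start = t  # the closing boundary may open the next segment
            else:
                tus.append(rec)
                serial += 1
                seg_start = t + 1
        i = j + 1
    if dropped:
        logger.warning("dropped %d TU-state runs failing the TSS/TTS boundary rule", dropped)
    return tus


def _make_record(
    state_path: np.ndarray,
    tu_posterior: np.ndarray,
    grid: BinGrid,
    model: HMMParameters,
    lo: int,
    hi: int,
    serial: int,
) -> TURecord | None:
    meta = model.state_meta
    if hi - lo + 1 < 3:  # TSS + >=1 body bin + TTS
        return None
    first, last = meta[state_path[lo]].role, meta[state_path[hi]].role
    body = [meta[s] for s in state_path[lo + 1 : hi]]
    if any(m.role in (ROLE_TSS, ROLE_TTS, ROLE_BACKGROUND) for m in body):
        return None
    strands = {m.strand for m in body}
    if first == ROLE_TSS and last == ROLE_TTS and strands == {"+"}:
        strand = "+"
    elif first == ROLE_TTS and last == ROLE_TSS and strands == {"-"}:
        strand = "-"
    else:
        return None
    contig, start, _ = grid.bin_bounds(lo)
    contig2, _, end = grid.bin_bounds(hi)
    if contig != contig2:
        return None
    return TURecord(
        id=f"TU{serial + 1:05d}",
        contig=contig,
        start=start,
        end=end,
        strand=strand,
        states=[meta[s].name for s in state_path[lo : hi + 1]],
        score=float(tu_posterior[lo : hi + 1].mean()),
    )


def write_tu_bed(tus: Sequence[TURecord], path: str | Path, header: str | None = None) -> None:
    """Write TU records as BED6; score = round(1000 × mean TU posterior)."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for tu in tus:
            score = int(round(1000 * min(max(tu.score, 0.0), 1.0)))
            fh.write(
                f"{tu.contig}\t{tu.start}\t{tu.end}\t{tu.id}\t{score}\t{tu.strand}\n"
            )


def call_tus(model: HMMParameters, class_matrix: ClassMatrix) -> list[TURecord]:
    """Convenience: decode the genome and refine the path into TU records."""
    states, tu_post = decode_genome(model, class_matrix)
    return refine_to_tus(states, tu_post, class_matrix.grid, model)
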