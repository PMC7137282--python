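"""Supervised training of the transcription-unit model.

From a transcript annotation, genome bins overlapping each transcript are
labelled with TU components (TSS, first/internal/last exons and introns,
TTS); body-internal transition probabilities are maximum-likelihood counts
along these bin-label sequences, and TU emission rows are mark frequencies
over labelled bins of transcripts that pass an RNA-Polymerase-II enrichment
filter. The remaining parameters — background emissions, every transition
touching TSS/TTS or background, and the initial distribution — are handed to
constrained Baum–Welch as free parameters.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .binarize import ClassMatrix
from .grid import BinGrid
from .hmm import EPS, HMMParameters, ObservationSequence, baum_welch
from .io import Transcript
from .topology import (
    BODY_ROLES,
    ROLE_TSS,
    ROLE_TTS,
    ModelTopology,
    build_topology,
)

__all__ = [
    "TrainingError",
    "BinLabelSequence",
    "label_annotation_bins",
    "component_coverage",
    "estimate_tu_transitions",
    "filter_polII_transcripts",
    "estimate_tu_emissions",
    "assemble_model",
    "train_model",
]

DEFAULT_SEED = 17


class TrainingError(ValueError):
    pass


@dataclass
class BinLabelSequence:
    """Per-transcript bin labels, stored in genome order."""

    transcript_id: str
    strand: str
    bins: np.ndarray  # global bin indices, genome order
    roles: list[str]  # component role per bin, genome order

    def oriented(self) -> tuple[np.ndarray, list[str]]:
        """(bins, roles) in transcript orientation (5'→3')."""
        if self.strand == "+":
            return self.bins, self.roles
        return self.bins[::-1], self.roles[::-1]


def _component_roles(n_exons: int) -> tuple[list[str], list[str]]:
    """Roles of exons and introns by transcript-orientation index."""
    exon_roles = []
    for e in range(n_exons):
        if e == 0:
            exon_roles.append("exon1")
        elif e == n_exons - 1:
            exon_roles.append("exonL")
        else:
            exon_roles.append("exonI")
    n_introns = n_exons - 1
    intron_roles = []
    for i in range(n_introns):
        if i == 0:
            intron_roles.append("intron1")
        elif i == n_introns - 1:
            intron_roles.append("intronL")
        else:
            intron_roles.append("intronI")
    return exon_roles, intron_roles


def _transcript_components(t: Transcript) -> list[tuple[int, int, str]]:
    """(start, end, role) per component, genome order."""
    n_exons = len(t.exons)
    exon_roles, intron_roles = _component_roles(n_exons)
    if t.strand == "-":
        exon_roles = exon_roles[::-1]
        intron_roles = intron_roles[::-1]
    comps = [(s, e, exon_roles[g]) for g, (s, e) in enumerate(t.exons)]
    comps += [(s, e, intron_roles[g]) for g, (s, e) in enumerate(t.introns)]
    comps.sort()
    return comps


def label_annotation_bins(
    transcripts: Sequence[Transcript],
    grid: BinGrid,
    min_bins: int = 3,
) -> list[BinLabelSequence]:
    """Label the bins each transcript overlaps with TU component roles.

    The TSS bin is the bin containing the transcript's 5' end (strand-aware)
    and the TTS bin the one containing its 3' end; they take precedence over
    body labels. Every other overlapped bin takes the role of the component
    covering the majority of the bin's overlap with the transcript (ties go
    to the component earliest in genome order). Transcripts spanning fewer
    than *min_bins* bins cannot host a TSS, body, and TTS and are skipped
    with a warning.
    """
    out: list[BinLabelSequence] = []
    skipped = 0
    w = grid.bin_width
    for t in transcripts:
        off = grid.contig_offset(t.contig)
        b0 = t.start // w
        bl = (t.end - 1) // w
        if bl - b0 + 1 < min_bins:
            skipped += 1
            continue
        comps = _transcript_components(t)
        roles: list[str] = []
        for local in range(b0, bl + 1):
            bin_start, bin_end = local * w, (local + 1) * w
            best_role, best_ov = None, -1
            for s, e, role in comps:
                ov = min(e, bin_end) - max(s, bin_start)
                if ov > best_ov and ov > 0:
                    best_role, best_ov = role, ov
            roles.append(best_role if best_role is not None else "exon1")
        tss_local, tts_local = (b0, bl) if t.strand == "+" else (bl, b0)
        roles[tss_local - b0] = ROLE_TSS
        roles[tts_local - b0] = ROLE_TTS
        out.append(
            BinLabelSequence(
                transcript_id=t.id,
                strand=t.strand,
                bins=np.arange(off + b0, off + bl + 1, dtype=np.int64),
                roles=roles,
            )
        )
    if skipped:
        warnings.warn(f"skipped {skipped} transcripts shorter than {min_bins} bins")
    return out


def component_coverage(transcripts: Sequence[Transcript], grid: BinGrid):
    """Per-transcript coverage (bp and bins) of each TU component.

    Every labelled bin contributes its overlap with the transcript to its
    role, so per-transcript bp coverages sum to the transcript length.
    """
    import pandas as pd

    labels = label_annotation_bins(transcripts, grid, min_bins=3)
    by_id = {t.id: t for t in transcripts}
    w = grid.bin_width
    rows = []
    for lab in labels:
        t = by_id[lab.transcript_id]
        bp: Counter = Counter()
        nbins: Counter = Counter()
        for gbin, role in zip(lab.bins, lab.roles):
            _, bin_start, bin_end = grid.bin_bounds(int(gbin))
            bp[role] += min(t.end, bin_end) - max(t.start, bin_start)
            nbins[role] += 1
        for role in bp:
            rows.append(
                {
                    "transcript_id": t.id,
                    "component": role,
                    "bp": int(bp[role]),
                    "bins": int(nbins[role]),
                }
            )
    return pd.DataFrame(rows, columns=["transcript_id", "component", "bp", "bins"])


def estimate_tu_transitions(
    labels: Sequence[BinLabelSequence],
    topology: ModelTopology | None = None,
) -> dict[tuple[str, str], float]:
    """Maximum-likelihood transition probabilities along bin-label sequences.

    Label pairs are counted in transcript orientation and mapped onto the
    forward chain; the reverse chain receives the strand-mirrored copy
    (the same counts, accumulated along the reversed sequences). Counts are
    normalized per source state over its observed targets. A body state that
    is never observed falls back to a uniform row over its allowed edges,
    with a warning. Observed pairs outside the topology's allowed edge set
    (caused by components shorter than a bin) are dropped with a warning, so
    no supervision mass ever lands on a forbidden edge.

    Returns ``{(src_state_name, dst_state_name): probability}`` covering both
    chains, including boundary edges into/out of TSS and TTS (those are free
    in the model but their ML estimates serve as EM starting points).
    """
    if topology is None:
        topology = build_topology()
    if not labels:
        raise TrainingError("no labelled transcripts")

    def _name(role: str, chain: str) -> str:
        return role if role in (ROLE_TSS, ROLE_TTS) else role + chain

    counts: dict[str, Counter] = defaultdict(Counter)
    for lab in labels:
        _, roles = lab.oriented()
        for a, b in zip(roles[:-1], roles[1:]):
            counts[_name(a, "+")][_name(b, "+")] += 1
        rev = roles[::-1]
        for a, b in zip(rev[:-1], rev[1:]):
            counts[_name(a, "-")][_name(b, "-")] += 1

    probs: dict[tuple[str, str], float] = {}
    off_grammar: Counter = Counter()
    for src, dsts in counts.items():
        i = topology.index[src]
        kept = {
            dst: c
            for dst, c in dsts.items()
            if topology.allowed[i, topology.index[dst]]
        }
        for dst, c in dsts.items():
            if dst not in kept:
                off_grammar[(src, dst)] += c
        total = sum(kept.values())
        for dst, c in kept.items():
            probs[(src, dst)] = c / total
    if off_grammar:
        # sub-bin components (an exon or intron shorter than a bin, or one
        # swallowed by the TSS/TTS bin) produce label adjacencies outside the
        # model grammar; they carry no supervision mass
        warnings.warn(
            f"dropped {sum(off_grammar.values())} off-grammar label transitions "
            f"({len(off_grammar)} distinct edges, e.g. {next(iter(off_grammar))})"
        )

    for role in BODY_ROLES:
        for chain in ("+", "-"):
            name = role + chain
            if name not in counts:
                i = topology.index[name]
                targets = np.flatnonzero(topology.allowed[i])
                warnings.warn(
                    f"component {name} never observed; uniform fallback over "
                    f"{len(targets)} allowed edges"
                )
                for j in targets:
                    probs[(name, topology.states[j].name)] = 1.0 / len(targets)
    return probs


def filter_polII_transcripts(
    labels: Sequence[BinLabelSequence],
    polII_calls: Mapping[str, np.ndarray] | np.ndarray,
    pooled: bool = True,
    seed: int = DEFAULT_SEED,
) -> tuple[list[BinLabelSequence], np.ndarray]:
    """Keep transcripts whose TSS/TTS bins are RNA-Pol-II enriched.

    Per transcript the feature is the mean binarized Pol II signal over its
    TSS and TTS bins; with several antibodies the means are either pooled
    into one scalar (default) or kept as a per-antibody feature vector.
    Transcripts are split by 2-means clustering (fixed seed) and the cluster
    with the higher pooled mean is retained. If all features are identical
    the clustering is degenerate and every transcript is retained, with a
    warning.

    Returns the retained labels and the boolean retained mask.
    """
    from sklearn.cluster import KMeans

    if isinstance(polII_calls, np.ndarray):
        polII_calls = {"polII": polII_calls}
    if not polII_calls:
        raise TrainingError("need at least one Pol II call vector")
    if len(labels) < 2:
        raise TrainingError("need at least two transcripts to cluster")
    vectors = [np.asarray(v, dtype=np.float64) for v in polII_calls.values()]
    feats = np.empty((len(labels), len(vectors)))
    for li, lab in enumerate(labels):
        ends = [int(lab.bins[0]), int(lab.bins[-1])]  # TSS and TTS bins
        for vi, v in enumerate(vectors):
            feats[li, vi] = v[ends].mean()
    pooled_feat = feats.mean(axis=1)
    X = pooled_feat[:, None] if pooled else feats
    if np.allclose(X, X[0]):
        warnings.warn("all Pol II features identical; retaining all transcripts")
        return list(labels), np.ones(len(labels), dtype=bool)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(X)
    means = [pooled_feat[km.labels_ == c].mean() for c in (0, 1)]
    keep = km.labels_ == int(np.argmax(means))
    return [lab for lab, k in zip(labels, keep) if k], keep


def estimate_tu_emissions(
    labels: Sequence[BinLabelSequence],
    class_matrix: ClassMatrix,
    by_strand: bool = False,
) -> dict[str, np.ndarray]:
    """Per-role mark frequencies over labelled bins: e = #(mark on) / #bins.

    By default forward- and reverse-strand transcripts share emission rows
    per role (a transcribed gene body carries the same marks regardless of
    strand); ``by_strand=True`` unties them, keying body roles as
    ``role+strand``. Roles with no labelled bins fall back to a uniform 0.5
    row with a warning. Entries are clipped to [1e-6, 1 − 1e-6].
    """
    if not labels:
        raise TrainingError("no labelled transcripts after filtering")
    n = class_matrix.n_marks
    num: dict[str, np.ndarray] = defaultdict(lambda: np.zeros(n))
    den: Counter = Counter()
    for lab in labels:
        for gbin, role in zip(lab.bins, lab.roles):
            key = role
            if by_strand and role not in (ROLE_TSS, ROLE_TTS):
                key = role + lab.strand
            num[key] += class_matrix.values[int(gbin)]
            den[key] += 1
    keys = [ROLE_TSS, ROLE_TTS] + (
        [r + s for r in BODY_ROLES for s in "+-"] if by_strand else list(BODY_ROLES)
    )
    out: dict[str, np.ndarray] = {}
    for key in keys:
        if den[key] == 0:
            warnings.warn(f"no bins labelled {key}; uniform 0.5 emission fallback")
            out[key] = np.full(n, 0.5)
        else:
            out[key] = np.clip(num[key] / den[key], EPS, 1 - EPS)
    return out


def assemble_model(
    topology: ModelTopology,
    transitions: Mapping[tuple[str, str], float],
    emissions: Mapping[str, np.ndarray],
    class_matrix: ClassMatrix,
    by_strand: bool = False,
) -> HMMParameters:
    """Build the full parameter set with supervision clamps installed.

    Body-internal transition entries come from *transitions* and are clamped;
    free transition entries (anything touching TSS/TTS or background) start
    uniform over the row's remaining mass. TU emission rows come from *emissions* and are
    clamped; background emission rows start from genome-wide mark
    frequencies, scaled per background state to break symmetry. The initial
    distribution starts uniform and is fully free.
    """
    k = topology.k
    n = class_matrix.n_marks
    A = np.zeros((k, k))
    supervised = topology.supervised
    for i in range(k):
        sup_j = np.flatnonzero(supervised[i])
        for j in sup_j:
            src, dst = topology.states[i].name, topology.states[j].name
            A[i, j] = transitions.get((src, dst), 0.0)
        free_j = np.flatnonzero(topology.free_transition[i])
        if len(free_j) == 0:
            continue
        clamped_mass = A[i].sum()
        if clamped_mass >= 1 - 1e-9:
            # degenerate annotation (e.g. no transcript ever leaves this
            # component to a free target): reserve a little free mass
            warnings.warn(
                f"row {topology.states[i].name}: supervised mass {clamped_mass:.4f} "
                "leaves nothing for free edges; rescaling to 0.999"
            )
            A[i, sup_j] *= (1 - 1e-3) / clamped_mass
            clamped_mass = 1 - 1e-3
        # free entries start uniform over the row's remaining mass; a
        # data-driven start could be exactly 0, which multiplicative EM
        # updates can never leave
        A[i, free_j] = (1.0 - clamped_mass) / len(free_j)

    emission = np.empty((k, n))
    genome_freq = np.clip(class_matrix.values.mean(axis=0), EPS, 1 - EPS)
    bg_scales = np.linspace(0.5, 1.5, int(topology.free_emission.sum()))
    bg_i = 0
    for i, meta in enumerate(topology.states):
        if topology.free_emission[i]:
            emission[i] = np.clip(genome_freq * bg_scales[bg_i], EPS, 1 - EPS)
            bg_i += 1
        else:
            key = meta.role
            if by_strand and meta.role not in (ROLE_TSS, ROLE_TTS):
                key = meta.role + meta.strand
            if key not in emissions:
                raise TrainingError(f"missing supervised emission row for {key!r}")
            row = np.asarray(emissions[key], dtype=np.float64)
            if row.shape != (n,):
                raise TrainingError(
                    f"emission row {key!r} has {row.shape} marks, class matrix has {n}"
                )
            emission[i] = row

    free_emission = np.repeat(topology.free_emission[:, None], n, axis=1)
    return HMMParameters(
        emission=emission,
        transition=A,
        initial=np.full(k, 1.0 / k),
        structural_zero=topology.structural_zero,
        free_transition=topology.free_transition,
        free_emission=free_emission,
        free_initial=np.ones(k, dtype=bool),
        state_meta=list(topology.states),
        marks=list(class_matrix.marks),
    )


def sequences_from_class_matrix(class_matrix: ClassMatrix) -> list[ObservationSequence]:
    """One observation sequence per contig (contigs are independent)."""
    return [
        ObservationSequence(values=block, contig=name, start_bin=start)
        for name, start, block in class_matrix.contig_blocks()
    ]


def train_model(
    transcripts: Sequence[Transcript],
    class_matrix: ClassMatrix,
    polII_calls: Mapping[str, np.ndarray] | np.ndarray,
    grid: BinGrid | None = None,
    seed: int = DEFAULT_SEED,
    max_iter: int = 100,
    tol: float = 1e-6,
    by_strand: bool = False,
    polII_pooled: bool = True,
) -> tuple[HMMParameters, dict]:
    """End-to-end supervised training.

    1. label annotation bins; 2. estimate body transitions from all
    transcripts; 3. filter transcripts by Pol II enrichment at TSS/TTS;
    4. estimate TU emissions from the filtered set; 5. assemble the 17-state
    model and fit the free parameters by constrained Baum–Welch on the class
    matrix (one sequence per contig, pooled sufficient statistics).
    """
    if grid is None:
        grid = class_matrix.grid
    topology = build_topology()
    labels = label_annotation_bins(transcripts, grid)
    if not labels:
        raise TrainingError("no usable transcripts in annotation")
    transitions = estimate_tu_transitions(labels, topology)
    filtered, keep = filter_polII_transcripts(
        labels, polII_calls, pooled=polII_pooled, seed=seed
    )
    emissions = estimate_tu_emissions(filtered, class_matrix, by_strand=by_strand)
    params = assemble_model(topology, transitions, emissions, class_matrix, by_strand)
    sequences = sequences_from_class_matrix(class_matrix)
    params, trace = baum_welch(params, sequences, max_iter=max_iter, tol=tol)
    info = {
        "n_transcripts": len(labels),
        "n_filtered": len(filtered),
        "retained_mask": keep,
        "loglik_trace": trace,
    }
    return params, info
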