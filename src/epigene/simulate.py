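"""Seeded synthetic-data generators.

These emulate the statistical structure the TU model assumes: a toy genome
carrying non-overlapping multi-exon transcripts on both strands, per-bin
histone-mark presence drawn from per-role Bernoulli archetypes, ChIP/control
read counts as binomial draws whose ChIP fraction is higher in enriched
bins, Pol II and nascent-RNA evidence derived from the planted TUs, and
class matrices sampled directly from a known HMM. Every generator is a pure
function of its configuration and seed.

The defaults define the study conditions used throughout the test suite:
a ~2 Mb two-contig genome at 200-bp bins carrying 40 TUs, well-separated
active-mark archetypes (promoter marks H3K4me3/H3K27ac at the TSS,
elongation mark H3K36me3 through the gene body, near-absent active marks in
background), and per-bin sequencing depth of 20–100 fragments with ChIP
fractions of 0.9 (enriched) versus 0.5 (background, i.e. ChIP ≈ control).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .binarize import ClassMatrix
from .grid import BinGrid, CountTrack, GenomicInterval
from .hmm import HMMParameters, ObservationSequence
from .io import Transcript
from .topology import BODY_ROLES, ROLE_BACKGROUND, ROLE_TSS, ROLE_TTS

__all__ = [
    "SimulationError",
    "SimulationConfig",
    "DEFAULT_MARKS",
    "simulate_annotation",
    "simulate_class_matrix",
    "simulate_counts",
    "SimulatedDataset",
    "simulate_dataset",
]


class SimulationError(ValueError):
    pass


DEFAULT_MARKS = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K36me3", "H3K27me3", "H3K9me3")

# Per-role mark-presence probabilities. Promoter marks peak at the TSS,
# H3K36me3 rises through the transcribed body, the enhancer-associated
# H3K4me1 flanks promoters, repressive marks stay near background in
# active TUs and slightly elevated in background chromatin.
DEFAULT_ARCHETYPES: dict[str, dict[str, float]] = {
    ROLE_TSS: {"H3K27ac": 0.90, "H3K4me1": 0.50, "H3K4me3": 0.95, "H3K36me3": 0.15, "H3K27me3": 0.02, "H3K9me3": 0.02},
    "exon1": {"H3K27ac": 0.60, "H3K4me1": 0.40, "H3K4me3": 0.50, "H3K36me3": 0.70, "H3K27me3": 0.02, "H3K9me3": 0.02},
    "intron1": {"H3K27ac": 0.35, "H3K4me1": 0.50, "H3K4me3": 0.15, "H3K36me3": 0.60, "H3K27me3": 0.02, "H3K9me3": 0.02},
    "exonI": {"H3K27ac": 0.25, "H3K4me1": 0.30, "H3K4me3": 0.10, "H3K36me3": 0.90, "H3K27me3": 0.02, "H3K9me3": 0.02},
    "intronI": {"H3K27ac": 0.15, "H3K4me1": 0.40, "H3K4me3": 0.05, "H3K36me3": 0.70, "H3K27me3": 0.02, "H3K9me3": 0.02},
    "exonL": {"H3K27ac": 0.15, "H3K4me1": 0.20, "H3K4me3": 0.05, "H3K36me3": 0.90, "H3K27me3": 0.02, "H3K9me3": 0.02},
    "intronL": {"H3K27ac": 0.15, "H3K4me1": 0.35, "H3K4me3": 0.05, "H3K36me3": 0.70, "H3K27me3": 0.02, "H3K9me3": 0.02},
    ROLE_TTS: {"H3K27ac": 0.15, "H3K4me1": 0.20, "H3K4me3": 0.05, "H3K36me3": 0.80, "H3K27me3": 0.02, "H3K9me3": 0.02},
    ROLE_BACKGROUND: {"H3K27ac": 0.03, "H3K4me1": 0.05, "H3K4me3": 0.03, "H3K36me3": 0.03, "H3K27me3": 0.10, "H3K9me3": 0.10},
}


@dataclass
class SimulationConfig:
    """Everything the generators need; outputs are a pure function of this."""

    seed: int = 17
    contig_sizes: dict = field(
        default_factory=lambda: {"chrS1": 1_200_000, "chrS2": 800_000}
    )
    bin_width: int = 200
    n_tus: int = 40
    mean_exons: float = 3.0  # exons per transcript: 1 + Poisson(mean − 1)
    mean_exon_bins: float = 3.0  # exon length: 1 + Geometric
    mean_intron_bins: float = 8.0
    mean_gap_bins: float = 60.0  # intergenic spacing between TUs
    marks: tuple = DEFAULT_MARKS
    archetypes: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ARCHETYPES.items()})
    # binomial count model: per-bin trials and ChIP success probabilities
    trials_min: int = 20
    trials_max: int = 100
    enriched_frac: float = 0.9
    background_frac: float = 0.5
    # Pol II occupancy (TU bins vs background) and antibody count
    polii_tu_prob: float = 0.9
    polii_bg_prob: float = 0.02
    n_polii_antibodies: int = 2
    # fraction of TUs withheld from nascent-RNA evidence (Pol II-positive,
    # RNA-seq-negative TUs)
    nascent_dropout: float = 0.0

    def __post_init__(self) -> None:
        for role, table in self.archetypes.items():
            for mark, p in table.items():
                if not 0 <= p <= 1:
                    raise SimulationError(f"archetype {role}/{mark} = {p} outside [0, 1]")
        if not 0 <= self.nascent_dropout <= 1:
            raise SimulationError("nascent_dropout must be in [0, 1]")
        if not (0 < self.background_frac < 1 and 0 < self.enriched_frac < 1):
            raise SimulationError("count-model fractions must be in (0, 1)")

    def grid(self) -> BinGrid:
        return BinGrid(list(self.contig_sizes.items()), bin_width=self.bin_width)

    def to_dict(self) -> dict:
        return asdict(self)


def _geometric_len(rng: np.random.Generator, mean: float) -> int:
    """1 + Geometric run length with the given mean (mean >= 1)."""
    if mean <= 1:
        return 1
    return 1 + rng.geometric(1.0 / mean)  # support {1, 2, ...}


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[Transcript], list[GenomicInterval]]:
    """Place non-overlapping, bin-aligned multi-exon transcripts.

    Returns the transcripts and matching truth TU intervals. Raises if the
    genome cannot host the requested number of TUs.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w = config.bin_width
    transcripts: list[Transcript] = []
    truth: list[GenomicInterval] = []
    remaining = config.n_tus
    for contig, length in config.contig_sizes.items():
        nbins = length // w
        cursor = 0
        while remaining > 0:
            cursor += _geometric_len(rng, config.mean_gap_bins)
            n_exons = 1 + rng.poisson(max(config.mean_exons - 1, 0))
            exon_bins = [_geometric_len(rng, config.mean_exon_bins) for _ in range(n_exons)]
            intron_bins = [
                _geometric_len(rng, config.mean_intron_bins) for _ in range(n_exons - 1)
            ]
            total = sum(exon_bins) + sum(intron_bins)
            if total < 3:  # must host TSS, body, and TTS bins
                exon_bins[0] += 3 - total
                total = 3
            if cursor + total > nbins:
                break
            start = cursor * w
            exons = []
            pos = start
            for e in range(n_exons):
                exons.append((pos, pos + exon_bins[e] * w))
                pos += exon_bins[e] * w
                if e < n_exons - 1:
                    pos += intron_bins[e] * w
            end = start + total * w
            strand = "+" if rng.random() < 0.5 else "-"
            tid = f"sim_tu_{config.n_tus - remaining + 1:04d}"
            transcripts.append(Transcript(tid, contig, start, end, strand, exons))
            truth.append(GenomicInterval(contig, start, end, strand, tid))
            cursor += total
            remaining -= 1
    if remaining > 0:
        raise SimulationError(
            f"genome too small: placed {config.n_tus - remaining} of {config.n_tus} TUs"
        )
    return transcripts, truth


def simulate_class_matrix(
    model: HMMParameters,
    grid: BinGrid,
    rng: np.random.Generator | int = 0,
) -> tuple[ClassMatrix, np.ndarray]:
    """Ancestral sampling: states along each contig, then Bernoulli marks.

    Returns the class matrix and the true state path (for recovery tests).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    m = grid.n_bins
    path = np.empty(m, dtype=np.int64)
    cum_init = np.cumsum(model.initial)
    cum_trans = np.cumsum(model.transition, axis=1)
    for name, _ in grid.contigs:
        sl = grid.contig_slice(name)
        u = rng.random(sl.stop - sl.start)
        s = int(np.searchsorted(cum_init, u[0] * cum_init[-1]))
        path[sl.start] = s
        for t in range(1, sl.stop - sl.start):
            row = cum_trans[s]
            s = int(np.searchsorted(row, u[t] * row[-1]))
            path[sl.start + t] = s
    obs = (rng.random((m, model.n)) < model.emission[path]).astype(np.uint8)
    marks = model.marks if model.marks is not None else [f"mark{j}" for j in range(model.n)]
    return ClassMatrix(grid, list(marks), obs), path


def simulate_counts(
    enrichment_mask: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    grid: BinGrid | None = None,
) -> tuple[CountTrack, CountTrack]:
    """ChIP/control count pair for a truth enrichment mask.

    Per bin, ``t`` total fragments are drawn uniformly from the configured
    depth range and split binomially between ChIP and control with ChIP
    success probability ``enriched_frac`` where the mask is 1, else
    ``background_frac``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if grid is None:
        grid = config.grid()
    mask = np.asarray(enrichment_mask)
    if mask.shape != (grid.n_bins,):
        raise SimulationError("enrichment mask does not match the grid")
    t = rng.integers(config.trials_min, config.trials_max + 1, size=grid.n_bins)
    p = np.where(mask > 0, config.enriched_frac, config.background_frac)
    chip = rng.binomial(t, p)
    return CountTrack(grid, chip), CountTrack(grid, t - chip)


@dataclass
class SimulatedDataset:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SimulationConfig
    grid: BinGrid
    transcripts: list[Transcript]
    tu_intervals: list[GenomicInterval]
    truth_roles: list[str]  # per-bin component role ('background' outside TUs)
    mark_presence: np.ndarray  # (m, n) truth enrichment per mark
    counts: dict  # mark -> (chip CountTrack, control CountTrack)
    polii_presence: np.ndarray
    polii_counts: dict  # antibody -> (chip, control)
    nascent_intervals: list[GenomicInterval]
    truth_tu_mask: np.ndarray  # per-bin 1 iff inside a planted TU


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full study fixture from one seed.

    Truth roles come from the same bin-labelling rule training uses; mark
    presence is Bernoulli per (bin role, mark) from the archetype table; Pol
    II occupancy covers whole TUs; nascent evidence is the truth TU interval
    set minus the configured dropout fraction.
    """
    from .grid import intervals_to_bin_mask
    from .training import label_annotation_bins

    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    transcripts, truth = simulate_annotation(config, rng)
    labels = label_annotation_bins(transcripts, grid)
    roles = [ROLE_BACKGROUND] * grid.n_bins
    for lab in labels:
        for gbin, role in zip(lab.bins, lab.roles):
            roles[int(gbin)] = role

    marks = list(config.marks)
    arch = np.array(
        [[config.archetypes[role][mark] for mark in marks] for role in
         [ROLE_TSS, ROLE_TTS, *BODY_ROLES, ROLE_BACKGROUND]]
    )
    role_index = {r: i for i, r in enumerate([ROLE_TSS, ROLE_TTS, *BODY_ROLES, ROLE_BACKGROUND])}
    role_idx = np.array([role_index[r] for r in roles])
    mark_presence = (rng.random((grid.n_bins, len(marks))) < arch[role_idx]).astype(np.uint8)

    counts = {
        mark: simulate_counts(mark_presence[:, j], config, rng, grid)
        for j, mark in enumerate(marks)
    }

    tu_mask = intervals_to_bin_mask(truth, grid)
    p_polii = np.where(tu_mask > 0, config.polii_tu_prob, config.polii_bg_prob)
    polii_presence = (rng.random(grid.n_bins) < p_polii).astype(np.uint8)
    polii_counts = {
        f"polII_ab{i + 1}": simulate_counts(polii_presence, config, rng, grid)
        for i in range(config.n_polii_antibodies)
    }

    keep = rng.random(len(truth)) >= config.nascent_dropout
    nascent = [iv for iv, k in zip(truth, keep) if k]
    return SimulatedDataset(
        config=config,
        grid=grid,
        transcripts=transcripts,
        tu_intervals=truth,
        truth_roles=roles,
        mark_presence=mark_presence,
        counts=counts,
        polii_presence=polii_presence,
        polii_counts=polii_counts,
        nascent_intervals=nascent,
        truth_tu_mask=tu_mask,
    )
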