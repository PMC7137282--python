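# Methods

## Binning and coordinates

All internal coordinates are 0-based half-open; GTF (1-based inclusive) is
converted at the boundary. The genome is tiled per contig with
non-overlapping bins of fixed width (default 200 bp, roughly one nucleosome
plus spacer); the last bin of a contig may be shorter. Bins carry a global
integer index across contigs. Fragment counting from BAM/SAM assigns each
retained properly paired fragment to the bin containing its midpoint,
`floor((leftmost_start + rightmost_end)/2)`, keeping reads with MAPQ ≥ 255
(unique alignments under STAR's convention) and dropping reads with flag bit
1024 (duplicates); both cutoffs are parameters. Single-end reads, if
present, contribute their own midpoint with a warning. Precomputed per-bin
count TSVs are accepted everywhere a BAM is, which also makes the package
fully testable from text fixtures.

## Enrichment calling

Per mark, bin counts `s_i` (ChIP) out of `t_i = chip_i + control_i` trials
are modelled as a two-component binomial mixture (background: ChIP and
control at comparable rates, ~0.5 ChIP fraction after equal sequencing
depth; enriched: higher ChIP fraction). Bins with `t_i = 0` carry no
information: they are excluded from the fit and never called. EM runs to a
log-likelihood tolerance of 1e-8 (max 1000 iterations) from a deterministic
start (background at the median per-bin ChIP fraction, enriched at the 90th
percentile, uniform weights); the log-likelihood is asserted non-decreasing.
The component with the larger success probability is "enriched". Bins are
ranked by decreasing posterior enrichment probability (ties broken by bin
index, so output is deterministic) and the q-value of a bin is the running
mean of (1 − posterior) down this ranking; a bin is called iff its q-value
is at or below the target FDR (default 0.2).

Two properties of this rule matter for interpretation. First, the q-value
sequence is monotone along the ranking by construction. Second, the rule
controls the *average* false-discovery fraction, so with sharply bimodal
posteriors it deliberately admits low-posterior bins until the average
reaches the threshold: at FDR 0.2 expect recall near 1 and precision near
0.8 on well-separated data. Callers who want a precision-oriented call set
should lower the FDR (0.05 gives F1 ≥ 0.95 on the default fixture); the
downstream HMM is robust to the permissive default because it smooths over
isolated false calls.

This module is a self-contained enrichment caller with the two parameters
the workflow needs (zero-count filtering, target FDR); externally produced
binarizations can be substituted via TSV at any point.

## The transcription-unit HMM

Observations are rows of the m × n binary class matrix; emission per state
is a product of independent Bernoullis, one per mark. The topology has 17
states: shared TSS and TTS, six gene-body roles (first/internal/last exon
and intron) per strand, and three background states. In genome order the
forward chain runs TSS→exon1→…→exonL→TTS and the reverse chain
TTS→exonL→…→exon1→TSS (the grammar mirrored edge-by-edge). Background
states form a free 3 × 3 block and connect to the TU chains only through
TSS/TTS; no edge joins forward and reverse body states; TSS and TTS have no
self-transitions (they occupy single bins, matching the labelling rule
below). Everything outside the allowed edge set is a structural zero —
exactly 0, never updated.

Parameters split into clamped and free sets. Clamped (supervised):
body-internal transitions and all TU emission rows. Free (fitted):
background emission rows, every allowed transition whose source or target
is TSS, TTS, or background (this includes TSS↔TTS and chain entry/exit
edges such as exon1→TTS), and the initial distribution.

Numerics: forward/backward uses per-position scaling with a per-bin shift
of the emission log-likelihood maximum, so sequences of 10^6 bins run
without underflow; Viterbi runs in log space with ties resolved to the
lowest state index. Emission estimates are clipped to [1e-6, 1 − 1e-6]
(supervised values may be exact 0/1); structural zeros stay exact. Each
contig is an independent sequence starting from the initial distribution;
Baum–Welch pools sufficient statistics across contigs. The constrained
M-step leaves clamped entries bit-identical and gives the free entries of
each transition row the row's leftover mass in proportion to their expected
counts, so rows remain stochastic. Constrained EM is still EM — the
log-likelihood is non-decreasing, and the implementation raises if an
iteration ever decreases it by more than 1e-8. A parameter row whose
clamped mass is already ≥ 1 while free entries remain is rejected at
construction; during model assembly the analogous degeneracy (an annotation
in which, say, no transcript is single-exon, putting zero observed mass on
exon1→TTS) is resolved by rescaling the clamped entries to 0.999 with a
warning rather than erroring, since the input is legitimate.

Models serialize to versioned JSON (matrices, masks, mark order, state
metadata), which is how a trained model is applied to new datasets without
retraining.

## Supervised training

1. **Labelling.** Bins overlapping each annotated transcript are labelled:
   the bin containing the 5′ end (strand-aware) is TSS, the 3′-end bin is
   TTS, and every other overlapped bin takes the component (exon/intron,
   indexed in transcript orientation) covering the majority of the bin,
   ties to the earliest component in genome order. Transcripts spanning
   fewer than 3 bins cannot host TSS, body, and TTS and are skipped.
   Components shorter than a bin can produce label adjacencies outside the
   model grammar (e.g. TSS directly followed by intron1); such pairs are
   dropped from supervision with a warning.
2. **Transitions.** Label pairs are counted along each transcript in
   transcript orientation (pooled over all transcripts and both strands)
   and normalized per source state; the reverse chain receives the
   mirrored copy, obtained by counting the reversed sequences. A body
   state never observed falls back to a uniform row over its allowed
   edges. Transitions are estimated from the full annotation.
3. **Pol II filter.** Per transcript, the mean binarized Pol II signal
   over its TSS and TTS bins (averaged across antibodies by default; a
   flag keeps per-antibody features) is clustered by 2-means with a fixed
   seed (default 17); the cluster with the higher mean is kept. If all
   features are identical the filter degenerates and keeps everything,
   with a warning. Only emissions use the filtered set.
4. **Emissions.** Per role, the emission probability of mark j is the
   fraction of role-labelled bins with a call for j, clipped to
   [1e-6, 1 − 1e-6]. Forward and reverse chains share emission rows per
   role by default — a transcribed gene body carries the same marks
   regardless of strand — with an untie flag to learn 12 independent body
   rows when the data warrant it. A role with no labelled bins falls back
   to a uniform 0.5 row.
5. **Assembly and EM.** Background emissions start at genome-wide mark
   frequencies scaled by (0.5, 1.0, 1.5) per background state — the scaling
   breaks the permutation symmetry of the three states deterministically.
   Free transition entries start uniform over each row's remaining mass
   (a count-based start could be exactly zero, which multiplicative EM
   updates can never leave); the initial distribution starts uniform.
   Constrained Baum–Welch then fits the free set (default: up to 100
   iterations, tolerance 1e-6 on the total log-likelihood).

## TU calling

One Viterbi and one forward/backward pass per contig. The per-bin TU
posterior (summed posterior mass of the 14 TU states) is the ranking score
used in evaluation. Maximal runs of TU states are split at boundary-state
changes and emitted as TUs iff, in genome order, they open with TSS and
close with TTS over forward-chain body states ("+"), or open with TTS and
close with TSS over reverse-chain body states ("−"); each TU therefore
spans at least 3 bins. Runs violating the rule — possible only at sequence
edges, since structural zeros enforce the grammar elsewhere, or when the
path wanders between boundary states without a proper body — are dropped
and counted in the log. No merging across background gaps and no further
length or posterior filter is applied; the topology already encodes the
TSS…TTS structure, and any extra refinement would be an undocumented
heuristic. Output is BED6 with score = round(1000 × mean TU posterior).

## Evaluation

The gold standard marks a bin actively transcribed iff the binarized Pol II
ChIP call AND the nascent-RNA call (≥ 1 bp overlap with a nascent
transcript) are both 1; bins under an optional exclusion track (assembly
gaps) leave every tally. Contingency counts give precision, recall and
specificity; ROC and PRC curves are built over descending score thresholds
with ties grouped, and AUCs are trapezoidal, integrated in threshold order
(so tied-recall points form zero-width segments). For score-less binary
prediction sets the curves degenerate to the single operating point plus
endpoints, which keeps cross-method numbers interpretable but not
equivalent to score-based AUCs. Because active bins are heavily
outnumbered, the headline estimator subsamples: each of n iterations takes
all positive bins (or a configured number) plus an equally sized random
draw of negatives, computes the curve AUC, and the estimate is
mean(L_AUC) − stdDev(L_AUC)/√n with the sample (n−1) standard deviation —
a conservative shrinkage of the mean by its spread. Resolution changes
(50/100/200/500 bp) recompute masks from intervals on a fresh grid;
vector-only input can only be coarsened (logical OR of child bins).

## Synthetic fixtures: what they emulate, and what they don't

The generator is a pure function of its config and seed. Defaults define
the study conditions used by the tests and the acceptance script: a two
contig, ~2 Mb genome at 200-bp bins; 40 non-overlapping, bin-aligned,
multi-exon transcripts (exon count 1 + Poisson(2), so ~13% single-exon;
exon/intron/gap lengths geometric with means 3/8/60 bins) on both strands;
per-role mark-presence probabilities with promoter marks at the TSS
(H3K4me3 0.95, H3K27ac 0.90), H3K36me3 rising through the body (0.6–0.9),
H3K4me1 flanking promoters, and background nearly devoid of active marks
(0.03–0.05) with mildly elevated repressive marks; sequencing depth 20–100
fragments per bin split binomially with ChIP fraction 0.9 in enriched bins
versus 0.5 in background; Pol II occupancy 0.9 across TU bins versus 0.02
outside, observed by two antibodies; nascent evidence equal to the planted
TU intervals minus a configurable dropout (default 0) that emulates
Pol II-positive but RNA-seq-negative TUs.

Not emulated: overdispersed count noise (binomial thinning, not negative
binomial — an NB option would add one parameter but the method consumes
only binarized calls), copy-number and mappability artefacts, fragment-level
read placement, overlapping/nested transcripts, sub-bin exon boundaries
(transcripts are bin-aligned), and enhancer states that mimic promoter
chromatin. Passing tests therefore demonstrate the correctness of the
machinery and its behaviour under the stated noise model, not performance
on real chromatin.

The background-emission recovery experiment gives the three background
states persistent dwell (self-transition 0.9, ~10-bin domains — chromatin
domains are persistent in reality) and distinct flavours (quiescent,
polycomb-like K27me3-high, heterochromatin-like K9me3-high). Persistence
matters: with memoryless background transitions the three states are
separable only as a static mixture and EM converges too slowly to matter,
whereas with domain structure the HMM context identifies them quickly.

The packaged `synthetic_pretrained_model.json` is trained on the default
fixture (seed 17) and exists to exercise the apply-without-retraining
workflow mechanically; it is synthetic and carries no information about any
real cell line.

## Problem sizes and determinism

Default test and acceptance workloads: 10,000-bin genomes for the
end-to-end pipeline, 50,000 bins for 2-state recovery, 100,000 bins for the
17-state background recovery, 100 random instances (k ≤ 4, T ≤ 8) for the
enumeration cross-checks. All randomness flows through
`numpy.random.default_rng` seeds held in the simulation config or passed
explicitly; k-means uses a fixed `random_state`. Reruns at the same seed
are byte-identical down to the written BED/GTF/TSV files.

## Known limitations

- Exon/intron sub-structure within a called TU is reported as state labels
  but not validated against splicing; the marks do not resolve functional
  versus non-functional exon use.
- Nested or bidirectionally overlapping TUs cannot be represented: one bin
  holds one state.
- TUs truncated by contig ends (or abutting TUs whose shared boundary bin
  serves both) can be dropped by the boundary rule; the count of dropped
  runs is logged.
- The Pol II transcript filter assumes a bimodal enrichment pattern; on
  uniformly active annotations the 2-means split can discard genuinely
  active transcripts whose TSS/TTS bins missed a call.
- The binarization FDR is an average-posterior control, not a per-bin
  guarantee; see the enrichment-calling section for the precision/recall
  trade-off at the default threshold.
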