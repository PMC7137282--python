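"""The 17-state transcription-unit model topology.

14 TU states and 3 background states. The TU chain is duplicated so that the
gene-body grammar runs TSS→…→TTS in genome order on the forward strand and
TTS→…→TSS on the reverse strand; the TSS and TTS states themselves are
shared between the two chains (6 body roles × 2 strands + TSS + TTS = 14).

Body roles follow the transcript grammar in transcript orientation::

    TSS → exon1 → (intron1 → (exonI → intronI)* → (exonI →) intronL → exonL
                   | intron1 → exonL) → TTS
    TSS → exon1 → TTS                      (single-exon transcripts)

Transitions *within* the body chains are supervised (estimated from an
annotation and clamped). Every allowed transition whose source or target is
TSS, TTS, or a background state is free (fitted by constrained Baum–Welch),
as are the background emission rows and the initial distribution. Everything
outside the allowed edge set is a structural zero; background states connect
to the TU chains only through TSS/TTS, and no edge links a forward gene-body
state to a reverse one. TSS and TTS occupy single bins (no self-transitions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hmm import StateMeta

__all__ = [
    "ROLE_TSS",
    "ROLE_TTS",
    "ROLE_BACKGROUND",
    "BODY_ROLES",
    "TU_ROLES",
    "ModelTopology",
    "build_topology",
]

ROLE_TSS = "TSS"
ROLE_TTS = "TTS"
ROLE_BACKGROUND = "background"
BODY_ROLES = ("exon1", "intron1", "exonI", "intronI", "exonL", "intronL")
TU_ROLES = (ROLE_TSS,) + BODY_ROLES + (ROLE_TTS,)

# body-internal grammar in transcript orientation (source role -> target roles)
_BODY_GRAMMAR = {
    "exon1": ("exon1", "intron1"),
    "intron1": ("intron1", "exonI", "exonL"),
    "exonI": ("exonI", "intronI", "intronL"),
    "intronI": ("intronI", "exonI"),
    "intronL": ("intronL", "exonL"),
    "exonL": ("exonL",),
}
# boundary edges in transcript orientation; free because they touch TSS/TTS
_BOUNDARY_GRAMMAR = (
    (ROLE_TSS, "exon1"),
    ("exon1", ROLE_TTS),
    ("exonL", ROLE_TTS),
)


@dataclass(frozen=True)
class ModelTopology:
    """State list plus allowed-edge and supervised/free masks (k = 17)."""

    states: tuple[StateMeta, ...]
    allowed: np.ndarray  # (k, k) bool
    free_transition: np.ndarray  # (k, k) bool; allowed & ~free == supervised
    free_emission: np.ndarray  # (k, n-agnostic) per-state bool (row level)
    index: dict  # state name -> index

    @property
    def k(self) -> int:
        return len(self.states)

    @property
    def structural_zero(self) -> np.ndarray:
        return ~self.allowed

    @property
    def supervised(self) -> np.ndarray:
        return self.allowed & ~self.free_transition

    def state_name(self, role: str, strand: str) -> str:
        if role in (ROLE_TSS, ROLE_TTS):
            return role
        if role == ROLE_BACKGROUND:
            raise KeyError("background states are not addressed by role/strand")
        return role + strand

    def mirror_permutation(self) -> np.ndarray:
        """Permutation swapping forward and reverse body states."""
        perm = np.arange(self.k)
        for role in BODY_ROLES:
            i, j = self.index[role + "+"], self.index[role + "-"]
            perm[i], perm[j] = j, i
        return perm


def build_topology(n_background: int = 3) -> ModelTopology:
    """Construct the duplicated-chain TU topology with background states."""
    states: list[StateMeta] = [StateMeta(ROLE_TSS, ROLE_TSS, "na")]
    states += [StateMeta(r + "+", r, "+") for r in BODY_ROLES]
    states.append(StateMeta(ROLE_TTS, ROLE_TTS, "na"))
    states += [StateMeta(r + "-", r, "-") for r in BODY_ROLES]
    states += [
        StateMeta(f"bg{i + 1}", ROLE_BACKGROUND, "na") for i in range(n_background)
    ]
    k = len(states)
    index = {m.name: i for i, m in enumerate(states)}
    allowed = np.zeros((k, k), dtype=bool)
    free = np.zeros((k, k), dtype=bool)

    def _fwd(role: str) -> int:
        return index[role] if role in (ROLE_TSS, ROLE_TTS) else index[role + "+"]

    def _rev(role: str) -> int:
        return index[role] if role in (ROLE_TSS, ROLE_TTS) else index[role + "-"]

    # forward chain: transcript orientation == genome order
    for src, dsts in _BODY_GRAMMAR.items():
        for dst in dsts:
            allowed[_fwd(src), _fwd(dst)] = True
    # reverse chain: genome order reverses the grammar (edge a->b becomes b->a)
    for src, dsts in _BODY_GRAMMAR.items():
        for dst in dsts:
            allowed[_rev(dst), _rev(src)] = True
    for a, b in _BOUNDARY_GRAMMAR:
        allowed[_fwd(a), _fwd(b)] = True
        free[_fwd(a), _fwd(b)] = True
        allowed[_rev(b), _rev(a)] = True
        free[_rev(b), _rev(a)] = True
    # TSS <-> TTS and background block: all free
    tss, tts = index[ROLE_TSS], index[ROLE_TTS]
    bg = [index[f"bg{i + 1}"] for i in range(n_background)]
    for a in (tss, tts):
        for b in (tss, tts):
            if a != b:  # single-bin TSS/TTS: no self-transitions
                allowed[a, b] = free[a, b] = True
        for g in bg:
            allowed[a, g] = free[a, g] = True
            allowed[g, a] = free[g, a] = True
    for g in bg:
        for h in bg:
            allowed[g, h] = free[g, h] = True

    free_emission_rows = np.array([m.role == ROLE_BACKGROUND for m in states])
    return ModelTopology(
        states=tuple(states),
        allowed=allowed,
        free_transition=free,
        free_emission=free_emission_rows,
        index=index,
    )
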