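"""Sequence comparison helpers shared by entity grouping and chain mapping."""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

from .structures import Chain

__all__ = ["sequence_identity", "residue_correspondence"]


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    return aligner


@lru_cache(maxsize=100_000)
def _identity_cached(s1: str, s2: str) -> float:
    if not s1 or not s2:
        return 0.0
    if s1 == s2:
        return 1.0
    alignment = _aligner().align(s1, s2)[0]
    matches = sum(
        1
        for (a0, a1), (b0, b1) in zip(*alignment.aligned)
        for i, j in zip(range(a0, a1), range(b0, b1))
        if s1[i] == s2[j]
    )
    return matches / max(len(s1), len(s2))


def sequence_identity(s1: str, s2: str) -> float:
    """Global sequence identity: matches / max(length).

    Exact-match shortcut first; otherwise a global pairwise alignment.
    """
    if s1 == s2:
        return 1.0
    # cache keyed on the sorted pair (identity is symmetric)
    a, b = (s1, s2) if s1 <= s2 else (s2, s1)
    return _identity_cached(a, b)


@lru_cache(maxsize=50_000)
def _aligned_pairs(s1: str, s2: str) -> tuple[tuple[int, int], ...]:
    alignment = _aligner().align(s1, s2)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return tuple(pairs)


def residue_correspondence(a: Chain, b: Chain
                           ) -> dict[tuple[int, str], tuple[int, str]]:
    """Map residue keys of chain ``a`` onto chain ``b`` by sequence alignment.

    Equal sequences map positionally; otherwise aligned positions map and
    gapped positions are absent from the result.
    """
    from .structures import chain_sequence

    sa, sb = chain_sequence(a), chain_sequence(b)
    if sa == sb:
        return {ra.key: rb.key for ra, rb in zip(a.residues, b.residues)}
    return {
        a.residues[i].key: b.residues[j].key
        for i, j in _aligned_pairs(sa, sb)
    }
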