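"""Inter-chain contacts, interfaces, interface weights, and stoichiometry.

A contact is an unordered pair of residues from two different chains whose
minimal inter-residue (heavy-atom) distance is strictly below the cutoff
(5 Å by default).  Interfaces partition a contact set by chain pair and
carry the log10 size weight used when aggregating per-interface scores.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from math import log10

import numpy as np
from scipy.spatial import cKDTree

from .sequence import sequence_identity
from .structures import Assembly, chain_sequence

__all__ = [
    "Contact",
    "Interface",
    "Stoichiometry",
    "StoichiometryError",
    "find_contacts",
    "extract_interfaces",
    "interface_weight",
    "parse_stoichiometry",
    "infer_stoichiometry",
    "stoichiometry_match",
]

DEFAULT_CONTACT_CUTOFF = 5.0
WEIGHT_FLOOR = 0.05

# One endpoint of a contact: (chain_id, (residue_index, insertion_code))
ResidueRef = tuple[str, tuple[int, str]]
# A contact is a canonically ordered pair of endpoints.
Contact = tuple[ResidueRef, ResidueRef]


def make_contact(a: ResidueRef, b: ResidueRef) -> Contact:
    """Canonical (sorted) unordered contact; endpoints must be inter-chain."""
    if a[0] == b[0]:
        raise ValueError("contacts are inter-chain only")
    return (a, b) if a <= b else (b, a)


@dataclass
class Interface:
    """One chain pair's contact set with its aggregation weight."""

    chains: tuple[str, str]
    contacts: frozenset[Contact]
    weight_mode: str = "residues"

    def __post_init__(self) -> None:
        self.chains = tuple(sorted(self.chains))  # type: ignore[assignment]

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def interface_residues(self) -> dict[str, set[tuple[int, str]]]:
        out: dict[str, set[tuple[int, str]]] = {c: set() for c in self.chains}
        for a, b in self.contacts:
            out[a[0]].add(a[1])
            out[b[0]].add(b[1])
        return out

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.interface_residues.values())

    @property
    def weight(self) -> float:
        return interface_weight(self)


def interface_weight(iface: Interface, mode: str | None = None,
                     floor: float = WEIGHT_FLOOR) -> float:
    """a_j = log10(interface size / 2), clamped below at ``floor``.

    Interface size is the number of distinct interface residues over both
    chains (default), or the number of contacts with ``mode="contacts"``.
    """
    mode = mode or iface.weight_mode
    if mode == "residues":
        size = iface.n_residues
    elif mode == "contacts":
        size = iface.n_contacts
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    if size < 1:
        raise ValueError("interface has no residues")
    return max(log10(size / 2), floor)


def find_contacts(a: Assembly, cutoff: float = DEFAULT_CONTACT_CUTOFF) -> set[Contact]:
    """All inter-chain residue pairs with minimal atom distance < cutoff."""
    per_chain = []
    for chain in a.chains:
        coords = chain.all_coords()
        labels = np.concatenate(
            [np.full(len(r.coords), i) for i, r in enumerate(chain.residues)]
        )
        per_chain.append((chain, cKDTree(coords), labels))
    contacts: set[Contact] = set()
    for i in range(len(per_chain)):
        ci, ti, li = per_chain[i]
        for j in range(i + 1, len(per_chain)):
            cj, tj, lj = per_chain[j]
            pairs = ti.query_ball_tree(tj, r=cutoff)
            for ai, neighbours in enumerate(pairs):
                if not neighbours:
                    continue
                pi = ti.data[ai]
                for aj in neighbours:
                    # query_ball_tree includes points at exactly r; the rule is strict <
                    if np.linalg.norm(pi - tj.data[aj]) < cutoff:
                        ri = ci.residues[li[ai]]
                        rj = cj.residues[lj[aj]]
                        contacts.add(make_contact((ci.id, ri.key), (cj.id, rj.key)))
    return contacts


def extract_interfaces(contacts: set[Contact], min_contacts: int = 1,
                       weight_mode: str = "residues") -> list[Interface]:
    """Partition a contact set into one Interface per chain pair."""
    by_pair: dict[tuple[str, str], set[Contact]] = {}
    for contact in contacts:
        pair = tuple(sorted((contact[0][0], contact[1][0])))
        by_pair.setdefault(pair, set()).add(contact)
    return [
        Interface(pair, frozenset(cs), weight_mode)
        for pair, cs in sorted(by_pair.items())
        if len(cs) >= min_contacts
    ]


class StoichiometryError(ValueError):
    pass


@dataclass
class Stoichiometry:
    """Entity copy-number composition, e.g. A2B2C2; ``defined=False`` for "An"."""

    counts: dict[str, int]
    defined: bool = True
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            raise StoichiometryError("no entities")
        if self.defined and any(c < 1 for c in self.counts.values()):
            raise StoichiometryError("copy counts must be >= 1")

    def __str__(self) -> str:
        if not self.defined:
            return "".join(f"{k}n" for k in sorted(self.counts))
        return "".join(f"{k}{v}" for k, v in sorted(self.counts.items()))

    @property
    def total_chains(self) -> int:
        return sum(self.counts.values())


_STOICH_RE = re.compile(r"([A-Z])(\d+|n)")


def parse_stoichiometry(s: str) -> Stoichiometry:
    """Parse a CASP-style stoichiometry string such as "A2B2C2" or "An"."""
    s = s.strip()
    pos = 0
    counts: dict[str, int] = {}
    defined = True
    while pos < len(s):
        m = _STOICH_RE.match(s, pos)
        if m is None:
            raise StoichiometryError(f"malformed stoichiometry at {s[pos:]!r}")
        label, num = m.group(1), m.group(2)
        if label in counts:
            raise StoichiometryError(f"duplicate entity label {label!r}")
        if num == "n":
            counts[label] = 1
            defined = False
        else:
            counts[label] = int(num)
        pos = m.end()
    if not counts:
        raise StoichiometryError(f"empty stoichiometry string {s!r}")
    return Stoichiometry(counts, defined)


def group_chains_by_entity(a: Assembly, identity_threshold: float = 0.95
                           ) -> list[list[str]]:
    """Single-linkage grouping of chains by pairwise sequence identity."""
    seqs = {c.id: chain_sequence(c) for c in a.chains}
    ids = list(seqs)
    parent = {c: c for c in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, ci in enumerate(ids):
        for cj in ids[i + 1:]:
            if sequence_identity(seqs[ci], seqs[cj]) >= identity_threshold:
                parent[find(ci)] = find(cj)
    groups: dict[str, list[str]] = {}
    for c in ids:
        groups.setdefault(find(c), []).append(c)
    return sorted(groups.values(), key=lambda g: (-len(g), seqs[g[0]]))


def infer_stoichiometry(a: Assembly, identity_threshold: float = 0.95
                        ) -> Stoichiometry:
    """Derive the stoichiometry of an assembly by entity grouping.

    Chains are grouped by pairwise sequence identity >= threshold
    (single linkage); entities are labelled A, B, ... in descending copy
    count, ties broken by representative sequence.
    """
    groups = group_chains_by_entity(a, identity_threshold)
    counts: dict[str, int] = {}
    sequences: dict[str, str] = {}
    for i, grp in enumerate(groups):
        label = chr(ord("A") + i) if i < 26 else f"E{i}"
        counts[label] = len(grp)
        sequences[label] = chain_sequence(a.chain(grp[0]))
    return Stoichiometry(counts, True, sequences)


def stoichiometry_match(pred: Stoichiometry, ref: Stoichiometry,
                        identity_threshold: float = 0.95) -> bool:
    """True iff copy counts match under the sequence-derived entity map.

    With sequences on both sides, each reference entity is paired with the
    predicted entity of highest sequence identity (>= threshold); all counts
    must then agree.  Without sequences the count multisets are compared.
    """
    if not pred.defined or not ref.defined:
        raise StoichiometryError("cannot compare undefined (filamentous) stoichiometry")
    if not (pred.sequences and ref.sequences):
        return sorted(pred.counts.values()) == sorted(ref.counts.values())
    if len(pred.counts) != len(ref.counts):
        return False
    used: set[str] = set()
    for rlabel, rseq in ref.sequences.items():
        best, best_id = None, 0.0
        for plabel, pseq in pred.sequences.items():
            if plabel in used:
                continue
            ident = sequence_identity(rseq, pseq)
            if ident > best_id:
                best, best_id = plabel, ident
        if best is None or best_id < identity_threshold:
            return False
        if pred.counts[best] != ref.counts[rlabel]:
            return False
        used.add(best)
    return True
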