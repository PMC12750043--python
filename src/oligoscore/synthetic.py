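"""Synthetic complexes, model ensembles, score tables, and MSAs.

Generators with known ground truth so every pipeline and statistic is
testable offline.  Complexes are CA-only bead chains: each declared
interface is realised as a pair of anti-parallel segments 4.5 Å apart
(every opposed bead pair is a contact under the strict 5 Å rule, and
off-diagonal pairs at sqrt(4.5^2 + 3.8^2) = 5.9 Å are not), while
undeclared chain pairs are kept tens of Å apart.  Every generator is a
pure function of its seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import MSA
from .ranking import ScoreTable
from .structures import AMINO3TO1, Assembly, Chain, Residue

__all__ = [
    "ComplexSpec",
    "PerturbationSpec",
    "SubmissionSet",
    "make_complex",
    "perturb_model",
    "make_submission_set",
    "make_msa",
]

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ONE_TO_THREE = {v: k for k, v in reversed(list(AMINO3TO1.items()))}
BOND_LENGTH = 3.8
CONTACT_GAP = 4.5
SITE_MIN_SPACING = 100.0


@dataclass(frozen=True)
class ComplexSpec:
    """Blueprint for a synthetic complex.

    ``entities`` maps entity labels to chain lengths (>= 10 residues);
    ``copies`` gives the copy count per entity; chain ids are assigned
    A, B, C, ... across entities in order.  ``interfaces`` lists
    (chain_id, chain_id, min_contacts) triples; undeclared pairs stay apart.
    """

    entities: dict[str, int]
    copies: dict[str, int] = field(default_factory=dict)
    interfaces: tuple[tuple[str, str, int], ...] = ()
    seed: int = 0
    id: str = "synthetic"

    def chain_entities(self) -> list[tuple[str, str]]:
        """[(chain_id, entity_label), ...] in generation order."""
        out = []
        letters = iter(string.ascii_uppercase + string.ascii_lowercase)
        for label in self.entities:
            for _ in range(self.copies.get(label, 1)):
                out.append((next(letters), label))
        return out


def _entity_sequences(spec: ComplexSpec) -> dict[str, str]:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 17]))
    seqs = {}
    for i, (label, length) in enumerate(spec.entities.items()):
        if length < 10:
            raise ValueError(f"entity {label}: chain length must be >= 10")
        # a distinct fixed prefix keeps entity sequences pairwise dissimilar
        prefix = ALPHABET[i % 20] * 4
        body = "".join(rng.choice(list(ALPHABET), size=length - 4))
        seqs[label] = prefix + body
    return seqs


def make_complex(spec: ComplexSpec) -> Assembly:
    """Deterministically lay out a CA-only assembly realising the spec.

    Declared chain pairs get at least their requested number of sub-5 Å
    contacts; undeclared pairs are separated by well over 12 Å.
    """
    chain_entities = spec.chain_entities()
    chain_ids = [c for c, _ in chain_entities]
    entity_of = dict(chain_entities)
    seqs = _entity_sequences(spec)

    sites: dict[str, list[tuple[int, int, bool]]] = {c: [] for c in chain_ids}
    for k, (ca, cb, min_contacts) in enumerate(spec.interfaces):
        for c in (ca, cb):
            if c not in entity_of:
                raise ValueError(f"interface references unknown chain {c!r}")
        if ca == cb:
            raise ValueError("interfaces are inter-chain")
        seg = max(int(min_contacts), 4)
        sites[ca].append((k, seg, False))
        sites[cb].append((k, seg, True))

    max_len = max(len(seqs[e]) for e in spec.entities)
    spacing = max(SITE_MIN_SPACING, BOND_LENGTH * max_len + 50.0)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 23]))

    chains: list[Chain] = []
    for idx, (chain_id, label) in enumerate(chain_entities):
        seq = seqs[label]
        n = len(seq)
        seg_total = sum(seg for _, seg, _ in sites[chain_id])
        if seg_total > n:
            raise ValueError(
                f"chain {chain_id}: {seg_total} interface residues demanded "
                f"but the chain has only {n}")
        coords = np.empty((n, 3))
        pos = 0
        for site_idx, seg, flip in sites[chain_id]:
            origin = np.array([site_idx * spacing, 0.0, 0.0])
            ts = np.arange(seg)
            xs = BOND_LENGTH * (ts if not flip else (seg - 1 - ts))
            ys = np.full(seg, CONTACT_GAP / 2 if not flip else -CONTACT_GAP / 2)
            coords[pos:pos + seg] = origin + np.column_stack(
                [xs, ys, np.zeros(seg)])
            pos += seg
        home = np.array([idx * spacing, 1000.0 + idx * 20.0, 0.0])
        rest = n - pos
        coords[pos:] = home + np.column_stack(
            [BOND_LENGTH * np.arange(rest), np.zeros(rest), np.zeros(rest)])
        coords += rng.uniform(-0.05, 0.05, size=coords.shape)
        residues = [
            Residue(index=i + 1, name=_ONE_TO_THREE.get(aa, "ALA"),
                    atom_names=["CA"], coords=coords[i:i + 1])
            for i, aa in enumerate(seq)
        ]
        chains.append(Chain(chain_id, residues))
    return Assembly(spec.id, chains, meta={"entity_of_chain": entity_of,
                                           "seed": spec.seed})


@dataclass(frozen=True)
class PerturbationSpec:
    """A single structural corruption applied to a model.

    kinds: ``rigid_shift`` (translate one chain by ``magnitude`` Å),
    ``rigid_rotation`` (rotate the whole assembly by ``angle`` degrees —
    scores are invariant), ``chain_delete``, ``chain_duplicate`` (appends a
    displaced copy, changing the inferred stoichiometry), and
    ``interface_swap`` (exchange the positions of two same-length chains).
    """

    kind: str
    magnitude: float = 0.0
    angle: float = 0.0
    chain: str | None = None
    other_chain: str | None = None
    offset: float = 50.0
    seed: int = 0


def _copy_assembly(a: Assembly, new_id: str | None = None) -> Assembly:
    chains = [
        Chain(c.id, [replace(r, coords=r.coords.copy(),
                             atom_names=list(r.atom_names))
                     for r in c.residues], c.molecule_class)
        for c in a.chains
    ]
    return Assembly(new_id or a.id, chains, dict(a.meta))


def perturb_model(a: Assembly, p: PerturbationSpec) -> Assembly:
    """Apply one perturbation; all other chains are untouched."""
    out = _copy_assembly(a)
    rng = np.random.default_rng(np.random.SeedSequence([p.seed & 0x7FFFFFFF, 31]))
    if p.kind == "rigid_shift":
        chain = out.chain(p.chain or out.chains[-1].id)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for res in chain.residues:
            res.coords = res.coords + p.magnitude * direction
    elif p.kind == "rigid_rotation":
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        theta = np.deg2rad(p.angle)
        k = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        rot = np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)
        centroid = np.vstack([c.all_coords() for c in out.chains]).mean(axis=0)
        for chain in out.chains:
            for res in chain.residues:
                res.coords = (res.coords - centroid) @ rot.T + centroid
    elif p.kind == "chain_delete":
        if p.chain is None or p.chain not in out.chain_ids:
            raise ValueError(f"unknown chain {p.chain!r}")
        out.chains = [c for c in out.chains if c.id != p.chain]
        if not out.chains:
            raise ValueError("cannot delete the last chain")
    elif p.kind == "chain_duplicate":
        source = out.chain(p.chain or out.chains[0].id)
        used = set(out.chain_ids)
        new_id = next(c for c in string.ascii_uppercase + string.ascii_lowercase
                      if c not in used)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dup = Chain(new_id, [replace(r, coords=r.coords + p.offset * direction,
                                     atom_names=list(r.atom_names))
                             for r in source.residues], source.molecule_class)
        out.chains.append(dup)
    elif p.kind == "interface_swap":
        if p.chain is None or p.other_chain is None:
            raise ValueError("interface_swap needs two chains")
        ca, cb = out.chain(p.chain), out.chain(p.other_chain)
        if len(ca) != len(cb):
            raise ValueError("interface_swap requires equal-length chains")
        for ra, rb in zip(ca.residues, cb.residues):
            ra.coords, rb.coords = rb.coords.copy(), ra.coords.copy()
    else:
        raise ValueError(f"unknown perturbation kind {p.kind!r}")
    return out


@dataclass
class SubmissionSet:
    """One simulated target with per-group model ensembles and their scores."""

    target: Assembly | None
    models: dict[tuple[str, int], Assembly]
    table: ScoreTable
    true_severity: dict[tuple[str, int], float]


def _severity_to_score(severity: float, rng: np.random.Generator,
                       metric: str) -> float:
    # exponential quality decay with shift magnitude, spanning [0, 1]
    base = float(np.exp(-severity / 8.0))
    noise = rng.normal(0.0, 0.01)
    return float(np.clip(base + noise, 0.0, 1.0))


def make_submission_set(
    target_spec: ComplexSpec,
    n_groups: int,
    models_per_group: int = 5,
    quality_profile=None,
    seed: int = 0,
    designation: str = "best-first",
    structural: bool = True,
    metric_profile: tuple[str, ...] = ("ics", "ips", "qs", "dockq"),
    phase: str = "1",
    target_id: str | None = None,
) -> SubmissionSet:
    """Simulate one target's submissions from per-group quality profiles.

    ``quality_profile`` is a per-group noise scale (Å of expected interface
    displacement; larger = worse); model severities are exponential draws
    scaled by it.  ``designation`` controls which model is labelled Model 1:
    ``best-first``, ``worst-first``, or ``random``.  With
    ``structural=False`` no 3D models are built: metric values are derived
    directly from the severities, which is exact for selection statistics
    and keeps large simulation studies cheap.
    """
    if n_groups < 1:
        raise ValueError("need at least one group")
    if quality_profile is None:
        quality_profile = [2.0 * (g + 1) for g in range(n_groups)]
    if len(quality_profile) != n_groups:
        raise ValueError("quality_profile length must equal n_groups")
    root = np.random.SeedSequence([seed & 0x7FFFFFFF, 47])
    streams = root.spawn(n_groups + 1)
    tid = target_id or target_spec.id

    target = make_complex(target_spec) if structural else None
    from . import pipelines  # deferred: pipelines imports nothing from here

    models: dict[tuple[str, int], Assembly] = {}
    severities: dict[tuple[str, int], float] = {}
    records: list[dict] = []
    for g in range(n_groups):
        group = f"G{g:02d}"
        rng = np.random.default_rng(streams[g])
        sev = quality_profile[g] * rng.exponential(1.0, size=models_per_group)
        order = np.arange(models_per_group)
        if designation == "best-first":
            order = np.argsort(sev)
        elif designation == "worst-first":
            order = np.argsort(sev)[::-1]
        elif designation == "random":
            order = rng.permutation(models_per_group)
        else:
            raise ValueError(f"unknown designation {designation!r}")
        for model_index, sev_idx in enumerate(order, start=1):
            severity = float(sev[sev_idx])
            severities[(group, model_index)] = severity
            if structural:
                pert = PerturbationSpec(
                    "rigid_shift", magnitude=severity,
                    chain=target.chains[-1].id,
                    seed=int(streams[g].generate_state(1)[0] % (2**31)) + model_index,
                )
                model = perturb_model(target, pert)
                model.meta.update(group=group, model=model_index)
                models[(group, model_index)] = model
                result = pipelines.evaluate_standard(target, model, metric_profile)
                values = result.aggregates
            else:
                values = {m: _severity_to_score(severity, rng, m)
                          for m in metric_profile}
            for metric in metric_profile:
                records.append(dict(group=group, target=tid, phase=phase,
                                    model=model_index, metric=metric,
                                    value=values.get(metric)))
    return SubmissionSet(target, models, ScoreTable.from_records(records),
                         severities)


def make_msa(n_seqs: int, cluster_sizes: list[int], within_identity: float,
             between_identity: float, length: int, seed: int = 0) -> MSA:
    """Build an MSA with an exact cluster structure.

    Sequences within a cluster share >= 2*within_identity - 1 identity by
    construction; sequences from different clusters agree only on the
    conserved fraction (= between_identity) of columns, because variable
    columns use disjoint per-cluster letter sets.
    """
    if sum(cluster_sizes) != n_seqs:
        raise ValueError("cluster sizes must sum to n_seqs")
    if not 0.0 <= between_identity < within_identity <= 1.0:
        raise ValueError("need 0 <= between_identity < within_identity <= 1")
    k = len(cluster_sizes)
    if 2 * k > len(ALPHABET) - 1:
        raise ValueError(f"at most {(len(ALPHABET) - 1) // 2} clusters supported")
    n_conserved = int(round(between_identity * length))
    n_variable = length - n_conserved
    d = int(round((1.0 - within_identity) * length))
    if d > n_variable:
        raise ValueError("within/between identity demands are incompatible "
                         "with the sequence length")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 59]))
    conserved_cols = np.sort(rng.choice(length, size=n_conserved, replace=False))
    conserved_letters = rng.choice(list(ALPHABET), size=n_conserved)
    is_conserved = np.zeros(length, dtype=bool)
    is_conserved[conserved_cols] = True
    variable_cols = np.flatnonzero(~is_conserved)

    seqs: list[str] = []
    for c, size in enumerate(cluster_sizes):
        ancestor_letter = ALPHABET[2 * c]
        mutant_letter = ALPHABET[2 * c + 1]
        template = np.empty(length, dtype="<U1")
        template[conserved_cols] = conserved_letters
        template[variable_cols] = ancestor_letter
        for _ in range(size):
            seq = template.copy()
            if d > 0:
                mut = rng.choice(variable_cols, size=d, replace=False)
                seq[mut] = mutant_letter
            seqs.append("".join(seq))
    return MSA(seqs)
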