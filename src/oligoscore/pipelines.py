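"""Target-level evaluation pipelines.

Three pipelines assemble the per-interface metrics into target-level scores:

* ``evaluate_standard`` — for models sharing the target's stoichiometry.
  Chains are mapped one-to-one (sequence first, then the assignment that
  maximises structural similarity); every target interface is scored
  against the mapped model interface and aggregated with log10-size
  weights.  Unmapped model chains are ignored, so spurious extra copies
  are not penalised — the documented asymmetry this module exists to expose.
* ``evaluate_rbm`` — Reciprocal Best Match, for stoichiometry mismatches.
  Each target interface is matched to its best-scoring model interface and
  vice versa; each direction is a weighted average and the final score is
  the minimum of the two, penalising both missing and spurious interfaces.
* ``evaluate_aa`` — antibody/nanobody–antigen targets: only cross-class
  interfaces are scored and the global-fold metrics are dropped.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import metrics
from .interfaces import Interface, extract_interfaces, find_contacts
from .sequence import residue_correspondence, sequence_identity
from .structures import Assembly, Chain, Residue, chain_sequence

__all__ = [
    "ChainMapping",
    "EvaluationResult",
    "METRIC_PROFILES",
    "map_chains",
    "aggregate_weighted",
    "evaluate_standard",
    "evaluate_rbm",
    "evaluate_aa",
]

# Table-driven per-category metric profiles.
METRIC_PROFILES: dict[str, tuple[str, ...]] = {
    "normal": ("ics", "ips", "dockq", "qs", "tm", "lddt"),
    "aa": ("ics", "ips", "dockq", "qs"),
    "hybrid": ("ics", "ips", "lddt"),
}

INTERFACE_METRICS = ("ics", "ips", "qs", "dockq")
GLOBAL_METRICS = ("tm", "lddt")

# identity threshold for considering a model chain a copy of a target entity;
# normalised by the shorter sequence so trimmed constructs still map
MAPPING_IDENTITY_THRESHOLD = 0.7
ENTITY_IDENTITY_THRESHOLD = 0.95
# below this identity a chain-to-chain residue correspondence is meaningless
# (global alignment of unrelated sequences can still match ~0.3-0.4 of the
# shorter chain by chance, so the floor sits above that)
RBM_FALLBACK_IDENTITY_FLOOR = 0.5
EXHAUSTIVE_LIMIT = 720


def _compat_identity(s1: str, s2: str) -> float:
    """Identity normalised by the shorter sequence (coverage-tolerant)."""
    if s1 == s2:
        return 1.0
    ident_max = sequence_identity(s1, s2)
    return ident_max * max(len(s1), len(s2)) / min(len(s1), len(s2))


@dataclass
class ChainMapping:
    """Partial injective map from target chain ids to model chain ids."""

    chain_map: dict[str, str] = field(default_factory=dict)
    identities: dict[str, float] = field(default_factory=dict)
    residue_maps: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = list(self.chain_map.values())
        if len(set(values)) != len(values):
            raise ValueError("chain mapping must be injective")

    @property
    def inverse(self) -> dict[str, str]:
        return {v: k for k, v in self.chain_map.items()}

    def inverse_residue_maps(self) -> dict[str, dict]:
        return {
            self.chain_map[t]: {v: k for k, v in rmap.items()}
            for t, rmap in self.residue_maps.items()
        }


def _entity_groups(chains: list[Chain]) -> list[list[str]]:
    groups: list[list[str]] = []
    for chain in chains:
        seq = chain_sequence(chain)
        for grp in groups:
            if sequence_identity(seq, grp[1]) >= ENTITY_IDENTITY_THRESHOLD:
                grp[0].append(chain.id)
                break
        else:
            groups.append([[chain.id], seq])  # type: ignore[list-item]
    return [(g[0], g[1]) for g in groups]  # type: ignore[return-value]


def _build_mapping(target: Assembly, model: Assembly,
                   chain_map: dict[str, str]) -> ChainMapping:
    residue_maps = {
        t: residue_correspondence(target.chain(t), model.chain(m))
        for t, m in chain_map.items()
    }
    identities = {
        t: _compat_identity(chain_sequence(target.chain(t)),
                            chain_sequence(model.chain(m)))
        for t, m in chain_map.items()
    }
    return ChainMapping(dict(chain_map), identities, residue_maps)


def _mapping_objective(target: Assembly, model: Assembly,
                       mapping: ChainMapping, objective: str) -> float:
    if objective == "lddt":
        value = metrics.lddt(target, model, mapping.chain_map, mapping.residue_maps)
    elif objective == "tm":
        value = metrics.tm_score(target, model, mapping.chain_map, mapping.residue_maps)
    else:
        raise ValueError(f"unknown mapping objective {objective!r}")
    return value if value is not None else 0.0


def map_chains(target: Assembly, model: Assembly,
               objective: str = "lddt",
               identity_threshold: float = MAPPING_IDENTITY_THRESHOLD,
               ) -> ChainMapping:
    """Best one-to-one target-to-model chain mapping.

    Chains are grouped into entities by sequence; within multi-copy
    entities the assignment maximising the structural objective is chosen
    (exhaustive search when the number of candidate assignments is small,
    otherwise a linear-assignment problem on per-pair objective values).
    """
    t_groups = _entity_groups(target.chains)
    m_groups = _entity_groups(model.chains)

    # pair target entities with model entities, greedily by identity
    pairs: list[tuple[list[str], list[str]]] = []
    candidates = sorted(
        (
            (-_compat_identity(tseq, mseq), ti, mi)
            for ti, (_, tseq) in enumerate(t_groups)
            for mi, (_, mseq) in enumerate(m_groups)
            if _compat_identity(tseq, mseq) >= identity_threshold
        ),
    )
    used_t: set[int] = set()
    used_m: set[int] = set()
    for _, ti, mi in candidates:
        if ti in used_t or mi in used_m:
            continue
        used_t.add(ti)
        used_m.add(mi)
        pairs.append((t_groups[ti][0], m_groups[mi][0]))
    if not pairs:
        return ChainMapping()

    # enumerate injective assignments per entity
    per_entity: list[list[dict[str, str]]] = []
    n_combos = 1
    for t_chains, m_chains in pairs:
        k = min(len(t_chains), len(m_chains))
        options = [
            dict(zip(t_sel, m_sel))
            for t_sel in itertools.combinations(t_chains, k)
            for m_sel in itertools.permutations(m_chains, k)
        ]
        per_entity.append(options)
        n_combos *= len(options)

    if n_combos == 1:
        merged: dict[str, str] = {}
        for opts in per_entity:
            merged.update(opts[0])
        return _build_mapping(target, model, merged)

    if n_combos <= EXHAUSTIVE_LIMIT:
        best_mapping, best_value = None, -np.inf
        for combo in itertools.product(*per_entity):
            merged = {}
            for part in combo:
                merged.update(part)
            mapping = _build_mapping(target, model, merged)
            value = _mapping_objective(target, model, mapping, objective)
            if value > best_value:
                best_mapping, best_value = mapping, value
        assert best_mapping is not None
        return best_mapping

    # large entities: linear assignment on per-pair objective values
    merged = {}
    for t_chains, m_chains in pairs:
        cost = np.zeros((len(t_chains), len(m_chains)))
        for i, t in enumerate(t_chains):
            sub_t = Assembly(target.id, [target.chain(t)])
            for j, m in enumerate(m_chains):
                sub_m = Assembly(model.id, [model.chain(m)])
                pair_map = _build_mapping(sub_t, sub_m, {t: m})
                cost[i, j] = -_mapping_objective(sub_t, sub_m, pair_map, objective)
        rows, cols = linear_sum_assignment(cost)
        merged.update({t_chains[i]: m_chains[j] for i, j in zip(rows, cols)})
    return _build_mapping(target, model, merged)


def aggregate_weighted(scores: Sequence[float], weights: Sequence[float]
                       ) -> float | None:
    """Log-size weighted average S_I = sum(a_j s_Ij) / sum(a_j)."""
    if len(scores) != len(weights):
        raise ValueError("scores and weights must have equal length")
    if len(scores) == 0:
        return None
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return float(np.dot(weights, np.asarray(scores, dtype=float)) / weights.sum())


@dataclass
class EvaluationResult:
    """Per-interface panels plus target-level aggregates for one model."""

    target_id: str
    model_id: str
    pipeline: str
    per_interface: dict[tuple[str, str], metrics.InterfaceScorePanel]
    weights: dict[tuple[str, str], float]
    aggregates: dict[str, float | None]
    mapping: ChainMapping | None = None
    directions: dict[str, tuple[float | None, float | None]] | None = None

    def as_dict(self) -> dict:
        return {
            "target": self.target_id,
            "model": self.model_id,
            "pipeline": self.pipeline,
            "aggregates": self.aggregates,
            "interfaces": {
                "-".join(pair): {**panel.as_dict(), "weight": self.weights[pair]}
                for pair, panel in self.per_interface.items()
            },
            "chain_mapping": self.mapping.chain_map if self.mapping else None,
        }


def _interface_residue_refs(contacts) -> set:
    refs = set()
    for a, b in contacts:
        refs.add(a)
        refs.add(b)
    return refs


def evaluate_standard(
    target: Assembly,
    model: Assembly,
    profile: Sequence[str] = METRIC_PROFILES["normal"],
    mapping: ChainMapping | None = None,
    min_contacts: int = 1,
    weight_mode: str = "residues",
    interface_filter: Callable[[tuple[str, str]], bool] | None = None,
) -> EvaluationResult:
    """Stoichiometry-matched evaluation through a one-to-one chain mapping."""
    if mapping is None:
        mapping = map_chains(target, model)
    t_ifaces = [
        i for i in extract_interfaces(find_contacts(target), min_contacts, weight_mode)
        if interface_filter is None or interface_filter(i.chains)
    ]
    if mapping.chain_map:
        mapped_model = Assembly(
            model.id, [model.chain(m) for m in mapping.chain_map.values()],
            model.meta,
        )
        model_contacts = metrics.translate_contacts(
            find_contacts(mapped_model), mapping.inverse,
            mapping.inverse_residue_maps(),
        )
    else:
        model_contacts = set()
    by_pair: dict[tuple[str, str], set] = {}
    for contact in model_contacts:
        pair = tuple(sorted((contact[0][0], contact[1][0])))
        by_pair.setdefault(pair, set()).add(contact)

    panels: dict[tuple[str, str], metrics.InterfaceScorePanel] = {}
    weights: dict[tuple[str, str], float] = {}
    for iface in t_ifaces:
        m_contacts = by_pair.get(iface.chains, set())
        mapped = all(c in mapping.chain_map for c in iface.chains)
        panel = metrics.InterfaceScorePanel(
            ics=metrics.ics(iface.contacts, m_contacts),
            ips=metrics.ips(_interface_residue_refs(iface.contacts),
                            _interface_residue_refs(m_contacts)),
            qs=metrics.qs(iface.contacts, m_contacts),
        )
        if mapped:
            panel.dockq = metrics.dockq(target, model, iface,
                                        mapping.chain_map, mapping.residue_maps)
        else:
            panel.dockq = 0.0
        panels[iface.chains] = panel
        weights[iface.chains] = iface.weight

    aggregates: dict[str, float | None] = {}
    for metric in profile:
        if metric in INTERFACE_METRICS:
            pairs = [(getattr(panels[p], metric), weights[p]) for p in panels
                     if getattr(panels[p], metric) is not None]
            aggregates[metric] = aggregate_weighted(
                [s for s, _ in pairs], [w for _, w in pairs])
    if not mapping.chain_map:
        return EvaluationResult(target.id, model.id, "standard", panels, weights,
                                {m: None for m in profile}, mapping)
    if "lddt" in profile:
        aggregates["lddt"] = metrics.lddt(target, model, mapping.chain_map,
                                          mapping.residue_maps)
    if "tm" in profile:
        aggregates["tm"] = metrics.tm_score(target, model, mapping.chain_map,
                                            mapping.residue_maps)
    return EvaluationResult(target.id, model.id, "standard", panels, weights,
                            aggregates, mapping)


def _score_interface_pair(
    ref: Assembly, other: Assembly,
    ref_iface: Interface, other_iface: Interface,
    orientation: dict[str, str],
    profile: Sequence[str],
) -> dict[str, float]:
    """Score one candidate interface pair under a fixed chain correspondence.

    ``orientation`` maps the reference interface's chains onto the other
    side's chains; all metrics are computed in the reference namespace.
    A residue correspondence between chains of unrelated sequence carries
    no signal, so pairings below the identity floor score zero outright.
    """
    floor_hit = any(
        _compat_identity(chain_sequence(ref.chain(rc)),
                         chain_sequence(other.chain(oc)))
        < RBM_FALLBACK_IDENTITY_FLOOR
        for rc, oc in orientation.items()
    )
    if floor_hit:
        return {m: 0.0 for m in profile}
    sub_ref = Assembly(ref.id, [ref.chain(c) for c in ref_iface.chains])
    sub_other = Assembly(other.id, [other.chain(c) for c in other_iface.chains])
    mapping = _build_mapping(sub_ref, sub_other, orientation)
    translated = metrics.translate_contacts(
        other_iface.contacts, mapping.inverse, mapping.inverse_residue_maps())
    out: dict[str, float] = {}
    if "ics" in profile:
        out["ics"] = metrics.ics(ref_iface.contacts, translated)
    if "ips" in profile:
        out["ips"] = metrics.ips(_interface_residue_refs(ref_iface.contacts),
                                 _interface_residue_refs(translated))
    if "qs" in profile:
        out["qs"] = metrics.qs(ref_iface.contacts, translated)
    if "dockq" in profile:
        value = metrics.dockq(sub_ref, sub_other, ref_iface,
                              mapping.chain_map, mapping.residue_maps)
        out["dockq"] = 0.0 if value is None else value
    if "lddt" in profile:
        value = metrics.lddt(sub_ref, sub_other, mapping.chain_map,
                             mapping.residue_maps)
        out["lddt"] = 0.0 if value is None else value
    if "tm" in profile:
        value = metrics.tm_score(sub_ref, sub_other, mapping.chain_map,
                                 mapping.residue_maps)
        out["tm"] = 0.0 if value is None else value
    return out


def _rbm_direction(
    ref: Assembly, other: Assembly,
    ref_ifaces: list[Interface], other_ifaces: list[Interface],
    profile: Sequence[str],
    identity_threshold: float = MAPPING_IDENTITY_THRESHOLD,
) -> tuple[dict[str, float | None], dict[tuple[str, str], dict[str, float]]]:
    """Best-match scores for every reference interface, weighted-averaged."""
    seqs_ref = {c.id: chain_sequence(c) for c in ref.chains}
    seqs_other = {c.id: chain_sequence(c) for c in other.chains}

    def compatible(rc: str, oc: str) -> bool:
        return _compat_identity(seqs_ref[rc], seqs_other[oc]) >= identity_threshold

    per_iface: dict[tuple[str, str], dict[str, float]] = {}
    for ref_iface in ref_ifaces:
        rc1, rc2 = ref_iface.chains
        candidates: list[tuple[Interface, dict[str, str]]] = []
        for other_iface in other_ifaces:
            oc1, oc2 = other_iface.chains
            if compatible(rc1, oc1) and compatible(rc2, oc2):
                candidates.append((other_iface, {rc1: oc1, rc2: oc2}))
            if oc1 != oc2 and compatible(rc1, oc2) and compatible(rc2, oc1):
                candidates.append((other_iface, {rc1: oc2, rc2: oc1}))
        if not candidates:
            # entity absent from the other side: allow any interface, residues
            # paired by alignment
            candidates = [
                (oi, dict(zip(ref_iface.chains, orient)))
                for oi in other_ifaces
                for orient in ([oi.chains, oi.chains[::-1]]
                               if oi.chains[0] != oi.chains[1] else [oi.chains])
            ]
        best = {m: 0.0 for m in profile}
        for other_iface, orientation in candidates:
            scored = _score_interface_pair(ref, other, ref_iface, other_iface,
                                           orientation, profile)
            for m in profile:
                best[m] = max(best[m], scored[m])
        per_iface[ref_iface.chains] = best

    weights = [i.weight for i in ref_ifaces]
    direction: dict[str, float | None] = {}
    for m in profile:
        scores = [per_iface[i.chains][m] for i in ref_ifaces]
        direction[m] = aggregate_weighted(scores, weights)
    return direction, per_iface


def evaluate_rbm(
    target: Assembly,
    model: Assembly,
    profile: Sequence[str] = METRIC_PROFILES["normal"],
    min_contacts: int = 1,
    weight_mode: str = "residues",
    interface_filter: Callable[[tuple[str, str]], bool] | None = None,
    model_interface_filter: Callable[[tuple[str, str]], bool] | None = None,
) -> EvaluationResult:
    """Reciprocal Best Match evaluation for stoichiometry-mismatched models."""
    t_ifaces = [
        i for i in extract_interfaces(find_contacts(target), min_contacts, weight_mode)
        if interface_filter is None or interface_filter(i.chains)
    ]
    m_ifaces = [
        i for i in extract_interfaces(find_contacts(model), min_contacts, weight_mode)
        if model_interface_filter is None or model_interface_filter(i.chains)
    ]
    if not t_ifaces and not m_ifaces:
        aggregates = {m: 1.0 for m in profile}
        return EvaluationResult(target.id, model.id, "rbm", {}, {}, aggregates,
                                directions={m: (1.0, 1.0) for m in profile})
    d1, per_iface = _rbm_direction(target, model, t_ifaces, m_ifaces, profile)
    d2, _ = _rbm_direction(model, target, m_ifaces, t_ifaces, profile)
    aggregates: dict[str, float | None] = {}
    directions: dict[str, tuple[float | None, float | None]] = {}
    for m in profile:
        a = d1[m] if d1[m] is not None else 0.0
        b = d2[m] if d2[m] is not None else 0.0
        aggregates[m] = min(a, b)
        directions[m] = (d1[m], d2[m])
    panels = {
        pair: metrics.InterfaceScorePanel(**{k: v for k, v in best.items()
                                             if k in ("ics", "ips", "qs",
                                                      "dockq", "lddt", "tm")})
        for pair, best in per_iface.items()
    }
    weights = {i.chains: i.weight for i in t_ifaces}
    return EvaluationResult(target.id, model.id, "rbm", panels, weights,
                            aggregates, None, directions)


def _concatenate_by_class(a: Assembly, classmap: dict[str, str]) -> Assembly:
    """Merge all antibody chains into one pseudo-chain and all antigen
    chains into another, renumbering residues sequentially."""
    merged: dict[str, list[Residue]] = {"antibody": [], "antigen": []}
    for chain_id in sorted(classmap):
        cls = classmap[chain_id]
        chain = a.chain(chain_id)
        for res in chain.residues:
            merged[cls].append(
                Residue(index=len(merged[cls]) + 1, name=res.name, icode="",
                        atom_names=list(res.atom_names), coords=res.coords.copy())
            )
    chains = [
        Chain("B" if cls == "antibody" else "G", residues)
        for cls, residues in merged.items() if residues
    ]
    return Assembly(a.id, chains, a.meta)


def evaluate_aa(
    target: Assembly,
    model: Assembly,
    classmap: dict[str, str],
    mode: Literal["per_interface", "concatenated"] = "per_interface",
    base: Literal["standard", "rbm"] = "standard",
    profile: Sequence[str] = METRIC_PROFILES["aa"],
) -> EvaluationResult:
    """Antibody/nanobody-antigen evaluation of cross-class interfaces only."""
    missing = [c.id for c in target.chains if c.id not in classmap]
    if missing:
        raise ValueError(f"classmap does not cover target chains: {missing}")
    profile = tuple(m for m in profile if m in INTERFACE_METRICS)

    if mode == "concatenated":
        merged_target = _concatenate_by_class(target, classmap)
        mapping = map_chains(target, model)
        model_classmap = {m: classmap[t] for t, m in mapping.chain_map.items()}
        if base == "rbm":
            model_classmap = _classify_by_entity(target, model, classmap)
        merged_model = _concatenate_by_class(model, model_classmap)
        if base == "standard":
            result = evaluate_standard(merged_target, merged_model, profile)
        else:
            result = evaluate_rbm(merged_target, merged_model, profile)
        result.pipeline = f"aa-concatenated-{base}"
        _warn_if_no_cross_class(result)
        return result

    def cross_class(pair: tuple[str, str]) -> bool:
        return classmap[pair[0]] != classmap[pair[1]]

    if base == "standard":
        result = evaluate_standard(target, model, profile,
                                   interface_filter=cross_class)
    else:
        model_classmap = _classify_by_entity(target, model, classmap)

        def cross_class_model(pair: tuple[str, str]) -> bool:
            ca, cb = model_classmap.get(pair[0]), model_classmap.get(pair[1])
            return ca is not None and cb is not None and ca != cb

        result = evaluate_rbm(target, model, profile,
                              interface_filter=cross_class,
                              model_interface_filter=cross_class_model)
    result.pipeline = f"aa-{base}"
    _warn_if_no_cross_class(result)
    return result


def _classify_by_entity(target: Assembly, model: Assembly,
                        classmap: dict[str, str]) -> dict[str, str]:
    """Assign each model chain the class of its most similar target chain."""
    t_seqs = {c.id: chain_sequence(c) for c in target.chains}
    out: dict[str, str] = {}
    for mchain in model.chains:
        mseq = chain_sequence(mchain)
        best, best_id = None, 0.0
        for t, tseq in t_seqs.items():
            ident = _compat_identity(mseq, tseq)
            if ident > best_id:
                best, best_id = t, ident
        if best is not None and best_id >= MAPPING_IDENTITY_THRESHOLD:
            out[mchain.id] = classmap[best]
    return out


def _warn_if_no_cross_class(result: EvaluationResult) -> None:
    if not result.per_interface:
        warnings.warn(
            f"{result.target_id}: no antibody-antigen interface in the target; "
            "scores are missing", stacklevel=2)
        for m in result.aggregates:
            result.aggregates[m] = None
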