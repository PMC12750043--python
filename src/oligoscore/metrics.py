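"""Per-interface and global similarity scores for complex model assessment.

Interface accuracy is measured on inter-chain residue contacts expressed in
the target's residue namespace: ICS (F1 of contacts), IPS (Jaccard of
interface residues), QS in Dice form, and DockQ.  Global accuracy uses
superposition-free lDDT and a TM-score under an iteratively optimised
superposition.  Empty-vs-empty contact sets score 1.0 (a correctly
predicted non-interface is not penalised).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .interfaces import Contact, Interface, find_contacts
from .structures import Assembly, Chain

__all__ = [
    "InterfaceScorePanel",
    "SuperpositionResult",
    "ics",
    "ips",
    "qs",
    "kabsch_superpose",
    "dockq",
    "lddt",
    "tm_score",
]

BACKBONE_ATOMS = ("CA", "N", "C", "O", "P", "C1'")
LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)

# residue_map[target_chain_id] maps target residue keys -> model residue keys
ResidueMaps = dict[str, dict[tuple[int, str], tuple[int, str]]]


@dataclass
class InterfaceScorePanel:
    """Per-interface metric values; ``None`` marks a missing value."""

    ics: float | None = None
    ips: float | None = None
    qs: float | None = None
    dockq: float | None = None
    lddt: float | None = None
    tm: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {k: getattr(self, k) for k in ("ics", "ips", "qs", "dockq", "lddt", "tm")}


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _f1(n_common: int, n_target: int, n_model: int) -> float:
    if n_target == 0 and n_model == 0:
        return 1.0
    if n_common == 0:
        return 0.0
    precision = n_common / n_model
    recall = n_common / n_target
    return 2 * precision * recall / (precision + recall)


def ics(target_contacts: Iterable[Contact], model_contacts: Iterable[Contact]) -> float:
    """Interface contact score: F1 of target vs model contact sets."""
    t, m = set(target_contacts), set(model_contacts)
    return _f1(len(t & m), len(t), len(m))


def ips(target_iface_residues: Iterable, model_iface_residues: Iterable) -> float:
    """Interface patch similarity: Jaccard coefficient of interface residues."""
    t, m = set(target_iface_residues), set(model_iface_residues)
    if not t and not m:
        return 1.0
    return len(t & m) / len(t | m)


def qs(target_contacts: Iterable[Contact], model_contacts: Iterable[Contact]) -> float:
    """QS in Dice form: shared contacts over total contacts of both sides."""
    t, m = set(target_contacts), set(model_contacts)
    if not t and not m:
        return 1.0
    if not t or not m:
        return 0.0
    return 2 * len(t & m) / (len(t) + len(m))


def kabsch_superpose(ref_coords: np.ndarray, mov_coords: np.ndarray
                     ) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mov`` onto ``ref`` (proper rotation)."""
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("paired N x 3 coordinate arrays required")
    if len(ref) < 3:
        raise ValueError("at least 3 paired points required")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    h = (mov - mov_c).T @ (ref - ref_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = ref_c - rotation @ mov_c
    moved = mov @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation, translation, rmsd)


def _atom_lookup(chain: Chain) -> dict:
    return {
        (res.key, name): res.coords[i]
        for res in chain.residues
        for i, name in enumerate(res.atom_names)
    }


def _paired_backbone(
    target_chain: Chain,
    model_chain: Chain,
    residue_map: dict,
    keys: Sequence | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired backbone coordinates of corresponding residues (atom-name matched)."""
    model_atoms = _atom_lookup(model_chain)
    ref, mov = [], []
    for res in target_chain.residues:
        if keys is not None and res.key not in keys:
            continue
        mkey = residue_map.get(res.key)
        if mkey is None:
            continue
        names = [n for n in res.atom_names if n in BACKBONE_ATOMS] or res.atom_names
        for i, name in enumerate(res.atom_names):
            if name not in names:
                continue
            mcoord = model_atoms.get((mkey, name))
            if mcoord is not None:
                ref.append(res.coords[i])
                mov.append(mcoord)
    if not ref:
        return np.empty((0, 3)), np.empty((0, 3))
    return np.asarray(ref), np.asarray(mov)


def translate_contacts(
    model_contacts: Iterable[Contact],
    model_to_target_chain: dict[str, str],
    model_to_target_residue: ResidueMaps,
) -> set[Contact]:
    """Express model contacts in the target's chain/residue namespace.

    Contacts whose chain or residue has no target counterpart are dropped
    (they cannot coincide with any target contact).
    """
    out: set[Contact] = set()
    for (c1, r1), (c2, r2) in model_contacts:
        t1, t2 = model_to_target_chain.get(c1), model_to_target_chain.get(c2)
        if t1 is None or t2 is None or t1 == t2:
            continue
        k1 = model_to_target_residue.get(c1, {}).get(r1)
        k2 = model_to_target_residue.get(c2, {}).get(r2)
        if k1 is None or k2 is None:
            continue
        a, b = (t1, k1), (t2, k2)
        out.add((a, b) if a <= b else (b, a))
    return out


def dockq(
    target: Assembly,
    model: Assembly,
    target_iface: Interface,
    chain_map: dict[str, str],
    residue_maps: ResidueMaps,
    contact_cutoff: float = 5.0,
    interface_cutoff: float = 10.0,
) -> float | None:
    """DockQ for one target interface against the mapped model chains.

    DockQ = (Fnat + 1/(1+(iRMS/1.5)^2) + 1/(1+(LRMS/8.5)^2)) / 3 with the
    established constants; the longer target chain is the receptor.
    Returns ``None`` when either chain is unmapped.
    """
    c1, c2 = target_iface.chains
    if c1 not in chain_map or c2 not in chain_map:
        return None
    t1, t2 = target.chain(c1), target.chain(c2)
    receptor, ligand = (c1, c2) if (len(t1), c2) >= (len(t2), c1) else (c2, c1)

    # Fnat: fraction of target contacts preserved among the mapped model chains
    sub_model = Assembly(
        model.id,
        [model.chain(chain_map[c1]), model.chain(chain_map[c2])],
    )
    inv_chain = {chain_map[c1]: c1, chain_map[c2]: c2}
    inv_res = {
        chain_map[c]: {v: k for k, v in residue_maps.get(c, {}).items()}
        for c in (c1, c2)
    }
    model_contacts = translate_contacts(
        find_contacts(sub_model, contact_cutoff), inv_chain, inv_res
    )
    t_contacts = set(target_iface.contacts)
    fnat = len(t_contacts & model_contacts) / len(t_contacts) if t_contacts else 1.0

    # iRMS: backbone RMSD over target interface residues (10 A definition)
    sub_target = Assembly(target.id, [t1, t2])
    wide = find_contacts(sub_target, interface_cutoff)
    iface_keys: dict[str, set] = {c1: set(), c2: set()}
    for (ca, ra), (cb, rb) in wide:
        iface_keys[ca].add(ra)
        iface_keys[cb].add(rb)
    ref_i, mov_i = [], []
    for c in (c1, c2):
        r, m = _paired_backbone(
            target.chain(c), model.chain(chain_map[c]),
            residue_maps.get(c, {}), keys=iface_keys[c],
        )
        ref_i.append(r)
        mov_i.append(m)
    ref_i, mov_i = np.vstack(ref_i), np.vstack(mov_i)
    irms = kabsch_superpose(ref_i, mov_i).rmsd if len(ref_i) >= 3 else None

    # LRMS: ligand backbone RMSD after superposing on the receptor backbone
    ref_r, mov_r = _paired_backbone(
        target.chain(receptor), model.chain(chain_map[receptor]),
        residue_maps.get(receptor, {}),
    )
    ref_l, mov_l = _paired_backbone(
        target.chain(ligand), model.chain(chain_map[ligand]),
        residue_maps.get(ligand, {}),
    )
    lrms = None
    if len(ref_r) >= 3 and len(ref_l) >= 1:
        sup = kabsch_superpose(ref_r, mov_r)
        moved = sup.apply(mov_l)
        lrms = float(np.sqrt(np.mean(np.sum((moved - ref_l) ** 2, axis=1))))

    terms = [fnat]
    terms.append(1.0 / (1.0 + (irms / 1.5) ** 2) if irms is not None else 0.0)
    terms.append(1.0 / (1.0 + (lrms / 8.5) ** 2) if lrms is not None else 0.0)
    return float(np.mean(terms))


def lddt(
    target: Assembly,
    model: Assembly,
    chain_map: dict[str, str],
    residue_maps: ResidueMaps,
    inclusion_radius: float = 15.0,
    thresholds: Sequence[float] = LDDT_THRESHOLDS,
) -> float | None:
    """Superposition-free local distance difference test.

    Every target atom pair within the inclusion radius (same-residue pairs
    excluded) is checked under each threshold; pairs involving unmapped
    target residues or atoms absent from the model count as unpreserved.
    """
    if not chain_map:
        return None
    coords, model_coords, residue_ids = [], [], []
    for chain in target.chains:
        mchain_id = chain_map.get(chain.id)
        mlookup = _atom_lookup(model.chain(mchain_id)) if mchain_id else {}
        rmap = residue_maps.get(chain.id, {})
        for res in chain.residues:
            mkey = rmap.get(res.key)
            for i, name in enumerate(res.atom_names):
                coords.append(res.coords[i])
                residue_ids.append((chain.id, res.key))
                mc = mlookup.get((mkey, name)) if mkey is not None else None
                model_coords.append(mc)
    coords = np.asarray(coords)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=inclusion_radius, output_type="ndarray")
    if len(pairs) == 0:
        return None
    thresholds = np.asarray(thresholds)
    total, n_pairs = 0.0, 0
    for i, j in pairs:
        if residue_ids[i] == residue_ids[j]:
            continue
        dt = np.linalg.norm(coords[i] - coords[j])
        if dt >= inclusion_radius:  # query_pairs includes the boundary
            continue
        n_pairs += 1
        mi, mj = model_coords[i], model_coords[j]
        if mi is None or mj is None:
            continue
        dm = np.linalg.norm(mi - mj)
        total += float(np.mean(abs(dt - dm) < thresholds))
    return total / n_pairs if n_pairs else None


def _d0(l_target: int) -> float:
    return max(1.24 * np.cbrt(l_target - 15.0) - 1.8, 0.5)


def _mapped_ca(target: Assembly, model: Assembly, chain_map: dict[str, str],
               residue_maps: ResidueMaps) -> tuple[np.ndarray, np.ndarray]:
    ref, mov = [], []
    for chain in target.chains:
        mchain_id = chain_map.get(chain.id)
        if mchain_id is None:
            continue
        mchain = model.chain(mchain_id)
        mres = {r.key: r for r in mchain.residues}
        rmap = residue_maps.get(chain.id, {})
        for res in chain.residues:
            mkey = rmap.get(res.key)
            if mkey is None or mkey not in mres:
                continue
            # representative atom: CA (or P/C1' for nucleic), else first atom
            def rep(r):
                for name in ("CA", "P", "C1'"):
                    if name in r.atom_names:
                        return r.coords[r.atom_names.index(name)]
                return r.coords[0]
            ref.append(rep(res))
            mov.append(rep(mres[mkey]))
    if not ref:
        return np.empty((0, 3)), np.empty((0, 3))
    return np.asarray(ref), np.asarray(mov)


def tm_score(
    target: Assembly,
    model: Assembly,
    chain_map: dict[str, str],
    residue_maps: ResidueMaps,
) -> float | None:
    """TM-score normalised by target length.

    TM = (1/L_target) sum 1/(1+(d_i/d0)^2) with d0 = 1.24 (L-15)^(1/3) - 1.8
    floored at 0.5.  The superposition is optimised by seed-and-extend over
    mapped representative atoms (windows of length >= 4, iterative
    refinement on the close-residue subset).
    """
    ref, mov = _mapped_ca(target, model, chain_map, residue_maps)
    n = len(ref)
    if n < 3:
        return None
    l_target = target.n_residues()
    d0 = _d0(l_target)

    def tm_of(d: np.ndarray) -> float:
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_target)

    best = 0.0
    windows = sorted({n, max(n // 2, 4), max(n // 4, 4), 4})
    cut = max(d0, 4.0)
    for w in windows:
        if w > n:
            continue
        for start in range(0, n - w + 1, max(1, w // 2)):
            idx = np.arange(start, start + w)
            for _ in range(30):
                sup = kabsch_superpose(ref[idx], mov[idx])
                d = np.linalg.norm(sup.apply(mov) - ref, axis=1)
                best = max(best, tm_of(d))
                new_idx = np.flatnonzero(d < cut)
                if len(new_idx) < 4:
                    new_idx = np.argsort(d)[:4]
                new_idx = np.sort(new_idx)
                if len(new_idx) == len(idx) and np.array_equal(new_idx, idx):
                    break
                idx = new_idx
    return min(best, 1.0)
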