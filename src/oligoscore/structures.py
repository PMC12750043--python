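"""Uniform assembly model for target and model structures.

Structures are read from PDB or mmCIF into a light-weight hierarchy
(:class:`Assembly` > :class:`Chain` > :class:`Residue`) holding only what
interface assessment needs: author residue numbering, residue names, and
heavy-atom coordinates.  Waters and non-polymer ligands are dropped on
read; alternate locations are resolved to the highest-occupancy copy.
CA-only (or P-only) structures are valid inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Residue",
    "Chain",
    "Assembly",
    "StructureError",
    "read_structure",
    "write_pdb",
    "min_residue_distance",
    "chain_sequence",
]


class StructureError(ValueError):
    """Raised for unreadable files or assemblies with no usable chains."""


AMINO3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine
    "SEC": "U", "PYL": "O",
}

NUC3TO1 = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DI": "I",
    "A": "A", "C": "C", "G": "G", "U": "U", "I": "I",
}

_WATER = {"HOH", "WAT", "DOD"}


@dataclass
class Residue:
    """One polymer residue: author numbering plus heavy-atom coordinates."""

    index: int
    name: str
    icode: str = ""
    atom_names: list[str] = field(default_factory=list)
    coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.coords) == 0:
            raise ValueError(f"residue {self.name}{self.index} has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"residue {self.name}{self.index}: non-finite coordinates")
        if not self.atom_names:
            self.atom_names = [f"X{i}" for i in range(len(self.coords))]

    @property
    def key(self) -> tuple[int, str]:
        return (self.index, self.icode)

    def one_letter(self) -> str:
        return AMINO3TO1.get(self.name) or NUC3TO1.get(self.name) or "X"


@dataclass
class Chain:
    id: str
    residues: list[Residue]
    molecule_class: Literal["protein", "nucleic", "other"] = "protein"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"chain {self.id} is empty")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"chain {self.id}: duplicate residue numbering")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, key: tuple[int, str]) -> Residue:
        return self._by_key[key]

    @property
    def _by_key(self) -> dict[tuple[int, str], Residue]:
        cached = getattr(self, "_key_cache", None)
        if cached is None or len(cached) != len(self.residues):
            cached = {r.key: r for r in self.residues}
            self._key_cache = cached
        return cached

    def all_coords(self) -> np.ndarray:
        return np.vstack([r.coords for r in self.residues])


@dataclass
class Assembly:
    """A multi-chain structure (target or model) with optional submission metadata."""

    id: str
    chains: list[Chain]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chains:
            raise StructureError(f"assembly {self.id}: no chains")
        ids = [c.id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"assembly {self.id}: duplicate chain ids")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(chain_id)

    @property
    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)


def _molecule_class(residues: Iterable[Residue]) -> str:
    names = [r.name for r in residues]
    n_aa = sum(n in AMINO3TO1 for n in names)
    n_nuc = sum(n in NUC3TO1 for n in names)
    if n_nuc > n_aa and n_nuc >= len(names) / 2:
        return "nucleic"
    if n_aa >= len(names) / 2:
        return "protein"
    return "other"


def _pick_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy alternate location, first on a tie."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        if atom.element.is_hydrogen:
            continue
        prev = by_name.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            by_name[atom.name] = atom
    return list(by_name.values())


def read_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
    *,
    keep_hetero: bool = False,
) -> Assembly:
    """Read a PDB or mmCIF file into an :class:`Assembly`.

    Waters are always dropped.  Non-polymer HETATM residues are dropped
    unless ``keep_hetero`` is set or the residue name belongs to the
    standard amino-acid/nucleotide vocabulary (e.g. MSE).
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no chains")
    model = st[0]
    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            name = gres.name.strip().upper()
            if name in _WATER:
                continue
            known = name in AMINO3TO1 or name in NUC3TO1
            if gres.het_flag == "H" and not known and not keep_hetero:
                continue
            atoms = _pick_altloc(gres)
            if not atoms:
                continue
            residues.append(
                Residue(
                    index=gres.seqid.num,
                    name=name,
                    icode=(gres.seqid.icode or "").strip(),
                    atom_names=[a.name for a in atoms],
                    coords=np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms]),
                )
            )
        if residues:
            chains.append(Chain(gchain.name, residues, _molecule_class(residues)))
    if not chains:
        raise StructureError(f"{path}: no chains")
    return Assembly(path.stem, chains)


def write_pdb(assembly: Assembly, path: str | Path) -> None:
    """Write a minimal PDB file (ATOM records only); used for fixtures."""
    lines = []
    serial = 1
    for chain in assembly.chains:
        for res in chain.residues:
            for atom_name, (x, y, z) in zip(res.atom_names, res.coords):
                element = atom_name.strip()[:1]
                name_field = atom_name if len(atom_name) >= 4 else f" {atom_name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name_field:<4s} {res.name:<3s} "
                    f"{chain.id[:1]}{res.index:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {chain.residues[-1].name:<3s} "
                     f"{chain.id[:1]}{chain.residues[-1].index:4d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def min_residue_distance(a: Residue, b: Residue) -> float:
    """Minimum Euclidean distance (Å) over all atom pairs of two residues."""
    return float(cdist(a.coords, b.coords).min())


def chain_sequence(c: Chain) -> str:
    """One-letter sequence; unknown residue codes map to 'X'."""
    return "".join(r.one_letter() for r in c.residues)
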