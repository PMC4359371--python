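"""Macromolecular structure container and PDB/mmCIF input-output.

The in-memory model is deliberately flat: an ordered tuple of atom records
carrying full identity (chain, residue number + insertion code, residue name,
atom name). Parsing and PDB serialization are delegated to gemmi; this layer
resolves alternate locations to one atom per identity (highest occupancy,
first in file order on ties), drops hydrogens, and keeps the first coordinate
model only — the conventions appropriate for crystal structures of
ring-shaped assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

from .errors import EmptyStructureError, FieldOverflowError, ParseError
from .transforms import RigidTransform

# Atom set of a polyalanine reduction. Glycine simply has no CB to keep.
_POLYALA_ATOMS = frozenset({"N", "CA", "C", "O", "CB"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its full identity and position in angstroms."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"invalid position for atom {self.atom_name}: {pos}")
        object.__setattr__(self, "position", pos)

    @property
    def key(self) -> tuple:
        """Identity key, unique within one structure."""
        return (self.chain_id, self.residue_number, self.insertion_code, self.atom_name)

    @property
    def residue_key(self) -> tuple:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass(frozen=True)
class StructureModel:
    """Ordered atom collection preserving input chain and residue order."""

    atoms: tuple
    source_id: str = ""
    model_index: int = 1

    def __post_init__(self) -> None:
        atoms = tuple(self.atoms)
        if not atoms:
            raise EmptyStructureError("structure contains no atoms")
        keys = set()
        for a in atoms:
            if a.key in keys:
                raise ParseError(f"duplicate atom identity {a.key} in {self.source_id!r}")
            keys.add(a.key)
        object.__setattr__(self, "atoms", atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of positions, in input order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def chain_ids(self) -> list:
        """Chain identifiers in order of first appearance."""
        seen: dict = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def select(
        self,
        chains: Optional[Iterable[str]] = None,
        atom_names: Optional[Iterable[str]] = None,
        predicate: Optional[Callable[[AtomRecord], bool]] = None,
    ) -> "StructureModel":
        """Subset by chain, atom name and/or arbitrary predicate.

        Raises EmptyStructureError when nothing survives.
        """
        chain_set = set(chains) if chains is not None else None
        name_set = set(atom_names) if atom_names is not None else None
        kept = [
            a
            for a in self.atoms
            if (chain_set is None or a.chain_id in chain_set)
            and (name_set is None or a.atom_name in name_set)
            and (predicate is None or predicate(a))
        ]
        if not kept:
            raise EmptyStructureError("selection matches no atoms")
        return StructureModel(tuple(kept), self.source_id, self.model_index)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = tuple(replace(a, position=c) for a, c in zip(self.atoms, coords))
        return StructureModel(atoms, self.source_id, self.model_index)

    def transformed(self, transform: RigidTransform) -> "StructureModel":
        return self.with_coords(transform.apply(self.coords))


def _is_amino(residue_name: str) -> bool:
    info = gemmi.find_tabulated_residue(residue_name)
    return info is not None and info.is_amino_acid()


def _is_water(residue_name: str) -> bool:
    info = gemmi.find_tabulated_residue(residue_name)
    return info is not None and info.is_water()


def _is_nucleic(residue_name: str) -> bool:
    info = gemmi.find_tabulated_residue(residue_name)
    return info is not None and info.is_nucleic_acid()


def read_structure(path: str, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    Only the first coordinate model is used. Hydrogens are dropped.
    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by file order).
    """
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r} (expected pdb, mmcif or auto)")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no coordinate models")
    model = st[0]
    records: list = []
    for chain in model:
        for res in chain:
            icode = res.seqid.icode.strip()
            is_het = res.het_flag == "H"
            # resolve altlocs: group atoms of this residue by name
            best: dict = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in res:
                if atom.name not in best or best[atom.name] is not atom:
                    continue
                records.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        insertion_code=icode,
                        residue_name=res.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ,
                        is_hetero=is_het,
                    )
                )
    if not records:
        raise EmptyStructureError(f"{path}: no atoms after filtering")
    try:
        model_num = int(model.num)
    except (AttributeError, TypeError, ValueError):
        model_num = 1
    return StructureModel(tuple(records), source_id=str(path), model_index=model_num)


def write_structure(model: StructureModel, path: str) -> None:
    """Write a StructureModel as a standard PDB file.

    Coordinates must fit the fixed-width %8.3f field (-1000 < x < 10000).
    """
    for a in model.atoms:
        if np.any(a.position >= 10000.0) or np.any(a.position <= -1000.0):
            raise FieldOverflowError(
                f"coordinate of atom {a.key} does not fit PDB fixed-width field: "
                f"{a.position}"
            )
    st = gemmi.Structure()
    st.name = model.source_id or "ringchannel"
    gmodel = gemmi.Model(1)
    chain_map: dict = {}
    for a in model.atoms:
        if a.chain_id not in chain_map:
            chain_map[a.chain_id] = gemmi.Chain(a.chain_id)
        chain = chain_map[a.chain_id]
        if (
            len(chain) == 0
            or chain[-1].seqid.num != a.residue_number
            or chain[-1].seqid.icode.strip() != a.insertion_code
            or chain[-1].name != a.residue_name
        ):
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            res.het_flag = "H" if a.is_hetero else "A"
            chain.add_residue(res)
        res = chain[-1]
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.position)
        atom.occ = a.occupancy
        res.add_atom(atom)
    for chain in chain_map.values():
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    doc_opts = gemmi.PdbWriteOptions(minimal=True, numbered_ter=False)
    st.write_pdb(str(path), doc_opts)


def to_polyalanine(model: StructureModel) -> StructureModel:
    """Truncate every amino-acid residue to the alanine atom set.

    Keeps N, CA, C, O, CB of amino-acid residues; removes waters and
    non-polymer heteroatoms. Nucleic-acid chains pass through unchanged.
    Coordinates and identities of retained atoms are untouched, so the
    operation is idempotent.
    """
    kept = []
    for a in model.atoms:
        if _is_water(a.residue_name):
            continue
        if _is_amino(a.residue_name):
            if a.atom_name in _POLYALA_ATOMS:
                kept.append(a)
        elif _is_nucleic(a.residue_name):
            kept.append(a)
        # other heteroatoms (ligands, ions) are dropped
    if not kept:
        raise EmptyStructureError("no atoms remain after polyalanine reduction")
    return StructureModel(tuple(kept), model.source_id, model.model_index)


def geometric_center(
    model: StructureModel, selection: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Unweighted mean position of (optionally chain-restricted) atoms.

    The center "of mass" used throughout is the plain geometric center:
    for a symmetric ring any per-atom weighting puts the center on the
    symmetry axis, which is all the axis determination needs.
    """
    sub = model if selection is None else model.select(chains=selection)
    return sub.coords.mean(axis=0)
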