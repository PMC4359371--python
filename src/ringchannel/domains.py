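"""Rigid-body domain motion between structures, and backbone dihedrals.

To compare how a domain sits relative to a reference frame shared by two
structures (e.g. two homologous subunits superposed on a common subdomain),
the mobile structure is first superposed on the reference over the frame
selection; the domain's reorientation is then the rotation magnitude Chi of
the least-squares rotation between the two centered domain coordinate sets,
and its displacement is the distance between the two domain centers in the
shared frame. Both numbers are invariant under a common rigid motion of the
pair and symmetric in the roles of mobile and reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .axis import least_squares_rotation
from .errors import CorrespondenceError
from .structures import StructureModel
from .transforms import RigidTransform


@dataclass(frozen=True)
class SelectionSpec:
    """Chain + inclusive residue ranges + optional atom-name restriction."""

    chain_id: str
    residue_ranges: tuple  # ((start, end), ...) inclusive
    atom_names: tuple = ("CA",)

    def __post_init__(self) -> None:
        ranges = tuple((int(s), int(e)) for s, e in self.residue_ranges)
        if not ranges:
            raise ValueError("at least one residue range required")
        for s, e in ranges:
            if s > e:
                raise ValueError(f"invalid residue range {s}-{e}")
        object.__setattr__(self, "residue_ranges", ranges)
        object.__setattr__(self, "atom_names", tuple(self.atom_names))

    @classmethod
    def parse(cls, text: str, atom_names: Tuple[str, ...] = ("CA",)) -> "SelectionSpec":
        """Parse 'A:1-98' or 'A:1-98,120-150'."""
        chain, _, rest = text.partition(":")
        if not chain or not rest:
            raise ValueError(f"cannot parse selection {text!r} (expected CHAIN:S-E[,S-E])")
        ranges = []
        for part in rest.split(","):
            s, _, e = part.partition("-")
            ranges.append((int(s), int(e)))
        return cls(chain, tuple(ranges), atom_names)


@dataclass(frozen=True)
class DomainComparison:
    """Rotation (deg) and center displacement (angstrom) of a domain."""

    reference_fit_rmsd: float
    domain_rotation_deg: float
    com_displacement: float
    n_reference_pairs: int
    n_domain_pairs: int


@dataclass(frozen=True)
class DihedralPair:
    """Backbone phi/psi of one residue; None marks an undefined angle."""

    phi_deg: Optional[float]
    psi_deg: Optional[float]


def _selection_atoms(model: StructureModel, sel: SelectionSpec) -> list:
    """Atoms grouped per range, in (range, residue, atom-name) order."""
    per_range = []
    for s, e in sel.residue_ranges:
        rows = []
        for a in model.atoms:
            if (
                a.chain_id == sel.chain_id
                and s <= a.residue_number <= e
                and a.atom_name in sel.atom_names
            ):
                rows.append(a)
        per_range.append(rows)
    return per_range


def _pair_selections(
    mobile: StructureModel,
    reference: StructureModel,
    sel_mobile: SelectionSpec,
    sel_reference: SelectionSpec,
) -> Tuple[np.ndarray, np.ndarray]:
    """Positional pairing: i-th residue of a range with the i-th of its peer."""
    if len(sel_mobile.residue_ranges) != len(sel_reference.residue_ranges):
        raise ValueError("selections must list the same number of residue ranges")
    for (ms, me), (rs, re_) in zip(
        sel_mobile.residue_ranges, sel_reference.residue_ranges
    ):
        if me - ms != re_ - rs:
            raise ValueError(
                f"range length mismatch: {ms}-{me} vs {rs}-{re_}"
            )
    # Pair by residue offset within the range and atom name.
    mob_pts, ref_pts = [], []
    for ((ms, _), (rs, _)), mob_rows, ref_rows in zip(
        zip(sel_mobile.residue_ranges, sel_reference.residue_ranges),
        _selection_atoms(mobile, sel_mobile),
        _selection_atoms(reference, sel_reference),
    ):
        ref_index = {
            (a.residue_number - rs, a.insertion_code, a.atom_name): a for a in ref_rows
        }
        for a in mob_rows:
            partner = ref_index.get((a.residue_number - ms, a.insertion_code, a.atom_name))
            if partner is not None:
                mob_pts.append(a.position)
                ref_pts.append(partner.position)
    if len(mob_pts) < 3:
        raise CorrespondenceError(
            f"only {len(mob_pts)} matched atom pairs (need >= 3)"
        )
    return np.asarray(mob_pts), np.asarray(ref_pts)


def superpose_on_selection(
    mobile: StructureModel,
    reference: StructureModel,
    sel_mobile: SelectionSpec,
    sel_reference: SelectionSpec,
) -> Tuple[RigidTransform, float, int]:
    """Least-squares rigid transform of mobile onto reference over selections.

    Returns (transform, rmsd, n_pairs); apply the transform to the whole
    mobile structure to bring it into the reference frame.
    """
    P, Q = _pair_selections(mobile, reference, sel_mobile, sel_reference)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    desc = least_squares_rotation(P - cp, Q - cq)
    transform = RigidTransform(desc.matrix, cq - desc.matrix @ cp)
    return transform, desc.fit_rmsd, desc.n_pairs


def domain_rotation(
    mobile_aligned: StructureModel,
    reference: StructureModel,
    domain_mobile: SelectionSpec,
    domain_reference: SelectionSpec,
    reference_fit_rmsd: float = float("nan"),
    n_reference_pairs: int = 0,
) -> DomainComparison:
    """Rotation and center displacement of a domain in a shared frame.

    mobile_aligned must already be superposed on the reference via
    superpose_on_selection over the frame selection. The rotation reported
    is Chi of the least-squares rotation between the centered domain point
    sets (range [0, 180] deg); the displacement is the distance between the
    domain geometric centers.
    """
    P, Q = _pair_selections(mobile_aligned, reference, domain_mobile, domain_reference)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    desc = least_squares_rotation(P - cp, Q - cq)
    return DomainComparison(
        reference_fit_rmsd=reference_fit_rmsd,
        domain_rotation_deg=desc.chi_deg,
        com_displacement=float(np.linalg.norm(cq - cp)),
        n_reference_pairs=n_reference_pairs,
        n_domain_pairs=desc.n_pairs,
    )


def compare_domain(
    mobile: StructureModel,
    reference: StructureModel,
    fit_mobile: SelectionSpec,
    fit_reference: SelectionSpec,
    domain_mobile: SelectionSpec,
    domain_reference: SelectionSpec,
) -> DomainComparison:
    """Convenience pipeline: superpose on the fit selection, then measure
    the domain's residual rotation and center displacement."""
    transform, rmsd, n_ref = superpose_on_selection(
        mobile, reference, fit_mobile, fit_reference
    )
    moved = mobile.transformed(transform)
    return domain_rotation(
        moved,
        reference,
        domain_mobile,
        domain_reference,
        reference_fit_rmsd=rmsd,
        n_reference_pairs=n_ref,
    )


def dihedral(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC convention.

    Right-handed, cis = 0, viewed from p1 toward p2; range (-180, 180].
    """
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1n, v), w))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang = 180.0
    return ang


def backbone_dihedrals(
    model: StructureModel, chain: str, residue_number: int, insertion_code: str = ""
) -> DihedralPair:
    """Phi/psi of one residue.

    phi = C(i-1)-N-CA-C, psi = N-CA-C-N(i+1); neighbors are the residues
    directly before/after in chain order. A missing neighbor or missing
    backbone atom leaves the affected angle undefined (None), never 0.
    """
    residues: list = []
    index: dict = {}
    for a in model.atoms:
        if a.chain_id != chain:
            continue
        rk = a.residue_key
        if rk not in index:
            index[rk] = len(residues)
            residues.append({})
        residues[index[rk]][a.atom_name] = a.position
    target_key = (chain, residue_number, insertion_code)
    if target_key not in index:
        raise KeyError(f"residue {residue_number}{insertion_code} not in chain {chain}")
    i = index[target_key]
    cur = residues[i]
    prev = residues[i - 1] if i > 0 else {}
    nxt = residues[i + 1] if i + 1 < len(residues) else {}
    phi = psi = None
    if all(k in cur for k in ("N", "CA", "C")):
        if "C" in prev:
            phi = dihedral(prev["C"], cur["N"], cur["CA"], cur["C"])
        if "N" in nxt:
            psi = dihedral(cur["N"], cur["CA"], cur["C"], nxt["N"])
    return DihedralPair(phi_deg=phi, psi_deg=psi)
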