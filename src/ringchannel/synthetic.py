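"""Synthetic Cn rings, ideal duplex-DNA point models and perturbations.

Every generator records machine-readable ground truth (axis line, expected
permutation angle 360/n, programmed constriction radius, per-atom radii) so
the axis-detection and radius pipeline can be tested end to end without any
external coordinate files. Geometry is deliberately minimal: pseudo-CA point
subunits and C1'-only DNA strands carry exactly the information the analyses
consume, with no pretense of realistic bond geometry (generate_peptide is
the one exception — it builds real backbone internal coordinates so torsion
recovery can be verified round-trip).
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .axis import AxisLine
from .structures import AtomRecord, StructureModel
from .transforms import RigidTransform

_Z = np.array([0.0, 0.0, 1.0])


def _frame_rotation(axis_direction: np.ndarray) -> np.ndarray:
    """Minimal rotation taking +Z onto the requested axis direction."""
    d = np.asarray(axis_direction, dtype=float)
    d = d / np.linalg.norm(d)
    cross = np.cross(_Z, d)
    s = np.linalg.norm(cross)
    c = float(np.dot(_Z, d))
    if s < 1e-12:
        return np.eye(3) if c > 0 else Rotation.from_rotvec([math.pi, 0, 0]).as_matrix()
    return Rotation.from_rotvec(cross / s * math.atan2(s, c)).as_matrix()


def default_template(
    constriction_radius: float = 10.0, n_wall_atoms: int = 40
) -> List[Tuple[int, str, np.ndarray]]:
    """L-shaped pseudo-CA subunit wall plus one innermost constriction atom.

    Residue 1 is the designated constriction atom at exactly
    (constriction_radius, 0, 0); the remaining atoms form a vertical wall
    strip 4 A further out and a horizontal arm extending radially outward,
    so the innermost atom is unambiguous.
    """
    atoms: List[Tuple[int, str, np.ndarray]] = [
        (1, "CA", np.array([constriction_radius, 0.0, 0.0]))
    ]
    n_vert = n_wall_atoms // 2
    n_horiz = n_wall_atoms - n_vert
    r_wall = constriction_radius + 4.0
    for i in range(n_vert):
        z = -10.0 + 20.0 * i / max(1, n_vert - 1)
        atoms.append((2 + i, "CA", np.array([r_wall, 1.5, z])))
    for j in range(n_horiz):
        r = r_wall + 1.0 + 9.0 * j / max(1, n_horiz - 1)
        atoms.append((2 + n_vert + j, "CA", np.array([r, -1.5, 10.0])))
    return atoms


@dataclass(frozen=True)
class SyntheticRingSpec:
    """Recipe for a Cn-symmetric assembly of identical pseudo-subunits."""

    n_subunits: int = 6
    template_atoms: Optional[Sequence[Tuple[int, str, np.ndarray]]] = None
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    constriction_radius: float = 10.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subunits < 3:
            raise ValueError("need at least 3 subunits for a ring")
        if self.constriction_radius <= 0:
            raise ValueError("constriction_radius must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        object.__setattr__(
            self, "axis_direction", np.asarray(self.axis_direction, dtype=float)
        )
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually built, for use as a test oracle."""

    axis: AxisLine
    chi_deg: float
    min_radius: float
    per_atom_radii: np.ndarray  # noiseless distances to the true axis


def generate_ring(spec: SyntheticRingSpec) -> Tuple[StructureModel, GroundTruth]:
    """Build a Cn ring: template rotated by k*360/n about the axis.

    The template's in-plane coordinates are scaled so its innermost atom
    sits exactly at spec.constriction_radius from the axis; chains are
    named A, B, C, ... in rotational order, sharing residue numbering and
    atom names, so the default cyclic chain order matches the construction.
    Gaussian noise (noise_sigma, isotropic per coordinate) is applied after
    the symmetric construction from one PRNG stream seeded by spec.seed.
    """
    n = spec.n_subunits
    if n > 26:
        raise ValueError("at most 26 subunits (single-letter chain IDs)")
    template = (
        list(spec.template_atoms)
        if spec.template_atoms is not None
        else default_template(spec.constriction_radius)
    )
    pts = np.array([np.asarray(p, dtype=float) for (_, _, p) in template])
    radii = np.hypot(pts[:, 0], pts[:, 1])
    r_min = radii.min()
    if r_min <= 0:
        raise ValueError("template atoms must be off the axis")
    scale = spec.constriction_radius / r_min
    pts = pts * np.array([scale, scale, 1.0])
    frame = _frame_rotation(spec.axis_direction)
    rng = np.random.default_rng(spec.seed)
    records = []
    true_radii = []
    for k in range(n):
        chain_id = string.ascii_uppercase[k]
        Rz = Rotation.from_rotvec([0, 0, math.radians(360.0 * k / n)]).as_matrix()
        sub = pts @ Rz.T
        placed = sub @ frame.T + spec.center
        true_radii.extend(np.hypot(sub[:, 0], sub[:, 1]).tolist())
        if spec.noise_sigma > 0:
            placed = placed + rng.normal(0.0, spec.noise_sigma, size=placed.shape)
        for (res_num, atom_name, _), pos in zip(template, placed):
            records.append(
                AtomRecord(
                    chain_id=chain_id,
                    residue_number=res_num,
                    insertion_code="",
                    residue_name="ALA",
                    atom_name=atom_name,
                    element="C",
                    position=pos,
                )
            )
    model = StructureModel(
        tuple(records), source_id=f"synthetic-C{n}-ring", model_index=1
    )
    truth = GroundTruth(
        axis=AxisLine(point=spec.center, direction=spec.axis_direction),
        chi_deg=360.0 / n,
        min_radius=spec.constriction_radius,
        per_atom_radii=np.array(true_radii),
    )
    return model, truth


def generate_duplex(
    n_bp: int,
    rise: float = 3.4,
    twist_deg: float = 34.3,
    radius: float = 9.4,
    axis: Optional[AxisLine] = None,
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> Tuple[StructureModel, GroundTruth]:
    """Ideal duplex as two antiparallel C1' point helices.

    Base pair i places a strand-A C1' at azimuth (i-1)*twist and height
    (i-1)*rise, and its strand-B partner diametrically opposite at the same
    height; strand-B residue numbering runs antiparallel, so residue j of B
    pairs with residue n_bp+1-j of A. Paired C1' midpoints lie exactly on
    the programmed axis.
    """
    if n_bp < 3:
        raise ValueError("a duplex needs at least 3 base pairs")
    if axis is None:
        axis = AxisLine(point=np.zeros(3), direction=_Z)
    frame = _frame_rotation(axis.direction)
    rng = np.random.default_rng(seed)
    a_rec, b_rec = [], []
    for i in range(1, n_bp + 1):
        theta = math.radians((i - 1) * twist_deg)
        z = (i - 1) * rise
        pa = np.array([radius * math.cos(theta), radius * math.sin(theta), z])
        pb = np.array([-radius * math.cos(theta), -radius * math.sin(theta), z])
        for strand, res_num, p, bucket in (
            ("A", i, pa, a_rec),
            ("B", n_bp + 1 - i, pb, b_rec),
        ):
            pos = p @ frame.T + axis.point
            if noise_sigma > 0:
                pos = pos + rng.normal(0.0, noise_sigma, size=3)
            bucket.append(
                AtomRecord(
                    chain_id=strand,
                    residue_number=res_num,
                    insertion_code="",
                    residue_name="DA",
                    atom_name="C1'",
                    element="C",
                    position=pos,
                )
            )
    b_rec.sort(key=lambda a: a.residue_number)
    model = StructureModel(
        tuple(a_rec + b_rec), source_id=f"synthetic-duplex-{n_bp}bp", model_index=1
    )
    truth = GroundTruth(
        axis=axis,
        chi_deg=float("nan"),
        min_radius=radius,
        per_atom_radii=np.full(2 * n_bp, float(radius)),
    )
    return model, truth


def apply_rigid_transform(
    model: StructureModel,
    transform: Optional[RigidTransform] = None,
    seed: Optional[int] = None,
    box: float = 50.0,
) -> Tuple[StructureModel, RigidTransform]:
    """Apply an explicit or seeded-random rigid transform; return both.

    Random transforms draw the rotation uniformly over SO(3) and the
    translation uniformly in [-box, box]^3 from one PRNG stream.
    """
    if transform is None:
        if seed is None:
            raise ValueError("provide either an explicit transform or a seed")
        transform = RigidTransform.random(np.random.default_rng(seed), box=box)
    return model.transformed(transform), transform


# -- backbone construction for torsion round-trips --------------------------

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7


def _place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta_deg: float, tau_deg: float
) -> np.ndarray:
    """Natural-extension placement: |cd| = r, angle(b,c,d) = theta,
    torsion(a,b,c,d) = tau."""
    theta = math.radians(theta_deg)
    tau = math.radians(tau_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -r * math.cos(theta),
            r * math.sin(theta) * math.cos(tau),
            r * math.sin(theta) * math.sin(tau),
        ]
    )
    return c + np.column_stack([bc, m, n]) @ d_local


def generate_peptide(
    phi_psi: Sequence[Tuple[float, float]], chain_id: str = "A"
) -> StructureModel:
    """Backbone-only (N, CA, C) polyalanine chain with prescribed torsions.

    phi_psi[i] gives (phi, psi) of residue i+1; the first residue's phi and
    the last residue's psi do not influence the construction (they have no
    flanking atoms). Idealized bond lengths/angles, omega fixed at 180.
    """
    n_res = len(phi_psi)
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    coords: List[dict] = []
    theta0 = math.radians(_ANGLE_N_CA_C)
    n1 = np.zeros(3)
    ca1 = np.array([_BOND_N_CA, 0.0, 0.0])
    c1 = ca1 + _BOND_CA_C * np.array([-math.cos(theta0), math.sin(theta0), 0.0])
    coords.append({"N": n1, "CA": ca1, "C": c1})
    for i in range(1, n_res):
        prev = coords[i - 1]
        psi_prev = phi_psi[i - 1][1]
        n_next = _place(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANGLE_CA_C_N, psi_prev)
        ca_next = _place(prev["CA"], prev["C"], n_next, _BOND_N_CA, _ANGLE_C_N_CA, 180.0)
        c_next = _place(prev["C"], n_next, ca_next, _BOND_CA_C, _ANGLE_N_CA_C, phi_psi[i][0])
        coords.append({"N": n_next, "CA": ca_next, "C": c_next})
    records = []
    for i, res in enumerate(coords, start=1):
        for name in ("N", "CA", "C"):
            records.append(
                AtomRecord(
                    chain_id=chain_id,
                    residue_number=i,
                    insertion_code="",
                    residue_name="ALA",
                    atom_name=name,
                    element=name[0],
                    position=res[name],
                )
            )
    return StructureModel(tuple(records), source_id="synthetic-peptide", model_index=1)
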