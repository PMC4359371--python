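"""Channel-axis determination for ring-shaped assemblies.

The central channel axis of a Cn ring is defined as the rotation axis of the
least-squares proper rotation that maps each subunit onto the next in cyclic
order (chains ABCDEF onto BCDEFA for a hexamer). The rotation is expressed in
polar angles (Omega, Phi, Chi): the axis direction in spherical coordinates
(Omega = inclination from +Z, Phi = azimuth) and the rotation magnitude Chi
about that axis,

    axis = (sin Omega cos Phi, sin Omega sin Phi, cos Omega).

With this convention, two successive polar rotations — first by
(0, 0, -Phi), then by (90, 90, -Omega) — carry the axis onto +Z: the first
removes the azimuth (rotation by -Phi about +Z), the second rotates by
-Omega about +Y, the axis that now holds the inclination. After centering
the ring on its geometric center and applying the two rotations, the radial
distance of any atom to the channel axis is simply sqrt(X^2 + Y^2).

For a ring that encircles duplex DNA, the channel axis may instead be taken
as the least-squares straight axis of the bound duplex (fit_dna_helical_axis).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import CorrespondenceError, DegenerateInputError, EmptyStructureError
from .structures import StructureModel, geometric_center
from .transforms import RigidTransform

_ORTHO_TOL = 1e-6
_AXIS_EPS = 1e-12


@dataclass(frozen=True)
class RingAssembly:
    """A structure plus the ordered cyclic list of chains forming the ring."""

    model: StructureModel
    ring_chains: tuple

    def __post_init__(self) -> None:
        chains = tuple(self.ring_chains)
        if len(chains) < 3:
            raise ValueError("a ring needs at least 3 chains")
        if len(set(chains)) != len(chains):
            raise ValueError("ring chain list contains duplicates")
        present = set(self.model.chain_ids())
        missing = [c for c in chains if c not in present]
        if missing:
            raise ValueError(f"ring chains not found in structure: {missing}")
        keys = _chain_key_map(self.model, chains)
        n = len(chains)
        for k in range(n):
            shared = keys[chains[k]].keys() & keys[chains[(k + 1) % n]].keys()
            if len(shared) < 3:
                raise CorrespondenceError(
                    f"chains {chains[k]} and {chains[(k + 1) % n]} share fewer "
                    "than 3 common (residue, atom) keys"
                )
        object.__setattr__(self, "ring_chains", chains)

    @property
    def n_subunits(self) -> int:
        return len(self.ring_chains)


@dataclass(frozen=True)
class RotationDescriptor:
    """A proper rotation with its polar-angle form and superposition residual."""

    matrix: np.ndarray
    omega_deg: float
    phi_deg: float
    chi_deg: float
    axis: np.ndarray
    fit_rmsd: float
    n_pairs: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))


@dataclass(frozen=True)
class ChannelAxisFrame:
    """The re-framing transform: center, then the two polar rotations."""

    pre_translation: np.ndarray
    rotation_sequence: tuple  # (R(0,0,-Phi), R(90,90,-Omega))
    composed: RigidTransform


@dataclass(frozen=True)
class AxisLine:
    """A line in space: point on the line plus unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm < _AXIS_EPS:
            raise ValueError("axis direction must be non-zero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / norm)


def least_squares_rotation(moving: np.ndarray, target: np.ndarray) -> RotationDescriptor:
    """Least-squares proper rotation mapping `moving` onto `target` (Kabsch).

    Both point sets must be paired, of equal length (>= 3 non-collinear
    points) and already centered on the origin. Reflections are excluded by
    the determinant correction, so the result is always a proper rotation.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("moving and target must be matching (n, 3) arrays")
    if P.shape[0] < 3:
        raise DegenerateInputError("need at least 3 point pairs")
    H = P.T @ Q
    # rank < 2 means the points cannot pin down a unique rotation
    if np.linalg.matrix_rank(np.vstack([P, Q]), tol=1e-9) < 2:
        raise DegenerateInputError("point sets are collinear or coincident")
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    resid = P @ R.T - Q
    rmsd = float(np.sqrt((resid**2).sum() / P.shape[0]))
    omega, phi, chi = rotation_to_polar(R)
    return RotationDescriptor(
        matrix=R,
        omega_deg=omega,
        phi_deg=phi,
        chi_deg=chi,
        axis=polar_axis(omega, phi),
        fit_rmsd=rmsd,
        n_pairs=P.shape[0],
    )


def polar_axis(omega_deg: float, phi_deg: float) -> np.ndarray:
    """Unit axis from spherical angles (inclination Omega, azimuth Phi)."""
    om = math.radians(omega_deg)
    ph = math.radians(phi_deg)
    return np.array(
        [math.sin(om) * math.cos(ph), math.sin(om) * math.sin(ph), math.cos(om)]
    )


def polar_to_rotation(omega_deg: float, phi_deg: float, chi_deg: float) -> np.ndarray:
    """Rotation by Chi (right-hand rule) about the axis given by (Omega, Phi)."""
    axis = polar_axis(omega_deg, phi_deg)
    return Rotation.from_rotvec(axis * math.radians(chi_deg)).as_matrix()


def rotation_to_polar(matrix: np.ndarray) -> Tuple[float, float, float]:
    """Decompose a proper rotation into canonical polar angles (deg).

    Canonical ranges: Chi in [0, 180], Phi in (-180, 180], Omega in [0, 180].
    Chi = 0 is reported as (0, 0, 0); at Chi = 180 the axis sign is fixed so
    that Omega <= 90 (z >= 0; on the equator, first non-zero of (x, y) > 0).
    For an axis along +/-Z the azimuth is undefined and reported as 0.
    """
    R = np.asarray(matrix, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
        raise ValueError("matrix is not orthogonal within tolerance")
    if np.linalg.det(R) < 0:
        raise ValueError("matrix is a reflection, not a proper rotation")
    rotvec = Rotation.from_matrix(R).as_rotvec()
    chi_rad = float(np.linalg.norm(rotvec))
    if chi_rad < 1e-12:
        return (0.0, 0.0, 0.0)
    axis = rotvec / chi_rad
    chi = math.degrees(chi_rad)
    # scipy returns chi in [0, 180]; at exactly 180 fix the axis sign
    if abs(chi - 180.0) < 1e-9:
        if axis[2] < -_AXIS_EPS:
            axis = -axis
        elif abs(axis[2]) <= _AXIS_EPS:
            if axis[0] < -_AXIS_EPS or (abs(axis[0]) <= _AXIS_EPS and axis[1] < 0):
                axis = -axis
    omega = math.degrees(math.acos(np.clip(axis[2], -1.0, 1.0)))
    if omega < 1e-9 or omega > 180.0 - 1e-9:
        phi = 0.0
    else:
        phi = math.degrees(math.atan2(axis[1], axis[0]))
        if phi <= -180.0:
            phi = 180.0
    return (omega, phi, chi)


def _chain_key_map(model: StructureModel, chains: Sequence[str]) -> dict:
    out: dict = {c: {} for c in chains}
    want = set(chains)
    for a in model.atoms:
        if a.chain_id in want:
            out[a.chain_id][(a.residue_number, a.insertion_code, a.atom_name)] = a
    return out


def permutation_fit(ring: RingAssembly, atoms: str = "all") -> RotationDescriptor:
    """Least-squares rotation mapping each ring subunit onto the next.

    Atom pairs are matched by (residue_number, insertion_code, atom_name)
    key equality between consecutive chains in the given cyclic order; the
    union of all pairs enters one superposition after centering on the
    geometric center of the ring chains. For a clean Cn ring, Chi is 360/n
    and the rotation axis is the channel axis through that center.

    atoms: "all" (default) or "ca" to restrict the fit to CA atoms.
    """
    if atoms not in ("all", "ca"):
        raise ValueError("atoms must be 'all' or 'ca'")
    chains = ring.ring_chains
    keys = _chain_key_map(ring.model, chains)
    if atoms == "ca":
        keys = {
            c: {k: a for k, a in d.items() if k[2] == "CA"} for c, d in keys.items()
        }
    center = geometric_center(ring.model, selection=chains)
    moving, target = [], []
    total_atoms = sum(len(d) for d in keys.values())
    n = len(chains)
    for k in range(n):
        src = keys[chains[k]]
        dst = keys[chains[(k + 1) % n]]
        for key in src.keys() & dst.keys():
            moving.append(src[key].position)
            target.append(dst[key].position)
    if len(moving) < 3:
        raise CorrespondenceError(
            "fewer than 3 matched atom pairs across consecutive ring chains"
        )
    if total_atoms and len(moving) < 0.5 * total_atoms:
        warnings.warn(
            f"only {len(moving)}/{total_atoms} atoms found a partner in the "
            "next chain; check chain order and numbering",
            stacklevel=2,
        )
    P = np.asarray(moving) - center
    Q = np.asarray(target) - center
    return least_squares_rotation(P, Q)


def channel_axis_frame(center: np.ndarray, desc: RotationDescriptor) -> ChannelAxisFrame:
    """Build the two-step re-framing transform from a permutation fit.

    Centering translation, then rotation by (0, 0, -Phi), then (90, 90, -Omega).
    The composed transform carries the permutation axis onto +Z.
    """
    r1 = polar_to_rotation(0.0, 0.0, -desc.phi_deg)
    r2 = polar_to_rotation(90.0, 90.0, -desc.omega_deg)
    composed = RigidTransform(r2 @ r1).compose(
        RigidTransform(np.eye(3), -np.asarray(center, dtype=float))
    )
    return ChannelAxisFrame(
        pre_translation=-np.asarray(center, dtype=float),
        rotation_sequence=(r1, r2),
        composed=composed,
    )


def align_axis_to_z(
    ring: RingAssembly, atoms: str = "all"
) -> Tuple[StructureModel, ChannelAxisFrame, RotationDescriptor]:
    """Re-frame a ring so its channel axis coincides with +Z.

    Runs permutation_fit, centers the whole structure on the geometric center
    of the ring chains, and applies the two successive polar rotations
    (0, 0, -Phi) then (90, 90, -Omega). Radial distances sqrt(X^2 + Y^2) in
    the output frame equal point-to-axis distances in the input frame.
    """
    desc = permutation_fit(ring, atoms=atoms)
    center = geometric_center(ring.model, selection=ring.ring_chains)
    frame = channel_axis_frame(center, desc)
    return ring.model.transformed(frame.composed), frame, desc


def align_line_to_z(model: StructureModel, axis: AxisLine) -> StructureModel:
    """Re-frame a structure so an arbitrary axis line coincides with +Z.

    Translates axis.point to the origin, then applies the minimal rotation
    taking the direction onto +Z (identity if already aligned).
    """
    d = axis.direction
    z = np.array([0.0, 0.0, 1.0])
    cross = np.cross(d, z)
    s = np.linalg.norm(cross)
    c = float(np.dot(d, z))
    if s < _AXIS_EPS:
        R = np.eye(3) if c > 0 else Rotation.from_rotvec([math.pi, 0, 0]).as_matrix()
    else:
        R = Rotation.from_rotvec(cross / s * math.atan2(s, c)).as_matrix()
    t = RigidTransform(R).compose(RigidTransform(np.eye(3), -axis.point))
    return model.transformed(t)


def fit_dna_helical_axis(
    model: StructureModel,
    strand_a: str,
    strand_b: str,
    register_offset: int = 0,
) -> AxisLine:
    """Least-squares straight axis of a bound DNA duplex.

    Residue i of strand_a (file order) is paired with residue N + 1 - i +
    register_offset of strand_b (antiparallel register); the midpoints of
    paired C1' atoms are collected and the returned line is the principal
    axis of the midpoint cloud through its centroid. Direction sign is fixed
    to a positive projection on the strand_a 5'->3' vector.
    """
    mids, a_pts = [], []
    a_res = _chain_c1_by_residue(model, strand_a)
    b_res = _chain_c1_by_residue(model, strand_b)
    if len(a_res) < 3 or len(b_res) < 3:
        raise EmptyStructureError(
            f"strands {strand_a}/{strand_b} need >= 3 residues with C1' atoms"
        )
    nb = len(b_res)
    for i, (_, pa) in enumerate(a_res):
        j = nb - 1 - i + register_offset
        if not 0 <= j < nb:
            continue
        pb = b_res[j][1]
        a_pts.append(pa)
        mids.append(0.5 * (pa + pb))
    if len(mids) < 3:
        raise CorrespondenceError("fewer than 3 paired C1' midpoints")
    M = np.asarray(mids)
    centroid = M.mean(axis=0)
    _, _, Vt = np.linalg.svd(M - centroid)
    direction = Vt[0]
    five_to_three = a_pts[-1] - a_pts[0]
    if float(np.dot(direction, five_to_three)) < 0:
        direction = -direction
    return AxisLine(point=centroid, direction=direction)


def _chain_c1_by_residue(model: StructureModel, chain: str) -> list:
    """(residue_key, C1' position) in file order; accepts C1' or C1* naming."""
    out = []
    seen_res = set()
    missing = 0
    by_res: dict = {}
    order = []
    for a in model.atoms:
        if a.chain_id != chain:
            continue
        rk = a.residue_key
        if rk not in seen_res:
            seen_res.add(rk)
            order.append(rk)
        if a.atom_name in ("C1'", "C1*"):
            by_res[rk] = a.position
    for rk in order:
        if rk in by_res:
            out.append((rk, by_res[rk]))
        else:
            missing += 1
    if missing:
        warnings.warn(
            f"chain {chain}: {missing} residues lack a C1' atom and were skipped",
            stacklevel=3,
        )
    return out
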