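"""Radial distances, minimum channel radius and radius-vs-height profiles.

Radii are distances of atom centers to the channel axis: after re-framing so
the axis is +Z, the radius of an atom is sqrt(X^2 + Y^2). No van der Waals
radius is subtracted and no probe sphere is rolled (unlike HOLE-style pore
tracing) — the minimum channel radius is a property of the atom centers and
is compared between structures measured the same way. The default atom set
is the polyalanine reduction of the ring chains, which removes side-chain
dependence from the constriction measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .axis import AxisLine, RingAssembly, align_axis_to_z, align_line_to_z
from .errors import EmptyStructureError
from .structures import AtomRecord, StructureModel, _is_amino, to_polyalanine

DEFAULT_BIN_WIDTH = 2.0  # angstrom; about one atom diameter


@dataclass(frozen=True)
class RadiusProfile:
    """Per-height-bin minimum radii and the global constriction."""

    bin_centers: tuple  # Z heights, angstrom
    bin_min_radius: tuple  # angstrom, None where a bin holds no atoms
    global_min_radius: float
    limiting_atom: AtomRecord
    bin_width: float
    z_window: Optional[Tuple[float, float]] = None


def radial_distances(aligned: StructureModel) -> List[Tuple[AtomRecord, float]]:
    """Per-atom distance to the +Z axis: sqrt(X^2 + Y^2).

    The model must already be framed with the channel axis on +Z.
    """
    xy = aligned.coords[:, :2]
    radii = np.sqrt((xy**2).sum(axis=1))
    return list(zip(aligned.atoms, radii.tolist()))


def _ring_atom_set(ring: RingAssembly, polyalanine: bool) -> StructureModel:
    sub = ring.model.select(chains=ring.ring_chains)
    if polyalanine:
        sub = to_polyalanine(sub)
    return sub


def min_channel_radius(
    ring: RingAssembly,
    polyalanine: bool = True,
    z_window: Optional[Tuple[float, float]] = None,
) -> Tuple[float, AtomRecord]:
    """Global minimum distance from a ring atom to the channel axis.

    Pipeline: optional polyalanine reduction of the ring chains, axis
    alignment via the permutation fit, minimum of sqrt(X^2 + Y^2); the
    result is invariant under rigid motion of the input. An optional
    z_window (in the aligned frame) restricts the search along the axis.
    """
    sub = _ring_atom_set(ring, polyalanine)
    sub_ring = RingAssembly(sub, ring.ring_chains)
    aligned, _, _ = align_axis_to_z(sub_ring)
    return _min_radius(aligned, z_window)


def _min_radius(
    aligned: StructureModel, z_window: Optional[Tuple[float, float]]
) -> Tuple[float, AtomRecord]:
    entries = radial_distances(aligned)
    if z_window is not None:
        zmin, zmax = min(z_window), max(z_window)
        entries = [(a, r) for a, r in entries if zmin <= a.position[2] <= zmax]
        if not entries:
            raise EmptyStructureError("no atoms inside the requested z window")
    atom, radius = min(entries, key=lambda e: e[1])
    return float(radius), atom


def radius_profile(
    ring: RingAssembly,
    bin_width: float = DEFAULT_BIN_WIDTH,
    polyalanine: bool = True,
    z_window: Optional[Tuple[float, float]] = None,
) -> RadiusProfile:
    """Minimum radius per Z bin plus the global constriction.

    Bins are contiguous intervals of width bin_width spanning the aligned
    atoms' Z range; a bin with no atoms reports None, never 0.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sub = _ring_atom_set(ring, polyalanine)
    sub_ring = RingAssembly(sub, ring.ring_chains)
    aligned, _, _ = align_axis_to_z(sub_ring)
    entries = radial_distances(aligned)
    if z_window is not None:
        zmin, zmax = min(z_window), max(z_window)
        entries = [(a, r) for a, r in entries if zmin <= a.position[2] <= zmax]
        if not entries:
            raise EmptyStructureError("no atoms inside the requested z window")
    zs = np.array([a.position[2] for a, _ in entries])
    lo, hi = float(zs.min()), float(zs.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    centers, minima = [], []
    for i in range(n_bins):
        z0 = lo + i * bin_width
        z1 = z0 + bin_width
        centers.append(z0 + 0.5 * bin_width)
        # half-open bins, last bin closed so the topmost atom is counted
        in_bin = [
            r
            for a, r in entries
            if (z0 <= a.position[2] < z1) or (i == n_bins - 1 and a.position[2] == z1)
        ]
        minima.append(min(in_bin) if in_bin else None)
    g_radius, g_atom = _min_radius(aligned, z_window)
    return RadiusProfile(
        bin_centers=tuple(centers),
        bin_min_radius=tuple(minima),
        global_min_radius=g_radius,
        limiting_atom=g_atom,
        bin_width=float(bin_width),
        z_window=z_window,
    )


def min_radius_about_line(
    model: StructureModel,
    axis: AxisLine,
    polyalanine: bool = True,
    z_window: Optional[Tuple[float, float]] = None,
) -> Tuple[float, AtomRecord]:
    """Minimum distance from a protein atom to an arbitrary axis line.

    Used when the channel axis is defined externally, e.g. as the helical
    axis of encircled duplex DNA: the model is re-framed so the line is +Z
    and the minimum radius is taken over amino-acid atoms only (optionally
    polyalanine-reduced).
    """
    prot = model.select(predicate=lambda a: _is_amino(a.residue_name))
    if polyalanine:
        prot = to_polyalanine(prot)
    aligned = align_line_to_z(prot, axis)
    return _min_radius(aligned, z_window)
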