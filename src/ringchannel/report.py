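"""Machine-readable reports with a stable, diffable serialization.

Reports are pydantic models (they double as the shipped schema); floats are
rounded to 6 decimals and keys sorted, so identical inputs always produce
byte-identical JSON.
"""

from __future__ import annotations

import json
from typing import List, Optional, Tuple

from pydantic import BaseModel, Field

from .axis import ChannelAxisFrame, RotationDescriptor
from .profile import RadiusProfile
from .structures import AtomRecord

FLOAT_DECIMALS = 6


class AtomId(BaseModel):
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str


class AxisReport(BaseModel):
    omega_deg: float
    phi_deg: float
    chi_deg: float
    axis: Tuple[float, float, float]
    center: Tuple[float, float, float]
    fit_rmsd: float
    n_pairs: int


class ProfileBin(BaseModel):
    z_center: float
    min_radius: Optional[float] = None


class ChannelReport(BaseModel):
    """Full channel-analysis report: axis, constriction and profile."""

    input: str
    ring_chains: List[str]
    polyalanine: bool
    n_atoms_analyzed: int
    axis: AxisReport
    global_min_radius: float
    limiting_atom: AtomId
    bin_width: float
    z_window: Optional[Tuple[float, float]] = None
    profile: List[ProfileBin] = Field(default_factory=list)


def atom_id(atom: AtomRecord) -> AtomId:
    return AtomId(
        chain_id=atom.chain_id,
        residue_number=atom.residue_number,
        insertion_code=atom.insertion_code,
        residue_name=atom.residue_name,
        atom_name=atom.atom_name,
    )


def axis_report(desc: RotationDescriptor, frame: ChannelAxisFrame) -> AxisReport:
    return AxisReport(
        omega_deg=desc.omega_deg,
        phi_deg=desc.phi_deg,
        chi_deg=desc.chi_deg,
        axis=tuple(desc.axis.tolist()),
        center=tuple((-frame.pre_translation).tolist()),
        fit_rmsd=desc.fit_rmsd,
        n_pairs=desc.n_pairs,
    )


def channel_report(
    source: str,
    ring_chains,
    polyalanine: bool,
    n_atoms: int,
    desc: RotationDescriptor,
    frame: ChannelAxisFrame,
    profile: RadiusProfile,
) -> ChannelReport:
    return ChannelReport(
        input=source,
        ring_chains=list(ring_chains),
        polyalanine=polyalanine,
        n_atoms_analyzed=n_atoms,
        axis=axis_report(desc, frame),
        global_min_radius=profile.global_min_radius,
        limiting_atom=atom_id(profile.limiting_atom),
        bin_width=profile.bin_width,
        z_window=profile.z_window,
        profile=[
            ProfileBin(z_center=z, min_radius=r)
            for z, r in zip(profile.bin_centers, profile.bin_min_radius)
        ],
    )


def _round_floats(obj):
    if isinstance(obj, float):
        v = round(obj, FLOAT_DECIMALS)
        return 0.0 if v == 0 else v  # avoid -0.0 wobble
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def to_json(model: BaseModel) -> str:
    """Deterministic JSON: sorted keys, floats at 6 decimals, newline-terminated."""
    payload = _round_floats(model.model_dump(mode="python"))
    return json.dumps(payload, sort_keys=True, indent=2) + "\n"
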