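# Methods

## Channel axis as the subunit-permutation rotation

Given a ring of n chains in a user-supplied cyclic order, every atom of
chain k is paired with the atom of chain k+1 (cyclically) carrying the same
`(residue number, insertion code, atom name)` key; no sequence alignment is
attempted, because rings of identical subunits share numbering and an
alignment step would only add silent failure modes. The union of all pairs,
centered on the unweighted geometric center of the ring chains, enters one
least-squares superposition solved by the standard SVD (Kabsch)
construction with determinant correction, so the result is always a proper
rotation. Its axis is the channel axis, through the geometric center; its
magnitude Χ is 360°/n for an ideal Cn ring. A warning is issued when fewer
than half the atoms find a partner; fewer than three pairs is an error.
An option restricts the fit to CA atoms; for identical subunits the
all-atom and CA-only fits agree, and the all-atom fit is the default
because it maximizes the pair count under noise.

"Center of mass" is implemented as the unweighted geometric center of the
selected (non-hydrogen) atoms. For any Cn-symmetric ring, any per-atom
weighting places the center on the symmetry axis, which is all the
downstream construction uses; an atomic-mass convention would change
nothing for the symmetric case and is not obviously preferable for the
asymmetric one.

## Polar angles and the two-step re-framing

A rotation is reported in polar angles (Ω, Φ, Χ): axis
`a = (sin Ω cos Φ, sin Ω sin Φ, cos Ω)`, right-handed rotation by Χ about
a. Canonical ranges are Χ ∈ [0°, 180°], Ω ∈ [0°, 180°], Φ ∈ (−180°, 180°];
the axis/angle sign ambiguity (a, Χ) ≡ (−a, −Χ) is resolved by keeping
Χ non-negative, the identity is reported as (0, 0, 0), Φ is set to 0 when
the axis is along ±Z (azimuth undefined), and at Χ = 180° (where (a, 180°)
≡ (−a, 180°)) the axis is flipped into the upper hemisphere (Ω ≤ 90°).

Re-framing applies, after centering, two successive polar rotations:
(0, 0, −Φ) — a rotation by −Φ about +Z that zeroes the axis azimuth — then
(90, 90, −Ω) — a rotation by −Ω about +Y that removes the inclination.
The composition provably maps a onto +Z, and the test suite verifies both
the algebraic identity on an (Ω, Φ) grid and, on generated rings, that
per-atom radii from this two-step procedure equal those from the minimal
single rotation taking a onto +Z to 1e-9 Å (rotations about Z cannot
change √(X²+Y²), so the residual Z-rotation by −Φ is harmless).

## Radii

Radii are distances of atom centers to the axis, computed as √(X²+Y²) in
the aligned frame. No van der Waals radius is subtracted and no probe is
rolled (HOLE-style solvent-pathway tracing answers a different question);
minimum radii are therefore comparable only between structures measured
the same way. The default atom set is the polyalanine reduction (N, CA, C,
O, CB per amino-acid residue; waters and non-polymer heteroatoms dropped)
of the ring chains only, which removes side-chain-dependent variation from
the constriction measurement. The profile bins atoms by aligned Z with a
default bin width of 2.0 Å (about one atom diameter — a cosmetic choice);
empty bins report an explicit null, never 0. An optional z-window restricts
the minimum along the axis for assemblies where capping domains near the
axis would otherwise dominate; the default is no restriction, and the CLI
accepts only an explicit `Z1:Z2` window because no non-arbitrary automatic
window exists (the atom set is already restricted to the ring chains).

For a ring encircling duplex DNA the axis may be defined from the DNA
instead: residue i of one strand is paired with residue N+1−i of the other
(antiparallel register, user-overridable offset), midpoints of paired C1′
atoms are collected, and the axis is the principal axis of the midpoint
cloud through its centroid, signed along the first strand's 5′→3′
direction. A straight line, not a curved helical axis, is fitted: the
encircled fragments are short (tens of base pairs), and the radius
computation downstream needs a single line. C1′ was chosen as the
reference atom because it is present in every nucleotide model and sits at
the glycosidic attachment, equidistant from the two backbones of an ideal
duplex; phosphate-based or base-pair-frame definitions would differ by
fractions of an Å for near-ideal B-DNA.

## Domain comparison and dihedrals

Rigid-body motion of a subdomain between two structures is measured in two
stages: (1) superpose the mobile structure onto the reference over a frame
selection (chain + inclusive residue ranges, CA atoms by default — robust
when comparing homologs with different side chains); (2) between the two
centered domain point sets, report Χ of the least-squares rotation (range
[0°, 180°]) and the distance between the domain geometric centers in the
shared frame. Residue pairing inside selections is positional (i-th residue
of a range with the i-th of its partner range), so homolog numbering
offsets are expressed by giving different ranges rather than by a hidden
alignment. Both numbers are invariant under a common rigid motion and
unchanged when the mobile/reference roles are swapped (Χ(R) = Χ(R⁻¹)).

Backbone φ (C(i−1)–N–CA–C) and ψ (N–CA–C–N(i+1)) use the IUPAC sign
convention (right-handed, cis = 0°), range (−180°, 180°]. A missing
neighbor or missing backbone atom leaves the affected angle undefined
(`None`), never 0. The implementation is the standard orthogonal-projection
torsion formula and is cross-checked against gemmi's dihedral routine in
the tests; a NeRF-style internal-coordinate builder (idealized bond
lengths/angles, ω = 180°) provides round-trip verification of prescribed
(φ, ψ) to 1e-6°.

## File handling

Reading and PDB writing go through gemmi. Only the first coordinate model
of a file is used (the intended inputs are crystal structures); hydrogens
are dropped on read (X-ray comparator structures have none, and radii
should not depend on protonation); alternate locations are resolved to the
highest-occupancy conformer, ties broken by file order; residue identity
keys include the insertion code and numbering is taken verbatim from the
file. Coordinates must fit the fixed-width PDB field (−1000 < x < 10000 Å)
on write. No symmetry-mate expansion or biological-assembly generation is
performed — the user supplies a complete ring and names its chains.

## Synthetic data: what it emulates and what it does not

The generator builds Cn assemblies by rotating a template subunit by
k·360°/n about a programmed axis through a programmed center. The default
template is ~40 pseudo-CA atoms forming an L-shaped wall (a vertical strip
4 Å outside the constriction and a horizontal arm extending outward) plus
one designated innermost atom placed exactly at the constriction radius;
user templates are scaled in the plane so their innermost atom lands on
the requested radius. Chains are lettered A, B, C, … in rotational order,
so the natural cyclic order matches the construction. Optional isotropic
Gaussian noise (per coordinate, one seeded PRNG stream per call) is added
after the symmetric construction; rigid perturbations draw a uniform
rotation (scipy's uniform SO(3) sampler) and a translation uniform in
[−50, 50]³ Å. Duplex fixtures are two antiparallel C1′-only point helices
(defaults: rise 3.4 Å, twist 34.3°, radius 9.4 Å — canonical B-DNA) whose
paired midpoints lie exactly on the programmed axis.

These fixtures exercise the geometry — axis recovery, polar-angle algebra,
radii, invariances — exactly, because the ground truth is the
construction. They do not emulate real coordinate error structure
(anisotropic displacement, correlated domain motions, missing loops,
alternate conformations beyond the altloc mechanism) or real subunit
asymmetry, so passing tests demonstrate correctness of the analysis, not
robustness to every pathology of experimental models. Noise robustness is
quantified under the simplest realistic model (isotropic σ = 0.2 Å, about
the coordinate uncertainty of a mid-resolution structure) on rings of 300
atoms per subunit, where the recovered axis stays within 0.5° of truth in
≥95% of replicates.

## Numerical choices and problem sizes

Degenerate superposition inputs (fewer than 3 pairs, collinear point sets)
raise typed errors rather than returning an arbitrary rotation. Rotation
matrices are validated to 1e-6 orthogonality on input and produced at
1e-9 or better; reported quantities in JSON are rounded to 6 decimals with
sorted keys so identical runs are byte-identical. The acceptance script
and test suite run entirely on generated data at modest sizes — rings of
3–8 subunits with 41–300 atoms per subunit, 20–100 replicates per
property — chosen so each property is measured well away from its
tolerance while the whole suite completes in a few seconds. The
independent cross-checks (sampled rotation search with Nelder-Mead
refinement; Fibonacci-sphere axis grid of 400 directions plus local
refinement; textbook point-to-line distances) share no code path with the
closed-form Kabsch/polar implementation they verify.

## Known limitations

- Hetero-oligomers are handled only insofar as consecutive chains share
  atom keys; genuinely non-identical subunits (e.g. the six distinct
  subunits of a eukaryotic replicative helicase) need compatible numbering.
- Only cyclic symmetry is considered; dihedral, helical or icosahedral
  assemblies are out of scope.
- The DNA axis fit assumes an essentially straight duplex; strongly bent
  DNA would need a local-helical-axis treatment.
- Minimum radii are atom-center distances, not solvent-accessible pore
  radii; subtract an appropriate van der Waals radius before comparing
  with probe-based tools.
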