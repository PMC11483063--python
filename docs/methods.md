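# Methods

## Scope and model

`symbond` implements the geometric stage of bond-centric protein
nanomaterial design: given cyclic oligomeric building blocks decorated with
heterodimeric bonding modules, it produces candidate arrangements in target
symmetric architectures, the rigid junction specifications a backbone
generator must realize, filtered design tables, and simulated small-angle
scattering patterns of lattice models. Everything downstream of geometry —
backbone generation, sequence design, interface energetics, structure
prediction — is out of scope; the package consumes those tools' outputs
(metric tables) and produces their inputs (junction gaps, placements).

All coordinates are Cartesian angstroms, right-handed axes, no implicit
origin shifts. The design stage operates at backbone (Cα) resolution;
full-atom structures read from PDB/mmCIF pass through unchanged.

## Rotation groups

Point groups Cn, Dn, T, O, I are generated by brute-force closure from
fixed generator sets (T: C3 about (1,1,1)/√3 and C2 about z; O: the same
plus C4 about z; I: C5 about the icosahedron vertex direction (0,1,φ) with
φ the golden ratio, and C2 about z). Closure deduplicates matrices at 1e-6
per entry (compositions of exact rotations accumulate ≤1e-12 error each),
verifies the expected order exactly, and sorts elements by (angle, axis)
for determinism. Angle/axis extraction uses the quaternion path
(scipy `Rotation`), which is stable for 180° elements where the
antisymmetric part of the matrix vanishes; a direct matrix-based extraction
was numerically unreliable there and was replaced.

Axes are undirected and sign-canonicalized (first nonzero component
positive). `axes_of_order(G, n)` reports every axis hosting an order-n
element together with the axis's maximal order; placement uses only axes
whose *maximal* order matches the component (a C2 dimer belongs on a true
2-fold axis, not on the C2 subgroup of a C4 axis).

## Building blocks

The toy generator produces ideal Cn α-helical bundles: one Cα helix
(rise 1.5 Å/residue, twist 100°/residue, helical radius 2.3 Å) placed at
`ring_radius` (default 15 Å) from the z axis and replicated by exact n-fold
rotation. The seed sets only the helix phase, so blocks are deterministic
and exactly symmetric. These fixtures reproduce the *geometry* of real
cyclic oligomers (a cyclic axis, a finite radial extent, a clash envelope)
but none of their chemistry: no side chains, no sequence, no real interface
shapes. Passing tests therefore demonstrate correctness of the placement
and scoring machinery, not designability of any particular protein.

Principal-axis detection superposes chain 0 onto chain 1; for a Cn ring
this transform is a rotation by 360/n about the cyclic axis, whose
direction and fixed line give the axis and center. The detected axis is
accepted only if the cyclic permutation RMSD is ≤ 2.0 Å.

Bonding modules are grafted rigidly through attachment frames expressed in
the reference chain's coordinates; symmetric grafting places n copies
related by the block's own Cn, heterotrimer mode places exactly one and
flags the block as symmetry-broken by occupancy (same backbone, one
occupied site). Grafts approaching the core closer than 2.0 Å Cα–Cα —
below the closest approach of packed backbones — are rejected.

## Placement

Architecture names encode the group and the per-component axis orders
("O43" → octahedral, components on C4 and C3 axes; "Dnm" → dihedral Dn
with components on the main axis and the perpendicular 2-folds; "Cn" →
cyclic). Single-digit polyhedral names ("O3") are single-component on-axis
cages. Single-digit dihedral names ("D4") denote docked assemblies whose
block axis is *not* a group axis; the block is treated as a free
asymmetric unit and expanded by all |G| elements. Its two degrees of
freedom are spin about its own axis and translation along a fixed generic
direction chosen off every group axis.

On-axis components are placed on the lexicographically smallest axis of
their order (outward convention: block +axis away from the group center; a
flip flag reverses it) and expanded by coset representatives — the first
group element mapping the oriented representative onto each distinct image
— giving |G|/n positions and |G| chains per component. When both
components share one axis order (T33), the second takes the antiparallel
orientation of the same axis, producing the two dual orbits of oriented
3-fold directions. Placed-axis angles therefore reproduce the group's
inter-axis angle table by construction; the test suite verifies this
against independent brute-force axis enumeration to 1e-6°.

The three-component dihedral arrangement fixes a C3 trimer on z and places
C2 dimers on perpendicular axes through the origin (exactly 90°), expanded
by the trimer's 3-fold. The dimer reference orientation is computed at
φ = 0 and then spun about the C3 axis, so φ and φ+120° give identical
assemblies up to relabeling. The dimer's radial offset defaults to the
trimer's radial extent plus 10 Å.

Clash screening counts unordered inter-chain Cα pairs below a cutoff
(default 4.0 Å, a typical backbone closest approach) using a k-d tree;
tests verify it against the O(N²) double loop.

## Junctions and filters

A junction gap is the rigid transform `goal ∘ start⁻¹` between two
orthonormal attachment frames. Closure error reports the origin distance
d_trans (Å), the relative rotation angle d_rot (degrees), and a combined
dimensionless score `(d_trans + L·d_rot[rad])/s` with lever arm L = 10 Å
and scale s = 10 Å. The lever arm converts rotational error into an
equivalent displacement at the far end of a ~10 Å junction segment; the
scale makes the score comparable to backbone-generator tolerance settings
(0.25 default, 0.1 for tight closure). No standard functional form exists
for this tolerance metric, so both constants are explicit parameters.

Filter cascades apply threshold inequalities exactly as printed — strict
`>`/`<` clauses reject boundary values, non-strict `≤` accept them — so
pLDDT = 90 fails `> 90`, ddG = −20 fails `< −20`, and a methionine count
of 5 passes `≤ 5`. Missing metrics fail the row with an explicit
"missing" reason by default (permissive mode), or raise in strict mode.
The Δsap clause applies only when a sap value is present. Superposition
RMSD uses proper-rotation Kabsch superposition (no reflections), checked
in the suite against an SVD-free numerical minimization.

## Lattices

Open architectures are generated as finite coordinate patches — no
periodic boundary — because microscopy and scattering comparisons are made
on finite crystallites. Edge blocks are retained and labeled by cell
index.

**P3 layers.** Hexagonal lattice vectors of equal length at 120°;
threefold sites at (0,0), (1/3,2/3), (2/3,1/3). Component A is fixed at
the origin site in the lattice plane; component B occupies (1/3,2/3) with
a z-offset and a spin about its 3-fold, the layer's free degrees of
freedom together with the spacing a. A finite square patch is not itself
3-fold symmetric, so the symmetry test verifies that rotating the patch
by 120° maps each chain onto an exact lattice translate of a chain of the
same site type.

**F432 crystals.** Octahedral cages (verified by applying all 24 group
elements to the Cα cloud) sit at FCC nodes with cubic axes aligned to the
cell; C3 linkers occupy the (¼,¼,¼)-type tetrahedral interstitial orbit
with their 3-fold along (1,1,1) — a threefold of the local neighbor
tetrahedron. The single free lattice parameter is a; each interior linker
site has exactly 4 equidistant cages at √3·a/4, and each interior cage
engages 4 linkers tetrahedrally, which is the machine-readable form of the
"4 cages + 4 linkers per local tetrahedron" connectivity (a cage
tetrahedron has exactly one interstitial center, so the 4+4 motif is a
coordination statement, not a literal 8-body cluster). The cage
orientation at FCC nodes relative to linker handedness is exposed as the
linker spin; the default is 0°.

Zone-axis projections are orthographic onto the plane normal to [hkl] with
a deterministic in-plane basis (e1 = hkl × ẑ normalized, x̂ if parallel;
e2 completes the right-handed triad). Bragg positions use
q = (4π/(√3·a))·√(h²+hk+k²) for the hexagonal layer and
q = (2π/a)·√(h²+k²+l²) with the all-even/all-odd face-centering rule for
the cubic crystal — selection rules and positions only, no intensities.

## Monte-Carlo Debye simulation

Scattering lengths default to atomic numbers (the q→0 X-ray limit);
q-dependent form factors and solvent-excluded-volume corrections are
deliberately omitted because lattice validation compares peak *positions*.
The pair-distance histogram samples ordered distinct pairs uniformly
(the second index is offset from the first by a nonzero shift modulo N,
exactly uniform over distinct pairs), accumulating bᵢbⱼ per bin; the
diagonal Σbᵢ² term is added analytically. Defaults: 10⁷ pairs, 1 Å bins,
r_max the bounding-box diagonal.

The transform rescales the sampled off-diagonal sum by N(N−1)/n_pairs and
evaluates sinc at the **b-weighted mean sampled distance of each bin**
rather than the bin midpoint. This removes first-order binning bias: a
two-scatterer system reproduces the closed form
I(q)/I(0) = (1 + sinc(qd))/2 exactly at any bin width. I(0) normalizes to
1 by construction and the sinc limit keeps I continuous at q = 0.

Verification fixtures and their sizes: (i) the two-point closed form;
(ii) a uniform sphere of R = 100 Å filled with 10⁶ random points, whose
profile must match the analytic form factor within 2% up to qR = 4 — the
cloud size is set by convergence of the *fixture*, since a random fill of
N points carries an intrinsic O(1/N) incoherent offset and coherent
fluctuations that at N ≲ 2·10⁵ rival the 2% band near the form-factor
minimum; (iii) MC-vs-exhaustive histogram agreement within 3 standard
errors on a 100-atom set; (iv) lattice-spacing recovery: a 4×4-cell P3
patch at a = 200 Å must show a profile maximum within one 0.001 Å⁻¹ grid
step of q₁ = 4π/(√3·200) = 0.03628 Å⁻¹. Multi-window merging scales later
windows onto earlier ones by least squares over shared overlap grid
points, mirroring low/mid/high-q experimental configurations
(0.003–0.007, 0.007–0.020, 0.020–0.200 Å⁻¹).

## Determinism and provenance

Grid DOF scans are deterministic; seeds affect only toy-block helix
phases and Monte-Carlo pair sampling. Every CLI artifact carries a sidecar
JSON with the configuration hash and seed, and no timestamps, so reruns
with identical configuration are byte-identical. Structures are written as
PDB when chain identifiers fit the single-character PDB field and as
mmCIF otherwise (assemblies beyond 62 chains, e.g. 120-chain I32 cages).

## Known limitations

- Toy blocks are Cα-only idealized bundles; real building-block and
  LHD-module internal geometry must be supplied by the user.
- The closure-score constants (lever arm, scale) are conventions, not
  measurements; scores are comparable only under fixed settings.
- The simulator omits instrument smearing, absolute calibration and
  background, so only peak positions — not intensities or widths — are
  comparable to experiment.
- Reconfiguration kinetics (cage↔layer exchange, capping modulators) are
  not modeled; the package is purely structural.
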