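# Methods

## The model

A closed CA shell is treated as a trivalent polyhedron whose faces are
pentamers and hexamers.  With `P` pentagons and `H` hexagons the shell has
`F = P + H` faces, `E = (5P + 6H)/2` edges and `V = (5P + 6H)/3` vertices;
`validate_shell` accepts a census iff `E` and `V` are integral and
`V − E + F = 2`, which algebraically forces `P = 12` (the Euler
characteristic reduces to `P/6 = 2`).  Two census families are exposed:

* Caspar–Klug icosahedra: `T = h² + hk + k²`, 12 pentamers,
  `10(T − 1)` hexamers, `60T` monomers, icosahedral symmetry.  `(h, k)`
  and `(k, h)` are mirror images; a handedness flag records the
  orientation without affecting counts.
* Dihedral capsules: two polar caps separated by `r` equatorial hexamer
  belts.  Five-fold capsules carry 12 pentamers and `5r` hexamers (D5);
  six-fold capsules a hexamer on each pole ringed by six pentamers, with
  `2 + 6r` hexamers in total (D6).  Only `r = 1` has been observed for
  each class; larger `r` are lattice extrapolations and are labelled as
  such.

## Interface parameterisation

The CTD–CTD dimer is parameterised exactly as in the interface-analysis
recipe the measurements follow: all backbone (N, CA, C) atoms of the
marker helix α8 are averaged for the whole-helix centroid; the centroids
of the first and second halves of the residue interval (odd counts give
the extra residue to the first half) are the start and end of the
directed axis vector; the crossing angle is the arccos of the normalised
dot product, reported over [0°, 180°].  The directed (N→C) convention is
deliberate: the hexamer–hexamer family sits near 95° and would alias onto
85° under an undirected [0°, 90°] convention.

**Twist aliasing.**  The half-centroid vector is not the least-squares
helix axis.  For an ideal α-helix (rise 1.5 Å, twist 100°/residue) the
per-half phasor sums leave a transverse residual that depends on the
residue count: a 14-residue helix (half-span 700° ≡ 340°) tracks the true
axis to 0.1°, while an 11–13-residue helix deviates by 3–6° (half-span
near 180° mod 360°).  This is a property of the estimator itself, is
fully shared between generator and pipeline (both measure the same
vector), and cancels entirely in crossing angles of helices built with
equal length.  The default marker interval is residues 186–201
(16 residues, covering the named α8 hydrophobic core A189–M197 plus
flanking turns; the true boundaries are not published and the interval is
configurable everywhere).

Interface records are classified by crossing angle with fixed boundaries
at 42.5° and 80° — the midpoints of the three family centres 20°, 65°,
95° — rather than by any data-driven clustering; determinism and direct
traceability were preferred over adaptivity, and the distance to the
nearest family centre is recorded with every label.  Capsule interfaces
additionally carry a POLAR/LONG/LAT tag: POLAR when both rings sit above
20° latitude (the pentamer caps sit at 26.6°–30°), otherwise LONG when
the inter-ring contact vector is within 45° of the principal axis and LAT
when not.  The 20° band is our choice; only the 45° contact-direction
threshold is inherited from the figure nomenclature.

## Rings, layers, conformers

Ring detection builds a graph on chains with an edge when the minimum
heavy-atom distance between NTD selections is below 6.0 Å; connected
components must have size 5 or 6 (anything else raises with the offending
component listed, since it almost always means a wrong cutoff or a
truncated assembly).  NTD rather than CTD contacts are used because the
NTDs cluster at the ring axis while the CTDs bridge rings.  The ring axis
is the best-fit-plane normal of the member NTD centroids, oriented
outward; members are ordered by azimuth about it.

Layer metrics use mass-weighted centres of mass over all heavy atoms of
each domain selection pooled over ring members (standard atomic weights
via gemmi; unknown elements fall back to carbon with a warning); the
whole-helix centroid above deliberately remains an unweighted backbone
mean, matching the published recipe.  Hydrogens and waters are excluded
from every geometric computation because their presence is
deposition-dependent.

The pentamer/hexamer conformer fingerprint is four heavy-atom
donor–acceptor distances (R143 guanidinium↔K182 main-chain O, R143↔Q181
side chain, D171↔S79′, K229↔D90′, where ′ is the next monomer in the
ring) with a 3.5 Å hydrogen-bond proxy and no angular term, so models
without hydrogens are usable; this over-counts marginal bonds and is a
documented limitation.  Pentamer-like requires R143↔K182 and K229↔D90′
closed; hexamer-like requires R143↔Q181 closed and K229↔D90′ open;
everything else is indeterminate.

## Point groups and superposition

C*n*/D*n* follow the crystallographic convention (principal axis +z, one
dihedral two-fold on +x); the icosahedral group uses the "I2" setting
(two-folds on x, y, z) and is produced by closure of a five-fold about an
icosahedron vertex direction and the two-fold about z, with the order-60
result asserted.  Operators are pure rotations about the origin; callers
centre the particle first.  Group checks use a 1e-9 tolerance since the
operators come from closed-form angles.  Rotation angles come from the
matrix trace; the axis is taken from the null space of `M − I` (stable at
all angles, unlike the antisymmetric part, which vanishes at 180°), with
its sign fixed by the antisymmetric part away from 180° and by a
largest-component-positive convention at 180°.

Superposition is Kabsch (SVD with reflection correction).  The
implementation is in-package and cross-checked in the test suite against
an independent library implementation, a Monte-Carlo residual expectation
(`rmsd → σ√3` for large point sets under isotropic noise) and a
random-rigid-transform optimality search.

## The synthetic generator

`make_shell` emulates exactly the observables the pipeline consumes and
nothing else.  Rings are placed on the exact symmetry directions of each
class (icosahedron vertices / face centres; polar caps at the icosahedral
cap latitude for D5 and at 60° for D6, with azimuths chosen so the
dihedral two-folds of the standard setting are honoured).  Every
inter-ring contact is realised as a marker-helix pair symmetric under the
local dyad: each helix is tilted half the target crossing angle from the
dyad and offset half the target displacement perpendicular to it, then
instantiated by rigidly transporting a canonical helix so that its
*measured* half-centroid vector and centroid land on the prescribed
values.  Recovery through the pipeline is therefore exact (~1e-13) at
zero noise, and the whole assembly carries its point group to machine
precision because every frame is built equivariantly from ring and edge
geometry.  Toy monomers are NTD/CTD blobs tagged with the diagnostic
residue numbers; each ring's blob atoms absorb a small common counter-
shift so the ring's mass-weighted CoM sits exactly at the recipe radius.

Defaults are the observed conditions where published (T=1 ring radius
86.3 Å, T=3 pentamer/hexamer radii 143.9/136.5 Å, NTD–CTD layer
separation 21.6 Å, interface targets 65°/12 Å for pentamer-involving
contacts and 95°/14 Å for hexamer–hexamer).  Capsule ring radii are not
published; 110/115 Å was chosen as consistent with the capsules being
larger than T=1 particles and gives ~9–11 Å of clearance between
non-interface CTDs, so contact detection is unambiguous even under noise.
Noise is isotropic Gaussian per atom coordinate with a mandatory recorded
seed; at σ = 0.3 Å the crossing-angle and displacement recovery errors
stay below 2° and 0.5 Å across all four classes (test suite,
fixed seed).

What the toys do **not** emulate: side-chain packing, clash avoidance,
flexible linkers, quasi-equivalent lattice strain, or realistic B-factors
— so passing the synthetic round trip validates the measurement and
bookkeeping machinery, not force-field-level realism.  Measurements on
deposited coordinates additionally depend on atom-selection conventions
(helix interval, which conformer of the NMR ensemble) that the deposited
entries leave open; `scripts/analyze_deposited.py` exposes those knobs.

## Numerical and interface conventions

* Residue numbering is 1-based, intervals inclusive; NTD 1–153 and CTD
  154–246 partition the 246-residue chain.
* Multi-model files: analyses default to model 1 (for the NMR ensemble,
  deposited model order is assumed to encode energy rank).
* Alternate locations collapse to the highest-occupancy conformer, ties
  broken first-seen, at read time.
* PDB output remaps multi-character chain IDs onto one character for up
  to 62 chains and refuses beyond; strict mode refuses any remapping and
  >99,999 atoms, advising mmCIF.  mmCIF preserves chain IDs exactly.
* Empty selections on analysis paths raise, never return silently empty.
* Report tables have fixed column order and fixed sort keys
  (`ring_a, ring_b, chain_a` for interfaces), so re-runs are
  byte-identical.
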