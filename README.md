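# capsgeom

Geometric analysis of retroviral capsid (CA) fullerene shells — the closed
polyhedral lattices of pentameric and hexameric CA rings that package a
retroviral genome.  The package is aimed at structural biologists who have
(or simulate) whole-shell atomic models — icosahedral T=1 / T=3 particles
and D5 / D6 capsules of the kind assembled in vitro by endogenous
betaretrovirus-like CA — and want quantitative answers to:

* **What is the shell census?**  A closed trivalent shell of pentagons and
  hexagons obeys Euler's formula `V − E + F = 2`, which forces exactly 12
  pentamers.  Caspar–Klug icosahedra indexed by `(h, k)` have
  `T = h² + hk + k²`, `60·T` monomers and `10·(T − 1)` hexamers; dihedral
  capsules insert equatorial hexamer belts between two icosahedron-like
  caps.
* **Where are the rings?**  CA N-terminal domains (NTD, residues 1–153)
  cluster around each local five-/six-fold axis while the C-terminal
  domains (CTD, 154–246) form an inner cage of inter-ring dimer contacts,
  so connected components of the NTD–NTD contact graph are exactly the
  pentamers and hexamers.
* **How are the rings joined?**  Every inter-ring CTD–CTD dimer is
  parameterised by its α8 helix pair: the helix centroid is the mean of
  the backbone (N, CA, C) atoms, the directed axis vector runs from the
  first-half centroid to the second-half centroid, the **crossing angle**
  is `arccos(û_a · û_b)` in `[0°, 180°]`, and the **displacement** is the
  whole-helix centroid distance.  Interfaces quantise into three families
  — near 20° (the solution dimer), near 65° (all pentamer-involving shell
  contacts) and near 95° (hexamer–hexamer contacts) — and `capsgeom`
  classifies each record with fixed boundaries at the family midpoints
  (42.5° and 80°).
* **What conformer is each monomer?**  The pentamer/hexamer switch is read
  from four diagnostic hydrogen-bond proxies (R143↔K182 main chain,
  R143↔Q181 side chain, D171↔S79′, K229↔D90′ at ≤ 3.5 Å heavy-atom
  distance).

The package also provides finite rotation point groups (C*n*, D*n*, and
icosahedral I in the "I2" setting with two-folds on x, y, z) for
symmetry-expanding asymmetric units, Kabsch superposition with
rotation-angle extraction, per-ring NTD/CTD layer metrics (centre-of-mass
radii and vertical separation), and a synthetic-shell generator that
builds complete T=1 / T=3 / D5 / D6 toy shells with a machine-readable
ground-truth manifest, so the entire pipeline is testable without any
downloads.

## Worked example

Generate a synthetic T=1 shell (60 chains, 12 pentamers) and run the full
pipeline on it:

```sh
$ capsgeom compose --t 3
{
  "label": "T3",
  "T": 3,
  "pentamers": 12,
  "hexamers": 20,
  "monomers": 180,
  "symmetry": "I",
  "euler_valid": true
}

$ capsgeom synth -c T1 --seed 7 --out demo
$ capsgeom analyze demo/T1.cif --out demo/report --fingerprints
{
  "fingerprint_states": { "pentamer-like": 60 },
  "interfaces_by_group": { "2": 30 },
  "interfaces_by_kind": { "pentamer-pentamer": 30 },
  "n_chains": 60,
  "n_interfaces": 30,
  "n_pentamers": 12,
  "n_rings": 12,
  ...
}
```

The summary says the contact graph found all 12 pentamer rings, the 30
inter-pentamer dimer interfaces (one per icosahedron edge), every
interface in group 2, and every monomer in the pentamer conformer state —
exactly the architecture the T=1 recipe encodes.  `demo/report/` holds the
sorted CSV tables; the first interface rows read

```
ring_a,ring_b,chain_a,chain_b,kind,topology,crossing_angle,displacement,group,...
ring00,ring01,A2,B2,pentamer-pentamer,,65.000000,12.000000,2,...
ring00,ring02,A3,C2,pentamer-pentamer,,65.000000,12.000000,2,...
```

i.e. the generator's 65° / 12 Å interface geometry is re-measured exactly.
The same pipeline runs on deposited assemblies
(`scripts/analyze_deposited.py` wraps it for the published T=1 / T=3
particles and the CTD solution dimer once those coordinate files have been
downloaded).

From Python:

```python
from capsgeom import caspar_klug, make_point_group, read_structure
from capsgeom import assembly

caspar_klug(1, 1).monomers        # 180
make_point_group("I").order       # 60
model = read_structure("demo/T1.cif")
rings = assembly.detect_rings(model)
records = assembly.enumerate_interfaces(model, rings)
```

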