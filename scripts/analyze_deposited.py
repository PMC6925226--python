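#!/usr/bin/env python
"""Headline geometric measurements on the deposited shell coordinates.

This reproduces the published interface and layer measurements from
locally available coordinate files (they are not bundled; fetch them
yourself, e.g. with ``wget https://files.rcsb.org/download/6SSJ.cif``):

* 6SSJ (T=1 assembly): CTD-CTD crossing angle / displacement (expect
  about 65 degrees / 12 A), NTD / CTD layer radii (86.3 / 64.7 A) and
  their vertical separation (21.6 A).
* 6SSM (T=3 assembly): pentamer vs hexamer ring radii (143.9 / 136.5 A).
* 6SAI (CTD NMR dimer, model 1): solution crossing angle (about 20
  degrees) and displacement (11 A).

Usage:
    python scripts/analyze_deposited.py --t1 6SSJ.cif [--t3 6SSM.cif]
                                        [--dimer 6SAI.pdb]

Deposited assemblies must contain the full particle (symmetry-expanded);
an asymmetric unit can be expanded first with ``capsgeom expand``.
"""

from __future__ import annotations

import argparse
import json

import numpy as np

from capsgeom import assembly as asm
from capsgeom.geometry import centroid_displacement, crossing_angle, helix_vector, layer_metrics
from capsgeom.structure import DomainScheme, read_structure, select


def analyze_shell(path: str, scheme: DomainScheme) -> dict:
    model = read_structure(path)
    first = select(model, model_num=model.model_nums()[0])
    centre = asm.particle_centre(first)
    rings = asm.detect_rings(first, scheme, centre=centre)
    interfaces = asm.enumerate_interfaces(first, rings, scheme)
    profile = asm.radial_profile(first, rings, scheme, centre)
    out = {
        "n_rings": len(rings),
        "n_interfaces": len(interfaces),
        "pentamer_radius": float(profile[profile["fold"] == 5]["radius"].mean()),
        "ntd_radius": float(profile[profile["fold"] == 5]["ntd_radius"].mean()),
        "ctd_radius": float(profile[profile["fold"] == 5]["ctd_radius"].mean()),
        "layer_separation": float(
            profile[profile["fold"] == 5]["vertical_displacement"].mean()),
    }
    if any(r.fold == 6 for r in rings):
        out["hexamer_radius"] = float(
            profile[profile["fold"] == 6]["radius"].mean())
    for kind in ("pentamer-pentamer", "pentamer-hexamer", "hexamer-hexamer"):
        recs = [r for r in interfaces if r.geometry.kind == kind]
        if recs:
            out[kind] = {
                "crossing_angle": float(np.mean(
                    [r.geometry.crossing_angle for r in recs])),
                "displacement": float(np.mean(
                    [r.geometry.displacement for r in recs])),
            }
    return out


def analyze_dimer(path: str, scheme: DomainScheme) -> dict:
    model = read_structure(path)
    first = select(model, model_num=model.model_nums()[0])  # lowest energy
    chains = first.chain_ids()
    if len(chains) != 2:
        raise SystemExit(f"{path}: expected a 2-chain dimer, found {chains}")
    iv = scheme.marker_interval
    ha = helix_vector(select(first, chain_ids=[chains[0]], residue_interval=iv), iv)
    hb = helix_vector(select(first, chain_ids=[chains[1]], residue_interval=iv), iv)
    return {
        "crossing_angle": crossing_angle(ha, hb),
        "displacement": centroid_displacement(ha, hb),
    }


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--t1", help="T=1 assembly coordinates (6SSJ)")
    parser.add_argument("--t3", help="T=3 assembly coordinates (6SSM)")
    parser.add_argument("--dimer", help="CTD solution dimer ensemble (6SAI)")
    parser.add_argument("--alpha8", default=None,
                        help="marker helix interval, e.g. 186-201")
    args = parser.parse_args()
    if not (args.t1 or args.t3 or args.dimer):
        parser.error("give at least one of --t1 / --t3 / --dimer")

    scheme = DomainScheme()
    if args.alpha8:
        lo, hi = (int(x) for x in args.alpha8.replace(":", "-").split("-"))
        scheme = DomainScheme(helices={**dict(scheme.helices), "alpha8": (lo, hi)})

    results = {}
    if args.t1:
        results["T1"] = analyze_shell(args.t1, scheme)
    if args.t3:
        results["T3"] = analyze_shell(args.t3, scheme)
    if args.dimer:
        results["solution_dimer"] = analyze_dimer(args.dimer, scheme)
    print(json.dumps(results, indent=2))


if __name__ == "__main__":
    main()
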