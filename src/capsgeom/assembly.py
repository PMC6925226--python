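"""Whole-particle pipeline: rings, interfaces, layers and conformer states.

Ring (capsomer) detection clusters chains by NTD-NTD heavy-atom contacts:
in these shells the NTDs pack around the local five-/six-fold axis while
the CTDs form the inter-ring inner cage, so NTD contact components are
exactly the pentamers and hexamers.  CTD-CTD contacts across ring
boundaries define the dimer interfaces, each parameterised by the marker
helix crossing angle and centroid displacement and classified into the
three discrete interface families:

* group 1 - solution-dimer-like, crossing angles near 20 degrees;
* group 2 - pentamer-pentamer and pentamer-hexamer contacts, near 65;
* group 3 - hexamer-hexamer contacts, near 95.

Boundaries sit at the midpoints of the family centres (42.5 and 80
degrees), a deterministic rule traceable to the reported centres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (
    EmptySelectionError,
    MissingAtomError,
    ParameterError,
    RingDetectionError,
)
from .geometry import (
    HelixVector,
    PairGeometry,
    atomic_mass,
    centroid_displacement,
    crossing_angle,
    helix_vector,
    layer_metrics,
)
from .structure import DomainScheme, StructureModel

__all__ = [
    "RingAssignment",
    "InterfaceRecord",
    "ConformationFingerprint",
    "particle_centre",
    "detect_rings",
    "enumerate_interfaces",
    "classify_interface",
    "radial_profile",
    "conformation_fingerprint",
    "interfaces_table",
    "rings_table",
    "fingerprints_table",
    "write_report",
]

GROUP_CENTRES = (20.0, 65.0, 95.0)
GROUP_BOUNDARIES = (42.5, 80.0)  # midpoints of the family centres
RING_CUTOFF = 6.0       # A, NTD-NTD heavy-atom contact for ring membership
INTERFACE_CUTOFF = 5.0  # A, CTD-CTD heavy-atom contact for dimer interfaces
HBOND_CUTOFF = 3.5      # A, heavy-atom donor-acceptor proxy for an H-bond


@dataclass(frozen=True)
class RingAssignment:
    ring_id: str
    chains: tuple[str, ...]   # ordered by angle about the ring axis
    fold: int
    centroid: np.ndarray      # mass-weighted CoM of member heavy atoms, A
    radius: float             # |centroid - particle centre|, A
    axis: np.ndarray          # unit, oriented outward from the particle centre

    def __post_init__(self):
        if self.fold != len(self.chains):
            raise ParameterError("ring fold must equal member count")


@dataclass(frozen=True)
class InterfaceRecord:
    chain_a: str
    chain_b: str
    ring_a: str
    ring_b: str
    geometry: PairGeometry
    group: int
    group_distance: float     # |angle - nearest family centre|, degrees
    min_contact: float        # min CTD-CTD heavy-atom distance, A


@dataclass(frozen=True)
class ConformationFingerprint:
    """Diagnostic NTD-CTD hydrogen-bond distances for one monomer.

    The pentamer conformation pairs the R143 guanidinium with the K182
    main-chain carbonyl and holds the inter-monomer K229-D90' salt bridge;
    the hexamer conformation swaps R143 onto the Q181 side chain and
    loses K229-D90'.  Distances are heavy-atom donor-acceptor minima.
    """

    chain: str
    neighbour_chain: str
    d_r143_k182mc: float
    d_r143_q181sc: float
    d_d171_s79: float
    d_k229_d90: float
    state: str  # pentamer-like / hexamer-like / indeterminate


# -- particle centre and ring detection -------------------------------------


def particle_centre(assembly: StructureModel) -> np.ndarray:
    """Unweighted centroid of all heavy atoms."""
    heavy = assembly.heavy()
    if not heavy.atoms:
        raise EmptySelectionError("assembly has no heavy atoms")
    return heavy.coords().mean(axis=0)


def _chain_selections(assembly: StructureModel, interval: tuple[int, int]):
    """Heavy-atom coordinates of one residue interval per chain (model 1)."""
    model_num = assembly.model_nums()[0]
    out: dict[str, np.ndarray] = {}
    for cid in assembly.chain_ids(model_num):
        sel = assembly.select(chain_ids=[cid], residue_interval=interval,
                              model_num=model_num, allow_empty=True).heavy()
        if sel.atoms:
            out[cid] = sel.coords()
    return out


def _contact_graph(coords: dict[str, np.ndarray], cutoff: float) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(coords)
    ids = sorted(coords)
    trees = {c: cKDTree(coords[c]) for c in ids}
    centres = {c: coords[c].mean(axis=0) for c in ids}
    radii = {c: float(np.linalg.norm(coords[c] - centres[c], axis=1).max()) for c in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if np.linalg.norm(centres[a] - centres[b]) > radii[a] + radii[b] + cutoff:
                continue
            d = trees[a].query(coords[b], k=1)[0].min()
            if d < cutoff:
                g.add_edge(a, b, distance=float(d))
    return g


def _min_distance(xa: np.ndarray, xb: np.ndarray) -> float:
    return float(cKDTree(xa).query(xb, k=1)[0].min())


def _ring_axis(centroids: np.ndarray, outward: np.ndarray) -> np.ndarray:
    """Normal of the best-fit plane of member centroids, oriented outward."""
    centred = centroids - centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    axis = vt[-1]
    if np.dot(axis, outward) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def detect_rings(assembly: StructureModel,
                 scheme: DomainScheme | None = None,
                 contact_cutoff: float = RING_CUTOFF,
                 centre: np.ndarray | None = None) -> list[RingAssignment]:
    """Partition chains into pentamer/hexamer rings via NTD-NTD contacts.

    Connected components of the NTD contact graph must all have size 5 or
    6; anything else raises :class:`RingDetectionError` listing the bad
    components (the usual causes are a wrong cutoff or a broken assembly).
    Members are ordered by angle about the ring axis, the best-fit-plane
    normal of the member NTD centroids.
    """
    scheme = scheme or DomainScheme()
    ntd = _chain_selections(assembly, scheme.ntd)
    if len(ntd) < 5:
        raise RingDetectionError(f"only {len(ntd)} chains carry an NTD selection")
    centre = particle_centre(assembly) if centre is None else np.asarray(centre, float)
    graph = _contact_graph(ntd, contact_cutoff)
    components = [sorted(c) for c in nx.connected_components(graph)]
    bad = [c for c in components if len(c) not in (5, 6)]
    if bad:
        raise RingDetectionError(
            f"{len(bad)} contact components are not pentamers/hexamers "
            f"(sizes {[len(c) for c in bad]}); check the contact cutoff",
            components=bad,
        )
    components.sort(key=lambda c: c[0])

    masses = {cid: np.array([atomic_mass(a.element) for a in
                             assembly.select(chain_ids=[cid]).heavy().atoms])
              for cid in ntd}
    rings = []
    for idx, members in enumerate(components):
        ntd_centroids = np.array([ntd[c].mean(axis=0) for c in members])
        ring_mid = ntd_centroids.mean(axis=0)
        axis = _ring_axis(ntd_centroids, outward=ring_mid - centre)
        # order members by azimuth about the axis
        e1 = np.cross(axis, [1.0, 0.0, 0.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(axis, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        rel = ntd_centroids - ring_mid
        order = np.argsort(np.arctan2(rel @ e2, rel @ e1))
        ordered = tuple(members[i] for i in order)
        # mass-weighted CoM over all heavy atoms of the members
        num, den = np.zeros(3), 0.0
        for c in members:
            xyz = assembly.select(chain_ids=[c]).heavy().coords()
            w = masses[c]
            num += (xyz * w[:, None]).sum(axis=0)
            den += w.sum()
        com = num / den
        rings.append(RingAssignment(
            ring_id=f"ring{idx:02d}", chains=ordered, fold=len(members),
            centroid=com, radius=float(np.linalg.norm(com - centre)),
            axis=axis,
        ))
    return rings


# -- interfaces -------------------------------------------------------------


def classify_interface(geom: PairGeometry) -> tuple[int, float]:
    """Family label (1/2/3) from fixed crossing-angle boundaries.

    angle < 42.5 -> 1; 42.5 <= angle < 80 -> 2; angle >= 80 -> 3.  Also
    returns the distance to the nearest family centre (20/65/95 degrees).
    """
    a = geom.crossing_angle
    if not 0.0 <= a <= 180.0:
        raise ParameterError(f"crossing angle {a} outside [0, 180]")
    group = 1 if a < GROUP_BOUNDARIES[0] else (2 if a < GROUP_BOUNDARIES[1] else 3)
    return group, float(min(abs(a - c) for c in GROUP_CENTRES))


def _interface_kind(fold_a: int, fold_b: int) -> str:
    names = {5: "pentamer", 6: "hexamer"}
    a, b = sorted((fold_a, fold_b))
    return f"{names[a]}-{names[b]}"


def _topology_tag(ring_a: RingAssignment, ring_b: RingAssignment,
                  principal_axis: np.ndarray,
                  centre: np.ndarray) -> str:
    """POLAR / LONG / LAT tag for capsule interfaces.

    Both rings above 20 degrees latitude -> POLAR (the polar caps);
    otherwise the inter-ring contact vector decides: within 45 degrees of
    the principal axis -> LONG, else LAT.
    """
    z = principal_axis / np.linalg.norm(principal_axis)
    ca = ring_a.centroid - centre
    cb = ring_b.centroid - centre
    lat_a = abs(np.dot(ca, z)) / max(np.linalg.norm(ca), 1e-9)
    lat_b = abs(np.dot(cb, z)) / max(np.linalg.norm(cb), 1e-9)
    polar = np.sin(np.radians(20.0))
    if lat_a > polar and lat_b > polar:
        return "POLAR"
    contact = ring_b.centroid - ring_a.centroid
    n = np.linalg.norm(contact)
    if n < 1e-9:
        return "LAT"
    return "LONG" if abs(np.dot(contact, z)) / n > np.cos(np.radians(45.0)) else "LAT"


def enumerate_interfaces(assembly: StructureModel,
                         rings: list[RingAssignment],
                         scheme: DomainScheme | None = None,
                         contact_cutoff: float = INTERFACE_CUTOFF,
                         principal_axis: np.ndarray | None = None,
                         centre: np.ndarray | None = None
                         ) -> list[InterfaceRecord]:
    """All inter-ring CTD-CTD dimer interfaces, parameterised and classified.

    A pair of chains in different rings forms an interface when the
    minimum heavy-atom distance between their CTD selections is below the
    cutoff; the marker helices then give the crossing angle and centroid
    displacement.  Each unordered pair is reported once, sorted by
    (ring_a, ring_b, chain_a).
    """
    scheme = scheme or DomainScheme()
    ctd = _chain_selections(assembly, scheme.ctd)
    ring_of = {c: r for r in rings for c in r.chains}
    fold_of = {r.ring_id: r.fold for r in rings}
    ring_by_id = {r.ring_id: r for r in rings}
    if centre is None:
        centre = np.mean([r.centroid for r in rings], axis=0)

    helices: dict[str, HelixVector] = {}

    def marker(cid: str) -> HelixVector:
        if cid not in helices:
            sel = assembly.select(chain_ids=[cid],
                                  residue_interval=scheme.marker_interval)
            helices[cid] = helix_vector(sel, scheme.marker_interval)
        return helices[cid]

    centres = {c: ctd[c].mean(axis=0) for c in ctd}
    radii = {c: float(np.linalg.norm(ctd[c] - centres[c], axis=1).max()) for c in ctd}
    ids = sorted(ctd)
    records = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if ring_of.get(a) is ring_of.get(b):
                continue
            if np.linalg.norm(centres[a] - centres[b]) > radii[a] + radii[b] + contact_cutoff:
                continue
            dmin = _min_distance(ctd[a], ctd[b])
            if dmin >= contact_cutoff:
                continue
            ra, rb = ring_of[a].ring_id, ring_of[b].ring_id
            ha, hb = marker(a), marker(b)
            topo = ""
            if principal_axis is not None:
                topo = _topology_tag(ring_by_id[ra], ring_by_id[rb],
                                     principal_axis, centre)
            geom = PairGeometry(
                crossing_angle=crossing_angle(ha, hb),
                displacement=centroid_displacement(ha, hb),
                members=((a, ra), (b, rb)),
                kind=_interface_kind(fold_of[ra], fold_of[rb]),
                topology=topo,
            )
            group, gdist = classify_interface(geom)
            records.append(InterfaceRecord(
                chain_a=a, chain_b=b, ring_a=ra, ring_b=rb,
                geometry=geom, group=group, group_distance=gdist,
                min_contact=dmin,
            ))
    records.sort(key=lambda r: (r.ring_a, r.ring_b, r.chain_a))
    return records


def unique_interfaces(records: list[InterfaceRecord],
                      angle_tol: float = 1.0,
                      displacement_tol: float = 0.5) -> list[InterfaceRecord]:
    """One representative per (kind, angle, displacement) cluster.

    Symmetry copies of the same contact agree in both parameters; the
    first record (in sorted order) represents each cluster.
    """
    reps: list[InterfaceRecord] = []
    for rec in records:
        for rep in reps:
            if (rep.geometry.kind == rec.geometry.kind
                    and abs(rep.geometry.crossing_angle - rec.geometry.crossing_angle) <= angle_tol
                    and abs(rep.geometry.displacement - rec.geometry.displacement) <= displacement_tol):
                break
        else:
            reps.append(rec)
    return reps


# -- radial / layer profile -------------------------------------------------


def radial_profile(assembly: StructureModel,
                   rings: list[RingAssignment],
                   scheme: DomainScheme | None = None,
                   centre: np.ndarray | None = None) -> pd.DataFrame:
    """Per-ring radial distances and NTD/CTD layer metrics.

    One row per ring: the all-atom CoM radius plus the layer metrics taken
    about the ring's own local axis.
    """
    scheme = scheme or DomainScheme()
    centre = particle_centre(assembly) if centre is None else np.asarray(centre, float)
    rows = []
    for ring in rings:
        members = assembly.select(chain_ids=ring.chains)
        lm = layer_metrics(members, scheme, centre=centre, axis=ring.axis)
        rows.append({
            "ring_id": ring.ring_id,
            "fold": ring.fold,
            "radius": ring.radius,
            "ntd_radius": lm.ntd_radius,
            "ctd_radius": lm.ctd_radius,
            "vertical_displacement": lm.vertical_displacement,
        })
    return pd.DataFrame(rows, columns=["ring_id", "fold", "radius", "ntd_radius",
                                       "ctd_radius", "vertical_displacement"])


# -- conformational fingerprint ---------------------------------------------

# heavy-atom donor/acceptor sets for the four diagnostic pairs
_FP_ATOMS = {
    "R143": (143, ("NE", "NH1", "NH2")),
    "Q181sc": (181, ("OE1", "NE2")),
    "K182mc": (182, ("O",)),
    "D171": (171, ("OD1", "OD2")),
    "S79": (79, ("OG",)),
    "K229": (229, ("NZ",)),
    "D90": (90, ("OD1", "OD2")),
}


def _fp_coords(model: StructureModel, key: str) -> np.ndarray:
    res_seq, names = _FP_ATOMS[key]
    pts = [np.asarray(a.position) for a in model.atoms
           if a.res_seq == res_seq and a.name in names]
    if not pts:
        raise MissingAtomError(
            f"residue {res_seq} is missing atoms {names} (needed for {key})"
        )
    return np.array(pts)


def conformation_fingerprint(monomer: StructureModel,
                             neighbour: StructureModel,
                             scheme: DomainScheme | None = None,
                             hbond_cutoff: float = HBOND_CUTOFF
                             ) -> ConformationFingerprint:
    """Assign the pentamer/hexamer conformer state of one monomer.

    ``neighbour`` is the adjacent monomer in the same ring (the one whose
    NTD receives this monomer's CTD contacts).  The hydrogen-bond proxy is
    a heavy-atom donor-acceptor distance below ``hbond_cutoff`` with no
    angular term, so deposited models without hydrogens are usable.
    """
    def dmin(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)).min())

    r143 = _fp_coords(monomer, "R143")
    d1 = dmin(r143, _fp_coords(monomer, "K182mc"))
    d2 = dmin(r143, _fp_coords(monomer, "Q181sc"))
    d3 = dmin(_fp_coords(monomer, "D171"), _fp_coords(neighbour, "S79"))
    d4 = dmin(_fp_coords(monomer, "K229"), _fp_coords(neighbour, "D90"))

    if d1 <= hbond_cutoff and d4 <= hbond_cutoff:
        state = "pentamer-like"
    elif d2 <= hbond_cutoff and d4 > hbond_cutoff:
        state = "hexamer-like"
    else:
        state = "indeterminate"
    chain = monomer.atoms[0].chain_id if monomer.atoms else ""
    nchain = neighbour.atoms[0].chain_id if neighbour.atoms else ""
    return ConformationFingerprint(
        chain=chain, neighbour_chain=nchain,
        d_r143_k182mc=d1, d_r143_q181sc=d2, d_d171_s79=d3, d_k229_d90=d4,
        state=state,
    )


def ring_fingerprints(assembly: StructureModel,
                      rings: list[RingAssignment],
                      scheme: DomainScheme | None = None
                      ) -> list[ConformationFingerprint]:
    """Fingerprint every monomer against its next ring neighbour."""
    out = []
    for ring in rings:
        for i, cid in enumerate(ring.chains):
            nid = ring.chains[(i + 1) % ring.fold]
            out.append(conformation_fingerprint(
                assembly.select(chain_ids=[cid]),
                assembly.select(chain_ids=[nid]),
                scheme,
            ))
    return out


# -- report tables ----------------------------------------------------------

INTERFACE_COLUMNS = ["ring_a", "ring_b", "chain_a", "chain_b", "kind", "topology",
                     "crossing_angle", "displacement", "group", "group_distance",
                     "min_contact"]
RING_COLUMNS = ["ring_id", "fold", "radius", "axis_x", "axis_y", "axis_z", "chains"]
FINGERPRINT_COLUMNS = ["chain", "neighbour_chain", "d_r143_k182mc", "d_r143_q181sc",
                       "d_d171_s79", "d_k229_d90", "state"]


def interfaces_table(records: list[InterfaceRecord]) -> pd.DataFrame:
    rows = [{
        "ring_a": r.ring_a, "ring_b": r.ring_b,
        "chain_a": r.chain_a, "chain_b": r.chain_b,
        "kind": r.geometry.kind, "topology": r.geometry.topology,
        "crossing_angle": r.geometry.crossing_angle,
        "displacement": r.geometry.displacement,
        "group": r.group, "group_distance": r.group_distance,
        "min_contact": r.min_contact,
    } for r in records]
    df = pd.DataFrame(rows, columns=INTERFACE_COLUMNS)
    return df.sort_values(["ring_a", "ring_b", "chain_a"]).reset_index(drop=True)


def rings_table(rings: list[RingAssignment]) -> pd.DataFrame:
    rows = [{
        "ring_id": r.ring_id, "fold": r.fold, "radius": r.radius,
        "axis_x": r.axis[0], "axis_y": r.axis[1], "axis_z": r.axis[2],
        "chains": "+".join(r.chains),
    } for r in rings]
    df = pd.DataFrame(rows, columns=RING_COLUMNS)
    return df.sort_values("ring_id").reset_index(drop=True)


def fingerprints_table(fps: list[ConformationFingerprint]) -> pd.DataFrame:
    rows = [{
        "chain": f.chain, "neighbour_chain": f.neighbour_chain,
        "d_r143_k182mc": f.d_r143_k182mc, "d_r143_q181sc": f.d_r143_q181sc,
        "d_d171_s79": f.d_d171_s79, "d_k229_d90": f.d_k229_d90,
        "state": f.state,
    } for f in fps]
    df = pd.DataFrame(rows, columns=FINGERPRINT_COLUMNS)
    return df.sort_values("chain").reset_index(drop=True)


def write_report(outdir: str | Path,
                 rings: list[RingAssignment],
                 interfaces: list[InterfaceRecord],
                 layers: pd.DataFrame,
                 fingerprints: list[ConformationFingerprint] | None = None,
                 parameters: dict | None = None) -> dict:
    """Write the deterministic CSV/JSON report set; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    idf = interfaces_table(interfaces)
    rdf = rings_table(rings)
    fdf = fingerprints_table(fingerprints or [])
    idf.to_csv(outdir / "interfaces.csv", index=False, float_format="%.6f")
    rdf.to_csv(outdir / "rings.csv", index=False, float_format="%.6f")
    layers.to_csv(outdir / "layers.csv", index=False, float_format="%.6f")
    fdf.to_csv(outdir / "fingerprints.csv", index=False, float_format="%.6f")
    summary = {
        "n_chains": int(sum(r.fold for r in rings)),
        "n_rings": len(rings),
        "n_pentamers": sum(1 for r in rings if r.fold == 5),
        "n_hexamers": sum(1 for r in rings if r.fold == 6),
        "n_interfaces": len(interfaces),
        "interfaces_by_kind": {str(k): int(v) for k, v in
                               idf.groupby("kind").size().sort_index().items()},
        "interfaces_by_group": {str(k): int(v) for k, v in
                                idf.groupby("group").size().sort_index().items()},
        "fingerprint_states": {str(k): int(v) for k, v in
                               fdf.groupby("state").size().sort_index().items()},
        "parameters": parameters or {},
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
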