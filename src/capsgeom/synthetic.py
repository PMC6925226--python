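"""Synthetic CA shells with exact ground truth for pipeline validation.

The generator emulates the geometry the analysis consumes — nothing more:
toy monomers are an NTD point-cloud "blob" and a CTD blob, each tagged
with the diagnostic residue numbers, plus one marker helix per chain at
its single inter-ring dimer interface.  Shells are built interface-first:

* Rings (pentamer/hexamer positions and folds) are placed on the exact
  symmetry directions of the shell class: icosahedron vertices and face
  centres for T=1/T=3, polar caps plus an equatorial belt for the D5/D6
  capsules.
* Every inter-ring contact is realised as a pair of marker helices whose
  half-centroid vectors cross at exactly the requested angle, with
  whole-helix centroids exactly the requested distance apart.  The pair
  is symmetric under the local dyad, so a shell built this way carries
  its point-group symmetry to machine precision.
* Each ring's mass-weighted centre of mass is placed exactly at the
  recipe radius along the ring axis (the blob atoms absorb the small
  counter-shift), so radial profiles recover recipe values exactly.

Every quantity the downstream pipeline should recover is recorded in a
:class:`GroundTruthManifest`.  With ``noise_sigma = 0`` the recovery is
exact to floating-point roundoff; with noise it degrades gracefully.

What the toys do NOT emulate: real side-chain packing, clash-free
density, flexible linkers, or quasi-equivalent deformations beyond the
explicit interface parameterisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ParameterError
from .geometry import atomic_mass, helix_vector
from .structure import Atom, DomainScheme, StructureModel

__all__ = [
    "ShellRecipe",
    "GroundTruthManifest",
    "make_ideal_helix",
    "make_two_helix_fixture",
    "make_toy_ring",
    "make_toy_monomer",
    "make_shell",
    "SHELL_CLASSES",
]

PHI = (1.0 + np.sqrt(5.0)) / 2.0

SHELL_CLASSES = ("T1", "T3", "D5", "D6")

#: interface targets per contact kind: (crossing angle deg, displacement A).
#: Pentamer-involving contacts sit in the 65-degree family, hexamer-hexamer
#: contacts in the 95-degree family; the 20-degree family is the solution
#: dimer and does not occur inside shells.
DEFAULT_INTERFACE_TARGETS: Mapping[str, tuple[float, float]] = {
    "pentamer-pentamer": (65.0, 12.0),
    "pentamer-hexamer": (65.0, 12.0),
    "hexamer-hexamer": (95.0, 14.0),
}

#: ring-centre radii (A) per shell class: (pentamer radius, hexamer radius)
DEFAULT_RADII: Mapping[str, tuple[float, float]] = {
    "T1": (86.3, 86.3),
    "T3": (143.9, 136.5),
    "D5": (110.0, 115.0),
    "D6": (110.0, 115.0),
}

_RING_CHARS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdef"
_BLOB_RHO = 4.5  # A, blob-circle radius about the ring axis


@dataclass(frozen=True)
class ShellRecipe:
    """Generator parameters for one shell (defaults mirror the study values)."""

    shell_class: str = "T1"
    pentamer_radius: float = 86.3
    hexamer_radius: float = 86.3
    layer_separation: float = 21.6
    interface_targets: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INTERFACE_TARGETS))
    seed: int = 0
    noise_sigma: float = 0.0
    helix_residues: tuple[int, int] = (186, 201)

    def __post_init__(self):
        if self.shell_class not in SHELL_CLASSES:
            raise ParameterError(
                f"shell class {self.shell_class!r} not in {SHELL_CLASSES}")
        if min(self.pentamer_radius, self.hexamer_radius) <= 0:
            raise ParameterError("ring radii must be positive")
        if self.noise_sigma < 0:
            raise ParameterError("noise sigma must be >= 0")

    @classmethod
    def for_class(cls, shell_class: str, seed: int = 0,
                  noise_sigma: float = 0.0, **overrides) -> "ShellRecipe":
        rp, rh = DEFAULT_RADII[shell_class]
        kwargs = dict(shell_class=shell_class, pentamer_radius=rp,
                      hexamer_radius=rh, seed=seed, noise_sigma=noise_sigma)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class GroundTruthManifest:
    """Machine-readable ground truth emitted alongside each synthetic shell."""

    shell_class: str
    symmetry: str
    rings: list[dict]        # ring, fold, axis, centroid, radius, chains
    interfaces: list[dict]   # chain_a/b, ring_a/b, kind, angle, displacement, topology
    parameters: dict

    @property
    def chain_rings(self) -> dict[str, str]:
        return {c: r["ring"] for r in self.rings for c in r["chains"]}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        return cls(**json.loads(Path(path).read_text()))


# -- ideal helices ----------------------------------------------------------

# backbone atom placement on the helical cylinder, relative to CA:
# (radius A, phase offset deg, axial offset A)
_BB_PARAMS = {"N": (1.50, -28.5, -0.95), "CA": (2.30, 0.0, 0.0),
              "C": (1.65, 24.0, 0.55)}
_BB_ELEMENTS = {"N": "N", "CA": "C", "C": "C"}


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ParameterError("zero-length vector")
    return v / n


def _frame_to(axis: np.ndarray) -> np.ndarray:
    """Minimal rotation taking +z onto ``axis``."""
    z = np.array([0.0, 0.0, 1.0])
    a = _unit(axis)
    c = float(np.dot(z, a))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, a)
    k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + k + k @ k / (1 + c)


def make_ideal_helix(n_residues: int, rise: float = 1.5, twist: float = 100.0,
                     helix_radius: float = 2.3, axis=(0.0, 0.0, 1.0),
                     origin=(0.0, 0.0, 0.0), seed: int | None = None,
                     noise_sigma: float = 0.0, chain_id: str = "A",
                     start_res: int = 1, model_num: int = 1,
                     serial_start: int = 1) -> StructureModel:
    """Poly-alanine N/CA/C backbone on an ideal helical path.

    The CA trace spans exactly ``(n_residues - 1) * rise`` along the axis.
    Gaussian coordinate noise is optional and seeded for determinism.
    """
    if n_residues < 4:
        raise ParameterError("an ideal helix needs >= 4 residues")
    rot = _frame_to(axis)
    origin = np.asarray(origin, dtype=float)
    rng = np.random.default_rng(seed) if noise_sigma > 0 else None
    z0 = (n_residues - 1) * rise / 2.0  # centre the CA trace on the origin
    atoms = []
    serial = serial_start
    for i in range(n_residues):
        phase = np.radians(twist * i)
        for name in ("N", "CA", "C"):
            r, dphi, dz = _BB_PARAMS[name]
            scale = r / _BB_PARAMS["CA"][0] * helix_radius if name != "CA" else helix_radius
            ang = phase + np.radians(dphi)
            local = np.array([scale * np.cos(ang), scale * np.sin(ang),
                              i * rise + dz - z0])
            pos = rot @ local + origin
            if rng is not None:
                pos = pos + rng.normal(0.0, noise_sigma, 3)
            atoms.append(Atom(serial=serial, name=name,
                              element=_BB_ELEMENTS[name], alt_loc="",
                              res_name="ALA", res_seq=start_res + i,
                              chain_id=chain_id, model_num=model_num,
                              position=tuple(pos)))
            serial += 1
    return StructureModel(atoms, title=f"ideal helix n={n_residues}")


class _HelixTemplate:
    """Canonical marker helix with its measured half-centroid frame."""

    def __init__(self, residues: tuple[int, int]):
        n = residues[1] - residues[0] + 1
        model = make_ideal_helix(n, start_res=residues[0], chain_id="T")
        hv = helix_vector(model, residues)
        self.coords = model.coords() - hv.centroid
        self.names = [a.name for a in model.atoms]
        self.res_seqs = [a.res_seq for a in model.atoms]
        self.elements = [a.element for a in model.atoms]
        v0 = hv.direction
        w0 = _unit(np.array([1.0, 0.0, 0.0])
                   - np.dot([1.0, 0.0, 0.0], v0) * v0)
        self.frame0 = np.column_stack([v0, w0, np.cross(v0, w0)])

    def place(self, centroid: np.ndarray, direction: np.ndarray,
              roll_ref: np.ndarray) -> np.ndarray:
        """Coordinates with the measured vector along ``direction``.

        ``roll_ref`` fixes the rotation about the axis; it is projected
        perpendicular to ``direction`` and must not be parallel to it.
        """
        u = _unit(direction)
        r = np.asarray(roll_ref, float) - np.dot(roll_ref, u) * u
        r = _unit(r)
        frame = np.column_stack([u, r, np.cross(u, r)])
        rot = frame @ self.frame0.T
        return self.coords @ rot.T + np.asarray(centroid, float)


def _helix_pair(p: np.ndarray, n: np.ndarray, t1: np.ndarray,
                angle: float, displacement: float,
                template: _HelixTemplate) -> list[tuple[np.ndarray, np.ndarray]]:
    """Two helices related by the dyad along ``n`` through ``p``.

    Each helix direction is tilted ``angle/2`` from the dyad in the
    (n, t1) plane, so the directed crossing angle is exactly ``angle``;
    the centroids sit ``displacement/2`` either side of ``p`` along
    n x t1, so the centroid distance is exactly ``displacement``.
    Returns [(coords, direction), ...] for the +t1 and -t1 tilts.
    """
    half = np.radians(angle) / 2.0
    t2 = np.cross(n, t1)
    out = []
    for sgn in (+1.0, -1.0):
        u = np.cos(half) * n + sgn * np.sin(half) * t1
        u = _unit(u)
        c = p + sgn * (displacement / 2.0) * t2
        roll = t1 if abs(np.dot(n, u)) > 1 - 1e-9 else n
        out.append((template.place(c, u, roll), u))
    return out


def make_two_helix_fixture(angle: float, displacement: float,
                           residues: tuple[int, int] = (186, 201)
                           ) -> StructureModel:
    """Two-chain fixture with exact crossing angle and centroid displacement.

    Chain A and chain B marker helices recover exactly (angle,
    displacement) under the half-centroid parameterisation.
    """
    if not 0.0 <= angle <= 180.0:
        raise ParameterError("angle must be in [0, 180] degrees")
    if displacement < 0:
        raise ParameterError("displacement must be >= 0")
    template = _HelixTemplate(residues)
    n = np.array([0.0, 0.0, 1.0])
    t1 = np.array([1.0, 0.0, 0.0])
    pair = _helix_pair(np.zeros(3), n, t1, angle, displacement, template)
    atoms = []
    serial = 1
    for cid, (coords, _u) in zip("AB", pair):
        for k, pos in enumerate(coords):
            atoms.append(Atom(serial=serial, name=template.names[k],
                              element=template.elements[k], alt_loc="",
                              res_name="ALA", res_seq=template.res_seqs[k],
                              chain_id=cid, model_num=1, position=tuple(pos)))
            serial += 1
    return StructureModel(atoms, title=f"two-helix fixture {angle} deg {displacement} A")


# -- toy monomers and rings -------------------------------------------------

_NTD_BLOB_RES = (10, 20, 30, 40, 50)
_CTD_BLOB_RES = (158, 160, 162, 164, 166)


def _member_body(chain_id: str, c_hat: np.ndarray, radius: float, w: np.ndarray,
                 w_next: np.ndarray, layer_separation: float, fold: int,
                 serial_start: int) -> list[Atom]:
    """Blob + diagnostic atoms for one ring member.

    ``w``/``w_next`` are the azimuthal unit vectors of this member and its
    ring neighbour.  The NTD-CTD hydrogen-bond fingerprint is built in the
    conformer state matching the ring fold: pentamer rings pair R143 with
    the K182 carbonyl and close K229-D90', hexamer rings pair R143 with
    the Q181 side chain and open K229-D90'.
    """
    tT = np.cross(c_hat, w)
    tT_next = np.cross(c_hat, w_next)
    q_ntd = radius * c_hat + _BLOB_RHO * w
    q_ctd = (radius - layer_separation) * c_hat + _BLOB_RHO * w
    q_ntd_next = radius * c_hat + _BLOB_RHO * w_next

    pentamer_state = fold == 5
    d_k182 = 2.9 if pentamer_state else 6.0
    d_q181 = 6.0 if pentamer_state else 2.9
    d_k229 = 2.9 if pentamer_state else 8.0

    spread = (-2.5, -1.25, 0.0, 1.25, 2.5)
    lift = (0.0, 0.5, 1.0, 0.5, 0.0)
    r143 = q_ntd + 2.0 * w - 1.0 * c_hat
    s79_next = q_ntd_next + 1.8 * tT_next + 0.5 * c_hat
    d90_next = q_ntd_next - 1.8 * tT_next + 1.0 * c_hat
    diag = _unit(w + tT)

    spec: list[tuple[str, str, str, int, np.ndarray]] = []
    for res, s, h in zip(_NTD_BLOB_RES, spread, lift):
        spec.append(("CA", "C", "GLY", res, q_ntd + s * tT + h * c_hat))
    spec.append(("OG", "O", "SER", 79, q_ntd + 1.8 * tT + 0.5 * c_hat))
    spec.append(("OD1", "O", "ASP", 90, q_ntd - 1.8 * tT + 1.0 * c_hat))
    spec.append(("NH1", "N", "ARG", 143, r143))
    for res, s, h in zip(_CTD_BLOB_RES, spread, lift):
        spec.append(("CA", "C", "GLY", res, q_ctd + s * tT + h * c_hat))
    spec.append(("OD1", "O", "ASP", 171, s79_next + 2.9 * c_hat))
    spec.append(("OE1", "O", "GLN", 181, r143 + d_q181 * diag))
    spec.append(("O", "O", "LYS", 182, r143 + d_k182 * w))
    spec.append(("NZ", "N", "LYS", 229, d90_next + d_k229 * c_hat))

    atoms = []
    for i, (name, element, res_name, res_seq, pos) in enumerate(spec):
        atoms.append(Atom(serial=serial_start + i, name=name, element=element,
                          alt_loc="", res_name=res_name, res_seq=res_seq,
                          chain_id=chain_id, model_num=1, position=tuple(pos)))
    return atoms


def _helix_atoms(chain_id: str, coords: np.ndarray, template: _HelixTemplate,
                 serial_start: int) -> list[Atom]:
    return [Atom(serial=serial_start + k, name=template.names[k],
                 element=template.elements[k], alt_loc="", res_name="ALA",
                 res_seq=template.res_seqs[k], chain_id=chain_id, model_num=1,
                 position=tuple(pos))
            for k, pos in enumerate(coords)]


def make_toy_ring(fold: int = 5, radius: float = 86.3,
                  layer_separation: float = 21.6,
                  axis=(0.0, 0.0, 1.0),
                  helix_residues: tuple[int, int] = (186, 201)) -> StructureModel:
    """One isolated pentamer/hexamer ring of toy monomers.

    Members sit at even azimuths about ``axis``; the pooled NTD and CTD
    mass-weighted centres of mass are calibrated to lie exactly at
    ``radius`` and ``radius - layer_separation`` along the axis, so layer
    metrics recover the construction values exactly.  Each member carries
    a tangential marker helix so interface code can consume the chains.
    """
    if fold not in (5, 6):
        raise ParameterError("fold must be 5 or 6")
    c_hat = _unit(np.asarray(axis, float))
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, c_hat)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = _unit(ref - np.dot(ref, c_hat) * c_hat)
    e2 = np.cross(c_hat, e1)
    template = _HelixTemplate(helix_residues)

    atoms: list[Atom] = []
    serial = 1
    for k in range(fold):
        az = 2 * np.pi * k / fold
        az_next = 2 * np.pi * ((k + 1) % fold) / fold
        w = np.cos(az) * e1 + np.sin(az) * e2
        w_next = np.cos(az_next) * e1 + np.sin(az_next) * e2
        cid = f"{_RING_CHARS[k]}"
        body = _member_body(cid, c_hat, radius, w, w_next, layer_separation,
                            fold, serial)
        serial += len(body)
        hx = template.place((radius - layer_separation) * c_hat
                            + (_BLOB_RHO + 4.0) * w,
                            np.cross(c_hat, w), c_hat)
        helix = _helix_atoms(cid, hx, template, serial)
        serial += len(helix)
        atoms.extend(body + helix)

    model = StructureModel(atoms, title=f"toy {fold}-fold ring")
    # Calibrate the pooled per-domain CoMs onto the construction values.
    # The NTD shift carries the four CTD diagnostic atoms with it (their
    # positions are defined relative to NTD reference atoms); the CTD CoM
    # is then restored exactly through the CTD blob CAs alone, so the
    # hydrogen-bond fingerprint distances stay at their built values.
    scheme = DomainScheme(helices={"alpha8": helix_residues})
    coords = model.coords()
    masses = np.array([atomic_mass(a.element) for a in model.atoms])

    def com_of(idx):
        return (coords[idx] * masses[idx, None]).sum(axis=0) / masses[idx].sum()

    ntd_idx = [i for i, a in enumerate(model.atoms)
               if scheme.ntd[0] <= a.res_seq <= scheme.ntd[1]]
    ctd_idx = [i for i, a in enumerate(model.atoms)
               if scheme.ctd[0] <= a.res_seq <= scheme.ctd[1]]
    fp_idx = [i for i in ctd_idx if model.atoms[i].res_seq in (171, 181, 182, 229)]
    blob_idx = [i for i in ctd_idx if model.atoms[i].res_seq in _CTD_BLOB_RES]

    delta_n = radius * c_hat - com_of(ntd_idx)
    coords[ntd_idx] += delta_n
    coords[fp_idx] += delta_n
    target_c = (radius - layer_separation) * c_hat
    coords[blob_idx] += (target_c - com_of(ctd_idx)) * (
        masses[ctd_idx].sum() / masses[blob_idx].sum())
    return model.with_coords(coords)


def make_toy_monomer(conformation: str = "pentamer", chain_id: str = "A",
                     origin=(0.0, 0.0, 0.0)) -> StructureModel:
    """A standalone two-domain toy monomer (NTD blob+helix, CTD blob+helix).

    ``conformation`` ("pentamer" or "hexamer") selects the intra-monomer
    R143 pairing (K182 main chain vs Q181 side chain).  The monomer passes
    the default domain-scheme selections and is suitable for NTD-aligned
    domain-motion comparisons.
    """
    if conformation not in ("pentamer", "hexamer"):
        raise ParameterError("conformation must be 'pentamer' or 'hexamer'")
    fold = 5 if conformation == "pentamer" else 6
    origin = np.asarray(origin, float)
    z = np.array([0.0, 0.0, 1.0])
    x = np.array([1.0, 0.0, 0.0])
    y = np.array([0.0, 1.0, 0.0])
    body = _member_body(chain_id, c_hat=z, radius=0.0, w=x, w_next=y,
                        layer_separation=21.6, fold=fold, serial_start=1)
    serial = len(body) + 1
    ntd_helix = make_ideal_helix(16, start_res=30, chain_id=chain_id,
                                 axis=z, origin=origin + np.array([0, -6.0, 4.0]),
                                 serial_start=serial)
    serial += ntd_helix.n_atoms
    ctd_helix = make_ideal_helix(16, start_res=186, chain_id=chain_id,
                                 axis=x, origin=origin + np.array([6.0, 0, -21.6]),
                                 serial_start=serial)
    shifted = [Atom(**{**a.__dict__, "position": tuple(np.asarray(a.position) + origin)})
               for a in body]
    return StructureModel(shifted + ntd_helix.atoms + ctd_helix.atoms,
                          title=f"toy monomer ({conformation})")


# -- shell layouts ----------------------------------------------------------


def _ico_vertices() -> np.ndarray:
    pts = []
    for a, b in [(1.0, PHI), (1.0, -PHI), (-1.0, PHI), (-1.0, -PHI)]:
        pts.append((0.0, a, b))
        pts.append((b, 0.0, a))
        pts.append((a, b, 0.0))
    return np.array([p / np.linalg.norm(p) for p in np.array(pts)])


def _ico_faces() -> np.ndarray:
    pts = [(sx, sy, sz) for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)]
    for a, b in [(PHI, 1 / PHI), (PHI, -1 / PHI), (-PHI, 1 / PHI), (-PHI, -1 / PHI)]:
        pts.append((0.0, a, b))
        pts.append((b, 0.0, a))
        pts.append((a, b, 0.0))
    return np.array([p / np.linalg.norm(p) for p in np.array(pts, dtype=float)])


def _adjacent_pairs(dirs_a: np.ndarray, dirs_b: np.ndarray | None = None):
    """Index pairs whose angular separation equals the minimum (1e-6 tol)."""
    same = dirs_b is None
    if same:
        dirs_b = dirs_a
    dots = dirs_a @ dirs_b.T
    if same:
        np.fill_diagonal(dots, -2.0)
    best = dots.max()
    out = []
    for i in range(len(dirs_a)):
        for j in range(len(dirs_b)):
            if same and j <= i:
                continue
            if dots[i, j] > best - 1e-6:
                out.append((i, j))
    return out


def _sph(theta_deg: float, az_deg: float) -> np.ndarray:
    t, p = np.radians(theta_deg), np.radians(az_deg)
    return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])


def _shell_layout(recipe: ShellRecipe):
    """Ring directions/folds/radii and the inter-ring contact list.

    Returns (symmetry name, ring dicts, edge index pairs).  Ring order and
    edge lists are deterministic.
    """
    rp, rh = recipe.pentamer_radius, recipe.hexamer_radius
    cls = recipe.shell_class
    rings: list[dict] = []
    edges: list[tuple[int, int]] = []

    def add(direction, fold):
        rings.append({"dir": _unit(direction),
                      "fold": fold,
                      "radius": rp if fold == 5 else rh})
        return len(rings) - 1

    if cls in ("T1", "T3"):
        verts = _ico_vertices()
        vi = [add(v, 5) for v in verts]
        edges += [(vi[i], vi[j]) for i, j in _adjacent_pairs(verts)] if cls == "T1" else []
        if cls == "T3":
            faces = _ico_faces()
            fi = [add(f, 6) for f in faces]
            edges += [(vi[i], fi[j]) for i, j in _adjacent_pairs(verts, faces)]
            edges += [(fi[i], fi[j]) for i, j in _adjacent_pairs(faces)]
        return "I", rings, edges

    theta_u = np.degrees(np.arccos(1 / np.sqrt(5)))  # icosahedral cap latitude
    if cls == "D5":
        top = add(_sph(0, 0), 5)
        bot = add(_sph(180, 0), 5)
        # azimuths chosen so the dihedral two-folds lie along the standard
        # D5 setting (one two-fold on +x): equatorial hexamers on the dyads
        u = [add(_sph(theta_u, 72 * k - 18), 5) for k in range(5)]
        l = [add(_sph(180 - theta_u, 72 * k + 18), 5) for k in range(5)]
        m = [add(_sph(90, 72 * k), 6) for k in range(5)]
        for k in range(5):
            edges.append((top, u[k]))
            edges.append((bot, l[k]))
            edges.append((u[k], u[(k + 1) % 5]))
            edges.append((l[k], l[(k + 1) % 5]))
            edges.append((m[k], u[k]))
            edges.append((m[k], u[(k + 1) % 5]))
            edges.append((m[k], l[k]))
            edges.append((m[k], l[(k - 1) % 5]))
            edges.append((m[k], m[(k + 1) % 5]))
        return "D5", rings, edges

    # D6 capsule: hexamer poles ringed by six pentamers, six equatorial hexamers
    top = add(_sph(0, 0), 6)
    bot = add(_sph(180, 0), 6)
    u = [add(_sph(60, 60 * k - 15), 5) for k in range(6)]
    l = [add(_sph(120, 60 * k + 15), 5) for k in range(6)]
    m = [add(_sph(90, 60 * k), 6) for k in range(6)]
    for k in range(6):
        edges.append((top, u[k]))
        edges.append((bot, l[k]))
        edges.append((u[k], u[(k + 1) % 6]))
        edges.append((l[k], l[(k + 1) % 6]))
        edges.append((m[k], u[k]))
        edges.append((m[k], u[(k + 1) % 6]))
        edges.append((m[k], l[k]))
        edges.append((m[k], l[(k - 1) % 6]))
        edges.append((m[k], m[(k + 1) % 6]))
    return "D6", rings, edges


def _interface_kind(fold_a: int, fold_b: int) -> str:
    names = {5: "pentamer", 6: "hexamer"}
    a, b = sorted((fold_a, fold_b))
    return f"{names[a]}-{names[b]}"


def _capsule_topology(ring_a: dict, ring_b: dict) -> str:
    """POLAR / LONG / LAT tag from ring latitudes and contact direction."""
    z = np.array([0.0, 0.0, 1.0])
    polar_band = np.sin(np.radians(20.0))
    la, lb = abs(ring_a["dir"] @ z), abs(ring_b["dir"] @ z)
    if la > polar_band and lb > polar_band:
        return "POLAR"
    contact = ring_b["dir"] * ring_b["radius"] - ring_a["dir"] * ring_a["radius"]
    frac = abs(contact @ z) / np.linalg.norm(contact)
    return "LONG" if frac > np.cos(np.radians(45.0)) else "LAT"


def make_shell(recipe: ShellRecipe) -> tuple[StructureModel, GroundTruthManifest]:
    """Build a complete synthetic shell plus its ground-truth manifest.

    Each chain occupies exactly one inter-ring dimer slot, so the chain
    count equals the fullerene census of the class and the interface
    count is half the chain count.
    """
    symmetry, rings, edges = _shell_layout(recipe)
    template = _HelixTemplate(recipe.helix_residues)
    sep = recipe.layer_separation

    # per-edge dyad frames and exact helix pairs
    edge_data = []
    for (i, j) in edges:
        ri, rj = rings[i], rings[j]
        n = _unit(ri["dir"] + rj["dir"])
        t1 = _unit(rj["dir"] - ri["dir"])
        kind = _interface_kind(ri["fold"], rj["fold"])
        angle, disp = recipe.interface_targets[kind]
        rc = (ri["radius"] + rj["radius"]) / 2.0 - sep
        p = rc * n
        pair = _helix_pair(p, n, t1, angle, disp, template)
        t2 = np.cross(n, t1)
        edge_data.append({"i": i, "j": j, "p": p, "t2": t2, "kind": kind,
                          "angle": angle, "disp": disp, "pair": pair})

    # slot assignment: one member per (ring, incident edge)
    incident: list[list[int]] = [[] for _ in rings]
    for e_idx, (i, j) in enumerate(edges):
        incident[i].append(e_idx)
        incident[j].append(e_idx)
    for r_idx, inc in enumerate(incident):
        if len(inc) != rings[r_idx]["fold"]:
            raise ParameterError(
                f"ring {r_idx}: {len(inc)} contacts != fold {rings[r_idx]['fold']}")

    atoms: list[Atom] = []
    ring_entries = []
    chain_of_slot: dict[tuple[int, int], str] = {}
    serial = 1
    ring_atom_slices: list[list[int]] = []
    body_atom_slices: list[list[int]] = []

    for r_idx, ring in enumerate(rings):
        c_hat = ring["dir"]
        # azimuthal direction of each incident contact about the ring axis
        members = []
        for e_idx in incident[r_idx]:
            p = edge_data[e_idx]["p"]
            w = _unit(p - np.dot(p, c_hat) * c_hat)
            members.append((e_idx, w))
        ref = members[0][1]
        e2 = np.cross(c_hat, ref)
        members.sort(key=lambda ew: np.arctan2(np.dot(ew[1], e2), np.dot(ew[1], ref)))

        ring_label = _RING_CHARS[r_idx]
        chain_ids = []
        ring_idx_list: list[int] = []
        body_idx_list: list[int] = []
        for k, (e_idx, w) in enumerate(members):
            cid = f"{ring_label}{k}"
            chain_ids.append(cid)
            chain_of_slot[(r_idx, e_idx)] = cid
            w_next = members[(k + 1) % len(members)][1]
            body = _member_body(cid, c_hat, ring["radius"], w, w_next, sep,
                                ring["fold"], serial)
            serial += len(body)
            ed = edge_data[e_idx]
            side = 0 if ed["i"] == r_idx else 1  # +t1 tilt faces the other ring
            coords, _u = ed["pair"][side]
            helix = _helix_atoms(cid, coords, template, serial)
            serial += len(helix)
            sgn = +1.0 if side == 0 else -1.0
            anchor = Atom(serial=serial, name="CA", element="C", alt_loc="",
                          res_name="GLY", res_seq=210, chain_id=cid, model_num=1,
                          position=tuple(ed["p"] + sgn * _unit(ed["t2"])))
            serial += 1
            start = len(atoms)
            atoms.extend(body + helix + [anchor])
            ring_idx_list.extend(range(start, len(atoms)))
            body_idx_list.extend(range(start, start + len(body)))
        ring_atom_slices.append(ring_idx_list)
        body_atom_slices.append(body_idx_list)
        ring_entries.append({
            "ring": ring_label, "fold": ring["fold"],
            "axis": [float(x) for x in c_hat],
            "centroid": [float(x) for x in ring["radius"] * c_hat],
            "radius": float(ring["radius"]),
            "chains": chain_ids,
        })

    model = StructureModel(atoms, title=f"synthetic {recipe.shell_class} shell")

    # ballast: shift each ring's blob/diagnostic atoms so the ring's
    # mass-weighted CoM lands exactly on the recipe radius
    coords = model.coords()
    masses = np.array([atomic_mass(a.element) for a in model.atoms])
    for r_idx, ring in enumerate(rings):
        all_idx = ring_atom_slices[r_idx]
        body_idx = body_atom_slices[r_idx]
        m_all = masses[all_idx].sum()
        m_body = masses[body_idx].sum()
        com = (coords[all_idx] * masses[all_idx, None]).sum(axis=0) / m_all
        target = ring["radius"] * rings[r_idx]["dir"]
        coords[body_idx] += (target - com) * (m_all / m_body)
    if recipe.noise_sigma > 0:
        rng = np.random.default_rng(recipe.seed)
        coords = coords + rng.normal(0.0, recipe.noise_sigma, coords.shape)
    model = model.with_coords(coords)

    interface_entries = []
    for e_idx, ed in enumerate(edge_data):
        i, j = ed["i"], ed["j"]
        entry = {
            "chain_a": chain_of_slot[(i, e_idx)],
            "chain_b": chain_of_slot[(j, e_idx)],
            "ring_a": ring_entries[i]["ring"],
            "ring_b": ring_entries[j]["ring"],
            "kind": ed["kind"],
            "angle": float(ed["angle"]),
            "displacement": float(ed["disp"]),
            "topology": _capsule_topology(rings[i], rings[j])
            if symmetry.startswith("D") else "",
        }
        interface_entries.append(entry)
    interface_entries.sort(key=lambda d: (d["ring_a"], d["ring_b"], d["chain_a"]))

    manifest = GroundTruthManifest(
        shell_class=recipe.shell_class,
        symmetry=symmetry,
        rings=ring_entries,
        interfaces=interface_entries,
        parameters={
            "pentamer_radius": recipe.pentamer_radius,
            "hexamer_radius": recipe.hexamer_radius,
            "layer_separation": recipe.layer_separation,
            "interface_targets": {k: list(v) for k, v in
                                  recipe.interface_targets.items()},
            "helix_residues": list(recipe.helix_residues),
            "seed": recipe.seed,
            "noise_sigma": recipe.noise_sigma,
        },
    )
    return model, manifest
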