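"""Core rigid-body geometry for interface and layer analysis.

The helix-vector parameterisation follows the published interface-analysis
recipe: the centroid of a helix is the unweighted mean of its backbone
(N, CA, C) atom positions, and the directed axis estimate runs from the
centroid of the first half of the residue interval to the centroid of the
second half (odd residue counts give the extra residue to the first half).
Crossing angles are the arccos of the normalised dot product of the two
directed vectors, reported in degrees over [0, 180]; displacements are
whole-helix centroid distances.

Superposition is least-squares (Kabsch, reflection-corrected); layer
metrics use mass-weighted centres of mass over heavy atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateGeometryError,
    EmptySelectionError,
    HelixTooShortError,
    IncompleteBackboneError,
    ParameterError,
)
from .pointgroup import RotationOperator, rotation_angle_axis
from .structure import DomainScheme, StructureModel

__all__ = [
    "HelixVector",
    "SuperpositionResult",
    "LayerMetrics",
    "PairGeometry",
    "helix_vector",
    "crossing_angle",
    "centroid_displacement",
    "superpose",
    "relative_domain_motion",
    "layer_metrics",
    "atomic_mass",
]

BACKBONE = ("N", "CA", "C")


@dataclass(frozen=True)
class HelixVector:
    """Directed axis estimate of one helix (half-centroid construction)."""

    start: np.ndarray      # first-half backbone centroid, A
    end: np.ndarray        # second-half backbone centroid, A
    centroid: np.ndarray   # whole-helix backbone centroid, A
    direction: np.ndarray  # unit, N-terminus -> C-terminus
    source: tuple[str, tuple[int, int]] = ("", (0, 0))

    @property
    def vector(self) -> np.ndarray:
        return self.end - self.start


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: RotationOperator
    translation: np.ndarray
    rmsd: float
    n_pairs: int
    rotation_angle: float  # degrees
    rotation_axis: np.ndarray

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, float) @ self.rotation.matrix.T + self.translation


@dataclass(frozen=True)
class LayerMetrics:
    """Radial and axial geometry of the NTD and CTD layers of one ring."""

    ntd_com: np.ndarray
    ctd_com: np.ndarray
    ntd_radius: float
    ctd_radius: float
    vertical_displacement: float
    axis: np.ndarray
    centre: np.ndarray


@dataclass(frozen=True)
class PairGeometry:
    """Crossing angle / displacement parameterisation of one CTD-CTD dimer."""

    crossing_angle: float  # degrees, [0, 180]
    displacement: float    # A between whole-helix centroids
    members: tuple = ()
    kind: str = ""         # pentamer-pentamer / pentamer-hexamer / hexamer-hexamer
    topology: str = ""     # POLAR / LONG / LAT for capsules, "" otherwise


# -- helix vectors ----------------------------------------------------------


def helix_vector(helix_atoms: StructureModel,
                 residue_interval: tuple[int, int] | None = None) -> HelixVector:
    """Directed axis of a helix from half-interval backbone centroids.

    ``helix_atoms`` must contain one chain's worth of residues; every
    residue of the interval needs N, CA and C atoms and the interval must
    hold at least 4 residues.
    """
    atoms = [a for a in helix_atoms.atoms if a.name in BACKBONE and not a.is_water]
    if residue_interval is not None:
        lo, hi = residue_interval
        atoms = [a for a in atoms if lo <= a.res_seq <= hi]
    if not atoms:
        raise EmptySelectionError("no backbone atoms in the helix interval")
    chains = {a.chain_id for a in atoms}
    if len(chains) > 1:
        raise ParameterError(f"helix interval spans several chains: {sorted(chains)}")
    chain = chains.pop()

    by_res: dict[int, dict[str, np.ndarray]] = {}
    for a in atoms:
        by_res.setdefault(a.res_seq, {})[a.name] = np.asarray(a.position)
    res_seqs = sorted(by_res)
    if len(res_seqs) < 4:
        raise HelixTooShortError(
            f"helix needs >= 4 residues, got {len(res_seqs)} in chain {chain}"
        )
    missing = [r for r in res_seqs if set(by_res[r]) != set(BACKBONE)]
    if missing:
        raise IncompleteBackboneError(
            f"chain {chain}: residues {missing} lack complete N/CA/C backbone"
        )

    stacked = np.array([by_res[r][n] for r in res_seqs for n in BACKBONE])
    centroid = stacked.mean(axis=0)
    m = len(res_seqs)
    first = res_seqs[: (m + 1) // 2]
    second = res_seqs[(m + 1) // 2:]
    start = np.array([by_res[r][n] for r in first for n in BACKBONE]).mean(axis=0)
    end = np.array([by_res[r][n] for r in second for n in BACKBONE]).mean(axis=0)
    v = end - start
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise DegenerateGeometryError("helix half-centroids coincide")
    interval = (res_seqs[0], res_seqs[-1])
    return HelixVector(start=start, end=end, centroid=centroid,
                       direction=v / norm, source=(chain, interval))


def crossing_angle(a: HelixVector, b: HelixVector) -> float:
    """Angle (degrees, [0, 180]) between the two directed helix vectors.

    Directed N->C vectors are used deliberately: interface families near
    95 degrees would alias onto 85 under an undirected [0, 90] convention.
    """
    va, vb = a.vector, b.vector
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na < 1e-9 or nb < 1e-9:
        raise DegenerateGeometryError("zero-length helix vector")
    cosang = np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def centroid_displacement(a: HelixVector, b: HelixVector) -> float:
    """Distance (A) between the whole-helix backbone centroids."""
    return float(np.linalg.norm(a.centroid - b.centroid))


# -- superposition ----------------------------------------------------------


def superpose(fixed: np.ndarray, moving: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Kabsch with reflection correction; inputs are equal-length paired
    coordinate lists with at least 3 non-collinear points.  The returned
    transform acts as ``x -> R x + t``.
    """
    fixed = np.asarray(fixed, dtype=float).reshape(-1, 3)
    moving = np.asarray(moving, dtype=float).reshape(-1, 3)
    if fixed.shape != moving.shape:
        raise ParameterError(f"paired coordinate shapes differ: {fixed.shape} vs {moving.shape}")
    n = len(fixed)
    if n < 3:
        raise DegenerateGeometryError(f"superposition needs >= 3 points, got {n}")
    cf, cm = fixed.mean(axis=0), moving.mean(axis=0)
    x, y = moving - cm, fixed - cf
    if np.linalg.matrix_rank(np.vstack([x, y]), tol=1e-8) < 2:
        raise DegenerateGeometryError("collinear points cannot fix a rotation")
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = cf - rot @ cm
    moved = moving @ rot.T + t
    rmsd = float(np.sqrt(((moved - fixed) ** 2).sum() / n))
    angle, axis = rotation_angle_axis(rot)
    return SuperpositionResult(
        rotation=RotationOperator(rot, label="superposition"),
        translation=t, rmsd=rmsd, n_pairs=n,
        rotation_angle=angle, rotation_axis=axis,
    )


def _paired_coords(ref: StructureModel, other: StructureModel,
                   interval: tuple[int, int],
                   atom_names: tuple[str, ...] | None) -> tuple[np.ndarray, np.ndarray]:
    def table(m):
        out = {}
        for a in m.atoms:
            if a.is_hydrogen or a.is_water:
                continue
            if interval[0] <= a.res_seq <= interval[1]:
                if atom_names is None or a.name in atom_names:
                    out[(a.res_seq, a.name)] = np.asarray(a.position)
        return out

    ta, tb = table(ref), table(other)
    keys = sorted(set(ta) & set(tb))
    if not keys:
        raise EmptySelectionError(f"no paired atoms in residue interval {interval}")
    return (np.array([ta[k] for k in keys]), np.array([tb[k] for k in keys]))


def relative_domain_motion(ref_monomer: StructureModel,
                           other_monomer: StructureModel,
                           scheme: DomainScheme | None = None
                           ) -> tuple[float, float]:
    """CTD rotation and shift of ``other`` relative to ``ref`` after NTD alignment.

    The two monomers are superposed on NTD CA atoms (paired by residue
    number); in that NTD-aligned frame the CTD-on-CTD residual
    superposition gives the rotation angle (degrees) and the CTD centroid
    displacement gives the shift (A).  This is the pentamer-vs-hexamer
    conformer comparison: a hexamer-state CTD shows a rotation of roughly
    15 degrees and shifts of a few Angstrom.
    """
    scheme = scheme or DomainScheme()
    ref_ntd, oth_ntd = _paired_coords(ref_monomer, other_monomer, scheme.ntd, ("CA",))
    align = superpose(ref_ntd, oth_ntd)
    ref_ctd, oth_ctd = _paired_coords(ref_monomer, other_monomer, scheme.ctd, None)
    oth_ctd_aligned = align.apply(oth_ctd)
    shift = float(np.linalg.norm(oth_ctd_aligned.mean(axis=0) - ref_ctd.mean(axis=0)))
    residual = superpose(ref_ctd, oth_ctd_aligned)
    return residual.rotation_angle, shift


# -- layer metrics ----------------------------------------------------------

_MASS_FALLBACK = 12.011


def atomic_mass(element: str) -> float:
    """Standard atomic weight; unknown symbols default to carbon (warned)."""
    import gemmi

    el = gemmi.Element(element.capitalize() if element else "X")
    w = el.weight
    if el.name in ("X", "") or w <= 0:
        warnings.warn(f"unknown element {element!r}; using carbon mass")
        return _MASS_FALLBACK
    return float(w)


def _mass_com(model: StructureModel) -> np.ndarray:
    heavy = model.heavy()
    if not heavy.atoms:
        raise EmptySelectionError("no heavy atoms for centre of mass")
    masses = np.array([atomic_mass(a.element) for a in heavy.atoms])
    return (heavy.coords() * masses[:, None]).sum(axis=0) / masses.sum()


def layer_metrics(ring: StructureModel,
                  scheme: DomainScheme | None = None,
                  centre: np.ndarray | None = None,
                  axis: np.ndarray | None = None) -> LayerMetrics:
    """NTD/CTD centre-of-mass radii and axial separation for one ring.

    Centres of mass are mass-weighted over all heavy atoms of each domain
    selection pooled over every chain present; the vertical displacement
    is the separation of the two CoMs projected on the ring axis.
    """
    scheme = scheme or DomainScheme()
    centre = np.zeros(3) if centre is None else np.asarray(centre, float)
    axis = np.array([0.0, 0.0, 1.0]) if axis is None else np.asarray(axis, float)
    nrm = np.linalg.norm(axis)
    if nrm < 1e-9:
        raise DegenerateGeometryError("zero-length ring axis")
    axis = axis / nrm
    ntd_com = _mass_com(ring.select(residue_interval=scheme.ntd))
    ctd_com = _mass_com(ring.select(residue_interval=scheme.ctd))
    return LayerMetrics(
        ntd_com=ntd_com, ctd_com=ctd_com,
        ntd_radius=float(np.linalg.norm(ntd_com - centre)),
        ctd_radius=float(np.linalg.norm(ctd_com - centre)),
        vertical_displacement=float(abs(np.dot(ntd_com - ctd_com, axis))),
        axis=axis, centre=centre,
    )
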