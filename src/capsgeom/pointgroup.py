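"""Finite rotation point groups and symmetry expansion of assemblies.

Supported groups are the cyclic C_n, dihedral D_n and icosahedral I groups
that describe closed CA shells.  Conventions:

* C_n / D_n: principal axis along +z; for D_n one two-fold along +x.
* I: the "I2" (222) setting with two-fold axes along x, y and z, the frame
  used by the common single-particle reconstruction packages.  The 60
  elements are produced by closure of a five-fold about an icosahedron
  vertex direction (0, 1, phi) and the two-fold about z.

Operators are pure rotations about the origin; callers translate the
particle centre to the origin first.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import DialectError, ParameterError
from .structure import Atom, StructureModel

__all__ = [
    "RotationOperator",
    "PointGroup",
    "make_point_group",
    "expand_assembly",
    "symmetry_axes",
    "rotation_angle_axis",
    "export_operators",
]

PHI = (1.0 + np.sqrt(5.0)) / 2.0
_TOL = 1e-9


@dataclass(frozen=True)
class RotationOperator:
    """A proper rotation (3x3 orthonormal, det +1)."""

    matrix: np.ndarray
    label: str = ""

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (3, 3):
            raise ParameterError("rotation matrix must be 3x3")
        if not np.allclose(m.T @ m, np.eye(3), atol=_TOL):
            raise ParameterError(f"operator {self.label!r} is not orthonormal")
        if not np.isclose(np.linalg.det(m), 1.0, atol=_TOL):
            raise ParameterError(f"operator {self.label!r} is not proper (det != +1)")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.matrix.T


@dataclass(frozen=True)
class PointGroup:
    """Named finite rotation group as an ordered operator list.

    ``operators[0]`` is always the identity.  ``axes`` lists the distinct
    rotation axes as (unit direction, fold) pairs.
    """

    name: str
    operators: tuple[RotationOperator, ...]
    axes: tuple[tuple[np.ndarray, int], ...] = field(default_factory=tuple)

    @property
    def order(self) -> int:
        return len(self.operators)

    def contains(self, matrix: np.ndarray, tol: float = 1e-6) -> bool:
        return any(np.allclose(op.matrix, matrix, atol=tol) for op in self.operators)


def _axis_rotation(axis, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def rotation_angle_axis(matrix: np.ndarray) -> tuple[float, np.ndarray]:
    """Rotation angle (degrees, [0, 180]) and unit axis of a proper rotation.

    The axis comes from the antisymmetric part away from 180 degrees and
    from the +1 eigenvector at 180 degrees; its sign convention makes the
    largest-magnitude component positive, which resolves the antipodal
    ambiguity deterministically.
    """
    m = np.asarray(matrix, dtype=float)
    cos_t = np.clip((np.trace(m) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cos_t)))
    if angle < 1e-8:
        return 0.0, np.array([0.0, 0.0, 1.0])
    # the axis spans the null space of (M - I); this is stable at all
    # angles, unlike the antisymmetric part, which vanishes at 180 degrees
    axis = np.linalg.svd(m - np.eye(3))[2][-1]
    w = np.array([m[2, 1] - m[1, 2], m[0, 2] - m[2, 0], m[1, 0] - m[0, 1]])
    if np.linalg.norm(w) > 1e-6:
        if np.dot(axis, w) < 0:
            axis = -axis
    else:
        i = int(np.argmax(np.abs(axis)))
        if axis[i] < 0:
            axis = -axis
    return angle, axis / np.linalg.norm(axis)


def _close_group(generators: list[np.ndarray], max_order: int = 120) -> list[np.ndarray]:
    """All distinct products of the generators (brute-force closure)."""
    ops: list[np.ndarray] = [np.eye(3)]

    def known(m):
        return any(np.allclose(m, o, atol=1e-6) for o in ops)

    frontier = [g for g in generators if not known(g)]
    ops.extend(frontier)
    while frontier:
        new = []
        for f in frontier:
            for o in list(ops):
                for prod in (f @ o, o @ f):
                    if not known(prod):
                        ops.append(prod)
                        new.append(prod)
        frontier = new
        if len(ops) > max_order:
            raise ParameterError("group closure exceeded the expected order")
    return ops


def make_point_group(name: str) -> PointGroup:
    """Build C{n} (n>=2), D{n} (n>=2) or I with the documented settings."""
    m = re.fullmatch(r"([CD])(\d+)", name) if name != "I" else None
    if name == "I":
        g5 = _axis_rotation((0.0, 1.0, PHI), 2 * np.pi / 5)
        g2 = _axis_rotation((0.0, 0.0, 1.0), np.pi)
        mats = _close_group([g5, g2])
        if len(mats) != 60:
            raise ParameterError(f"icosahedral closure produced {len(mats)} operators")
    elif m:
        kind, n = m.group(1), int(m.group(2))
        if n < 2:
            raise ParameterError(f"{name}: fold must be >= 2")
        mats = [_axis_rotation((0, 0, 1), 2 * np.pi * k / n) for k in range(n)]
        if kind == "D":
            flip = _axis_rotation((1, 0, 0), np.pi)
            mats += [r @ flip for r in mats[:n]]
    else:
        raise ParameterError(f"unknown point group {name!r} (expected C<n>, D<n> or I)")

    ops = tuple(
        RotationOperator(mat, label=f"{name}.{i}") for i, mat in enumerate(mats)
    )
    group = PointGroup(name=name, operators=ops)
    axes = tuple(symmetry_axes(group))
    return PointGroup(name=name, operators=ops, axes=axes)


def symmetry_axes(group: PointGroup) -> list[tuple[np.ndarray, int]]:
    """Distinct rotation axes with their folds (antipodal axes merged).

    For I this yields 6 five-folds, 10 three-folds and 15 two-folds; for
    D_n the principal n-fold plus n two-folds; for C_n a single axis.
    """
    by_axis: list[tuple[np.ndarray, float]] = []  # (axis, min positive angle)
    for op in group.operators[1:]:
        angle, axis = rotation_angle_axis(op.matrix)
        if angle < 1e-8:
            continue
        for i, (a, best) in enumerate(by_axis):
            if np.allclose(a, axis, atol=1e-6) or np.allclose(a, -axis, atol=1e-6):
                by_axis[i] = (a, min(best, angle))
                break
        else:
            by_axis.append((axis, angle))
    out = []
    for axis, min_angle in by_axis:
        fold = int(round(360.0 / min_angle))
        out.append((axis, fold))
    out.sort(key=lambda t: (-t[1], -t[0][2], -t[0][1], -t[0][0]))
    return out


def expand_assembly(asu: StructureModel, group: PointGroup,
                    separator: str = ".") -> StructureModel:
    """Apply every group operator to the asymmetric unit.

    Each copy's chains get the suffix ``<separator><op index>``; the
    identity copy (index 0) preserves the input coordinates bitwise.
    Output atom count is ``len(asu) * group.order``.
    """
    atoms: list[Atom] = []
    for i, op in enumerate(group.operators):
        if i == 0:
            for a in asu.atoms:
                atoms.append(Atom(**{**a.__dict__, "chain_id": f"{a.chain_id}{separator}0"}))
            continue
        xyz = asu.coords() @ op.matrix.T
        for a, p in zip(asu.atoms, xyz):
            atoms.append(Atom(**{
                **a.__dict__,
                "chain_id": f"{a.chain_id}{separator}{i}",
                "position": (float(p[0]), float(p[1]), float(p[2])),
            }))
    if len({a.chain_id for a in atoms}) > 62 * group.order:
        raise DialectError("chain-ID namespace exhausted; write the result as mmCIF")
    return StructureModel(atoms, source_format=asu.source_format,
                          title=f"{asu.title} x {group.name}".strip())


def export_operators(group: PointGroup) -> str:
    """Plain-text 4x4 matrix list (Chimera/RELION style) for interoperability."""
    lines = [f"# point group {group.name}, {group.order} operators"]
    for i, op in enumerate(group.operators):
        lines.append(f"# operator {i} {op.label}")
        for r in range(3):
            row = op.matrix[r]
            lines.append(f"{row[0]: .12f} {row[1]: .12f} {row[2]: .12f}  0.000000000000")
        lines.append(" 0.000000000000  0.000000000000  0.000000000000  1.000000000000")
    return "\n".join(lines) + "\n"
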