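"""Pentamer/hexamer census of closed fullerene CA shells.

A closed shell built from pentameric and hexameric rings is a trivalent
polyhedron whose faces are pentagons and hexagons; Euler's formula
V - E + F = 2 then forces exactly twelve pentagons regardless of size.
Two families are covered:

* Caspar-Klug icosahedra indexed by (h, k): T = h^2 + hk + k^2, built from
  60T monomers as 12 pentamers and 10(T - 1) hexamers.
* Dihedral capsules: two icosahedron-like polar caps separated by
  equatorial rings of hexamers.  A five-fold capsule with r equatorial
  rings has 12 pentamers and 5r hexamers (D5 symmetry); a six-fold capsule
  has hexamers at both poles, a ring of six pentamers around each, and
  2 + 6r hexamers in total (D6 symmetry).  The experimentally observed
  capsules are the r = 1 members; other r are lattice extrapolations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError

__all__ = [
    "ShellComposition",
    "ShellValidity",
    "caspar_klug",
    "capsule_composition",
    "validate_shell",
]


@dataclass(frozen=True)
class ShellComposition:
    """Ring census of one closed shell class."""

    label: str
    T: int | None
    pentamers: int
    hexamers: int
    monomers: int
    symmetry: str
    handedness: int = 0  # sign(h - k) for chiral Caspar-Klug classes

    def __post_init__(self):
        if min(self.pentamers, self.hexamers, self.monomers) < 0:
            raise ParameterError("ring counts must be non-negative")
        if self.monomers != 5 * self.pentamers + 6 * self.hexamers:
            raise ParameterError(
                f"{self.label}: monomers {self.monomers} != "
                f"5*{self.pentamers} + 6*{self.hexamers}"
            )

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "T": self.T,
            "pentamers": self.pentamers,
            "hexamers": self.hexamers,
            "monomers": self.monomers,
            "symmetry": self.symmetry,
        }


@dataclass(frozen=True)
class ShellValidity:
    """Euler-formula report for a hypothetical (P, H) shell."""

    pentamers: int
    hexamers: int
    vertices: int | None
    edges: int | None
    faces: int
    valid: bool
    reason: str = ""


def caspar_klug(h: int, k: int) -> ShellComposition:
    """Composition of the (h, k) Caspar-Klug icosahedral class.

    T = h^2 + hk + k^2; the shell holds 60T monomers in 12 pentamers and
    10(T - 1) hexamers with icosahedral symmetry.  (h, k) and (k, h) are
    mirror-related and share a census; the handedness flag records the
    orientation without affecting any count.
    """
    h, k = int(h), int(k)
    if h < 0 or k < 0 or (h == 0 and k == 0):
        raise ParameterError("need integers h >= 1, k >= 0 (h = k = 0 is no lattice)")
    T = h * h + h * k + k * k
    hexamers = 10 * (T - 1)
    return ShellComposition(
        label=f"T{T}", T=T, pentamers=12, hexamers=hexamers,
        monomers=60 * T, symmetry="I",
        handedness=(h > k) - (h < k),
    )


def capsule_composition(pole: int, equatorial_rings: int) -> ShellComposition:
    """Composition of a dihedral capsule with ``equatorial_rings`` hexamer belts.

    ``pole=5``: icosahedron-like caps (a pentamer on each pole); each belt
    adds 5 hexamers / 30 monomers.  ``r=0`` degenerates to the T=1
    icosahedron and the symmetry label is elevated accordingly.

    ``pole=6``: a hexamer on each pole ringed by six pentamers; hexamers =
    2 + 6r, monomers = 60 + 6*hexamers.
    """
    r = int(equatorial_rings)
    if r < 0:
        raise ParameterError("equatorial_rings must be >= 0")
    if pole == 5:
        if r == 0:
            return ShellComposition(label="T1", T=1, pentamers=12, hexamers=0,
                                    monomers=60, symmetry="I")
        hexamers = 5 * r
        return ShellComposition(
            label=f"D5-capsule-r{r}", T=None, pentamers=12, hexamers=hexamers,
            monomers=60 + 30 * r, symmetry="D5",
        )
    if pole == 6:
        hexamers = 2 + 6 * r
        return ShellComposition(
            label=f"D6-capsule-r{r}", T=None, pentamers=12, hexamers=hexamers,
            monomers=5 * 12 + 6 * hexamers, symmetry="D6",
        )
    raise ParameterError(f"pole must be 5 or 6, got {pole!r}")


def validate_shell(pentamers: int, hexamers: int) -> ShellValidity:
    """Euler-formula check of a trivalent pentagon/hexagon polyhedron.

    F = P + H faces, E = (5P + 6H)/2 edges, V = (5P + 6H)/3 vertices;
    the shell closes iff E and V are integers and V - E + F = 2, which
    forces P = 12.  Invalidity is reported, never raised.
    """
    p, h = int(pentamers), int(hexamers)
    if p < 0 or h < 0:
        raise ParameterError("ring counts must be non-negative")
    slots = 5 * p + 6 * h
    faces = p + h
    if slots % 2 or slots % 3:
        return ShellValidity(p, h, None, None, faces, False,
                             reason="edge/vertex counts are not integral")
    edges = slots // 2
    vertices = slots // 3
    if vertices - edges + faces != 2:
        return ShellValidity(p, h, vertices, edges, faces, False,
                             reason=f"Euler characteristic {vertices - edges + faces} != 2")
    return ShellValidity(p, h, vertices, edges, faces, True)
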