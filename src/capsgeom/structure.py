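"""Atomic models: reading, selecting and writing PDB/mmCIF coordinates.

The in-memory representation is a flat, ordered list of :class:`Atom`
records tagged with model / chain / residue identifiers.  File parsing and
serialisation are delegated to gemmi; the flat list keeps downstream
geometry code simple and order-deterministic.

Residue numbering is 1-based and all intervals are inclusive on both ends.
The default :class:`DomainScheme` places the capsid protein's N-terminal
domain (NTD) at residues 1-153 and the C-terminal domain (CTD) at residues
154-246, with the CTD dimerisation helix alpha-8 (the marker helix used for
interface analysis) modelled at residues 186-201.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DialectError,
    EmptySelectionError,
    EmptyStructureError,
    ParameterError,
    ParseError,
)

__all__ = [
    "Atom",
    "StructureModel",
    "DomainScheme",
    "read_structure",
    "write_structure",
    "select",
]

#: residue names treated as solvent and excluded from geometric analyses
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: elements excluded from "heavy atom" computations
HYDROGEN_ELEMENTS = frozenset({"H", "D", "T"})


@dataclass(frozen=True)
class Atom:
    """One atom record.  Coordinates are Cartesian, in Angstrom."""

    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    res_seq: int
    chain_id: str
    model_num: int
    position: tuple[float, float, float]
    occupancy: float = 1.0
    b_iso: float = 0.0

    def __post_init__(self):
        if not all(np.isfinite(self.position)):
            raise ParameterError(f"non-finite position for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ParameterError(
                f"occupancy {self.occupancy} outside [0, 1] for atom {self.name}"
            )

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in HYDROGEN_ELEMENTS

    @property
    def is_water(self) -> bool:
        return self.res_name.upper() in WATER_NAMES


class StructureModel:
    """An ordered collection of atoms read from (or destined for) a file.

    Order is preserved exactly as given; two structures built from the same
    records compare equal atom-by-atom.
    """

    def __init__(self, atoms: Sequence[Atom], *, source_format: str = "memory",
                 title: str = ""):
        self.atoms: list[Atom] = list(atoms)
        self.source_format = source_format
        self.title = title

    # -- basic introspection ------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def model_nums(self) -> list[int]:
        seen: list[int] = []
        for a in self.atoms:
            if a.model_num not in seen:
                seen.append(a.model_num)
        return seen

    def chain_ids(self, model_num: int | None = None) -> list[str]:
        if model_num is None:
            nums = self.model_nums()
            model_num = nums[0] if nums else None
        seen: list[str] = []
        for a in self.atoms:
            if a.model_num == model_num and a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in file order."""
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def heavy(self) -> "StructureModel":
        """Non-hydrogen, non-water atoms (the default analysis set)."""
        kept = [a for a in self.atoms if not (a.is_hydrogen or a.is_water)]
        return StructureModel(kept, source_format=self.source_format, title=self.title)

    def with_coords(self, xyz: np.ndarray) -> "StructureModel":
        """Copy of the model with coordinates replaced row-for-row."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ParameterError(f"coordinate array shape {xyz.shape} != ({len(self.atoms)}, 3)")
        new = [replace(a, position=tuple(p)) for a, p in zip(self.atoms, xyz)]
        return StructureModel(new, source_format=self.source_format, title=self.title)

    def residues(self, chain_id: str, model_num: int | None = None):
        """Mapping res_seq -> {atom_name: Atom} for one chain."""
        if model_num is None:
            model_num = self.model_nums()[0]
        out: dict[int, dict[str, Atom]] = {}
        for a in self.atoms:
            if a.model_num == model_num and a.chain_id == chain_id:
                out.setdefault(a.res_seq, {})[a.name] = a
        return out

    # -- selection ----------------------------------------------------------

    def select(self, chain_ids: Iterable[str] | None = None,
               residue_interval: tuple[int, int] | None = None,
               atom_names: Iterable[str] | None = None,
               model_num: int | None = None,
               allow_empty: bool = False) -> "StructureModel":
        return select(self, chain_ids=chain_ids, residue_interval=residue_interval,
                      atom_names=atom_names, model_num=model_num,
                      allow_empty=allow_empty)


def select(model: StructureModel,
           chain_ids: Iterable[str] | None = None,
           residue_interval: tuple[int, int] | None = None,
           atom_names: Iterable[str] | None = None,
           model_num: int | None = None,
           allow_empty: bool = False) -> StructureModel:
    """Sub-structure matching every given filter (inclusive residue interval).

    Raises :class:`EmptySelectionError` when nothing matches, unless
    ``allow_empty`` is set; analysis paths always leave it off so that a
    mis-specified domain scheme fails loudly.
    """
    chains = set(chain_ids) if chain_ids is not None else None
    names = set(atom_names) if atom_names is not None else None
    lo, hi = residue_interval if residue_interval is not None else (None, None)
    kept = []
    for a in model.atoms:
        if chains is not None and a.chain_id not in chains:
            continue
        if lo is not None and not (lo <= a.res_seq <= hi):
            continue
        if names is not None and a.name not in names:
            continue
        if model_num is not None and a.model_num != model_num:
            continue
        kept.append(a)
    if not kept and not allow_empty:
        raise EmptySelectionError(
            f"selection matched no atoms (chains={chains}, residues={residue_interval}, "
            f"atoms={names}, model={model_num})"
        )
    return StructureModel(kept, source_format=model.source_format, title=model.title)


# -- domain scheme ---------------------------------------------------------


def _check_interval(name: str, iv: tuple[int, int]) -> tuple[int, int]:
    lo, hi = int(iv[0]), int(iv[1])
    if lo > hi:
        raise ParameterError(f"{name} interval {iv} is empty")
    return lo, hi


@dataclass(frozen=True)
class DomainScheme:
    """Residue intervals for the two CA domains and named helices.

    ``marker_helix`` names the helix used for CTD-CTD interface
    parameterisation (the dimerisation helix alpha-8 by default).
    """

    ntd: tuple[int, int] = (1, 153)
    ctd: tuple[int, int] = (154, 246)
    helices: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"alpha8": (186, 201), "alpha11": (237, 246)}
    )
    marker_helix: str = "alpha8"

    def __post_init__(self):
        ntd = _check_interval("NTD", self.ntd)
        ctd = _check_interval("CTD", self.ctd)
        if not (ntd[1] < ctd[0] or ctd[1] < ntd[0]):
            raise ParameterError(f"NTD {ntd} and CTD {ctd} overlap")
        for hname, iv in self.helices.items():
            lo, hi = _check_interval(hname, iv)
            in_ntd = ntd[0] <= lo and hi <= ntd[1]
            in_ctd = ctd[0] <= lo and hi <= ctd[1]
            if not (in_ntd or in_ctd):
                raise ParameterError(
                    f"helix {hname} {iv} does not lie inside exactly one domain"
                )
        if self.marker_helix not in self.helices:
            raise ParameterError(f"marker helix {self.marker_helix!r} not defined")

    @property
    def marker_interval(self) -> tuple[int, int]:
        return tuple(self.helices[self.marker_helix])

    def domain_of(self, res_seq: int) -> str | None:
        if self.ntd[0] <= res_seq <= self.ntd[1]:
            return "NTD"
        if self.ctd[0] <= res_seq <= self.ctd[1]:
            return "CTD"
        return None


# -- file I/O ---------------------------------------------------------------

_PDB_CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


def _dedup_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep the highest-occupancy conformer per atom site (ties: first seen)."""
    best: dict[tuple, int] = {}
    for i, a in enumerate(atoms):
        key = (a.model_num, a.chain_id, a.res_seq, a.res_name, a.name)
        j = best.get(key)
        if j is None or a.occupancy > atoms[j].occupancy:
            best[key] = i
    keep = sorted(best.values())
    return [atoms[i] for i in keep]


def read_structure(path: str | Path, format_hint: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Format is auto-detected from extension/content when no hint is given.
    Alternate-location duplicates are resolved to the highest-occupancy
    conformer so that downstream geometry is deterministic.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format_hint:
            fmt = {"pdb": gemmi.CoorFormat.Pdb, "cif": gemmi.CoorFormat.Mmcif,
                   "mmcif": gemmi.CoorFormat.Mmcif}.get(format_hint.lower())
            if fmt is None:
                raise ParameterError(f"unknown format hint {format_hint!r}")
            st = gemmi.read_structure(str(path), format=fmt)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc

    fmt_name = "pdb" if path.suffix.lower() in {".pdb", ".ent"} else "cif"
    atoms: list[Atom] = []
    for model in st:
        mnum = int(getattr(model, "num", 0) or 0) or 1
        for chain in model:
            for res in chain:
                for at in res:
                    alt = at.altloc if at.altloc not in ("\x00", "") else ""
                    occ = float(at.occ)
                    atoms.append(Atom(
                        serial=int(at.serial),
                        name=at.name,
                        element=at.element.name,
                        alt_loc=alt,
                        res_name=res.name,
                        res_seq=int(res.seqid.num),
                        chain_id=chain.name,
                        model_num=mnum,
                        position=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=min(max(occ, 0.0), 1.0),
                        b_iso=float(at.b_iso),
                    ))
    if not atoms:
        raise EmptyStructureError(f"{path}: no atoms parsed")
    atoms = _dedup_altlocs(atoms)
    return StructureModel(atoms, source_format=fmt_name, title=st.name or "")


def _to_gemmi(model: StructureModel, chain_map: Mapping[str, str] | None = None):
    import gemmi

    st = gemmi.Structure()
    st.name = model.title or "capsgeom model"
    cur_model = None
    cur_chain = None
    cur_res = None
    cur_key = (None, None, None)
    for a in model.atoms:
        cid = chain_map[a.chain_id] if chain_map else a.chain_id
        if cur_model is None or cur_key[0] != a.model_num:
            cur_model = gemmi.Model(a.model_num)
            st.add_model(cur_model)
            cur_chain = None
        if cur_chain is None or cur_key[:2] != (a.model_num, cid):
            cur_chain = gemmi.Chain(cid)
            st[-1].add_chain(cur_chain)
            cur_res = None
        if cur_res is None or cur_key != (a.model_num, cid, a.res_seq):
            cur_res = gemmi.Residue()
            cur_res.name = a.res_name
            cur_res.seqid = gemmi.SeqId(a.res_seq, " ")
            cur_res.het_flag = "A"
            st[-1][-1].add_residue(cur_res)
        ga = gemmi.Atom()
        ga.name = a.name
        ga.element = gemmi.Element(a.element)
        if a.alt_loc:
            ga.altloc = a.alt_loc
        ga.pos = gemmi.Position(*a.position)
        ga.occ = a.occupancy
        ga.b_iso = a.b_iso
        ga.serial = a.serial
        st[-1][-1][-1].add_atom(ga)
        cur_key = (a.model_num, cid, a.res_seq)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path,
                    format: str | None = None, strict: bool = False) -> None:
    """Write PDB or mmCIF (by ``format`` or file extension).

    PDB chain columns hold a single character; when a model has more chains
    than single characters (or multi-character IDs) the writer remaps chain
    IDs onto [A-Za-z0-9] for up to 62 chains and errors beyond that.  With
    ``strict=True`` any remapping or >99,999 atom serial raises a
    :class:`DialectError` advising mmCIF instead.
    """
    if not model.atoms:
        raise EmptySelectionError("refusing to write an empty model")
    path = Path(path)
    fmt = (format or ("pdb" if path.suffix.lower() in {".pdb", ".ent"} else "cif")).lower()
    if fmt not in {"pdb", "cif", "mmcif"}:
        raise ParameterError(f"unknown format {format!r}")

    chain_map = None
    if fmt == "pdb":
        cids = []
        for a in model.atoms:
            if a.chain_id not in cids:
                cids.append(a.chain_id)
        needs_remap = any(len(c) != 1 for c in cids)
        if len(model.atoms) > 99999 and strict:
            raise DialectError(">99,999 atoms cannot be written as strict PDB; use mmCIF")
        if needs_remap:
            if strict:
                raise DialectError(
                    "multi-character chain IDs cannot be written as strict PDB; use mmCIF"
                )
            if len(cids) > len(_PDB_CHAIN_ALPHABET):
                raise DialectError(
                    f"{len(cids)} chains exceed the PDB chain-ID namespace; use mmCIF"
                )
            chain_map = {c: _PDB_CHAIN_ALPHABET[i] for i, c in enumerate(cids)}
            warnings.warn("chain IDs remapped to single characters for PDB output")

    st = _to_gemmi(model, chain_map)
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        doc = st.make_mmcif_document()
        doc.write_file(str(path))
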