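"""Structure model: PDB input, chain selection and van der Waals radius assignment.

The internal model is deliberately small: an ordered list of heavy atoms with
author residue numbering, chain ids and an assigned radius.  All downstream
geometry (solvent-accessible surface area, contacts, pocket grids) works on
these atoms only — hydrogens, waters and heteroatoms are excluded at parse
time, matching the heavy-atom conventions of classical surface-area tools.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Atom",
    "Structure",
    "RadiusSet",
    "ParseError",
    "StructureError",
    "BACKBONE_ATOM_NAMES",
    "parse_structure",
    "strip_chains",
    "assign_radii",
    "write_pdb",
]

#: Protein backbone atom names.  Everything else is treated as side chain;
#: for glycine the CA takes the role of the (absent) side chain so that
#: glycine can still register side-chain contacts.
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class StructureError(ValueError):
    """Invalid structure content or operation."""


class ParseError(StructureError):
    """PDB input could not be parsed into a usable structure."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom with author numbering and an assigned radius."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""
    icode: str = ""
    radius: float | None = None  # Å, set by assign_radii

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.serial} {self.name}: bad position {self.position!r}")
        object.__setattr__(self, "position", pos)
        if self.radius is not None and not self.radius > 0:
            raise StructureError(f"atom {self.serial} {self.name}: radius must be > 0")

    @property
    def is_sidechain(self) -> bool:
        if self.residue_name == "GLY":
            return self.name == "CA" or self.name not in BACKBONE_ATOM_NAMES
        return self.name not in BACKBONE_ATOM_NAMES

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """Identity of the parent residue: (chain, author number, insertion code)."""
        return (self.chain_id, self.residue_number, self.icode)

    @property
    def residue_label(self) -> str:
        """Human-readable residue tag, e.g. ``TRP5`` (insertion code appended)."""
        return f"{self.residue_name}{self.residue_number}{self.icode.strip()}"


@dataclass
class Structure:
    """Ordered collection of atoms from one model of one entry."""

    atoms: list[Atom]
    source_id: str = ""
    model_index: int = 1

    def __post_init__(self) -> None:
        self.atoms = list(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def coords(self) -> np.ndarray:
        """(n, 3) array of positions in Å."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.position for a in self.atoms])

    def radii(self) -> np.ndarray:
        """(n,) array of assigned radii; raises if any atom is unassigned."""
        out = np.empty(len(self.atoms))
        for i, a in enumerate(self.atoms):
            if a.radius is None:
                raise StructureError(
                    f"atom {a.serial} {a.name} ({a.residue_label}) has no radius; "
                    "call assign_radii first"
                )
            out[i] = a.radius
        return out

    def residue_keys(self) -> list[tuple[str, int, str]]:
        return [a.residue_key for a in self.atoms]

    def select(self, indices: Sequence[int]) -> "Structure":
        """Sub-structure with the given atom indices (original order kept)."""
        idx = sorted(set(int(i) for i in indices))
        return Structure([self.atoms[i] for i in idx], self.source_id, self.model_index)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Structure":
        """Rigidly transformed copy (rotation applied before translation)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        atoms = [dataclasses.replace(a, position=R @ a.position + t) for a in self.atoms]
        return Structure(atoms, self.source_id, self.model_index)


# ---------------------------------------------------------------------------
# Radii

@dataclass
class RadiusSet:
    """Van der Waals radii, looked up by (residue, atom name) then element.

    The default set covers the heavy elements of standard amino acids
    (C 1.70, N 1.55, O 1.52, S 1.80 Å); a per-atom override table and a
    global default can be supplied, e.g. from a YAML config.
    """

    name: str = "default"
    by_atom: dict[tuple[str, str], float] = field(default_factory=dict)
    by_element: dict[str, float] = field(default_factory=dict)
    default: float | None = None

    REQUIRED_ELEMENTS = ("C", "N", "O", "S")

    def __post_init__(self) -> None:
        for value in list(self.by_atom.values()) + list(self.by_element.values()):
            if not (1.0 <= value <= 2.5):
                raise StructureError(f"radius {value} outside the plausible 1.0–2.5 Å range")

    @classmethod
    def from_defaults(cls) -> "RadiusSet":
        return cls(
            name="default",
            by_element={"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80},
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RadiusSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        by_atom = {
            (str(res).upper(), str(at).upper()): float(r)
            for key, r in (raw.get("by_atom") or {}).items()
            for res, at in [str(key).split("/", 1)]
        }
        by_element = {str(k).upper(): float(v) for k, v in (raw.get("by_element") or {}).items()}
        return cls(
            name=str(raw.get("name", Path(path).stem)),
            by_atom=by_atom,
            by_element=by_element,
            default=None if raw.get("default") is None else float(raw["default"]),
        )

    def lookup(self, atom: Atom) -> float:
        r = self.by_atom.get((atom.residue_name.upper(), atom.name.upper()))
        if r is None:
            r = self.by_element.get(atom.element.upper())
        if r is None:
            r = self.default
        if r is None:
            raise StructureError(
                f"no radius for atom {atom.serial} {atom.name} "
                f"({atom.residue_label}, element {atom.element!r}) in set {self.name!r}"
            )
        return float(r)


def assign_radii(s: Structure, radius_set: RadiusSet | None = None) -> Structure:
    """Return a copy of *s* with every atom's radius set from *radius_set*."""
    rs = radius_set or RadiusSet.from_defaults()
    atoms = [dataclasses.replace(a, radius=rs.lookup(a)) for a in s.atoms]
    return Structure(atoms, s.source_id, s.model_index)


# ---------------------------------------------------------------------------
# Parsing

def _read_gemmi(source: str | os.PathLike):
    import gemmi

    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        name = Path(source).stem
        try:
            st = gemmi.read_structure(str(source), format=gemmi.CoorFormat.Pdb)
        except (RuntimeError, ValueError) as exc:
            raise ParseError(f"{source}: {exc}") from exc
    else:
        name = "input"
        try:
            st = gemmi.read_pdb_string(str(source))
        except (RuntimeError, ValueError) as exc:
            raise ParseError(f"PDB text: {exc}") from exc
    return st, name


def parse_structure(
    source: str | os.PathLike,
    model_policy: str = "first",
    model_index: int | None = None,
    altloc_policy: str = "occupancy",
) -> Structure:
    """Read ATOM records of one model from PDB text or a PDB file.

    Hydrogens, waters and HETATM records are dropped.  Alternate locations
    are resolved to one atom per (residue, atom name): with the default
    ``occupancy`` policy the highest-occupancy conformer wins, ties broken
    by altloc letter.

    Parameters
    ----------
    source:
        Path to a PDB file, or PDB-format text.
    model_policy:
        ``"first"`` uses the first model (NMR ensembles collapse to model 1);
        ``"index"`` selects the model whose number equals *model_index*.
    """
    if altloc_policy != "occupancy":
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    st, name = _read_gemmi(source)
    if len(st) == 0:
        raise ParseError(f"{name}: no models in input")
    if model_policy == "first":
        model = st[0]
    elif model_policy == "index":
        matches = [m for m in st if m.num == model_index]
        if not matches:
            raise ParseError(f"{name}: model {model_index} not present")
        model = matches[0]
    else:
        raise ValueError(f"unknown model policy {model_policy!r}")

    atoms: list[Atom] = []
    best: dict[tuple, int] = {}  # (chain, resnum, icode, resname, atomname) -> index in atoms
    for chain in model:
        for res in chain:
            if res.het_flag != "A" or res.name in _WATER_NAMES:
                continue
            for a in res:
                if a.element.name in ("H", "D"):
                    continue
                icode = res.seqid.icode.strip()
                altloc = a.altloc if a.altloc and a.altloc != "\0" else ""
                atom = Atom(
                    serial=a.serial,
                    name=a.name,
                    element=a.element.name,
                    residue_name=res.name,
                    residue_number=res.seqid.num,
                    chain_id=chain.name,
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                    altloc=altloc,
                    icode=icode,
                )
                key = (chain.name, res.seqid.num, icode, res.name, a.name)
                if key in best:
                    j = best[key]
                    old = atoms[j]
                    if (atom.occupancy, _altloc_rank(atom.altloc)) > (
                        old.occupancy, _altloc_rank(old.altloc)
                    ):
                        atoms[j] = atom
                else:
                    best[key] = len(atoms)
                    atoms.append(atom)
    if not atoms:
        raise ParseError(f"{name}: no protein ATOM records found")
    return Structure(atoms, source_id=name, model_index=model.num)


def _altloc_rank(altloc: str) -> int:
    # higher rank wins on occupancy ties; blank < ... < B < A
    return -ord(altloc) if altloc else -1000


def strip_chains(s: Structure, drop: Iterable[str]) -> Structure:
    """Remove every atom whose chain is in *drop*; order is preserved."""
    drop = set(drop)
    unknown = drop - s.chains
    if unknown:
        raise StructureError(f"chains {sorted(unknown)} not in structure (has {sorted(s.chains)})")
    kept = [a for a in s.atoms if a.chain_id not in drop]
    if not kept:
        raise StructureError("stripping would leave an empty structure")
    return Structure(kept, s.source_id, s.model_index)


def write_pdb(s: Structure, path: str | os.PathLike) -> None:
    """Write the structure as minimal PDB ATOM records (via gemmi)."""
    import gemmi

    from itertools import groupby

    st = gemmi.Structure()
    st.name = s.source_id or "model"
    model = gemmi.Model(s.model_index)
    for chain_id, chain_atoms in groupby(s.atoms, key=lambda a: a.chain_id):
        ch = gemmi.Chain(chain_id)
        for (num, icode, rname), res_atoms in groupby(
            chain_atoms, key=lambda a: (a.residue_number, a.icode, a.residue_name)
        ):
            res = gemmi.Residue()
            res.name = rname
            res.seqid = gemmi.SeqId(num, icode or " ")
            res.het_flag = "A"
            for a in res_atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.position)
                ga.occ = a.occupancy
                ga.serial = a.serial
                res.add_atom(ga)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
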