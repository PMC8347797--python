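"""Protein structure model: residues, atoms, charges, distances.

The container is deliberately minimal: an ordered list of residues, each an
ordered list of atoms with coordinates in Å and (optionally) point charges in
units of the elementary charge e.  Residue indices are re-based to a gapless
1..N on load because the fragmentation index arithmetic (one-body windows,
concap spans, sequence-separation rules) requires contiguous positions; the
author numbering from the PDB file is kept as metadata.

PDB files are read and written through Biopython's ``Bio.PDB`` layer; PQR
files (coordinates + charges combined) through MDAnalysis; plain charge
tables through pandas.
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import (
    ChargeLookupError,
    EmptyStructureError,
    FormatError,
    FragshiftError,
    MissingChargeError,
)

#: residue names treated as solvent by the optional water-stripping step
WATER_NAMES = frozenset({"HOH", "WAT", "H2O", "SOL", "TIP3"})

DEFAULT_CHROMOPHORE = "LYR"


@dataclass
class Atom:
    """A single atom: serial, name, element, coordinates (Å), charge (e)."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    charge: float | None = None
    residue_index: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise FragshiftError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.name:
            raise FragshiftError("atom name must be nonempty")

    def distance_to(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.coords - other.coords))


@dataclass
class Residue:
    """A residue: 1-based sequence index, name, ordered atoms."""

    index: int
    name: str
    atoms: list[Atom]
    is_chromophore: bool = False
    author_seq: int | None = None
    hetero: bool = False

    def __post_init__(self) -> None:
        if not self.atoms:
            raise FragshiftError(f"residue {self.index} ({self.name}) has no atoms")
        for a in self.atoms:
            a.residue_index = self.index

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise FragshiftError(f"residue {self.index} ({self.name}) has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def total_charge(self) -> float:
        if any(a.charge is None for a in self.atoms):
            raise MissingChargeError(f"residue {self.index} has uncharged atoms")
        return float(sum(a.charge for a in self.atoms))


@dataclass
class ProteinStructure:
    """Ordered residues with a free-text label (variant / snapshot id)."""

    residues: list[Residue]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptyStructureError("structure has zero residues")
        for k, res in enumerate(self.residues, start=1):
            if res.index != k:
                raise FragshiftError(
                    f"residue indices must be contiguous 1..N; got {res.index} at position {k}"
                )
        flags = [r.index for r in self.residues if r.is_chromophore]
        if len(flags) > 1:
            raise FragshiftError(f"more than one chromophore designated: {flags}")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def chromophore_index(self) -> int | None:
        for r in self.residues:
            if r.is_chromophore:
                return r.index
        return None

    def residue(self, index: int) -> Residue:
        if not 1 <= index <= self.n_residues:
            raise FragshiftError(f"residue index {index} out of range 1..{self.n_residues}")
        return self.residues[index - 1]

    def iter_atoms(self) -> Iterator[Atom]:
        for res in self.residues:
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def has_charges(self) -> bool:
        return all(a.charge is not None for a in self.iter_atoms())

    def total_charge(self) -> float:
        return sum(r.total_charge() for r in self.residues)

    def copy(self, label: str | None = None) -> "ProteinStructure":
        out = _copy.deepcopy(self)
        if label is not None:
            out.label = label
        return out


@dataclass
class ChargeSet:
    """A named charge model: (residue index, atom name) -> charge in e."""

    label: str
    values: dict[tuple[int, str], float] = field(default_factory=dict)

    def total_charge(self) -> float:
        return float(sum(self.values.values()))

    def check_integer_total(self, tol: float = 1e-6) -> None:
        total = self.total_charge()
        if abs(total - round(total)) > tol:
            raise FragshiftError(
                f"charge set {self.label!r}: total {total:.8f} e is not an integer (tol {tol})"
            )

    @classmethod
    def from_csv(
        cls, path: str | Path, label: str | None = None, check_integer_total: bool = True
    ) -> "ChargeSet":
        """Read a charge table with columns residue_index, atom_name, charge_e."""
        df = pd.read_csv(path)
        required = {"residue_index", "atom_name", "charge_e"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"{path}: charge CSV must have columns {sorted(required)}; got {list(df.columns)}"
            )
        keys = list(zip(df["residue_index"].astype(int), df["atom_name"].astype(str)))
        dupes = pd.Series(keys).duplicated()
        if dupes.any():
            first = keys[int(np.flatnonzero(dupes)[0])]
            raise FormatError(f"{path}: duplicate charge-table key {first}")
        cs = cls(
            label=label or Path(path).stem,
            values={k: float(q) for k, q in zip(keys, df["charge_e"])},
        )
        if check_integer_total:
            cs.check_integer_total()
        return cs

    def to_csv(self, path: str | Path) -> None:
        rows = [(r, n, q) for (r, n), q in sorted(self.values.items())]
        pd.DataFrame(rows, columns=["residue_index", "atom_name", "charge_e"]).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# operations


def attach_charges(structure: ProteinStructure, charges: ChargeSet) -> ProteinStructure:
    """Return a copy of *structure* with every atom's charge populated.

    Every (residue index, atom name) of the structure must be present in the
    charge set; missing keys are reported all at once.  Inputs are left
    unmodified.
    """
    missing = [
        (res.index, a.name)
        for res in structure.residues
        for a in res.atoms
        if (res.index, a.name) not in charges.values
    ]
    if missing:
        raise ChargeLookupError(missing)
    out = structure.copy()
    for res in out.residues:
        for a in res.atoms:
            a.charge = charges.values[(res.index, a.name)]
    return out


def min_residue_distance(res_i: Residue, res_j: Residue) -> float:
    """Minimum Euclidean distance (Å) between any two atoms of the residues."""
    if not res_i.atoms or not res_j.atoms:
        raise FragshiftError("min_residue_distance: empty residue")
    return float(cdist(res_i.coords, res_j.coords).min())


def distances_to_residue(structure: ProteinStructure, index: int) -> dict[int, float]:
    """Per-residue minimum distance (Å) to the residue at *index*."""
    ref = structure.residue(index)
    return {
        res.index: min_residue_distance(ref, res)
        for res in structure.residues
        if res.index != index
    }


# ---------------------------------------------------------------------------
# file I/O


def _element_of(bio_atom) -> str:
    el = (bio_atom.element or "").strip()
    if el:
        return el.capitalize()
    stripped = bio_atom.get_name().strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def read_pdb(
    path: str | Path,
    chromophore: str = DEFAULT_CHROMOPHORE,
    strip_water: bool = False,
    label: str | None = None,
) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Residues are re-indexed contiguously 1..N in file order (author numbering
    kept in ``Residue.author_seq``).  ATOM and HETATM records sharing the
    chromophore residue's author number and name are merged into a single
    residue flagged ``is_chromophore``.  Only the first model and first chain
    are used; for alternate locations Biopython's highest-occupancy conformer
    is taken.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        bio = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise FormatError(f"{path}: {exc}") from exc

    models = list(bio.get_models())
    if not models:
        raise EmptyStructureError(f"{path}: no models")
    chains = list(models[0].get_chains())
    if not chains:
        raise EmptyStructureError(f"{path}: no chains")
    chain = chains[0]

    raw: list[Residue] = []
    for bres in chain.get_residues():
        hetfield, resseq, icode = bres.get_id()
        name = bres.get_resname().strip()
        if strip_water and name in WATER_NAMES:
            continue
        atoms = [
            Atom(
                serial=int(a.get_serial_number() or 0),
                name=a.get_name().strip(),
                element=_element_of(a),
                coords=np.array(a.get_coord(), dtype=float),
            )
            for a in bres.get_atoms()
        ]
        if not atoms:
            continue
        # merge ATOM/HETATM split of the same author residue (the chromophore
        # is often deposited with its backbone as ATOM and the rest as HETATM)
        if raw and raw[-1].author_seq == int(resseq) and raw[-1].name == name:
            raw[-1].atoms.extend(atoms)
            continue
        raw.append(
            Residue(
                index=len(raw) + 1,
                name=name,
                atoms=atoms,
                author_seq=int(resseq),
                hetero=hetfield.strip() != "",
            )
        )
    if not raw:
        raise EmptyStructureError(f"{path}: zero residues parsed")
    for res in raw:
        res.is_chromophore = res.name == chromophore
        for a in res.atoms:
            a.residue_index = res.index
    return ProteinStructure(residues=raw, label=label or path.stem)


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write the structure as a single-chain PDB file via Bio.PDB."""
    from Bio.PDB import PDBIO
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure(structure.label or "frag")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg(" ")
    serial = 0
    for res in structure.residues:
        hetfield = f"H_{res.name}" if res.hetero else " "
        sb.init_residue(res.name, hetfield, res.author_seq or res.index, " ")
        for atom in res.atoms:
            serial += 1
            name = atom.name
            fullname = name if len(name) >= 4 else f" {name:<3s}"
            sb.init_atom(
                name,
                np.asarray(atom.coords, dtype=float),
                0.0,
                1.0,
                " ",
                fullname,
                serial,
                element=atom.element.upper(),
            )
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))


def read_pqr(
    path: str | Path,
    chromophore: str = DEFAULT_CHROMOPHORE,
    label: str | None = None,
    check_integer_total: bool = True,
) -> tuple[ProteinStructure, ChargeSet]:
    """Read a PQR file (coordinates + charges) via MDAnalysis.

    Returns the charged structure and the extracted :class:`ChargeSet`.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda

        try:
            u = mda.Universe(str(path))
        except Exception as exc:
            raise FormatError(f"{path}: {exc}") from exc

    residues: list[Residue] = []
    for res in u.residues:
        atoms = [
            Atom(
                serial=int(a.id),
                name=str(a.name),
                element=str(getattr(a, "element", "") or a.name[:1]).capitalize(),
                coords=np.array(a.position, dtype=float),
                charge=float(a.charge),
            )
            for a in res.atoms
        ]
        residues.append(
            Residue(
                index=len(residues) + 1,
                name=str(res.resname).strip(),
                atoms=atoms,
                author_seq=int(res.resid),
                is_chromophore=str(res.resname).strip() == chromophore,
            )
        )
    if not residues:
        raise EmptyStructureError(f"{path}: zero residues parsed")
    struct = ProteinStructure(residues=residues, label=label or Path(path).stem)
    cs = ChargeSet(
        label=(label or Path(path).stem),
        values={
            (r.index, a.name): float(a.charge) for r in struct.residues for a in r.atoms
        },
    )
    if check_integer_total:
        cs.check_integer_total()
    return struct, cs


def charge_set_from_structure(structure: ProteinStructure, label: str) -> ChargeSet:
    """Extract the attached charges of a structure as a ChargeSet."""
    if not structure.has_charges():
        raise MissingChargeError("structure has uncharged atoms")
    return ChargeSet(
        label=label,
        values={(r.index, a.name): float(a.charge) for r in structure.residues for a in r.atoms},
    )
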