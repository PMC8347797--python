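"""Deterministic synthetic test systems.

Real inputs to this toolkit come from rhodopsin-like membrane proteins with
a retinal-Schiff-base chromophore; the generators here emulate the features
the bookkeeping actually exercises, at desk scale:

* a short ideal-helix polypeptide (backbone N, CA, C per residue) with one
  chromophore residue carrying a collinear polyene chain C1..C_k,
* reproducible per-atom point charges whose per-residue sums are rounded so
  the structure's total charge is an integer,
* variant series that differ only in one residue's charges (geometry held
  fixed, so field differences are purely electrostatic), and
* Gaussian-jittered snapshot ensembles standing in for thermal sampling.

They do not emulate real protein geometry, sidechain chemistry, or
correlated thermal motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .structure import Atom, ChargeSet, ProteinStructure, Residue, attach_charges

CHROMOPHORE_NAME = "LYR"


@dataclass(frozen=True)
class FixtureParams:
    """Geometry, charge, and ensemble parameters of the toy system."""

    n_residues: int = 11
    chromophore_position: int = 6
    atoms_per_residue: int = 3
    helix_rise: float = 1.5  # Å per residue
    helix_twist: float = 100.0  # degrees per residue
    helix_radius: float = 2.3  # Å
    polyene_length: int = 10  # atoms C1..C_k, 1.0 Å spacing
    charge_scale: float = 0.1  # e, std-dev of raw atomic charges
    jitter_sigma: float = 0.05  # Å, snapshot displacement per coordinate
    n_snapshots: int = 100
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_residues < 7:
            raise ParameterError("n_residues must be ≥ 7")
        if not 3 <= self.chromophore_position <= self.n_residues - 2:
            raise ParameterError(
                "chromophore_position must satisfy 3 ≤ m ≤ n_residues − 2"
            )
        if self.atoms_per_residue < 3:
            raise ParameterError("atoms_per_residue must be ≥ 3 (N, CA, C backbone)")
        if self.polyene_length < 10:
            raise ParameterError("polyene_length must be ≥ 10 (field probes C1..C10)")
        for name in ("helix_rise", "helix_twist", "helix_radius"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.jitter_sigma < 0 or self.charge_scale < 0:
            raise ParameterError("charge_scale and jitter_sigma must be ≥ 0")


def _backbone_atoms(i: int, p: FixtureParams, serial0: int) -> list[Atom]:
    """N, CA, C (+ optional sidechain dummies) of residue i on an ideal helix."""
    twist = np.deg2rad(p.helix_twist)
    theta = (i - 1) * twist
    names = ["N", "CA", "C"]
    offsets = [(-0.35, -0.5), (0.0, 0.0), (0.35, 0.5)]
    atoms = []
    for k, (name, (dth, dz)) in enumerate(zip(names, offsets)):
        ang = theta + dth
        atoms.append(
            Atom(
                serial=serial0 + k,
                name=name,
                element=name[0],
                coords=np.array(
                    [
                        p.helix_radius * np.cos(ang),
                        p.helix_radius * np.sin(ang),
                        (i - 1) * p.helix_rise + dz,
                    ]
                ),
            )
        )
    for extra in range(p.atoms_per_residue - 3):
        r = p.helix_radius + 1.0 * (extra + 1)
        atoms.append(
            Atom(
                serial=serial0 + 3 + extra,
                name=f"CB{extra + 1}",
                element="C",
                coords=np.array(
                    [r * np.cos(theta), r * np.sin(theta), (i - 1) * p.helix_rise]
                ),
            )
        )
    return atoms


def make_toy_protein(
    p: FixtureParams | None = None, charge_label: str = "amber"
) -> tuple[ProteinStructure, ChargeSet]:
    """Build the charged toy helix; deterministic for fixed params.

    The chromophore residue additionally carries a collinear polyene chain
    C1..C_k extending radially outward from its CA at 1.0 Å spacing.
    Charges are drawn from a seeded normal distribution and shifted within
    each residue so the residue total is an integer.
    """
    p = p or FixtureParams()
    residues: list[Residue] = []
    serial = 1
    for i in range(1, p.n_residues + 1):
        atoms = _backbone_atoms(i, p, serial)
        is_chromo = i == p.chromophore_position
        if is_chromo:
            theta = np.deg2rad(p.helix_twist) * (i - 1)
            u = np.array([np.cos(theta), np.sin(theta), 0.0])
            ca = atoms[1].coords
            for k in range(1, p.polyene_length + 1):
                atoms.append(
                    Atom(
                        serial=serial + len(atoms),
                        name=f"C{k}",
                        element="C",
                        coords=ca + u * (1.0 * k),
                    )
                )
        serial += len(atoms)
        residues.append(
            Residue(
                index=i,
                name=CHROMOPHORE_NAME if is_chromo else "ALA",
                atoms=atoms,
                is_chromophore=is_chromo,
            )
        )
    structure = ProteinStructure(residues=residues, label=f"toy-n{p.n_residues}-s{p.seed}")

    rng = np.random.default_rng(p.seed)
    values: dict[tuple[int, str], float] = {}
    for res in structure.residues:
        raw = rng.normal(0.0, p.charge_scale, size=len(res.atoms))
        total = raw.sum()
        raw += (round(total) - total) / len(raw)
        for a, q in zip(res.atoms, raw):
            values[(res.index, a.name)] = float(q)
    charges = ChargeSet(label=charge_label, values=values)
    return attach_charges(structure, charges), charges


def make_variant_series(
    structure: ProteinStructure,
    charges: ChargeSet,
    residue: int,
    charge_deltas: list[float],
) -> list[tuple[str, ChargeSet]]:
    """Charge-only mutants: shift one residue's total charge by each delta.

    The named residue may not be the chromophore or one of its ±2 sequence
    neighbours (that would change the one-body fragment chemistry, which a
    charge-swap mutant is meant to hold fixed).  Each delta is spread evenly
    over the residue's atoms; geometry is untouched.
    """
    m = structure.chromophore_index
    if m is not None and abs(residue - m) <= 2:
        raise ParameterError(
            f"residue {residue} is the chromophore or a ±2 neighbour (m={m})"
        )
    res = structure.residue(residue)
    out = []
    for delta in charge_deltas:
        values = dict(charges.values)
        per_atom = delta / len(res.atoms)
        for a in res.atoms:
            values[(residue, a.name)] += per_atom
        label = f"{charges.label}:r{residue}{delta:+.3f}"
        out.append((label, ChargeSet(label=label, values=values)))
    return out


def make_snapshots(
    structure: ProteinStructure, n: int, sigma: float, seed: int
) -> list[ProteinStructure]:
    """Gaussian-jittered copies of the structure (a mock thermal ensemble).

    Each coordinate of each atom is displaced by an independent
    Normal(0, sigma) draw; sigma = 0 returns identical copies.  Deterministic
    per seed.
    """
    if n < 1:
        raise ParameterError("n must be ≥ 1")
    if sigma < 0:
        raise ParameterError("sigma must be ≥ 0")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        snap = structure.copy(label=f"{structure.label}/snap{k:03d}")
        if sigma > 0:
            for atom in snap.iter_atoms():
                atom.coords = atom.coords + rng.normal(0.0, sigma, size=3)
        out.append(snap)
    return out
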