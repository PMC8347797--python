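"""QM engine contract, analytic mock engines, and result import/export.

A QM engine maps a :class:`~fragshift.fragments.FragmentSpec` to a
:class:`QMResult`.  Real electronic-structure runs live outside this package
(fragment inputs are exported as XYZ + point-charge files and results
imported from JSON/CSV); the engines here are analytic models whose
full-system answer is known in closed form, so the fragment assembly can be
checked for exactness:

* :class:`CoulombEngine` — the ground-state energy is literally the Coulomb
  energy of the fragment's point charges plus their interaction with the
  embedding charges.  Assembling these fragment energies must recover the
  full system's Coulomb energy exactly.
* :class:`AdditiveExcitationEngine` — the excitation energy of any
  chromophore-containing fragment is a base value plus an additive kernel
  contribution from every environment atom, whether it sits in the QM region
  or in the embedding.  Because QM and embedded atoms contribute identically,
  all two-body corrections vanish and the assembled excitation equals the
  full-system value.  Passing a different ``qm_kernel`` breaks that symmetry
  ("contrast" engine): two-body corrections then become nonzero exactly for
  residues within the cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .errors import (
    ConfigurationError,
    FormatError,
    FragshiftError,
    InvariantError,
    MissingChargeError,
    SingularityError,
)
from .fragments import FragmentSpec, GmfccConfig

Kernel = Callable[[float, float], float]


@dataclass
class QMResult:
    """Energies of one fragment, in eV."""

    fragment_id: str
    e_ground: float
    e_excited: float | None = None
    omega: float | None = None
    oscillator_strength: float | None = None

    def __post_init__(self) -> None:
        if self.omega is None and self.e_excited is not None:
            self.omega = self.e_excited - self.e_ground
        if self.omega is not None:
            if self.e_excited is not None and abs(
                self.omega - (self.e_excited - self.e_ground)
            ) > 1e-9:
                raise InvariantError(
                    f"{self.fragment_id}: omega inconsistent with e_excited − e_ground"
                )
            if self.omega < 0:
                raise InvariantError(
                    f"{self.fragment_id}: negative excitation energy {self.omega:.6f} eV"
                )


class QMEngine(Protocol):
    def compute(self, spec: FragmentSpec) -> QMResult: ...


def compute_all(engine: QMEngine, specs: list[FragmentSpec]) -> dict[str, QMResult]:
    return {spec.id: engine.compute(spec) for spec in specs}


# ---------------------------------------------------------------------------
# mock engines


class CoulombEngine:
    """Point-charge electrostatics as a stand-in ground-state Hamiltonian.

    e_ground = Σ_{a<b ∈ QM} k q_a q_b / r_ab + Σ_{a ∈ QM, c ∈ embedding}
    k q_a q_c / r_ac.  Cap hydrogens carry zero charge and contribute
    nothing.  No excitation energy is produced.
    """

    def __init__(self, cfg: GmfccConfig | None = None):
        self.k = (cfg or GmfccConfig()).coulomb_k_ev_A

    def compute(self, spec: FragmentSpec) -> QMResult:
        coords = np.array([a.coords for a in spec.qm_atoms]).reshape(-1, 3)
        charges = []
        for a in spec.qm_atoms:
            if a.charge is None:
                raise MissingChargeError(f"fragment {spec.id}: atom {a.name} has no charge")
            charges.append(a.charge)
        charges = np.asarray(charges, dtype=float)

        energy = 0.0
        if len(charges) > 1:
            d = pdist(coords)
            qprod = np.array(
                [charges[i] * charges[j] for i in range(len(charges)) for j in range(i + 1, len(charges))]
            )
            live = qprod != 0
            if np.any(d[live] == 0):
                raise SingularityError(f"fragment {spec.id}: coincident charged atoms")
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(live & (d > 0), qprod / np.where(d > 0, d, 1.0), 0.0)
            energy += self.k * float(terms.sum())
        if spec.embedding:
            epos = np.array([e.position for e in spec.embedding])
            eq = np.array([e.charge for e in spec.embedding])
            d = cdist(coords, epos)
            qprod = np.outer(charges, eq)
            live = qprod != 0
            if np.any(d[live] == 0):
                raise SingularityError(
                    f"fragment {spec.id}: embedding charge coincides with a QM atom"
                )
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(live & (d > 0), qprod / np.where(d > 0, d, 1.0), 0.0)
            energy += self.k * float(terms.sum())
        return QMResult(fragment_id=spec.id, e_ground=energy)


def coulomb_kernel(k: float = GmfccConfig().coulomb_k_ev_A, scale: float = 1.0) -> Kernel:
    """kernel(q, r) = scale · k · q / r — a Coulomb-potential-like shift model."""

    def kernel(q: float, r: float) -> float:
        if r <= 0:
            raise SingularityError("kernel evaluated at zero distance")
        return scale * k * q / r

    return kernel


class AdditiveExcitationEngine:
    """Excitation energy = ω0 + additive environment-atom kernel contributions.

    Every non-chromophore source atom — QM-resident or embedded — shifts the
    excitation by ``kernel(q, r)`` with r its distance to a fixed reference
    atom of the chromophore.  ``qm_kernel`` (default: same as ``kernel``)
    applies to environment atoms inside the QM region; choosing a different
    one models a non-classical short-range effect and makes two-body
    corrections nonzero.
    """

    def __init__(
        self,
        omega0: float,
        kernel: Kernel,
        chromophore_index: int,
        reference_atom: str = "C1",
        qm_kernel: Kernel | None = None,
    ):
        self.omega0 = omega0
        self.kernel = kernel
        self.qm_kernel = qm_kernel or kernel
        self.m = chromophore_index
        self.reference_atom = reference_atom

    def _reference(self, spec: FragmentSpec) -> np.ndarray:
        for a in spec.qm_atoms:
            if a.residue_index == self.m and a.name == self.reference_atom:
                return a.coords
        raise ConfigurationError(
            f"fragment {spec.id}: chromophore reference atom {self.reference_atom!r} not found"
        )

    def compute(self, spec: FragmentSpec) -> QMResult:
        if not spec.contains_residue(self.m):
            return QMResult(fragment_id=spec.id, e_ground=0.0)
        ref = self._reference(spec)
        omega = self.omega0
        for a in spec.qm_atoms:
            if a.residue_index is None or a.residue_index == self.m:
                continue  # caps and chromophore atoms are not environment
            if a.charge is None:
                raise MissingChargeError(f"fragment {spec.id}: atom {a.name} has no charge")
            omega += self.qm_kernel(a.charge, float(np.linalg.norm(a.coords - ref)))
        for e in spec.embedding:
            if e.source[0] == self.m:
                continue
            omega += self.kernel(e.charge, float(np.linalg.norm(e.position - ref)))
        return QMResult(fragment_id=spec.id, e_ground=0.0, omega=omega)


def full_system_excitation(
    structure, m: int, engine: AdditiveExcitationEngine
) -> float:
    """Closed-form full-system ω of the additive model (the assembly oracle).

    Every non-chromophore atom contributes through the QM kernel, as if the
    whole protein were one QM region.
    """
    ref = structure.residue(m).atom(engine.reference_atom).coords
    omega = engine.omega0
    for res in structure.residues:
        if res.index == m:
            continue
        for a in res.atoms:
            omega += engine.qm_kernel(a.charge, float(np.linalg.norm(a.coords - ref)))
    return omega


# ---------------------------------------------------------------------------
# result import/export


def _result_from_row(row: dict) -> QMResult:
    try:
        fid = str(row["fragment_id"])
        e_ground = float(row["e_ground"])
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"result row {row!r}: missing/invalid required column") from exc

    def opt(key):
        v = row.get(key)
        if v is None:
            return None
        v = float(v)
        return None if np.isnan(v) else v

    return QMResult(
        fragment_id=fid,
        e_ground=e_ground,
        e_excited=opt("e_excited"),
        omega=opt("omega"),
        oscillator_strength=opt("oscillator_strength"),
    )


def load_results(path: str | Path) -> dict[str, QMResult]:
    """Load per-fragment QM results from JSON (list of records) or CSV."""
    import pandas as pd

    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if isinstance(rows, dict):
            rows = [dict(fragment_id=k, **v) for k, v in rows.items()]
    else:
        df = pd.read_csv(path)
        if "fragment_id" not in df.columns or "e_ground" not in df.columns:
            raise FormatError(f"{path}: need columns fragment_id and e_ground")
        rows = df.to_dict("records")
    out: dict[str, QMResult] = {}
    for row in rows:
        res = _result_from_row(row)
        if res.fragment_id in out:
            raise FragshiftError(f"{path}: duplicate fragment_id {res.fragment_id!r}")
        out[res.fragment_id] = res
    return out


def save_results(results: dict[str, QMResult], path: str | Path) -> None:
    rows = [
        {
            "fragment_id": r.fragment_id,
            "e_ground": r.e_ground,
            "e_excited": r.e_excited,
            "omega": r.omega,
            "oscillator_strength": r.oscillator_strength,
        }
        for r in results.values()
    ]
    Path(path).write_text(json.dumps(rows, indent=1))
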