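"""Projected electric field along the chromophore polyene chain.

The scalar probe of electrostatic colour tuning: the difference of the
Coulomb potentials generated by the protein's point charges at two atoms of
the conjugated chain (by default C10 and C1 of the retinal-Schiff-base
residue), divided by the probe separation,

    E = [ Σ_i k q_i (1/|r_i − r_a| − 1/|r_i − r_b|) ] / |r_a − r_b|,

with the chromophore's own charges excluded by default.  k = 14.3996
V·Å·e⁻¹ (vacuum, no dielectric screening) and 1 V/Å = 100 MV/cm, so the
result is reported in MV/cm.  A stronger field from C10 toward C1 opposes
the charge-transfer direction of the excitation and blue-shifts the
absorption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, FragshiftError, SingularityError
from .fragments import GmfccConfig
from .structure import ProteinStructure

V_PER_A_TO_MV_PER_CM = 100.0


@dataclass
class FieldResult:
    field: float  # MV/cm, projected from probe_b toward probe_a
    probe_a: str
    probe_b: str
    probe_distance: float  # Å
    charge_model: str = ""
    label: str = ""


def electric_field(
    structure: ProteinStructure,
    probe_a: str = "C10",
    probe_b: str = "C1",
    exclude: set[int] | None = None,
    charge_model: str = "",
    cfg: GmfccConfig | None = None,
) -> FieldResult:
    """Projected field (MV/cm) between two named atoms of the chromophore.

    ``exclude`` is a set of residue indices whose charges are omitted; by
    default the whole chromophore residue is excluded.
    """
    cfg = cfg or GmfccConfig()
    m = structure.chromophore_index
    if m is None:
        raise ConfigurationError("no chromophore designated; cannot locate probe atoms")
    chromo = structure.residue(m)
    ra = chromo.atom(probe_a).coords
    rb = chromo.atom(probe_b).coords
    d_ab = float(np.linalg.norm(ra - rb))
    if d_ab == 0:
        raise FragshiftError("probe atoms coincide")
    if exclude is None:
        exclude = {m}

    total = 0.0
    for res in structure.residues:
        if res.index in exclude:
            continue
        for atom in res.atoms:
            if atom.charge is None:
                raise FragshiftError(
                    f"residue {res.index} atom {atom.name}: charge missing for field"
                )
            if atom.charge == 0.0:
                continue
            da = float(np.linalg.norm(atom.coords - ra))
            db = float(np.linalg.norm(atom.coords - rb))
            if da == 0 or db == 0:
                raise SingularityError(
                    f"source charge at residue {res.index} atom {atom.name} coincides with a probe"
                )
            total += cfg.coulomb_k_ev_A * atom.charge * (1.0 / da - 1.0 / db)
    return FieldResult(
        field=total / d_ab * V_PER_A_TO_MV_PER_CM,
        probe_a=probe_a,
        probe_b=probe_b,
        probe_distance=d_ab,
        charge_model=charge_model,
        label=structure.label,
    )


def ev_to_nm(e: float, hc_ev_nm: float = GmfccConfig().hc_ev_nm) -> float:
    """Photon energy (eV) → wavelength (nm)."""
    if e <= 0:
        raise FragshiftError(f"energy must be positive, got {e}")
    return hc_ev_nm / e


def nm_to_ev(l: float, hc_ev_nm: float = GmfccConfig().hc_ev_nm) -> float:
    """Wavelength (nm) → photon energy (eV)."""
    if l <= 0:
        raise FragshiftError(f"wavelength must be positive, got {l}")
    return hc_ev_nm / l
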