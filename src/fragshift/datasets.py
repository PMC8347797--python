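"""Reference data for the blue proteorhodopsin (BPR, PR105Q) mutant series.

Published benchmark tables for the position-105 colour-tuning series of
blue-absorbing proteorhodopsin: experimental absorption maxima at high pH
(ASP97 deprotonated) together with fragment-QM predictions at the
TD-B3LYP/6-31G* level, the GMFCC per-residue decomposition of the PR105D
excitation energy, and the ensemble-averaged projected electric field
between retinal atoms C10 and C1 under two charge models.  These tables are
the inputs of the statistics layer's benchmark reproduction; nothing here
is computed by this package.
"""

from __future__ import annotations

import pandas as pd

# Experimental absorption maxima (nm) and fragment-QM wavelengths (nm) with
# one-body (1B) and one-plus-two-body (2B) corrections, ten variants at
# position 105.
_MUTANT_ABSORPTION = [
    # variant, exp_nm, calc_1b_nm, calc_2b_nm
    ("Q105D", 510, 495, 512),
    ("Q105W", 527, 504, 521),
    ("Q105C", 512, 507, 511),
    ("Q105L", 516, 518, 522),
    ("PR105Q", 493, 495, 496),
    ("Q105M", 524, 512, 528),
    ("Q105Y", 524, 519, 525),
    ("Q105V", 523, 520, 525),
    ("Q105I", 517, 512, 518),
    ("Q105K", 529, 537, 538),
]

# GMFCC per-residue decomposition of the PR105D excitation energy: two-body
# (residue + chromophore) excitation in eV, ensemble-averaged over 100
# snapshots.  The first row is the bare chromophore (monomer).
_RESIDUE_DECOMPOSITION = [
    ("LYR231", 2.2348),
    ("LEU40", 2.2329),
    ("VAL68", 2.2392),
    ("THR69", 2.2322),
    ("ALA72", 2.2317),
    ("TYR95", 2.2326),
    ("ASP97", 2.5027),
    ("TRP98", 2.2182),
    ("THR101", 2.2258),
    ("VAL102", 2.2265),
    ("ASP105", 2.2779),
    ("MET134", 2.2084),
    ("LEU135", 2.2155),
    ("GLY138", 2.2395),
    ("ALA151", 2.2183),
    ("PHE152", 2.2119),
    ("GLY155", 2.2345),
    ("CYS156", 2.2202),
    ("TRP159", 2.2239),
    ("TRP197", 2.2344),
    ("TYR200", 2.2551),
    ("PRO201", 2.2289),
    ("TYR204", 2.2308),
    ("TYR223", 2.2343),
    ("ASP227", 2.4446),
    ("PHE228", 2.2364),
    ("PHE234", 2.2344),
    ("GLY235", 2.2341),
]

# Ensemble-averaged projected electric field (MV/cm) between C10 and C1
# under the Amber ff14SB and polarized protein-specific charge (PPC) models,
# with experimental and fragment-QM excitation energies (eV) and the
# C10–C1 distance (Å).
_FIELD_CORRELATION = [
    # variant, exp_ev, calc_2b_ev, calc_1b_ev, field_amber, field_ppc, c10_c1_A
    ("Q105D", 2.436, 2.428, 2.509, 22.7, 25.9, 9.849),
    ("Q105W", 2.357, 2.382, 2.460, 22.1, 21.1, 9.809),
    ("Q105C", 2.427, 2.431, 2.445, 20.2, 18.3, 9.799),
    ("Q105L", 2.408, 2.378, 2.396, 19.8, 20.0, 9.826),
    ("PR105Q", 2.520, 2.502, 2.509, 19.6, 21.6, 9.826),
    ("Q105M", 2.371, 2.353, 2.422, 19.2, 21.1, 9.824),
    ("Q105Y", 2.371, 2.365, 2.391, 17.5, 18.0, 9.830),
    ("Q105V", 2.375, 2.365, 2.390, 17.0, 16.3, 9.850),
    ("Q105I", 2.403, 2.398, 2.427, 16.7, 16.7, 9.855),
    ("Q105K", 2.349, 2.311, 2.315, 13.2, 16.3, 9.857),
]


def mutant_absorption_table() -> pd.DataFrame:
    """Experimental vs fragment-QM absorption wavelengths (nm), 10 variants."""
    return pd.DataFrame(
        _MUTANT_ABSORPTION, columns=["variant", "exp_nm", "calc_1b_nm", "calc_2b_nm"]
    )


def residue_decomposition_table() -> pd.DataFrame:
    """Two-body excitation energies (eV) of the PR105D per-residue decomposition."""
    return pd.DataFrame(_RESIDUE_DECOMPOSITION, columns=["residue", "ex_ev"])


def chromophore_monomer_ex_ev() -> float:
    """Bare-chromophore (monomer) excitation energy of the decomposition, eV."""
    return _RESIDUE_DECOMPOSITION[0][1]


def field_correlation_table() -> pd.DataFrame:
    """Mean projected field (MV/cm) vs excitation energies (eV), 10 variants."""
    return pd.DataFrame(
        _FIELD_CORRELATION,
        columns=[
            "variant",
            "exp_ev",
            "calc_2b_ev",
            "calc_1b_ev",
            "field_amber",
            "field_ppc",
            "c10_c1_A",
        ],
    )
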