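"""Per-residue spectral-shift decomposition (GMFCC, background charges off).

Each residue's contribution is the two-body (residue + chromophore)
excitation minus the bare-chromophore excitation: positive ΔEx = blue
shift, negative ΔWL.  Here a contrast engine (short-range QM effects differ
from the classical kernel) plays the role of the electronic-structure code.
"""

import fragshift as fs

structure, _ = fs.make_toy_protein()
m = structure.chromophore_index
engine = fs.AdditiveExcitationEngine(
    omega0=2.3,
    kernel=fs.coulomb_kernel(),
    chromophore_index=m,
    qm_kernel=fs.coulomb_kernel(scale=2.0),
)
cfg = fs.GmfccConfig(cutoff_2b=6.0)
omega_m, shifts = fs.residue_decomposition(structure, m, cfg, engine)

print(f"bare chromophore: Ex = {omega_m:.4f} eV ({fs.ev_to_nm(omega_m):.1f} nm)")
print(f"{'residue':>8s} {'Ex (eV)':>9s} {'dEx (meV)':>10s} {'dWL (nm)':>9s}")
for s in shifts:
    print(
        f"{s.residue_name}{s.residue_index:<3d} {s.ex_pair:9.4f} "
        f"{s.delta_ex:10.2f} {s.delta_wl:9.3f}"
    )

# Residues with positive dEx push the absorption to higher energy (blue);
# the published analysis identifies the two aspartates flanking the Schiff
# base as the dominant blue-shifters in proteorhodopsin this way.
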