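# fragshift

Fragment-based quantum-chemistry bookkeeping for predicting protein
chromophore excitation energies and absorption spectral shifts.

Proteins such as proteorhodopsin tune the colour of their retinal
protonated-Schiff-base chromophore through the electrostatic environment of
the binding pocket. Computing a vertical excitation energy for the whole
protein at the QM level is intractable, but the excitation is local to one
chromophore, so the protein can be fractionated into small overlapping
fragments whose QM energies are reassembled. `fragshift` implements the
bookkeeping of that scheme — generalized molecular fractionation with
conjugate caps, with electrostatic embedding (EE-GMFCC) — for structures in
PDB/PQR format, together with the downstream colour-tuning analyses:
per-residue spectral-shift decomposition, the projected electric field along
the polyene chain, and mutant-series ensemble statistics. It is a library
for computational spectroscopists who run their own electronic-structure
engine; analytic mock engines are included so the entire assembly machinery
can be validated exactly without one.

## The method

A protein of *N* residues is divided into *N* − 2 one-body fragments
Cap\*<sub>i−1</sub>A<sub>i</sub>Cap<sub>i+1</sub> (each residue with its
sequence neighbours as conjugate caps, severed peptide bonds saturated by
hydrogen link atoms), minus the *N* − 3 concap overlaps
Cap\*<sub>i</sub>Cap<sub>i+1</sub>, plus two-body corrections for residue
pairs in spatial contact. With the chromophore at residue *m* and a minimum
inter-residue atom distance |R<sub>mj</sub>| ≤ λ₂ (default 4 Å, sequence
window m ± 2 excluded), the vertical excitation energy is

    ω = ω_1B + ω_2B
      = ω(Frag m−1) + ω(Frag m) + ω(Frag m+1) − ω(Concap m−1,m) − ω(Concap m,m+1)
        + Σ_j [ ω(m,j) − ω(m) ]

Every fragment sees the rest of the protein as background point charges
(electrostatic embedding); the ground-state assembly additionally subtracts
the double-counted charge–charge interactions, which `fragshift` tracks by
signed multiplicity counting over all background charge pairs. Switching the
embedding off (GMFCC) gives the per-residue decomposition: a residue's
spectral contribution is ΔEx = ω(residue + chromophore) − ω(chromophore),
reported in meV and as a wavelength shift ΔWL = hc/ω<sub>pair</sub> −
hc/ω<sub>mono</sub> in nm (negative = blue shift). The electrostatic origin
of the tuning is probed by the projected field between two polyene atoms
(default C10 and C1 of the retinal chain),

    E = [ Σ_{i∉chromophore} k q_i ( 1/|r_i − r_C10| − 1/|r_i − r_C1| ) ] / |r_C10 − r_C1| ,

in MV/cm with k = 14.3996 V·Å·e⁻¹ (vacuum).

## Worked example

The additive mock engine makes the full-system excitation known in closed
form, so the fragment assembly can be checked end to end
(`examples/02_assembly_oracles.py`):

```python
import fragshift as fs

structure, charges = fs.make_toy_protein()      # 11-residue helix, chromophore at 6
m = structure.chromophore_index
engine = fs.AdditiveExcitationEngine(2.3, fs.coulomb_kernel(), m)
full = fs.full_system_excitation(structure, m, engine)
rep = fs.run_excitation(structure, m, fs.GmfccConfig(cutoff_2b=6.0), engine)
print(full, rep.omega_total, rep.pair_corrections)
```

prints

```
full-system excitation (additive model): 2.409600670 eV
  assembled (cutoff   6.0 Å): 2.409600670 eV  |err| = 1.78e-15  max|2B| = 4.44e-16
```

— the assembled ω equals the full-system value to machine precision, and
every two-body correction vanishes identically because QM-resident and
embedded environment atoms contribute through the same kernel. The
statistics layer reproduces the published benchmark of the blue
proteorhodopsin position-105 mutant series
(`examples/05_mutant_statistics.py`):

```
    1B: MUE = 8.0 nm  mean dev = -5.6 nm  R = 0.710  fit: y = 0.841x + 76.57
 1B+2B: MUE = 3.5 nm  mean dev = +2.1 nm  R = 0.936  fit: y = 0.998x + 3.36
```

i.e. adding the two-body QM corrections halves the mean unsigned error
against experiment and lifts the correlation from 0.71 to 0.94.

## Command line

A thin CLI wraps the library: `fragshift inspect` (residue distances to the
chromophore), `fragshift fragment` (XYZ + point-charge export with a
manifest), `fragshift assemble` / `decompose` (imported QM results →
ω report / per-residue shift table), `fragshift field`, `fragshift stats`,
and `fragshift simulate` (writes a toy system with expected values).

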