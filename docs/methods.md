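# Methods

## Fragmentation scheme

`fragshift` implements the bookkeeping of generalized molecular
fractionation with conjugate caps, electrostatically embedded (EE-GMFCC),
for proteins with one locally excited chromophore. The scheme assumes the
excitation is local: the chromophore's excited state in isolation must be
qualitatively the same as in the protein, so that only fragments containing
the chromophore carry an excitation energy and the environment acts through
electrostatics plus short-range two-body QM corrections.

Ground state. A protein of N residues yields N−2 one-body fragments (each
residue plus both sequence neighbours, sign +1), N−3 two-residue concaps
(sign −1, cancelling the overlap between adjacent one-body fragments), and,
for every residue pair with sequence separation ≥ 3 whose minimum
inter-atomic distance is within the two-body cutoff, a pair fragment (+1)
with two monomer subtractions (−1 each). Three-body and higher terms are
neglected. Fragmentation requires N ≥ 5; smaller systems are rejected.

Excitation. Only the chromophore-containing fragments are needed: the three
one-body fragments centred on m−1, m, m+1, the two concaps {m−1,m} and
{m,m+1}, the chromophore monomer, and one pair {m,j} per residue j with
|R(m,j)| ≤ λ₂ and j outside the window [m−2, m+2]. The total is
ω = ω_1B + Σ_j [ω(m,j) − ω(m)]. The chromophore must sit at 3 ≤ m ≤ N−2 so
all five one-body/concap fragments exist. No embedding-charge correction is
applied to the excitation: with excited-state atomic charges approximated
equal to the ground-state ones, the correction terms are identical in the
ground- and excited-state totals and cancel in the difference, so the
excitation path never constructs them.

Caps. Severed backbone C–N bonds are saturated by hydrogen link atoms
placed along the severed-bond direction: 1.09 Å from the fragment's C
(replacing the downstream N) and 1.01 Å from the fragment's N (replacing
the upstream C). Both lengths are configuration knobs
(`GmfccConfig.cap_bond_lengths`). Cap hydrogens carry zero charge and never
enter any embedding set. A peptide bond is only considered present when
both partner atoms exist — toy residues without backbone atoms simply have
no bonds to sever — while a half-present bond raises an error. Discontiguous
pair spans cap each member independently.

Cutoffs. The two-body cutoff default is 4 Å on the minimum distance between
any two atoms of the residues (hydrogens included), compared inclusively.
The ground-state sequence-separation threshold (j ≥ i+3) and the excitation
exclusion window (±2) are separate config knobs with those defaults.

## Double-count correction

With embedding on, each fragment energy Ẽ includes the fragment's
interaction with all background charges, so background pair interactions
are counted multiple times across the fragment sum. Rather than
transcribing per-fragment index sets, the `CorrectionLedger` counts, for
every unordered pair of structure atoms, the signed number of fragment
energies in which that pair's interaction appears (QM–QM or QM–background),
and subtracts the Coulomb sum weighted by (net multiplicity − 1). By
construction this leaves every pair interaction counted exactly once; for
the generic interior pair the net multiplicity is 1 (weight 0), for a
distant unselected pair it is 2 (weight 1), and for a two-body-selected
pair the monomer subtractions already restore it to 1. The construction is
validated by an exactness oracle: with a pure point-charge engine the
assembled ground-state energy equals the brute-force full-system Coulomb
energy to ~1e-15 eV for arbitrary chains and any cutoff. In GMFCC mode
there are no background charges and the correction is zero.

## Mock engines

Real electronic-structure calculations are out of scope; fragments are
exported as XYZ + point-charge sidecar files and results imported from
JSON/CSV. Two analytic engines validate the assembly:

* `CoulombEngine`: e_ground is the Coulomb energy of the fragment's charges
  plus the QM–embedding interaction (k = 14.3996 eV·Å·e⁻²).
* `AdditiveExcitationEngine(ω0, kernel)`: ω of a chromophore-containing
  fragment is ω0 plus kernel(q, r) summed over every non-chromophore,
  non-cap source atom, QM-resident or embedded, with r measured to a fixed
  chromophore reference atom (default C1). Because both populations use the
  same kernel, the assembled ω equals the closed-form full-system value and
  all two-body corrections are identically zero. Supplying a distinct
  `qm_kernel` (the "contrast" engine) models short-range non-classical
  effects: corrections then become nonzero exactly for the residues the
  distance rule selects.

## Electric field and conversions

The colour-tuning probe is the projected field between two chromophore
atoms (defaults C10, C1): the difference of Coulomb potentials at the two
probes divided by their separation, sources being all charges outside the
chromophore residue (the whole residue is excluded by default, not only the
polyene). Vacuum permittivity is assumed — no dielectric screening — with
k = 14.3996 V·Å·e⁻¹ and 1 V/Å = 100 MV/cm. Energy/wavelength conversions
use hc = 1239.84193 eV·nm, which reproduces the published wavelength
differences of the benchmark tables to ±0.1 nm.

## Statistics layer

Variant ensembles are reduced by arithmetic snapshot means; wavelengths are
converted per snapshot and then averaged (for the near-symmetric ensembles
involved, the most probable and mean wavelengths nearly coincide, so this
choice matters little but is fixed for reproducibility). Series statistics
are the sample Pearson correlation (not R² of the fit) and ordinary least
squares with the calculated quantity regressed on the reference (calc vs
experiment; field vs one-body energy). Comparisons against published
statistics carry documented tolerances (±0.005 on R, ±0.01 on the
wavelength slope) because the published values were computed from unrounded
means while the tables print rounded columns; for the same reason one
decomposition row's meV shift recomputed from the printed 4-decimal
energies differs from the printed shift by 0.1 meV, and wavelength shifts
are compared at ±0.1–0.2 nm.

## Synthetic fixtures

`make_toy_protein` builds an ideal helix (rise 1.5 Å, twist 100°, radius
2.3 Å) with N, CA, C backbone atoms per residue and one chromophore residue
carrying a collinear 10-atom polyene (C1..C10, 1.0 Å spacing) extending
radially. Atomic charges are seeded Gaussian draws (σ = 0.1 e) shifted
within each residue so every residue total — and hence the structure
total — is an integer. Variant series are charge-only edits of one residue
(geometry fixed, so field differences are purely electrostatic; residues
within ±2 of the chromophore are refused because that would change one-body
fragment chemistry). Snapshot ensembles apply independent Normal(0, σ)
jitter per coordinate (default σ = 0.05 Å, 100 snapshots).

The toy helix carries backbone atoms only, so its inter-residue contact
distances are larger than in an all-atom protein: examples and ensemble
tests use a 6 Å two-body cutoff to exercise the pair machinery, while the
production default stays 4 Å. Tests that specifically check the 4 Å
selection rule use controlled single-atom geometries with residues placed
inside and outside the shell. The fixtures do not emulate real protein
geometry, sidechain chemistry, anisotropic or correlated thermal motion, or
real charge models — passing tests demonstrate the correctness of the
fragmentation, assembly, correction, field, and statistics arithmetic, not
the physical accuracy of any engine.

## Problem sizes and determinism

The test suite and the acceptance script run on toy scales chosen as the
smallest systems that exercise every code path: random single-atom chains
of N = 5..12 (ten per run) for the ground-state oracle, the 11- and
25-residue helices for the excitation pipeline, and 100-snapshot ensembles
for the statistics. All randomness flows through numpy's seeded
`default_rng`; identical seeds give bitwise-identical fixtures.

## Known limitations

* Single chain, first model only; altlocs resolved to highest occupancy;
  no insertion-code bookkeeping beyond sequential re-indexing.
* Hydrogen link atoms only; no disulfide or sidechain severing; no
  three-body terms.
* One excitation energy per fragment; excited-state root selection is the
  external engine's responsibility.
* The ledger's Coulomb correction assumes point-charge electrostatics for
  the over-counted background interactions — exact for the mock engines,
  the standard approximation for real ones.
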