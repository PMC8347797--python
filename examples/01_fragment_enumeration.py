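"""Enumerate EE-GMFCC fragments around a chromophore.

Builds the toy helix (11 residues, retinal-like chromophore at position 6),
enumerates the excitation fragment set, and prints each fragment's role.
"""

import fragshift as fs

structure, charges = fs.make_toy_protein()
m = structure.chromophore_index
print(f"toy helix: N={structure.n_residues} residues, chromophore at {m}")

cfg = fs.GmfccConfig(cutoff_2b=6.0)  # backbone-only toy: neighbours sit ~5 Å out
specs = fs.excitation_fragments(structure, m, cfg)
print(f"{len(specs)} fragments (cutoff {cfg.cutoff_2b} Å):")
for spec in specs:
    print(
        f"  {spec.id:<10s} kind={spec.kind:<8s} sign={spec.sign:+d} "
        f"span={spec.span}  qm_atoms={len(spec.qm_atoms)} "
        f"(caps {len(spec.cap_atoms)})  embedding={len(spec.embedding)}"
    )

# The one-body fragments are the chromophore and its sequence neighbours with
# conjugate caps; concaps (sign −1) cancel the overlap; pair fragments add
# two-body corrections for spatially close residues; the embedding column
# counts the background point charges representing the rest of the protein.
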