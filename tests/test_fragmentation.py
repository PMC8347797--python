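"""Fragment enumeration: spans, pair selection, caps, embedding, counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fragshift as fs
from fragshift.errors import (
    CappingError,
    InvalidChromophorePositionError,
    MissingChargeError,
    SizeError,
)
from fragshift.fragments import CONCAP, MONOMER, ONE_BODY, PAIR

from conftest import single_atom_chain


def kinds(specs):
    out = {}
    for s in specs:
        out.setdefault(s.kind, []).append(s)
    return out


# ---------------------------------------------------------------------------
# excitation fragment enumeration


def test_excitation_spans_around_chromophore_m5_n10():
    s = single_atom_chain(10, spread=10.0, charges=[0.0] * 10)  # nothing within cutoff
    specs = fs.excitation_fragments(s, m=5, cfg=fs.GmfccConfig(embedding_enabled=False))
    by = kinds(specs)
    assert len(specs) == 5
    assert sorted(sp.span for sp in by[ONE_BODY]) == [(3, 4, 5), (4, 5, 6), (5, 6, 7)]
    assert sorted(sp.span for sp in by[CONCAP]) == [(4, 5), (5, 6)]
    assert all(sp.sign == +1 for sp in by[ONE_BODY])
    assert all(sp.sign == -1 for sp in by[CONCAP])


def test_excitation_pair_added_within_cutoff_and_monomer_emitted_once():
    s = single_atom_chain(10, spread=10.0, charges=[0.0] * 10)
    # place residue 9 at 3.5 Å from the residue-5 chromophore
    s.residue(9).atoms[0].coords = s.residue(5).atoms[0].coords + np.array([0, 3.5, 0])
    specs = fs.excitation_fragments(s, m=5, cfg=fs.GmfccConfig(embedding_enabled=False))
    by = kinds(specs)
    assert [sp.span for sp in by[PAIR]] == [(5, 9)]
    assert [sp.span for sp in by[MONOMER]] == [(5,)]
    assert by[PAIR][0].sign == +1 and by[MONOMER][0].sign == -1


def test_excitation_sequence_neighbours_excluded_even_when_touching():
    s = single_atom_chain(10, spread=10.0, charges=[0.0] * 10)
    # residue 6 almost on top of the chromophore: still excluded (j in [m-2, m+2])
    s.residue(6).atoms[0].coords = s.residue(5).atoms[0].coords + np.array([0, 0.1, 0])
    specs = fs.excitation_fragments(s, m=5, cfg=fs.GmfccConfig(embedding_enabled=False))
    assert PAIR not in kinds(specs)


@pytest.mark.parametrize("m", [1, 2, 9, 10])
def test_excitation_chromophore_too_close_to_terminus_rejected(m):
    s = single_atom_chain(10, charges=[0.0] * 10)
    with pytest.raises(InvalidChromophorePositionError):
        fs.excitation_fragments(s, m=m, cfg=fs.GmfccConfig(embedding_enabled=False))


# ---------------------------------------------------------------------------
# ground-state enumeration


def test_ground_state_enumeration_linear_chain():
    s = single_atom_chain(5, spread=4.0, charges=[1.0] * 5)
    specs, _ = fs.ground_state_fragments(s, fs.GmfccConfig(cutoff_2b=100.0))
    by = kinds(specs)
    assert sorted(sp.span for sp in by[ONE_BODY]) == [(1, 2, 3), (2, 3, 4), (3, 4, 5)]
    assert sorted(sp.span for sp in by[CONCAP]) == [(2, 3), (3, 4)]
    assert sorted(sp.span for sp in by[PAIR]) == [(1, 4), (1, 5), (2, 5)]
    assert sorted(sp.span[0] for sp in by[MONOMER]) == [1, 2, 4, 5]


def test_ground_state_tiny_cutoff_drops_all_pairs():
    s = single_atom_chain(5, spread=4.0, charges=[1.0] * 5)
    specs, ledger = fs.ground_state_fragments(s, fs.GmfccConfig(cutoff_2b=0.1))
    by = kinds(specs)
    assert len(by[ONE_BODY]) == 3 and len(by[CONCAP]) == 2
    assert PAIR not in by and MONOMER not in by


def test_ground_state_requires_five_residues():
    with pytest.raises(SizeError):
        fs.ground_state_fragments(single_atom_chain(4, charges=[0.0] * 4))


@settings(deadline=None, derandomize=True, max_examples=20)
@given(
    n=st.integers(min_value=5, max_value=12),
    seed=st.integers(min_value=0, max_value=10_000),
    cutoff=st.sampled_from([2.0, 4.0, 8.0, 100.0]),
)
def test_fragment_count_laws_and_pair_rule(n, seed, cutoff):
    """|1B| = N−2, |concap| = N−3; pairs match a brute-force double loop."""
    s = single_atom_chain(n, seed=seed)
    cfg = fs.GmfccConfig(cutoff_2b=cutoff)
    specs, _ = fs.ground_state_fragments(s, cfg)
    by = kinds(specs)
    assert len(by[ONE_BODY]) == n - 2
    assert len(by[CONCAP]) == n - 3
    expected_pairs = sorted(
        (i, j)
        for i in range(1, n + 1)
        for j in range(i + cfg.ground_state_min_separation, n + 1)
        if fs.min_residue_distance(s.residue(i), s.residue(j)) <= cutoff
    )
    assert sorted(sp.span for sp in by.get(PAIR, [])) == expected_pairs


def test_lowering_cutoff_never_adds_pairs(toy_structure):
    m = toy_structure.chromophore_index
    prev = None
    for cutoff in (100.0, 8.0, 6.0, 4.0, 1.0):
        specs = fs.excitation_fragments(
            toy_structure, m, fs.GmfccConfig(cutoff_2b=cutoff)
        )
        js = {sp.span for sp in specs if sp.kind == PAIR}
        if prev is not None:
            assert js <= prev
        prev = js


# ---------------------------------------------------------------------------
# capping


def test_cap_counts_mid_span_and_terminus(toy_structure):
    cfg = fs.GmfccConfig()
    assert len(fs.cap_hydrogens((4, 5, 6), toy_structure, cfg)) == 2
    assert len(fs.cap_hydrogens((1, 2, 3), toy_structure, cfg)) == 1
    n = toy_structure.n_residues
    assert len(fs.cap_hydrogens((n - 2, n - 1, n), toy_structure, cfg)) == 1


def test_cap_hydrogen_placed_along_severed_bond():
    # C(0,0,0) of residue 1 bonded to N(1.33,0,0) of residue 2; capping the
    # span {1} replaces the N side with H at C–H = 1.09 Å along the bond.
    residues = [
        fs.Residue(
            index=1,
            name="ALA",
            atoms=[
                fs.Atom(serial=1, name="N", element="N", coords=[-2.4, 0, 0]),
                fs.Atom(serial=2, name="CA", element="C", coords=[-1.2, 0, 0]),
                fs.Atom(serial=3, name="C", element="C", coords=[0, 0, 0]),
            ],
        ),
        fs.Residue(
            index=2,
            name="ALA",
            atoms=[
                fs.Atom(serial=4, name="N", element="N", coords=[1.33, 0, 0]),
                fs.Atom(serial=5, name="CA", element="C", coords=[2.5, 0, 0]),
                fs.Atom(serial=6, name="C", element="C", coords=[3.7, 0, 0]),
            ],
        ),
    ]
    s = fs.ProteinStructure(residues=residues)
    caps = fs.cap_hydrogens((1,), s, fs.GmfccConfig())
    assert len(caps) == 1
    np.testing.assert_allclose(caps[0].coords, [1.09, 0, 0], atol=1e-12)
    assert caps[0].charge == 0.0
    # the complementary span {2} gets the hydrogen bonded to its N at 1.01 Å
    caps2 = fs.cap_hydrogens((2,), s, fs.GmfccConfig())
    np.testing.assert_allclose(caps2[0].coords, [1.33 - 1.01, 0, 0], atol=1e-12)


def test_half_present_peptide_bond_is_a_capping_error():
    residues = [
        fs.Residue(
            index=1,
            name="ALA",
            atoms=[fs.Atom(serial=1, name="C", element="C", coords=[0, 0, 0])],
        ),
        fs.Residue(
            index=2,
            name="ALA",
            atoms=[fs.Atom(serial=2, name="CA", element="C", coords=[2, 0, 0])],
        ),
    ]
    s = fs.ProteinStructure(residues=residues)
    with pytest.raises(CappingError):
        fs.cap_hydrogens((2,), s, fs.GmfccConfig())


def test_caps_never_collide_with_structure_atoms(toy_structure):
    cfg = fs.GmfccConfig(cutoff_2b=6.0)
    specs = fs.excitation_fragments(toy_structure, cfg=cfg)
    coords = np.array([a.coords for a in toy_structure.iter_atoms()])
    for sp in specs:
        for cap in sp.cap_atoms:
            dmin = np.min(np.linalg.norm(coords - cap.coords, axis=1))
            assert dmin > 0.5


# ---------------------------------------------------------------------------
# embedding


def test_embedding_counts_and_charge_partition(toy):
    structure, _ = toy
    cfg = fs.GmfccConfig()
    specs = fs.excitation_fragments(structure, cfg=cfg)
    total = structure.total_charge()
    for sp in specs:
        span_q = sum(structure.residue(i).total_charge() for i in sp.span)
        emb_q = sum(e.charge for e in sp.embedding)
        assert span_q + emb_q == pytest.approx(total, abs=1e-9)
        n_span_atoms = sum(len(structure.residue(i).atoms) for i in sp.span)
        assert len(sp.embedding) == structure.n_atoms - n_span_atoms
        # QM sources and embedding sources partition the structure atoms
        assert not set(sp.source_keys) & {e.source for e in sp.embedding}


def test_gmfcc_mode_has_no_embedding(toy_structure):
    specs = fs.excitation_fragments(
        toy_structure, cfg=fs.GmfccConfig(embedding_enabled=False)
    )
    assert all(not sp.embedding for sp in specs)


def test_embedding_requires_charges():
    s = single_atom_chain(10, spread=10.0, charges=[0.0] * 10)
    for res in s.residues:
        res.atoms[0].charge = None
    with pytest.raises(MissingChargeError):
        fs.excitation_fragments(s, m=5, cfg=fs.GmfccConfig())


# ---------------------------------------------------------------------------
# export / manifest


def test_export_and_manifest_round_trip(toy, tmp_path):
    structure, _ = toy
    specs = fs.excitation_fragments(structure, cfg=fs.GmfccConfig(cutoff_2b=6.0))
    manifest = fs.export_fragments(specs, tmp_path / "frags")
    back = fs.specs_from_manifest(manifest)
    assert [(s.id, s.kind, s.span, s.sign) for s in back] == [
        (s.id, s.kind, s.span, s.sign) for s in specs
    ]
    xyz = (tmp_path / "frags" / "1b_6.xyz").read_text().splitlines()
    assert int(xyz[0]) == len([s for s in specs if s.id == "1b:6"][0].qm_atoms)
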