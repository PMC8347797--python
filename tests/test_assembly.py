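"""Energy assembly: arithmetic identities, exactness oracles, decomposition."""

import numpy as np
import pytest

import fragshift as fs
from fragshift.errors import CompletenessError
from fragshift.fragments import FragmentSpec

from conftest import brute_coulomb, single_atom_chain


def skeleton(frag_id, kind, span, sign):
    return FragmentSpec(
        id=frag_id,
        kind=kind,
        span=tuple(span),
        center_residues=tuple(span),
        qm_atoms=[],
        cap_atoms=[],
        sign=sign,
    )


def excitation_skeletons(m=5, pair_js=()):
    specs = [skeleton(f"1b:{c}", "one_body", (c - 1, c, c + 1), +1) for c in (m - 1, m, m + 1)]
    specs += [skeleton(f"cc:{i}-{i + 1}", "concap", (i, i + 1), -1) for i in (m - 1, m)]
    specs += [skeleton(f"pair:{m}-{j}", "pair", (m, j), +1) for j in pair_js]
    if pair_js:
        specs.append(skeleton(f"mono:{m}", "monomer", (m,), -1))
    return specs


def omega_results(mapping):
    return {
        fid: fs.QMResult(fragment_id=fid, e_ground=0.0, omega=w) for fid, w in mapping.items()
    }


class TestExcitationArithmetic:
    def test_one_body_only(self):
        specs = excitation_skeletons()
        results = omega_results(
            {"1b:4": 2.0, "1b:5": 2.1, "1b:6": 2.2, "cc:4-5": 2.05, "cc:5-6": 2.15}
        )
        rep = fs.assemble_excitation(results, specs)
        assert rep.omega_1b == pytest.approx(2.10, abs=1e-12)
        assert rep.omega_total == pytest.approx(2.10, abs=1e-12)
        assert rep.pair_corrections == {}

    def test_equal_fragments_identity(self):
        specs = excitation_skeletons()
        results = omega_results({s.id: 2.3 for s in specs})
        assert fs.assemble_excitation(results, specs).omega_total == pytest.approx(
            2.3, abs=1e-12
        )

    def test_pair_corrections_added(self):
        specs = excitation_skeletons(pair_js=(9, 11))
        results = omega_results(
            {
                "1b:4": 2.0,
                "1b:5": 2.1,
                "1b:6": 2.2,
                "cc:4-5": 2.05,
                "cc:5-6": 2.15,
                "pair:5-9": 2.30,
                "pair:5-11": 2.15,
                "mono:5": 2.20,
            }
        )
        rep = fs.assemble_excitation(results, specs)
        assert rep.pair_corrections == pytest.approx({9: 0.10, 11: -0.05})
        assert rep.omega_total == pytest.approx(2.15, abs=1e-12)
        # arithmetic identity between fields
        assert rep.omega_total == pytest.approx(
            rep.omega_1b + sum(rep.pair_corrections.values()), abs=1e-15
        )

    def test_missing_result_lists_ids(self):
        specs = excitation_skeletons()
        results = omega_results({"1b:4": 2.0, "1b:5": 2.1, "1b:6": 2.2, "cc:4-5": 2.05})
        with pytest.raises(CompletenessError) as err:
            fs.assemble_excitation(results, specs)
        assert "cc:5-6" in err.value.missing_ids

    def test_result_map_ordering_irrelevant(self):
        specs = excitation_skeletons(pair_js=(9,))
        vals = {
            "1b:4": 2.0,
            "1b:5": 2.1,
            "1b:6": 2.2,
            "cc:4-5": 2.05,
            "cc:5-6": 2.15,
            "pair:5-9": 2.3,
            "mono:5": 2.2,
        }
        fwd = fs.assemble_excitation(omega_results(vals), specs)
        rev = fs.assemble_excitation(
            omega_results(dict(reversed(list(vals.items())))), specs
        )
        assert fwd.omega_total == rev.omega_total


class TestGroundStateOracle:
    def test_unit_chain_matches_full_coulomb(self, unit_chain):
        cfg = fs.GmfccConfig(cutoff_2b=100.0)
        e = fs.run_ground(unit_chain, cfg, fs.CoulombEngine(cfg))
        assert e == pytest.approx(23.099358333, abs=1e-6)
        assert e == pytest.approx(brute_coulomb(unit_chain), abs=1e-9)

    def test_zero_charges_give_zero(self):
        s = single_atom_chain(6, charges=[0.0] * 6)
        cfg = fs.GmfccConfig()
        assert fs.run_ground(s, cfg, fs.CoulombEngine(cfg)) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("cutoff", [0.5, 4.0, 100.0])
    def test_random_chains_exact_for_any_cutoff(self, seed, cutoff):
        s = single_atom_chain(8, seed=seed)
        cfg = fs.GmfccConfig(cutoff_2b=cutoff)
        e = fs.run_ground(s, cfg, fs.CoulombEngine(cfg))
        assert e == pytest.approx(brute_coulomb(s), abs=1e-9)

    def test_ledger_correction_counts_unselected_distant_pairs(self, unit_chain):
        # with no 2B pairs selected, each distant pair (sep ≥ 3) is described
        # classically twice (once in each member's embedding); the correction
        # is exactly their Coulomb sum
        _, ledger = fs.ground_state_fragments(unit_chain, fs.GmfccConfig(cutoff_2b=0.1))
        k = fs.GmfccConfig().coulomb_k_ev_A
        expected = k * (1 / 12 + 1 / 16 + 1 / 12)  # pairs (1,4), (1,5), (2,5)
        assert ledger.correction_energy == pytest.approx(expected, abs=1e-12)
        # with every distant pair promoted to QM, nothing is over-counted
        _, ledger_full = fs.ground_state_fragments(unit_chain, fs.GmfccConfig(cutoff_2b=100.0))
        assert ledger_full.correction_energy == 0.0


class TestExcitationOracle:
    def test_additive_mock_reproduces_full_system_any_cutoff(self, toy):
        structure, _ = toy
        m = structure.chromophore_index
        engine = fs.AdditiveExcitationEngine(2.3, fs.coulomb_kernel(), m)
        full = fs.full_system_excitation(structure, m, engine)
        for cutoff in (0.1, 4.0, 6.0, 100.0):
            rep = fs.run_excitation(structure, m, fs.GmfccConfig(cutoff_2b=cutoff), engine)
            assert rep.omega_total == pytest.approx(full, abs=1e-9)
            for corr in rep.pair_corrections.values():
                assert corr == pytest.approx(0.0, abs=1e-12)

    def test_contrast_mock_gives_nonzero_corrections_within_cutoff(self, toy):
        structure, _ = toy
        m = structure.chromophore_index
        engine = fs.AdditiveExcitationEngine(
            2.3, fs.coulomb_kernel(), m, qm_kernel=fs.coulomb_kernel(scale=2.0)
        )
        cfg = fs.GmfccConfig(cutoff_2b=6.0)
        rep = fs.run_excitation(structure, m, cfg, engine)
        selected = {
            res.index
            for res in structure.residues
            if abs(res.index - m) > cfg.exclusion_window
            and fs.min_residue_distance(structure.residue(m), res) <= cfg.cutoff_2b
        }
        assert selected  # the fixture must exercise the pair path
        assert set(rep.pair_corrections) == selected
        assert all(abs(v) > 1e-9 for v in rep.pair_corrections.values())


class TestDecomposition:
    def test_shift_from_printed_energies(self):
        # blue-shifting aspartate vs bare chromophore
        d_ex, d_wl = fs.shift_from_energies(2.5027, 2.2348)
        assert d_ex == pytest.approx(267.9, abs=1e-9)
        assert d_wl == pytest.approx(-59.4, abs=0.2)
        # red-shifting methionine; the printed 4-decimal energies carry
        # ±0.05 meV rounding, so the meV shift is compared at that resolution
        d_ex, d_wl = fs.shift_from_energies(2.2084, 2.2348)
        assert d_ex == pytest.approx(-26.3, abs=0.15)
        assert d_wl == pytest.approx(6.6, abs=0.1)

    def test_zero_shift_when_pair_equals_monomer(self):
        assert fs.shift_from_energies(2.2, 2.2) == (0.0, 0.0)

    def test_decomposition_matches_kernel_sums(self, toy):
        structure, _ = toy
        m = structure.chromophore_index
        kernel = fs.coulomb_kernel()
        engine = fs.AdditiveExcitationEngine(2.3, kernel, m)
        cfg = fs.GmfccConfig(cutoff_2b=6.0)
        omega_m, shifts = fs.residue_decomposition(structure, m, cfg, engine)
        assert omega_m == pytest.approx(2.3, abs=1e-12)  # GMFCC monomer sees nothing
        ref = structure.residue(m).atom("C1").coords
        for shift in shifts:
            expected = sum(
                kernel(a.charge, float(np.linalg.norm(a.coords - ref)))
                for a in structure.residue(shift.residue_index).atoms
            )
            assert shift.delta_ex == pytest.approx(expected * 1000.0, abs=1e-9)

    def test_decomposition_sum_rule(self, toy):
        """GMFCC monomer ω plus all ΔEx equals the GMFCC pair-sum assembly."""
        structure, _ = toy
        m = structure.chromophore_index
        engine = fs.AdditiveExcitationEngine(
            2.3, fs.coulomb_kernel(), m, qm_kernel=fs.coulomb_kernel(scale=1.7)
        )
        cfg = fs.GmfccConfig(cutoff_2b=6.0, embedding_enabled=False)
        omega_m, shifts = fs.residue_decomposition(structure, m, cfg, engine)
        specs = fs.excitation_fragments(structure, m, cfg)
        results = fs.compute_all(engine, specs)
        pair_sum = omega_m + sum(
            results[f"pair:{m}-{s.residue_index}"].omega - results[f"mono:{m}"].omega
            for s in shifts
        )
        assert omega_m + sum(s.delta_ex for s in shifts) / 1000.0 == pytest.approx(
            pair_sum, abs=1e-12
        )
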