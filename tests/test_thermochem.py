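"""BDE/BE arithmetic, redox trees and potentials, pKa, chemical shifts."""

import networkx as nx
import pytest
from hypothesis import given, strategies as st

import liqprop.constants as c
from liqprop import synthetic
from liqprop.errors import (
    CompletenessError,
    PhaseError,
    StoichiometryError,
    ValidationError,
    ValidityError,
)
from liqprop.molgraph import MolGraph
from liqprop.thermochem import (
    QMDoc,
    RedoxTreeSpec,
    Shielding,
    chemical_shift,
    compute_bde,
    compute_be,
    compute_pka,
    compute_redox,
    plan_redox_tree,
)


def doc(label, H=None, G=None, E=None, charge=0, phase="gas", ok=True, n_h=0):
    return QMDoc(
        label=label, charge=charge, phase=phase,
        solvent="water" if phase == "solution" else None,
        E_elec=E, H=H, G=G, all_freqs_real=ok, n_h=n_h,
    )


class TestBDE:
    def test_forced_arithmetic(self):
        bde = compute_bde(doc("p", H=-1.0), doc("f1", H=-0.4), doc("f2", H=-0.5))
        assert bde == pytest.approx(0.1 * c.HARTREE_EV, rel=1e-12)
        assert bde == pytest.approx(2.7211, abs=5e-4)

    def test_ring_open_identity(self):
        assert compute_bde(doc("p", H=-2.0), doc("open", H=-2.0),
                           mode="ring-open") == 0.0

    def test_toy_molecules_recover_assigned_strengths(self):
        els = ["C", "O", "C", "H", "H"]
        bonds = [(0, 1), (1, 2), (0, 3), (2, 4)]
        toy = synthetic.gen_toy_molecules(MolGraph.from_bonds(els, bonds),
                                          seed=9)
        principal = toy.qmdoc(label="principal")
        for bond in bonds:
            f1, f2 = toy.fragment_docs(bond)
            bde_ha = compute_bde(principal, f1, f2) / c.HARTREE_EV
            assert bde_ha == pytest.approx(
                toy.bond_strengths[frozenset(bond)], abs=1e-10
            )

    def test_imaginary_frequencies_gate(self):
        with pytest.raises(ValidityError, match="true minimum"):
            compute_bde(doc("p", H=-1.0), doc("f1", H=-0.4, ok=False),
                        doc("f2", H=-0.5))

    def test_charge_conservation(self):
        with pytest.raises(StoichiometryError):
            compute_bde(doc("p", H=-1.0), doc("f1", H=-0.4, charge=1),
                        doc("f2", H=-0.5))

    def test_missing_enthalpy(self):
        with pytest.raises(ValidationError, match="H"):
            compute_bde(doc("p", G=-1.0), doc("f1", H=-0.4), doc("f2", H=-0.5))


class TestBE:
    def test_zero_binding_not_exergonic(self):
        res = compute_be(doc("c", E=-0.9), doc("a", E=-0.4), doc("b", E=-0.5))
        assert res.value_ev == 0.0
        assert not res.exergonic

    def test_negative_binding_is_exergonic(self):
        res = compute_be(doc("c", E=-0.91), doc("a", E=-0.4), doc("b", E=-0.5))
        assert res.value_ev == pytest.approx(-0.01 * c.HARTREE_EV, rel=1e-10)
        assert res.value_ev == pytest.approx(-0.2721, abs=5e-4)
        assert res.exergonic

    def test_imaginary_complex_rejected(self):
        with pytest.raises(ValidityError):
            compute_be(doc("c", E=-1.0, ok=False), doc("a", E=-0.4),
                       doc("b", E=-0.5))

    def test_toy_complex_binding_equals_minus_link_strength(self):
        els = ["C", "H", "O", "H"]
        bonds = [(0, 1), (2, 3), (0, 2)]  # (0,2) links the two moieties
        toy = synthetic.gen_toy_molecules(MolGraph.from_bonds(els, bonds),
                                          seed=4)
        complex_doc = toy.qmdoc(label="complex")
        m1 = toy.qmdoc([0, 1], label="m1")
        m2 = toy.qmdoc([2, 3], label="m2")
        res = compute_be(complex_doc, m1, m2)
        assert res.value_ev / c.HARTREE_EV == pytest.approx(
            -toy.bond_strengths[frozenset((0, 2))], abs=1e-12
        )


class TestPlanRedoxTree:
    def test_adiabatic_single_step_ip_both_phases(self):
        spec = RedoxTreeSpec(method="adiabatic", directions=("oxidation",),
                             phases=("gas", "solution"), n_electrons=1)
        states = [n.state for n in plan_redox_tree(spec)]
        assert sorted(states) == sorted(
            [(0, 0, "gas"), (1, 0, "gas"), (0, 0, "solution"),
             (1, 0, "solution")]
        )

    def test_homo_lumo_needs_reference_only(self):
        spec = RedoxTreeSpec(method="homo_lumo", phases=("gas",))
        assert [n.state for n in plan_redox_tree(spec)] == [(0, 0, "gas")]

    def test_two_electron_multistep_reduction_in_solution(self):
        spec = RedoxTreeSpec(method="adiabatic", directions=("reduction",),
                             phases=("solution",), n_electrons=2,
                             electron_transfer="multi-step")
        states = [n.state for n in plan_redox_tree(spec)]
        assert states == [(0, 0, "solution"), (-1, 0, "solution"),
                          (-2, 0, "solution")]

    def test_vertical_children_reuse_parent_geometry(self):
        spec = RedoxTreeSpec(method="vertical", directions=("oxidation",),
                             phases=("gas",))
        nodes = plan_redox_tree(spec)
        by_state = {n.state: n for n in nodes}
        assert by_state[(0, 0, "gas")].reoptimize
        assert not by_state[(1, 0, "gas")].reoptimize

    def test_deterministic_and_insertion_order_independent(self):
        a = RedoxTreeSpec(method="pcet", directions=("reduction", "oxidation"),
                          phases=("solution", "gas"), n_electrons=2,
                          h_sites=(3,))
        b = RedoxTreeSpec(phases=("gas", "solution"), h_sites=(3,),
                          directions=("oxidation", "reduction"),
                          n_electrons=2, method="pcet")
        assert plan_redox_tree(a) == plan_redox_tree(b)
        assert plan_redox_tree(a) == plan_redox_tree(a)

    def test_pcet_without_sites_rejected(self):
        with pytest.raises(ValidationError, match="site"):
            RedoxTreeSpec(method="pcet")

    def test_pcet_interleaves_charge_and_hydrogen(self):
        spec = RedoxTreeSpec(method="pcet", directions=("reduction",),
                             phases=("solution",), n_electrons=1, h_sites=(0,))
        states = {n.state for n in plan_redox_tree(spec)}
        assert states == {(0, 0, "solution"), (-1, 0, "solution"),
                          (1, 1, "solution"), (0, 1, "solution")}
        # every child differs from its parent by exactly one transfer
        nodes = {n.state: n for n in plan_redox_tree(spec)}
        for n in nodes.values():
            if n.parent is None:
                continue
            dq = abs(n.state[0] - n.parent[0])
            dh = abs(n.state[1] - n.parent[1])
            assert (dq, dh) in {(1, 0), (1, 1)}


class TestComputeRedox:
    def _docs(self, g_ref_sol, g_red_sol):
        return {
            (1, 0, "solution"): doc("ox", G=g_ref_sol, charge=1,
                                    phase="solution"),
            (0, 0, "solution"): doc("red", G=g_red_sol, phase="solution"),
        }

    def _spec(self):
        return RedoxTreeSpec(method="adiabatic", directions=("reduction",),
                             phases=("solution",), reference_charge=1)

    def test_worked_example_potential_and_li_scale(self):
        # G(ox, sol) - G(red, sol) = 0.2 Ha, one electron
        res = compute_redox(self._docs(-99.8, -100.0), self._spec())
        e_abs = res.potentials["reduction"]["absolute"]
        assert e_abs == pytest.approx(0.2 * c.HARTREE_EV, rel=1e-10)
        assert e_abs == pytest.approx(5.4423, abs=5e-4)
        assert res.potentials["reduction"]["Li+/Li"] == pytest.approx(
            e_abs - 1.4, rel=1e-12
        )
        assert res.potentials["reduction"]["Li+/Li"] == pytest.approx(4.0423,
                                                                      abs=5e-4)

    def test_identical_states_give_zero_dg(self):
        res = compute_redox(self._docs(-100.0, -100.0), self._spec())
        assert res.dg_red_ev["solution"] == 0.0
        assert res.potentials["reduction"]["absolute"] == 0.0
        assert res.potentials["reduction"]["Li+/Li"] == -1.4

    def test_zero_offset_scale_equals_absolute(self):
        spec = self._spec()
        spec.scale_offsets = {"abs-copy": 0.0}
        res = compute_redox(self._docs(-99.8, -100.0), spec)
        assert (res.potentials["reduction"]["abs-copy"]
                == res.potentials["reduction"]["absolute"])

    def test_scale_conversion_is_exact_for_every_scale(self):
        spec = self._spec()
        spec.scale_offsets = {"A": 1.4, "B": 4.44, "C": -0.3}
        res = compute_redox(self._docs(-99.73, -100.0), spec)
        e_abs = res.potentials["reduction"]["absolute"]
        for name, offset in spec.scale_offsets.items():
            assert res.potentials["reduction"][name] == e_abs - offset

    def test_thermodynamic_cycle_from_gas_plus_solvation(self):
        # no direct solution documents: G(sol) = G(gas) + dG_solv
        docs = {
            (1, 0, "gas"): QMDoc("ox", 1, G=-99.8, dG_solv=-0.05),
            (0, 0, "gas"): QMDoc("red", 0, G=-100.0, dG_solv=-0.01),
        }
        res = compute_redox(docs, self._spec())
        dg = (-100.0 - 0.01) - (-99.8 - 0.05)
        assert res.dg_red_ev["solution"] == pytest.approx(dg * c.HARTREE_EV,
                                                          rel=1e-12)

    def test_missing_state_lists_it(self):
        with pytest.raises(CompletenessError, match="q=\\+1"):
            compute_redox({(0, 0, "solution"): doc("red", G=-100.0,
                                                   phase="solution")},
                          self._spec())

    def test_pcet_outputs_pka_when_proton_g_supplied(self):
        spec = RedoxTreeSpec(method="pcet", directions=("reduction",),
                             phases=("solution",), n_electrons=1, h_sites=(0,),
                             proton_free_energy=-0.1)
        docs = {
            (0, 0, "solution"): doc("ref", G=-100.0, phase="solution"),
            (-1, 0, "solution"): doc("red", G=-100.1, charge=-1,
                                     phase="solution"),
            (1, 1, "solution"): doc("prot", G=-100.15, charge=1, n_h=1,
                                    phase="solution"),
            (0, 1, "solution"): doc("prot-red", G=-100.3, charge=0, n_h=1,
                                    phase="solution"),
        }
        res = compute_redox(docs, spec)
        label = "q+1_h1->q+0_h0"
        assert label in res.pka
        expected = compute_pka(docs[(1, 1, "solution")],
                               docs[(0, 0, "solution")], -0.1)
        assert res.pka[label] == pytest.approx(expected, rel=1e-12)
        assert res.deprotonation_dg_ev[label] == pytest.approx(
            (-100.0 - (-100.15)) * c.HARTREE_EV, rel=1e-12
        )

    def test_gas_phase_ip(self):
        spec = RedoxTreeSpec(method="adiabatic", directions=("oxidation",),
                             phases=("gas",))
        docs = {
            (0, 0, "gas"): doc("ref", G=-100.0),
            (1, 0, "gas"): doc("ox", G=-99.7, charge=1),
        }
        res = compute_redox(docs, spec)
        assert res.ip_ev == pytest.approx(0.3 * c.HARTREE_EV, rel=1e-12)


class TestPKa:
    def test_rt_ln10_normalization(self):
        # dG = 1.36449 kcal/mol at 298.15 K corresponds to pKa = 1.000
        dg_ha = 1.36449 * 4184.0 / c.N_A / c.HARTREE_J
        prot = doc("HA", G=-100.0, phase="solution")
        deprot = doc("A-", G=-100.0 + dg_ha, charge=-1, phase="solution")
        assert compute_pka(prot, deprot, 0.0) == pytest.approx(1.000, abs=1e-3)

    def test_zero_dg_gives_zero(self):
        prot = doc("HA", G=-100.0, phase="solution")
        deprot = doc("A-", G=-100.0, charge=-1, phase="solution")
        assert compute_pka(prot, deprot, 0.0) == 0.0

    def test_linearity_in_dg(self):
        prot = doc("HA", G=-100.0, phase="solution")
        d1 = doc("A-", G=-99.99, charge=-1, phase="solution")
        d2 = doc("A-", G=-99.98, charge=-1, phase="solution")
        assert compute_pka(prot, d2, 0.0) == pytest.approx(
            2 * compute_pka(prot, d1, 0.0), rel=1e-12
        )

    def test_gas_phase_rejected(self):
        with pytest.raises(PhaseError):
            compute_pka(doc("HA", G=-100.0), doc("A-", G=-99.9, charge=-1),
                        0.0)


class TestChemicalShift:
    def test_equal_shieldings_give_zero(self):
        assert chemical_shift(190.0, 190.0) == 0.0

    def test_forced_arithmetic(self):
        assert chemical_shift(60.0, 190.0) == 130.0

    @given(st.floats(-500, 500), st.floats(-500, 500))
    def test_antisymmetry(self, a, b):
        assert chemical_shift(a, b) == -chemical_shift(b, a)

    def test_nucleus_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            chemical_shift(Shielding("13C", 60.0), Shielding("1H", 30.0))

    def test_matching_nuclei_accepted(self):
        assert chemical_shift(Shielding("13C", 60.0),
                              Shielding("13C", 190.0)) == 130.0
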