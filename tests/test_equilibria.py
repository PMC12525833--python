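"""Model assembly and mass-balance speciation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import aquaspec as aq
from aquaspec.equilibria import ModelError

from conftest import oracle_fixed_ph

GOLDEN = (-1 + np.sqrt(5.0)) / 2000.0  # free M = free L of the quadratic toy


class TestAssembly:
    def test_charges_computed_and_validated(self):
        comps = [aq.Component("H", 1, "proton"),
                 aq.Component("Cu", 2, "metal"),
                 aq.Component("PEA", -2, "ligand")]
        model = aq.assemble_model(
            comps,
            [aq.SpeciesDef("ML", {"Cu": 1, "PEA": 1}, 5.63),
             aq.SpeciesDef("M2L(OH)2", {"Cu": 2, "PEA": 1, "H": -2}, -4.55)],
            25, 0.15, pKw=13.75)
        assert len(model.species) == 2
        assert model.species_by_label("ML").charge == 0
        assert model.species_by_label("M2L(OH)2").charge == 0

    def test_empty_species_list_gives_components_only(self):
        model = aq.assemble_model([aq.Component("Cu", 2, "metal")], [], 25, 0.15)
        assert model.species == ()

    def test_undeclared_component_rejected(self):
        with pytest.raises(ModelError, match="Mg"):
            aq.assemble_model(
                [aq.Component("Cu", 2, "metal")],
                [aq.SpeciesDef("MgL", {"Mg": 1}, 1.0)], 25, 0.15)

    def test_duplicate_labels_rejected(self):
        comps = [aq.Component("Cu", 2, "metal")]
        sp = [aq.SpeciesDef("X", {"Cu": 1}, 1.0),
              aq.SpeciesDef("X", {"Cu": 2}, 2.0)]
        with pytest.raises(ModelError, match="duplicate"):
            aq.assemble_model(comps, sp, 25, 0.15)

    def test_nonfinite_logbeta_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            aq.SpeciesDef("ML", {"Cu": 1}, float("nan"))

    def test_hydroxo_index_range_enforced_for_metal_species(self):
        comps = [aq.Component("H", 1, "proton"), aq.Component("Cu", 2, "metal")]
        with pytest.raises(ModelError, match="outside"):
            aq.assemble_model(
                comps, [aq.SpeciesDef("bad", {"Cu": 1, "H": -5}, -50.0)], 25, 0.15)
        # ligand protonation beyond r = +1 stays legal (e.g. LH3+)
        comps = [aq.Component("H", 1, "proton"), aq.Component("L", -2, "ligand")]
        m = aq.assemble_model(
            comps, [aq.SpeciesDef("LH3", {"L": 1, "H": 3}, 17.0)], 25, 0.15)
        assert m.species_by_label("LH3").charge == 1


class TestSolve:
    def test_quadratic_toy_closed_form(self, simple_ml_model):
        """M + L = ML, logK 3, both totals 1 mM: the mass balance is a
        quadratic with free M = free L = (sqrt(5)-1)/2000."""
        res = aq.solve_speciation(
            simple_ml_model,
            aq.SolutionSpec(totals={"M": 1e-3, "L": 1e-3}, fixed_pH=7.0))
        assert res.converged
        assert res.free["M"] == pytest.approx(GOLDEN, rel=1e-9)
        assert res.free["L"] == pytest.approx(GOLDEN, rel=1e-9)
        assert res.species_conc["ML"] == pytest.approx(1e-3 - GOLDEN, rel=1e-9)

    def test_no_complexes_free_equals_totals(self):
        model = aq.assemble_model(
            [aq.Component("Cu", 2, "metal"), aq.Component("Na", 1)], [], 25, 0.15)
        res = aq.solve_speciation(
            model, aq.SolutionSpec(totals={"Cu": 2e-3, "Na": 0.1}, fixed_pH=7.0))
        assert res.free["Cu"] == 2e-3
        assert res.free["Na"] == 0.1

    def test_binuclear_hydroxo_dominates_at_physiological_pH(self, cu_pea_37):
        """Cu-PEA at C_M 2 mM / C_L 4 mM, 37 degC, pH 7.4: the dimer
        Cu2L(OH)2 holds ~80% of copper."""
        res = aq.solve_speciation(
            cu_pea_37,
            aq.SolutionSpec(totals={"Cu": 2e-3, "PEA": 4e-3, "Cl": 0.15},
                            fixed_pH=7.4))
        assert res.percent_of[("M2L(OH)2", "Cu")] == pytest.approx(80.0, abs=5.0)

    def test_zero_total_component_gives_zero_free(self, cu_pea_37):
        res = aq.solve_speciation(
            cu_pea_37,
            aq.SolutionSpec(totals={"Cu": 1e-3, "PEA": 0.0, "Cl": 0.15},
                            fixed_pH=7.0))
        assert res.free["PEA"] == 0.0
        assert res.species_conc["ML"] == 0.0
        assert res.converged

    @pytest.mark.parametrize("ph", [4.0, 7.4, 9.5])
    def test_solver_agrees_with_bisection_oracle(self, ph):
        """Newton solution vs nested-bisection oracle on a chloride-free
        Zn-PEA model (one metal, one ligand, fixed pH)."""
        model = aq.packaged_model("Zn", "PEA", 25, 0.15, include_chloride=False)
        totals = {"Zn": 1.5e-3, "PEA": 3e-3}
        res = aq.solve_speciation(
            model, aq.SolutionSpec(totals=totals, fixed_pH=ph))
        m_ref, l_ref = oracle_fixed_ph(model, totals, ph)
        assert res.free["Zn"] == pytest.approx(m_ref, rel=1e-6)
        assert res.free["PEA"] == pytest.approx(l_ref, rel=1e-6)

    def test_full_proton_balance_strong_acid(self):
        """With only H as component, T_H = 5 mM gives [H] from the
        charge balance [H] - Kw/[H] = C."""
        model = aq.assemble_model([aq.Component("H", 1, "proton")], [],
                                  25, 0.15, pKw=13.75)
        res = aq.solve_speciation(model, aq.SolutionSpec(totals={"H": 5e-3}))
        c = 5e-3
        kw = 10**-13.75
        expect = 0.5 * (c + np.sqrt(c * c + 4 * kw))
        assert res.free["H"] == pytest.approx(expect, rel=1e-10)
        # excess base: T_H negative
        res = aq.solve_speciation(model, aq.SolutionSpec(totals={"H": -1e-3}))
        assert -np.log10(res.free["H"]) == pytest.approx(13.75 - 3.0, abs=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(cm=st.floats(1e-4, 5e-3), cl=st.floats(1e-4, 8e-3),
           ph=st.floats(2.5, 10.5))
    def test_mass_balance_residual_property(self, cm, cl, ph):
        """Relative mass-balance error stays below 1e-10 across random
        conditions of the Cu-PEA model."""
        model = aq.packaged_model("Cu", "PEA", 25, 0.15)
        res = aq.solve_speciation(
            model, aq.SolutionSpec(totals={"Cu": cm, "PEA": cl, "Cl": 0.15},
                                   fixed_pH=ph))
        assert res.converged
        assert res.residual <= 1e-10

    def test_mononuclear_distribution_independent_of_metal_total(self, zn_pea_25):
        """Every Zn-PEA complex is 1:1 in the metal, so each metal ion
        partitions independently: scaling the metal total by 1e-6 leaves
        the metal percentage distribution unchanged (ligand-depletion
        terms are second order and vanish at trace metal)."""
        t1 = {"Zn": 1e-12, "PEA": 4e-3, "Cl": 0.15}
        t2 = {"Zn": 1e-15, "PEA": 4e-3, "Cl": 0.15}
        r1 = aq.solve_speciation(zn_pea_25, aq.SolutionSpec(totals=t1, fixed_pH=7.0))
        r2 = aq.solve_speciation(zn_pea_25, aq.SolutionSpec(totals=t2, fixed_pH=7.0))
        for key, val in r1.percent_of.items():
            if key[1] == "Zn":
                assert r2.percent_of[key] == pytest.approx(val, abs=1e-6)

    def test_binuclear_share_grows_with_metal_total(self, cu_pea_37):
        """Contrast: the Cu-PEA dimer is second order in copper, so its
        share rises with the metal total."""
        shares = []
        for cm in (2e-5, 2e-4, 2e-3):
            res = aq.solve_speciation(
                cu_pea_37, aq.SolutionSpec(
                    totals={"Cu": cm, "PEA": 4e-3, "Cl": 0.15}, fixed_pH=7.4))
            shares.append(res.percent_of[("M2L(OH)2", "Cu")])
        assert shares[0] < shares[1] < shares[2]

    def test_bound_fraction_monotone_in_ligand_total(self, cu_pea_25):
        """At fixed pH the complexed-metal fraction is non-decreasing in
        the total ligand concentration."""
        fractions = []
        for cl in [1e-4, 3e-4, 1e-3, 3e-3, 1e-2]:
            res = aq.solve_speciation(
                cu_pea_25,
                aq.SolutionSpec(totals={"Cu": 1e-3, "PEA": cl, "Cl": 0.15},
                                fixed_pH=6.5))
            bound = 1.0 - res.free["Cu"] / 1e-3
            fractions.append(bound)
        assert all(b >= a - 1e-12 for a, b in zip(fractions, fractions[1:]))


class TestPercentages:
    def test_quadratic_toy_percentages(self, simple_ml_model):
        res = aq.solve_speciation(
            simple_ml_model,
            aq.SolutionSpec(totals={"M": 1e-3, "L": 1e-3}, fixed_pH=7.0))
        table = aq.formation_percentages(res, "M")
        pct = dict(zip(table["species"], table["percent"]))
        assert pct["ML"] == pytest.approx(38.19660, abs=1e-3)
        assert pct["M"] == pytest.approx(61.80340, abs=1e-3)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-8)

    def test_zero_total_reference_rejected(self, simple_ml_model):
        res = aq.solve_speciation(
            simple_ml_model,
            aq.SolutionSpec(totals={"M": 1e-3, "L": 1e-3}, fixed_pH=7.0))
        with pytest.raises(ValueError, match="zero total"):
            aq.formation_percentages(res, "H")

    def test_zn_pea_protonated_complex_dominates_mid_pH(self):
        """The Zn-PEA MLH+ complex is the leading species between pH 4
        and 8 at 37 degC (its exact ceiling depends on the externally
        estimated second ligand protonation constant)."""
        model = aq.packaged_model("Zn", "PEA", 37, 0.15)
        best = 0.0
        for ph in np.arange(4.0, 8.0001, 0.1):
            res = aq.solve_speciation(
                model, aq.SolutionSpec(
                    totals={"Zn": 2e-3, "PEA": 4e-3, "Cl": 0.15},
                    fixed_pH=float(ph)))
            best = max(best, res.percent_of[("MLH", "Zn")])
        assert best > 55.0

    def test_zn_ppc_ml_maximum_near_45_percent(self):
        model = aq.packaged_model("Zn", "PPC", 37, 0.15)
        best = 0.0
        for ph in np.arange(4.0, 7.5001, 0.1):
            res = aq.solve_speciation(
                model, aq.SolutionSpec(
                    totals={"Zn": 2e-3, "PPC": 4e-3, "Cl": 0.15},
                    fixed_pH=float(ph)))
            best = max(best, res.percent_of[("ML", "Zn")])
        assert best == pytest.approx(45.0, abs=5.0)


class TestBackDerive:
    @pytest.mark.parametrize("logbeta, logk, kind, expect", [
        (12.32, 2.18, "protonated", 10.14),    # Zn-PEA MLH -> PEA LH
        (-12.55, 4.55, "hydrolyzed", -17.10),  # Zn-PEA ML(OH)2 -> Zn(OH)2
        (-4.55, 6.17, "hydrolyzed", -10.72),   # Cu-PEA M2L(OH)2 -> Cu2(OH)2
    ])
    def test_overall_minus_stepwise_identity(self, logbeta, logk, kind, expect):
        assert aq.back_derive_auxiliary(logbeta, logk, kind) == pytest.approx(expect)

    def test_unknown_reaction_kind_rejected(self):
        with pytest.raises(ValueError, match="reaction_kind"):
            aq.back_derive_auxiliary(1.0, 0.5, "weird")
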