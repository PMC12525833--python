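"""Titration simulation, electrode calibration and e.m.f. refinement."""

import numpy as np
import pytest

import aquaspec as aq
from aquaspec import synthetic as syn
from aquaspec.potentiometry import nernst_slope


@pytest.fixture(scope="module")
def acid_model():
    return aq.assemble_model([aq.Component("H", 1, "proton")], [],
                             25, 0.15, pKw=13.75)


@pytest.fixture(scope="module")
def acid_protocol():
    return aq.TitrationProtocol(
        initial_volume=0.025,
        initial_totals={"H": 5e-3},
        titrant=aq.Titrant("OH", 0.1),
        volumes=tuple(np.round(np.linspace(0.05, 2.4, 50), 4)),
        temperature=25.0)


@pytest.fixture(scope="module")
def truth_calib():
    return aq.ElectrodeCalibration(E0=380.0, pKw=13.75)


class TestSimulate:
    def test_strong_acid_first_point_matches_charge_balance(
            self, acid_model, acid_protocol, truth_calib):
        curve = aq.simulate_titration(acid_model, acid_protocol, truth_calib)
        v0 = acid_protocol.volumes[0]
        c = acid_protocol.totals_at(v0)["H"]
        h = 0.5 * (c + np.sqrt(c * c + 4 * 10**-13.75))
        assert curve.emf[0] == pytest.approx(
            380.0 + nernst_slope(25.0) * np.log10(h), abs=1e-8)

    def test_equivalence_inflection(self, acid_model, acid_protocol, truth_calib):
        """e.m.f. falls fastest at the equivalence volume (1.25 mL for
        5 mM acid in 25 mL vs 0.1 M base)."""
        curve = aq.simulate_titration(acid_model, acid_protocol, truth_calib)
        dE = np.diff(curve.emf) / np.diff(curve.volumes)
        v_mid = 0.5 * (np.array(curve.volumes[1:]) + np.array(curve.volumes[:-1]))
        assert v_mid[np.argmin(dE)] == pytest.approx(1.25, abs=0.1)

    def test_empty_volume_list_single_point(self, acid_model, truth_calib):
        prot = aq.TitrationProtocol(0.025, {"H": 5e-3}, aq.Titrant("OH", 0.1),
                                    (), 25.0)
        curve = aq.simulate_titration(acid_model, prot, truth_calib)
        assert len(curve.emf) == 1

    def test_cu_pea_titration_monotone_pH(self, truth_calib):
        """pH rises monotonically with added base across the Cu-PEA
        protocol window."""
        bundle = syn.packaged_scenario("Cu", "PEA", 25, 0.15, n_points=40)
        curve = aq.simulate_titration(bundle.model, bundle.protocols[0],
                                      truth_calib)
        pH = (truth_calib.E0 - np.array(curve.emf)) / nernst_slope(25.0)
        assert np.all(np.diff(pH) > 0)
        assert pH[0] < 3.0 and pH[-1] > 9.5

    def test_non_nernstian_slope_rejected(self, acid_model, acid_protocol):
        bad = aq.ElectrodeCalibration(E0=380.0, slope=45.0, pKw=13.75)
        with pytest.raises(ValueError, match="Nernstian"):
            aq.simulate_titration(acid_model, acid_protocol, bad)

    def test_decreasing_volumes_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            aq.TitrationProtocol(0.025, {"H": 5e-3}, aq.Titrant("OH", 0.1),
                                 (0.2, 0.1), 25.0)


class TestCalibrate:
    def test_noiseless_round_trip(self, acid_model, acid_protocol, truth_calib):
        curve = aq.simulate_titration(acid_model, acid_protocol, truth_calib)
        cal = aq.calibrate_electrode(curve)
        assert cal.E0 == pytest.approx(380.0, abs=1e-6)
        assert cal.pKw == pytest.approx(13.75, abs=1e-6)

    def test_noisy_estimates_cluster_on_truth(self, acid_model, acid_protocol,
                                              truth_calib):
        """Monte-Carlo over 100 seeds at sigma_E = 0.15 mV: at least 95%
        of E0 estimates fall within 3 empirical standard errors of the
        truth (and the scatter itself is sub-0.1 mV)."""
        clean = aq.simulate_titration(acid_model, acid_protocol, truth_calib)
        base = np.array(clean.emf)
        est = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = aq.TitrationCurve(
                protocol=acid_protocol, volumes=clean.volumes,
                emf=tuple(base + rng.normal(0, 0.15, len(base))),
                sigma_E=0.15, sigma_V=0.0)
            est.append(aq.calibrate_electrode(noisy).E0)
        est = np.array(est)
        se = est.std(ddof=1)
        assert se < 0.1
        coverage = np.mean(np.abs(est - 380.0) < 3 * se)
        assert coverage >= 0.95

    def test_acid_branch_only_unidentifiable(self, acid_model, truth_calib):
        prot = aq.TitrationProtocol(0.025, {"H": 5e-3}, aq.Titrant("OH", 0.1),
                                    tuple(np.linspace(0.05, 1.0, 20)), 25.0)
        curve = aq.simulate_titration(acid_model, prot, truth_calib)
        with pytest.raises(ValueError, match="alkaline"):
            aq.calibrate_electrode(curve)


class TestRefine:
    @pytest.mark.parametrize("metal,ligand", [
        ("Cu", "PEA"), ("Cu", "PPC"), ("Zn", "PEA"), ("Zn", "PPC")])
    def test_noiseless_round_trip_every_packaged_model(self, metal, ligand):
        """refine(simulate(theta)) returns theta to 1e-4 at zero noise,
        starting from constants displaced by 0.3 log units."""
        bundle = syn.packaged_scenario(metal, ligand, 25, 0.15, n_points=80)
        calib = syn.DEFAULT_CALIBRATION
        curves = [syn.make_synthetic_titration(
            bundle, syn.NoiseSpec(0, 0, 0, None), i)
            for i in range(len(bundle.protocols))]
        start = {k: v + 0.3 for k, v in bundle.truth.items()}
        result = aq.refine_formation_constants(
            curves, bundle.model.with_logbetas(start),
            list(bundle.truth), calib)
        assert result.converged
        for label, true in bundle.truth.items():
            assert result.refined[label][0] == pytest.approx(true, abs=1e-4)

    def test_standard_errors_shrink_with_point_count(self):
        """Asymptotic standard deviations scale roughly as 1/sqrt(n)."""
        calib = syn.DEFAULT_CALIBRATION
        sds = {}
        for n in (40, 160):
            bundle = syn.packaged_scenario("Cu", "PEA", 25, 0.15, n_points=n)
            curves = [syn.make_synthetic_titration(
                bundle, syn.NoiseSpec(seed=11 + i), i) for i in range(3)]
            r = aq.refine_formation_constants(
                curves, bundle.model, ["ML", "M2L(OH)2"], calib,
                propagate_sigma_V=True)
            sds[n] = r.refined["ML"][1]
        ratio = sds[40] / sds[160]
        assert ratio == pytest.approx(2.0, rel=0.5)

    def test_unformed_species_raises_singularity(self):
        """A species that never forms in the titration window leaves a
        singular normal matrix and must be named in the error."""
        bundle = syn.packaged_scenario("Cu", "PEA", 25, 0.15, n_points=30)
        model = aq.assemble_model(
            bundle.model.components,
            list(bundle.model.species) + [
                aq.SpeciesDef("ML2", {"Cu": 1, "PEA": 2}, -25.0)],
            25, 0.15, pKw=bundle.model.pKw)
        curves = [syn.make_synthetic_titration(
            bundle, syn.NoiseSpec(0, 0, 0, None), 0)]
        curves = [aq.TitrationCurve(protocol=c.protocol, volumes=c.volumes,
                                    emf=c.emf, sigma_E=0.15, sigma_V=0.0)
                  for c in curves]
        with pytest.raises(np.linalg.LinAlgError, match="ML2"):
            aq.refine_formation_constants(
                curves, model, ["ML", "ML2"], syn.DEFAULT_CALIBRATION)

    def test_unknown_free_parameter_rejected(self):
        bundle = syn.packaged_scenario("Cu", "PEA", 25, 0.15, n_points=10)
        curve = syn.make_synthetic_titration(bundle, syn.NoiseSpec(0, 0, 0, None))
        with pytest.raises(KeyError, match="nope"):
            aq.refine_formation_constants(
                [curve], bundle.model, ["nope"], syn.DEFAULT_CALIBRATION)
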