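"""Ground-truth-known synthetic titrations and shift curves.

Every generator is a pure function of its inputs plus a seed: the same
(bundle, noise) pair always yields byte-identical data.  Noise follows
the stated instrument accuracies of automated potentiometric benches —
sigma_E = 0.15 mV on the e.m.f. and sigma_V = 0.002 mL on delivered
volume — and 0.002 ppm on chemical shifts.  Volume noise perturbs the
*delivered* volume before the speciation solve while the recorded
abscissa stays nominal, exactly how a burette error enters real data.

The packaged scenarios rebuild the study systems (Cu/Zn x PEA/PPC) from
the printed constants so refinement code can be exercised against known
truth without any deposited data.  The per-species NMR shifts packaged
here are synthetic: they are chosen so the free-ligand endpoint shifts
match the reported spectra, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import constants
from .equilibria import EquilibriumModel
from .nmr import ShiftTitration, SpeciesShifts, predict_observed_shifts
from .potentiometry import (ElectrodeCalibration, TitrationCurve,
                            TitrationProtocol, Titrant, nernst_slope,
                            simulate_titration)

__all__ = [
    "NoiseSpec", "ScenarioBundle",
    "packaged_constants", "packaged_scenario", "default_protocols",
    "make_synthetic_titration", "make_synthetic_shift_titration",
    "PEA_FREE_LIGAND_SHIFTS", "PPC_FREE_LIGAND_SHIFTS",
    "ZN_PEA_COMPLEX_SHIFTS", "DEFAULT_CALIBRATION",
]

packaged_constants = constants.packaged_constants

#: default electrode truth used by the generators (E0 mV; Nernstian slope)
DEFAULT_CALIBRATION = ElectrodeCalibration(E0=380.0)


@dataclass(frozen=True)
class NoiseSpec:
    sigma_E: float = 0.15      # mV
    sigma_V: float = 0.002     # mL
    sigma_delta: float = 0.002  # ppm
    seed: int | None = None

    def __post_init__(self):
        if min(self.sigma_E, self.sigma_V, self.sigma_delta) < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.seed is None and (self.sigma_E > 0 or self.sigma_V > 0
                                  or self.sigma_delta > 0):
            raise ValueError("a seed is mandatory whenever any sigma is nonzero")


@dataclass(frozen=True)
class ScenarioBundle:
    model: EquilibriumModel
    truth: Mapping[str, float]           # species -> true logbeta
    protocols: tuple[TitrationProtocol, ...]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "truth", dict(self.truth))
        object.__setattr__(self, "provenance", dict(self.provenance))
        labels = {s.label for s in self.model.species}
        extra = set(self.truth) - labels
        if extra:
            raise ValueError(f"truth refers to unknown species {sorted(extra)}")


def default_protocols(metal: str, ligand: str, temperature: float,
                      ionic_strength: float, n_points: int = 80,
                      titrant_conc: float = 0.1) -> tuple[TitrationProtocol, ...]:
    """Five NaOH titrations spanning the study's concentration design:
    metal 1-2 mmol/L, ligand 1-4 mmol/L, metal:ligand 0.33-1, HCl 2-8
    mmol/L, 25 mL starting volume.

    The proton total counts the two (PEA) or one (PPC) protons the
    zwitterionic ligand carries when dissolved, on top of the HCl.
    Refining several correlated constants (protonated plus two hydroxo
    complexes) needs the full spread of metal:ligand ratios — a narrow
    design leaves the e.m.f. objective multimodal.
    """
    nH = 2 if ligand == "PEA" else 1
    designs = [(1e-3, 3e-3, 6e-3), (2e-3, 4e-3, 8e-3), (1e-3, 1e-3, 2e-3),
               (2e-3, 2e-3, 5e-3), (1.5e-3, 4e-3, 8e-3)]
    protocols = []
    for cm, cl, ch in designs:
        th = ch + nH * cl
        # enough base for the mineral acid, ligand protons and metal hydroxide
        vmax = 1000 * 0.025 * (th + 2 * cm) / titrant_conc
        vols = np.round(np.linspace(0.02, 0.96 * vmax, n_points), 4)
        protocols.append(TitrationProtocol(
            initial_volume=0.025,
            initial_totals={metal: cm, ligand: cl, "H": th,
                            "Cl": ionic_strength},
            titrant=Titrant("OH", titrant_conc),
            volumes=tuple(vols),
            temperature=temperature,
            ionic_strength=ionic_strength,
        ))
    return tuple(protocols)


def packaged_scenario(metal: str, ligand: str, temperature: float = 25.0,
                   ionic_strength: float = 0.15, n_points: int = 80,
                   ) -> ScenarioBundle:
    """Full refinement scenario for one study system at a printed (T, I)."""
    model = constants.packaged_model(metal, ligand, temperature, ionic_strength)
    truth = {s.label: s.logbeta for s in
             constants.packaged_constants(metal, ligand, temperature,
                                                ionic_strength)}
    return ScenarioBundle(
        model=model,
        truth=truth,
        protocols=default_protocols(metal, ligand, temperature,
                                    ionic_strength, n_points),
        provenance={s.label: s.source for s in model.species},
    )


def make_synthetic_titration(bundle: ScenarioBundle, noise: NoiseSpec,
                             protocol_index: int = 0,
                             calib: ElectrodeCalibration = DEFAULT_CALIBRATION,
                             ) -> TitrationCurve:
    """Simulate one protocol and apply seeded Gaussian noise.

    Draw order is fixed (volumes first, then e.m.f.) so identical seeds
    give identical curves.
    """
    protocol = bundle.protocols[protocol_index]
    rng = np.random.default_rng(noise.seed)
    nominal = np.asarray(protocol.volumes)
    delivered = nominal.copy()
    if noise.sigma_V > 0:
        delivered = delivered + rng.normal(0.0, noise.sigma_V, len(nominal))
        # a burette cannot withdraw: keep the delivered series strictly
        # increasing (ties broken at the nanolitre level)
        delivered = np.maximum.accumulate(np.maximum(delivered, 1e-6))
        delivered = delivered + np.arange(len(delivered)) * 1e-9
    clean = simulate_titration(
        bundle.model,
        TitrationProtocol(
            initial_volume=protocol.initial_volume,
            initial_totals=protocol.initial_totals,
            titrant=protocol.titrant,
            volumes=tuple(delivered),
            temperature=protocol.temperature,
            ionic_strength=protocol.ionic_strength),
        calib)
    emf = np.asarray(clean.emf)
    if noise.sigma_E > 0:
        emf = emf + rng.normal(0.0, noise.sigma_E, len(emf))
    return TitrationCurve(protocol=protocol, volumes=protocol.volumes,
                          emf=tuple(float(e) for e in emf),
                          sigma_E=noise.sigma_E, sigma_V=noise.sigma_V)


def make_synthetic_shift_titration(
    bundle: ScenarioBundle,
    nuclei: Sequence[str],
    truth_shifts: SpeciesShifts,
    noise: NoiseSpec,
    pH_grid: Sequence[float],
    totals: Mapping[str, float],
) -> ShiftTitration:
    """Fast-exchange shift titration with seeded Gaussian delta-noise."""
    pH = tuple(float(p) for p in pH_grid)
    if len(pH) == 0:
        return ShiftTitration(pH=(), observed={n: () for n in nuclei},
                              totals=totals,
                              temperature=bundle.model.temperature,
                              ionic_strength=bundle.model.ionic_strength,
                              sigma_delta=noise.sigma_delta)
    clean = predict_observed_shifts(bundle.model, truth_shifts, pH, totals)
    rng = np.random.default_rng(noise.seed)
    observed = {}
    for nuc in nuclei:
        vals = np.asarray(clean[nuc])
        if noise.sigma_delta > 0:
            vals = vals + rng.normal(0.0, noise.sigma_delta, len(vals))
        observed[nuc] = tuple(float(v) for v in vals)
    return ShiftTitration(pH=pH, observed=observed, totals=totals,
                          temperature=bundle.model.temperature,
                          ionic_strength=bundle.model.ionic_strength,
                          sigma_delta=noise.sigma_delta)


# ---------------------------------------------------------------------------
# synthetic per-species shifts (ppm).  Chosen so the noiseless free-ligand
# titrations reproduce the reported endpoint shifts: PEA CH2(1) 4.05 -> 3.73
# and CH2(2) 3.22 -> 2.79 over pH 1.67-11.00; PPC CH2(1) 4.24 -> 4.10 and
# CH2(2) 3.60 -> 3.53 over pH 1.90-10.00 with a pH-invariant N(CH3)3 singlet
# at 3.16.  These are constructed values, not measurements.
# ---------------------------------------------------------------------------

PEA_FREE_LIGAND_SHIFTS = SpeciesShifts(
    nuclei=("CH2(1)", "CH2(2)"),
    delta={
        ("PEA", "CH2(1)"): 3.72, ("PEAH", "CH2(1)"): 3.78,
        ("PEAH2", "CH2(1)"): 4.05, ("PEAH3", "CH2(1)"): 4.06,
        ("PEA", "CH2(2)"): 2.785, ("PEAH", "CH2(2)"): 2.83,
        ("PEAH2", "CH2(2)"): 3.22, ("PEAH3", "CH2(2)"): 3.22,
    },
)

PPC_FREE_LIGAND_SHIFTS = SpeciesShifts(
    nuclei=("CH2(1)", "CH2(2)", "N(CH3)3"),
    delta={
        ("PPC", "CH2(1)"): 4.10, ("PPCH", "CH2(1)"): 4.235,
        ("PPCH2", "CH2(1)"): 4.27,
        ("PPC", "CH2(2)"): 3.53, ("PPCH", "CH2(2)"): 3.595,
        ("PPCH2", "CH2(2)"): 3.63,
        ("PPC", "N(CH3)3"): 3.16, ("PPCH", "N(CH3)3"): 3.16,
        ("PPCH2", "N(CH3)3"): 3.16,
    },
)

#: synthetic shifts of the Zn-PEA complexes (deshielded CH2 envelopes in
#: the reported 3.7-4.6 / 2.7-3.6 ppm windows)
ZN_PEA_COMPLEX_SHIFTS = SpeciesShifts(
    nuclei=("CH2(1)", "CH2(2)"),
    delta={
        **PEA_FREE_LIGAND_SHIFTS.delta,
        ("MLH", "CH2(1)"): 4.10, ("ML", "CH2(1)"): 4.25,
        ("MLOH", "CH2(1)"): 4.40, ("ML(OH)2", "CH2(1)"): 4.55,
        ("MLH", "CH2(2)"): 3.00, ("ML", "CH2(2)"): 3.20,
        ("MLOH", "CH2(2)"): 3.40, ("ML(OH)2", "CH2(2)"): 3.55,
    },
)
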