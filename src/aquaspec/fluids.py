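"""Copper speciation in plasma and cerebrospinal-fluid compositions.

The module assembles a multi-component fixed-pH model of the major
inorganic matrix of human plasma or CSF (Na, K, Ca, Mg, Cl, carbonate,
phosphate) plus the phospholipid headgroup ligands PEA and PPC and,
optionally, the chelator d-penicillamine (PEN), and reports how total
copper partitions among free metal, inorganic side complexes and the
organic ligands.  The built-in compositions reflect Wilson's-disease
conditions (elevated non-ceruloplasmin copper) at pH 7.4, 37 degC,
I = 0.15 mol/L.

Fluids are treated as externally buffered: speciation is solved at
fixed pH rather than by a full proton balance.  The carbonate,
phosphate and alkaline-earth side equilibria are literature-style
auxiliary values (provenance ``external``); each report lists the
active auxiliaries so tolerance-based comparisons stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .constants import (LIGAND_CHARGE, auxiliary_species, pkw,
                        packaged_constants)
from .equilibria import (Component, EquilibriumModel, SolutionSpec,
                         SpeciesDef, assemble_model, solve_speciation)

__all__ = [
    "FluidComposition", "CompetitionReport",
    "builtin_fluid", "build_fluid_model", "simulate_fluid",
    "ligand_competition", "PEN_MOLAR_MASS", "PEN_PLASMA_UG_PER_L",
]

#: d-penicillamine molar mass, g/mol (overridable in ligand_competition)
PEN_MOLAR_MASS = 149.21
#: plasma PEN concentration after an 800 mg oral dose, ug/L
PEN_PLASMA_UG_PER_L = 28.0

_BUILTIN: dict[str, dict[str, float]] = {
    # mol/L; carbonate totals entered on the CO3 component, phosphate on PO4
    "plasma_WD": {
        "Na": 142e-3, "K": 4.6e-3, "Ca": 2.5e-3, "Mg": 0.9e-3,
        "Cl": 101e-3, "CO3": 24e-3, "PO4": 1.0e-3,
        "PEA": 1.70e-6, "PPC": 1.70e-6, "Cu": 3.2e-6,
    },
    "CSF_WD": {
        "Na": 141e-3, "K": 2.9e-3, "Ca": 1.25e-6, "Mg": 1.2e-6,
        "Cl": 124e-3, "CO3": 21e-3, "PO4": 0.15e-3,
        "PEA": 1e-6, "PPC": 1e-6, "Cu": 1.6e-6,
    },
}


@dataclass(frozen=True)
class FluidComposition:
    name: str
    totals: Mapping[str, float]
    pH: float = 7.4
    temperature: float = 37.0
    ionic_strength: float = 0.15

    def __post_init__(self):
        object.__setattr__(self, "totals", dict(self.totals))
        for k, v in self.totals.items():
            if v < 0:
                raise ValueError(f"negative total for {k!r}")


def builtin_fluid(name: str) -> FluidComposition:
    """One of the packaged Wilson's-disease fluid compositions."""
    if name not in _BUILTIN:
        raise KeyError(
            f"unknown fluid {name!r}; available: {sorted(_BUILTIN)}")
    return FluidComposition(name=name, totals=_BUILTIN[name])


# ---------------------------------------------------------------------------
# auxiliary matrix equilibria (all literature-style, provenance "external";
# 37 degC, I = 0.15 mol/L, concentration scale)
# ---------------------------------------------------------------------------

_MATRIX_SPECIES: list[SpeciesDef] = [
    # carbonate protonation (CO2(aq) folded into the second constant)
    SpeciesDef("HCO3", {"CO3": 1, "H": 1}, 9.85, source="external"),
    SpeciesDef("H2CO3", {"CO3": 1, "H": 2}, 15.95, source="external"),
    # phosphate protonation
    SpeciesDef("HPO4", {"PO4": 1, "H": 1}, 11.55, source="external"),
    SpeciesDef("H2PO4", {"PO4": 1, "H": 2}, 18.25, source="external"),
    SpeciesDef("H3PO4", {"PO4": 1, "H": 3}, 20.20, source="external"),
    # copper carbonato / phosphato complexes
    SpeciesDef("CuCO3", {"Cu": 1, "CO3": 1}, 5.50, source="external"),
    SpeciesDef("Cu(CO3)2", {"Cu": 1, "CO3": 2}, 8.90, source="external"),
    SpeciesDef("CuHPO4", {"Cu": 1, "PO4": 1, "H": 1}, 15.00, source="external"),
    # alkaline-earth buffering of carbonate/phosphate
    SpeciesDef("CaCO3", {"Ca": 1, "CO3": 1}, 3.10, source="external"),
    SpeciesDef("MgCO3", {"Mg": 1, "CO3": 1}, 2.90, source="external"),
    SpeciesDef("CaHCO3", {"Ca": 1, "CO3": 1, "H": 1}, 10.95, source="external"),
    SpeciesDef("MgHCO3", {"Mg": 1, "CO3": 1, "H": 1}, 10.90, source="external"),
    SpeciesDef("CaHPO4", {"Ca": 1, "PO4": 1, "H": 1}, 13.00, source="external"),
    SpeciesDef("MgHPO4", {"Mg": 1, "PO4": 1, "H": 1}, 13.10, source="external"),
    # headgroup binding of Mg (literature) — weak but present
    SpeciesDef("MgPEA", {"Mg": 1, "PEA": 1}, 2.00, source="external"),
    SpeciesDef("MgPPC", {"Mg": 1, "PPC": 1}, 1.60, source="external"),
]

_PEN_SPECIES: list[SpeciesDef] = [
    SpeciesDef("CuPEN", {"Cu": 1, "PEN": 1}, 9.5, source="external"),
    SpeciesDef("Cu(PEN)2", {"Cu": 1, "PEN": 2}, 16.9, source="external"),
]

_COMPONENTS = {
    "H": Component("H", 1, "proton"),
    "Cu": Component("Cu", 2, "metal"),
    "PEA": Component("PEA", -2, "ligand"),
    "PPC": Component("PPC", -1, "ligand"),
    "PEN": Component("PEN", -2, "ligand"),
    "Na": Component("Na", 1, "spectator"),
    "K": Component("K", 1, "spectator"),
    "Ca": Component("Ca", 2, "spectator"),
    "Mg": Component("Mg", 2, "spectator"),
    "Cl": Component("Cl", -1, "spectator"),
    "CO3": Component("CO3", -2, "spectator"),
    "PO4": Component("PO4", -3, "spectator"),
}


def build_fluid_model(fluid: FluidComposition,
                      ligands: Sequence[str] = ("PEA", "PPC"),
                      *, include_pen: bool = False,
                      pen_protonation: Sequence[SpeciesDef] | None = (),
                      ) -> EquilibriumModel:
    """Joint equilibrium model of the fluid matrix plus declared ligands.

    ``pen_protonation``: an empty tuple means "use the packaged external
    set"; ``None`` is rejected — silently assuming a fully deprotonated
    competitor would grossly overstate its binding.
    """
    t, i = fluid.temperature, fluid.ionic_strength
    species: list[SpeciesDef] = []
    for lig in ligands:
        try:
            complexes = packaged_constants("Cu", lig, t, i)
        except KeyError as exc:
            raise KeyError(
                f"no Cu-{lig} formation constants at ({t} degC, I={i}): {exc}"
            ) from exc
        # qualify generic labels (ML, M2L(OH)2) with the ligand name so
        # multi-ligand fluid models stay unambiguous
        species += [replace(s, label=f"{lig}:{s.label}") for s in complexes]
        species += auxiliary_species(None, lig, t, i)
    species += auxiliary_species("Cu", None, t, i)
    species += [s for s in _MATRIX_SPECIES
                if all(n in ("Cu", "H") or n in fluid.totals or n in ligands
                       for n in s.stoich)
                and all(n in ligands for n in s.stoich if n in LIGAND_CHARGE)]
    if include_pen:
        if pen_protonation is None:
            raise ValueError(
                "PEN protonation constants are required; refusing to model "
                "the competitor as fully deprotonated")
        species += list(_PEN_SPECIES)
        species += (list(pen_protonation) if pen_protonation
                    else auxiliary_species(None, "PEN", t, i))
    comps = [_COMPONENTS["H"], _COMPONENTS["Cu"]]
    comps += [_COMPONENTS[l] for l in ligands]
    if include_pen:
        comps.append(_COMPONENTS["PEN"])
    for name in ("Na", "K", "Ca", "Mg", "Cl", "CO3", "PO4"):
        if name in fluid.totals:
            comps.append(_COMPONENTS[name])
    return assemble_model(comps, species, t, i, pKw=pkw(t, i))


@dataclass
class CompetitionReport:
    fluid: str
    species_percent: dict[str, float]          # % of total metal, by species
    ligand_bound_percent: dict[str, float]     # % of total metal, by ligand
    free_metal_percent: float
    inorganic_percent: float                   # hydroxo/chloro/carbonato/...
    percent_of_complexed: dict[str, float]     # renormalised over bound metal
    active_auxiliaries: dict[str, str]         # species -> provenance
    conservation_error: float                  # |100 - sum| in points


def _report(model: EquilibriumModel, fluid: FluidComposition,
            ligands: Sequence[str], metal: str = "Cu") -> CompetitionReport:
    spec = SolutionSpec(totals=dict(fluid.totals), fixed_pH=fluid.pH)
    res = solve_speciation(model, spec, raise_on_failure=True)
    total = fluid.totals[metal]
    sp_pct: dict[str, float] = {}
    lig_pct = {l: 0.0 for l in ligands}
    inorganic = 0.0
    for s in model.species:
        p = s.stoich.get(metal, 0)
        if p <= 0:
            continue
        pct = 100.0 * p * res.species_conc[s.label] / total
        sp_pct[s.label] = pct
        owners = [l for l in ligands if s.stoich.get(l, 0) > 0]
        if owners:
            lig_pct[owners[0]] += pct
        else:
            inorganic += pct
    free_pct = 100.0 * res.free[metal] / total
    bound = sum(sp_pct.values())
    of_complexed = ({k: 100.0 * v / bound for k, v in sp_pct.items()}
                    if bound > 0 else {k: 0.0 for k in sp_pct})
    return CompetitionReport(
        fluid=fluid.name,
        species_percent=sp_pct,
        ligand_bound_percent=lig_pct,
        free_metal_percent=free_pct,
        inorganic_percent=inorganic,
        percent_of_complexed=of_complexed,
        active_auxiliaries={s.label: s.source for s in model.species
                            if s.source in ("external", "derived")},
        conservation_error=abs(100.0 - free_pct - bound),
    )


def simulate_fluid(fluid: FluidComposition,
                   ligands: Sequence[str] = ("PEA", "PPC"),
                   ) -> CompetitionReport:
    """Fixed-pH copper speciation in the fluid with the given ligands."""
    model = build_fluid_model(fluid, ligands)
    return _report(model, fluid, ligands)


def ligand_competition(fluid: FluidComposition,
                       ligands: Sequence[str] = ("PEA", "PPC"),
                       *, competitor_conc: float | None = None,
                       competitor_molar_mass: float = PEN_MOLAR_MASS,
                       pen_protonation: Sequence[SpeciesDef] | None = (),
                       ) -> CompetitionReport:
    """Add the PEN chelator to the fluid and re-run the speciation.

    ``competitor_conc`` in mol/L; the default converts the packaged
    28 ug/L therapeutic plasma level with the configured molar mass.
    """
    if competitor_conc is None:
        competitor_conc = PEN_PLASMA_UG_PER_L * 1e-6 / competitor_molar_mass
    model = build_fluid_model(fluid, ligands, include_pen=True,
                              pen_protonation=pen_protonation)
    totals = dict(fluid.totals)
    totals["PEN"] = competitor_conc
    fluid2 = FluidComposition(name=fluid.name, totals=totals, pH=fluid.pH,
                              temperature=fluid.temperature,
                              ionic_strength=fluid.ionic_strength)
    return _report(model, fluid2, list(ligands) + ["PEN"])
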