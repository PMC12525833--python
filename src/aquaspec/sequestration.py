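"""Sequestering-ability curves chi(pL) and the pL0.5 statistic.

chi is the fraction of a *trace* metal held in metal–ligand complexes
at fixed pH, temperature and ionic strength, as a function of
pL = -log10 of the total ligand concentration.  For mononuclear-only
binding the curve is the Boltzmann-type sigmoid

    chi = 1 / (1 + 10^(pL - pL0.5)),

and pL0.5 — the total ligand concentration sequestering half of the
trace metal — equals the log of the summed conditional constants.  The
statistic folds every side reaction (ligand protonation, metal
hydrolysis, chloride) into a single medium- and pH-aware measure of
effective binding strength.

The trace metal concentration defaults to 1e-12 mol/L; any value small
enough to keep binuclear species empty gives the same curve (see the
trace-limit test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .equilibria import EquilibriumModel, SolutionSpec, solve_speciation

__all__ = ["SequestrationCurve", "chi_of_pL", "estimate_pL05",
           "DEFAULT_PL_GRID", "TRACE_METAL_CONC"]

TRACE_METAL_CONC = 1e-12
DEFAULT_PL_GRID = np.round(np.arange(1.0, 12.0 + 1e-9, 0.02), 10)


@dataclass
class SequestrationCurve:
    pL: np.ndarray
    chi: np.ndarray
    pH: float
    temperature: float
    ionic_strength: float
    trace_metal_conc: float
    pL05: float | None = None         # logistic fit (the reported value)
    pL05_fit: float | None = None
    pL05_bisect: float | None = None  # direct chi = 0.5 root


def chi_of_pL(model: EquilibriumModel, pH: float,
              trace_metal_conc: float = TRACE_METAL_CONC,
              pL_grid: np.ndarray | None = None,
              background_totals: Mapping[str, float] | None = None,
              ) -> SequestrationCurve:
    """Bound-metal fraction chi over a pL grid at fixed pH.

    Every species containing both the metal and the ligand counts,
    weighted by its metal stoichiometry p.  ``background_totals``
    defaults to chloride at the medium concentration when the model
    declares a Cl component.
    """
    pL = np.asarray(DEFAULT_PL_GRID if pL_grid is None else pL_grid, dtype=float)
    metals = [c.name for c in model.components if c.role == "metal"]
    ligs = [c.name for c in model.components if c.role == "ligand"]
    if len(metals) != 1 or len(ligs) != 1:
        raise ValueError("chi(pL) needs exactly one metal and one ligand")
    metal, lig = metals[0], ligs[0]
    if background_totals is None:
        background_totals = (
            {"Cl": model.ionic_strength}
            if any(c.name == "Cl" for c in model.components) else {})

    both = [(s.label, s.stoich[metal]) for s in model.species
            if s.stoich.get(metal, 0) > 0 and s.stoich.get(lig, 0) > 0]

    chi = np.empty(len(pL))
    warm = None
    # sweep from high ligand (low pL) so warm starts track the sigmoid
    order = np.argsort(pL)
    for i in order:
        totals = {metal: trace_metal_conc, lig: 10.0 ** (-pL[i]),
                  **background_totals}
        res = solve_speciation(model, SolutionSpec(totals=totals, fixed_pH=pH),
                               x0=warm, raise_on_failure=False)
        if not res.converged:
            raise RuntimeError(
                f"speciation failed at pL = {pL[i]:.2f} "
                f"(residual {res.residual:.2e})")
        warm = {k: np.log10(f) for k, f in res.free.items() if f > 0}
        chi[i] = sum(p * res.species_conc[lab] for lab, p in both) / trace_metal_conc
    return SequestrationCurve(
        pL=pL, chi=chi, pH=float(pH), temperature=model.temperature,
        ionic_strength=model.ionic_strength,
        trace_metal_conc=float(trace_metal_conc))


def estimate_pL05(curve: SequestrationCurve) -> float:
    """pL0.5 by least-squares logistic fit, cross-checked by direct
    root-finding of chi = 0.5; both are stored on the curve and the fit
    value is returned."""
    pL, chi = curve.pL, curve.chi
    if chi.max() < 0.5 or chi.min() > 0.5:
        raise ValueError("chi never crosses 0.5 on the grid; widen the pL range")

    # bisection analogue: the curve is monotone non-increasing in pL
    k = int(np.argmax(chi < 0.5))  # first grid point below half
    if k == 0:
        raise ValueError("chi = 0.5 crossing is not bracketed by the grid")
    x0, x1 = pL[k - 1], pL[k]
    y0, y1 = chi[k - 1], chi[k]
    bisect = float(x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0))

    def resid(p):
        return 1.0 / (1.0 + 10.0 ** (pL - p[0])) - chi

    sol = least_squares(resid, [bisect], method="lm", xtol=1e-14, ftol=1e-14)
    fit = float(sol.x[0])
    curve.pL05_fit = fit
    curve.pL05_bisect = bisect
    curve.pL05 = fit
    return fit
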