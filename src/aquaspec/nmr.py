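"""Fast-exchange NMR shift modelling and joint constant/shift refinement.

Under fast mutual exchange every ligand environment contributes one
population-weighted resonance: the observed shift of a nucleus is the
ligand-mole-fraction average of the per-species shifts,

    delta_obs = sum_s x_s delta(s),   x_s = q_s [s] / C_L,

with q_s the ligand stoichiometry of species s (so binuclear M2L
species weigh by their single ligand, and metal-referenced weighting
would be wrong).  Free ligand protonation states count as species; the
fully deprotonated ligand is keyed by the component name.

Refinement is separable: for any trial set of formation constants the
shifts enter linearly and are solved exactly by linear least squares,
while the outer nonlinear iteration adjusts only the free log beta
values.  Minor-species constants stay fixed, mirroring standard
practice for shift titrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .equilibria import EquilibriumModel, SolutionSpec, solve_speciation

__all__ = [
    "SpeciesShifts",
    "ShiftTitration",
    "NmrRefinement",
    "ligand_mole_fractions",
    "predict_observed_shifts",
    "refine_shift_model",
]

#: a species is "populated" when its ligand mole fraction exceeds this
POPULATION_EPS = 1e-4


@dataclass(frozen=True)
class SpeciesShifts:
    """Per-species, per-nucleus chemical shifts (ppm)."""
    nuclei: tuple[str, ...]
    delta: Mapping[tuple[str, str], float]  # (species-label, nucleus) -> ppm

    def __post_init__(self):
        object.__setattr__(self, "delta", dict(self.delta))
        for (sp, nuc), v in self.delta.items():
            if nuc not in self.nuclei:
                raise ValueError(f"shift given for undeclared nucleus {nuc!r}")
            if not np.isfinite(v):
                raise ValueError(f"non-finite shift for ({sp}, {nuc})")


@dataclass(frozen=True)
class ShiftTitration:
    pH: tuple[float, ...]
    observed: Mapping[str, tuple[float, ...]]  # nucleus -> ppm per point
    totals: Mapping[str, float]                # analytical C_L (and C_M)
    temperature: float = 25.0
    ionic_strength: float = 0.15
    sigma_delta: float = 0.002

    def __post_init__(self):
        object.__setattr__(self, "observed",
                           {k: tuple(v) for k, v in self.observed.items()})
        object.__setattr__(self, "totals", dict(self.totals))
        p = np.asarray(self.pH)
        if len(p) > 1:
            d = np.diff(p)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("pH must be strictly monotone over the titration")
        for nuc, vals in self.observed.items():
            if len(vals) != len(self.pH):
                raise ValueError(f"nucleus {nuc!r}: {len(vals)} shifts for "
                                 f"{len(self.pH)} pH points")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite shift for nucleus {nuc!r}")


def _ligand_component(model: EquilibriumModel) -> str:
    lig = [c.name for c in model.components if c.role == "ligand"]
    if len(lig) != 1:
        raise ValueError("shift model requires exactly one ligand component")
    return lig[0]


def ligand_mole_fractions(model: EquilibriumModel, pH: Sequence[float],
                          totals: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    """Ligand species labels and their mole-fraction matrix x[point, species].

    The free deprotonated ligand is included under its component name.
    """
    lig = _ligand_component(model)
    CL = float(totals[lig])
    if CL <= 0:
        raise ValueError("ligand total must be positive")
    carriers = [(lig, 1)] + [(s.label, s.stoich[lig]) for s in model.species
                             if s.stoich.get(lig, 0) > 0]
    X = np.zeros((len(pH), len(carriers)))
    warm = None
    for i, p in enumerate(pH):
        res = solve_speciation(model, SolutionSpec(totals=totals, fixed_pH=float(p)),
                               x0=warm, raise_on_failure=True)
        warm = {k: np.log10(f) for k, f in res.free.items() if f > 0}
        for j, (label, q) in enumerate(carriers):
            conc = res.free[lig] if label == lig else res.species_conc[label]
            X[i, j] = q * conc / CL
    return [label for label, _ in carriers], X


def predict_observed_shifts(model: EquilibriumModel, shifts: SpeciesShifts,
                            pH: Sequence[float], totals: Mapping[str, float],
                            ) -> dict[str, np.ndarray]:
    """Fast-exchange observed shift per nucleus along a pH series."""
    labels, X = ligand_mole_fractions(model, pH, totals)
    out: dict[str, np.ndarray] = {}
    for nuc in shifts.nuclei:
        d = np.zeros(len(labels))
        for j, label in enumerate(labels):
            if (label, nuc) in shifts.delta:
                d[j] = shifts.delta[(label, nuc)]
            elif np.any(X[:, j] > POPULATION_EPS):
                raise KeyError(
                    f"species {label!r} is populated but has no shift for "
                    f"nucleus {nuc!r}")
        out[nuc] = X @ d
    return out


@dataclass
class NmrRefinement:
    logbetas: dict[str, tuple[float, float]]       # label -> (value, sd)
    deltas: dict[tuple[str, str], float]           # refined shifts
    fixed_logbetas: dict[str, float]
    variance: float
    model: EquilibriumModel
    converged: bool
    n_points: int


def refine_shift_model(
    titrations: Sequence[ShiftTitration],
    model: EquilibriumModel,
    free_logbetas: Sequence[str],
    free_deltas: Sequence[tuple[str, str]],
    shifts: SpeciesShifts,
) -> NmrRefinement:
    """Joint refinement of formation constants and per-species shifts.

    ``shifts`` supplies the fixed shift values; pairs listed in
    ``free_deltas`` must not also appear there (they are solved, not
    assumed).  Species whose ligand mole fraction never leaves trace
    level are unidentifiable and rejected.
    """
    if not titrations:
        raise ValueError("at least one shift titration is required")
    labels = {s.label for s in model.species}
    missing = set(free_logbetas) - labels
    if missing:
        raise KeyError(f"free log beta for unknown species: {sorted(missing)}")
    if len(set(free_logbetas)) != len(list(free_logbetas)):
        raise ValueError("duplicate entries in free_logbetas")
    overlap = set(free_deltas) & set(shifts.delta)
    if overlap:
        raise ValueError(
            f"shift pairs declared both fixed and free: {sorted(overlap)}")
    free_logbetas = list(free_logbetas)
    free_deltas = list(free_deltas)

    obs_all = {nuc: np.concatenate([np.asarray(t.observed[nuc])
                                    for t in titrations])
               for nuc in shifts.nuclei}
    sig_all = np.concatenate([
        np.full(len(t.pH) * len(shifts.nuclei),
                t.sigma_delta if t.sigma_delta > 0 else 0.002)
        for t in titrations])

    state: dict = {}

    def design(theta: np.ndarray):
        m = model.with_logbetas(dict(zip(free_logbetas, theta)))
        mats, lab = [], None
        for t in titrations:
            l, X = ligand_mole_fractions(m, t.pH, t.totals)
            lab = l
            mats.append(X)
        return lab, np.vstack(mats)

    def residuals(theta: np.ndarray) -> np.ndarray:
        lab, X = design(theta)
        col = {l: j for j, l in enumerate(lab)}
        deltas: dict[tuple[str, str], float] = {}
        rs = []
        for nuc in shifts.nuclei:
            fixed_vec = np.zeros(len(lab))
            free_cols = []
            for j, l in enumerate(lab):
                if (l, nuc) in shifts.delta:
                    fixed_vec[j] = shifts.delta[(l, nuc)]
                elif (l, nuc) in free_deltas:
                    free_cols.append(j)
                elif np.any(X[:, j] > POPULATION_EPS):
                    raise KeyError(
                        f"populated species {l!r} has neither a fixed nor a "
                        f"free shift for nucleus {nuc!r}")
            y = obs_all[nuc] - X @ fixed_vec
            if free_cols:
                Xf = X[:, free_cols]
                span = Xf.max(axis=0)
                dead = [lab[free_cols[k]] for k in range(len(free_cols))
                        if span[k] < POPULATION_EPS]
                if dead:
                    raise ValueError(
                        f"species never populated above trace level: {dead} "
                        "(shift unidentifiable)")
                coef, *_ = np.linalg.lstsq(Xf, y, rcond=None)
                y = y - Xf @ coef
                for k, j in enumerate(free_cols):
                    deltas[(lab[j], nuc)] = float(coef[k])
            rs.append(y)
        state["deltas"] = deltas
        return np.concatenate(rs) / sig_all

    theta0 = np.array([model.species_by_label(l).logbeta for l in free_logbetas])
    if free_logbetas:
        for l in free_logbetas:
            # identifiability guard on the starting model
            lab, X = design(theta0)
            j = lab.index(l)
            if np.max(X[:, j]) < POPULATION_EPS:
                raise ValueError(
                    f"species {l!r} never exceeds trace population in the "
                    "titration window; its constant is unidentifiable")
        sol = least_squares(residuals, theta0, method="lm",
                            diff_step=1e-6, xtol=1e-15, ftol=1e-15,
                            gtol=1e-15)
        theta = sol.x
        r = sol.fun
        n, p = len(r), len(theta) + len(free_deltas)
        variance = float(r @ r) / max(n - p, 1)
        try:
            cov = variance * np.linalg.inv(sol.jac.T @ sol.jac)
            sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            sd = np.full(len(theta), np.nan)
        converged = bool(sol.success)
    else:
        r = residuals(theta0)
        theta, sd = theta0, np.zeros(0)
        n, p = len(r), len(free_deltas)
        variance = float(r @ r) / max(n - p, 1)
        converged = True

    refined = {l: (float(t), float(s))
               for l, t, s in zip(free_logbetas, theta, sd)}
    return NmrRefinement(
        logbetas=refined,
        deltas=dict(state.get("deltas", {})),
        fixed_logbetas={s.label: s.logbeta for s in model.species
                        if s.label not in refined},
        variance=variance,
        model=model.with_logbetas({l: v for l, (v, _) in refined.items()}),
        converged=converged,
        n_points=n,
    )
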