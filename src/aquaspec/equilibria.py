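"""Metal–ligand–proton equilibrium models and mass-balance speciation.

The chemical model is the classical generalised formation scheme

    p M + q L + r H  ⇌  M_p L_q H_r        (overall constant beta)

on the concentration scale in a constant ionic medium (here NaCl).
Negative ``r`` encodes hydroxo species: water autoprotolysis is folded
into beta, so e.g. ``M2L(OH)2`` is written with ``r = -2`` and its
concentration is ``beta * [M]^2 [L] [H]^-2``.  pH throughout means
``-log10 [H+]`` (free-concentration scale, no activity correction
inside the solver; ionic-strength effects live in
:mod:`aquaspec.medium`).

Speciation is solved in log10 free-concentration space with a damped
Newton iteration (analytic Jacobian built from the stoichiometry outer
product, steps clipped to one log-unit, backtracking line search) and a
beta-continuation fallback for hostile starting points.  This gives
strict positivity and robust convergence over the 10+ orders of
magnitude spanned between trace-metal and matrix components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Component",
    "SpeciesDef",
    "EquilibriumModel",
    "SolutionSpec",
    "SpeciationResult",
    "ModelError",
    "ConvergenceError",
    "assemble_model",
    "solve_speciation",
    "formation_percentages",
    "back_derive_auxiliary",
]

LN10 = float(np.log(10.0))

ROLES = ("proton", "metal", "ligand", "spectator")

#: maximum Newton iterations / convergence tolerance on log10 increments
MAX_ITER = 200
STEP_TOL = 1e-12
#: Newton step clip, in log10 units
STEP_CLIP = 1.0


class ModelError(ValueError):
    """Raised for an inconsistent chemical model definition."""


class ConvergenceError(RuntimeError):
    """Raised when the mass-balance solver cannot converge and the caller
    asked for a hard failure."""


@dataclass(frozen=True)
class Component:
    """A basis component of the model (free metal ion, free fully
    deprotonated ligand, the proton, or a spectator such as Na+)."""

    name: str
    charge: int
    role: str = "spectator"

    def __post_init__(self):
        if self.role not in ROLES:
            raise ModelError(f"unknown role {self.role!r} for component {self.name!r}; "
                             f"expected one of {ROLES}")


@dataclass(frozen=True)
class SpeciesDef:
    """A complex species defined by its stoichiometry in the components
    and its overall formation constant (log10 beta) at one (T, I)."""

    label: str
    stoich: Mapping[str, int]
    logbeta: float
    charge: int | None = None
    source: str = ""

    def __post_init__(self):
        if not np.isfinite(self.logbeta):
            raise ValueError(f"non-finite logbeta for species {self.label!r}")
        object.__setattr__(self, "stoich", dict(self.stoich))


@dataclass(frozen=True)
class EquilibriumModel:
    """Components + species + constants, all valid at one (T, I)."""

    components: tuple[Component, ...]
    species: tuple[SpeciesDef, ...]
    temperature: float  # degC
    ionic_strength: float  # mol/L
    medium: str = "NaCl"
    pKw: float = 13.75

    # -- convenience accessors -------------------------------------------
    @property
    def component_names(self) -> list[str]:
        return [c.name for c in self.components]

    def component(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def proton(self) -> Component | None:
        for c in self.components:
            if c.role == "proton":
                return c
        return None

    def species_by_label(self, label: str) -> SpeciesDef:
        for s in self.species:
            if s.label == label:
                return s
        raise KeyError(label)

    def stoich_matrix(self) -> np.ndarray:
        """(n_species, n_components) signed stoichiometry matrix."""
        idx = {n: i for i, n in enumerate(self.component_names)}
        N = np.zeros((len(self.species), len(self.components)))
        for k, s in enumerate(self.species):
            for name, nu in s.stoich.items():
                N[k, idx[name]] = nu
        return N

    def logbetas(self) -> np.ndarray:
        return np.array([s.logbeta for s in self.species], dtype=float)

    def with_logbetas(self, updates: Mapping[str, float]) -> "EquilibriumModel":
        """Return a copy with some species constants replaced."""
        unknown = set(updates) - {s.label for s in self.species}
        if unknown:
            raise KeyError(f"unknown species {sorted(unknown)}")
        new = tuple(
            replace(s, logbeta=float(updates[s.label])) if s.label in updates else s
            for s in self.species
        )
        return replace(self, species=new)


@dataclass(frozen=True)
class SolutionSpec:
    """Analytical (total) concentrations of one solution condition.

    ``fixed_pH`` switches the solver to buffered mode: the free proton
    concentration is clamped to ``10**-fixed_pH`` and the proton total
    is ignored.  The proton total, when used, is counted relative to the
    fully deprotonated ligand zero level and may be negative (excess
    strong base).
    """

    totals: Mapping[str, float]
    fixed_pH: float | None = None
    volume: float | None = None  # L, for titration bookkeeping

    def __post_init__(self):
        object.__setattr__(self, "totals", dict(self.totals))
        for name, tot in self.totals.items():
            if name != "H" and tot < 0:
                raise ValueError(f"negative total for component {name!r}")


@dataclass
class SpeciationResult:
    free: dict[str, float]
    species_conc: dict[str, float]
    percent_of: dict[tuple[str, str], float]
    converged: bool
    residual: float
    iterations: int
    model: EquilibriumModel
    spec: SolutionSpec


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

def assemble_model(
    components: Iterable[Component],
    species_defs: Iterable[SpeciesDef],
    temperature: float,
    ionic_strength: float,
    pKw: float = 13.75,
    medium: str = "NaCl",
) -> EquilibriumModel:
    """Validate and assemble an :class:`EquilibriumModel`.

    Charges of the species are computed from the component charges; a
    declared species charge that disagrees is rejected.  The hydroxo
    index r is restricted to [-4, +1] for metal-containing species
    (the reaction-(1) family); pure ligand protonation species may carry
    larger positive r.
    """
    comps = tuple(components)
    names = [c.name for c in comps]
    if len(set(names)) != len(names):
        raise ModelError("duplicate component names")
    protons = [c for c in comps if c.role == "proton"]
    if len(protons) > 1:
        raise ModelError("more than one proton component")
    charge_of = {c.name: c.charge for c in comps}
    metal_names = {c.name for c in comps if c.role == "metal"}

    out: list[SpeciesDef] = []
    labels: set[str] = set()
    for s in species_defs:
        if s.label in labels:
            raise ModelError(f"duplicate species label {s.label!r}")
        labels.add(s.label)
        unknown = set(s.stoich) - set(names)
        if unknown:
            raise ModelError(
                f"species {s.label!r} references undeclared component(s) {sorted(unknown)}")
        r = s.stoich.get("H", 0) if protons and protons[0].name == "H" else (
            s.stoich.get(protons[0].name, 0) if protons else 0)
        if any(s.stoich.get(m, 0) for m in metal_names) and not (-4 <= r <= 1):
            raise ModelError(
                f"species {s.label!r}: proton index r={r} outside [-4, +1]")
        if r != 0 and not protons:
            raise ModelError(
                f"species {s.label!r} has proton stoichiometry but the model "
                "declares no proton component")
        charge = int(sum(nu * charge_of[n] for n, nu in s.stoich.items()))
        if s.charge is not None and s.charge != charge:
            raise ModelError(
                f"species {s.label!r}: declared charge {s.charge} != computed {charge}")
        out.append(replace(s, charge=charge))

    if pKw <= 0:
        raise ModelError("pKw must be positive")
    return EquilibriumModel(
        components=comps,
        species=tuple(out),
        temperature=float(temperature),
        ionic_strength=float(ionic_strength),
        medium=medium,
        pKw=float(pKw),
    )


# ---------------------------------------------------------------------------
# the solver
# ---------------------------------------------------------------------------

def _newton(logb: np.ndarray, A: np.ndarray, totals: np.ndarray,
            x0: np.ndarray, max_iter: int = MAX_ITER) -> tuple[np.ndarray, bool, int]:
    """Damped Newton on the mass balances in log10 free-concentration space.

    ``A`` is the (n_species, n_unknowns) stoichiometry, ``logb`` the
    effective log constants (fixed contributions folded in).  Returns
    (x, converged, iterations).
    """
    n = len(totals)
    scale = np.maximum(np.abs(totals), 1e-15)
    x = x0.copy()

    def residual(xv):
        c = 10.0 ** np.clip(logb + A @ xv, -300, 300)
        free = 10.0 ** xv
        calc = free + A.T @ c
        return (calc - totals) / scale, c, free

    R, c, free = residual(x)
    it = 0
    stalls = 0
    for it in range(1, max_iter + 1):
        J = (np.diag(free) + A.T @ (c[:, None] * A)) * LN10 / scale[:, None]
        try:
            dx = np.linalg.solve(J, -R)
        except np.linalg.LinAlgError:
            dx, *_ = np.linalg.lstsq(J, -R, rcond=None)
        raw = np.max(np.abs(dx))
        dx = np.clip(dx, -STEP_CLIP, STEP_CLIP)
        # backtracking line search on the residual norm
        t, best = 1.0, None
        r0 = float(np.dot(R, R))
        for _ in range(40):
            Rn, cn, fn = residual(x + t * dx)
            if np.all(np.isfinite(Rn)) and np.dot(Rn, Rn) < r0:
                best = (Rn, cn, fn, t)
                break
            t *= 0.5
        if best is None:
            # accept the damped step anyway; may still make progress
            Rn, cn, fn = residual(x + t * dx)
            best = (Rn, cn, fn, t)
            stalls += 1
            if stalls >= 5:  # line search dead: hand over to the fallback
                return x, False, it
        else:
            stalls = 0
        R, c, free = best[0], best[1], best[2]
        x = x + best[3] * dx
        if raw * best[3] < STEP_TOL or np.max(np.abs(R)) < 1e-14:
            return x, True, it
    return x, np.max(np.abs(R)) < 1e-10, it


def _bracket_ph(model: EquilibriumModel, spec: SolutionSpec) -> dict | None:
    """Scalar-bracketing fallback for the full proton balance.

    Solves the (robust) fixed-pH subproblem along a Brent iteration on
    the proton mass balance and returns log10 free concentrations to
    warm-start the full Newton, or None when bracketing fails.
    """
    from scipy.optimize import brentq

    proton = model.proton
    t_h = float(spec.totals.get(proton.name, 0.0))
    kw = 10.0 ** (-model.pKw)
    warm: dict[str, float] | None = None
    state: dict = {}

    def g(ph: float) -> float:
        nonlocal warm
        res = solve_speciation(
            model, SolutionSpec(totals=spec.totals, fixed_pH=ph), x0=warm)
        warm = {k: np.log10(f) for k, f in res.free.items() if f > 0}
        state[round(ph, 12)] = dict(warm)
        h = 10.0 ** (-ph)
        calc = h - kw / h + sum(
            s.stoich.get(proton.name, 0) * res.species_conc[s.label]
            for s in model.species)
        return calc - t_h

    lo, hi = 0.3, model.pKw - 0.3
    try:
        if g(lo) < 0 or g(hi) > 0:
            return None
        ph = brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16)
    except (ValueError, RuntimeError, ConvergenceError):
        return None
    key = min(state, key=lambda p: abs(p - ph))
    out = dict(state[key])
    out[proton.name] = -ph
    return out


def solve_speciation(
    model: EquilibriumModel,
    spec: SolutionSpec,
    *,
    x0: Mapping[str, float] | None = None,
    raise_on_failure: bool = False,
) -> SpeciationResult:
    """Solve free and species concentrations for one condition.

    In fixed-pH mode the proton column is folded into effective
    constants.  In full mode the proton balance includes hydroxide via
    an internal OH pseudo-species with log beta = -pKw.  ``x0`` may
    carry log10 free-concentration warm starts keyed by component name
    (used heavily along titration curves and pL grids).
    """
    names = model.component_names
    idx = {n: i for i, n in enumerate(names)}
    N = model.stoich_matrix()
    logb = model.logbetas()
    proton = model.proton
    fixed = spec.fixed_pH is not None

    totals = np.array([float(spec.totals.get(n, 0.0)) for n in names])
    if proton is None and not fixed and any(
            s.stoich.get("H", 0) for s in model.species):
        raise ModelError("proton stoichiometry present but no proton component")

    # non-proton components with zero total: free = 0, species containing
    # them vanish (the continuation limit of total -> 0)
    dead = {
        i for i, c in enumerate(model.components)
        if c is not proton and totals[i] == 0.0 and np.any(N[:, i] != 0)
    }
    keep_species = [k for k in range(len(model.species))
                    if not any(N[k, i] > 0 for i in dead)]

    logb_eff = logb[keep_species].copy()
    A_full = N[np.ix_(keep_species, range(len(names)))]

    hidx = idx[proton.name] if proton is not None else None
    if fixed:
        hfree = 10.0 ** (-float(spec.fixed_pH))
        if hidx is not None:
            logb_eff = logb_eff + A_full[:, hidx] * (-float(spec.fixed_pH))

    # unknowns: components that occur in some retained species with a
    # positive total (plus the proton in full mode)
    unknown_idx: list[int] = []
    for i, c in enumerate(model.components):
        if i in dead:
            continue
        if c is proton:
            if not fixed:
                unknown_idx.append(i)
            continue
        if totals[i] > 0 and np.any(A_full[:, i] != 0):
            unknown_idx.append(i)

    A = A_full[:, unknown_idx]
    t_solve = totals[unknown_idx]

    # hydroxide pseudo-species joins the proton balance in full mode
    if not fixed and proton is not None and hidx in unknown_idx:
        row = np.zeros(len(unknown_idx))
        row[unknown_idx.index(hidx)] = -1.0
        A = np.vstack([A, row])
        logb_eff = np.append(logb_eff, -model.pKw)

    # initial guess
    def default_guess() -> np.ndarray:
        g = np.empty(len(unknown_idx))
        for j, i in enumerate(unknown_idx):
            c = model.components[i]
            if c is proton:
                th = totals[i]
                if th > 1e-12:
                    g[j] = np.log10(th) - 0.5
                elif th < -1e-12:
                    g[j] = min(-model.pKw - np.log10(-th), -4.0)
                else:
                    g[j] = -7.0
            else:
                g[j] = np.log10(max(totals[i], 1e-30)) - 3.0
        return g

    if x0 is not None and all(n in x0 for n in (names[i] for i in unknown_idx)):
        start = np.array([float(x0[names[i]]) for i in unknown_idx])
    else:
        start = default_guess()

    if len(unknown_idx) == 0:
        x, ok, it = np.empty(0), True, 0
    else:
        x, ok, it = _newton(logb_eff, A, t_solve, start)
        if not ok:
            x, ok, it2 = _newton(logb_eff, A, t_solve, default_guess())
            it += it2
        if not ok and not fixed and proton is not None and hidx in unknown_idx:
            # robust fallback: bracket the proton balance in pH.  The
            # analytical proton total is strictly decreasing in pH, so a
            # scalar root of T_H(pH) - T_H over the fixed-pH subproblem
            # always exists inside (0, pKw); the full Newton then
            # polishes from that solution.
            guess = _bracket_ph(model, spec)
            if guess is not None:
                start2 = np.array([guess.get(names[i], start[j])
                                   for j, i in enumerate(unknown_idx)])
                x, ok, it2 = _newton(logb_eff, A, t_solve, start2)
                it += it2
        if not ok:
            # continuation: ramp the formation constants up in stages
            xx = default_guess()
            for lam in (0.25, 0.5, 0.75, 1.0):
                xx, ok, itc = _newton(logb_eff * lam, A, t_solve, xx)
                it += itc
            x, ok, itf = _newton(logb_eff, A, t_solve, xx)
            it += itf

    # assemble outputs -----------------------------------------------------
    free = {}
    for i, c in enumerate(model.components):
        if i in dead:
            free[c.name] = 0.0
        elif c is proton and fixed:
            free[c.name] = hfree
        elif i in unknown_idx:
            free[c.name] = float(10.0 ** x[unknown_idx.index(i)])
        else:
            free[c.name] = float(totals[i])

    species_conc = {s.label: 0.0 for s in model.species}
    fullx = np.array([np.log10(free[n]) if free[n] > 0 else -np.inf for n in names])
    for k in keep_species:
        expo = logb[k] + float(N[k] @ np.where(np.isfinite(fullx), fullx, 0.0))
        if any(N[k, i] != 0 and not np.isfinite(fullx[i]) for i in range(len(names))):
            conc = 0.0
        else:
            conc = float(10.0 ** expo)
        species_conc[model.species[k].label] = conc

    # residual: max relative mass-balance error over components with totals
    resid = 0.0
    for i, c in enumerate(model.components):
        if c is proton and fixed:
            continue
        calc = free[c.name] + sum(
            N[k, i] * species_conc[model.species[k].label] for k in keep_species)
        if c is proton and not fixed:
            calc -= 10.0 ** (-model.pKw) / free[c.name] if free[c.name] > 0 else 0.0
        resid = max(resid, abs(calc - totals[i]) / max(abs(totals[i]), 1e-15))

    percent: dict[tuple[str, str], float] = {}
    for i, c in enumerate(model.components):
        if c.role not in ("metal", "ligand") or totals[i] <= 0:
            continue
        percent[(c.name, c.name)] = 100.0 * free[c.name] / totals[i]
        for k in keep_species:
            s = model.species[k]
            nu = s.stoich.get(c.name, 0)
            if nu > 0:
                percent[(s.label, c.name)] = (
                    100.0 * nu * species_conc[s.label] / totals[i])

    if not ok and raise_on_failure:
        raise ConvergenceError(
            f"speciation did not converge (residual {resid:.2e} after {it} iterations)")

    return SpeciationResult(
        free=free,
        species_conc=species_conc,
        percent_of=percent,
        converged=bool(ok),
        residual=float(resid),
        iterations=int(it),
        model=model,
        spec=spec,
    )


def formation_percentages(result: SpeciationResult, reference: str) -> pd.DataFrame:
    """Percent of the reference component held by each species.

    The free reference component appears as a row labelled with the
    component name.  Percentages follow ``100 * nu * c_s / total(ref)``;
    rows are sorted by species label for bit-stable output.
    """
    model = result.model
    total = float(result.spec.totals.get(reference, 0.0))
    if total <= 0:
        raise ValueError(f"reference component {reference!r} has zero total")
    rows = [(reference, 100.0 * result.free[reference] / total)]
    for s in model.species:
        nu = s.stoich.get(reference, 0)
        if nu > 0:
            rows.append((s.label, 100.0 * nu * result.species_conc[s.label] / total))
    df = pd.DataFrame(rows, columns=["species", "percent"])
    return df.sort_values("species", kind="stable").reset_index(drop=True)


def back_derive_auxiliary(logbeta: float, logK_stepwise: float,
                          reaction_kind: str) -> float:
    """Reconstruct an auxiliary constant from an overall/stepwise pair.

    For a protonated complex, ``M + LH_r = MLH_r`` has
    ``logK = logbeta(MLH_r) - logbeta(LH_r)``, so the ligand protonation
    constant is ``logbeta - logK``.  For a hydrolysed complex the same
    identity returns the metal hydrolysis constant of ``M_p(OH)_r``.
    Both constants must refer to the same (T, I).
    """
    if reaction_kind not in ("protonated", "hydrolyzed"):
        raise ValueError(
            f"reaction_kind must be 'protonated' or 'hydrolyzed', got {reaction_kind!r}")
    return float(logbeta) - float(logK_stepwise)
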