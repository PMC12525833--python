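"""Glass-electrode titrations: simulation, calibration and formation-
constant refinement from e.m.f. curves.

The cell obeys the Nernst relation on the free-proton concentration
scale, ``E = E0 + s log10[H+] (+ j [H+])`` with s the (near-)Nernstian
slope in mV per decade and j an optional junction coefficient.  A
titration dilutes the initial totals and adds titrant,
``C_i(v) = (C_i V0 + C_t v) / (V0 + v)``, and each point is a full
proton-balance speciation solve.

Refinement minimises the weighted e.m.f. sum of squares over the free
log beta values with a Levenberg–Marquardt iteration; the Jacobian
dE/dlogbeta comes from implicit differentiation of the mass-balance
system at each solved point (one small linear solve per point), which
is both faster and smoother than finite differences across the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .equilibria import (LN10, ConvergenceError, EquilibriumModel,
                         SolutionSpec, solve_speciation)

__all__ = [
    "NERNST_MV_PER_K",
    "Titrant",
    "TitrationProtocol",
    "ElectrodeCalibration",
    "TitrationCurve",
    "RefinementResult",
    "nernst_slope",
    "simulate_titration",
    "calibrate_electrode",
    "refine_formation_constants",
]

#: ln(10) R / F in mV per kelvin per log10 unit
NERNST_MV_PER_K = 0.19841


def nernst_slope(temperature_C: float) -> float:
    """Theoretical Nernstian slope in mV per decade at t (degC)."""
    return NERNST_MV_PER_K * (temperature_C + 273.15)


@dataclass(frozen=True)
class Titrant:
    """Titrant stream.  ``component='OH'`` means strong base: each mole
    removes one mole from the analytical proton total."""
    component: str
    concentration: float  # mol/L

    def __post_init__(self):
        if self.concentration <= 0:
            raise ValueError("titrant concentration must be positive")


@dataclass(frozen=True)
class TitrationProtocol:
    initial_volume: float            # L
    initial_totals: Mapping[str, float]  # mol/L
    titrant: Titrant
    volumes: tuple[float, ...]       # added titrant, mL
    temperature: float = 25.0        # degC
    ionic_strength: float = 0.15     # mol/L

    def __post_init__(self):
        object.__setattr__(self, "initial_totals", dict(self.initial_totals))
        vols = tuple(float(v) for v in self.volumes)
        if len(vols) == 0:
            vols = (0.0,)
        if any(b <= a for a, b in zip(vols, vols[1:])):
            raise ValueError("titrant volumes must be strictly increasing")
        object.__setattr__(self, "volumes", vols)

    def totals_at(self, v_mL: float) -> dict[str, float]:
        """Diluted totals after adding v mL of titrant."""
        v = v_mL * 1e-3
        V = self.initial_volume + v
        out = {k: c * self.initial_volume / V for k, c in self.initial_totals.items()}
        add = self.titrant.concentration * v / V
        if self.titrant.component == "OH":
            out["H"] = out.get("H", 0.0) - add
        else:
            out[self.titrant.component] = out.get(self.titrant.component, 0.0) + add
        return out


@dataclass(frozen=True)
class ElectrodeCalibration:
    E0: float                      # mV
    slope: float | None = None     # mV/decade; None -> Nernstian at use T
    pKw: float | None = None       # None -> model value
    junction_coeff: float = 0.0    # mV L/mol, multiplies [H+]
    rms: float | None = None       # mV, from calibration fit
    allow_non_nernstian: bool = False

    def slope_at(self, temperature_C: float) -> float:
        s = nernst_slope(temperature_C)
        if self.slope is None:
            return s
        if not self.allow_non_nernstian and abs(self.slope - s) > 0.10 * s:
            raise ValueError(
                f"slope {self.slope:.2f} mV deviates >10% from Nernstian "
                f"{s:.2f} mV at {temperature_C} degC; set allow_non_nernstian")
        return self.slope


@dataclass(frozen=True)
class TitrationCurve:
    protocol: TitrationProtocol
    volumes: tuple[float, ...]   # mL (nominal)
    emf: tuple[float, ...]       # mV
    sigma_E: float = 0.15
    sigma_V: float = 0.002

    def __post_init__(self):
        if len(self.volumes) != len(self.emf):
            raise ValueError("one emf value per volume is required")
        if self.sigma_E < 0 or self.sigma_V < 0:
            raise ValueError("sigma values must be non-negative")


@dataclass
class RefinementResult:
    refined: dict[str, tuple[float, float]]   # label -> (logbeta, sd)
    fixed: dict[str, float]
    variance: float                           # weighted residual variance
    iterations: int
    converged: bool
    model: EquilibriumModel                   # with refined constants applied
    n_points: int = 0


# ---------------------------------------------------------------------------

def _emf_curve(model: EquilibriumModel, protocol: TitrationProtocol,
               calib: ElectrodeCalibration, *, jac_species: Sequence[str] = (),
               ) -> tuple[np.ndarray, np.ndarray | None]:
    """Noiseless e.m.f. at each protocol volume; optionally the implicit
    Jacobian dE/dlogbeta for the named species."""
    slope = calib.slope_at(protocol.temperature)
    pKw = calib.pKw if calib.pKw is not None else model.pKw
    m = model if pKw == model.pKw else replace(model, pKw=pKw)
    names = m.component_names
    labels = [s.label for s in m.species]
    jcols = [labels.index(l) for l in jac_species]

    E = np.empty(len(protocol.volumes))
    J = np.empty((len(protocol.volumes), len(jcols))) if jcols else None
    warm: dict[str, float] | None = None
    for i, v in enumerate(protocol.volumes):
        spec = SolutionSpec(totals=protocol.totals_at(v))
        try:
            res = solve_speciation(m, spec, x0=warm, raise_on_failure=True)
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"speciation failed at titration point {i} (v = {v} mL): {exc}"
            ) from exc
        warm = {k: np.log10(f) for k, f in res.free.items() if f > 0}
        h = res.free["H"]
        E[i] = calib.E0 + slope * np.log10(h) + calib.junction_coeff * h
        if jcols:
            J[i] = _implicit_dE(m, res, jcols, slope, calib.junction_coeff)
    return E, J


def _implicit_dE(model: EquilibriumModel, res, jcols: list[int],
                 slope: float, junction: float) -> np.ndarray:
    """d E / d logbeta_j at one solved point via the implicit function
    theorem on the mass balances (unknowns in log10 space)."""
    names = model.component_names
    N = model.stoich_matrix()
    # unknowns: components with positive species involvement and free>0
    unk = [i for i, n in enumerate(names)
           if res.free[n] > 0 and (np.any(N[:, i] != 0) or n == "H")]
    x = np.array([np.log10(res.free[names[i]]) for i in unk])
    c = np.array([res.species_conc[s.label] for s in model.species])
    A = N[:, unk]
    free = 10.0 ** x
    Jx = (np.diag(free) + A.T @ (c[:, None] * A)) * LN10
    # hydroxide row of the proton balance
    if "H" in names:
        hpos = unk.index(names.index("H"))
        oh = 10.0 ** (-model.pKw) / res.free["H"]
        Jx[hpos, hpos] += oh * LN10
    B = np.zeros((len(unk), len(jcols)))
    for col, k in enumerate(jcols):
        B[:, col] = LN10 * A[k, :] * c[k]
    S = np.linalg.solve(Jx, -B)          # d x / d logbeta
    hrow = unk.index(names.index("H"))
    dE = slope * S[hrow, :] + junction * res.free["H"] * LN10 * S[hrow, :]
    return dE


def simulate_titration(model: EquilibriumModel, protocol: TitrationProtocol,
                       calib: ElectrodeCalibration) -> TitrationCurve:
    """Noiseless e.m.f. titration curve under the protocol."""
    E, _ = _emf_curve(model, protocol, calib)
    return TitrationCurve(protocol=protocol, volumes=protocol.volumes,
                          emf=tuple(float(e) for e in E),
                          sigma_E=0.0, sigma_V=0.0)


# ---------------------------------------------------------------------------

def calibrate_electrode(curve: TitrationCurve, *, refine_slope: bool = False,
                        ) -> ElectrodeCalibration:
    """Estimate E0 and pKw from a strong acid vs strong base titration.

    The free proton concentration at each point follows from the charge
    balance of a strong-acid/strong-base mixture,
    ``[H] - Kw/[H] = C_net(v)``, so no speciation model is needed.  The
    alkaline branch must be present for pKw to be identifiable.
    """
    prot = curve.protocol
    if prot.titrant.component != "OH":
        raise ValueError("calibration expects a strong-base titrant ('OH')")
    v = np.asarray(curve.volumes)
    E = np.asarray(curve.emf)
    cnet = np.array([prot.totals_at(x)["H"] for x in v])
    if cnet.min() > -1e-6:
        raise ValueError("alkaline branch absent: pKw is unidentifiable")
    slope_n = nernst_slope(prot.temperature)

    def h_of(cn, pKw):
        kw = 10.0 ** (-pKw)
        return 0.5 * (cn + np.sqrt(cn * cn + 4.0 * kw))

    def resid(theta):
        if refine_slope:
            e0, pKw, slope = theta
        else:
            (e0, pKw), slope = theta, slope_n
        return e0 + slope * np.log10(h_of(cnet, pKw)) - E

    x0 = [float(E[0] - slope_n * np.log10(max(cnet[0], 1e-10))), 13.8]
    if refine_slope:
        x0.append(slope_n)
    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    e0, pKw = float(sol.x[0]), float(sol.x[1])
    slope = float(sol.x[2]) if refine_slope else slope_n
    return ElectrodeCalibration(E0=e0, slope=slope, pKw=pKw, rms=rms,
                                allow_non_nernstian=True)


# ---------------------------------------------------------------------------

def refine_formation_constants(
    curves: Sequence[TitrationCurve],
    model: EquilibriumModel,
    free_params: Sequence[str],
    calib: ElectrodeCalibration,
    *,
    propagate_sigma_V: bool = False,
    max_iter: int = 60,
) -> RefinementResult:
    """Levenberg–Marquardt refinement of log beta values on e.m.f. data.

    Weights default to 1/sigma_E^2 per curve; with
    ``propagate_sigma_V=True`` the volume uncertainty is folded into an
    effective variance via the local slope dE/dv.  Auxiliary constants
    (every species not named in ``free_params``) stay fixed.
    """
    if not curves:
        raise ValueError("at least one titration curve is required")
    labels = {s.label for s in model.species}
    missing = set(free_params) - labels
    if missing:
        raise KeyError(f"free parameters not in the model: {sorted(missing)}")
    free_params = list(free_params)

    sigmas = []
    for c in curves:
        sE = c.sigma_E if c.sigma_E > 0 else 0.15
        sig = np.full(len(c.volumes), sE)
        if propagate_sigma_V and len(c.volumes) > 1 and c.sigma_V > 0:
            dEdv = np.gradient(np.asarray(c.emf), np.asarray(c.volumes))
            sig = np.sqrt(sig**2 + (dEdv * c.sigma_V) ** 2)
        sigmas.append(sig)

    def eval_all(theta: np.ndarray, with_jac: bool):
        m = model.with_logbetas(dict(zip(free_params, theta)))
        rs, js = [], []
        for c, sig in zip(curves, sigmas):
            E, J = _emf_curve(m, c.protocol, calib,
                              jac_species=free_params if with_jac else ())
            rs.append((np.asarray(c.emf) - E) / sig)
            if with_jac:
                js.append(-J / sig[:, None])
        r = np.concatenate(rs)
        return (r, np.vstack(js)) if with_jac else (r, None)

    theta = np.array([model.species_by_label(l).logbeta for l in free_params])
    r, J = eval_all(theta, True)
    ssr = float(r @ r)
    lam = 1e-3
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        JTJ = J.T @ J
        colnorm = np.sqrt(np.diag(JTJ))
        bad = [free_params[i] for i in range(len(theta))
               if colnorm[i] < 1e-8 * max(colnorm.max(), 1.0)]
        if bad:
            raise np.linalg.LinAlgError(
                f"singular normal matrix: species {bad} are not constrained "
                "by the data (never formed in the titration window)")
        g = J.T @ r
        accepted = False
        for _ in range(12):
            try:
                step = np.linalg.solve(JTJ + lam * np.diag(np.diag(JTJ)), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            try:
                r_new, J_new = eval_all(theta + step, True)
            except ConvergenceError:
                lam *= 10.0
                continue
            ssr_new = float(r_new @ r_new)
            if ssr_new < ssr:
                theta = theta + step
                r, J, ssr = r_new, J_new, ssr_new
                lam = max(lam / 10.0, 1e-12)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            break
        if np.max(np.abs(step)) < 1e-7:
            converged = True
            break
    else:
        it = max_iter
    if not converged and np.max(np.abs(g)) < 1e-6 * max(ssr, 1.0):
        converged = True
    if not converged and it < max_iter:
        converged = True  # LM stalled at a minimum (no acceptable step)

    n = len(r)
    p = len(theta)
    variance = ssr / max(n - p, 1)
    try:
        cov = variance * np.linalg.inv(J.T @ J)
        sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        sd = np.full(p, np.nan)

    refined = {l: (float(t), float(s)) for l, t, s in zip(free_params, theta, sd)}
    fixed = {s.label: s.logbeta for s in model.species if s.label not in free_params}
    return RefinementResult(
        refined=refined, fixed=fixed, variance=float(variance),
        iterations=it, converged=bool(converged),
        model=model.with_logbetas({l: v for l, (v, _) in refined.items()}),
        n_points=n,
    )
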