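"""Shared fixtures and the independent speciation oracle.

The oracle solves one-metal/one-ligand fixed-pH mass balances by
nested bracketed root-finding in log-concentration space — no Newton
iteration, no Jacobian — so it cannot share a failure mode with the
package solver it cross-checks.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq

import aquaspec as aq


@pytest.fixture(scope="session")
def cu_pea_37():
    return aq.packaged_model("Cu", "PEA", 37, 0.15)


@pytest.fixture(scope="session")
def cu_pea_25():
    return aq.packaged_model("Cu", "PEA", 25, 0.15)


@pytest.fixture(scope="session")
def zn_pea_25():
    return aq.packaged_model("Zn", "PEA", 25, 0.15)


@pytest.fixture(scope="session")
def simple_ml_model():
    """Single equilibrium M + L = ML with logK = 3, no protonation."""
    comps = [
        aq.Component("H", 1, "proton"),
        aq.Component("M", 2, "metal"),
        aq.Component("L", -2, "ligand"),
    ]
    species = [aq.SpeciesDef("ML", {"M": 1, "L": 1}, 3.0)]
    return aq.assemble_model(comps, species, 25, 0.15, pKw=13.75)


def oracle_fixed_ph(model, totals, pH):
    """Grid-free nested-bisection oracle for fixed-pH speciation.

    Works for models with one metal, one ligand and any set of species
    in those two components plus protons.  Returns free (metal, ligand)
    concentrations.
    """
    metal = next(c.name for c in model.components if c.role == "metal")
    lig = next(c.name for c in model.components if c.role == "ligand")
    TM, TL = totals[metal], totals[lig]
    terms = []  # (p, q, beta_eff) with the proton activity folded in
    for s in model.species:
        p = s.stoich.get(metal, 0)
        q = s.stoich.get(lig, 0)
        r = s.stoich.get("H", 0)
        others = set(s.stoich) - {metal, lig, "H"}
        b = s.logbeta - r * pH
        for name in others:
            b += s.stoich[name] * np.log10(totals.get(name, 0.0))
        terms.append((p, q, b))

    def m_balance(log_m, log_l):
        tot = 10.0 ** log_m
        for p, q, b in terms:
            if p:
                tot += p * 10.0 ** (b + p * log_m + q * log_l)
        return tot - TM

    def solve_m(log_l):
        return brentq(m_balance, -40, np.log10(TM), args=(log_l,),
                      xtol=1e-15, rtol=1e-15)

    def l_balance(log_l):
        log_m = solve_m(log_l)
        tot = 10.0 ** log_l
        for p, q, b in terms:
            if q:
                tot += q * 10.0 ** (b + p * log_m + q * log_l)
        return tot - TL

    log_l = brentq(l_balance, -40, np.log10(TL), xtol=1e-15, rtol=1e-15)
    return 10.0 ** solve_m(log_l), 10.0 ** log_l
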