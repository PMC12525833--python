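"""YAML/CSV/JSON I/O, plotting and provenance logging.

Model files are YAML documents with ``model`` (components, species with
{M: p, L: q, H: r} stoichiometries, T/I/medium/pKw) and optional
``conditions`` blocks; speciation results are written as long-format
CSV (condition, species, concentration, percent) with bit-stable
species ordering and six-decimal precision.  Plots (distribution
diagrams, chi(pL) curves) go through matplotlib's Agg backend.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .equilibria import (Component, EquilibriumModel, SolutionSpec,
                         SpeciesDef, assemble_model, formation_percentages,
                         solve_speciation)

__all__ = [
    "load_model_config", "write_model_config",
    "speciation_table", "write_speciation_csv",
    "read_titration_csv", "write_titration_csv",
    "plot_distribution_diagram", "plot_sequestration_curve",
    "write_provenance",
]

CSV_FLOAT_FORMAT = "%.6g"
#: default pH sweep for distribution diagrams
PH_SWEEP = np.round(np.arange(2.0, 11.0 + 1e-9, 0.05), 10)


class SchemaError(ValueError):
    """YAML config violates the model schema; message carries the field path."""


def _require(mapping: Mapping, key: str, path: str):
    if key not in mapping:
        raise SchemaError(f"missing field {path}.{key}")
    return mapping[key]


def load_model_config(path) -> tuple[EquilibriumModel, list[SolutionSpec]]:
    """Load a model + solution conditions from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    m = _require(raw, "model", "$")
    comps = []
    for i, c in enumerate(_require(m, "components", "$.model")):
        comps.append(Component(
            name=_require(c, "name", f"$.model.components[{i}]"),
            charge=int(_require(c, "charge", f"$.model.components[{i}]")),
            role=c.get("role", "spectator")))
    species = []
    for i, s in enumerate(m.get("species", [])):
        label = _require(s, "label", f"$.model.species[{i}]")
        if "logbeta" not in s:
            raise SchemaError(
                f"species {label!r} has no logbeta field "
                f"($.model.species[{i}].logbeta)")
        species.append(SpeciesDef(
            label=label,
            stoich=_require(s, "stoich", f"$.model.species[{i}]"),
            logbeta=float(s["logbeta"]),
            source=s.get("source", "")))
    model = assemble_model(
        comps, species,
        temperature=float(_require(m, "temperature", "$.model")),
        ionic_strength=float(_require(m, "ionic_strength", "$.model")),
        pKw=float(m.get("pKw", 13.75)),
        medium=m.get("medium", "NaCl"))
    conditions = []
    for i, c in enumerate(raw.get("conditions", []) or []):
        conditions.append(SolutionSpec(
            totals=_require(c, "totals", f"$.conditions[{i}]"),
            fixed_pH=c.get("fixed_pH"),
            volume=c.get("volume")))
    return model, conditions


def write_model_config(path, model: EquilibriumModel,
                       conditions: Sequence[SolutionSpec] = ()) -> None:
    doc = {
        "model": {
            "temperature": model.temperature,
            "ionic_strength": model.ionic_strength,
            "medium": model.medium,
            "pKw": model.pKw,
            "components": [
                {"name": c.name, "charge": c.charge, "role": c.role}
                for c in model.components],
            "species": [
                {"label": s.label, "stoich": dict(s.stoich),
                 "logbeta": s.logbeta,
                 **({"source": s.source} if s.source else {})}
                for s in model.species],
        },
    }
    if conditions:
        doc["conditions"] = [
            {"totals": dict(c.totals),
             **({"fixed_pH": c.fixed_pH} if c.fixed_pH is not None else {}),
             **({"volume": c.volume} if c.volume is not None else {})}
            for c in conditions]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------

def speciation_table(model: EquilibriumModel, conditions: Sequence[SolutionSpec],
                     reference: str | None = None) -> pd.DataFrame:
    """Long-format results over conditions: one row per (condition, species).

    ``reference`` picks the percentage denominator component; the
    default is the (single) metal, falling back to the ligand.
    """
    if reference is None:
        metals = [c.name for c in model.components if c.role == "metal"]
        ligands = [c.name for c in model.components if c.role == "ligand"]
        reference = metals[0] if metals else ligands[0]
    rows = []
    for k, cond in enumerate(conditions):
        res = solve_speciation(model, cond, raise_on_failure=True)
        label = (f"pH={cond.fixed_pH:g}" if cond.fixed_pH is not None
                 else f"cond{k}")
        pct = formation_percentages(res, reference)
        pctmap = dict(zip(pct["species"], pct["percent"]))
        for s in sorted([reference] + [sp.label for sp in model.species
                                       if sp.stoich.get(reference, 0) > 0]):
            conc = res.free[reference] if s == reference else res.species_conc[s]
            rows.append({"condition": label, "species": s,
                         "concentration": conc, "percent": pctmap.get(s, 0.0)})
    return pd.DataFrame(rows)


def write_speciation_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def read_titration_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"v_mL", "E_mV"} <= set(df.columns):
        raise SchemaError("titration CSV requires columns v_mL and E_mV")
    return df


def write_titration_csv(path, curve) -> None:
    pd.DataFrame({"v_mL": curve.volumes, "E_mV": curve.emf}).to_csv(
        path, index=False, float_format=CSV_FLOAT_FORMAT)


# ---------------------------------------------------------------------------

def _agg():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_distribution_diagram(model: EquilibriumModel, totals: Mapping[str, float],
                              reference: str, path, pH_grid=PH_SWEEP) -> None:
    """Percent-vs-pH distribution diagram for the reference component."""
    plt = _agg()
    series: dict[str, list[float]] = {}
    warm = None
    for p in pH_grid:
        res = solve_speciation(model, SolutionSpec(totals=totals, fixed_pH=float(p)),
                               x0=warm, raise_on_failure=True)
        warm = {k: np.log10(f) for k, f in res.free.items() if f > 0}
        pct = formation_percentages(res, reference)
        for sp, val in zip(pct["species"], pct["percent"]):
            series.setdefault(sp, []).append(val)
    fig, ax = plt.subplots(figsize=(6, 4))
    for sp in sorted(series):
        ax.plot(pH_grid, series[sp], label=sp)
    ax.set_xlabel("pH")
    ax.set_ylabel(f"% of total {reference}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sequestration_curve(curve, path) -> None:
    plt = _agg()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.pL, curve.chi, "-")
    if curve.pL05 is not None:
        ax.axvline(curve.pL05, ls="--", color="grey")
        ax.set_title(f"pL0.5 = {curve.pL05:.2f}")
    ax.set_xlabel("pL")
    ax.set_ylabel("chi")
    ax.invert_xaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_provenance(path, *, command: str, inputs: Mapping, seed=None) -> None:
    """JSON run log: command, inputs, constants provenance, version, seed."""
    from . import __version__
    doc = {"command": command, "inputs": dict(inputs), "seed": seed,
           "aquaspec_version": __version__}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=str))
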