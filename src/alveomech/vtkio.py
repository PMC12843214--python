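"""Legacy-ASCII VTK export and flat key/value configuration files."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .geometry import PhenotypeParams, Mesh, REGION_LABELS
from .fem import Solution
from .materials import (LinearElastic, OgdenParams, MaterialCard,
                        default_material_set)

__all__ = ["write_vtk", "load_config", "params_from_config",
           "materials_from_config", "save_config"]

_REGION_CODE = {label: i for i, label in enumerate(REGION_LABELS)}


def write_vtk(path, mesh: Mesh, solution: Solution | None = None) -> None:
    """Write the mesh (and optionally a solution) as a legacy-ASCII VTK
    unstructured grid: region codes as cell data, displacements as point
    vectors, stress components as cell data."""
    lines = ["# vtk DataFile Version 3.0",
             "alveomech cross-section", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    for x, y in mesh.nodes:
        lines.append(f"{x:.12g} {y:.12g} 0")
    lines.append(f"CELLS {mesh.n_elements} {4 * mesh.n_elements}")
    for tri in mesh.elements:
        lines.append(f"3 {tri[0]} {tri[1]} {tri[2]}")
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend(["5"] * mesh.n_elements)

    lines.append(f"CELL_DATA {mesh.n_elements}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(_REGION_CODE[r]) for r in mesh.element_region)
    if solution is not None:
        for name, comp in (("stress_xx", (0, 0)), ("stress_yy", (1, 1)),
                           ("stress_xy", (0, 1))):
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{s[comp]:.12g}" for s in solution.element_stress)
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        lines.append("VECTORS displacement double")
        for ux, uy in solution.node_displacements:
            lines.append(f"{ux:.12g} {uy:.12g} 0")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_PARAM_FIELDS = {f.name for f in dataclasses.fields(PhenotypeParams)}


def load_config(path) -> dict:
    """Flat key/value config (YAML syntax)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat key/value mapping")
    return cfg


def params_from_config(cfg: dict) -> PhenotypeParams:
    """PhenotypeParams from flat config keys matching the field names;
    unknown geometry keys are ignored (they may belong to other blocks)."""
    kw = {k: float(v) for k, v in cfg.items() if k in _PARAM_FIELDS}
    return PhenotypeParams(**kw)


def materials_from_config(cfg: dict,
                          cortical_E: float = 12500.0) -> MaterialCard:
    """Material card from the optional ``materials`` config block: a list of
    entries with keys region, model (linear|ogden) and either E_GPa/nu or
    mu_MPa/alpha/bulk_MPa.  Unlisted regions keep their defaults."""
    card = default_material_set(cortical_E=cortical_E)
    mats = dict(card.materials)
    pdl_model = card.pdl_model
    pdl_ogden = card.pdl_ogden
    for entry in cfg.get("materials", []):
        region = entry["region"]
        model = entry.get("model", "linear")
        if model == "linear":
            mats[region] = LinearElastic(E=float(entry["E_GPa"]) * 1000.0,
                                         nu=float(entry.get("nu", 0.3)))
        elif model == "ogden":
            if region != "PDL":
                raise ValueError("the ogden model is only supported for PDL")
            pdl_model = "ogden"
            pdl_ogden = OgdenParams(mu=float(entry["mu_MPa"]),
                                    alpha=float(entry["alpha"]),
                                    bulk=float(entry["bulk_MPa"]))
        else:
            raise ValueError(f"unknown material model {model!r}")
    return MaterialCard(materials=mats, pdl_model=pdl_model,
                        pdl_ogden=pdl_ogden)


def save_config(path, params: PhenotypeParams, extra: dict | None = None) -> None:
    cfg = dataclasses.asdict(params)
    if extra:
        cfg.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
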