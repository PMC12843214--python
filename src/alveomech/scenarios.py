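"""The three transverse loading protocols and the end-to-end pipeline.

CONVENTIONAL: a single buccal force at the bracket point, intact cortex.
CORTICOTOMY: the same crown force with a softened corticotomy band in the
buccal plate.  BPS (Bone Protection System): corticotomy plus skeletal
anchorage — part of the net transverse force is delivered through mini-implant
(ANCHOR) nodes on the corticotomised buccal plate instead of the bracket, so
the bone segment is carried along with the root.  The net transverse force is
held at ``crown_force`` in every protocol so the scenarios stay comparable.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (PhenotypeParams, Mesh, TrackingNodes, build_outline,
                       generate_mesh, locate_tracking_nodes)
from .materials import default_material_set
from .fem import LoadCase, Solution, solve_linear, solve_newton
from .metrics import (DisplacementSummary, PDLStressProfile,
                      displacement_summary, pdl_stress_profile)

__all__ = ["ScenarioSpec", "ScenarioResult", "make_scenario",
           "build_load_case", "run_scenario", "run_comparison",
           "CONVENTIONAL", "CORTICOTOMY", "BPS", "SCENARIO_NAMES"]

CONVENTIONAL = "CONVENTIONAL"
CORTICOTOMY = "CORTICOTOMY"
BPS = "BPS"
SCENARIO_NAMES = (CONVENTIONAL, CORTICOTOMY, BPS)

log = logging.getLogger("alveomech")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """One loading protocol with its force-system parameters.

    ``crown_force`` is the net transverse buccal force (N); for BPS,
    ``anchor_force_fraction`` of it is delivered through the ANCHOR node set
    and the remainder through the bracket.
    """

    name: str
    crown_force: float = 1.0
    corticotomy_depth: float = 0.0
    anchor_force_fraction: float = 0.0
    anchor_direction: tuple = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ScenarioError(f"unknown scenario {self.name!r}")
        if not self.crown_force > 0:
            raise ScenarioError(f"crown_force must be > 0, got {self.crown_force!r}")
        if not 0.0 <= self.anchor_force_fraction <= 1.0:
            raise ScenarioError(
                f"anchor_force_fraction must be in [0, 1], got "
                f"{self.anchor_force_fraction!r}")
        nrm = float(np.hypot(*self.anchor_direction))
        if not np.isclose(nrm, 1.0, atol=1e-9):
            raise ScenarioError("anchor_direction must be a unit vector")
        if self.name == CONVENTIONAL:
            if self.corticotomy_depth != 0 or self.anchor_force_fraction != 0:
                raise ScenarioError(
                    "CONVENTIONAL requires corticotomy_depth = 0 and "
                    "anchor_force_fraction = 0")
        elif self.name == CORTICOTOMY:
            if self.corticotomy_depth <= 0:
                raise ScenarioError("CORTICOTOMY requires corticotomy_depth > 0")
            if self.anchor_force_fraction != 0:
                raise ScenarioError("CORTICOTOMY requires anchor_force_fraction = 0")
        else:  # BPS
            if self.corticotomy_depth <= 0 or self.anchor_force_fraction <= 0:
                raise ScenarioError(
                    "BPS requires corticotomy_depth > 0 and "
                    "anchor_force_fraction > 0")


#: Protocol defaults: ~1 N per tooth at the crown; 3 mm corticotomy; 70 % of
#: the net transverse load through the skeletal anchorage under BPS.
_DEFAULTS = {
    CONVENTIONAL: dict(crown_force=1.0, corticotomy_depth=0.0,
                       anchor_force_fraction=0.0),
    CORTICOTOMY: dict(crown_force=1.0, corticotomy_depth=3.0,
                      anchor_force_fraction=0.0),
    BPS: dict(crown_force=1.0, corticotomy_depth=3.0,
              anchor_force_fraction=0.7),
}


def make_scenario(name: str, **overrides) -> ScenarioSpec:
    """Scenario with protocol defaults filled in; overrides are validated
    against the protocol invariants."""
    if name not in _DEFAULTS:
        raise ScenarioError(f"unknown scenario {name!r}")
    kw = dict(_DEFAULTS[name])
    kw.update(overrides)
    return ScenarioSpec(name=name, **kw)


def build_load_case(spec: ScenarioSpec, mesh: Mesh) -> LoadCase:
    """Force system for a scenario: bracket point load, optional anchor loads
    shared equally over the ANCHOR set, basal boundary fixed.  Pure forces
    only (no applied moments — no active torque expression)."""
    for required in ("CROWN_LOAD", "FIXED_BOUNDARY"):
        if len(mesh.node_sets.get(required, ())) == 0:
            raise ScenarioError(f"required node set {required} is empty")
    loads = []
    crown_part = (1.0 - spec.anchor_force_fraction) * spec.crown_force
    crown_node = int(mesh.node_sets["CROWN_LOAD"][0])
    loads.append((crown_node, np.array([crown_part, 0.0])))
    if spec.anchor_force_fraction > 0:
        anchor = mesh.node_sets.get("ANCHOR", ())
        if len(anchor) == 0:
            raise ScenarioError("required node set ANCHOR is empty")
        share = spec.anchor_force_fraction * spec.crown_force / len(anchor)
        d = np.asarray(spec.anchor_direction, dtype=float)
        for n in anchor:
            loads.append((int(n), share * d))
    dirichlet = [(int(n), (0, 1), (0.0, 0.0))
                 for n in mesh.node_sets["FIXED_BOUNDARY"]]
    return LoadCase(point_loads=loads, dirichlet=dirichlet, load_factor=1.0)


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    cortical_E: float                     # MPa
    solution: Solution
    tracking: TrackingNodes
    summary: DisplacementSummary
    pdl_profile: PDLStressProfile
    mesh: Mesh


def run_scenario(params: PhenotypeParams, spec: ScenarioSpec,
                 cortical_E: float = 12500.0, h_pdl: float = 0.1,
                 h_far: float = 0.5, pdl_model: str = "linear",
                 newton_steps: int = 5, mats=None) -> ScenarioResult:
    """Full pipeline: geometry -> mesh -> materials -> solve -> readouts.

    Deterministic for fixed inputs.  The phenotype's corticotomy depth is
    overridden by the scenario's."""
    t0 = time.perf_counter()
    params = replace(params, corticotomy_depth=spec.corticotomy_depth)
    try:
        outlines = build_outline(params)
    except Exception as exc:
        raise ScenarioError(f"geometry stage failed: {exc}") from exc
    try:
        mesh = generate_mesh(outlines, h_pdl=h_pdl, h_far=h_far)
    except Exception as exc:
        raise ScenarioError(f"meshing stage failed: {exc}") from exc
    log.info("stage=mesh scenario=%s nodes=%d elements=%d",
             spec.name, mesh.n_nodes, mesh.n_elements)
    if mats is None:
        mats = default_material_set(cortical_E=cortical_E, pdl_model=pdl_model)
    else:
        pdl_model = mats.pdl_model
    load = build_load_case(spec, mesh)
    try:
        if pdl_model == "ogden":
            sol = solve_newton(mesh, mats, load, steps=newton_steps)
        else:
            sol = solve_linear(mesh, mats, load)
    except Exception as exc:
        raise ScenarioError(f"solver stage failed: {exc}") from exc
    tracking = locate_tracking_nodes(mesh, params)
    summary = displacement_summary(sol, tracking)
    profile = pdl_stress_profile(sol, mesh)
    log.info("stage=solve scenario=%s E=%g residual=%.3g wall=%.2fs",
             spec.name, cortical_E, sol.residual_norm, time.perf_counter() - t0)
    return ScenarioResult(spec=spec, cortical_E=cortical_E, solution=sol,
                          tracking=tracking, summary=summary,
                          pdl_profile=profile, mesh=mesh)


def run_comparison(params: PhenotypeParams | None = None,
                   cortical_E_values=(12500.0, 27500.0),
                   **kwargs) -> list:
    """All three protocols at each cortical modulus (deterministic order:
    scenario, then E)."""
    params = params or PhenotypeParams()
    results = []
    for name in SCENARIO_NAMES:
        for E in cortical_E_values:
            results.append(run_scenario(params, make_scenario(name), E, **kwargs))
    return results
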