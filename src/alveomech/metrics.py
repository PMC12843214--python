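"""Post-processing readouts: displacement-pattern classification, PDL
stress-regime profiles, and the qualitative scenario comparison table.

Pattern classification is by sign concordance only: crown and apex moving in
the same buccolingual direction (both above the tie tolerance) is
translation-dominant, anything else tipping-dominant.  The PDL profile samples
the normal stress across the ligament mid-line from crest (arc position 0) to
apex (1) on each side; negative values are compression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import Mesh, PDL, TrackingNodes
from .fem import Solution, displacement_at

__all__ = ["DisplacementSummary", "PDLStressProfile", "ComparisonTable",
           "displacement_summary", "pdl_stress_profile",
           "qualitative_comparison",
           "TIPPING_DOMINANT", "TRANSLATION_DOMINANT"]

TIPPING_DOMINANT = "tipping_dominant"
TRANSLATION_DOMINANT = "translation_dominant"
THIRDS = ("cervical", "middle", "apical")

#: Displacements below this magnitude (um) count as zero when classifying.
TIE_TOLERANCE_UM = 0.01
#: Minimum contiguous fraction of the buccal arc that must be tensile for the
#: tensile-band flag.
TENSILE_BAND_FRACTION = 0.5


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class DisplacementSummary:
    crown_disp_x: float                   # um, +x buccal
    apex_disp_x: float                    # um
    pattern: str
    crown_apex_discrepancy: float         # um, |crown - apex|


def classify_pattern(crown_um: float, apex_um: float,
                     tie_tolerance: float = TIE_TOLERANCE_UM) -> str:
    """Sign-concordance pattern rule with a tie tolerance: values below the
    tolerance are treated as zero, which conservatively reads as tipping."""
    c = crown_um if abs(crown_um) > tie_tolerance else 0.0
    a = apex_um if abs(apex_um) > tie_tolerance else 0.0
    if c != 0.0 and a != 0.0 and np.sign(c) == np.sign(a):
        return TRANSLATION_DOMINANT
    return TIPPING_DOMINANT


def displacement_summary(sol: Solution, tracking: TrackingNodes,
                         tie_tolerance: float = TIE_TOLERANCE_UM
                         ) -> DisplacementSummary:
    crown = float(displacement_at(sol, tracking.crown_node)[0])
    apex = float(displacement_at(sol, tracking.apex_node)[0])
    return DisplacementSummary(
        crown_disp_x=crown, apex_disp_x=apex,
        pattern=classify_pattern(crown, apex, tie_tolerance),
        crown_apex_discrepancy=abs(crown - apex))


# ---------------------------------------------------------------------------
# PDL stress profile
# ---------------------------------------------------------------------------

@dataclass
class PDLStressProfile:
    """Normal-stress samples along the PDL mid-line on both sides.

    ``samples`` columns: side (buccal/palatal), arc (0 = crest, 1 = apex),
    x, y, normal_stress (MPa, negative = compression), third.
    """

    samples: pd.DataFrame
    peak_compression_location: tuple      # (side, third)
    buccal_tensile_band: bool
    tensile_band_fraction: float          # threshold used for the flag
    marginal_buccal_mean_stress: float    # MPa, mean over buccal cervical third

    def tensile_run_fraction(self, side: str = "buccal") -> float:
        """Longest contiguous run of tensile samples as an arc fraction."""
        s = self.samples[self.samples["side"] == side]
        tensile = (s["normal_stress"].to_numpy() > 0).astype(int)
        best = run = 0
        for v in tensile:
            run = run + 1 if v else 0
            best = max(best, run)
        return best / max(len(tensile), 1)


def _third_of(arc: float) -> str:
    if arc < 1.0 / 3.0:
        return "cervical"
    if arc < 2.0 / 3.0:
        return "middle"
    return "apical"


def pdl_stress_profile(sol: Solution, mesh: Mesh, n_samples: int = 60,
                       tensile_band_fraction: float = TENSILE_BAND_FRACTION
                       ) -> PDLStressProfile:
    """Sample n.sigma.n across the PDL mid-line, n the outward root-surface
    normal; flag a continuous buccal tensile band and locate the compression
    peak by (side, third)."""
    pdl_el = mesh.region_elements(PDL)
    if len(pdl_el) == 0:
        raise MetricsError("mesh has no PDL region")
    meta = mesh.meta
    params = meta.get("params")
    if params is None:
        raise MetricsError("mesh carries no geometry metadata for profiling")
    L = params.root_length
    t = params.pdl_thickness

    # element-constant stresses: nearest-PDL-centroid lookup
    centroids = mesh.nodes[mesh.elements[pdl_el]].mean(axis=1)
    tree = cKDTree(centroids)
    sig = sol.element_stress[pdl_el]

    arcs = (np.arange(n_samples) + 0.5) / n_samples
    rows = []
    for side, sign in (("buccal", 1.0), ("palatal", -1.0)):
        ys = -arcs * L
        hw = params.half_width(ys)
        # outward surface normal of x = +-w(y):  (sign, -sign * dw/dy)
        dwdy = np.gradient(hw, ys)
        nx = np.full_like(ys, sign)
        ny = -sign * dwdy
        nrm = np.hypot(nx, ny)
        nx, ny = nx / nrm, ny / nrm
        px = sign * hw + nx * (t / 2.0)
        py = ys + ny * (t / 2.0)
        _, idx = tree.query(np.column_stack([px, py]))
        s = sig[idx]
        normal = (nx * (s[:, 0, 0] * nx + s[:, 0, 1] * ny)
                  + ny * (s[:, 1, 0] * nx + s[:, 1, 1] * ny))
        for a, x_, y_, ns in zip(arcs, px, py, normal):
            rows.append((side, float(a), float(x_), float(y_), float(ns),
                         _third_of(a)))
    df = pd.DataFrame(rows, columns=["side", "arc", "x", "y",
                                     "normal_stress", "third"])

    peak = df.loc[df["normal_stress"].idxmin()]
    peak_loc = (str(peak["side"]), str(peak["third"]))

    buc = df[df["side"] == "buccal"]
    marginal = buc[buc["third"] == "cervical"]["normal_stress"].mean()

    profile = PDLStressProfile(
        samples=df, peak_compression_location=peak_loc,
        buccal_tensile_band=False,
        tensile_band_fraction=tensile_band_fraction,
        marginal_buccal_mean_stress=float(marginal))
    profile.buccal_tensile_band = (
        profile.tensile_run_fraction("buccal") >= tensile_band_fraction)
    return profile


# ---------------------------------------------------------------------------
# Qualitative comparison table
# ---------------------------------------------------------------------------

@dataclass
class ComparisonTable:
    """One row per scenario x cortical modulus run."""

    rows: pd.DataFrame

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.rows.to_json(path, orient="records", indent=2)


def qualitative_comparison(results) -> ComparisonTable:
    """Assemble the per-run qualitative table (deterministic ordering:
    scenario name order as given, then cortical modulus)."""
    results = list(results)
    if not results:
        raise MetricsError("no scenario results to compare")
    order = {"CONVENTIONAL": 0, "CORTICOTOMY": 1, "BPS": 2}
    results.sort(key=lambda r: (order.get(r.spec.name, 99), r.cortical_E))
    rows = []
    for r in results:
        rows.append({
            "scenario": r.spec.name,
            "cortical_E_MPa": r.cortical_E,
            "crown_disp_um": r.summary.crown_disp_x,
            "apex_disp_um": r.summary.apex_disp_x,
            "pattern": r.summary.pattern,
            "peak_compression_side": r.pdl_profile.peak_compression_location[0],
            "peak_compression_third": r.pdl_profile.peak_compression_location[1],
            "buccal_tensile_band": r.pdl_profile.buccal_tensile_band,
            "marginal_buccal_mean_stress_MPa":
                r.pdl_profile.marginal_buccal_mean_stress,
        })
    return ComparisonTable(rows=pd.DataFrame(rows))
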