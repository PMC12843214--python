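"""Constitutive models: plane-strain linear elasticity per region and a
one-term Ogden hyperelastic law for the periodontal ligament.

Units are mm-N-MPa throughout; GPa is accepted only at the config boundary
(converted by 1000).  The Ogden law is the compressible deviatoric/volumetric
split W = (2 mu / alpha^2) (lbar1^a + lbar2^a + lbar3^a - 3) + K/2 (J - 1)^2
with lbar_i = J^(-1/3) lambda_i, whose consistent small-strain shear modulus
is mu; with K >> mu the linearized Young modulus approaches 3 mu.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (TOOTH, PDL, CORT_BUCCAL, CORT_PALATAL, CANCELLOUS,
                       CORTICOTOMY_BAND)

__all__ = [
    "LinearElastic", "OgdenParams", "MaterialCard",
    "plane_strain_matrix", "ogden_stress", "ogden_principal_stress",
    "default_material_set",
]


class MaterialError(ValueError):
    pass


@dataclass(frozen=True)
class LinearElastic:
    """Isotropic linear elasticity: Young's modulus E (MPa), Poisson nu."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise MaterialError(f"E must be > 0, got {self.E!r}")
        if not 0 <= self.nu < 0.5:
            raise MaterialError(
                f"nu must be in [0, 0.5) (incompressible limit not "
                f"representable in plane strain), got {self.nu!r}")


@dataclass(frozen=True)
class OgdenParams:
    """One-term Ogden parameters: mu (MPa), exponent alpha, bulk modulus (MPa).

    Near-incompressibility contract: bulk >= 100 mu.
    """

    mu: float = 0.2
    alpha: float = 2.0
    bulk: float = 100.0

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise MaterialError(f"mu must be > 0, got {self.mu!r}")
        if self.bulk < 100.0 * self.mu:
            raise MaterialError(
                f"bulk must be >= 100*mu for near-incompressibility "
                f"(bulk={self.bulk!r}, mu={self.mu!r})")


@dataclass(frozen=True)
class MaterialCard:
    """Region label -> material model, plus the PDL model flag."""

    materials: dict
    pdl_model: str = "linear"              # "linear" | "ogden"
    pdl_ogden: OgdenParams = field(default_factory=OgdenParams)

    def __post_init__(self) -> None:
        if self.pdl_model not in ("linear", "ogden"):
            raise MaterialError(f"unknown pdl_model {self.pdl_model!r}")

    def require_regions(self, labels) -> None:
        missing = [lb for lb in set(labels) if lb not in self.materials]
        if missing:
            raise MaterialError(f"no material assigned for regions {sorted(missing)}")

    def with_pdl_model(self, pdl_model: str) -> "MaterialCard":
        return replace(self, pdl_model=pdl_model)


def plane_strain_matrix(mat: LinearElastic) -> np.ndarray:
    """3x3 plane-strain constitutive matrix mapping engineering strain
    (eps_xx, eps_yy, gamma_xy) to stress (sig_xx, sig_yy, tau_xy), MPa."""
    E, nu = mat.E, mat.nu
    c = 1.0 / ((1.0 + nu) * (1.0 - 2.0 * nu))
    base = c * np.array([
        [1.0 - nu, nu, 0.0],
        [nu, 1.0 - nu, 0.0],
        [0.0, 0.0, (1.0 - 2.0 * nu) / 2.0],
    ])
    return E * base         # scaling in E is exact by construction


# ---------------------------------------------------------------------------
# Ogden hyperelasticity
# ---------------------------------------------------------------------------

def ogden_principal_stress(p: OgdenParams, stretches) -> np.ndarray:
    """Principal Cauchy stresses (MPa) for principal stretches (l1, l2, l3)."""
    lam = np.asarray(stretches, dtype=float)
    if lam.shape != (3,) or np.any(lam <= 0):
        raise MaterialError("stretches must be three positive values")
    J = lam.prod()
    lbar = J ** (-1.0 / 3.0) * lam
    la = lbar ** p.alpha
    dev = (2.0 * p.mu / (p.alpha * J)) * (la - la.mean())
    return dev + p.bulk * (J - 1.0)


def _ogden_stress_batch(p: OgdenParams, F: np.ndarray) -> np.ndarray:
    """Plane-strain (lambda3 = 1) Cauchy stress for a batch of 2x2 deformation
    gradients, shape (..., 2, 2)."""
    F = np.asarray(F, dtype=float)
    J = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    if np.any(J <= 0):
        raise MaterialError("inverted element: det(F) <= 0")
    # left Cauchy-Green tensor b = F F^T, symmetric 2x2
    b11 = F[..., 0, 0] ** 2 + F[..., 0, 1] ** 2
    b22 = F[..., 1, 0] ** 2 + F[..., 1, 1] ** 2
    b12 = F[..., 0, 0] * F[..., 1, 0] + F[..., 0, 1] * F[..., 1, 1]
    tr = b11 + b22
    disc = np.sqrt(np.maximum((0.5 * (b11 - b22)) ** 2 + b12 ** 2, 0.0))
    e1 = 0.5 * tr + disc
    e2 = 0.5 * tr - disc
    lam1 = np.sqrt(e1)
    lam2 = np.sqrt(np.maximum(e2, 1e-300))
    Jm13 = J ** (-1.0 / 3.0)
    la1 = (Jm13 * lam1) ** p.alpha
    la2 = (Jm13 * lam2) ** p.alpha
    la3 = Jm13 ** p.alpha
    mean = (la1 + la2 + la3) / 3.0
    vol = p.bulk * (J - 1.0)
    s1 = (2.0 * p.mu / (p.alpha * J)) * (la1 - mean) + vol
    s2 = (2.0 * p.mu / (p.alpha * J)) * (la2 - mean) + vol
    # principal direction of b for e1: (b12, e1 - b11), or x-axis if isotropic
    vx = np.where(disc > 1e-14 * tr, b12, 1.0)
    vy = np.where(disc > 1e-14 * tr, e1 - b11, 0.0)
    # handle b12 == 0 with distinct eigenvalues (axis-aligned b)
    axis_aligned = (np.abs(b12) < 1e-300) & (disc > 1e-14 * tr)
    vx = np.where(axis_aligned, np.where(b11 >= b22, 1.0, 0.0), vx)
    vy = np.where(axis_aligned, np.where(b11 >= b22, 0.0, 1.0), vy)
    nrm = np.sqrt(vx ** 2 + vy ** 2)
    vx, vy = vx / nrm, vy / nrm
    sig = np.empty(F.shape[:-2] + (2, 2))
    sig[..., 0, 0] = s1 * vx ** 2 + s2 * vy ** 2
    sig[..., 1, 1] = s1 * vy ** 2 + s2 * vx ** 2
    sig[..., 0, 1] = (s1 - s2) * vx * vy
    sig[..., 1, 0] = sig[..., 0, 1]
    return sig


def ogden_stress(p: OgdenParams, F: np.ndarray) -> np.ndarray:
    """2x2 Cauchy stress (MPa) for a single plane-strain deformation gradient."""
    F = np.asarray(F, dtype=float)
    if F.shape != (2, 2):
        raise MaterialError(f"F must be 2x2, got shape {F.shape}")
    return _ogden_stress_batch(p, F[None])[0]


# ---------------------------------------------------------------------------
# Default material set
# ---------------------------------------------------------------------------

#: Fixed defaults for the regions the study does not vary (MPa).
DEFAULT_TOOTH = LinearElastic(E=18000.0, nu=0.30)
DEFAULT_CANCELLOUS = LinearElastic(E=1000.0, nu=0.30)
DEFAULT_PDL_LINEAR = LinearElastic(E=0.68, nu=0.45)
CORTICAL_NU = 0.30
#: Stiffness knock-down of the corticotomy band relative to cortical bone.
BAND_SOFTENING = 1e-3


def default_material_set(cortical_E: float = 12500.0,
                         pdl_model: str = "linear",
                         band_softening: float = BAND_SOFTENING,
                         pdl_ogden: OgdenParams | None = None) -> MaterialCard:
    """Material card covering every region label.

    ``cortical_E`` (MPa) is the density-dependent cortical-bone modulus — the
    quantity the study varies (12.5 or 27.5 GPa).  The corticotomy band gets
    ``cortical_E * band_softening`` (non-zero to keep the system regular).
    """
    if not cortical_E > 0:
        raise MaterialError(f"cortical_E must be > 0, got {cortical_E!r}")
    if not 0 < band_softening <= 1:
        raise MaterialError(f"band_softening must be in (0, 1], got {band_softening!r}")
    cort = LinearElastic(E=cortical_E, nu=CORTICAL_NU)
    band = LinearElastic(E=cortical_E * band_softening, nu=CORTICAL_NU)
    mats = {
        TOOTH: DEFAULT_TOOTH,
        CANCELLOUS: DEFAULT_CANCELLOUS,
        PDL: DEFAULT_PDL_LINEAR,
        CORT_BUCCAL: cort,
        CORT_PALATAL: cort,
        CORTICOTOMY_BAND: band,
    }
    return MaterialCard(materials=mats, pdl_model=pdl_model,
                        pdl_ogden=pdl_ogden or OgdenParams())
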