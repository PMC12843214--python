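"""Synthetic inputs: phenotype parameter draws and duplicate-measurement
studies for exercising the measurement and reliability analytics.

The thin phenotype class anchors its buccal cortical thickness range to the
pre-treatment spread observed clinically (0.18-1.11 mm).  The measurement
study model is: true site value ~ Normal(mean, sd) truncated at 0, treatment
effect ~ Normal added to form the post value, and each duplicate reading =
true value + independent examiner noise, so the Dahlberg error estimates the
examiner noise sd and the ICC estimates sigma_b^2 / (sigma_b^2 + sigma_e^2).
All draws come from a seeded generator; there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import PhenotypeParams
from .cbct import MeasurementTable, PairedMeasurements

__all__ = ["PhenotypeClass", "SynthStudySpec", "THIN_PHENOTYPE",
           "NORMAL_PHENOTYPE", "sample_phenotype", "synth_measurement_study",
           "write_table"]


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class PhenotypeClass:
    """Named range of buccal cortical and PDL thicknesses (mm intervals)."""

    label: str
    buccal_cortical_range: tuple
    pdl_range: tuple

    def __post_init__(self) -> None:
        for name in ("buccal_cortical_range", "pdl_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise SynthError(f"{name} must be a positive interval with "
                                 f"lower < upper, got ({lo}, {hi})")


THIN_PHENOTYPE = PhenotypeClass("thin", (0.18, 1.11), (0.15, 0.25))
NORMAL_PHENOTYPE = PhenotypeClass("normal", (1.11, 2.0), (0.15, 0.25))


@dataclass(frozen=True)
class SynthStudySpec:
    """Generating model of a duplicate-measurement treatment study."""

    n_sites: int = 100
    true_mean_mm: float = 8.0
    true_sd_mm: float = 1.0
    examiner_noise_sd_mm: float = 0.1
    effect_mean_mm: float = 0.3
    effect_sd_mm: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise SynthError(f"n_sites must be >= 1, got {self.n_sites}")
        for name in ("true_sd_mm", "examiner_noise_sd_mm", "effect_sd_mm"):
            if getattr(self, name) < 0:
                raise SynthError(f"{name} must be >= 0")


def sample_phenotype(cls: PhenotypeClass, seed: int,
                     base: PhenotypeParams | None = None) -> PhenotypeParams:
    """Uniform draw of the class intervals on top of default geometry;
    deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    base = base or PhenotypeParams()
    bct = float(rng.uniform(*cls.buccal_cortical_range))
    pdl = float(rng.uniform(*cls.pdl_range))
    return replace(base, buccal_cortical_thickness=bct, pdl_thickness=pdl)


def _truncated_normal(rng, mean, sd, size):
    """Normal(mean, sd) truncated below at 0 (physical lengths)."""
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def synth_measurement_study(spec: SynthStudySpec):
    """Generate (measurement table, duplicate readings) under the study model.

    Returns ``(table, duplicates)``: a pre/post MeasurementTable whose deltas
    realize the treatment-effect distribution, and PairedMeasurements of two
    noisy readings of each pre-treatment true value.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sites
    true = _truncated_normal(rng, spec.true_mean_mm, spec.true_sd_mm, n)
    effect = (np.full(n, spec.effect_mean_mm) if spec.effect_sd_mm == 0
              else rng.normal(spec.effect_mean_mm, spec.effect_sd_mm, n))
    post = np.maximum(true + effect, 0.0)
    labels = [str(i + 1) for i in range(n)]
    table = MeasurementTable(
        site_type="ridge_width", arch="none",
        rows=pd.DataFrame({"segment": labels, "pre_mm": true, "post_mm": post}))
    noise = rng.normal(0.0, spec.examiner_noise_sd_mm, (n, 2)) \
        if spec.examiner_noise_sd_mm > 0 else np.zeros((n, 2))
    dup = PairedMeasurements(labels=labels, m1=true + noise[:, 0],
                             m2=true + noise[:, 1])
    return table, dup


def write_table(t: MeasurementTable, path) -> None:
    """Write a table in the CSV dialect ``read_table`` accepts, keeping
    enough digits to round-trip to 1e-9 mm."""
    t.rows.to_csv(path, index=False, float_format="%.12g")
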