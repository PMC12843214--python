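"""CBCT-derived linear-measurement analytics and reliability statistics.

Measurement tables pair pre- and post-treatment values by anatomical segment:
alveolar ridge width is the bucco-palatal distance between the outer cortical
plates at mid-root level, buccal plate thickness the perpendicular distance
from the root surface to the buccal cortex.  Reliability of duplicate
measurements is summarized by the Dahlberg error sqrt(sum d^2 / 2n) and the
two-way random-effects, absolute-agreement, single-measurement intraclass
correlation coefficient (ICC(A,1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MeasurementTable", "ChangeTable", "PairedMeasurements",
           "read_table", "compute_changes", "dahlberg_error", "icc",
           "fixture_path", "load_fixture"]

SITE_TYPES = ("ridge_width", "buccal_plate")
ARCHES = ("maxilla", "mandible", "none")

#: Shipped fixture tables (transcribed pre/post linear measurements).
FIXTURES = {
    ("ridge_width", "maxilla"): "table3_maxilla.csv",
    ("ridge_width", "mandible"): "table3_mandible.csv",
    ("buccal_plate", "none"): "table4_buccal_plate.csv",
}


class TableError(ValueError):
    pass


@dataclass
class MeasurementTable:
    """Paired pre/post linear measurements (mm) by segment."""

    site_type: str
    arch: str
    rows: pd.DataFrame                    # columns: segment, pre_mm, post_mm

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise TableError(f"unknown site_type {self.site_type!r}")
        if self.arch not in ARCHES:
            raise TableError(f"unknown arch {self.arch!r}")
        r = self.rows
        for col in ("segment", "pre_mm", "post_mm"):
            if col not in r.columns:
                raise TableError(f"missing column {col!r}")
        if (r["pre_mm"] < 0).any() or (r["post_mm"] < 0).any():
            raise TableError("measurements must be >= 0 mm")
        if r["segment"].duplicated().any():
            dup = r["segment"][r["segment"].duplicated()].iloc[0]
            raise TableError(f"duplicate segment label {dup!r}")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class ChangeTable:
    """Per-segment treatment change (delta = post - pre) with a summary.

    ``delta_mm`` is full precision; ``delta_reported`` is rounded to 2
    decimals half-up, matching the precision clinical tables print.  Sign
    counts in the summary use the reported value, so a change that rounds to
    0.00 counts as zero.
    """

    rows: pd.DataFrame
    summary: dict


@dataclass
class PairedMeasurements:
    """Duplicate readings (mm) of the same sites by the same examiner."""

    labels: list
    m1: np.ndarray
    m2: np.ndarray

    def __post_init__(self) -> None:
        self.m1 = np.asarray(self.m1, dtype=float)
        self.m2 = np.asarray(self.m2, dtype=float)
        if not (len(self.labels) == len(self.m1) == len(self.m2)):
            raise TableError("labels, m1, m2 must have equal length")
        if len(self.m1) < 1:
            raise TableError("at least one measurement pair is required")

    def __len__(self) -> int:
        return len(self.m1)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_MINUS_VARIANTS = str.maketrans({"−": "-", "–": "-"})


def _parse_number(cell: str, row: int, col: str) -> float:
    s = str(cell).strip().translate(_MINUS_VARIANTS)
    try:
        return float(s)
    except ValueError:
        raise TableError(
            f"non-numeric value {cell!r} in column {col!r}, row {row}") from None


def read_table(path, site_type: str, arch: str = "none") -> MeasurementTable:
    """Read a segment,pre_mm,post_mm CSV.  The Unicode minus (U+2212) is
    accepted and normalized; parse errors name the offending row."""
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for col in ("segment", "pre_mm", "post_mm"):
        if col not in df.columns:
            raise TableError(f"missing column {col!r} in {path}")
    out = pd.DataFrame({
        "segment": df["segment"].astype(str).str.strip(),
        "pre_mm": [_parse_number(v, i + 2, "pre_mm")
                   for i, v in enumerate(df["pre_mm"])],
        "post_mm": [_parse_number(v, i + 2, "post_mm")
                    for i, v in enumerate(df["post_mm"])],
    })
    if out["segment"].duplicated().any():
        dup = out["segment"][out["segment"].duplicated()]
        raise TableError(
            f"duplicate segment label {dup.iloc[0]!r} at row {dup.index[0] + 2}")
    return MeasurementTable(site_type=site_type, arch=arch, rows=out)


def fixture_path(name: str) -> Path:
    """Path of a shipped fixture CSV inside the package data directory."""
    return Path(resources.files("alveomech").joinpath("data", name))


def load_fixture(site_type: str, arch: str = "none") -> MeasurementTable:
    """Load one of the shipped measurement tables."""
    try:
        fname = FIXTURES[(site_type, arch)]
    except KeyError:
        raise TableError(f"no shipped fixture for ({site_type!r}, {arch!r})") from None
    return read_table(fixture_path(fname), site_type=site_type, arch=arch)


# ---------------------------------------------------------------------------
# Change arithmetic
# ---------------------------------------------------------------------------

def round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def compute_changes(t: MeasurementTable) -> ChangeTable:
    """Recompute delta = post - pre per segment (never trusted from input)."""
    if len(t) == 0:
        raise TableError("empty measurement table")
    rows = t.rows.copy()
    rows["delta_mm"] = rows["post_mm"] - rows["pre_mm"]
    rows["delta_reported"] = [round_half_up(v) for v in rows["delta_mm"]]
    rep = rows["delta_reported"]
    summary = {
        "n": int(len(rows)),
        "mean_delta_mm": float(rows["delta_mm"].mean()),
        "min_delta_mm": float(rows["delta_mm"].min()),
        "max_delta_mm": float(rows["delta_mm"].max()),
        "n_positive": int((rep > 0).sum()),
        "n_negative": int((rep < 0).sum()),
        "n_zero": int((rep == 0).sum()),
    }
    return ChangeTable(rows=rows, summary=summary)


# ---------------------------------------------------------------------------
# Reliability statistics
# ---------------------------------------------------------------------------

def dahlberg_error(p: PairedMeasurements) -> float:
    """Dahlberg duplicate-measurement error sqrt(sum d^2 / 2n), mm."""
    d = p.m1 - p.m2
    return float(math.sqrt(np.sum(d * d) / (2.0 * len(p))))


def icc(p: PairedMeasurements) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single
    measurement, from the two-way ANOVA decomposition with k = 2 readings."""
    n = len(p)
    if n < 3:
        raise TableError("ICC requires at least 3 measurement pairs")
    data = np.column_stack([p.m1, p.m2])     # (n subjects, k raters)
    k = 2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    if np.allclose(data, grand):
        raise TableError("undefined ICC: zero total variance")
    ss_total = np.sum((data - grand) ** 2)
    ss_rows = k * np.sum((subj_means - grand) ** 2)
    ss_cols = n * np.sum((rater_means - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise TableError("undefined ICC: zero total variance")
    return float((msr - mse) / denom)
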