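"""Descriptive aggregation of per-specimen results into study tables.

Small-sample cadaveric studies report mean, SD and range per ligament.
The SD convention here is the population SD (divisor n), which is the
convention the bundled reference tables follow; with a single specimen
(the DOB case) the SD and range are reported as missing rather than
zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import EmptyResultError, ValidationError
from .morphometry import MorphometryRecord
from .tensile import TensileResult


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), matching printed tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SummaryStats:
    """Count, mean, population SD and range of one quantity."""

    n: int
    mean: float
    sd: float | None
    min: float | None
    max: float | None

    def __post_init__(self) -> None:
        if self.n >= 2:
            tol = 1e-9 * max(1.0, abs(self.max), abs(self.min))
            if not (self.min - tol <= self.mean <= self.max + tol):
                raise ValidationError("mean must lie within [min, max]")
        if self.sd is not None and self.sd < 0:
            raise ValidationError("sd must be non-negative")


def aggregate(values) -> SummaryStats:
    """Mean, population SD (divisor n) and range of a value list.

    A single value yields ``sd``/``min``/``max`` of None: one specimen
    carries no dispersion information, and reporting 0 would be
    misleading in a study table.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise EmptyResultError("cannot aggregate an empty value list")
    if not np.isfinite(arr).all():
        raise ValidationError("values must be finite")
    if arr.size == 1:
        return SummaryStats(n=1, mean=float(arr[0]), sd=None, min=None, max=None)
    return SummaryStats(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std()),  # population SD
        min=float(arr.min()),
        max=float(arr.max()),
    )


_TENSILE_QUANTITIES = (
    "csa",
    "first_peak_force",
    "ultimate_force",
    "stiffness",
    "ultimate_strain",
)


def _tensile_rows(records: list[TensileResult]) -> list[dict]:
    rows = []
    for rec in records:
        row = {"ligament_id": rec.ligament_id}
        for q in _TENSILE_QUANTITIES:
            v = getattr(rec, q)
            if v is not None:
                row[q] = v
        rows.append(row)
    return rows


def _morphometry_rows(records: list[MorphometryRecord]) -> list[dict]:
    rows = []
    for rec in records:
        row = {"ligament_id": rec.ligament_id}
        for pos, v in rec.radial_attachment_pct.items():
            row[f"radial_attachment_pct_{pos}"] = v
        for pos, v in rec.ulnar_attachment_pct.items():
            row[f"ulnar_attachment_pct_{pos}"] = v
        for pos, v in rec.fan_out_deg.items():
            row[f"fan_out_deg_{pos}"] = v
        if rec.width_radial is not None:
            row["width_radial"] = rec.width_radial
        if rec.width_ulnar is not None:
            row["width_ulnar"] = rec.width_ulnar
        row["mean_thickness"] = rec.mean_thickness
        rows.append(row)
    return rows


def make_table(
    records,
    decimals: int = 2,
    decimals_by_quantity: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Summary table (one row per ligament x quantity) with Mean/SD/Range.

    *records* is a homogeneous list of TensileResult or
    MorphometryRecord.  Values are rounded half-up to *decimals* places
    (overridable per quantity, e.g. 1 decimal for strain columns, to
    mirror tables whose inputs carry one decimal).  Single-specimen
    groups leave SD and Range empty.
    """
    records = list(records)
    if not records:
        warnings.warn("make_table received no records; returning empty table",
                      stacklevel=2)
        return pd.DataFrame(
            columns=["ligament_id", "quantity", "n", "mean", "sd", "min", "max"]
        )
    kinds = {type(r) for r in records}
    if kinds == {TensileResult}:
        rows = _tensile_rows(records)
    elif kinds == {MorphometryRecord}:
        rows = _morphometry_rows(records)
    else:
        raise TypeError(f"records must be homogeneous, got {sorted(k.__name__ for k in kinds)}")
    overrides = decimals_by_quantity or {}
    df = pd.DataFrame(rows)
    out = []
    quantities = [c for c in df.columns if c != "ligament_id"]
    for lig in pd.unique(df["ligament_id"]):
        sub = df[df["ligament_id"] == lig]
        for q in quantities:
            vals = sub[q].dropna()
            if vals.empty:
                continue
            st = aggregate(vals)
            dp = overrides.get(q, decimals)
            out.append(
                {
                    "ligament_id": lig,
                    "quantity": q,
                    "n": st.n,
                    "mean": round_half_up(st.mean, dp),
                    "sd": None if st.sd is None else round_half_up(st.sd, dp),
                    "min": None if st.min is None else round_half_up(st.min, dp),
                    "max": None if st.max is None else round_half_up(st.max, dp),
                }
            )
    return pd.DataFrame(out)
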