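"""Risk surface, class thresholds, Critical Dugong Habitat, MPA gap.

The consolidated risk surface is the cellwise product of the season-averaged
habitat suitability and the min-max-normalized fishing pressure.  Risk is
classified on the percent-of-range scale of the product (low 0-25, moderate
25-50, high 50-100, upper-inclusive boundaries); suitability uses the fixed
absolute quarters of [0, 1].  A Critical Dugong Habitat cell is a high-risk
cell with suitability strictly above 0.75.  The MPA gap report accounts
high-risk area inside and outside the protected-area mask in km².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import DomainError, Grid, masked_area

__all__ = [
    "SUITABILITY_CLASSES",
    "RISK_CLASSES",
    "CDHReport",
    "combine_seasons",
    "risk_surface",
    "classify_risk",
    "classify_suitability",
    "extract_cdh",
    "mpa_gap_report",
]

# Integer class codes carried in class grids.
SUITABILITY_CLASSES = {0: "unsuitable", 1: "low", 2: "moderate", 3: "high"}
RISK_CLASSES = {0: "low", 1: "moderate", 2: "high"}
RISK_HIGH = 2


@dataclass
class CDHReport:
    """Per-region protected-area gap accounting for high-risk habitat."""

    total_high_risk_km2: float
    protected_high_risk_km2: float
    outside_high_risk_km2: float
    pct_protected: float | None
    pct_outside: float | None
    pct_outside_int: int | None
    cdh_km2: float | None = None
    class_area_table: pd.DataFrame | None = None

    def to_text(self) -> str:
        lines = [
            f"High-risk area:            {self.total_high_risk_km2:.2f} km2",
            f"  protected (inside MPA):  {self.protected_high_risk_km2:.2f} km2",
            f"  outside MPA network:     {self.outside_high_risk_km2:.2f} km2",
        ]
        if self.pct_protected is not None:
            lines.append(f"  protected share:         {self.pct_protected:.1f}%")
            lines.append(f"  outside share:           about {self.pct_outside_int:d}%")
        else:
            lines.append("  protected share:         undefined (no high-risk area)")
        if self.cdh_km2 is not None:
            lines.append(f"Critical Dugong Habitat:   {self.cdh_km2:.2f} km2")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": [
                    "total_high_risk_km2",
                    "protected_high_risk_km2",
                    "outside_high_risk_km2",
                    "pct_protected",
                    "pct_outside",
                    "cdh_km2",
                ],
                "value": [
                    self.total_high_risk_km2,
                    self.protected_high_risk_km2,
                    self.outside_high_risk_km2,
                    self.pct_protected,
                    self.pct_outside,
                    self.cdh_km2,
                ],
            }
        )


def combine_seasons(suitability: list[Grid]) -> Grid:
    """Cellwise mean of the seasonal suitability grids (mask-intersected)."""
    if not suitability:
        raise DomainError("need at least one seasonal grid")
    first = suitability[0]
    for g in suitability[1:]:
        if not first.same_template(g):
            raise DomainError("seasonal grids must share a template")
    mask = np.logical_and.reduce([g.mask for g in suitability])
    mean = np.mean([g.values for g in suitability], axis=0)
    return first.with_values(np.where(mask, mean, 0.0), mask=mask)


def risk_surface(combined_suitability: Grid, pressure: Grid) -> Grid:
    """Suitability x normalized pressure; bounded by each factor."""
    if not combined_suitability.same_template(pressure):
        raise DomainError("suitability and pressure must share a template")
    pv = pressure.valid_values()
    if pv.size and (pv.max() > 1.0 + 1e-9 or pv.min() < -1e-9):
        raise DomainError("pressure must be min-max normalized to [0, 1] first")
    mask = combined_suitability.mask & pressure.mask
    vals = combined_suitability.values * pressure.values
    return combined_suitability.with_values(np.where(mask, vals, 0.0), mask=mask)


def _percent_of_range(grid: Grid):
    vals = grid.valid_values()
    if vals.size == 0:
        raise DomainError("no valid cells to classify")
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return None
    return np.where(grid.mask, 100.0 * (grid.values - lo) / (hi - lo), 0.0)


def classify_risk(risk: Grid) -> Grid:
    """Percent-of-range risk classes: [0,25] low, (25,50] moderate, (50,100] high."""
    pct = _percent_of_range(risk)
    if pct is None:
        warnings.warn("classify_risk: constant surface, all cells low risk", stacklevel=2)
        return risk.with_values(np.zeros_like(risk.values), degenerate=True)
    codes = np.zeros_like(risk.values)
    codes[pct > 25.0] = 1
    codes[pct > 50.0] = 2
    return risk.with_values(np.where(risk.mask, codes, 0.0))


def classify_suitability(suitability: Grid) -> Grid:
    """Fixed quarters of [0,1], upper-inclusive: 0.25 -> unsuitable, 0.75 -> moderate."""
    vals = suitability.valid_values()
    if vals.size and (vals.min() < -1e-12 or vals.max() > 1.0 + 1e-12):
        raise DomainError("suitability values must lie in [0, 1]")
    v = suitability.values
    codes = np.zeros_like(v)
    codes[v > 0.25] = 1
    codes[v > 0.5] = 2
    codes[v > 0.75] = 3
    return suitability.with_values(np.where(suitability.mask, codes, 0.0))


def extract_cdh(risk_class: Grid, suitability: Grid) -> Grid:
    """CDH mask: high risk class AND suitability strictly above 0.75."""
    if not risk_class.same_template(suitability):
        raise DomainError("risk class and suitability must share a template")
    mask = risk_class.mask & suitability.mask
    cdh = (risk_class.values == RISK_HIGH) & (suitability.values > 0.75) & mask
    return risk_class.with_values(cdh.astype(float), mask=mask)


def mpa_gap_report(
    high_risk_mask: Grid,
    mpa_mask: Grid,
    cell_area_km2: float | None = None,
    cdh_mask: Grid | None = None,
    risk_class: Grid | None = None,
) -> CDHReport:
    """Protected-area gap accounting over the high-risk mask.

    ``pct_protected`` is reported to one decimal; the outside share is
    additionally rounded to the nearest integer (the two reporting styles,
    e.g. "5.5%" protected and "about 95%" outside).
    """
    if not high_risk_mask.same_template(mpa_mask):
        raise DomainError("masks must share a template")
    area = cell_area_km2 if cell_area_km2 is not None else high_risk_mask.cell_area_km2
    total = masked_area(high_risk_mask, area)
    inter = high_risk_mask.with_values(
        high_risk_mask.values * mpa_mask.values,
        mask=high_risk_mask.mask & mpa_mask.mask,
    )
    protected = masked_area(inter, area)
    outside = total - protected
    if total > 0:
        raw_pct = 100.0 * protected / total
        pct_protected = round(raw_pct, 1)
        pct_outside = round(100.0 - raw_pct, 1)
        pct_outside_int = int(round(100.0 - raw_pct))
    else:
        pct_protected = pct_outside = pct_outside_int = None
    cdh_km2 = masked_area(cdh_mask, area) if cdh_mask is not None else None

    table = None
    if risk_class is not None:
        rows = []
        for code, label in RISK_CLASSES.items():
            cls_mask = risk_class.with_values((risk_class.values == code).astype(float))
            cls_total = masked_area(cls_mask, area)
            cls_inside = masked_area(
                cls_mask.with_values(
                    cls_mask.values * mpa_mask.values, mask=cls_mask.mask & mpa_mask.mask
                ),
                area,
            )
            rows.append(
                {
                    "risk_class": label,
                    "total_km2": cls_total,
                    "inside_mpa_km2": cls_inside,
                    "outside_mpa_km2": cls_total - cls_inside,
                }
            )
        table = pd.DataFrame(rows)

    return CDHReport(
        total_high_risk_km2=total,
        protected_high_risk_km2=protected,
        outside_high_risk_km2=outside,
        pct_protected=pct_protected,
        pct_outside=pct_outside,
        pct_outside_int=pct_outside_int,
        cdh_km2=cdh_km2,
        class_area_table=table,
    )
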