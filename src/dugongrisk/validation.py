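"""Boat-survey ground truthing: IDW threat surfaces and map agreement.

Threat counts at survey points are interpolated by global inverse-distance
weighting; the power is selected by scanning a grid (default 0.001-10 in
steps of 0.01) for the minimum leave-one-out RMSE.  The interpolated
surface is classified with the same percent-of-range rule as model risk,
and agreement between the two class maps is summarized by a confusion
matrix and Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import DomainError, Grid, PointSet
from .risk import RISK_CLASSES, classify_risk

__all__ = ["IDWConfig", "idw", "select_power", "classify_threat", "agreement", "cohens_kappa"]


@dataclass(frozen=True)
class IDWConfig:
    power_min: float = 0.001
    power_max: float = 10.0
    power_step: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.power_min < self.power_max:
            raise ValueError("need 0 < power_min < power_max")
        if self.power_step == 0:
            raise ValueError("power_step must be nonzero")

    @property
    def powers(self) -> np.ndarray:
        step = abs(self.power_step)
        return np.arange(self.power_min, self.power_max + step / 2.0, step)


def _finite_counts(points: PointSet):
    counts = points.counts
    keep = np.isfinite(counts)
    return points.x[keep], points.y[keep], counts[keep]


def idw(points: PointSet, template: Grid, power: float) -> Grid:
    """Global inverse-distance-weighted interpolation of point counts.

    A cell whose center coincides with a sample (distance below 1/100 of a
    cell) takes that sample's value exactly; everywhere else the value is
    the d^(-power)-weighted mean of all samples (a convex combination, so
    the output is bounded by the sample min/max).
    """
    px, py, pz = _finite_counts(points)
    if px.size < 2:
        raise DomainError("IDW needs at least 2 points with finite counts")
    xs, ys = template.cell_centers()
    d = np.hypot(xs.ravel()[:, None] - px[None, :], ys.ravel()[:, None] - py[None, :])
    snap_tol = min(abs(template.transform.cell_w), abs(template.transform.cell_h)) / 100.0
    out = np.empty(d.shape[0])
    coincident = d < snap_tol
    has_snap = coincident.any(axis=1)
    with np.errstate(divide="ignore", over="ignore"):
        w = np.power(np.where(coincident, np.inf, d), -float(power))
    w[~np.isfinite(w)] = 0.0
    wsum = w.sum(axis=1)
    wsum[wsum == 0] = 1.0
    out = (w @ pz) / wsum
    if has_snap.any():
        nearest = np.where(coincident, d, np.inf).argmin(axis=1)
        out[has_snap] = pz[nearest[has_snap]]
    vals = out.reshape(template.shape)
    return template.with_values(np.where(template.mask, vals, 0.0))


def select_power(points: PointSet, template: Grid, config: IDWConfig | None = None):
    """Power minimizing leave-one-out RMSE; ties go to the smallest power.

    Returns ``(power, rmse_table)`` where the table holds the scanned
    powers and their LOOCV RMSE.
    """
    config = config or IDWConfig()
    px, py, pz = _finite_counts(points)
    n = px.size
    if n < 3:
        raise DomainError("power selection needs at least 3 points")
    d = np.hypot(px[:, None] - px[None, :], py[:, None] - py[None, :])
    np.fill_diagonal(d, np.inf)
    powers = config.powers
    rmses = np.empty(powers.size)
    with np.errstate(divide="ignore", over="ignore"):
        for i, p in enumerate(powers):
            w = d ** (-float(p))
            w[~np.isfinite(w)] = 0.0
            wsum = w.sum(axis=1)
            pred = np.where(wsum > 0, (w @ pz) / np.where(wsum > 0, wsum, 1.0), pz.mean())
            rmses[i] = np.sqrt(np.mean((pred - pz) ** 2))
    best = int(np.argmin(np.round(rmses, 12)))  # first (= smallest power) on ties
    table = pd.DataFrame({"power": powers, "loocv_rmse": rmses})
    return float(powers[best]), table


def classify_threat(surface: Grid) -> Grid:
    """Percent-of-range threat classes (shared rule with model risk)."""
    return classify_risk(surface)


def cohens_kappa(confusion: np.ndarray) -> float:
    """kappa = (p_o - p_e) / (1 - p_e); 0 when agreement is chance-only."""
    confusion = np.asarray(confusion, dtype=float)
    total = confusion.sum()
    if total <= 0:
        raise DomainError("empty confusion matrix")
    p_o = np.trace(confusion) / total
    row = confusion.sum(axis=1) / total
    col = confusion.sum(axis=0) / total
    p_e = float(row @ col)
    if np.isclose(p_e, 1.0):
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def agreement(model_classes: Grid, survey_classes: Grid):
    """3x3 confusion over jointly valid cells plus Cohen's kappa.

    Returns ``(confusion DataFrame, kappa)``.
    """
    if not model_classes.same_template(survey_classes):
        raise DomainError("class grids must share a template")
    shared = model_classes.mask & survey_classes.mask
    if not shared.any():
        raise DomainError("no shared valid cells")
    a = model_classes.values[shared].astype(int)
    b = survey_classes.values[shared].astype(int)
    labels = sorted(RISK_CLASSES)
    mat = np.zeros((len(labels), len(labels)))
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            mat[i, j] = np.sum((a == la) & (b == lb))
    names = [RISK_CLASSES[l] for l in labels]
    confusion = pd.DataFrame(mat, index=names, columns=names)
    return confusion, cohens_kappa(mat)
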