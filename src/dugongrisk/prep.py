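"""Occurrence cleaning and predictor screening.

Mirrors the pre-modelling workflow of presence-only SDM studies: spatial
rarefaction to one observation per analysis-grid cell, month-based season
assignment, kernel-density sampling-bias surfaces, and greedy collinearity
pruning of the predictor stack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import DomainError, Grid, PointSet

__all__ = [
    "SeasonDefinition",
    "ani_seasons",
    "rarefy",
    "split_by_season",
    "kde_bias_surface",
    "screen_predictors",
]


@dataclass(frozen=True)
class SeasonDefinition:
    """Site-specific month → season mapping (every month mapped once)."""

    month_to_season: dict
    site: str = "unnamed"

    def __post_init__(self) -> None:
        months = set(self.month_to_season)
        if months != set(range(1, 13)):
            raise ValueError("every month 1-12 must be mapped to exactly one season")

    @property
    def seasons(self) -> tuple[str, ...]:
        seen: list[str] = []
        for m in range(1, 13):
            s = self.month_to_season[m]
            if s not in seen:
                seen.append(s)
        return tuple(seen)


def ani_seasons() -> SeasonDefinition:
    """Monsoon calendar for an oceanic-island site: Jan-Apr pre-monsoon,
    May-Sep (southwest) monsoon, Oct-Dec post-monsoon."""
    mapping = {}
    for m in (1, 2, 3, 4):
        mapping[m] = "pre_monsoon"
    for m in (5, 6, 7, 8, 9):
        mapping[m] = "monsoon"
    for m in (10, 11, 12):
        mapping[m] = "post_monsoon"
    return SeasonDefinition(month_to_season=mapping, site="ANI")


def rarefy(points: PointSet, template: Grid, seed: int = 0) -> PointSet:
    """Spatially rarefy to at most one point per valid template cell.

    The retained point in each occupied cell is chosen uniformly at random
    under ``seed``.  Points falling off-grid or on invalid cells are dropped
    with a warning.  Idempotent for any fixed grid.
    """
    if len(points) == 0:
        return points
    rows, cols = points.cells(template)
    nr, nc = template.shape
    on_grid = (rows >= 0) & (rows < nr) & (cols >= 0) & (cols < nc)
    valid = on_grid.copy()
    valid[on_grid] &= template.mask[rows[on_grid], cols[on_grid]]
    n_dropped = int((~valid).sum())
    if n_dropped:
        warnings.warn(f"rarefy: dropped {n_dropped} point(s) off-grid or on invalid cells", stacklevel=2)
    idx = np.flatnonzero(valid)
    cell_ids = rows[idx] * nc + cols[idx]
    rng = np.random.default_rng(seed)
    keep = []
    for cid in np.unique(cell_ids):
        members = idx[cell_ids == cid]
        keep.append(int(rng.choice(members)))
    return points.subset(sorted(keep))


def split_by_season(points: PointSet, seasons: SeasonDefinition):
    """Partition records into seasonal point sets.

    Records with an explicit season tag use it; otherwise the month of the
    record's date decides.  Records with neither are excluded.  Returns
    ``(mapping season -> PointSet, n_excluded)``.
    """
    buckets: dict[str, list[int]] = {s: [] for s in seasons.seasons}
    n_excluded = 0
    for i, row in points.df.iterrows():
        season = row["season"]
        if season is None or (isinstance(season, float) and np.isnan(season)):
            date = row["date"]
            if date is None or (isinstance(date, float) and np.isnan(date)):
                n_excluded += 1
                continue
            month = pd.Timestamp(date).month
            season = seasons.month_to_season[month]
        if season not in buckets:
            buckets[season] = []
        buckets[season].append(i)
    out = {s: points.subset(ix) if ix else PointSet(pd.DataFrame(columns=PointSet.COLUMNS)) for s, ix in buckets.items()}
    return out, n_excluded


def kde_bias_surface(points: PointSet, template: Grid, bandwidth=None) -> Grid:
    """Gaussian kernel-density sampling-effort surface on the template grid.

    A product Gaussian kernel with per-axis bandwidths (Silverman's rule,
    ``sigma * n^(-1/6)`` for two dimensions, unless given) is summed over
    the points at every cell center.  The surface is floored at 1% of its
    maximum (so bias-weighted background sampling is defined everywhere at
    sea) and rescaled to a maximum of 1.
    """
    n = len(points)
    if n < 2:
        raise DomainError("kernel density surface needs at least 2 points")
    px, py = points.x, points.y
    if bandwidth is None:
        hx = px.std(ddof=1) * n ** (-1.0 / 6.0)
        hy = py.std(ddof=1) * n ** (-1.0 / 6.0)
    else:
        hx = hy = float(bandwidth)
    cell = min(abs(template.transform.cell_w), abs(template.transform.cell_h))
    hx = max(hx, cell)
    hy = max(hy, cell)
    xs, ys = template.cell_centers()
    dx = (xs.ravel()[:, None] - px[None, :]) / hx
    dy = (ys.ravel()[:, None] - py[None, :]) / hy
    dens = np.exp(-0.5 * (dx**2 + dy**2)).sum(axis=1).reshape(template.shape)
    peak = dens[template.mask].max() if template.mask.any() else dens.max()
    if peak <= 0:
        raise DomainError("degenerate kernel density surface")
    dens = np.maximum(dens, 0.01 * peak)
    dens = dens / peak
    dens = np.clip(dens, None, 1.0)
    return template.with_values(np.where(template.mask, dens, 0.0))


def screen_predictors(stack: dict, threshold: float = 0.7):
    """Greedy collinearity pruning of a named predictor stack.

    Pearson correlations are computed over jointly valid cells.  While any
    pair exceeds ``|r| >= threshold``, the member of the worst pair with the
    higher mean absolute correlation to all remaining predictors is dropped.
    Constant layers are dropped first (correlation undefined).  Returns
    ``(retained names, correlation table)`` with the table computed on the
    original non-constant set.
    """
    if not stack:
        raise DomainError("screen_predictors needs at least one predictor")
    names = sorted(stack)
    joint = np.logical_and.reduce([stack[n].mask for n in names])
    data = {}
    for name in names:
        vals = stack[name].values[joint]
        if vals.size == 0 or vals.std() == 0:
            warnings.warn(f"screen_predictors: dropping constant layer {name!r}", stacklevel=2)
            continue
        data[name] = vals
    names = list(data)
    if len(names) <= 1:
        corr = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
        return names, corr
    mat = np.corrcoef(np.vstack([data[n] for n in names]))
    corr = pd.DataFrame(mat, index=names, columns=names)

    retained = list(names)
    while len(retained) > 1:
        sub = corr.loc[retained, retained].to_numpy().copy()
        np.fill_diagonal(sub, 0.0)
        absmax = np.abs(sub).max()
        if absmax < threshold:
            break
        i, j = np.unravel_index(np.abs(sub).argmax(), sub.shape)
        mean_i = np.abs(sub[i]).sum() / (len(retained) - 1)
        mean_j = np.abs(sub[j]).sum() / (len(retained) - 1)
        if mean_i > mean_j or (mean_i == mean_j and retained[i] > retained[j]):
            drop = retained[i]
        else:
            drop = retained[j]
        retained.remove(drop)
    return retained, corr
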