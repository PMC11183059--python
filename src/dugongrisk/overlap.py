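"""Niche similarity statistics between suitability surfaces.

Both statistics compare the two surfaces after normalizing each to sum 1
over their shared valid cells: Warren's I is one minus half the squared
Hellinger distance; Schoener's D is one minus half the L1 distance.  Both
are symmetric, scale-invariant, and lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import DomainError, Grid

__all__ = ["OverlapResult", "warren_I", "schoener_D", "niche_overlap", "overlap_matrix"]


@dataclass(frozen=True)
class OverlapResult:
    I: float
    D: float
    n_shared_cells: int


def _shared_distributions(a: Grid, b: Grid):
    if a.shape != b.shape:
        raise DomainError("surfaces must share a grid template")
    shared = a.mask & b.mask
    n = int(shared.sum())
    if n < 1:
        raise DomainError("no shared valid cells")
    va, vb = a.values[shared], b.values[shared]
    if np.any(va < 0) or np.any(vb < 0):
        raise DomainError("suitability surfaces must be nonnegative")
    sa, sb = va.sum(), vb.sum()
    if sa <= 0 or sb <= 0:
        raise DomainError("all-zero surface over shared cells")
    return va / sa, vb / sb, n


def warren_I(a: Grid, b: Grid) -> float:
    """I = 1 - 0.5 * sum (sqrt(pX) - sqrt(pY))^2."""
    pa, pb, _ = _shared_distributions(a, b)
    return float(1.0 - 0.5 * np.sum((np.sqrt(pa) - np.sqrt(pb)) ** 2))


def schoener_D(a: Grid, b: Grid) -> float:
    """D = 1 - 0.5 * sum |pX - pY|."""
    pa, pb, _ = _shared_distributions(a, b)
    return float(1.0 - 0.5 * np.sum(np.abs(pa - pb)))


def niche_overlap(a: Grid, b: Grid) -> OverlapResult:
    pa, pb, n = _shared_distributions(a, b)
    return OverlapResult(
        I=float(1.0 - 0.5 * np.sum((np.sqrt(pa) - np.sqrt(pb)) ** 2)),
        D=float(1.0 - 0.5 * np.sum(np.abs(pa - pb))),
        n_shared_cells=n,
    )


def overlap_matrix(surfaces: dict, statistic: str = "I") -> pd.DataFrame:
    """Pairwise overlap across named surfaces (e.g. seasons)."""
    if statistic not in ("I", "D"):
        raise ValueError("statistic must be 'I' or 'D'")
    names = list(surfaces)
    mat = np.ones((len(names), len(names)))
    for i, ni in enumerate(names):
        for j in range(i + 1, len(names)):
            res = niche_overlap(surfaces[ni], surfaces[names[j]])
            mat[i, j] = mat[j, i] = res.I if statistic == "I" else res.D
    return pd.DataFrame(mat, index=names, columns=names)
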