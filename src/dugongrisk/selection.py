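"""Candidate-settings evaluation and selection by least AICc.

Candidate feature-class/regularization combinations are fit on the full
occurrence set for AICc and on data partitions (random k-fold for > 50
points, leave-one-out jackknife otherwise) for mean±SD test AUC.  The
selected candidate is the AICc argmin, ties broken by higher test AUC, then
smaller nonzero-coefficient count, then input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import DomainError, Grid, PointSet
from . import maxent

__all__ = ["SettingsEvalResult", "partition", "aicc_value", "aicc", "select"]

JACKKNIFE_MAX_N = 50
DEFAULT_K = 5


@dataclass
class SettingsEvalResult:
    classes: tuple[str, ...]
    reg_multiplier: float
    K: int
    AICc: float
    mean_test_AUC: float
    sd_test_AUC: float
    folds: int

    @property
    def auc_label(self) -> str:
        return f"AUC ± SD = {self.mean_test_AUC:.3f} ± {self.sd_test_AUC:.3f}"


def partition(points: PointSet, seed: int = 0, k: int = DEFAULT_K) -> np.ndarray:
    """Fold assignment per point: k-fold above 50 points, else jackknife."""
    n = len(points)
    if n < 3:
        raise DomainError("need at least 3 points to partition")
    if n <= JACKKNIFE_MAX_N:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k
    return folds


def aicc_value(K: int, n: int, loglik: float) -> float:
    """Small-sample AIC: 2K - 2L + 2K(K+1)/(n-K-1); undefined if n <= K+1."""
    if n <= K + 1:
        return float("nan")
    return 2.0 * K - 2.0 * loglik + 2.0 * K * (K + 1) / (n - K - 1)


def aicc(model: maxent.MaxEntModel, occurrence_cells: np.ndarray, stack: dict) -> float:
    """AICc of a fitted model at its occurrence cells.

    Raw values are standardized to sum 1 over the full valid grid before the
    log-likelihood is accumulated; K counts nonzero coefficients.
    Over-parameterized models (n <= K+1) return NaN, the exclusion marker.
    """
    occurrence_cells = np.asarray(occurrence_cells, dtype=int)
    raw = maxent.predict_raw(model, stack)
    p = raw.values.ravel().copy()
    valid = raw.mask.ravel()
    total = p[valid].sum()
    if total <= 0:
        raise DomainError("degenerate raw prediction")
    p = p / total
    pi = p[occurrence_cells]
    if np.any(pi <= 0):
        return float("nan")
    L = float(np.log(pi).sum())
    return aicc_value(model.n_nonzero, occurrence_cells.size, L)


def _presence_cells(points: PointSet, template: Grid) -> np.ndarray:
    rows, cols = points.cells(template)
    return rows * template.shape[1] + cols


def select(
    candidates: list,
    presences: PointSet,
    background_cells: np.ndarray,
    stack: dict,
    seed: int = 0,
    k: int = DEFAULT_K,
    max_iter: int = 500,
):
    """Evaluate all candidates and return (best, full table).

    ``candidates`` is a list of (FeatureExpansion, reg_multiplier) pairs.
    Each candidate is fit on the full data for AICc and per-fold for test
    AUC (scored presence vs background).  NaN-AICc candidates are excluded.
    """
    if not candidates:
        raise DomainError("need at least one candidate")
    template = next(iter(stack.values()))
    cells = _presence_cells(presences, template)
    folds = partition(presences, seed=seed, k=k)
    results = []
    for expansion, mult in candidates:
        model = maxent.fit(stack, cells, background_cells, expansion, mult, max_iter=max_iter)
        crit = aicc(model, cells, stack)
        test_aucs = []
        for f in np.unique(folds):
            train, test = cells[folds != f], cells[folds == f]
            if train.size < 3 or test.size < 1:
                continue
            m_f = maxent.fit(stack, train, background_cells, expansion, mult, max_iter=max_iter)
            test_aucs.append(
                maxent.auc(
                    maxent._model_scores(m_f, stack, test),
                    maxent._model_scores(m_f, stack, background_cells),
                )
            )
        results.append(
            SettingsEvalResult(
                classes=expansion.classes,
                reg_multiplier=mult,
                K=model.n_nonzero,
                AICc=crit,
                mean_test_AUC=float(np.mean(test_aucs)) if test_aucs else float("nan"),
                sd_test_AUC=float(np.std(test_aucs, ddof=1)) if len(test_aucs) > 1 else 0.0,
                folds=int(np.unique(folds).size),
            )
        )
    table = pd.DataFrame(
        {
            "classes": ["+".join(r.classes) for r in results],
            "reg_multiplier": [r.reg_multiplier for r in results],
            "K": [r.K for r in results],
            "AICc": [r.AICc for r in results],
            "mean_test_AUC": [r.mean_test_AUC for r in results],
            "sd_test_AUC": [r.sd_test_AUC for r in results],
            "folds": [r.folds for r in results],
        }
    )
    usable = [(i, r) for i, r in enumerate(results) if np.isfinite(r.AICc)]
    if not usable:
        raise DomainError("all candidates over-parameterized (AICc undefined)")
    best = min(
        usable,
        key=lambda ir: (
            ir[1].AICc,
            -(ir[1].mean_test_AUC if np.isfinite(ir[1].mean_test_AUC) else -np.inf),
            ir[1].K,
            ir[0],
        ),
    )[1]
    return best, table
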