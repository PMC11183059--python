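"""Presence-only maximum-entropy suitability model.

The model is the Gibbs distribution over background cells

    p(x) = exp(lambda . f(x)) / Z(lambda),

fit by maximizing the L1-penalized presence log-likelihood

    (1/m) sum_presence lambda . f(x) - log Z(lambda) - sum_j beta_j |lambda_j|,

where Z sums exp(lambda . f) over the background sample and beta_j are
per-feature regularization weights (published default tables per feature
class, scaled by a single multiplier).  Optimization is proximal gradient
(FISTA with backtracking); the normative contract is the stationarity
condition |presence mean - model mean| <= beta for zero coefficients, not
the particular solver.

The canonical map output is the logistic transform
``e^H r / (1 + e^H r)`` of the normalized raw distribution ``r``, with
``H`` the entropy of the raw distribution over the background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from .geo import DomainError, Grid

__all__ = [
    "FeatureExpansion",
    "MaxEntModel",
    "build_features",
    "sample_background",
    "fit",
    "predict_raw",
    "predict_logistic",
    "logistic_from_raw",
    "raw_entropy",
    "auc",
    "variable_contribution",
    "DEFAULT_BACKGROUND_SIZE",
]

DEFAULT_BACKGROUND_SIZE = 10_000

_CLASS_ORDER = ("linear", "quadratic", "product", "hinge", "threshold")

# Published default regularization beta by feature class, interpolated in
# the presence sample size m (values beyond the table ends are clamped).
_BETA_TABLES = {
    "linear": ((10, 30, 100), (1.0, 0.2, 0.05)),
    "quadratic": ((10, 17, 30, 100), (1.3, 0.8, 0.5, 0.25)),
    "product": ((0, 10, 17, 30, 100), (2.6, 1.6, 0.9, 0.55, 0.05)),
    "hinge": ((0, 1), (0.5, 0.5)),
    "threshold": ((0, 100), (2.0, 1.0)),
}

_MIN_FEATURE_SD = 0.01


@dataclass(frozen=True)
class FeatureExpansion:
    """Feature-class configuration (the MaxEnt "settings" axis)."""

    classes: tuple[str, ...] = ("linear", "quadratic", "hinge")
    hinge_knots: int = 5

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("at least one feature class is required")
        for cls in self.classes:
            if cls not in _CLASS_ORDER:
                raise ValueError(f"unknown feature class {cls!r}")
        if "hinge" in self.classes and self.hinge_knots < 2:
            raise ValueError("hinge expansion needs >= 2 knots")

    @property
    def tag(self) -> str:
        return "".join(c[0].upper() for c in _CLASS_ORDER if c in self.classes)


def _stack_names(stack: dict) -> list[str]:
    return sorted(stack)


def stack_matrix(stack: dict, cells: np.ndarray) -> np.ndarray:
    """Predictor values at flat cell indices, columns in sorted name order."""
    return np.column_stack([stack[n].values.ravel()[cells] for n in _stack_names(stack)])


def background_scaling(stack: dict, cells: np.ndarray) -> dict:
    """Per-predictor (min, max) over the background cells."""
    out = {}
    for name in _stack_names(stack):
        vals = stack[name].values.ravel()[cells]
        lo, hi = float(vals.min()), float(vals.max())
        if hi == lo:
            hi = lo + 1.0
        out[name] = (lo, hi)
    return out


def build_features(
    stack: dict,
    cells: np.ndarray,
    expansion: FeatureExpansion,
    scaling: dict | None = None,
):
    """Design matrix (cells x features) for the expansion.

    Predictors are min-max scaled to [0, 1] using the background scaling
    (clamped outside it); hinge features are forward/reverse piecewise-linear
    ramps at equally spaced knots.  Feature ordering is deterministic:
    predictors in sorted name order, classes in a fixed order.  Returns
    ``(matrix, feature names, feature->predictor map)``.
    """
    cells = np.asarray(cells)
    if cells.size == 0:
        raise DomainError("empty cell list")
    names = _stack_names(stack)
    if scaling is None:
        scaling = background_scaling(stack, cells)
    raw = stack_matrix(stack, cells)
    z = np.empty_like(raw)
    for j, name in enumerate(names):
        lo, hi = scaling[name]
        z[:, j] = np.clip((raw[:, j] - lo) / (hi - lo), 0.0, 1.0)

    columns, feat_names, feat_pred = [], [], []

    def add(col, fname, preds):
        columns.append(col)
        feat_names.append(fname)
        feat_pred.append(preds)

    if "linear" in expansion.classes:
        for j, name in enumerate(names):
            add(z[:, j], f"linear({name})", (name,))
    if "quadratic" in expansion.classes:
        for j, name in enumerate(names):
            add(z[:, j] ** 2, f"quadratic({name})", (name,))
    if "product" in expansion.classes:
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                add(z[:, a] * z[:, b], f"product({names[a]},{names[b]})", (names[a], names[b]))
    if "hinge" in expansion.classes:
        knots = np.linspace(0.0, 1.0, expansion.hinge_knots)
        for j, name in enumerate(names):
            for k in knots[:-1]:
                add(
                    np.maximum(0.0, (z[:, j] - k) / (1.0 - k)),
                    f"hinge_fwd({name},{k:.6g})",
                    (name,),
                )
            for k in knots[1:]:
                add(np.maximum(0.0, (k - z[:, j]) / k), f"hinge_rev({name},{k:.6g})", (name,))
    if "threshold" in expansion.classes:
        thr = np.linspace(0.0, 1.0, expansion.hinge_knots + 2)[1:-1]
        for j, name in enumerate(names):
            for t in thr:
                add((z[:, j] > t).astype(float), f"threshold({name},{t:.6g})", (name,))

    return np.column_stack(columns), feat_names, feat_pred


def sample_background(template: Grid, bias: Grid | None, n: int, seed: int) -> np.ndarray:
    """Draw background cell indices without replacement, ∝ bias.

    Uniform when ``bias`` is None.  Requests exceeding the number of valid
    cells clamp to all of them (with a warning).
    """
    import warnings

    sea = np.flatnonzero(template.mask.ravel())
    if sea.size == 0:
        raise DomainError("template has no valid cells")
    if bias is None:
        weights = np.ones(sea.size)
    else:
        if bias.shape != template.shape:
            raise DomainError("bias grid must share the template's shape")
        weights = bias.values.ravel()[sea]
        if np.any(weights <= 0):
            raise DomainError("bias must be strictly positive on valid cells")
    if n >= sea.size:
        if n > sea.size:
            warnings.warn(
                f"background request {n} exceeds {sea.size} valid cells; using all",
                stacklevel=2,
            )
        return np.sort(sea)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(sea, size=n, replace=False, p=weights / weights.sum())
    return np.sort(chosen)


@dataclass
class MaxEntModel:
    """A fitted maximum-entropy model."""

    expansion: FeatureExpansion
    feature_names: list[str]
    feature_predictors: list[tuple[str, ...]]
    lam: np.ndarray
    beta: np.ndarray
    reg_multiplier: float
    scaling: dict
    logZ: float
    H: float
    background_cells: np.ndarray
    presence_cells: np.ndarray
    converged: bool
    n_iter: int
    training_meta: dict = field(default_factory=dict)

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(np.abs(self.lam) > 1e-8))

    def save(self, path) -> None:
        doc = {
            "classes": list(self.expansion.classes),
            "hinge_knots": self.expansion.hinge_knots,
            "feature_names": self.feature_names,
            "feature_predictors": [list(p) for p in self.feature_predictors],
            "lam": self.lam.tolist(),
            "beta": self.beta.tolist(),
            "reg_multiplier": self.reg_multiplier,
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "logZ": self.logZ,
            "H": self.H,
            "background_cells": self.background_cells.tolist(),
            "presence_cells": self.presence_cells.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "training_meta": self.training_meta,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path) -> "MaxEntModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            expansion=FeatureExpansion(tuple(doc["classes"]), doc["hinge_knots"]),
            feature_names=doc["feature_names"],
            feature_predictors=[tuple(p) for p in doc["feature_predictors"]],
            lam=np.array(doc["lam"]),
            beta=np.array(doc["beta"]),
            reg_multiplier=doc["reg_multiplier"],
            scaling={k: tuple(v) for k, v in doc["scaling"].items()},
            logZ=doc["logZ"],
            H=doc["H"],
            background_cells=np.array(doc["background_cells"], dtype=int),
            presence_cells=np.array(doc["presence_cells"], dtype=int),
            converged=doc["converged"],
            n_iter=doc["n_iter"],
            training_meta=doc["training_meta"],
        )


def penalized_loglik(lam, F_pres, F_bg, beta) -> float:
    """The objective fit() maximizes; exposed for oracle checks."""
    eta_bg = F_bg @ lam
    c = eta_bg.max()
    logZ = c + np.log(np.exp(eta_bg - c).sum())
    return float((F_pres @ lam).mean() - logZ - np.sum(beta * np.abs(lam)))


def default_betas(expansion, feature_names, F_pres, reg_multiplier) -> np.ndarray:
    """Per-feature L1 weights: class table value x sqrt(var_presence/m)."""
    m = F_pres.shape[0]
    sd = F_pres.std(axis=0)
    sd = np.maximum(sd, _MIN_FEATURE_SD)
    beta = np.empty(F_pres.shape[1])
    for j, fname in enumerate(feature_names):
        cls = fname.split("(")[0].split("_")[0]
        if cls not in _BETA_TABLES:
            cls = "linear"
        xs, ys = _BETA_TABLES[cls]
        beta[j] = np.interp(m, xs, ys)
    return reg_multiplier * beta * sd / np.sqrt(m)


def fit(
    stack: dict,
    presence_cells: np.ndarray,
    background_cells: np.ndarray,
    expansion: FeatureExpansion | None = None,
    reg_multiplier: float = 1.0,
    max_iter: int = 1000,
    tol: float = 1e-7,
) -> MaxEntModel:
    """Fit the L1-penalized maximum-entropy model.

    ``presence_cells`` and ``background_cells`` are flat indices on the
    shared grid template.  Converges when the penalized objective improves
    by less than ``tol``; a model hitting ``max_iter`` is returned flagged
    non-converged.
    """
    expansion = expansion or FeatureExpansion()
    presence_cells = np.asarray(presence_cells, dtype=int)
    background_cells = np.asarray(background_cells, dtype=int)
    if presence_cells.size < 3:
        raise DomainError("need at least 3 presence cells")
    if reg_multiplier <= 0:
        raise ValueError("reg_multiplier must be positive")

    scaling = background_scaling(stack, background_cells)
    F_bg, feat_names, feat_pred = build_features(stack, background_cells, expansion, scaling)
    F_pres, _, _ = build_features(stack, presence_cells, expansion, scaling)
    beta = default_betas(expansion, feat_names, F_pres, reg_multiplier)
    pres_mean = F_pres.mean(axis=0)

    J = F_bg.shape[1]
    lam = np.zeros(J)
    y = lam.copy()
    t_mom = 1.0
    L = 1.0

    def smooth(l):
        eta = F_bg @ l
        c = eta.max()
        w = np.exp(eta - c)
        Z = w.sum()
        logZ = c + np.log(Z)
        g = logZ - pres_mean @ l
        grad = (F_bg.T @ (w / Z)) - pres_mean
        return g, grad

    def penalty(l):
        return np.sum(beta * np.abs(l))

    obj_prev = -(smooth(lam)[0] + penalty(lam))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g_y, grad_y = smooth(y)
        while True:
            step = 1.0 / L
            cand = np.sign(y - step * grad_y) * np.maximum(
                np.abs(y - step * grad_y) - step * beta, 0.0
            )
            g_c, _ = smooth(cand)
            diff = cand - y
            if g_c <= g_y + grad_y @ diff + 0.5 * L * (diff @ diff) + 1e-12:
                break
            L *= 2.0
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        y = cand + ((t_mom - 1.0) / t_next) * (cand - lam)
        lam_prev, lam = lam, cand
        t_mom = t_next
        obj = -(g_c + penalty(lam))
        if obj < obj_prev:  # restart momentum on non-monotone step
            y = lam.copy()
            t_mom = 1.0
        if abs(obj - obj_prev) < tol:
            converged = True
            obj_prev = obj
            break
        obj_prev = obj
        L = max(L / 2.0, 1e-6)

    eta_bg = F_bg @ lam
    c = eta_bg.max()
    w = np.exp(eta_bg - c)
    logZ = float(c + np.log(w.sum()))
    p = w / w.sum()
    H = float(-(p * np.log(np.clip(p, 1e-300, None))).sum())

    return MaxEntModel(
        expansion=expansion,
        feature_names=feat_names,
        feature_predictors=feat_pred,
        lam=lam,
        beta=beta,
        reg_multiplier=reg_multiplier,
        scaling=scaling,
        logZ=logZ,
        H=H,
        background_cells=background_cells,
        presence_cells=presence_cells,
        converged=converged,
        n_iter=it,
        training_meta={"tol": tol, "max_iter": max_iter, "objective": obj_prev},
    )


def _model_scores(model: MaxEntModel, stack: dict, cells: np.ndarray) -> np.ndarray:
    F, _, _ = build_features(stack, cells, model.expansion, model.scaling)
    return F @ model.lam


def predict_raw(model: MaxEntModel, stack: dict) -> Grid:
    """Raw Gibbs output: exp(lambda.f) normalized to sum 1 over background."""
    for preds in model.feature_predictors:
        for p in preds:
            if p not in stack:
                raise DomainError(f"predictor {p!r} missing from stack")
    template = next(iter(stack.values()))
    mask = np.logical_and.reduce([g.mask for g in stack.values()])
    cells = np.flatnonzero(mask.ravel())
    eta = _model_scores(model, stack, cells)
    eta_bg = _model_scores(model, stack, model.background_cells)
    c = eta_bg.max()
    Z = np.exp(eta_bg - c).sum()
    raw = np.exp(eta - c) / Z
    out = np.zeros(template.shape).ravel()
    out[cells] = raw
    return template.with_values(out.reshape(template.shape), mask=mask)


def raw_entropy(raw_values: np.ndarray) -> float:
    """Entropy of a normalized raw distribution."""
    p = np.asarray(raw_values, dtype=float)
    p = p / p.sum()
    return float(-(p * np.log(np.clip(p, 1e-300, None))).sum())


def logistic_from_raw(raw: np.ndarray, H: float) -> np.ndarray:
    s = np.exp(H) * np.asarray(raw, dtype=float)
    return s / (1.0 + s)


def predict_logistic(model: MaxEntModel, stack: dict) -> Grid:
    """Logistic suitability in (0,1): e^H raw / (1 + e^H raw)."""
    raw = predict_raw(model, stack)
    vals = logistic_from_raw(raw.values, model.H)
    return raw.with_values(np.where(raw.mask, vals, 0.0))


def auc(presence_scores, background_scores) -> float:
    """Mann-Whitney AUC: P(presence > background) + 0.5 P(tie)."""
    ps = np.asarray(presence_scores, dtype=float)
    bs = np.asarray(background_scores, dtype=float)
    if ps.size == 0 or bs.size == 0:
        raise DomainError("AUC needs non-empty score lists")
    labels = np.concatenate([np.ones(ps.size), np.zeros(bs.size)])
    scores = np.concatenate([ps, bs])
    if np.unique(scores).size == 1:
        return 0.5
    return float(roc_auc_score(labels, scores))


def training_auc(model: MaxEntModel, stack: dict) -> float:
    pres = _model_scores(model, stack, model.presence_cells)
    bg = _model_scores(model, stack, model.background_cells)
    return auc(pres, bg)


def variable_contribution(
    model: MaxEntModel, stack: dict, presence_cells: np.ndarray | None = None, seed: int = 0, n_perm: int = 3
) -> dict:
    """Permutation importance as percent contributions summing to 100.

    Each predictor's valid-cell values are permuted ``n_perm`` times; the
    mean drop in training AUC, floored at 0, is normalized across
    predictors.  Predictors whose features all carry zero coefficients
    contribute exactly 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    presence_cells = (
        np.asarray(presence_cells, dtype=int) if presence_cells is not None else model.presence_cells
    )
    names = _stack_names(stack)
    if len(names) == 1:
        return {names[0]: 100.0}
    base = auc(
        _model_scores(model, stack, presence_cells),
        _model_scores(model, stack, model.background_cells),
    )
    rng = np.random.default_rng(seed)
    active = {
        p
        for preds, l in zip(model.feature_predictors, model.lam)
        if abs(l) > 1e-8
        for p in preds
    }
    drops = {}
    for name in names:
        if name not in active:
            drops[name] = 0.0
            continue
        grid = stack[name]
        vals = grid.values.ravel().copy()
        valid = np.flatnonzero(grid.mask.ravel())
        acc = 0.0
        for _ in range(n_perm):
            perm = vals.copy()
            perm[valid] = vals[valid][rng.permutation(valid.size)]
            stack_p = dict(stack)
            stack_p[name] = grid.with_values(perm.reshape(grid.shape))
            perm_auc = auc(
                _model_scores(model, stack_p, presence_cells),
                _model_scores(model, stack_p, model.background_cells),
            )
            acc += base - perm_auc
        drops[name] = max(acc / n_perm, 0.0)
    total = sum(drops.values())
    if total <= 0:
        pool = [n for n in names if n in active] or names
        return {n: (100.0 / len(pool) if n in pool else 0.0) for n in names}
    return {n: 100.0 * d / total for n, d in drops.items()}
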