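import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dugongrisk import maxent
from dugongrisk.geo import DomainError
from dugongrisk.maxent import (
    FeatureExpansion,
    MaxEntModel,
    auc,
    build_features,
    fit,
    logistic_from_raw,
    penalized_loglik,
    predict_logistic,
    predict_raw,
    raw_entropy,
    sample_background,
    variable_contribution,
)
from tests.conftest import make_grid


def toy_stack(values, mask=None):
    return {"x": make_grid(np.asarray(values, dtype=float), mask=mask)}


def test_build_features_linear_quadratic_columns():
    stack = toy_stack(np.array([[0.0, 2.0, 4.0, 8.0]]))
    cells = np.arange(4)
    F, names, _ = build_features(stack, cells, FeatureExpansion(("linear", "quadratic")))
    scaled = np.array([0.0, 0.25, 0.5, 1.0])
    assert np.allclose(F[:, names.index("linear(x)")], scaled)
    assert np.allclose(F[:, names.index("quadratic(x)")], scaled**2)


def test_hinge_features_closed_form():
    stack = toy_stack(np.array([[0.0, 0.75, 1.0]]))
    cells = np.arange(3)
    F, names, _ = build_features(stack, cells, FeatureExpansion(("hinge",), hinge_knots=3))
    at = F[1]  # x = 0.75 on the [0,1] scale
    expect = {
        "hinge_fwd(x,0)": 0.75,
        "hinge_fwd(x,0.5)": 0.5,
        "hinge_rev(x,0.5)": 0.0,
        "hinge_rev(x,1)": 0.25,
    }
    for fname, val in expect.items():
        assert at[names.index(fname)] == pytest.approx(val)


def test_build_features_empty_cells_raises():
    with pytest.raises(DomainError):
        build_features(toy_stack(np.zeros((2, 2))), np.array([]), FeatureExpansion())


def test_sample_background_uniform_all_and_point_mass():
    tmpl = make_grid(np.zeros((4, 4)))
    cells = sample_background(tmpl, None, 16, seed=0)
    assert np.array_equal(cells, np.arange(16))

    bias_vals = np.full((4, 4), 1e-9)
    bias_vals[2, 3] = 1.0
    bias = make_grid(bias_vals)
    one = sample_background(tmpl, bias, 1, seed=0)
    assert one.tolist() == [2 * 4 + 3]


def test_sample_background_inclusion_frequency_tracks_bias():
    tmpl = make_grid(np.zeros((1, 3)))
    bias = make_grid(np.array([[0.2, 0.3, 0.5]]))
    hits = np.zeros(3)
    n_seeds = 2000
    for seed in range(n_seeds):
        hits[sample_background(tmpl, bias, 1, seed=seed)[0]] += 1
    for j, w in enumerate([0.2, 0.3, 0.5]):
        se = np.sqrt(w * (1 - w) / n_seeds)
        assert abs(hits[j] / n_seeds - w) < 3 * se


def test_fit_full_shrinkage_gives_uniform_raw():
    rng = np.random.default_rng(0)
    stack = toy_stack(rng.uniform(size=(5, 5)))
    bg = np.arange(25)
    model = fit(stack, np.array([3, 7, 11]), bg, FeatureExpansion(("linear",)), reg_multiplier=1e6)
    assert np.all(model.lam == 0.0)
    raw = predict_raw(model, stack)
    assert np.allclose(raw.values.ravel()[bg], 1.0 / 25.0)


def test_fit_balanced_feature_stays_zero():
    # Presence mean equals background mean -> subgradient condition holds at 0.
    vals = np.array([[0.0, 1.0, 0.0, 1.0, 0.5, 0.5]])
    stack = toy_stack(vals)
    model = fit(stack, np.array([0, 1, 4]), np.arange(6), FeatureExpansion(("linear",)))
    assert np.all(np.abs(model.lam) < 1e-8)


def test_fit_matches_brute_force_grid_search():
    vals = np.array([[0.0, 0.2, 0.4, 0.6, 0.8, 1.0]])
    stack = toy_stack(vals)
    presence = np.array([3, 4, 5])
    bg = np.arange(6)
    model = fit(stack, presence, bg, FeatureExpansion(("linear",)), reg_multiplier=1.0, tol=1e-12)
    F_bg, _, _ = build_features(stack, bg, model.expansion, model.scaling)
    F_pres, _, _ = build_features(stack, presence, model.expansion, model.scaling)
    grid = np.arange(-10.0, 10.0 + 1e-9, 1e-3)
    objs = [penalized_loglik(np.array([l]), F_pres, F_bg, model.beta) for l in grid]
    best = grid[int(np.argmax(objs))]
    assert abs(model.lam[0] - best) <= 2e-3


def test_predict_raw_conservation_and_reeval(default_scenario):
    sc = default_scenario
    stack = {n: sc.env_stack[n] for n in ("depth", "kd")}
    tmpl = next(iter(stack.values()))
    bg = sample_background(tmpl, None, 800, seed=2)
    rng = np.random.default_rng(3)
    presence = rng.choice(bg, size=40, replace=False)
    model = fit(stack, presence, bg, FeatureExpansion(("linear", "quadratic")))
    raw = predict_raw(model, stack)
    assert raw.values.ravel()[bg].sum() == pytest.approx(1.0, abs=1e-12)
    # Re-evaluation oracle: direct exp/normalize loop.
    F_bg, _, _ = build_features(stack, bg, model.expansion, model.scaling)
    e = np.exp(F_bg @ model.lam)
    assert np.allclose(raw.values.ravel()[bg], e / e.sum(), atol=1e-12)


def test_predict_raw_monotone_in_single_positive_feature():
    vals = np.linspace(0, 1, 12).reshape(1, 12)
    stack = toy_stack(vals)
    model = fit(stack, np.array([9, 10, 11]), np.arange(12), FeatureExpansion(("linear",)))
    if model.lam[0] > 0:
        raw = predict_raw(model, stack).values.ravel()
        assert np.all(np.diff(raw) >= -1e-15)


def test_logistic_uniform_and_closed_form():
    N = 50
    uniform = np.full(N, 1.0 / N)
    H = raw_entropy(uniform)
    assert H == pytest.approx(np.log(N), abs=1e-12)
    assert np.allclose(logistic_from_raw(uniform, H), 0.5, atol=1e-12)

    raw = np.array([0.5, 0.3, 0.2])
    H = -(raw * np.log(raw)).sum()
    expect = np.exp(H) * raw / (1.0 + np.exp(H) * raw)
    assert np.allclose(logistic_from_raw(raw, raw_entropy(raw)), expect, atol=1e-12)
    # Strictly increasing in the raw value.
    assert np.all(np.diff(logistic_from_raw(np.sort(raw), H)) > 0)


def test_auc_oracles():
    assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0
    assert auc([0.3, 0.7], [0.3, 0.7]) == 0.5
    assert auc([0.9, 0.4], [0.5, 0.1]) == 0.75
    with pytest.raises(DomainError):
        auc([], [0.5])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(0.01, 0.99), min_size=2, max_size=12),
    st.lists(st.floats(0.01, 0.99), min_size=2, max_size=12),
)
def test_auc_invariant_under_monotone_transform(pres, bg):
    before = auc(pres, bg)
    after = auc(np.exp(3.0 * np.asarray(pres)), np.exp(3.0 * np.asarray(bg)))
    assert before == pytest.approx(after, abs=1e-12)


def test_shrinkage_monotonicity():
    rng = np.random.default_rng(5)
    stack = {
        "a": make_grid(rng.uniform(size=(8, 8))),
        "b": make_grid(rng.uniform(size=(8, 8))),
    }
    bg = np.arange(64)
    presence = rng.choice(64, size=12, replace=False)
    counts = []
    for mult in (0.5, 1.0, 2.0, 4.0, 8.0):
        model = fit(stack, presence, bg, FeatureExpansion(("linear", "quadratic")), mult)
        counts.append(model.n_nonzero)
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_variable_contribution_normalization_and_zero(default_scenario):
    sc = default_scenario
    stack = {n: sc.env_stack[n] for n in ("depth", "kd", "sst_mean")}
    tmpl = next(iter(stack.values()))
    bg = sample_background(tmpl, None, 600, seed=6)
    # Presences drawn from deep-water tail: depth should matter, and a
    # predictor whose coefficients are all zero contributes exactly 0.
    depth = stack["depth"].values.ravel()
    presence = bg[np.argsort(depth[bg])[-30:]]
    model = fit(stack, presence, bg, FeatureExpansion(("linear",)))
    contrib = variable_contribution(model, stack, seed=0, n_perm=3)
    assert sum(contrib.values()) == pytest.approx(100.0, abs=1e-9)
    zero_preds = {
        p
        for preds, l in zip(model.feature_predictors, model.lam)
        if abs(l) <= 1e-8
        for p in preds
    } - {
        p
        for preds, l in zip(model.feature_predictors, model.lam)
        if abs(l) > 1e-8
        for p in preds
    }
    for p in zero_preds:
        assert contrib[p] == 0.0


def test_variable_contribution_single_predictor(default_scenario):
    stack = {"depth": default_scenario.env_stack["depth"]}
    tmpl = stack["depth"]
    bg = sample_background(tmpl, None, 400, seed=7)
    presence = bg[:20]
    model = fit(stack, presence, bg, FeatureExpansion(("linear",)))
    assert variable_contribution(model, stack, seed=0) == {"depth": 100.0}


def test_contribution_recovers_single_driver():
    """On truths driven by one predictor, that predictor gets the largest
    permutation contribution in nearly every seeded run."""
    from dugongrisk.pipeline import presence_cells
    from dugongrisk.prep import rarefy
    from dugongrisk.synthetic import ScenarioConfig, generate_scenario, make_truth, sample_occurrences

    wins = 0
    for seed in range(20):
        sc = generate_scenario(ScenarioConfig(seed=seed, grid_shape=(60, 60)))
        stack = sc.env_stack
        truth = make_truth(stack, {"sst_mean": 2.0}, -1.0)
        pts = sample_occurrences(truth, sc.bias_field, 80, seed + 200)
        tmpl = next(iter(stack.values()))
        rare = rarefy(pts, tmpl, seed=seed)
        bg = sample_background(tmpl, None, 2000, seed + 1)
        model = fit(
            stack, presence_cells(rare, tmpl), bg, FeatureExpansion(("linear", "quadratic")), 1.0, max_iter=300
        )
        contrib = variable_contribution(model, stack, seed=seed, n_perm=3)
        wins += max(contrib, key=contrib.get) == "sst_mean"
    assert wins >= 18


def test_model_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    stack = toy_stack(rng.uniform(size=(6, 6)))
    model = fit(stack, np.array([1, 5, 9]), np.arange(36), FeatureExpansion(("linear", "quadratic")))
    path = tmp_path / "model.json"
    model.save(path)
    back = MaxEntModel.load(path)
    assert np.array_equal(back.lam, model.lam)
    assert back.H == model.H and back.logZ == model.logZ
    assert back.scaling == model.scaling
    raw_a = predict_raw(model, stack)
    raw_b = predict_raw(back, stack)
    assert np.array_equal(raw_a.values, raw_b.values)
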