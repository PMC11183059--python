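import numpy as np
import pytest
from shapely.geometry import Polygon

from dugongrisk.geo import DomainError, PolygonSet, rasterize
from dugongrisk.risk import (
    RISK_HIGH,
    classify_risk,
    classify_suitability,
    combine_seasons,
    extract_cdh,
    mpa_gap_report,
    risk_surface,
)
from tests.conftest import make_grid


def test_combine_seasons_identity_mean_bounds():
    a = make_grid(np.array([[0.2, 0.9]]))
    assert np.array_equal(combine_seasons([a]).values, a.values)
    b = make_grid(np.array([[0.4, 0.5]]))
    c = make_grid(np.array([[0.6, 0.1]]))
    out = combine_seasons([a, b, c])
    assert out.values[0, 0] == pytest.approx(0.4)
    stacked = np.stack([g.values for g in (a, b, c)])
    assert np.all(out.values >= stacked.min(axis=0) - 1e-12)
    assert np.all(out.values <= stacked.max(axis=0) + 1e-12)


def test_combine_seasons_intersects_masks():
    mask = np.array([[True, False]])
    a = make_grid(np.array([[0.2, 0.9]]), mask=mask)
    b = make_grid(np.array([[0.4, 0.5]]))
    out = combine_seasons([a, b])
    assert not out.mask[0, 1]


def test_risk_surface_product_and_annihilation():
    suit = make_grid(np.array([[0.8, 0.6]]))
    press = make_grid(np.array([[0.9, 0.0]]))
    out = risk_surface(suit, press)
    assert out.values[0, 0] == pytest.approx(0.72)
    assert out.values[0, 1] == 0.0
    with pytest.raises(DomainError):
        risk_surface(suit, make_grid(np.array([[1.5, 0.2]])))


def test_risk_bounded_by_factors_random():
    rng = np.random.default_rng(1)
    suit = make_grid(rng.uniform(0, 1, (20, 20)))
    press = make_grid(rng.uniform(0, 1, (20, 20)))
    out = risk_surface(suit, press)
    assert np.all(out.values <= suit.values + 1e-15)
    assert np.all(out.values <= press.values + 1e-15)


def test_classify_risk_boundaries_and_histogram():
    vals = np.array([[0.0, 0.2, 0.25, 0.26, 0.5, 0.501, 0.6, 1.0]])
    grid = make_grid(vals)
    out = classify_risk(grid)
    # Range is [0,1] so values are already percent/100.
    assert out.values[0, 4] == 1  # exactly 50% -> moderate
    assert out.values[0, 6] == 2  # 60% -> high
    pct = 100.0 * (vals - vals.min()) / (vals.max() - vals.min())
    expect_counts = [
        int((pct <= 25.0).sum()),
        int(((pct > 25.0) & (pct <= 50.0)).sum()),
        int((pct > 50.0).sum()),
    ]
    got_counts = [int((out.values == k).sum()) for k in (0, 1, 2)]
    assert got_counts == expect_counts


def test_classify_risk_constant_surface_degenerate():
    with pytest.warns(UserWarning):
        out = classify_risk(make_grid(np.full((3, 3), 0.4)))
    assert out.degenerate and np.all(out.values == 0)


def test_classify_suitability_fixed_bins():
    vals = np.array([[0.0, 0.25, 0.26, 0.5, 0.75, 0.76, 1.0]])
    out = classify_suitability(make_grid(vals))
    assert out.values.tolist()[0] == [0, 0, 1, 1, 2, 3, 3]
    counts = [int((out.values == k).sum()) for k in range(4)]
    loop = [0, 0, 0, 0]
    for v in vals.ravel():
        loop[0 if v <= 0.25 else 1 if v <= 0.5 else 2 if v <= 0.75 else 3] += 1
    assert counts == loop
    with pytest.raises(DomainError):
        classify_suitability(make_grid(np.array([[1.2]])))


def test_extract_cdh_strict_threshold_and_subset():
    risk_class = make_grid(np.array([[2.0, 2.0, 1.0, 2.0]]))
    suit = make_grid(np.array([[0.8, 0.74, 0.9, 0.76]]))
    cdh = extract_cdh(risk_class, suit)
    assert cdh.values.tolist()[0] == [1.0, 0.0, 0.0, 1.0]
    assert np.all(cdh.values <= (risk_class.values == RISK_HIGH))
    assert np.all(cdh.values <= (suit.values > 0.75))


def _binary_grid(n_ones, total, cell_area):
    vals = np.zeros(total)
    vals[:n_ones] = 1.0
    side = int(np.sqrt(total))
    assert side * side == total
    return make_grid(vals.reshape(side, side), cell=np.sqrt(cell_area))


def test_mpa_gap_report_printed_region_numbers():
    """The printed regional areas (26.16 of 478.59 km² protected) reproduce
    the 5.5% / ~95% split."""
    cell_area = 0.01  # km²
    total_cells = 47859
    protected_cells = 2616
    side = 300
    high = np.zeros(side * side)
    high[:total_cells] = 1.0
    mpa = np.zeros(side * side)
    mpa[:protected_cells] = 1.0
    high_grid = make_grid(high.reshape(side, side), cell=0.1)
    mpa_grid = make_grid(mpa.reshape(side, side), cell=0.1)
    report = mpa_gap_report(high_grid, mpa_grid, cell_area_km2=cell_area)
    assert report.total_high_risk_km2 == pytest.approx(478.59)
    assert report.protected_high_risk_km2 == pytest.approx(26.16)
    assert report.pct_protected == 5.5
    assert report.pct_outside_int == 95


def test_mpa_gap_full_cover_and_disjoint():
    high = make_grid(np.ones((4, 4)))
    report = mpa_gap_report(high, make_grid(np.ones((4, 4))))
    assert report.pct_protected == 100.0 and report.outside_high_risk_km2 == 0.0
    none = mpa_gap_report(high, make_grid(np.zeros((4, 4))))
    assert none.pct_protected == 0.0 and none.pct_outside_int == 100


def test_mpa_gap_conservation_and_monotonicity():
    rng = np.random.default_rng(3)
    high = make_grid((rng.random((12, 12)) > 0.6).astype(float))
    tmpl = high
    small = PolygonSet([Polygon([(2, 2), (6, 2), (6, 6), (2, 6), (2, 2)])])
    large = PolygonSet([Polygon([(1, 1), (9, 1), (9, 9), (1, 9), (1, 1)])])
    r_small = mpa_gap_report(high, rasterize(small, tmpl))
    r_large = mpa_gap_report(high, rasterize(large, tmpl))
    for r in (r_small, r_large):
        assert r.protected_high_risk_km2 + r.outside_high_risk_km2 == pytest.approx(
            r.total_high_risk_km2, abs=1e-9
        )
    assert r_large.pct_protected >= r_small.pct_protected


def test_mpa_gap_zero_total_undefined():
    report = mpa_gap_report(make_grid(np.zeros((3, 3))), make_grid(np.ones((3, 3))))
    assert report.pct_protected is None and report.pct_outside_int is None


def test_end_to_end_cdh_sits_on_suitable_pressured_cells():
    """Full pipeline, five seeds: Critical Dugong Habitat concentrates on
    cells with higher generating suitability and higher fishing pressure
    than the rest of the sea; the CDH class is non-degenerate in most
    seeds."""
    import warnings

    from dugongrisk.maxent import FeatureExpansion
    from dugongrisk.pipeline import PipelineConfig, run_all
    from dugongrisk.synthetic import ScenarioConfig

    nonempty = 0
    for seed in range(5):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_all(
                PipelineConfig(
                    seed=seed,
                    scenario=ScenarioConfig(seed=seed),
                    use_bias=False,
                    select_settings=False,
                    candidates=[(FeatureExpansion(("linear", "quadratic", "hinge")), 1.0)],
                )
            )
        sc = out["scenario"]
        cdh = out["cdh"].values.astype(bool) & out["cdh"].mask
        if not cdh.any():
            continue
        nonempty += 1
        rest = ~cdh & out["cdh"].mask
        truth_mean = np.mean([g.values for g in sc.true_dugong.values()], axis=0)
        assert truth_mean[cdh].mean() > truth_mean[rest].mean()
        assert sc.pressure.values[cdh].mean() > sc.pressure.values[rest].mean()
    assert nonempty >= 4
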