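"""Synthetic coastal seascapes with known ground truth.

Generates a planar study region — a connected land strip with a smooth
coastline, environmental predictor fields, a latent seagrass suitability
surface, seasonal dugong suitability truths, biased occurrence samples, a
coarse fishing-pressure grid, rectangular MPAs and boat-survey counts — so
that every downstream stage of the pipeline can be tested against a known
generating process without any external download.

All artifacts are deterministic functions of ``(ScenarioConfig, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon

from .geo import (
    DomainError,
    Grid,
    GridTransform,
    PointSet,
    PolygonSet,
    align_to_template,
    write_grid,
    write_polygons,
)

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "generate_environment",
    "make_truth",
    "sample_occurrences",
    "generate_pressure",
    "generate_surveys",
    "generate_mpas",
    "generate_scenario",
    "write_scenario",
]

# Month draws per season used to date synthetic occurrences (ANI-style
# monsoon calendar: Jan-Apr pre-monsoon, May-Sep monsoon, Oct-Dec post).
SEASON_MONTHS = {
    "pre_monsoon": (1, 2, 3, 4),
    "monsoon": (5, 6, 7, 8, 9),
    "post_monsoon": (10, 11, 12),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the synthetic study region.

    Defaults mirror the study conditions at desk scale: a 100x100 grid of
    1-km cells, three monsoon-calendar seasons with ~60 presences each, a
    ~10% connected coastal land strip, a 10-cell (10 km) coarse fishing
    pressure grid and rectangular MPAs covering ~15% of the sea.
    """

    grid_shape: tuple[int, int] = (100, 100)
    cell_km: float = 1.0
    seed: int = 0
    n_presence: int = 60
    season_names: tuple[str, ...] = ("pre_monsoon", "monsoon", "post_monsoon")
    env_field_params: dict = field(
        default_factory=lambda: {
            "depth": {"sigma": 8.0, "scale": 15.0},
            "slope": {"sigma": 5.0, "scale": 4.0},
            "sst_mean": {"sigma": 12.0, "scale": 1.5},
            "kd": {"sigma": 6.0, "scale": 0.15},
            "wave_height": {"sigma": 10.0, "scale": 0.6},
        }
    )
    truth_coefficients: dict = field(
        default_factory=lambda: {
            "depth": -1.2,
            "dist_shore": -1.0,
            "kd": -0.3,
            "slope": -0.2,
            "wave_height": -1.5,
        }
    )
    # The seagrass stage sees every abiotic layer; the dugong stage sees this
    # reduced set plus the modelled seagrass layer, so the biotic predictor
    # carries information (e.g. wave exposure) the dugong stack lacks.
    dugong_predictors: tuple[str, ...] = ("depth", "slope", "dist_shore", "sst_mean", "kd")
    truth_intercept: float = -2.0
    core_amplitude: float = 4.0
    core_sigma_cells: float = 8.0
    dugong_seagrass_coef: float = 0.5
    dugong_coefficients: dict = field(default_factory=lambda: {"depth": -0.5, "dist_shore": -0.35})
    dugong_intercept: float = -3.5
    dugong_core_amplitude: float = 8.0
    season_shift_cells: float = 4.0
    season_bump_amplitude: float = 1.5
    season_bump_sigma_cells: float = 8.0
    bias_strength: float = 0.0
    n_landing_sites: int = 3
    pressure_block_cells: int = 10
    mpa_fraction: float = 0.15
    survey_n: int = 25
    survey_rate: float = 30.0
    survey_noise_sd: float = 0.0
    n_seagrass_presence: int = 120
    land_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_presence < 1:
            raise ValueError("n_presence must be >= 1")
        if self.grid_shape[0] < 20 or self.grid_shape[1] < 20:
            raise ValueError("grid_shape must be at least (20, 20)")
        if not 0.0 <= self.mpa_fraction <= 1.0:
            raise ValueError("mpa_fraction must lie in [0, 1]")
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")
        if self.pressure_block_cells < 1:
            raise ValueError("pressure_block_cells must be >= 1")


@dataclass
class Scenario:
    """A complete generated study region with its ground truth."""

    config: ScenarioConfig
    env_stack: dict
    land_mask: Grid
    true_seagrass: Grid
    true_dugong: dict
    occurrences: dict
    seagrass_occurrences: PointSet
    bias_field: Grid
    pressure: Grid
    mpas: PolygonSet
    survey_points: PointSet

    @property
    def sea_mask(self) -> np.ndarray:
        return self.land_mask.values == 0


def _template(config: ScenarioConfig) -> GridTransform:
    rows, _cols = config.grid_shape
    return GridTransform(x0=0.0, y0=rows * config.cell_km, cell_w=config.cell_km, cell_h=config.cell_km)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance Gaussian-filtered white noise."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def generate_environment(config: ScenarioConfig):
    """Build the named predictor stack and the land mask.

    Land is a connected western coastal strip whose width follows a smooth
    random curve around ``land_fraction`` of the columns.  ``dist_shore`` is
    the exact Euclidean distance transform of the land mask (km); the other
    fields are smooth filtered noise plus shore-distance gradients.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    rows, cols = config.grid_shape
    transform = _template(config)

    base_width = max(2.0, config.land_fraction * cols)
    wiggle = _smooth_field(rng, (rows,), sigma=6.0) * base_width * 0.4
    widths = np.clip(np.round(base_width + wiggle), 1, cols // 3).astype(int)
    land = np.zeros((rows, cols), dtype=bool)
    for r in range(rows):
        land[r, : widths[r]] = True
    sea = ~land

    dist = ndimage.distance_transform_edt(sea) * config.cell_km

    p = config.env_field_params
    depth = 1.0 + 1.4 * dist + _smooth_field(rng, (rows, cols), p["depth"]["sigma"]) * p["depth"]["scale"]
    depth = np.clip(depth, 0.5, None)
    gy, gx = np.gradient(depth, config.cell_km)
    slope = np.degrees(np.arctan(np.hypot(gx, gy) / 1000.0)) * 50.0
    slope = slope + np.abs(_smooth_field(rng, (rows, cols), p["slope"]["sigma"])) * p["slope"]["scale"]
    lat = np.linspace(1.0, -1.0, rows)[:, None] * np.ones((1, cols))
    sst = 28.0 + 1.2 * lat + _smooth_field(rng, (rows, cols), p["sst_mean"]["sigma"]) * p["sst_mean"]["scale"]
    kd = 0.08 + 0.3 * np.exp(-dist / 15.0) + np.abs(_smooth_field(rng, (rows, cols), p["kd"]["sigma"])) * p["kd"]["scale"]
    # Wave exposure grows offshore plus its own swell field, independent of
    # the depth noise.
    wave = 0.3 + 0.8 * (1.0 - np.exp(-dist / 25.0)) + _smooth_field(
        rng, (rows, cols), p["wave_height"]["sigma"]
    ) * p["wave_height"]["scale"]
    wave = np.clip(wave, 0.05, None)

    def grid(vals):
        return Grid(values=np.where(sea, vals, 0.0), transform=transform, mask=sea.copy())

    stack = {
        "depth": grid(depth),
        "slope": grid(slope),
        "dist_shore": grid(dist),
        "sst_mean": grid(sst),
        "kd": grid(kd),
        "wave_height": grid(wave),
    }
    land_mask = Grid(
        values=land.astype(float), transform=transform, mask=np.ones((rows, cols), dtype=bool)
    )
    return stack, land_mask


def _standardize(grid: Grid) -> np.ndarray:
    vals = grid.valid_values()
    sd = vals.std()
    return np.where(grid.mask, (grid.values - vals.mean()) / (sd if sd > 0 else 1.0), 0.0)


def make_truth(stack: dict, coefficients: dict, intercept: float = 0.0, extra: np.ndarray | None = None) -> Grid:
    """Inverse-logit of a linear combination of standardized predictors."""
    for name in coefficients:
        if name not in stack:
            raise ValueError(f"unknown predictor {name!r} in truth coefficients")
    template = next(iter(stack.values()))
    lin = np.full(template.shape, float(intercept))
    mask = template.mask.copy()
    for name, coef in coefficients.items():
        lin = lin + coef * _standardize(stack[name])
        mask &= stack[name].mask
    if extra is not None:
        lin = lin + extra
    with np.errstate(over="ignore"):
        truth = 1.0 / (1.0 + np.exp(-lin))
    return template.with_values(np.where(mask, truth, 0.0), mask=mask)


def sample_occurrences(
    truth: Grid, bias_field: Grid, n: int, seed: int, season: str | None = None
) -> PointSet:
    """Draw ``n`` presence points ∝ truth x bias over sea cells.

    Cells are drawn with replacement from the normalized product weights;
    each point is jittered uniformly within its cell and dated with a random
    month of its season (mid-month) for season-splitting tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if truth.shape != bias_field.shape:
        raise DomainError("truth and bias grids must share a template")
    weights = np.where(truth.mask & bias_field.mask, truth.values * bias_field.values, 0.0)
    total = weights.sum()
    if total <= 0:
        raise DomainError("truth x bias has zero total weight")
    rng = np.random.default_rng(seed)
    flat = weights.ravel() / total
    idx = rng.choice(flat.size, size=n, replace=True, p=flat)
    rows, cols = np.unravel_index(idx, truth.shape)
    t = truth.transform
    x = t.x0 + (cols + rng.uniform(0.0, 1.0, size=n)) * t.cell_w
    y = t.y0 - (rows + rng.uniform(0.0, 1.0, size=n)) * t.cell_h
    dates = None
    if season is not None:
        months = SEASON_MONTHS.get(season)
        if months:
            m = rng.choice(months, size=n)
            dates = [f"2020-{int(mi):02d}-15" for mi in m]
    return PointSet.from_arrays(x, y, date=dates, season=[season] * n if season else None)


def make_bias_field(config: ScenarioConfig, land_mask: Grid, seed: int) -> Grid:
    """Sampling-effort surface: Gaussian blobs at coastal "landing sites".

    The normalized blob field is raised to ``bias_strength``; strength 0
    gives a uniform field (unbiased sampling).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    sea = land_mask.values == 0
    rows, cols = sea.shape
    dist = ndimage.distance_transform_edt(sea)
    coastal = np.argwhere(sea & (dist <= 5))
    if len(coastal) == 0:
        coastal = np.argwhere(sea)
    sites = coastal[rng.choice(len(coastal), size=min(config.n_landing_sites, len(coastal)), replace=False)]
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    blob = np.zeros((rows, cols))
    sigma = 0.15 * max(rows, cols)
    for sr, sc in sites:
        blob += np.exp(-((rr - sr) ** 2 + (cc - sc) ** 2) / (2.0 * sigma**2))
    blob /= blob.max()
    bias = np.power(np.clip(blob, 1e-6, None), config.bias_strength)
    return land_mask.with_values(np.where(sea, bias, 0.0), mask=sea)


def generate_pressure(config: ScenarioConfig, template: Grid, dist_shore: Grid | None = None) -> Grid:
    """Piecewise-constant fishing-pressure field on coarse blocks.

    Emulates a 10-km gridded-polygon pressure product: lognormal block
    values on a ``pressure_block_cells``-factor coarse grid, aligned to the
    1-km template by nearest-neighbour resampling and masked to sea.  When
    ``dist_shore`` is given, block values carry a shore-proximity gradient
    (fishing effort concentrates in nearshore waters, the same shallow
    habitats the animals use), so modelled risk and survey threat share the
    coastal signal observed in real seascapes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    b = config.pressure_block_cells
    rows, cols = template.shape
    crows, ccols = -(-rows // b), -(-cols // b)
    coarse_vals = np.exp(0.5 * ndimage.gaussian_filter(rng.standard_normal((crows, ccols)), 1.0))
    if dist_shore is not None:
        shore = np.zeros((crows, ccols))
        for R in range(crows):
            for C in range(ccols):
                block = dist_shore.values[R * b : (R + 1) * b, C * b : (C + 1) * b]
                bmask = dist_shore.mask[R * b : (R + 1) * b, C * b : (C + 1) * b]
                shore[R, C] = block[bmask].mean() if bmask.any() else block.mean()
        coarse_vals = coarse_vals * (0.25 + np.exp(-shore / 12.0))
    t = template.transform
    coarse = Grid(
        values=coarse_vals,
        transform=GridTransform(x0=t.x0, y0=t.y0, cell_w=t.cell_w * b, cell_h=t.cell_h * b),
        mask=np.ones((crows, ccols), dtype=bool),
    )
    aligned = align_to_template(coarse, template, method="nearest")
    return aligned


def generate_surveys(pressure: Grid, n: int, noise_sd: float, seed: int, rate: float = 6.0) -> PointSet:
    """Boat-survey counts at centroids of non-overlapping 2x2-cell blocks.

    Counts are Poisson with mean ``rate x`` the block's mean pressure,
    optionally inflated by multiplicative lognormal noise.
    """
    if n < 3:
        raise ValueError("need at least 3 survey blocks")
    rng = np.random.default_rng(seed)
    rows, cols = pressure.shape
    blocks = [
        (r, c)
        for r in range(0, rows - 1, 2)
        for c in range(0, cols - 1, 2)
        if pressure.mask[r : r + 2, c : c + 2].all()
    ]
    if n > len(blocks):
        raise DomainError(f"requested {n} survey blocks but only {len(blocks)} are available")
    chosen = rng.choice(len(blocks), size=n, replace=False)
    t = pressure.transform
    xs, ys, counts = [], [], []
    for bi in chosen:
        r, c = blocks[bi]
        local = float(pressure.values[r : r + 2, c : c + 2].mean())
        noise = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
        counts.append(int(rng.poisson(rate * local * noise)))
        xs.append(t.x0 + (c + 1.0) * t.cell_w)
        ys.append(t.y0 - (r + 1.0) * t.cell_h)
    return PointSet.from_arrays(xs, ys, count=counts, source="boat-survey")


def generate_mpas(config: ScenarioConfig, land_mask: Grid, seed: int) -> PolygonSet:
    """Rectangular MPAs accumulating to ~``mpa_fraction`` of the sea area."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    sea = land_mask.values == 0
    target = config.mpa_fraction * sea.sum()
    t = land_mask.transform
    rows, cols = sea.shape
    covered = np.zeros_like(sea)
    polys, labels = [], []
    attempts = 0
    while covered[sea].sum() < target and attempts < 200:
        attempts += 1
        h = int(rng.integers(8, max(9, rows // 4)))
        w = int(rng.integers(8, max(9, cols // 4)))
        r0 = int(rng.integers(0, rows - h))
        c0 = int(rng.integers(0, cols - w))
        block = sea[r0 : r0 + h, c0 : c0 + w]
        if block.mean() < 0.5:
            continue
        covered[r0 : r0 + h, c0 : c0 + w] |= sea[r0 : r0 + h, c0 : c0 + w]
        x0 = t.x0 + c0 * t.cell_w
        x1 = t.x0 + (c0 + w) * t.cell_w
        y1 = t.y0 - r0 * t.cell_h
        y0 = t.y0 - (r0 + h) * t.cell_h
        polys.append(Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1), (x0, y0)]))
        labels.append(f"MPA_{len(polys)}")
    return PolygonSet(polygons=polys, labels=labels, crs_tag=land_mask.crs_tag)


def _season_center(config: ScenarioConfig, land_mask: Grid, season_index: int) -> tuple[float, float]:
    """Hotspot center: nearshore column, shifting alongshore season to season."""
    rows, cols = config.grid_shape
    coast_col = min(config.land_fraction * cols + 8.0, cols - 5.0)
    base_row = rows * 0.35
    return (base_row + config.season_shift_cells * season_index, coast_col)


def generate_scenario(config: ScenarioConfig | None = None) -> Scenario:
    """Generate the full scenario: environment, truths, samples, pressure."""
    config = config or ScenarioConfig()
    stack, land_mask = generate_environment(config)
    sea = land_mask.values == 0
    rows, cols = config.grid_shape

    # A static dense-meadow core raises the seagrass surface well above the
    # general coastal band; dugong suitability inherits it through the
    # seagrass term, so stage-2 models can learn it from the biotic layer.
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    core_r, core_c = _season_center(config, land_mask, 1)
    core = config.core_amplitude * np.exp(
        -((rr - core_r) ** 2 + (cc - core_c) ** 2) / (2.0 * config.core_sigma_cells**2)
    )
    true_seagrass = make_truth(stack, config.truth_coefficients, config.truth_intercept, extra=core)
    bias_field = make_bias_field(config, land_mask, config.seed)

    # Dugong truth: driven by the seagrass surface plus abiotic terms and a
    # season-shifting Gaussian hotspot.
    sg_std = (true_seagrass.values - true_seagrass.valid_values().mean()) / max(
        true_seagrass.valid_values().std(), 1e-12
    )
    true_dugong: dict[str, Grid] = {}
    occurrences: dict[str, PointSet] = {}
    seeds = np.random.SeedSequence([config.seed, 505]).generate_state(len(config.season_names) + 1)
    # The dense-meadow core supports disproportionate grazing: the dugong
    # truth carries a direct core term co-located with the seagrass core
    # (learnable through a steep response to the seagrass predictor).
    dugong_core = (config.dugong_core_amplitude / config.core_amplitude) * core
    for i, season in enumerate(config.season_names):
        cr, ccol = _season_center(config, land_mask, i)
        bump = config.season_bump_amplitude * np.exp(
            -((rr - cr) ** 2 + (cc - ccol) ** 2) / (2.0 * config.season_bump_sigma_cells**2)
        )
        extra = config.dugong_seagrass_coef * sg_std + dugong_core + bump + config.dugong_intercept
        truth = make_truth(stack, config.dugong_coefficients, 0.0, extra=extra)
        truth = truth.with_values(np.where(sea, truth.values, 0.0), mask=sea.copy())
        true_dugong[season] = truth
        occurrences[season] = sample_occurrences(
            truth, bias_field, config.n_presence, int(seeds[i]) % (2**31), season=season
        )

    seagrass_occ = sample_occurrences(
        true_seagrass, bias_field, config.n_seagrass_presence, int(seeds[-1]) % (2**31)
    )

    pressure = generate_pressure(
        config,
        land_mask.with_values(land_mask.values, mask=sea.copy()),
        dist_shore=stack["dist_shore"],
    )
    mpas = generate_mpas(config, land_mask, config.seed)
    surveys = generate_surveys(
        pressure,
        config.survey_n,
        config.survey_noise_sd,
        int(np.random.SeedSequence([config.seed, 606]).generate_state(1)[0]) % (2**31),
        rate=config.survey_rate,
    )

    return Scenario(
        config=config,
        env_stack=stack,
        land_mask=land_mask,
        true_seagrass=true_seagrass,
        true_dugong=true_dugong,
        occurrences=occurrences,
        seagrass_occurrences=seagrass_occ,
        bias_field=bias_field,
        pressure=pressure,
        mpas=mpas,
        survey_points=surveys,
    )


def write_scenario(scenario: Scenario, outdir) -> dict:
    """Write the scenario in the same formats the pipeline reads.

    Rasters as GeoTIFF, MPAs as GeoJSON, points as CSV.  Returns the path
    manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for name, grid in scenario.env_stack.items():
        p = outdir / f"env_{name}.tif"
        write_grid(grid, p)
        paths[f"env_{name}"] = str(p)
    for name, grid in [
        ("land_mask", scenario.land_mask),
        ("true_seagrass", scenario.true_seagrass),
        ("bias_field", scenario.bias_field),
        ("pressure", scenario.pressure),
    ]:
        p = outdir / f"{name}.tif"
        write_grid(grid, p)
        paths[name] = str(p)
    for season, truth in scenario.true_dugong.items():
        p = outdir / f"true_dugong_{season}.tif"
        write_grid(truth, p)
        paths[f"true_dugong_{season}"] = str(p)
    occ = PointSet(pd.concat([ps.df for ps in scenario.occurrences.values()], ignore_index=True))
    occ.write_csv(outdir / "occurrences.csv")
    paths["occurrences"] = str(outdir / "occurrences.csv")
    scenario.seagrass_occurrences.write_csv(outdir / "seagrass_occurrences.csv")
    paths["seagrass_occurrences"] = str(outdir / "seagrass_occurrences.csv")
    scenario.survey_points.write_csv(outdir / "surveys.csv")
    paths["surveys"] = str(outdir / "surveys.csv")
    write_polygons(scenario.mpas, outdir / "mpas.geojson")
    paths["mpas"] = str(outdir / "mpas.geojson")
    return paths
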