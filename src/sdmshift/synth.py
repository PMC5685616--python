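"""Synthetic landscapes, virtual species, future climates, and reserves.

The generator emulates the statistical structure the downstream analysis
assumes: smooth spatially autocorrelated continuous predictors on a
2.5 arc-minute grid, an 11-class categorical habitat mosaic, future layers
formed by additive deltas on the standardized scale, presence-only samples
drawn proportionally to a known (inverse-logit) suitability surface, and
rectangular/circular protected-area polygons.

A single master seed is split into fixed per-component sub-seeds so the
stack, the species, and the reserves can each be regenerated independently
and reproducibly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .errors import ConfigError, PlacementError, SimulationError
from .grid import OccurrenceSet, PredictorStack, ProtectedArea, RasterGrid

# fixed sub-seed offsets (see module docstring)
_SEED_STACK = 101
_SEED_SPECIES = 211
_SEED_PAS = 307
_SEED_NDVI = 401


@dataclass
class SyntheticWorldConfig:
    """Parameters of the synthetic study region.

    Defaults describe the desk-scale world used throughout the test-suite
    and the analysis scripts: a 100 x 120 grid at 2.5 arc-minutes with six
    continuous predictors (the first three "temperature-like", the rest
    "precipitation-like"), an 11-class habitat mosaic, three future time
    slices under a severe and a moderate emissions scenario, ten species
    with 150 presences each, and 25 reserves.
    """

    seed: int = 0
    n_rows: int = 100
    n_cols: int = 120
    origin_x: float = 25.0
    origin_y: float = 32.0
    cell_size: float = 2.5 / 60.0
    sea_fraction: float = 0.08
    smooth_sigma: float = 8.0

    n_continuous: int = 6
    n_temperature_like: int = 3
    collinear_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    n_habitat_classes: int = 11
    n_habitat_patches: int = 40

    times: tuple[int, ...] = (2020, 2050, 2080)
    #: per-scenario multiplier on the per-slice deltas (severe vs moderate)
    scenarios: dict[str, float] = field(
        default_factory=lambda: {"A2a": 1.0, "B2a": 0.6}
    )
    #: per-slice additive shift (standardized SD units) for temperature-like
    #: and precipitation-like predictors
    temp_delta_sd: float = 0.5
    precip_delta_sd: float = -0.2
    #: explicit per-predictor per-slice deltas; overrides the two rates above
    future_deltas: list[float] | None = None

    n_species: int = 10
    n_presences_per_species: int = 150
    #: per-species coefficient vectors on the standardized predictors;
    #: None draws them randomly with one dominant coefficient
    response_spec: list[list[float]] | None = None
    #: magnitude of the dominant coefficient and SD of the minor ones
    dominant_eta: float = 5.0
    eta_sd: float = 1.5
    #: negative intercept makes species range-restricted (suitable habitat
    #: a small fraction of the landscape, as in arid-country floras)
    species_intercept: float = -6.0

    n_pas: int = 25
    pa_placement: str = "random"

    ndvi_n_composites: int = 12
    ndvi_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        for name in ("n_rows", "n_cols", "n_continuous", "n_habitat_classes",
                     "n_species", "n_presences_per_species", "n_pas",
                     "ndvi_n_composites"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for i, j, r in self.collinear_pairs:
            if not abs(r) < 1.0:
                raise ConfigError("collinear pair |r| must be < 1")
            if not (0 <= i < self.n_continuous and 0 <= j < self.n_continuous and i != j):
                raise ConfigError("collinear pair indices out of range")
        if self.pa_placement not in ("random", "richness-biased"):
            raise ConfigError(f"unknown pa_placement {self.pa_placement!r}")


@dataclass
class TrueSpecies:
    """Simulation ground truth: coefficients and the suitability surface."""

    species_id: str
    true_eta: np.ndarray
    true_suitability: RasterGrid


# ---------------------------------------------------------------------------
# Predictor stacks
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Low-order spatial polynomial plus Gaussian-filtered white noise."""
    n_rows, n_cols = shape
    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    u = xx / max(n_cols - 1, 1) - 0.5
    v = yy / max(n_rows - 1, 1) - 0.5
    coef = rng.normal(0.0, 1.0, 6)
    poly = (coef[0] * u + coef[1] * v + coef[2] * u * v
            + coef[3] * u ** 2 + coef[4] * v ** 2 + coef[5])
    noise = gaussian_filter(rng.normal(0.0, 1.0, shape), sigma=sigma, mode="nearest")
    noise /= max(noise.std(), 1e-12)
    return poly + 0.8 * noise


def _land_mask(rng: np.random.Generator, cfg: SyntheticWorldConfig) -> np.ndarray:
    if cfg.sea_fraction <= 0:
        return np.ones((cfg.n_rows, cfg.n_cols), dtype=bool)
    sea_field = _smooth_field(rng, (cfg.n_rows, cfg.n_cols), cfg.smooth_sigma)
    thresh = np.quantile(sea_field, cfg.sea_fraction)
    return sea_field > thresh


def _standardize(values: np.ndarray, land: np.ndarray) -> np.ndarray:
    mu = values[land].mean()
    sd = values[land].std()
    return (values - mu) / max(sd, 1e-12)


def base_deltas(cfg: SyntheticWorldConfig) -> np.ndarray:
    """Per-predictor additive shift per time slice (standardized units)."""
    if cfg.future_deltas is not None:
        d = np.asarray(cfg.future_deltas, dtype=float)
        if d.shape != (cfg.n_continuous,):
            raise ConfigError("future_deltas must have one value per continuous predictor")
        return d
    d = np.full(cfg.n_continuous, cfg.precip_delta_sd)
    d[: cfg.n_temperature_like] = cfg.temp_delta_sd
    return d


def make_predictor_stack(
    cfg: SyntheticWorldConfig,
) -> tuple[PredictorStack, dict[tuple[int, str], PredictorStack]]:
    """Build the current predictor stack and one future stack per
    time-slice x scenario.

    Continuous layers are standardized to zero mean / unit SD over land;
    requested collinear pairs are induced by mixing surfaces so the sample
    correlation lands within 0.1 of the target. The habitat layer is a
    Voronoi mosaic of integer class codes and, like the other categorical
    content, does not change in the future stacks.
    """
    rng = np.random.default_rng(cfg.seed + _SEED_STACK)
    shape = (cfg.n_rows, cfg.n_cols)
    land = _land_mask(rng, cfg)
    mask = ~land

    raw = [_smooth_field(rng, shape, cfg.smooth_sigma) for _ in range(cfg.n_continuous)]
    std = [_standardize(f, land) for f in raw]
    targets = {}
    for i, j, r in cfg.collinear_pairs:
        if j in targets:
            raise ConfigError(f"predictor {j} targeted by two collinear pairs")
        targets[j] = (i, r)
    for j, (i, r) in targets.items():
        if targets.get(i, (None,))[0] == j:
            raise ConfigError("cyclic collinear pair specification")
        mixed = r * std[i] + math.sqrt(1.0 - r * r) * std[j]
        std[j] = _standardize(mixed, land)

    def _grid(vals: np.ndarray) -> RasterGrid:
        return RasterGrid(vals, mask.copy(), cfg.origin_x, cfg.origin_y,
                          cfg.cell_size, "geographic")

    names = [f"env{k}" for k in range(cfg.n_continuous)]
    kinds = ["continuous"] * cfg.n_continuous
    layers = [_grid(v) for v in std]

    # Voronoi-style habitat mosaic
    seeds_rc = np.column_stack(
        [rng.integers(0, cfg.n_rows, cfg.n_habitat_patches),
         rng.integers(0, cfg.n_cols, cfg.n_habitat_patches)]
    )
    patch_class = rng.integers(1, cfg.n_habitat_classes + 1, cfg.n_habitat_patches)
    yy, xx = np.mgrid[0:cfg.n_rows, 0:cfg.n_cols]
    d2 = (yy[..., None] - seeds_rc[:, 0]) ** 2 + (xx[..., None] - seeds_rc[:, 1]) ** 2
    habitat = patch_class[np.argmin(d2, axis=-1)].astype(float)
    layers.append(_grid(habitat))
    names.append("habitat")
    kinds.append("categorical")

    current = PredictorStack(layers=layers, names=names, kinds=kinds)

    deltas = base_deltas(cfg)
    futures: dict[tuple[int, str], PredictorStack] = {}
    for t_idx, time in enumerate(cfg.times, start=1):
        for scen, mult in cfg.scenarios.items():
            fut_layers = []
            for k in range(cfg.n_continuous):
                shifted = std[k] + deltas[k] * t_idx * mult
                fut_layers.append(_grid(shifted))
            fut_layers.append(_grid(habitat.copy()))
            futures[(time, scen)] = PredictorStack(
                layers=fut_layers, names=list(names), kinds=list(kinds)
            )
    return current, futures


# ---------------------------------------------------------------------------
# Species and presences
# ---------------------------------------------------------------------------

def true_suitability(stack: PredictorStack, eta: Sequence[float],
                     intercept: float = 0.0) -> RasterGrid:
    """Inverse-logit suitability surface over the continuous predictors.

    Deliberately not the maximum-entropy family, so recovery tests probe
    robustness rather than self-confirmation.
    """
    eta = np.asarray(eta, dtype=float)
    cont = stack.continuous_indices()
    if eta.shape != (len(cont),):
        raise ConfigError("eta length must match the number of continuous predictors")
    lin = np.full(stack.grid.shape, intercept)
    for w, idx in zip(eta, cont):
        lin = lin + w * stack.layers[idx].values
    suit = expit(lin)
    return stack.grid.like(suit, mask=~stack.land_mask)


def make_species_and_presences(
    stack: PredictorStack,
    eta: Sequence[float],
    n: int,
    seed: int,
    species_id: str = "sp",
    intercept: float = 0.0,
) -> tuple[TrueSpecies, OccurrenceSet]:
    """Draw n presence cells without replacement with probability
    proportional to the true suitability over land."""
    suit = true_suitability(stack, eta, intercept)
    land = stack.land_mask
    rows, cols = np.nonzero(land)
    weights = suit.values[rows, cols]
    positive = weights > 0
    if n > positive.sum():
        raise SimulationError(
            f"requested {n} presences but only {int(positive.sum())} cells have "
            "positive suitability"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=False, p=weights / weights.sum())
    grid = stack.grid
    cells = {(int(rows[i]), int(cols[i])) for i in idx}
    xs, ys = grid.cell_center(rows[idx], cols[idx])
    records = list(zip(xs.tolist(), ys.tolist()))
    species = TrueSpecies(species_id=species_id, true_eta=np.asarray(eta, float),
                          true_suitability=suit)
    occ = OccurrenceSet(species_id=species_id, records=records, cells=cells)
    return species, occ


def make_species_set(
    stack: PredictorStack, cfg: SyntheticWorldConfig
) -> tuple[list[TrueSpecies], dict[str, OccurrenceSet]]:
    """Generate the configured community: coefficients from response_spec,
    or random vectors with one dominant coefficient (|dominant_eta|) and a
    negative intercept, giving each species a strong environmental signal
    and a restricted range."""
    n_cont = len(stack.continuous_indices())
    rng = np.random.default_rng(cfg.seed + _SEED_SPECIES)
    species_list: list[TrueSpecies] = []
    occurrences: dict[str, OccurrenceSet] = {}
    for s in range(cfg.n_species):
        sid = f"sp{s:03d}"
        if cfg.response_spec is not None:
            eta = np.asarray(cfg.response_spec[s], dtype=float)
        else:
            eta = rng.normal(0.0, cfg.eta_sd, n_cont)
            dom = rng.integers(0, n_cont)
            eta[dom] = cfg.dominant_eta * rng.choice([-1.0, 1.0])
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sp, occ = make_species_and_presences(
            stack, eta, cfg.n_presences_per_species, seed=sub_seed,
            species_id=sid, intercept=cfg.species_intercept,
        )
        species_list.append(sp)
        occurrences[sid] = occ
    return species_list, occurrences


# ---------------------------------------------------------------------------
# NDVI composites
# ---------------------------------------------------------------------------

def make_ndvi_stack(
    cfg: SyntheticWorldConfig,
    base: float | np.ndarray | None = None,
    amplitude: float | np.ndarray | None = None,
) -> list[RasterGrid]:
    """Vegetation-index composites with a seasonal sinusoidal signal.

    value(cell, t) = base + amplitude * sin(2*pi*t/T + phase) + noise,
    clipped to [-1, 1]. Base and amplitude default to smooth spatial
    fields; scalars may be passed to build controlled test series.
    """
    if cfg.ndvi_n_composites < 3:
        raise ConfigError("need at least 3 composites")
    rng = np.random.default_rng(cfg.seed + _SEED_NDVI)
    shape = (cfg.n_rows, cfg.n_cols)
    land_rng = np.random.default_rng(cfg.seed + _SEED_STACK)
    land = _land_mask(land_rng, cfg)
    if base is None:
        f = _smooth_field(rng, shape, cfg.smooth_sigma)
        f = (f - f.min()) / max(f.max() - f.min(), 1e-12)
        base = 0.1 + 0.5 * f
    if amplitude is None:
        g = _smooth_field(rng, shape, cfg.smooth_sigma)
        g = (g - g.min()) / max(g.max() - g.min(), 1e-12)
        amplitude = 0.3 * g
    phase = 2.0 * math.pi * rng.random()
    n = cfg.ndvi_n_composites
    composites = []
    for t in range(n):
        season = np.broadcast_to(
            np.asarray(amplitude, float), shape
        ) * math.sin(2.0 * math.pi * t / n + phase)
        vals = np.broadcast_to(np.asarray(base, float), shape) + season
        if cfg.ndvi_noise_sd > 0:
            vals = vals + rng.normal(0.0, cfg.ndvi_noise_sd, shape)
        vals = np.clip(vals, -1.0, 1.0)
        composites.append(
            RasterGrid(vals, ~land, cfg.origin_x, cfg.origin_y, cfg.cell_size,
                       "geographic")
        )
    return composites


# ---------------------------------------------------------------------------
# Protected areas
# ---------------------------------------------------------------------------

def make_protected_areas(
    cfg: SyntheticWorldConfig,
    grid: RasterGrid,
    richness_hint: RasterGrid | None = None,
    land_mask: np.ndarray | None = None,
) -> list[ProtectedArea]:
    """Place non-overlapping rectangular and circular reserves on land.

    "richness-biased" placement samples reserve centres with probability
    proportional to the cubed (min-max scaled) hint raster, mimicking
    reserves deliberately sited on diversity hotspots. When n_pas >= 5 the
    last reserve is a sub-cell polygon so the small-reserve rule is always
    exercised.
    """
    if cfg.n_pas < 1:
        raise ConfigError("n_pas must be >= 1")
    if cfg.pa_placement == "richness-biased" and richness_hint is None:
        raise ConfigError("richness-biased placement needs a richness_hint")
    from shapely.geometry import Polygon as ShpPolygon

    rng = np.random.default_rng(cfg.seed + _SEED_PAS)
    land = ~grid.mask if land_mask is None else land_mask
    rows, cols = np.nonzero(land)
    if len(rows) == 0:
        raise PlacementError("no land cells to place reserves on")
    if richness_hint is not None:
        h = richness_hint.values[rows, cols].astype(float)
        h = (h - h.min()) / max(h.max() - h.min(), 1e-12)
        weights = h ** 3 + 1e-9
        weights /= weights.sum()
    else:
        weights = None

    cs = grid.cell_size
    placed: list[ProtectedArea] = []
    shapes: list[ShpPolygon] = []
    n_subcell = 1 if cfg.n_pas >= 5 else 0
    for k in range(cfg.n_pas):
        subcell = k == cfg.n_pas - 1 and n_subcell
        ok = False
        for _ in range(300):
            if cfg.pa_placement == "richness-biased":
                i = rng.choice(len(rows), p=weights)
            else:
                i = rng.integers(0, len(rows))
            cx, cy = grid.cell_center(int(rows[i]), int(cols[i]))
            cx, cy = float(cx), float(cy)
            if subcell:
                half_w = half_h = 0.15 * cs
                verts = _rect(cx, cy, half_w, half_h)
            elif rng.random() < 0.5:
                half_w = rng.uniform(1.5, 5.0) * cs
                half_h = rng.uniform(1.5, 5.0) * cs
                verts = _rect(cx, cy, half_w, half_h)
            else:
                radius = rng.uniform(1.5, 5.0) * cs
                ang = np.linspace(0.0, 2.0 * math.pi, 25)[:-1]
                verts = [(cx + radius * math.cos(a), cy + radius * math.sin(a))
                         for a in ang]
            poly = ShpPolygon(verts)
            if any(poly.intersects(p) for p in shapes):
                continue
            shapes.append(poly)
            placed.append(
                ProtectedArea(pa_id=f"pa{k:02d}", vertices=verts,
                              established_rank=k)
            )
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place reserve {k} without overlap after 300 tries"
            )
    return placed


def _rect(cx: float, cy: float, half_w: float, half_h: float):
    return [
        (cx - half_w, cy - half_h),
        (cx + half_w, cy - half_h),
        (cx + half_w, cy + half_h),
        (cx - half_w, cy + half_h),
    ]
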