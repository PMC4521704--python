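"""Synthetic country tables and raster worlds for testing the pipeline.

The generator emulates the statistical structure the analysis assumes:
countries with log-uniform GDP per capita, heavy-tailed (log-normal)
stocks, true system shares drawn from the bounded logistic curves plus
clipped Gaussian observation noise, and per-unit raster fixtures with
urban cores, rural background population, a controllable unsuitable
fraction, and spatially clustered commercial production.  Every unit's
constructed livestock layer sums exactly to its stock, and the true
per-pixel system layers are returned for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .curves import (
    CountryRecord,
    ShareCurveParams,
    SystemShares,
    shares_chicken,
    shares_pig,
)
from .rasters import RasterBundle, RasterGrid

__all__ = ["WorldSpec", "simulate_country_table", "simulate_unit_rasters", "simulate_world"]

Species = Literal["chicken", "pig"]

# Default true curves.  The chicken transition spans roughly
# 1,000-10,000 USD per capita and the pig transition is wider
# (1,000-30,000 USD), with extensive shares above 0.9 at the poor end
# and a few percent at the rich end; saturation below 1 for pigs.
_CHICKEN_TRUE = ShareCurveParams(mu=-1.1, lam=3.9, alpha=1.0)
_PIG_EXT_TRUE = ShareCurveParams(mu=-0.75, lam=4.3, alpha=0.95)
_PIG_INT_TRUE = ShareCurveParams(mu=-0.75, lam=4.4, alpha=0.95)


@dataclass
class WorldSpec:
    """Parameters of one synthetic world.

    Stocks are log-normal (median ~5 M head, sigma 2 on the log scale)
    to produce the heavy-tailed weights the stock-weighted bootstrap
    relies on.  Observation noise is Gaussian on the proportion scale,
    clipped to [0, 1].
    """

    n_units: int = 60
    gdp_range: tuple[float, float] = (500.0, 60000.0)
    chicken_params: ShareCurveParams = field(default_factory=lambda: _CHICKEN_TRUE)
    pig_ext_params: ShareCurveParams = field(default_factory=lambda: _PIG_EXT_TRUE)
    pig_int_params: ShareCurveParams = field(default_factory=lambda: _PIG_INT_TRUE)
    stock_log_mean: float = math.log(5e6)
    stock_log_sd: float = 2.0
    observed_fraction: float = 0.45
    noise_sd: float = 0.03
    grid_shape: tuple[int, int] = (40, 40)
    urban_fraction: float = 0.08
    unsuitable_fraction: float = 0.05
    n_intensive_clusters: int = 3
    pint_form: str = "as_printed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if not (0 < self.observed_fraction <= 1):
            raise ValueError("observed_fraction must be in (0, 1]")
        if self.gdp_range[0] <= 0 or self.gdp_range[1] <= self.gdp_range[0]:
            raise ValueError("gdp_range must be an increasing positive interval")


def _noisy(value: float, sd: float, rng: np.random.Generator) -> float:
    return float(np.clip(value + rng.normal(0.0, sd), 0.0, 1.0)) if sd > 0 else value


def true_shares(spec: WorldSpec, species: Species, g: float) -> SystemShares:
    """The generating system shares at log10-GDP ``g``."""
    if species == "chicken":
        return shares_chicken(spec.chicken_params, g)
    return shares_pig(spec.pig_ext_params, spec.pig_int_params, g, form=spec.pint_form)


def simulate_country_table(
    spec: WorldSpec, species: Species = "chicken"
) -> tuple[list[CountryRecord], dict[int, SystemShares]]:
    """Country records plus the generating truth, deterministic under seed.

    GDP is log-uniform on the spec range; a fraction of units carries
    observed shares (true share + clipped Gaussian noise).  Unit ids are
    ``U001``... and map to integers 1..n for the raster unit grid.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = np.log10(spec.gdp_range[0]), np.log10(spec.gdp_range[1])
    g = rng.uniform(lo, hi, size=spec.n_units)
    stocks = rng.lognormal(spec.stock_log_mean, spec.stock_log_sd, size=spec.n_units)
    observed = rng.random(spec.n_units) < spec.observed_fraction

    records: list[CountryRecord] = []
    truth: dict[int, SystemShares] = {}
    for i in range(spec.n_units):
        sh = true_shares(spec, species, float(g[i]))
        truth[i + 1] = sh
        obs_ext = obs_int = None
        if observed[i]:
            obs_ext = _noisy(sh.p_ext, spec.noise_sd, rng)
            if species == "pig":
                obs_int = _noisy(sh.p_int, spec.noise_sd, rng)
        records.append(
            CountryRecord(
                unit_id=f"U{i + 1:03d}",
                gdp_ppp=float(10.0 ** g[i]),
                stock=float(stocks[i]),
                observed_p_ext=obs_ext,
                observed_p_int=obs_int,
            )
        )
    return records, truth


def _blob(shape: tuple[int, int], centre: tuple[int, int], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius**2


def simulate_unit_rasters(
    spec: WorldSpec,
    record: CountryRecord,
    shares: SystemShares,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Input layers and truth layers for one admin unit.

    The population grid has a lognormal rural background plus one or two
    dense urban cores; elevation/slope/snow layers mark a controllable
    unsuitable fraction.  The livestock total is constructed as true
    extensive stock (proportional to suitable rural population) plus
    commercial stock in a few high-density clusters — commercial
    production is far more spatially clustered than backyard production
    — scaled so the unit sum equals the record's stock exactly.

    Returns ``(layers, truth)`` where ``layers`` holds population,
    urban, elevation, slope, snow_ice and livestock arrays, and
    ``truth`` the generating extensive/commercial per-pixel layers.
    """
    shape = spec.grid_shape
    npix = shape[0] * shape[1]

    population = rng.lognormal(3.0, 1.0, size=shape)
    urban = np.zeros(shape, dtype=bool)
    if spec.urban_fraction > 0:
        n_cores = rng.integers(1, 3)
        target_urban = spec.urban_fraction * npix
        for _ in range(n_cores):
            centre = (int(rng.integers(shape[0])), int(rng.integers(shape[1])))
            radius = max(1.0, math.sqrt(target_urban / (math.pi * n_cores)))
            urban |= _blob(shape, centre, radius)
        population[urban] *= 50.0  # dense cores

    elevation = rng.uniform(0.0, 2000.0, size=shape)
    slope = rng.uniform(0.0, 30.0, size=shape)
    snow_ice = np.zeros(shape, dtype=bool)
    if spec.unsuitable_fraction > 0:
        r = max(1.0, math.sqrt(spec.unsuitable_fraction * npix / math.pi))
        highland = _blob(shape, (int(rng.integers(shape[0])), int(rng.integers(shape[1]))), r)
        elevation[highland] = rng.uniform(5000.0, 6500.0, size=int(highland.sum()))
        snow_ice |= highland & (elevation > 6000.0)
        steep = rng.random(shape) < spec.unsuitable_fraction / 4.0
        slope[steep] = rng.uniform(45.0, 80.0, size=int(steep.sum()))

    suitable = (elevation <= 4750.0) & (slope <= 40.0) & ~urban & ~snow_ice
    if not np.any(suitable & (population > 0)):
        # guarantee a rural foothold so allocation stays well-posed
        i, j = np.unravel_index(int(np.argmax(~urban)), shape)
        urban[i, j] = False
        elevation[i, j] = 100.0
        slope[i, j] = 1.0
        snow_ice[i, j] = False
        suitable = (elevation <= 4750.0) & (slope <= 40.0) & ~urban & ~snow_ice

    rural = np.where(suitable, population, 0.0)
    ext_stock = shares.p_ext * record.stock
    extensive = rural * (ext_stock / rural.sum()) if ext_stock > 0 else np.zeros(shape)

    com_stock = record.stock - ext_stock
    commercial = np.zeros(shape)
    if com_stock > 0:
        suit_idx = np.flatnonzero(suitable)
        centres = rng.choice(suit_idx, size=min(spec.n_intensive_clusters, suit_idx.size),
                             replace=False)
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        for flat in centres:
            ci, cj = np.unravel_index(int(flat), shape)
            kern = np.exp(-(((rr - ci) ** 2 + (cc - cj) ** 2) / (2 * 1.5**2)))
            commercial += kern * rng.uniform(0.5, 1.5)
        commercial *= suitable
        commercial *= com_stock / commercial.sum()

    livestock = extensive + commercial
    layers = {
        "population": population,
        "urban": urban,
        "elevation": elevation,
        "slope": slope,
        "snow_ice": snow_ice,
        "livestock": livestock,
    }
    truth = {"extensive": extensive, "commercial": commercial}
    return layers, truth


def simulate_world(
    spec: WorldSpec, species: Species = "chicken"
) -> tuple[list[CountryRecord], dict[int, SystemShares], RasterBundle, dict[str, np.ndarray]]:
    """A complete tiled world: table, truth shares, raster bundle, truth layers.

    Units are laid out as square tiles on one global grid; the unit-id
    raster marks tile membership.  Deterministic under ``spec.seed``.
    """
    records, truth_shares = simulate_country_table(spec, species)
    rng = np.random.default_rng(spec.seed + 1)

    n_side = math.ceil(math.sqrt(spec.n_units))
    th, tw = spec.grid_shape
    H, W = n_side * th, n_side * tw

    full = {
        "population": np.zeros((H, W)),
        "urban": np.zeros((H, W), dtype=bool),
        "elevation": np.full((H, W), 9999.0),  # outside-unit pixels unsuitable
        "slope": np.zeros((H, W)),
        "snow_ice": np.zeros((H, W), dtype=bool),
        "livestock": np.zeros((H, W)),
    }
    unit_map = np.zeros((H, W), dtype=int)
    truth_ext = np.zeros((H, W))
    truth_com = np.zeros((H, W))

    for i, rec in enumerate(records):
        r0, c0 = (i // n_side) * th, (i % n_side) * tw
        sl = np.s_[r0 : r0 + th, c0 : c0 + tw]
        layers, truth = simulate_unit_rasters(spec, rec, truth_shares[i + 1], rng)
        for k in full:
            full[k][sl] = layers[k]
        unit_map[sl] = i + 1
        truth_ext[sl] = truth["extensive"]
        truth_com[sl] = truth["commercial"]

    def grid(a: np.ndarray) -> RasterGrid:
        return RasterGrid(values=a, xllcorner=0.0, yllcorner=0.0, cellsize=0.083333)

    bundle = RasterBundle(
        livestock=grid(full["livestock"]),
        population=grid(full["population"]),
        urban=full["urban"],
        elevation=grid(full["elevation"]),
        slope=grid(full["slope"]),
        snow_ice=full["snow_ice"],
        unit_map=unit_map,
    )
    return records, truth_shares, bundle, {"extensive": truth_ext, "commercial": truth_com}
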