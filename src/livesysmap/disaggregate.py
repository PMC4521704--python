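"""Dasymetric disaggregation of national stocks into per-system rasters.

Within each admin unit the extensive stock (p_ext × national total) is
spread over the rural population in biophysically suitable pixels;
commercial stock is the per-pixel remainder of the total livestock
layer.  Where allocated extensive stock exceeds the total in a pixel,
the total is raised to the extensive value and the accumulated deficit
is removed pro-rata from the commercial stock elsewhere in the unit, so
the national total is conserved exactly.  For pigs the commercial layer
is further split into semi-intensive and intensive parts in the unit's
share ratio.

All functions treat the ``unit_map`` integer grid (id ≥ 1; 0 = outside)
as the authority for unit membership and nodata pixels as unsuitable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .curves import SystemShares
from .rasters import RasterBundle, RasterGrid, require_coregistered

__all__ = [
    "ELEVATION_LIMIT_M",
    "SLOPE_LIMIT_PCT",
    "build_mask",
    "rural_population",
    "rescale_totals",
    "allocate_extensive",
    "intensive_by_difference",
    "split_pig_intensive",
    "disaggregate_species",
    "DisaggregationResult",
]

#: pixels above this elevation (m a.s.l.) are unsuitable for production
ELEVATION_LIMIT_M = 4750.0
#: pixels steeper than this slope gradient (percent) are unsuitable
SLOPE_LIMIT_PCT = 40.0

CONSERVATION_RTOL = 1e-6


def build_mask(
    elevation: RasterGrid,
    slope: RasterGrid,
    urban: np.ndarray,
    snow_ice: np.ndarray,
) -> np.ndarray:
    """Boolean suitability mask.

    A pixel is suitable iff elevation ≤ 4,750 m, slope ≤ 40 %, it is not
    urban and not permanently snow/ice covered ("higher than" in the
    exclusion criteria is read strictly, so the thresholds themselves
    are suitable).  Nodata elevation or slope renders a pixel unsuitable.
    """
    require_coregistered(elevation, slope)
    urban = np.asarray(urban, dtype=bool)
    snow_ice = np.asarray(snow_ice, dtype=bool)
    if urban.shape != elevation.shape or snow_ice.shape != elevation.shape:
        raise ValueError("urban/snow_ice shape mismatch with elevation grid")
    ok_elev = elevation.valid() & (elevation.values <= ELEVATION_LIMIT_M)
    ok_slope = slope.valid() & (slope.values <= SLOPE_LIMIT_PCT)
    return ok_elev & ok_slope & ~urban & ~snow_ice


def rural_population(
    population: RasterGrid, urban: np.ndarray, mask: np.ndarray
) -> RasterGrid:
    """Population restricted to suitable, non-urban pixels (else 0)."""
    urban = np.asarray(urban, dtype=bool)
    if urban.shape != population.shape or np.shape(mask) != population.shape:
        raise ValueError("urban/mask shape mismatch with population grid")
    vals = population.filled(0.0)
    out = np.where(~urban & mask, vals, 0.0)
    return population.like(out)


def _unit_sums(values: np.ndarray, unit_map: np.ndarray) -> dict[int, float]:
    ids = np.unique(unit_map)
    ids = ids[ids > 0]
    return {int(u): float(values[unit_map == u].sum()) for u in ids}


def rescale_totals(
    livestock: RasterGrid,
    unit_map: np.ndarray,
    unit_totals: Mapping[int | str, float],
) -> RasterGrid:
    """Scale each unit's pixels so its sum equals the reported stock total.

    Harmonizes a gridded livestock layer with FAOSTAT-style national (or
    provincial) head counts before disaggregation.  Idempotent.
    """
    unit_map = np.asarray(unit_map, dtype=int)
    if unit_map.shape != livestock.shape:
        raise ValueError("unit_map shape mismatch with livestock grid")
    vals = livestock.filled(0.0)
    out = vals.copy()
    for u, s in _unit_sums(vals, unit_map).items():
        total = float(unit_totals[u])
        sel = unit_map == u
        if total == 0:
            out[sel] = 0.0
        elif s > 0:
            out[sel] = vals[sel] * (total / s)
        else:
            raise ValueError(f"unit {u}: stock total {total} > 0 but gridded sum is 0")
    return livestock.like(out)


def allocate_extensive(
    rural: RasterGrid,
    unit_map: np.ndarray,
    p_ext: Mapping[int | str, float],
    unit_totals: Mapping[int | str, float],
) -> RasterGrid:
    """Spread each unit's extensive stock equally over its rural population.

    Pixel value = rural_pop × (p_ext · total / Σ rural_pop in unit), so
    the unit sum equals p_ext · total exactly and pixel values are
    proportional to rural population.
    """
    unit_map = np.asarray(unit_map, dtype=int)
    if unit_map.shape != rural.shape:
        raise ValueError("unit_map shape mismatch with rural grid")
    vals = rural.filled(0.0)
    out = np.zeros_like(vals)
    for u, rsum in _unit_sums(vals, unit_map).items():
        ext_stock = float(p_ext[u]) * float(unit_totals[u])
        sel = unit_map == u
        if ext_stock == 0:
            continue
        if rsum <= 0:
            raise ValueError(
                f"unit {u}: extensive stock {ext_stock:.1f} > 0 but no rural "
                "population in suitable pixels"
            )
        out[sel] = vals[sel] * (ext_stock / rsum)
    return rural.like(out)


def intensive_by_difference(
    total: RasterGrid,
    extensive: RasterGrid,
    unit_map: np.ndarray,
) -> tuple[RasterGrid, RasterGrid, pd.DataFrame]:
    """Commercial stock as the per-pixel remainder, with overflow correction.

    Raw commercial = total − extensive.  In overflow pixels (raw < 0)
    the total is replaced by the extensive value and commercial set to
    0; the per-unit deficit D (sum of shortfalls) is then removed
    pro-rata from the remaining commercial pixels — each scaled by
    (S−D)/S where S is the unit's raw positive commercial sum — so the
    unit total is unchanged.  One pass suffices because extensive never
    changes and commercial only shrinks (asserted).

    Returns the commercial grid, the corrected total grid, and a
    per-unit ledger (deficit, pixels overflowed, sums).

    Raises
    ------
    ValueError
        If a unit's deficit exceeds its entire commercial stock (D > S):
        conservation would be impossible.
    """
    require_coregistered(total, extensive)
    unit_map = np.asarray(unit_map, dtype=int)
    if unit_map.shape != total.shape:
        raise ValueError("unit_map shape mismatch")

    tot = total.filled(0.0)
    ext = extensive.filled(0.0)
    raw = tot - ext
    in_unit = unit_map > 0  # no accounting outside admin units
    intensive = np.where((raw > 0) & in_unit, raw, 0.0)
    corrected = np.where((raw < 0) & in_unit, ext, tot)

    rows = []
    ids = np.unique(unit_map)
    for u in ids[ids > 0]:
        sel = unit_map == u
        neg = sel & (raw < 0)
        deficit = float(-raw[neg].sum())
        s_pos = float(intensive[sel].sum())
        if deficit > 0:
            if deficit > s_pos * (1 + 1e-12):
                raise ValueError(
                    f"unit {u}: extensive overflow deficit {deficit:.3f} exceeds "
                    f"commercial stock {s_pos:.3f}; cannot conserve the unit total"
                )
            intensive[sel] *= (s_pos - deficit) / s_pos
        unit_total = float(tot[sel].sum())
        check = float(ext[sel].sum() + intensive[sel].sum())
        assert abs(check - unit_total) <= CONSERVATION_RTOL * max(unit_total, 1.0), (
            f"unit {u}: conservation violated after overflow pass"
        )
        rows.append(
            {
                "unit": int(u),
                "overflow_deficit": deficit,
                "pixels_overflowed": int(neg.sum()),
                "extensive_sum": float(ext[sel].sum()),
                "commercial_sum": float(intensive[sel].sum()),
                "total_before": unit_total,
            }
        )
    ledger = pd.DataFrame(rows)
    return total.like(intensive), total.like(corrected), ledger


def split_pig_intensive(
    intensive_plus_semi: RasterGrid,
    unit_map: np.ndarray,
    unit_shares: Mapping[int | str, SystemShares],
) -> tuple[RasterGrid, RasterGrid]:
    """Split the commercial pig layer into semi-intensive and intensive.

    Every pixel of a unit is divided in the unit's p_sint : p_int ratio
    (semi-intensively raised pigs are not assumed to follow rural
    population, so the split is spatially uniform within the unit).
    """
    unit_map = np.asarray(unit_map, dtype=int)
    if unit_map.shape != intensive_plus_semi.shape:
        raise ValueError("unit_map shape mismatch")
    vals = intensive_plus_semi.filled(0.0)
    semi = np.zeros_like(vals)
    inten = np.zeros_like(vals)
    ids = np.unique(unit_map)
    for u in ids[ids > 0]:
        sel = unit_map == u
        sh = unit_shares[int(u)]
        denom = sh.p_sint + sh.p_int
        if denom == 0:
            if np.any(vals[sel] > 0):
                raise ValueError(
                    f"unit {u}: commercial pixels present but p_sint + p_int = 0"
                )
            continue
        semi[sel] = vals[sel] * (sh.p_sint / denom)
        inten[sel] = vals[sel] * (sh.p_int / denom)
    return intensive_plus_semi.like(semi), intensive_plus_semi.like(inten)


@dataclass
class DisaggregationResult:
    """Per-system rasters plus the per-unit conservation ledger."""

    extensive: RasterGrid
    intensive: RasterGrid
    semi_intensive: RasterGrid | None
    mask: np.ndarray
    ledger: pd.DataFrame

    def system_grids(self) -> dict[str, RasterGrid]:
        out = {"extensive": self.extensive, "intensive": self.intensive}
        if self.semi_intensive is not None:
            out["semi_intensive"] = self.semi_intensive
        return out

    def check_conservation(self, rtol: float = CONSERVATION_RTOL) -> bool:
        err = self.ledger["conservation_error"].abs()
        scale = self.ledger["stock_total"].clip(lower=1.0)
        return bool((err <= rtol * scale).all())


def disaggregate_species(
    bundle: RasterBundle,
    unit_shares: Mapping[int | str, SystemShares],
    unit_totals: Mapping[int | str, float] | None = None,
    species: str = "chicken",
    rescale: bool = True,
) -> DisaggregationResult:
    """Full per-species disaggregation pathway.

    Composes suitability masking, rural-population extraction, optional
    harmonization of the gridded totals with reported unit stocks,
    population-weighted extensive allocation, commercial-by-difference
    with overflow correction and, for pigs, the semi/intensive split.

    ``unit_totals`` defaults to the masked gridded sums (i.e. the grid
    is taken at face value).  The total layer is zeroed outside the
    suitability mask before any accounting, so every output raster is
    zero on unsuitable pixels.
    """
    if species not in ("chicken", "pig"):
        raise ValueError(f"unknown species {species!r}")
    unit_map = bundle.unit_map
    ids = [int(u) for u in np.unique(unit_map) if u > 0]
    missing = [u for u in ids if u not in unit_shares]
    if missing:
        raise KeyError(f"no system shares for units {missing}")

    mask = build_mask(bundle.elevation, bundle.slope, bundle.urban, bundle.snow_ice)
    rural = rural_population(bundle.population, bundle.urban, mask)

    total = bundle.livestock.like(np.where(mask, bundle.livestock.filled(0.0), 0.0))
    if unit_totals is None:
        unit_totals = _unit_sums(total.values, unit_map)
    if rescale:
        total = rescale_totals(total, unit_map, unit_totals)

    p_ext = {u: unit_shares[u].p_ext for u in ids}
    try:
        extensive = allocate_extensive(rural, unit_map, p_ext, unit_totals)
        commercial, corrected_total, overflow = intensive_by_difference(
            total, extensive, unit_map
        )
    except ValueError as exc:
        raise ValueError(f"disaggregation failed ({species}): {exc}") from exc

    if species == "pig":
        semi, intensive = split_pig_intensive(commercial, unit_map, unit_shares)
    else:
        semi, intensive = None, commercial

    rows = []
    for u in ids:
        sel = unit_map == u
        e = float(extensive.values[sel].sum())
        i = float(intensive.values[sel].sum())
        s = float(semi.values[sel].sum()) if semi is not None else 0.0
        stock = float(unit_totals[u])
        ov = overflow[overflow["unit"] == u].iloc[0]
        rows.append(
            {
                "unit": u,
                "stock_total": stock,
                "p_ext": p_ext[u],
                "extensive_sum": e,
                "semi_sum": s,
                "intensive_sum": i,
                "overflow_deficit": float(ov["overflow_deficit"]),
                "pixels_overflowed": int(ov["pixels_overflowed"]),
                "conservation_error": e + s + i - stock,
            }
        )
    ledger = pd.DataFrame(rows)
    return DisaggregationResult(
        extensive=extensive,
        intensive=intensive,
        semi_intensive=semi,
        mask=mask,
        ledger=ledger,
    )
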