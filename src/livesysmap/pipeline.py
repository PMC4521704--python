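"""Pipeline orchestration: fit → bootstrap → predict/clip → disaggregate.

The five-step pathway for one species:

i.   fit the share curve(s) to units with observed shares;
ii.  bootstrap the fit (stock-weighted resampling) and predict per-unit
     shares, retaining observed values inside the 1-99 percentile
     envelope and clipping those outside;
iii. spread each unit's extensive stock over its suitable rural
     population;
iv.  obtain commercial stock per pixel by difference from the total;
v.   correct overflow pixels pro-rata so unit totals are conserved
     (pigs: split the commercial layer into semi-intensive/intensive).

All randomness flows from the single configured seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd
import yaml

from .bootstrap import BootstrapConfig, BootstrapEnsemble, predict_unit_share, run_bootstrap
from .curves import CountryRecord, PintForm, SystemShares, combine_pig_shares
from .disaggregate import DisaggregationResult, disaggregate_species
from .rasters import RasterBundle, read_ascii_grid, write_ascii_grid
from .io import read_country_table

__all__ = ["PipelineConfig", "predict_final_shares", "run_pipeline", "run_on_world"]

log = logging.getLogger("livesysmap")


@dataclass
class PipelineConfig:
    """Configuration for one end-to-end species run.

    Raster paths are ESRI ASCII grids; boolean layers (urban, snow/ice,
    unit ids) are grids of 0/1 or integer ids.
    """

    species: Literal["chicken", "pig"] = "chicken"
    country_table: str = "country.csv"
    raster_dir: str = "rasters"
    output_dir: str = "output"
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    pint_form: PintForm = "as_printed"
    rescale: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        boot = BootstrapConfig(**raw.pop("bootstrap", {}))
        cfg = cls(bootstrap=boot, **raw)
        # one seed drives everything, including the bootstrap
        cfg.bootstrap = replace(boot, seed=cfg.seed)
        return cfg


def predict_final_shares(
    records: Sequence[CountryRecord],
    ensembles: Mapping[str, BootstrapEnsemble],
    species: str,
) -> tuple[dict[str, SystemShares], pd.DataFrame]:
    """Final per-unit system shares under the median/percentile-clip rule.

    ``ensembles`` maps ``"ext"`` (and for pigs ``"int"``) to bootstrap
    ensembles whose prediction units cover every record.  Returns the
    shares keyed by unit id plus a provenance table.
    """
    shares: dict[str, SystemShares] = {}
    rows = []
    for rec in records:
        pe, tag_e = predict_unit_share(ensembles["ext"], rec.unit_id, rec.observed_p_ext)
        if species == "chicken":
            sh = SystemShares(p_ext=pe, p_sint=0.0, p_int=1.0 - pe)
            tag_i = ""
        else:
            pi, tag_i = predict_unit_share(ensembles["int"], rec.unit_id, rec.observed_p_int)
            sh = combine_pig_shares(pe, pi)
        shares[rec.unit_id] = sh
        lo_e, hi_e = ensembles["ext"].percentiles(rec.unit_id)
        rows.append(
            {
                "unit_id": rec.unit_id,
                "median_ext": ensembles["ext"].median(rec.unit_id),
                "p_low_ext": lo_e,
                "p_high_ext": hi_e,
                "p_ext": sh.p_ext,
                "p_sint": sh.p_sint,
                "p_int": sh.p_int,
                "provenance_ext": tag_e,
                "provenance_int": tag_i,
            }
        )
    return shares, pd.DataFrame(rows)


def run_on_world(
    records: Sequence[CountryRecord],
    bundle: RasterBundle,
    species: str,
    boot_config: BootstrapConfig,
    pint_form: PintForm = "as_printed",
    rescale: bool = True,
) -> tuple[DisaggregationResult, pd.DataFrame, dict[str, BootstrapEnsemble]]:
    """Library entry point: full pathway on in-memory inputs.

    Unit ids in the table are matched to the unit_map by enumeration
    order (record *k* ↔ id *k+1*), the layout :func:`simulate_world`
    produces and the CLI writes.
    """
    ensembles = {
        "ext": run_bootstrap(records, f"{species}_ext" if species == "pig" else "chicken_ext",
                             boot_config, predict_units=records, form=pint_form)
    }
    if species == "pig":
        ensembles["int"] = run_bootstrap(records, "pig_int", boot_config,
                                         predict_units=records, form=pint_form)
    log.info(
        "bootstrap: %s converged, %s discarded",
        {k: len(v.params) for k, v in ensembles.items()},
        {k: v.n_discarded for k, v in ensembles.items()},
    )

    shares_by_id, provenance = predict_final_shares(records, ensembles, species)
    unit_shares = {i + 1: shares_by_id[rec.unit_id] for i, rec in enumerate(records)}
    unit_totals = {i + 1: rec.stock for i, rec in enumerate(records)}

    result = disaggregate_species(
        bundle, unit_shares, unit_totals=unit_totals, species=species, rescale=rescale
    )
    n_clip = int((provenance["provenance_ext"].str.startswith("clipped")).sum())
    log.info(
        "disaggregation: %d units, %d clipped observations, %d overflow pixels",
        len(records), n_clip, int(result.ledger["pixels_overflowed"].sum()),
    )
    return result, provenance, ensembles


def _read_bundle(raster_dir: str | Path) -> RasterBundle:
    d = Path(raster_dir)
    g = {name: read_ascii_grid(d / f"{name}.asc")
         for name in ("livestock", "population", "urban", "elevation", "slope",
                      "snow_ice", "unit_map")}
    return RasterBundle(
        livestock=g["livestock"],
        population=g["population"],
        urban=g["urban"].values > 0.5,
        elevation=g["elevation"],
        slope=g["slope"],
        snow_ice=g["snow_ice"].values > 0.5,
        unit_map=g["unit_map"].values.astype(int),
    )


def run_pipeline(config: PipelineConfig) -> DisaggregationResult:
    """Run the full pathway from files on disk and write all outputs."""
    records = read_country_table(config.country_table)
    bundle = _read_bundle(config.raster_dir)
    boot = replace(config.bootstrap, seed=config.seed)
    result, provenance, ensembles = run_on_world(
        records, bundle, config.species, boot,
        pint_form=config.pint_form, rescale=config.rescale,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, grid in result.system_grids().items():
        write_ascii_grid(grid, out / f"{config.species}_{name}.asc")
    result.ledger.to_csv(out / "ledger.csv", index=False)
    provenance.to_csv(out / "unit_shares.csv", index=False)
    for key, ens in ensembles.items():
        ens.params_frame().to_csv(out / f"ensemble_{key}.csv", index=False)
    return result
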