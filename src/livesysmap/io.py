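"""Tables, parameter files and descriptive reports.

Country tables are CSV with columns ``unit_id, gdp_ppp_usd, stock,
observed_p_ext, observed_p_int`` (empty cell = unobserved).  Fitted
parameters are JSON; ensembles, predictions and conservation ledgers
are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bootstrap import BootstrapEnsemble
from .curves import CountryRecord, FitResult

__all__ = [
    "read_country_table",
    "write_country_table",
    "write_fit_json",
    "read_fit_json",
    "write_ensemble_csv",
    "productivity_report",
    "compare_rasters",
]

_REQUIRED_COLS = ("unit_id", "gdp_ppp_usd", "stock")
_OPTIONAL_COLS = ("observed_p_ext", "observed_p_int")


def read_country_table(path: str | Path) -> list[CountryRecord]:
    """Read and validate a country/province table from CSV."""
    df = pd.read_csv(path)
    for col in _REQUIRED_COLS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    records = []
    for _, row in df.iterrows():
        def opt(col: str) -> float | None:
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        records.append(
            CountryRecord(
                unit_id=str(row["unit_id"]),
                gdp_ppp=float(row["gdp_ppp_usd"]),
                stock=float(row["stock"]),
                observed_p_ext=opt("observed_p_ext"),
                observed_p_int=opt("observed_p_int"),
            )
        )
    return records


def write_country_table(records: Sequence[CountryRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in records],
            "gdp_ppp_usd": [r.gdp_ppp for r in records],
            "stock": [r.stock for r in records],
            "observed_p_ext": [r.observed_p_ext for r in records],
            "observed_p_int": [r.observed_p_int for r in records],
        }
    ).to_csv(path, index=False)


def write_fit_json(fit: FitResult, species: str, path: str | Path) -> None:
    payload = {
        "species": species,
        "target": fit.target,
        "form": fit.form,
        "mu": float(fit.params.mu),
        "lambda": float(fit.params.lam),
        "alpha": float(fit.params.alpha),
        "rss": float(fit.rss),
        "converged": bool(fit.converged),
        "n_obs": int(fit.n_obs),
        "se": {k: float(v) for k, v in fit.se.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fit_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_ensemble_csv(ensemble: BootstrapEnsemble, path: str | Path) -> None:
    ensemble.params_frame().to_csv(path, index=False)


def productivity_report(
    production_tonnes: Sequence[float],
    stock: Sequence[float],
    gdp_ppp: Sequence[float],
    unit_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Meat output per animal (kg/head/year) and its income correlation.

    Productivity = 1000 · production_tonnes / stock.  The correlation is
    Pearson's r between log10 productivity and log10 GDP per capita over
    units with stock > 0; NaN when fewer than two such units exist.
    """
    prod = np.asarray(production_tonnes, float)
    stk = np.asarray(stock, float)
    gdp = np.asarray(gdp_ppp, float)
    ids = list(unit_ids) if unit_ids is not None else [str(i) for i in range(len(stk))]
    keep = stk > 0
    productivity = np.full(len(stk), np.nan)
    productivity[keep] = 1000.0 * prod[keep] / stk[keep]
    table = pd.DataFrame(
        {"unit_id": ids, "gdp_ppp_usd": gdp, "stock": stk,
         "productivity_kg_per_head": productivity, "included": keep}
    )
    ok = keep & (productivity > 0) & (gdp > 0)
    if ok.sum() < 2:
        return table, float("nan")
    r = float(np.corrcoef(np.log10(productivity[ok]), np.log10(gdp[ok]))[0, 1])
    return table, r


def compare_rasters(a, b, density_breaks: Sequence[float]) -> tuple[float, pd.DataFrame]:
    """Pearson r and a density-class cross-tabulation of two rasters.

    Only pixels valid in both layers enter; classes are defined by
    ``density_breaks`` (right-open bins via ``np.digitize``).
    """
    valid = a.valid() & b.valid()
    if not a.same_grid(b):
        raise ValueError("rasters are not co-registered")
    if not np.any(valid):
        raise ValueError("no jointly valid pixels to compare")
    av, bv = a.values[valid], b.values[valid]
    if np.std(av) == 0 or np.std(bv) == 0:
        r = 1.0 if np.allclose(av, bv) else float("nan")
    else:
        r = float(np.corrcoef(av, bv)[0, 1])
    breaks = np.asarray(density_breaks, float)
    ca = np.digitize(av, breaks)
    cb = np.digitize(bv, breaks)
    n_cls = len(breaks) + 1
    tab = np.zeros((n_cls, n_cls), dtype=int)
    np.add.at(tab, (ca, cb), 1)
    labels = [f"class_{i}" for i in range(n_cls)]
    return r, pd.DataFrame(tab, index=labels, columns=labels)
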