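"""Stock-weighted Monte-Carlo bootstrap of the share-curve fit.

Countries are resampled with replacement with probability proportional
to their national stock, so large producers dominate the fitted curves.
Each replicate refits the curve; non-converged replicates are discarded
(and counted).  Per-unit predictions are the ensemble of converged
curves evaluated at the unit's log10-GDP; the final per-unit share is
the ensemble median, or the observed value if it lies inside the
1-99 percentile envelope of the predictions (observations outside the
envelope are clipped to it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .curves import (
    CountryRecord,
    FitTarget,
    PintForm,
    ShareCurveParams,
    curve_value,
    fit_share_curve,
)

__all__ = [
    "BootstrapConfig",
    "BootstrapEnsemble",
    "weighted_resample",
    "run_bootstrap",
    "predict_unit_share",
]

Provenance = Literal["predicted", "observed_retained", "clipped_low", "clipped_high"]


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: 1,000 replicates of 25 countries by default,
    with 1/99 percentile clipping of observed values."""

    n_reps: int = 1000
    sample_size: int = 25
    seed: int = 0
    percentile_low: float = 1.0
    percentile_high: float = 99.0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.sample_size < 4:
            raise ValueError("sample_size must be >= 4")
        if not (0 <= self.percentile_low < self.percentile_high <= 100):
            raise ValueError("need 0 <= low < high <= 100")


@dataclass
class BootstrapEnsemble:
    """Converged replicate parameter sets and per-unit predicted shares."""

    target: FitTarget
    form: PintForm
    params: list[ShareCurveParams]
    unit_ids: list[str]
    unit_g: np.ndarray
    predictions: np.ndarray  # (n_units, n_converged)
    n_requested: int
    n_discarded: int
    config: BootstrapConfig = field(default_factory=BootstrapConfig)

    def __post_init__(self) -> None:
        if self.predictions.shape != (len(self.unit_ids), len(self.params)):
            raise ValueError("prediction matrix shape mismatch")

    def _row(self, unit_id: str) -> np.ndarray:
        try:
            i = self.unit_ids.index(unit_id)
        except ValueError:
            raise KeyError(f"unit {unit_id!r} not in ensemble") from None
        return self.predictions[i]

    def median(self, unit_id: str) -> float:
        return float(np.median(self._row(unit_id)))

    def percentiles(self, unit_id: str, low: float | None = None, high: float | None = None):
        lo = self.config.percentile_low if low is None else low
        hi = self.config.percentile_high if high is None else high
        p = np.percentile(self._row(unit_id), [lo, hi])  # linear interpolation
        return float(p[0]), float(p[1])

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(len(self.params)),
                "mu": [p.mu for p in self.params],
                "lambda": [p.lam for p in self.params],
                "alpha": [p.alpha for p in self.params],
                "converged": True,
            }
        )


def weighted_resample(
    records: Sequence[CountryRecord], sample_size: int, rng: np.random.Generator
) -> list[CountryRecord]:
    """Draw ``sample_size`` records with replacement, probability ∝ stock."""
    stocks = np.array([r.stock for r in records], dtype=float)
    total = stocks.sum()
    if not (total > 0):
        raise ValueError("total stock over records must be positive")
    idx = rng.choice(len(records), size=sample_size, replace=True, p=stocks / total)
    return [records[i] for i in idx]


def run_bootstrap(
    records: Sequence[CountryRecord],
    target: FitTarget,
    config: BootstrapConfig,
    predict_units: Sequence[CountryRecord] | None = None,
    form: PintForm = "as_printed",
) -> BootstrapEnsemble:
    """Resample-and-refit ensemble for one share curve.

    ``records`` supplies the observed data pool (units without the
    relevant observed share are ignored); ``predict_units`` the units at
    which every converged curve is evaluated (defaults to ``records``).

    Raises
    ------
    RuntimeError
        If fewer than half of the replicates converge.
    """
    share_attr = "observed_p_int" if target == "pig_int" else "observed_p_ext"
    pool = [r for r in records if getattr(r, share_attr) is not None]
    if not pool:
        raise ValueError(f"no observed records for target {target!r}")
    units = list(predict_units) if predict_units is not None else list(records)

    # with stock-proportional weights a dominant producer can yield
    # draws with too few distinct GDP values to pose the regression at
    # all; such draws are redrawn (they never reached the optimizer),
    # unlike genuine non-converged fits, which are discarded
    n_min = 5 if target != "chicken_ext" else 4
    max_redraws = 1000

    rng = np.random.default_rng(config.seed)
    kept: list[ShareCurveParams] = []
    n_discarded = 0
    for _ in range(config.n_reps):
        sample = None
        for _attempt in range(max_redraws):
            cand = weighted_resample(pool, config.sample_size, rng)
            if len({r.g for r in cand}) >= n_min:
                sample = cand
                break
        if sample is None:
            n_discarded += 1
            continue
        fit = fit_share_curve(sample, target, form=form)
        if fit.converged:
            kept.append(fit.params)
        else:
            n_discarded += 1

    if len(kept) < 0.5 * config.n_reps:
        raise RuntimeError(
            f"only {len(kept)}/{config.n_reps} bootstrap replicates converged; "
            "ensemble unreliable"
        )

    g = np.array([u.g for u in units])
    preds = np.column_stack([np.asarray(curve_value(p, g, target, form)) for p in kept]) \
        if kept else np.empty((len(units), 0))
    return BootstrapEnsemble(
        target=target,
        form=form,
        params=kept,
        unit_ids=[u.unit_id for u in units],
        unit_g=g,
        predictions=preds,
        n_requested=config.n_reps,
        n_discarded=n_discarded,
        config=config,
    )


def predict_unit_share(
    ensemble: BootstrapEnsemble,
    unit_id: str,
    observed: float | None = None,
) -> tuple[float, Provenance]:
    """Final share for one unit under the median / percentile-clip rule.

    Without an observation the ensemble median is used.  An observation
    inside the [low, high] percentile envelope of the unit's predicted
    shares is retained; outside, it is clipped to the nearer bound.
    """
    if ensemble.predictions.shape[1] == 0:
        raise ValueError("ensemble is empty")
    if observed is None:
        return ensemble.median(unit_id), "predicted"
    p_lo, p_hi = ensemble.percentiles(unit_id)
    if observed < p_lo:
        return p_lo, "clipped_low"
    if observed > p_hi:
        return p_hi, "clipped_high"
    return float(observed), "observed_retained"
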