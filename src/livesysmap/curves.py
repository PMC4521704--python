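"""Bounded logistic curves linking production-system shares to national income.

The proportion of extensively raised animals declines with wealth.  With
``g = log10(GDP per capita, USD PPP)`` the curves are

* chicken, extensive::

      P_ext(g) = 1 / (1 + exp(4·μ·(λ − g) + 2))

* pig, extensive (share saturates at α ≤ 1)::

      P_ext(g) = α / (1 + exp(4·(μ/α)·(λ − g) + 2))

* pig, intensive, ``as_printed`` form::

      P_int(g) = 1 − α / (1 + exp(4·(μ/α)·(λ − g) + 2))

  and a ``bounded`` alternative ``α·σ(u)`` with the same exponent
  ``u``, whose range is (0, α) rather than (1−α, 1).

The μ/α scaling makes μ the slope of the curve (per log10-USD) at the
point where the share equals half its range, and λ positions that
transition on the income axis.  Curves are fitted to observed national
shares by bounded nonlinear least squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

__all__ = [
    "ShareCurveParams",
    "SystemShares",
    "CountryRecord",
    "FitResult",
    "p_ext_chicken",
    "p_ext_pig",
    "p_int_pig",
    "shares_chicken",
    "shares_pig",
    "fit_share_curve",
]

PintForm = Literal["as_printed", "bounded"]
FitTarget = Literal["chicken_ext", "pig_ext", "pig_int"]


@dataclass(frozen=True)
class ShareCurveParams:
    """Parameters of one bounded logistic share curve.

    Attributes
    ----------
    mu
        Slope of the share curve at its midpoint, per log10-USD.
        Negative for extensive shares (they fall with income).
    lam
        Position parameter, in log10-USD.
    alpha
        Asymptotic bound of the share, in (0, 1]; fixed to 1 for chickens.
    """

    mu: float
    lam: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu) and math.isfinite(self.lam)):
            raise ValueError("mu and lam must be finite")
        if self.mu == 0:
            raise ValueError("mu must be nonzero")
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")


@dataclass(frozen=True)
class SystemShares:
    """Proportions of stock in each production system; they sum to 1.

    Chickens have only extensive and intensive systems (p_sint = 0);
    pigs additionally have a semi-intensive tier.
    """

    p_ext: float
    p_sint: float
    p_int: float

    def __post_init__(self) -> None:
        for name in ("p_ext", "p_sint", "p_int"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.p_ext + self.p_sint + self.p_int - 1.0) > 1e-12:
            raise ValueError("system shares must sum to 1")


@dataclass
class CountryRecord:
    """One admin unit: a country, or a Chinese province treated identically."""

    unit_id: str
    gdp_ppp: float
    stock: float
    observed_p_ext: float | None = None
    observed_p_int: float | None = None

    def __post_init__(self) -> None:
        if not (self.gdp_ppp > 0 and math.isfinite(self.gdp_ppp)):
            raise ValueError(f"unit {self.unit_id}: GDP per capita must be positive")
        if not (self.stock >= 0):
            raise ValueError(f"unit {self.unit_id}: stock must be >= 0")
        for name in ("observed_p_ext", "observed_p_int"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 1):
                raise ValueError(f"unit {self.unit_id}: {name}={v} outside [0, 1]")

    @property
    def g(self) -> float:
        """log10 GDP per capita (USD PPP)."""
        return math.log10(self.gdp_ppp)


def _check_g(g) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("log10-GDP values must be finite")
    return g


def _exponent(params: ShareCurveParams, g: np.ndarray) -> np.ndarray:
    return 4.0 * (params.mu / params.alpha) * (params.lam - g) + 2.0


def p_ext_chicken(params: ShareCurveParams, g):
    """Extensive chicken share at log10-GDP ``g``; alpha must be 1."""
    if params.alpha != 1.0:
        raise ValueError("chicken curve has alpha fixed to 1")
    return expit(-_exponent(params, _check_g(g)))


def p_ext_pig(params: ShareCurveParams, g):
    """Extensive pig share at log10-GDP ``g``; range (0, alpha)."""
    return params.alpha * expit(-_exponent(params, _check_g(g)))


def p_int_pig(params: ShareCurveParams, g, form: PintForm = "as_printed"):
    """Intensive pig share at log10-GDP ``g``.

    ``as_printed`` evaluates 1 − α·σ(−u), range (1−α, 1);
    ``bounded`` evaluates α·σ(u), range (0, α).  Both increase with g
    when mu < 0.
    """
    u = _exponent(params, _check_g(g))
    if form == "as_printed":
        return 1.0 - params.alpha * expit(-u)
    if form == "bounded":
        return params.alpha * expit(u)
    raise ValueError(f"unknown p_int form: {form!r}")


def shares_chicken(params: ShareCurveParams, g: float) -> SystemShares:
    """Chicken system shares: intensive is the complement of extensive."""
    pe = float(p_ext_chicken(params, g))
    return SystemShares(p_ext=pe, p_sint=0.0, p_int=1.0 - pe)


def shares_pig(
    ext_params: ShareCurveParams,
    int_params: ShareCurveParams,
    g: float,
    form: PintForm = "as_printed",
) -> SystemShares:
    """Pig system shares; the semi-intensive share is the residual.

    If the two fitted curves overlap so that p_ext + p_int > 1, the
    residual is clamped to 0 and p_ext, p_int rescaled proportionally
    to sum to 1 (a warning is emitted).
    """
    pe = float(p_ext_pig(ext_params, g))
    pi = float(p_int_pig(int_params, g, form=form))
    return combine_pig_shares(pe, pi)


def combine_pig_shares(p_ext: float, p_int: float) -> SystemShares:
    """Assemble pig shares from extensive and intensive proportions."""
    ps = 1.0 - (p_ext + p_int)
    if ps < 0:
        warnings.warn(
            f"p_ext + p_int = {p_ext + p_int:.4f} > 1; clamping semi-intensive "
            "share to 0 and renormalizing",
            stacklevel=2,
        )
        tot = p_ext + p_int
        return SystemShares(p_ext=p_ext / tot, p_sint=0.0, p_int=p_int / tot)
    return SystemShares(p_ext=p_ext, p_sint=ps, p_int=p_int)


def curve_value(params: ShareCurveParams, g, target: FitTarget, form: PintForm = "as_printed"):
    """Evaluate the curve named by ``target`` at ``g``."""
    if target == "chicken_ext":
        return p_ext_chicken(params, g)
    if target == "pig_ext":
        return p_ext_pig(params, g)
    if target == "pig_int":
        return p_int_pig(params, g, form=form)
    raise ValueError(f"unknown target: {target!r}")


@dataclass
class FitResult:
    """Outcome of one nonlinear least-squares curve fit."""

    params: ShareCurveParams
    rss: float
    converged: bool
    n_obs: int
    target: FitTarget
    form: PintForm = "as_printed"
    se: dict[str, float] = field(default_factory=dict)


def _observed_share(rec: CountryRecord, target: FitTarget) -> float | None:
    return rec.observed_p_int if target == "pig_int" else rec.observed_p_ext


def fit_share_curve(
    records: Sequence[CountryRecord],
    target: FitTarget,
    init: ShareCurveParams | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    form: PintForm = "as_printed",
) -> FitResult:
    """Fit one share curve to observed national shares.

    Chicken fits estimate (mu, lam) with alpha fixed at 1; pig fits
    additionally estimate alpha in (0, 1].  Uses bounded trust-region
    least squares; a fit that does not converge is returned flagged,
    not raised, so bootstrap replicates can be discarded.

    Raises
    ------
    ValueError
        If there are fewer observations with distinct GDP values than
        the curve needs (4 for two-parameter, 5 for three-parameter fits).
    """
    obs = [(r.g, _observed_share(r, target)) for r in records]
    obs = [(g, y) for g, y in obs if y is not None]
    if not obs:
        raise ValueError(f"no records with observed shares for target {target!r}")
    g = np.array([p[0] for p in obs])
    y = np.array([p[1] for p in obs])

    free_alpha = target != "chicken_ext"
    n_min = 5 if free_alpha else 4
    if len(np.unique(g)) < n_min:
        raise ValueError(
            f"need >= {n_min} records with distinct GDP values for {target!r}, "
            f"got {len(np.unique(g))}"
        )

    if init is None:
        if free_alpha:
            a0 = min(1.0, float(np.max(y)) + 0.05) if target == "pig_ext" else 0.95
            a0 = max(a0, 0.05)
        else:
            a0 = 1.0
        init = ShareCurveParams(mu=-1.0, lam=float(np.median(g)), alpha=a0)

    bounds = bounds or {}
    lo_mu, hi_mu = bounds.get("mu", (-50.0, 50.0))
    lo_lam, hi_lam = bounds.get("lam", (float(g.min()) - 5.0, float(g.max()) + 5.0))
    lo_a, hi_a = bounds.get("alpha", (1e-6, 1.0))

    def unpack(x: np.ndarray) -> ShareCurveParams:
        if free_alpha:
            mu, lam, alpha = x
        else:
            (mu, lam), alpha = x, 1.0
        return ShareCurveParams(mu=mu if mu != 0 else 1e-12, lam=lam, alpha=alpha)

    def residuals(x: np.ndarray) -> np.ndarray:
        return np.asarray(curve_value(unpack(x), g, target, form)) - y

    x0 = [init.mu, init.lam] + ([init.alpha] if free_alpha else [])
    lo = [lo_mu, lo_lam] + ([lo_a] if free_alpha else [])
    hi = [hi_mu, hi_lam] + ([hi_a] if free_alpha else [])
    x0 = np.clip(x0, lo, hi)

    sol = least_squares(
        residuals, x0, bounds=(lo, hi), method="trf",
        ftol=1e-12, xtol=1e-12, gtol=1e-12,
    )
    params = unpack(sol.x)
    rss = float(2.0 * sol.cost)
    converged = bool(sol.success) and np.all(np.isfinite(sol.x))

    # Gauss-Newton covariance for approximate standard errors
    se: dict[str, float] = {}
    n_par = len(sol.x)
    if converged and len(y) > n_par:
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.inv(jtj) * rss / (len(y) - n_par)
            diag = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
            names = ["mu", "lam"] + (["alpha"] if free_alpha else [])
            se = dict(zip(names, diag.tolist()))
        except np.linalg.LinAlgError:
            pass

    return FitResult(
        params=params, rss=rss, converged=converged,
        n_obs=len(y), target=target, form=form, se=se,
    )
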