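import numpy as np

from livesysmap.curves import CountryRecord, ShareCurveParams, p_ext_chicken, p_ext_pig


def make_records(params: ShareCurveParams, g: np.ndarray, target: str = "chicken_ext",
                 noise_sd: float = 0.0, rng: np.random.Generator | None = None,
                 stocks: np.ndarray | None = None) -> list[CountryRecord]:
    """Records with observed shares lying exactly (or noisily) on a curve."""
    if target == "chicken_ext":
        y = np.asarray(p_ext_chicken(params, g), dtype=float)
    else:
        y = np.asarray(p_ext_pig(params, g), dtype=float)
    if noise_sd > 0:
        assert rng is not None
        y = np.clip(y + rng.normal(0.0, noise_sd, size=len(y)), 0.0, 1.0)
    if stocks is None:
        stocks = np.ones(len(y))
    kw = "observed_p_int" if target == "pig_int" else "observed_p_ext"
    return [
        CountryRecord(unit_id=f"u{i}", gdp_ppp=float(10.0 ** g[i]), stock=float(stocks[i]),
                      **{kw: float(y[i])})
        for i in range(len(y))
    ]
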