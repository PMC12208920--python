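"""Purpose-built data simulators shared across test modules."""

import numpy as np
import pandas as pd


def did_panel(seed, n=80, effect=1.0, confounded=True):
    """Two-period panel for DiD calibration: treatment probability rises
    with poverty (confounding), rates share a common secular trend, and
    treated units get a multiplicative `effect` on the post-period rate."""
    rng = np.random.default_rng(seed)
    poverty = rng.uniform(5, 40, n)
    gini = rng.uniform(45, 65, n)
    logit = -2.5 + (0.08 * poverty if confounded else 0.0)
    treated = rng.random(n) < 1 / (1 + np.exp(-logit))
    pop = rng.integers(10_000, 80_000, n)
    base_rate = 6.0 * np.exp(0.01 * poverty + rng.normal(0, 0.15, n))
    rows = []
    for i in range(n):
        for year, post in ((2004, 0), (2019, 1)):
            rate = base_rate[i] * (0.8 ** post)          # common trend
            if treated[i] and post:
                rate *= effect
            deaths = rng.poisson(pop[i] / 1000 * rate)
            rows.append({
                "municipality": f"M{i:03d}", "year": year,
                "deaths": int(deaths), "population": int(pop[i]),
                "poverty_rate": poverty[i], "gini": gini[i],
                "treated": int(treated[i])})
    return pd.DataFrame(rows)
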