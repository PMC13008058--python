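"""Shared simulation helpers for the model-fitting test suites."""

import numpy as np
import pandas as pd

TWO_HUMP = dict(c1=500.0, w1=200.0, h1=2.2, c2=1400.0, w2=220.0, h2=1.8)


def two_hump_curve(cdd, p=TWO_HUMP):
    cdd = np.asarray(cdd, dtype=float)
    return p["h1"] * np.exp(-0.5 * ((cdd - p["c1"]) / p["w1"]) ** 2) + p["h2"] * np.exp(
        -0.5 * ((cdd - p["c2"]) / p["w2"]) ** 2
    )


def sim_vc_data(
    seed,
    n_sites=100,
    years=(2018, 2019, 2020, 2021, 2022),
    obs_per_site_year=4,
    alpha=0.3,
    gamma=0.1,
    betas=(0.3, -0.2),
    f_focal=None,
    sigma_site=0.3,
    phenology=True,
):
    """Draw observations from the varying-coefficient Poisson model directly.

    Covariates v1, v2 are iid standard normal per site-year; ``f_focal`` is
    an optional callable added to v1's coefficient along CDD.  Defaults give
    500 site-years.  Returns a tidy frame with site_id, year, cdd, v1, v2,
    count.
    """
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sigma_site, n_sites)
    y0 = np.mean(years)
    rows = []
    for s in range(n_sites):
        for yr in years:
            v1, v2 = rng.normal(size=2)
            cdd = rng.uniform(150.0, 2200.0, obs_per_site_year)
            f0 = two_hump_curve(cdd) if phenology else np.zeros_like(cdd)
            coef1 = betas[0] + (f_focal(cdd) if f_focal is not None else 0.0)
            eta = alpha + f0 + coef1 * v1 + betas[1] * v2 + gamma * (yr - y0) + b[s]
            counts = rng.poisson(np.exp(eta))
            rows += [(f"s{s:03d}", yr, c, v1, v2, k) for c, k in zip(cdd, counts)]
    return pd.DataFrame(rows, columns=["site_id", "year", "cdd", "v1", "v2", "count"])
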