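"""Replicate-world simulation studies of the Monte Carlo framework.

These experiments quantify the statistical calibration of the imputation
machinery under known, correctly specified conditions:

* :func:`coverage_experiment` -- across many replicate worlds, how often do
  the imputed-site posterior intervals contain the true ΔSOC?
* :func:`null_regression_experiment` -- with no true ΔSOC-aridity
  association, how often does the posterior repeated regression call the
  slope significant (type-I error)?
* :func:`signal_regression_experiment` -- with a strong true association,
  does the posterior median slope carry the correct sign?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import as_rng, spawn_seeds
from .config import BiasParams
from .imputation import (SiteDelta, calibrate_bias, draw_imputed,
                         draw_measured, merge_ensemble, posterior_regression,
                         posterior_summaries)


@dataclass
class CoverageResult:
    coverage_pct: float  # % of imputed sites with truth inside the interval
    n_evaluations: int
    nominal_pct: float


def coverage_experiment(n_worlds: int = 200, n_measured: int = 10,
                        n_imputed: int = 5, bias: BiasParams | None = None,
                        m: int = 1000, n_pixels: int = 10, pixel_sd: float = 8.0,
                        level: float = 95.0, seed: int = 0) -> CoverageResult:
    """Empirical coverage of imputed-site posterior credible intervals.

    Each replicate world draws true site ΔSOC values, constructs the
    gridded product so the linear bias holds exactly in distribution,
    calibrates the bias on the measured sites, imputes the unmeasured
    sites with M draws each and checks whether the known truth falls in
    the central ``level`` % interval.
    """
    from .synthetic import generate_gridded_estimates

    bias = bias or BiasParams()
    hits = 0
    total = 0
    for ws in spawn_seeds(seed, n_worlds):
        rng = as_rng(ws)
        n = n_measured + n_imputed
        truth = rng.uniform(-20.0, 80.0, n)
        est = generate_gridded_estimates(truth, bias, n_pixels, rng,
                                         pixel_sd=pixel_sd)
        g_mean = est.deltas["delta_mean"].to_numpy()
        g_se = est.deltas["delta_se"].to_numpy()

        pairs = pd.DataFrame({
            "site_id": [f"W{i}" for i in range(n_measured)],
            "field": truth[:n_measured],
            "gridded": g_mean[:n_measured],
        })
        model = calibrate_bias(pairs)
        lo_q, hi_q = (100.0 - level) / 2.0, (100.0 + level) / 2.0
        for j in range(n_measured, n):
            site = SiteDelta(f"W{j}", float(g_mean[j]), float(g_se[j]), "gridded")
            draws = draw_imputed(site, model, m, rng)
            lo, hi = np.percentile(draws, [lo_q, hi_q])
            hits += int(lo <= truth[j] <= hi)
            total += 1
    return CoverageResult(coverage_pct=100.0 * hits / total,
                          n_evaluations=total, nominal_pct=level)


def null_regression_experiment(n_sites: int = 15, se: float = 10.0,
                               m: int = 1000, n_rep: int = 1000,
                               seed: int = 0) -> dict:
    """Type-I error of the posterior repeated regression under a null world.

    All sites share one true ΔSOC (no aridity association); each site's
    draws scatter around it with SD ``se``, so each repetition regresses
    independent noise on AI and the fraction of P < 0.05 repetitions
    estimates the size of the test.
    """
    rng = as_rng(seed)
    ai = np.linspace(0.32, 2.17, n_sites)
    draws = {}
    sources = {}
    for i in range(n_sites):
        site = SiteDelta(f"N{i}", 20.0, se, "field")
        draws[site.site_id] = draw_measured(site, m, rng)
        sources[site.site_id] = "field"
    ens = merge_ensemble(draws, sources)
    reg = posterior_regression(ens, {f"N{i}": ai[i] for i in range(n_sites)},
                               n_rep=n_rep)
    return reg.summaries


def signal_regression_experiment(n_worlds: int = 100, n_sites: int = 15,
                                 slope: float = 57.0, intercept: float = -38.0,
                                 site_sd: float = 18.0, se: float = 10.0,
                                 m: int = 200, n_rep: int = 200,
                                 seed: int = 0) -> dict:
    """Sign agreement of the posterior median slope under a strong signal.

    Returns the fraction of replicate worlds whose posterior median slope
    has the sign of the generating slope, plus the median R² across worlds.
    """
    ai = np.linspace(0.32, 2.17, n_sites)
    correct = 0
    r2_medians = []
    for ws in spawn_seeds(seed, n_worlds):
        rng = as_rng(ws)
        truth = intercept + slope * ai + rng.normal(0.0, site_sd, n_sites)
        draws, sources = {}, {}
        for i in range(n_sites):
            site = SiteDelta(f"S{i}", float(truth[i]), se, "field")
            draws[site.site_id] = draw_measured(site, m, rng)
            sources[site.site_id] = "field"
        ens = merge_ensemble(draws, sources)
        reg = posterior_regression(ens, {f"S{i}": ai[i] for i in range(n_sites)},
                                   n_rep=n_rep)
        correct += int(np.sign(reg.summaries["slope_median"]) == np.sign(slope))
        r2_medians.append(reg.summaries["r2_median"])
    return {"frac_correct_sign": correct / n_worlds,
            "median_r2": float(np.median(r2_medians)),
            "n_worlds": n_worlds}


def interval_summary_experiment(n_worlds: int, **kwargs) -> pd.DataFrame:
    """Convenience wrapper returning one coverage row per configuration."""
    res = coverage_experiment(n_worlds=n_worlds, **kwargs)
    return pd.DataFrame([{"coverage_pct": res.coverage_pct,
                          "n": res.n_evaluations,
                          "nominal_pct": res.nominal_pct}])
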