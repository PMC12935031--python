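"""Seeded generator of a complete synthetic terracing study with known truth.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage of the pipeline can be exercised against a
known ground truth:

* sites along an aridity gradient (AI = MAP/PET), with site-level true ΔSOC
  following a configurable linear AI trend plus Gaussian site noise;
* depth-explicit cut/fill/control soil profiles with exponentially decaying
  SOC, a Gaussian buried-topsoil bump in fill positions and climate-graded
  surface depletion in cut positions;
* 26 geochemical covariates with climate-linked linear trends (humid sites
  rich in reactive oxides and acidic; arid sites rich in base cations) and
  lognormal noise, plus a soil-respiration response wired to latent oxide /
  cation signals with climate-dependent weights;
* a gridded control product related to field truth by the linear bias
  ``field = alpha + beta * gridded + N(0, sigma)`` by construction;
* FTIR spectra as Gaussian peaks on a configurable baseline with recorded
  per-band true heights;
* daily phenology series with stored true growing-season integrals;
* literature-synthesis records with controllable exclusion flags.

All generators take an explicit seed (or ``numpy`` Generator) and are fully
deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import as_rng, spawn_seeds
from .config import BiasParams, DeltaSocModel, WorldConfig
from .ftir import Spectrum
from .stats import classify_climate

# ---------------------------------------------------------------------------
# Geochemical covariates: name -> (value at AI=1, slope per AI unit,
# latent signal it loads on, loading weight).  Positive slopes increase
# toward the humid end.  Units follow field convention: oxides g/kg,
# exchangeable cations and TRB cmol/kg, OC fractions % of total C.
# ---------------------------------------------------------------------------
COVARIATE_TRENDS: dict[str, tuple[float, float, str, float]] = {
    # organically complexed (pyrophosphate) oxides -- humid-enriched
    "Fe_p": (2.0, 1.5, "ox", 0.8),
    "Al_p": (1.5, 1.0, "ox", 0.8),
    "Mn_p": (0.3, 0.15, "ox", 0.6),
    # poorly crystalline (oxalate) oxides -- humid-enriched
    "Fe_o": (3.0, 2.0, "ox", 0.8),
    "Al_o": (2.0, 1.2, "ox", 0.8),
    "Mn_o": (0.5, 0.25, "ox", 0.6),
    # crystalline (dithionite) oxides -- arid-enriched
    "Fe_d": (8.0, -2.0, "cat", 0.3),
    "Al_d": (3.0, -0.8, "cat", 0.3),
    "Mn_d": (0.8, -0.2, "cat", 0.3),
    "Fe_d_Fe_t": (0.5, -0.08, "cat", 0.2),
    # exchangeable base cations and total reserve in bases -- arid-enriched
    "K_ex": (0.8, -0.25, "cat", 0.7),
    "Ca_ex": (12.0, -4.0, "cat", 0.8),
    "Mg_ex": (3.0, -1.0, "cat", 0.8),
    "Na_ex": (0.4, -0.12, "cat", 0.6),
    "TRB": (25.0, -8.0, "cat", 0.8),
    # pH: alkaline arid soils, acidic humid soils
    "pH": (6.8, -1.0, "cat", 0.3),
    # organic-matter composition
    "CN": (10.0, 1.5, "chem", 0.7),
    "poc": (20.0, 3.0, "chem", 0.5),
    "micro_agg": (30.0, 2.0, "chem", 0.4),
    "s_c": (45.0, -4.0, "chem", 0.4),
    "arom_aliph": (1.2, -0.25, "chem", 0.7),
    "arom_acid": (0.8, -0.15, "chem", 0.7),
    "aliph_acid": (0.7, 0.1, "chem", 0.5),
}

#: The full 26-covariate panel: the trend table above plus soil texture.
COVARIATE_NAMES: tuple[str, ...] = tuple(COVARIATE_TRENDS) + ("clay", "silt", "sand")

#: Default FTIR peak placement: band name -> (center cm^-1, Gaussian SD cm^-1).
#: Centers sit inside the interpretation bands (aliphatic C-H 2898-2976 and
#: 2839-2870, carboxylic 1570-1720, aromatic C=C 1500-1550 cm^-1).
DEFAULT_PEAKS: dict[str, tuple[float, float]] = {
    "aliph_1": (2937.0, 18.0),
    "aliph_2": (2854.0, 8.0),
    "acid": (1645.0, 35.0),
    "arom": (1525.0, 12.0),
}


@dataclass
class GriddedEstimates:
    """Per-site gridded ΔSOC estimates plus layered stock profiles."""

    deltas: pd.DataFrame  # site_id, delta_mean, delta_se, n_pixels
    layers: pd.DataFrame  # site_id, schema, layer_top, layer_bottom, stock, total_stock


@dataclass
class World:
    """A complete synthetic study with its ground truth."""

    config: WorldConfig
    sites: pd.DataFrame
    horizons: pd.DataFrame
    gridded: GriddedEstimates
    spectra: list[Spectrum]
    spectra_truth: pd.DataFrame
    phenology: pd.DataFrame
    phenology_truth: pd.DataFrame
    synthesis: pd.DataFrame
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sites
# ---------------------------------------------------------------------------

def generate_sites(config: WorldConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate site climates and true site-level ΔSOC.

    AI values are evenly spaced across ``config.ai_range`` (so the gradient
    is always fully spanned); MAT and PET follow deterministic climate
    trends along the gradient; true ΔSOC follows the configured linear AI
    model plus Gaussian site noise.
    """
    rng = as_rng(config.seed if rng is None else rng)
    n = config.n_sites
    lo, hi = config.ai_range
    ai = np.linspace(lo, hi, n)
    pet = 1450.0 - 330.0 * ai  # mm/yr, drier sites more evaporative
    map_mm = ai * pet
    mat = 19.0 - 6.5 * (ai - lo) / (hi - lo) + rng.normal(0.0, 1.0, n)
    dm = config.delta_soc_model
    true_delta = dm.intercept + dm.slope * ai + rng.normal(0.0, dm.site_sd, n)
    cls = [classify_climate(a) for a in ai]
    return pd.DataFrame({
        "site_id": [f"S{i + 1:02d}" for i in range(n)],
        "ai": ai,
        "mat": mat,
        "map": map_mm,
        "pet": pet,
        "climate_binary": [c.binary for c in cls],
        "climate_zone": [c.zone for c in cls],
        "true_delta_soc": true_delta,
    })


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def soc_depth_function(ai: float, config: WorldConfig, position: str = "control",
                       delta: float = 0.0):
    """Noise-free SOC(%) depth curve for a given position.

    Control: exponential decay with an AI-dependent surface value.  Fill:
    the control curve scaled by ``1 + delta/100`` plus the Gaussian
    buried-topsoil bump.  Cut: the scaled curve times a surface-depletion
    factor that is stronger at the arid end of the gradient.
    """
    soc0 = config.soc_surface_base + config.soc_surface_per_ai * ai
    zs = config.soc_efold_depth

    def control(z):
        return soc0 * np.exp(-np.asarray(z, float) / zs)

    if position == "control":
        return control
    scale = 1.0 + delta / 100.0
    if position == "fill":
        amp = config.fill_bump_rel * soc0
        zc, w = config.fill_bump_center, config.fill_bump_width

        def fill(z):
            z = np.asarray(z, float)
            return control(z) * scale + amp * np.exp(-0.5 * ((z - zc) / w) ** 2)

        return fill
    if position == "cut":
        lo, hi = config.ai_range
        frac = np.clip((ai - lo) / (hi - lo), 0.0, 1.0)
        dep = config.cut_depletion_arid + frac * (config.cut_depletion_humid
                                                  - config.cut_depletion_arid)

        def cut(z):
            z = np.asarray(z, float)
            return control(z) * scale * (1.0 - dep * np.exp(-z / 15.0))

        return cut
    raise ValueError(f"unknown position {position!r}")


def true_density_function(ai: float, config: WorldConfig, position: str = "control",
                          delta: float = 0.0):
    """Noise-free SOC density (kg C m^-2 cm^-1) depth curve.

    Combines the SOC depth curve with the generator's true pedotransfer
    bulk density at the site's (noise-free) texture.
    """
    soc_f = soc_depth_function(ai, config, position, delta)
    clay = 16.0 + 5.0 * ai
    silt = 36.0
    a, b, c, d = config.bd_coefs

    def density(z):
        soc = soc_f(z)
        bd = a * soc + b * clay + c * silt + d
        return soc / 100.0 * bd * 10.0

    return density


def _texture(ai: float, n: int, rng: np.random.Generator, noise: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    clay = 16.0 + 5.0 * ai + rng.normal(0.0, 8.0 * noise, n)
    silt = 36.0 + rng.normal(0.0, 8.0 * noise, n)
    clay = np.clip(clay, 2.0, 60.0)
    silt = np.clip(silt, 5.0, 70.0)
    sand = 100.0 - clay - silt
    return clay, silt, sand


def generate_profiles(site: Mapping, config: WorldConfig,
                      rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Generate all horizons for one site (cut, fill and control profiles)."""
    if config.depth_max <= 0:
        raise ValueError("depth_max must be > 0")
    rng = as_rng(rng)
    ai = float(site["ai"])
    delta = float(site.get("true_delta_soc", 0.0)) if hasattr(site, "get") else float(site["true_delta_soc"])
    site_id = site["site_id"]

    edges = np.arange(0.0, config.depth_max + config.layer_thickness / 2,
                      config.layer_thickness)
    tops, bots = edges[:-1], edges[1:]
    mids = 0.5 * (tops + bots)
    n_hz = len(mids)

    lo, hi = config.ai_range
    wetness = np.clip((ai - 0.8) / 0.4, 0.0, 1.0)  # 0 at arid end, 1 humid
    a_ox = 1.5 + 4.5 * wetness  # ligand-exchange weight on respiration
    a_cat = 5.5 - 4.5 * wetness  # cation-bridging weight
    site_spr_intercept = rng.normal(0.0, 2.0)

    rows = []
    for position in ("cut", "fill", "control"):
        soc_f = soc_depth_function(ai, config, position, delta)
        for rep in range(config.n_profiles_per_position):
            profile_effect = rng.normal(0.0, config.profile_corr_sd) if config.profile_corr_sd > 0 else 0.0
            soc = soc_f(mids) * np.exp(
                rng.normal(0.0, config.soc_noise_sd, n_hz)
                - config.soc_noise_sd**2 / 2 + profile_effect)
            soc = np.maximum(soc, 0.0)
            clay, silt, sand = _texture(ai, n_hz, rng, config.geochem_noise_sd)

            # latent per-sample signals shared between covariates and SPR
            u = {k: rng.normal(0.0, 1.0, n_hz) for k in ("ox", "cat", "chem")}

            geo: dict[str, np.ndarray] = {}
            s = config.geochem_noise_sd
            for name, (base, slope, latent, w) in COVARIATE_TRENDS.items():
                trend = max(base + slope * (ai - 1.0), 0.01)
                shared = w * u[latent] + np.sqrt(1.0 - w**2) * rng.normal(0.0, 1.0, n_hz)
                vals = trend * np.exp(s * shared - s**2 / 2)
                if name == "pH":
                    vals = np.clip(vals, 3.5, 9.0)
                if name == "Fe_d_Fe_t":
                    vals = np.clip(vals, 0.02, 0.98)
                geo[name] = vals

            spr = (15.0 + a_ox * u["ox"] + a_cat * u["cat"]
                   - 4.0 * mids / config.depth_max + site_spr_intercept
                   + rng.normal(0.0, 2.0, n_hz))
            spr = np.maximum(spr, 0.1)

            posl = (150.0 + 2600.0 * mids / config.depth_max) * np.exp(
                rng.normal(0.0, 0.1, n_hz))

            a, b, c, d = config.bd_coefs
            bd_true = a * soc + b * clay + c * silt + d
            bd_meas = bd_true + rng.normal(0.0, config.bd_noise_sd, n_hz)
            bd_meas = np.clip(bd_meas, 0.3, 2.2)

            df = pd.DataFrame({
                "site_id": site_id,
                "profile_id": f"{site_id}-{position}-{rep + 1}",
                "position": position,
                "depth_top": tops,
                "depth_bottom": bots,
                "soc": soc,
                "clay": clay,
                "silt": silt,
                "sand": sand,
                "gravel_mass_frac": rng.uniform(0.0, 8.0, n_hz),
                "bd_measured": bd_meas,
                "spr": spr,
                "posl": posl,
                "ai": ai,
            })
            for name, vals in geo.items():
                df[name] = vals
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Gridded product
# ---------------------------------------------------------------------------

def generate_gridded_estimates(true_control_deltas: Sequence[float],
                               bias: BiasParams,
                               n_pixels: int,
                               seed: int | np.random.Generator | None = None,
                               pixel_sd: float = 8.0,
                               site_ids: Sequence[str] | None = None,
                               total_stocks: Sequence[float] | None = None) -> GriddedEstimates:
    """Gridded ΔSOC means/SEs plus layered control stock profiles per site.

    The gridded truth for each site is the inverse-bias image of the field
    truth plus noise, constructed as the linear projection conditional so
    that ``field = alpha + beta * gridded + N(0, sigma)`` holds by
    construction with the residual uncorrelated with the gridded value
    (hence an OLS regression of field on gridded recovers alpha, beta and
    sigma).  Observed pixel values scatter around the gridded truth with
    independent pixel noise, and the reported SE is the pixel SD over
    ``sqrt(n_pixels)``.
    """
    if n_pixels < 2:
        raise ValueError("n_pixels must be >= 2")
    if pixel_sd < 0:
        raise ValueError("pixel_sd must be >= 0")
    rng = as_rng(seed)
    truth = np.asarray(true_control_deltas, dtype=float)
    n = len(truth)
    if site_ids is None:
        site_ids = [f"S{i + 1:02d}" for i in range(n)]

    v_t = truth.var(ddof=1) if n > 1 else 0.0
    if bias.sigma == 0 or n < 3 or v_t <= bias.sigma**2:
        # not enough truth spread to embed the residual noise: fall back to
        # the deterministic inverse image
        gridded_true = (truth - bias.alpha) / bias.beta
    else:
        m_t = truth.mean()
        tau2 = (v_t - bias.sigma**2) / bias.beta**2
        mu_g = (m_t - bias.alpha) / bias.beta
        cond_mean = mu_g + bias.beta * tau2 * (truth - m_t) / v_t
        cond_sd = np.sqrt(tau2 * bias.sigma**2 / v_t)
        gridded_true = cond_mean + rng.normal(0.0, cond_sd, n)
    pixels = gridded_true[:, None] + rng.normal(0.0, pixel_sd, (n, n_pixels))
    mean = pixels.mean(axis=1)
    se = pixels.std(axis=1, ddof=1) / np.sqrt(n_pixels)

    deltas = pd.DataFrame({
        "site_id": list(site_ids),
        "delta_mean": mean,
        "delta_se": se,
        "n_pixels": n_pixels,
        "gridded_truth": gridded_true,
    })

    if total_stocks is None:
        total_stocks = 12.0 * np.exp(rng.normal(0.0, 0.25, n))
    total_stocks = np.asarray(total_stocks, dtype=float)

    from .stocks import GRIDDED_SCHEMAS  # local import to avoid cycle at import time

    zs = 40.0  # e-folding depth of the gridded stock density, cm
    layer_rows = []
    for i, sid in enumerate(site_ids):
        for schema, bounds in GRIDDED_SCHEMAS.items():
            bounds = np.asarray(bounds)
            cdf = 1.0 - np.exp(-bounds / zs)
            frac = np.diff(cdf) / cdf[-1]
            stocks = total_stocks[i] * frac
            for t, b, s in zip(bounds[:-1], bounds[1:], stocks):
                layer_rows.append({
                    "site_id": sid, "schema": schema,
                    "layer_top": float(t), "layer_bottom": float(b),
                    "stock": float(s), "total_stock": float(stocks.sum()),
                })
    return GriddedEstimates(deltas=deltas, layers=pd.DataFrame(layer_rows))


# ---------------------------------------------------------------------------
# FTIR spectra
# ---------------------------------------------------------------------------

def generate_spectra(band_amplitudes: Sequence[Mapping[str, float]],
                     baseline_params: tuple[float, ...] = (0.05, 0.0),
                     seed: int | np.random.Generator | None = None,
                     wavenumbers: np.ndarray | None = None,
                     noise_sd: float = 0.0,
                     sample_ids: Sequence[str] | None = None,
                     peaks: Mapping[str, tuple[float, float]] | None = None) -> tuple[list[Spectrum], pd.DataFrame]:
    """Reflectance spectra with Gaussian peaks at the interpretation bands.

    ``band_amplitudes`` is one mapping per sample from band name
    (``aliph_1``, ``aliph_2``, ``acid``, ``arom``) to peak amplitude in
    absorbance units.  ``baseline_params`` are polynomial coefficients
    (constant, linear, [quadratic]) in units of 1000 cm^-1 relative to
    500 cm^-1.  ``peaks`` overrides the default band placement
    (name -> (center, Gaussian SD)).  Returns the spectra plus a tidy
    ground-truth table of analytic band heights above baseline at each band
    center.
    """
    rng = as_rng(seed)
    peaks = dict(DEFAULT_PEAKS) if peaks is None else {**DEFAULT_PEAKS, **peaks}
    if wavenumbers is None:
        wavenumbers = np.arange(500.0, 4000.0 + 1e-9, 4.0)
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    if np.any(np.diff(wavenumbers) <= 0):
        raise ValueError("wavenumber grid must be strictly increasing")

    x = (wavenumbers - 500.0) / 1000.0
    baseline = np.zeros_like(wavenumbers)
    for p, coef in enumerate(baseline_params):
        baseline = baseline + coef * x**p

    spectra: list[Spectrum] = []
    truth_rows = []
    for i, amps in enumerate(band_amplitudes):
        sid = sample_ids[i] if sample_ids is not None else f"sample{i + 1}"
        absorb = baseline.copy()
        for name, amp in amps.items():
            if amp < 0:
                raise ValueError(f"band amplitude for {name!r} must be >= 0")
            center, width = peaks[name]
            absorb = absorb + amp * np.exp(-0.5 * ((wavenumbers - center) / width) ** 2)
        if noise_sd > 0:
            absorb = absorb + rng.normal(0.0, noise_sd, len(wavenumbers))
        absorb = np.maximum(absorb, 0.0)
        reflect = np.power(10.0, -absorb)
        spectra.append(Spectrum(wavenumbers=wavenumbers.copy(), values=reflect,
                                mode="reflectance", sample_id=sid))
        row = {"sample_id": sid}
        for name in peaks:
            center, _ = peaks[name]
            # analytic Gaussian-sum height above the baseline at the center
            h = sum(a * np.exp(-0.5 * ((center - peaks[b][0]) / peaks[b][1]) ** 2)
                    for b, a in amps.items())
            row[f"true_height_{name}"] = float(h)
        truth_rows.append(row)
    return spectra, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Phenology
# ---------------------------------------------------------------------------

def generate_phenology(season: tuple[int, int] = (100, 280),
                       seed: int | np.random.Generator | None = None,
                       base: float = 0.05,
                       amplitude: float = 1.0,
                       scale: float = 1.0,
                       noise_sd: float = 0.0,
                       n_days: int = 365) -> tuple[pd.DataFrame, float]:
    """Daily plant-phenology-index series with a known season integral.

    The seasonal curve is ``scale * (base + amplitude * sin^2(pi * t))``
    inside the growing season (t the season fraction) and ``scale * base``
    outside; the returned truth is the noise-free daily sum over the season
    (the definition of total plant productivity, TPP).
    """
    start, end = season
    if not (0 <= start < end < n_days):
        raise ValueError("season must satisfy 0 <= start < end < n_days")
    rng = as_rng(seed)
    days = np.arange(n_days)
    ppi = np.full(n_days, base, dtype=float)
    in_season = (days >= start) & (days <= end)
    t = (days[in_season] - start) / (end - start)
    ppi[in_season] = base + amplitude * np.sin(np.pi * t) ** 2
    ppi *= scale
    true_tpp = float(ppi[in_season].sum())
    if noise_sd > 0:
        ppi = np.maximum(ppi + rng.normal(0.0, noise_sd, n_days), 0.0)
    series = pd.DataFrame({"day": days, "ppi": ppi,
                           "season_start": start, "season_end": end})
    return series, true_tpp


# ---------------------------------------------------------------------------
# Literature synthesis records
# ---------------------------------------------------------------------------

def generate_synthesis_records(n: int,
                               seed: int | np.random.Generator | None = None,
                               flag_probs: Mapping[str, float] | None = None,
                               ai_range: tuple[float, float] = (0.25, 2.5),
                               delta_model: DeltaSocModel | None = None) -> pd.DataFrame:
    """Paired terraced/control SOC records emulating a literature synthesis.

    ``flag_probs`` gives independent probabilities for each exclusion
    condition: ``missing_control``, ``young`` (terrace age < 1 yr),
    ``paddy``, ``fluvial_gravel``, ``desert``.  All default to 0 (clean
    records).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(seed)
    probs = {"missing_control": 0.0, "young": 0.0, "paddy": 0.0,
             "fluvial_gravel": 0.0, "desert": 0.0}
    if flag_probs:
        unknown = set(flag_probs) - set(probs)
        if unknown:
            raise ValueError(f"unknown flags: {sorted(unknown)}")
        probs.update(flag_probs)
    dm = delta_model or DeltaSocModel()

    ai = rng.uniform(*ai_range, n)
    pet = 1450.0 - 330.0 * np.clip(ai, 0.2, 2.5)
    soc_control = 8.0 * np.exp(rng.normal(0.0, 0.4, n))
    delta = dm.intercept + dm.slope * ai + rng.normal(0.0, dm.site_sd, n)
    delta = np.maximum(delta, -95.0)
    soc_terraced = soc_control * (1.0 + delta / 100.0)

    young = rng.random(n) < probs["young"]
    age = np.where(young, rng.uniform(0.0, 1.0, n),
                   np.exp(rng.normal(3.5, 1.0, n)) + 1.0)
    soil_types = rng.choice(["Cambisol", "Luvisol", "Vertisol", "Podzol", "Umbrisol"], n)

    df = pd.DataFrame({
        "study_id": [f"study{i + 1:03d}" for i in range(n)],
        "soc_terraced": soc_terraced,
        "soc_control": soc_control,
        "depth": rng.uniform(20.0, 100.0, n).round(0),
        "ai": ai,
        "map": ai * pet,
        "pet": pet,
        "mat": rng.uniform(4.0, 19.0, n),
        "soil_type": soil_types,
        "terrace_age": age,
        "paddy": rng.random(n) < probs["paddy"],
        "fluvial_gravel": rng.random(n) < probs["fluvial_gravel"],
        "desert": rng.random(n) < probs["desert"],
        "true_delta_soc": delta,
    })
    missing = rng.random(n) < probs["missing_control"]
    df.loc[missing, "soc_control"] = np.nan
    return df


# ---------------------------------------------------------------------------
# Whole world
# ---------------------------------------------------------------------------

def generate_world(config: WorldConfig, n_synthesis: int = 99) -> World:
    """Generate the full synthetic study from one seed."""
    seeds = spawn_seeds(config.seed, 6)
    sites = generate_sites(config, as_rng(seeds[0]))

    prof_rng = as_rng(seeds[1])
    horizons = pd.concat(
        [generate_profiles(row, config, prof_rng) for _, row in sites.iterrows()],
        ignore_index=True)

    gridded = generate_gridded_estimates(
        sites["true_delta_soc"].to_numpy(), config.bias, config.n_pixels,
        as_rng(seeds[2]), pixel_sd=config.pixel_sd,
        site_ids=sites["site_id"].tolist())

    spec_rng = as_rng(seeds[3])
    amps = []
    for ai in sites["ai"]:
        jitter = np.exp(spec_rng.normal(0.0, 0.1, 4))
        amps.append({
            "aliph_1": max(0.25 + 0.05 * ai, 0.02) * jitter[0],
            "aliph_2": max(0.12 + 0.02 * ai, 0.02) * jitter[1],
            "acid": 0.40 * jitter[2],
            "arom": max(0.45 - 0.10 * (ai - 1.0), 0.05) * jitter[3],
        })
    spectra, spectra_truth = generate_spectra(
        amps, baseline_params=(0.05, 0.01), seed=spec_rng,
        sample_ids=sites["site_id"].tolist())

    phen_rng = as_rng(seeds[4])
    phen_frames, truth_rows = [], []
    for _, row in sites.iterrows():
        dtpp = phen_rng.normal(31.0, 12.0)  # terracing productivity gain, %
        for treatment, scale in (("control", 1.0), ("terraced", 1.0 + dtpp / 100.0)):
            series, true_tpp = generate_phenology(
                seed=phen_rng, amplitude=0.5 + 0.4 * row["ai"], scale=scale,
                noise_sd=0.02)
            series.insert(0, "treatment", treatment)
            series.insert(0, "site_id", row["site_id"])
            phen_frames.append(series)
            truth_rows.append({"site_id": row["site_id"], "treatment": treatment,
                               "true_tpp": true_tpp, "true_delta_tpp": dtpp})
    phenology = pd.concat(phen_frames, ignore_index=True)
    phenology_truth = pd.DataFrame(truth_rows)

    synthesis = generate_synthesis_records(
        n_synthesis, as_rng(seeds[5]),
        flag_probs={"missing_control": 0.05, "young": 0.03, "paddy": 0.05,
                    "fluvial_gravel": 0.03, "desert": 0.02})

    truth = {
        "seed": config.seed,
        "bias": {"alpha": config.bias.alpha, "beta": config.bias.beta,
                 "sigma": config.bias.sigma},
        "delta_soc_model": {"slope": config.delta_soc_model.slope,
                            "intercept": config.delta_soc_model.intercept,
                            "site_sd": config.delta_soc_model.site_sd},
        "true_site_deltas": dict(zip(sites["site_id"], sites["true_delta_soc"])),
    }
    return World(config=config, sites=sites, horizons=horizons, gridded=gridded,
                 spectra=spectra, spectra_truth=spectra_truth, phenology=phenology,
                 phenology_truth=phenology_truth, synthesis=synthesis, truth=truth)


def write_world(world: World, outdir: str | Path) -> dict[str, Path]:
    """Write the world as tidy CSV tables plus a truth.json sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p

    _write("sites", world.sites)
    _write("horizons", world.horizons)
    _write("gridded", world.gridded.deltas)
    _write("gridded_layers", world.gridded.layers)
    spec_long = pd.concat([
        pd.DataFrame({"sample_id": s.sample_id, "wavenumber": s.wavenumbers,
                      "value": s.values})
        for s in world.spectra], ignore_index=True)
    _write("spectra", spec_long)
    _write("spectra_truth", world.spectra_truth)
    _write("phenology", world.phenology)
    _write("phenology_truth", world.phenology_truth)
    _write("synthesis", world.synthesis)

    tp = outdir / "truth.json"
    with open(tp, "w") as fh:
        json.dump(world.truth, fh, indent=2, default=float)
    paths["truth"] = tp
    return paths
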