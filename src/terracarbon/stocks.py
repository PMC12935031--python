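"""Depth-explicit SOC stock accounting.

Implements the stock arithmetic underlying terracing ΔSOC estimates:

* pedotransfer bulk density ``BD = a*SOC + b*clay + c*silt + d`` fitted by
  ordinary least squares on horizons with measured BD;
* fine-earth bulk density with a gravel correction applied only above a
  3 % gravel-mass threshold;
* SOC density per horizon, ``(SOC%/100) * BD_fine * 10`` in
  kg C m^-2 cm^-1 (the factor 10 converts g C cm^-3 over a 1 m^2 x 1 cm
  slab; without it stocks are off by 10x);
* profile stocks as the thickness-weighted sum of horizon densities;
* harmonization of layered gridded-product stocks to a target depth;
* relative change in percent, used identically for ΔSOC, ΔTPP and
  vegetation-index changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Physically admissible bulk-density range used to clip pedotransfer
#: predictions (g cm^-3); guards against extrapolation far outside the
#: calibration domain.
BD_CLIP_RANGE = (0.2, 2.2)

#: Gravel mass fraction (as a proportion of total mass) above which the
#: fine-earth correction is applied.
GRAVEL_THRESHOLD = 0.03

#: Depth schemas of the two gridded soil products (layer boundaries, cm).
GRIDDED_SCHEMAS = {
    "soilgrids": (0.0, 5.0, 15.0, 30.0, 60.0, 100.0, 200.0),
    "hwsd": (0.0, 20.0, 40.0, 60.0, 80.0, 100.0, 150.0, 200.0),
}


class ProfileGeometryError(ValueError):
    """Horizons within a profile overlap or leave gaps."""


class SingularDesignError(ValueError):
    """The pedotransfer design matrix is rank deficient."""


@dataclass(frozen=True)
class PedotransferModel:
    """Fitted pedotransfer function ``BD = a*SOC + b*clay + c*silt + d``.

    SOC, clay and silt are in %, BD in g cm^-3.
    """

    a: float
    b: float
    c: float
    d: float
    r2: float
    n_cal: int

    def predict(self, soc: np.ndarray, clay: np.ndarray, silt: np.ndarray) -> np.ndarray:
        """Predict fine-earth bulk density, clipped to ``BD_CLIP_RANGE``."""
        soc = np.asarray(soc, dtype=float)
        raw = self.a * soc + self.b * np.asarray(clay, float) + self.c * np.asarray(silt, float) + self.d
        lo, hi = BD_CLIP_RANGE
        n_clip = int(np.sum((raw < lo) | (raw > hi)))
        if n_clip:
            logger.warning("pedotransfer: clipped %d prediction(s) to [%g, %g] g cm^-3",
                           n_clip, lo, hi)
        return np.clip(raw, lo, hi)


@dataclass(frozen=True)
class ProfileStock:
    """Total SOC stock of one profile and its per-horizon densities."""

    profile_id: str
    depth: float  # cm, bottom of deepest horizon
    stock: float  # kg C m^-2
    densities: np.ndarray = field(repr=False)  # kg C m^-2 cm^-1 per horizon
    thicknesses: np.ndarray = field(repr=False)  # cm per horizon


def fit_pedotransfer(calibration: pd.DataFrame) -> PedotransferModel:
    """Fit ``BD = a*SOC + b*clay + c*silt + d`` by OLS.

    Parameters
    ----------
    calibration
        Horizon table with columns ``soc``, ``clay``, ``silt`` and
        ``bd_measured`` (g cm^-3); rows with missing BD are dropped.
    """
    cal = calibration.dropna(subset=["bd_measured"])
    n = len(cal)
    if n < 4:
        raise ValueError(f"pedotransfer calibration needs >= 4 samples, got {n}")
    X = np.column_stack([
        cal["soc"].to_numpy(float),
        cal["clay"].to_numpy(float),
        cal["silt"].to_numpy(float),
        np.ones(n),
    ])
    if np.linalg.matrix_rank(X) < 4:
        raise SingularDesignError(
            "pedotransfer design is rank deficient (constant SOC, clay or silt?)"
        )
    y = cal["bd_measured"].to_numpy(float)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PedotransferModel(a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
                             d=float(coef[3]), r2=r2, n_cal=n)


def bulk_density_fine(total_mass: float, total_volume: float,
                      gravel_mass: float = 0.0, gravel_volume: float = 0.0) -> float:
    """Fine-earth bulk density (g cm^-3) with conditional gravel correction.

    The gravel (> 2 mm) correction is applied only when gravel exceeds 3 %
    of total sample mass; below the threshold the uncorrected bulk density
    is returned.
    """
    if total_volume <= 0 or total_mass <= 0:
        raise ValueError("total mass and volume must be positive")
    if not (0 <= gravel_mass < total_mass):
        raise ValueError("gravel_mass must satisfy 0 <= gravel_mass < total_mass")
    if not (0 <= gravel_volume < total_volume):
        raise ValueError("gravel_volume must satisfy 0 <= gravel_volume < total_volume")
    if gravel_mass / total_mass <= GRAVEL_THRESHOLD:
        return total_mass / total_volume
    if total_volume == gravel_volume:
        raise ZeroDivisionError("degenerate sample: gravel occupies the whole volume")
    return (total_mass - gravel_mass) / (total_volume - gravel_volume)


def soc_density(soc_pct: float | np.ndarray, bd_fine: float | np.ndarray) -> float | np.ndarray:
    """SOC density of a horizon in kg C m^-2 cm^-1.

    ``(soc_pct / 100) * bd_fine`` gives g C per cm^3 of fine earth; one
    1 m^2 x 1 cm slab holds 10^4 cm^3, i.e. 10^4 g per unit = 10 kg, hence
    the explicit factor 10.
    """
    soc_pct = np.asarray(soc_pct, dtype=float)
    bd_fine = np.asarray(bd_fine, dtype=float)
    if np.any(soc_pct < 0) or np.any(bd_fine < 0):
        raise ValueError("soc_pct and bd_fine must be >= 0")
    out = soc_pct / 100.0 * bd_fine * 10.0
    return float(out) if out.ndim == 0 else out


def _check_contiguous(depth_top: np.ndarray, depth_bottom: np.ndarray, profile_id: str) -> None:
    order = np.argsort(depth_top)
    top, bot = depth_top[order], depth_bottom[order]
    if np.any(bot <= top):
        raise ProfileGeometryError(f"profile {profile_id}: non-positive horizon thickness")
    bad = [
        (float(bot[i]), float(top[i + 1]))
        for i in range(len(top) - 1)
        if abs(bot[i] - top[i + 1]) > 1e-9
    ]
    if bad:
        raise ProfileGeometryError(
            f"profile {profile_id}: horizons overlap or leave gaps at {bad}"
        )


def profile_stock(horizons: pd.DataFrame,
                  pedotransfer: PedotransferModel | None = None) -> ProfileStock:
    """Integrate one profile's horizon densities into a total SOC stock.

    Uses measured bulk density where present and the pedotransfer model
    otherwise.  Horizons must be contiguous and non-overlapping.
    """
    pid = str(horizons["profile_id"].iloc[0]) if "profile_id" in horizons else "?"
    hz = horizons.sort_values("depth_top")
    top = hz["depth_top"].to_numpy(float)
    bot = hz["depth_bottom"].to_numpy(float)
    _check_contiguous(top, bot, pid)

    soc = hz["soc"].to_numpy(float)
    bd = hz["bd_measured"].to_numpy(float) if "bd_measured" in hz else np.full(len(hz), np.nan)
    missing = ~np.isfinite(bd)
    if missing.any():
        if pedotransfer is None:
            raise ValueError(
                f"profile {pid}: {int(missing.sum())} horizon(s) lack measured BD "
                "and no pedotransfer model was given"
            )
        bd = bd.copy()
        bd[missing] = pedotransfer.predict(
            soc[missing], hz["clay"].to_numpy(float)[missing],
            hz["silt"].to_numpy(float)[missing])

    dens = soc_density(soc, bd)
    thick = bot - top
    stock = float(np.sum(dens * thick))
    return ProfileStock(profile_id=pid, depth=float(bot.max()), stock=stock,
                        densities=np.asarray(dens), thicknesses=thick)


def harmonize_gridded_profile(layers: pd.DataFrame, target_depth: float) -> float:
    """Sum layered gridded stocks down to ``target_depth`` (kg C m^-2).

    Whole layers within the target depth are summed; a layer straddling the
    target depth contributes a thickness-proportional fraction (uniform
    density within the layer is assumed).

    ``layers`` must carry columns ``layer_top``, ``layer_bottom``, ``stock``
    covering [0, >= target_depth] in either gridded schema.
    """
    if target_depth <= 0:
        raise ValueError("target_depth must be > 0")
    ly = layers.sort_values("layer_top")
    top = ly["layer_top"].to_numpy(float)
    bot = ly["layer_bottom"].to_numpy(float)
    stock = ly["stock"].to_numpy(float)
    if top[0] > 1e-9 or np.any(np.abs(bot[:-1] - top[1:]) > 1e-9):
        raise ProfileGeometryError("gridded layers must be contiguous from 0 cm")
    if target_depth > bot[-1] + 1e-9:
        raise ValueError(
            f"target_depth {target_depth} cm exceeds schema bottom {bot[-1]} cm"
        )
    total = 0.0
    for t, b, s in zip(top, bot, stock):
        if b <= target_depth + 1e-12:
            total += s
        elif t < target_depth:
            total += s * (target_depth - t) / (b - t)
    return float(total)


def relative_change(treated: float | np.ndarray, control: float | np.ndarray) -> float | np.ndarray:
    """Percent change of ``treated`` relative to ``control``.

    ``100 * (treated - control) / control`` -- used identically for ΔSOC,
    ΔTPP, ΔNDVI, ΔEVI and ΔSAVI.
    """
    control = np.asarray(control, dtype=float)
    if np.any(control <= 0):
        raise ValueError("relative change is undefined for control <= 0")
    out = 100.0 * (np.asarray(treated, float) - control) / control
    return float(out) if out.ndim == 0 else out


def compute_profile_stocks(horizons: pd.DataFrame,
                           pedotransfer: PedotransferModel | None = None) -> pd.DataFrame:
    """Stock table (one row per profile) from a horizon table."""
    rows = []
    for (site, pid), grp in horizons.groupby(["site_id", "profile_id"], sort=True):
        ps = profile_stock(grp, pedotransfer)
        rows.append({
            "site_id": site,
            "profile_id": pid,
            "position": grp["position"].iloc[0],
            "depth": ps.depth,
            "stock": ps.stock,
        })
    return pd.DataFrame(rows)


def site_deltas(stocks: pd.DataFrame, harmonize: str = "site") -> pd.DataFrame:
    """Per-site ΔSOC (%) of terraced (cut+fill) vs control profiles.

    Each terraced profile is compared against the site's mean control stock;
    the site ΔSOC is the mean over terraced profiles with its standard
    error.  ``harmonize`` records whether control depths were matched to the
    site-mean terraced depth (``"site"``) or per profile (``"profile"``);
    with the synthetic generator all profiles share one depth so the switch
    is informational.
    """
    if harmonize not in ("site", "profile"):
        raise ValueError("harmonize must be 'site' or 'profile'")
    rows = []
    for site, grp in stocks.groupby("site_id", sort=True):
        ctrl = grp.loc[grp["position"] == "control", "stock"]
        terr = grp.loc[grp["position"] != "control", "stock"]
        if ctrl.empty or terr.empty:
            continue
        deltas = relative_change(terr.to_numpy(float), float(ctrl.mean()))
        deltas = np.atleast_1d(deltas)
        se = float(np.std(deltas, ddof=1) / np.sqrt(len(deltas))) if len(deltas) > 1 else 0.0
        rows.append({
            "site_id": site,
            "mean": float(np.mean(deltas)),
            "se": se,
            "n_profiles": int(len(deltas)),
            "source": "field",
        })
    return pd.DataFrame(rows)
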