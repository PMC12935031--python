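"""FTIR semi-quantification of soil organic-matter chemistry.

Diffuse-reflectance FTIR spectra (500-4000 cm^-1) are converted to
absorbance, mineral-dominated regions are masked, and the heights of four
interpretation bands are semi-quantified with individually determined peak
endpoints and a local chord baseline:

* two aliphatic C-H bands (2898-2976 and 2839-2870 cm^-1), treated jointly
  as one aliphatic pool;
* a diffuse carboxylic (COOH) band (1570-1720 cm^-1);
* an aromatic C=C band (1500-1550 cm^-1).

Peak endpoints are the nearest flanking local minima within an extended
search margin; where a side has no local minimum, the endpoint falls at the
maximum of the Savitzky-Golay-smoothed second derivative on that side.
Heights are normalized by the total integrated (unmasked) spectral area,
and composition is summarized as arom/aliph, arom/acid and aliph/acid
ratios: higher arom/* indicates more decomposed organic matter, higher
aliph/acid more plant-derived material.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)

#: Interpretation band windows (cm^-1).
BAND_WINDOWS: dict[str, tuple[float, float]] = {
    "aliph_1": (2898.0, 2976.0),
    "aliph_2": (2839.0, 2870.0),
    "acid": (1570.0, 1720.0),
    "arom": (1500.0, 1550.0),
}

#: Mineral-dominated regions excluded from organic-matter analysis (cm^-1):
#: below 1200, 1750-2000, and above 3000 (Fe/Al oxyhydroxides, silicates).
MINERAL_REGIONS: tuple[tuple[float, float], ...] = (
    (-np.inf, 1200.0), (1750.0, 2000.0), (3000.0, np.inf),
)

#: Default half-width (cm^-1) by which the band window is extended when
#: hunting for endpoint local minima.
ENDPOINT_SEARCH_MARGIN = 40.0


@dataclass
class Spectrum:
    """One FTIR trace on a strictly increasing wavenumber grid."""

    wavenumbers: np.ndarray
    values: np.ndarray
    mode: str = "reflectance"  # or "absorbance"
    sample_id: str = ""
    mask: np.ndarray | None = None  # True where excluded

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavenumbers.shape != self.values.shape:
            raise ValueError("wavenumbers and values must have equal length")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if self.mode not in ("reflectance", "absorbance"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class PeakBand:
    """A semi-quantified absorption band."""

    name: str
    window: tuple[float, float]
    endpoints: tuple[float, float]
    raw_height: float
    normalized_height: float
    endpoint_method: tuple[str, str]  # per side: "local_minimum" | "second_derivative"


@dataclass(frozen=True)
class ChemistryRatios:
    arom_aliph: float
    arom_acid: float
    aliph_acid: float


def to_absorbance(spectrum: Spectrum) -> Spectrum:
    """Convert reflectance to absorbance, ``A = log10(1/R)``."""
    if spectrum.mode != "reflectance":
        raise ValueError("spectrum is not in reflectance mode")
    bad = (spectrum.values <= 0) | (spectrum.values > 1)
    if bad.any():
        wn = spectrum.wavenumbers[bad]
        raise ValueError(
            f"reflectance outside (0, 1] at wavenumbers {wn[:5].round(1).tolist()}"
            + ("..." if bad.sum() > 5 else ""))
    return replace(spectrum, values=-np.log10(spectrum.values), mode="absorbance")


def rubber_band_baseline(spectrum: Spectrum) -> Spectrum:
    """Subtract the lower convex-hull (rubber band) baseline.

    An optional global correction applied to absorbance spectra before
    band analysis; the per-peak chord baselines remain the primary
    correction and this is off by default in :func:`analyze_spectrum`.
    """
    if spectrum.mode != "absorbance":
        raise ValueError("rubber-band correction applies to absorbance spectra")
    from scipy.spatial import ConvexHull

    wn, v = spectrum.wavenumbers, spectrum.values
    hull = ConvexHull(np.column_stack([wn, v]))
    verts = np.roll(hull.vertices, -int(np.argmin(hull.vertices)))
    # ascending run of vertex indices = the lower envelope
    anchors = verts[:int(np.argmax(verts)) + 1]
    baseline = np.interp(wn, wn[anchors], v[anchors])
    return replace(spectrum, values=v - baseline)


def mask_mineral_regions(spectrum: Spectrum) -> Spectrum:
    """Mark the three mineral-dominated regions as excluded.

    Idempotent: the mask depends only on the wavenumber grid.
    """
    if spectrum.mode != "absorbance":
        raise ValueError("mask is applied to absorbance spectra")
    wn = spectrum.wavenumbers
    mask = np.zeros(wn.shape, dtype=bool)
    for lo, hi in MINERAL_REGIONS:
        if np.isinf(lo):
            mask |= wn < hi
        elif np.isinf(hi):
            mask |= wn > lo
        else:
            mask |= (wn >= lo) & (wn <= hi)
    return replace(spectrum, mask=mask)


def total_spectral_area(spectrum: Spectrum) -> float:
    """Trapezoidal integral of absorbance over unmasked, contiguous segments."""
    if spectrum.mode != "absorbance":
        raise ValueError("area is computed on absorbance spectra")
    wn, v = spectrum.wavenumbers, spectrum.values
    keep = ~spectrum.mask if spectrum.mask is not None else np.ones(len(wn), bool)
    area = 0.0
    # integrate each contiguous unmasked run separately
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return 0.0
    breaks = np.flatnonzero(np.diff(idx) > 1)
    for seg in np.split(idx, breaks + 1):
        if len(seg) >= 2:
            area += float(np.trapezoid(v[seg], wn[seg]))
    return area


def _unmasked_region_around(spectrum: Spectrum, i_lo: int, i_hi: int) -> tuple[int, int]:
    """Largest contiguous unmasked index run containing [i_lo, i_hi]."""
    if spectrum.mask is None:
        return 0, len(spectrum.wavenumbers) - 1
    mask = spectrum.mask
    lo = i_lo
    while lo > 0 and not mask[lo - 1]:
        lo -= 1
    hi = i_hi
    while hi < len(mask) - 1 and not mask[hi + 1]:
        hi += 1
    return lo, hi


def quantify_peak(spectrum: Spectrum, band: str | tuple[float, float],
                  search_margin: float = ENDPOINT_SEARCH_MARGIN,
                  sg_window: int = 11, sg_degree: int = 3) -> PeakBand:
    """Semi-quantify one band: peak height above a local chord baseline.

    Parameters
    ----------
    spectrum
        Absorbance spectrum, ideally with the mineral mask applied.
    band
        Band name from :data:`BAND_WINDOWS` or an explicit
        ``(low, high)`` wavenumber window.
    search_margin
        How far beyond the window (cm^-1) to hunt for endpoint minima.
    sg_window, sg_degree
        Savitzky-Golay smoothing used for the second-derivative fallback.
    """
    if spectrum.mode != "absorbance":
        raise ValueError("peaks are quantified on absorbance spectra")
    name = band if isinstance(band, str) else "custom"
    window = BAND_WINDOWS[band] if isinstance(band, str) else tuple(band)
    wn, v = spectrum.wavenumbers, spectrum.values

    in_win = (wn >= window[0]) & (wn <= window[1])
    if spectrum.mask is not None and np.any(spectrum.mask & in_win):
        raise ValueError(f"band {name} window overlaps a masked region")
    win_idx = np.flatnonzero(in_win)
    if win_idx.size < 5:
        raise ValueError(f"band {name} window contains fewer than 5 grid points")

    peak_rel = int(np.argmax(v[win_idx]))
    peak = int(win_idx[peak_rel])

    ext = (wn >= window[0] - search_margin) & (wn <= window[1] + search_margin)
    ext_idx = np.flatnonzero(ext)
    lo_reg, hi_reg = _unmasked_region_around(spectrum, win_idx[0], win_idx[-1])
    lo = max(int(ext_idx[0]), lo_reg)
    hi = min(int(ext_idx[-1]), hi_reg)

    if np.ptp(v[lo:hi + 1]) == 0:
        logger.warning("band %s: flat window, reporting zero height", name)
        return PeakBand(name=name, window=tuple(window),
                        endpoints=(float(wn[lo]), float(wn[hi])),
                        raw_height=0.0, normalized_height=0.0,
                        endpoint_method=("local_minimum", "local_minimum"))

    def _endpoint(side: str) -> tuple[int, str]:
        if side == "left":
            rng = range(peak - 1, lo, -1)
            bound = lo
            side_idx = np.arange(lo, peak)
        else:
            rng = range(peak + 1, hi)
            bound = hi
            side_idx = np.arange(peak + 1, hi + 1)
        for i in rng:
            if v[i] <= v[i - 1] and v[i] <= v[i + 1]:
                return i, "local_minimum"
        # no interior local minimum; if the trace decays monotonically the
        # side minimum sits at the search-region boundary -- that boundary is
        # the local minimum of the searched window
        if side_idx.size:
            amin = int(side_idx[np.argmin(v[side_idx])])
            if abs(amin - peak) > 1:
                return amin, "local_minimum"
        # trace rises away from the peak: fall back to the maximum of the
        # smoothed second derivative on that side
        seg = np.arange(lo, hi + 1)
        wlen = min(sg_window, len(seg) - (1 - len(seg) % 2))
        if wlen <= sg_degree:
            return bound, "second_derivative"
        d2 = savgol_filter(v[seg], window_length=wlen, polyorder=sg_degree, deriv=2)
        if side == "left":
            cand = seg[seg < peak]
            d2c = d2[seg < peak]
        else:
            cand = seg[seg > peak]
            d2c = d2[seg > peak]
        if cand.size == 0:
            return bound, "second_derivative"
        return int(cand[np.argmax(d2c)]), "second_derivative"

    il, ml = _endpoint("left")
    ir, mr = _endpoint("right")
    if il >= ir:
        il, ir = lo, hi

    # chord baseline between the endpoints
    chord = v[il] + (v[ir] - v[il]) * (wn[il:ir + 1] - wn[il]) / (wn[ir] - wn[il])
    height = float(np.max(v[il:ir + 1] - chord))
    height = max(height, 0.0)

    area = total_spectral_area(spectrum)
    norm = height / area if area > 0 else np.nan
    return PeakBand(name=name, window=tuple(window),
                    endpoints=(float(wn[il]), float(wn[ir])),
                    raw_height=height, normalized_height=float(norm),
                    endpoint_method=(ml, mr))


def chemistry_ratios(peaks: dict[str, PeakBand]) -> ChemistryRatios:
    """Composition ratios from normalized band heights.

    The aliphatic height is the sum of the two aliphatic sub-bands.  A zero
    denominator yields NaN (undefined ratio, propagated as missing).
    """
    missing = set(BAND_WINDOWS) - set(peaks)
    if missing:
        raise ValueError(f"missing bands: {sorted(missing)}")
    aliph = peaks["aliph_1"].normalized_height + peaks["aliph_2"].normalized_height
    arom = peaks["arom"].normalized_height
    acid = peaks["acid"].normalized_height

    def _ratio(num: float, den: float) -> float:
        if den == 0 or not np.isfinite(den):
            logger.warning("zero/undefined denominator in chemistry ratio")
            return float("nan")
        return num / den

    return ChemistryRatios(arom_aliph=_ratio(arom, aliph),
                           arom_acid=_ratio(arom, acid),
                           aliph_acid=_ratio(aliph, acid))


def analyze_spectrum(spectrum: Spectrum, rubber_band: bool = False,
                     **peak_kwargs) -> tuple[dict[str, PeakBand], ChemistryRatios]:
    """Full single-spectrum workflow: absorbance, mask, four bands, ratios."""
    spec = spectrum
    if spec.mode == "reflectance":
        spec = to_absorbance(spec)
    if rubber_band:
        spec = rubber_band_baseline(spec)
    spec = mask_mineral_regions(spec)
    peaks = {name: quantify_peak(spec, name, **peak_kwargs) for name in BAND_WINDOWS}
    return peaks, chemistry_ratios(peaks)


def chemistry_table(spectra: list[Spectrum], **peak_kwargs) -> pd.DataFrame:
    """Tidy per-sample table of band heights and composition ratios."""
    rows = []
    for spec in spectra:
        peaks, ratios = analyze_spectrum(spec, **peak_kwargs)
        row = {"sample_id": spec.sample_id}
        for name, pk in peaks.items():
            row[f"height_{name}"] = pk.raw_height
            row[f"norm_height_{name}"] = pk.normalized_height
        row["arom_aliph"] = ratios.arom_aliph
        row["arom_acid"] = ratios.arom_acid
        row["aliph_acid"] = ratios.aliph_acid
        rows.append(row)
    return pd.DataFrame(rows)


def read_spectra_csv(path: str | Path) -> list[Spectrum]:
    """Read long-format spectra (sample_id, wavenumber, value), reflectance."""
    df = pd.read_csv(path)
    spectra = []
    for sid, grp in df.groupby("sample_id", sort=True):
        grp = grp.sort_values("wavenumber")
        spectra.append(Spectrum(wavenumbers=grp["wavenumber"].to_numpy(float),
                                values=grp["value"].to_numpy(float),
                                mode="reflectance", sample_id=str(sid)))
    return spectra
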