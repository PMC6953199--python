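"""Bioclimatic trait construction: photoperiod model and trait correlations.

Daylength follows the CBM model (Forsythe et al. 1995): day-of-year J gives a
revolution angle, then solar declination, then daylength from the sunrise
hour angle. The daylength coefficient p (degrees) sets the horizon definition:
p = 0 is the geometric sunrise/sunset, p = 0.8333 the apparent (refracted)
sunrise/sunset used for civil daylength tables.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

__all__ = ["daylength", "annual_max_daylength", "mdl", "trait_correlations"]

logger = logging.getLogger(__name__)

DEFAULT_COEFFICIENT = 0.8333  # degrees; apparent sunrise/sunset


def daylength(latitude: float, day_of_year, coefficient: float = DEFAULT_COEFFICIENT):
    """Hours of daylight at a latitude (degrees N) for day(s) of year 1-365.

    theta = 0.2163108 + 2 atan(0.9671396 tan(0.00860 (J - 186)))
    delta = asin(0.39795 cos theta)          (solar declination, radians)
    D = 24 - (24/pi) acos[(sin(p deg) + sin(lat) sin(delta)) /
                          (cos(lat) cos(delta))]

    The acos argument is clamped to [-1, 1] (polar day/night); clamping is
    logged at debug level.
    """
    lat = float(latitude)
    if not math.isfinite(lat):
        raise ValueError("latitude must be finite")
    j = np.asarray(day_of_year, dtype=float)
    if not np.all(np.isfinite(j)):
        raise ValueError("day_of_year must be finite")
    theta = 0.2163108 + 2.0 * np.arctan(0.9671396 * np.tan(0.00860 * (j - 186.0)))
    delta = np.arcsin(0.39795 * np.cos(theta))
    lat_rad = math.radians(lat)
    p_rad = math.radians(coefficient)
    num = math.sin(p_rad) + math.sin(lat_rad) * np.sin(delta)
    den = math.cos(lat_rad) * np.cos(delta)
    arg = num / den
    clipped = np.clip(arg, -1.0, 1.0)
    n_clamped = int(np.sum(arg != clipped))
    if n_clamped:
        logger.debug("daylength: clamped acos argument at %d day(s)", n_clamped)
    d = 24.0 - (24.0 / math.pi) * np.arccos(clipped)
    return float(d) if np.isscalar(day_of_year) else d


def annual_max_daylength(latitude: float, coefficient: float = DEFAULT_COEFFICIENT) -> float:
    """Maximum daylength over days 1-365."""
    return float(np.max(daylength(latitude, np.arange(1, 366), coefficient)))


def mdl(
    latitude: float,
    sowing_doy: int,
    harvest_doy: int,
    coefficient: float = DEFAULT_COEFFICIENT,
) -> float:
    """Maximum daylength (h) over the sowing-to-harvest window.

    The window wraps past day 365 when harvest precedes sowing in the
    calendar (autumn sowing).
    """
    sowing_doy = int(sowing_doy)
    harvest_doy = int(harvest_doy)
    for d in (sowing_doy, harvest_doy):
        if not 1 <= d <= 365:
            raise ValueError("day-of-year must lie in 1..365")
    if harvest_doy >= sowing_doy:
        days = np.arange(sowing_doy, harvest_doy + 1)
    else:
        days = np.concatenate(
            [np.arange(sowing_doy, 366), np.arange(1, harvest_doy + 1)]
        )
    return float(np.max(daylength(latitude, days, coefficient)))


def trait_correlations(
    traits: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations among trait columns.

    Returns (r matrix, n matrix) where n counts complete pairs; pairs with
    fewer than 3 complete observations get NaN and are flagged by n.
    """
    if columns is None:
        columns = [c for c in traits.columns if c != "sample_id"]
    k = len(columns)
    r = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            x = traits[columns[i]].to_numpy(float)
            y = traits[columns[j]].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            n[i, j] = n[j, i] = int(ok.sum())
            if n[i, j] < 3:
                continue
            xi, yi = x[ok], y[ok]
            if np.std(xi) == 0 or np.std(yi) == 0:
                continue
            r[i, j] = r[j, i] = float(np.corrcoef(xi, yi)[0, 1])
    np.fill_diagonal(r, 1.0)
    rdf = pd.DataFrame(r, index=columns, columns=columns)
    ndf = pd.DataFrame(n, index=columns, columns=columns)
    return rdf, ndf
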