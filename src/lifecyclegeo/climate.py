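"""BIOCLIM-style climate summaries and interannual variability metrics.

The pipeline characterizes each region by quarterly climate extremes
(BIOCLIM convention: a "quarter" is any three consecutive calendar months,
with December wrapping into January), by between-year variability of
precipitation (IPV, a coefficient of variation) and temperature (ITV, a
standard deviation), and by a median-aggregated human-footprint score.

Array conventions
-----------------
Monthly climatologies have the month axis first: shape ``(12, ...)``.
Multi-year cubes have shape ``(n_years, 12, ...)``. Trailing axes index
pixels and are preserved by every function, so grids may be passed either
flattened or as ``(rows, cols)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: BIOCLIM variables produced by :func:`quarterly_bioclim`. The driver models
#: need bio1, bio8-bio11, bio12 and bio16-bio19; bio2-7 and 13-15 describe
#: within-year structure the models do not use and are not computed.
BIOCLIM_VARS = ("bio1", "bio8", "bio9", "bio10", "bio11", "bio12", "bio16", "bio17", "bio18", "bio19")


def _window_stats(temp: np.ndarray, prec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean temperature and precipitation total of the 12 wrapped 3-month windows.

    Returns arrays of shape ``(12, ...)`` where index s is the window starting
    at calendar month s (0-based).
    """
    t2 = np.concatenate([temp, temp[:2]], axis=0)
    p2 = np.concatenate([prec, prec[:2]], axis=0)
    win_t = np.stack([t2[s : s + 3].mean(axis=0) for s in range(12)], axis=0)
    win_p = np.stack([p2[s : s + 3].sum(axis=0) for s in range(12)], axis=0)
    return win_t, win_p


def quarterly_bioclim(temp: np.ndarray, prec: np.ndarray) -> dict[str, np.ndarray]:
    """Per-pixel quarterly BIOCLIM variables from a 12-month climatology.

    Quarters are the 12 moving 3-calendar-month windows (December wraps to
    January). Warmest/coldest quarters maximize/minimize the window mean
    temperature; wettest/driest maximize/minimize the window precipitation
    total. Ties are broken toward the earliest starting month.

    Parameters
    ----------
    temp, prec:
        Monthly mean temperature (degC) and precipitation (mm), shape (12, ...).

    Returns
    -------
    dict mapping variable name (see :data:`BIOCLIM_VARS`) to an array with
    the trailing shape of the inputs. Pixels with any missing month are NaN
    in every output.
    """
    temp = np.asarray(temp, dtype=float)
    prec = np.asarray(prec, dtype=float)
    if temp.shape[0] != 12 or prec.shape[0] != 12:
        raise ValueError("expected 12 monthly layers on the first axis")
    if temp.shape != prec.shape:
        raise ValueError("temperature and precipitation shapes differ")

    mask = np.isnan(temp).any(axis=0) | np.isnan(prec).any(axis=0)
    # argmax/argmin propagate badly through NaN; compute on filled copies and
    # re-mask at the end.
    t = np.where(np.isnan(temp), 0.0, temp)
    p = np.where(np.isnan(prec), 0.0, prec)
    win_t, win_p = _window_stats(t, p)

    warmest = np.argmax(win_t, axis=0)
    coldest = np.argmin(win_t, axis=0)
    wettest = np.argmax(win_p, axis=0)
    driest = np.argmin(win_p, axis=0)

    def pick(arr: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.take_along_axis(arr, idx[None, ...], axis=0)[0]

    out = {
        "bio1": t.mean(axis=0),
        "bio8": pick(win_t, wettest),
        "bio9": pick(win_t, driest),
        "bio10": pick(win_t, warmest),
        "bio11": pick(win_t, coldest),
        "bio12": p.sum(axis=0),
        "bio16": pick(win_p, wettest),
        "bio17": pick(win_p, driest),
        "bio18": pick(win_p, warmest),
        "bio19": pick(win_p, coldest),
    }
    for key, val in out.items():
        out[key] = np.where(mask, np.nan, val)
    return out


def climatology(cube: np.ndarray) -> np.ndarray:
    """Multi-year monthly normals: mean over the year axis of a (years, 12, ...) cube."""
    cube = np.asarray(cube, dtype=float)
    if cube.ndim < 2 or cube.shape[1] != 12:
        raise ValueError("expected cube of shape (n_years, 12, ...)")
    return cube.mean(axis=0)


def interannual_variability(temp_cube: np.ndarray, prec_cube: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel IPV and ITV from multi-year monthly cubes.

    IPV is the coefficient of variation (sample s.d. over mean, ddof=1) of
    yearly precipitation totals; ITV is the sample s.d. of yearly mean
    temperatures. Both measure variability *between* years, unlike the
    within-year seasonality BIOCLIM variables. Pixels whose mean yearly
    precipitation is zero have undefined IPV and are returned NaN.

    Returns ``(ipv, itv)`` with the cubes' trailing shape.
    """
    temp_cube = np.asarray(temp_cube, dtype=float)
    prec_cube = np.asarray(prec_cube, dtype=float)
    for cube in (temp_cube, prec_cube):
        if cube.ndim < 2 or cube.shape[1] != 12:
            raise ValueError("expected cubes of shape (n_years, 12, ...)")
    if temp_cube.shape[0] < 2:
        raise ValueError("need at least 2 years for variability metrics")

    yearly_p = prec_cube.sum(axis=1)  # (years, ...)
    yearly_t = temp_cube.mean(axis=1)
    mean_p = yearly_p.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ipv = yearly_p.std(axis=0, ddof=1) / mean_p
    ipv = np.where(mean_p > 0, ipv, np.nan)
    itv = yearly_t.std(axis=0, ddof=1)
    return ipv, itv


def aggregate_region(values: np.ndarray, region_of_pixel: np.ndarray) -> pd.Series:
    """Median of per-pixel values within each region.

    NaN pixels (masked) are ignored; a region whose pixels are all masked
    gets NaN and is later dropped from model fits. ``region_of_pixel`` holds
    a region id per pixel; id -1 marks pixels outside every region.
    """
    vals = np.asarray(values, dtype=float).ravel()
    regions = np.asarray(region_of_pixel).ravel()
    if vals.shape != regions.shape:
        raise ValueError("values and region index shapes differ")
    df = pd.DataFrame({"region": regions, "value": vals})
    df = df[df["region"] != -1]
    out = df.groupby("region")["value"].median()
    out.index.name = "region"
    return out


def region_climate_table(
    temp_cube: np.ndarray,
    prec_cube: np.ndarray,
    region_of_pixel: np.ndarray,
    footprint: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the per-region predictor table.

    BIOCLIM variables are computed on the multi-year climatology, IPV/ITV on
    the full cubes, each per pixel, then median-aggregated within regions
    (the regional grain of every predictor in the driver models).

    Returns a DataFrame indexed by region id with columns bio1, bio8-bio11,
    bio12, bio16-bio19, ipv, itv and (when supplied) footprint.
    """
    temp_clim = climatology(temp_cube)
    prec_clim = climatology(prec_cube)
    bio = quarterly_bioclim(temp_clim, prec_clim)
    ipv, itv = interannual_variability(temp_cube, prec_cube)

    cols = {name: aggregate_region(arr, region_of_pixel) for name, arr in bio.items()}
    cols["ipv"] = aggregate_region(ipv, region_of_pixel)
    cols["itv"] = aggregate_region(itv, region_of_pixel)
    if footprint is not None:
        cols["footprint"] = aggregate_region(footprint, region_of_pixel)
    return pd.DataFrame(cols)
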