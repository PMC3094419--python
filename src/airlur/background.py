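"""Regional background concentration from rural sites.

The large-area model enters the regional background a priori: for each
urban/traffic site it is the inverse-distance-weighted mean of the annual
means measured at rural background sites within 50 km (rural sites just
outside the study border take part, precisely to avoid border effects);
rural sites themselves use their own measured mean.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

BACKGROUND_COLUMN = "background_no2"


class NoRuralSiteInRange(RuntimeError):
    pass


def idw_background(
    point: tuple[float, float],
    rural_xy: np.ndarray,
    rural_conc: np.ndarray,
    radius: float = 50_000.0,
    power: float = 1.0,
    d_clamp: float = 1.0,
) -> float:
    """Inverse-distance-weighted mean of rural concentrations within radius.

    Weights are d^(-power), normalised; distances below ``d_clamp`` metres
    are clamped so a coincident rural site dominates without a singularity.
    Raises :class:`NoRuralSiteInRange` when no rural site lies within the
    radius (the caller may widen it).
    """
    rural_xy = np.asarray(rural_xy, dtype=float)
    rural_conc = np.asarray(rural_conc, dtype=float)
    d = np.hypot(rural_xy[:, 0] - point[0], rural_xy[:, 1] - point[1])
    ok = d <= radius
    if not ok.any():
        raise NoRuralSiteInRange(f"no rural site within {radius} m of {point}")
    d = np.maximum(d[ok], d_clamp)
    w = d ** (-power)
    w = w / w.sum()
    return float(np.dot(w, rural_conc[ok]))


def idw_weights(
    point: tuple[float, float],
    rural_xy: np.ndarray,
    radius: float = 50_000.0,
    power: float = 1.0,
    d_clamp: float = 1.0,
) -> np.ndarray:
    """Normalised weights (zero outside the radius); sums to 1."""
    rural_xy = np.asarray(rural_xy, dtype=float)
    d = np.hypot(rural_xy[:, 0] - point[0], rural_xy[:, 1] - point[1])
    w = np.zeros(len(d))
    ok = d <= radius
    if not ok.any():
        raise NoRuralSiteInRange(f"no rural site within {radius} m of {point}")
    w[ok] = np.maximum(d[ok], d_clamp) ** (-power)
    return w / w.sum()


def assign_background(
    sites: pd.DataFrame,
    table: pd.DataFrame,
    rural_means: Mapping[str, float],
    radius: float = 50_000.0,
    power: float = 1.0,
) -> pd.DataFrame:
    """Add the ``background_no2`` column to a predictor table.

    ``rural_means`` maps rural / rural_external site ids to their measured
    annual mean. Urban and traffic sites receive the IDW value over those
    sites; a rural site present in the table receives its own mean.
    """
    rural = sites[sites["site_type"].isin(["rural", "rural_external"])]
    rural = rural[rural["site_id"].isin(rural_means.keys())]
    if rural.empty:
        raise NoRuralSiteInRange("no rural site with a measured mean")
    rural_xy = rural[["x", "y"]].to_numpy(float)
    rural_conc = np.array([rural_means[sid] for sid in rural["site_id"]])

    out = table.copy()
    values = {}
    for _, site in sites.iterrows():
        sid = site["site_id"]
        if sid not in out.index:
            continue
        if site["site_type"] in ("rural", "rural_external") and sid in rural_means:
            values[sid] = float(rural_means[sid])
        else:
            values[sid] = idw_background(
                (float(site["x"]), float(site["y"])), rural_xy, rural_conc, radius, power
            )
    out[BACKGROUND_COLUMN] = pd.Series(values)
    if out[BACKGROUND_COLUMN].isna().any():
        missing = out.index[out[BACKGROUND_COLUMN].isna()].tolist()
        raise ValueError(f"sites without coordinates in the site table: {missing}")
    return out
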