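"""Per-site covariates: reef slope from depth transects, chlorophyll-a from
masked satellite pixel boxes.

Reef slope is the angle of the single least-squares line through depth
versus cumulative along-track (haversine) distance for a transect run
perpendicular to the reef, reported as negative degrees (descending
offshore).  Site chlorophyll-a is the mean and sd of the unmasked pixels of
a 3×3 box centred on the site, after removing every pixel inshore of the
30 m isobath (shallow-water contamination such as bottom reflectance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EARTH_RADIUS_M",
    "haversine_distance",
    "SlopeEstimate",
    "estimate_reef_slope",
    "apply_depth_mask",
    "ChlBox",
    "summarize_chl_box",
    "MissingCovariateError",
    "site_covariates_table",
]

EARTH_RADIUS_M = 6_371_000.0

#: hand-held transponder depth limit; deeper readings are unreliable and dropped
TRANSPONDER_MAX_DEPTH_M = 70.0


class MissingCovariateError(ValueError):
    """Raised when a site covariate cannot be computed (e.g. fully masked box)."""


def haversine_distance(p1, p2) -> float:
    """Great-circle distance in metres between (lat, lon) points in degrees."""
    lat1, lon1 = float(p1[0]), float(p1[1])
    lat2, lon2 = float(p2[0]), float(p2[1])
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if abs(lat) > 90 or abs(lon) > 180:
            raise ValueError(f"invalid coordinates ({lat}, {lon})")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a)))


@dataclass
class SlopeEstimate:
    """Reef slope angle for one site (negative = descending offshore)."""

    site_id: str
    slope_deg: float
    r2: float
    n: int


def estimate_reef_slope(readings: pd.DataFrame, site_id: str = "",
                        max_depth: float = TRANSPONDER_MAX_DEPTH_M) -> SlopeEstimate:
    """OLS slope of depth against cumulative along-track distance.

    ``readings`` must carry lat, lon, depth_m columns in transect order.
    Readings deeper than ``max_depth`` (transponder limit) are dropped first.
    The angle is −arctan(depth gain per metre), in degrees, so offshore-
    descending transects give values in (−90, 0].
    """
    for col in ("lat", "lon", "depth_m"):
        if col not in readings.columns:
            raise KeyError(f"transect table lacks column {col!r}")
    sub = readings[readings["depth_m"] <= max_depth].reset_index(drop=True)
    if len(sub) < 3:
        raise ValueError("need at least 3 usable readings for a slope estimate")
    pts = sub[["lat", "lon"]].to_numpy()
    seg = np.array([haversine_distance(pts[i], pts[i + 1]) for i in range(len(pts) - 1)])
    dist = np.concatenate([[0.0], np.cumsum(seg)])
    if dist[-1] <= 0:
        raise ValueError("degenerate transect: all readings at the same position")
    depth = sub["depth_m"].to_numpy(dtype=float)
    ss_tot = float(np.sum((depth - depth.mean()) ** 2))
    if ss_tot == 0:
        # flat profile: slope 0 by definition, r2 undefined
        return SlopeEstimate(site_id, 0.0, np.nan, len(sub))
    res = stats.linregress(dist, depth)
    slope_deg = -float(np.degrees(np.arctan(res.slope)))
    return SlopeEstimate(site_id, slope_deg, float(res.rvalue ** 2), len(sub))


def apply_depth_mask(values: np.ndarray, bathymetry: np.ndarray,
                     threshold: float = 30.0) -> np.ma.MaskedArray:
    """Mask pixels inshore of the depth ``threshold`` isobath.

    Pixels whose bathymetric depth is strictly shallower than the threshold
    are excluded (boundary pixels at exactly the threshold are kept).
    """
    values = np.asarray(values, dtype=float)
    bathymetry = np.asarray(bathymetry, dtype=float)
    if values.shape != bathymetry.shape:
        raise ValueError(
            f"grid shapes differ: values {values.shape} vs bathymetry {bathymetry.shape}"
        )
    prior = np.ma.getmaskarray(np.ma.asarray(values))
    return np.ma.masked_array(values, mask=prior | (bathymetry < threshold))


@dataclass
class ChlBox:
    """3×3 chlorophyll-a pixel box around a site, with exclusion mask."""

    site_id: str
    values: np.ndarray   # mg m^-3
    masked: np.ndarray   # boolean, True = excluded


def summarize_chl_box(box: ChlBox):
    """Mean and sample sd (ddof=1) of the unmasked pixels of a site box.

    Returns (chl_mean, chl_sd, n_valid); sd is NaN when only one pixel
    survives masking.  Raises :class:`MissingCovariateError` when every
    pixel is masked.
    """
    vals = np.asarray(box.values, dtype=float)
    mask = np.asarray(box.masked, dtype=bool)
    if vals.shape != mask.shape:
        raise ValueError("values and mask shapes differ")
    keep = vals[~mask]
    keep = keep[np.isfinite(keep)]
    n = len(keep)
    if n == 0:
        raise MissingCovariateError(f"site {box.site_id}: all pixels masked")
    mean = float(keep.mean())
    sd = float(keep.std(ddof=1)) if n > 1 else float("nan")
    return mean, sd, n


def site_covariates_table(transects: Optional[pd.DataFrame] = None,
                          chl_boxes: Optional[list] = None,
                          slopes: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Assemble the per-site covariate table (site_id, slope_deg, slope_r2,
    chl_mean, chl_sd, chl_n).

    Either raw ``transects`` (site_id, lat, lon, depth_m; slope estimated per
    site) or a precomputed ``slopes`` table may be given.  ``chl_boxes`` is a
    list of :class:`ChlBox`.  Sites where a covariate cannot be derived get
    NaN (they are dropped later at model time, with a log entry).
    """
    slope_rows = []
    if slopes is not None:
        slope_df = slopes.copy()
    elif transects is not None:
        for site, sub in transects.groupby("site_id", observed=True):
            try:
                est = estimate_reef_slope(sub, site_id=site)
                slope_rows.append({"site_id": site, "slope_deg": est.slope_deg,
                                   "slope_r2": est.r2})
            except ValueError:
                slope_rows.append({"site_id": site, "slope_deg": np.nan,
                                   "slope_r2": np.nan})
        slope_df = pd.DataFrame(slope_rows)
    else:
        slope_df = pd.DataFrame(columns=["site_id", "slope_deg", "slope_r2"])
    chl_rows = []
    for box in chl_boxes or []:
        try:
            mean, sd, n = summarize_chl_box(box)
        except MissingCovariateError:
            mean, sd, n = np.nan, np.nan, 0
        chl_rows.append({"site_id": box.site_id, "chl_mean": mean,
                         "chl_sd": sd, "chl_n": n})
    chl_df = pd.DataFrame(chl_rows) if chl_rows else pd.DataFrame(
        columns=["site_id", "chl_mean", "chl_sd", "chl_n"])
    out = pd.merge(slope_df, chl_df, on="site_id", how="outer")
    return out.sort_values("site_id").reset_index(drop=True)
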