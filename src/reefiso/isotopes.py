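"""Stable-isotope processing: delta notation, C:N condition proxy, lipid correction.

Raw mass-spectrometer output is a heavy/light isotope ratio; values are
reported in delta notation (per mil deviation from a reference standard:
V-PDB for carbon, atmospheric N₂ for nitrogen).  Tissue C:N (mass-percent
ratio) is a lipid-content proxy; muscle δ¹³C is arithmetically corrected
for lipid depletion whenever C:N exceeds 3.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InvalidMeasurementError",
    "compute_delta",
    "compute_cn_ratio",
    "lipid_normalize_d13c",
    "aggregate_site_depth",
    "read_tissue_table",
    "write_tissue_table",
    "read_baseline_table",
    "process_tissue_table",
]

#: C:N mass ratio above which muscle δ¹³C is lipid-corrected (strict inequality).
CN_LIPID_THRESHOLD = 3.5

#: Molar-ratio conversion: (C:N molar) = (C:N mass) × (14.007 / 12.011).
_MASS_TO_MOLAR = 14.007 / 12.011

TISSUE_COLUMNS = [
    "fish_id",
    "site_id",
    "atoll",
    "depth",
    "fl_mm",
    "tl_mm",
    "d13c",
    "d15n",
    "pct_c",
    "pct_n",
    "cn",
]

BASELINE_COLUMNS = ["kind", "site_id", "replicate", "d13c", "d15n"]


class InvalidMeasurementError(ValueError):
    """Raised for physically impossible isotope inputs (non-positive ratios etc.)."""


def compute_delta(r_sample, r_standard):
    """Per-mil delta value δX = ((R_sample / R_standard) − 1) × 1000.

    Parameters
    ----------
    r_sample : float or array
        Heavy/light isotope ratio of the sample. Must be > 0.
    r_standard : float or array
        Heavy/light isotope ratio of the reference standard. Must be > 0.

    Returns
    -------
    float or ndarray
        Delta value in per mil (‰).
    """
    r_sample = np.asarray(r_sample, dtype=float)
    r_standard = np.asarray(r_standard, dtype=float)
    if np.any(r_sample <= 0) or np.any(r_standard <= 0):
        raise InvalidMeasurementError("isotope ratios must be strictly positive")
    out = (r_sample / r_standard - 1.0) * 1000.0
    return out if out.ndim else float(out)


def delta_to_ratio(delta, r_standard):
    """Invert delta notation: R_sample = R_standard × (1 + δ/1000)."""
    return np.asarray(r_standard, dtype=float) * (1.0 + np.asarray(delta, dtype=float) / 1000.0)


def compute_cn_ratio(pct_c, pct_n, molar: bool = False):
    """Tissue carbon-to-nitrogen ratio from percent dry weight.

    The condition proxy is the mass-percent ratio; set ``molar=True`` for the
    molar ratio (mass ratio × 14.007/12.011).
    """
    pct_c = np.asarray(pct_c, dtype=float)
    pct_n = np.asarray(pct_n, dtype=float)
    if np.any(pct_n <= 0):
        raise InvalidMeasurementError("percent nitrogen must be strictly positive")
    if np.any(pct_c < 0):
        raise InvalidMeasurementError("percent carbon must be non-negative")
    out = pct_c / pct_n
    if molar:
        out = out * _MASS_TO_MOLAR
    return out if out.ndim else float(out)


def lipid_normalize_d13c(d13c, cn, threshold: float = CN_LIPID_THRESHOLD):
    """Lipid-correct δ¹³C for high tissue lipid content.

    When C:N > ``threshold`` (strictly), applies

        δ¹³C_normalized = δ¹³C_untreated − 3.32 + 0.99 × C:N

    otherwise returns δ¹³C unchanged.

    Returns
    -------
    (value, corrected) : tuple
        The (possibly corrected) per-mil value and a boolean flag (or boolean
        array) recording whether the correction was applied.
    """
    d13c = np.asarray(d13c, dtype=float)
    cn = np.asarray(cn, dtype=float)
    if np.any(cn <= 0):
        raise InvalidMeasurementError("C:N ratio must be strictly positive")
    corrected = cn > threshold
    out = np.where(corrected, d13c - 3.32 + 0.99 * cn, d13c)
    if out.ndim == 0:
        return float(out), bool(corrected)
    return out, corrected


def aggregate_site_depth(samples: pd.DataFrame, response: str) -> pd.DataFrame:
    """Mean, n and sd of a per-fish response per observed (site, depth) cell.

    The hypothesis models are fitted at site-depth level; this is the
    aggregation that takes the per-fish tissue table down to one row per
    sampled cell.  Cells with no samples are simply absent (never zero-filled).

    Parameters
    ----------
    samples : DataFrame
        Must carry ``site_id`` and ``depth`` columns plus the response column.
    response : str
        Column to aggregate (e.g. ``d15n``, ``d13c_normalized``, ``cn``).
    """
    required = {"site_id", "depth", response}
    missing = required - set(samples.columns)
    if missing:
        raise KeyError(f"missing columns: {sorted(missing)}")
    if len(samples) == 0:
        return pd.DataFrame(columns=["site_id", "depth", "mean", "n", "sd"])
    sub = samples.dropna(subset=[response])
    grouped = sub.groupby(["site_id", "depth"], observed=True)[response]
    out = grouped.agg(mean="mean", n="size", sd="std").reset_index()
    return out


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_tissue_table(path) -> pd.DataFrame:
    """Read a per-fish tissue CSV (fish_id, site_id, atoll, depth, fl_mm,
    tl_mm, d13c, d15n, pct_c, pct_n, cn)."""
    df = pd.read_csv(path)
    missing = {"fish_id", "site_id", "atoll", "depth", "d13c", "d15n"} - set(df.columns)
    if missing:
        raise ValueError(f"tissue table {path} missing columns {sorted(missing)}")
    return df


def write_tissue_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_baseline_table(path) -> pd.DataFrame:
    """Read a POM/zooplankton baseline CSV (kind, site_id, replicate, d13c, d15n)."""
    df = pd.read_csv(path)
    missing = {"kind", "d13c", "d15n"} - set(df.columns)
    if missing:
        raise ValueError(f"baseline table {path} missing columns {sorted(missing)}")
    bad = set(df["kind"].unique()) - {"POM", "zooplankton"}
    if bad:
        raise ValueError(f"unknown baseline kinds: {sorted(bad)}")
    return df


def process_tissue_table(df: pd.DataFrame, cn_tol: float = 0.01) -> pd.DataFrame:
    """Derive C:N and lipid-normalized δ¹³C columns on a tissue table.

    A supplied ``cn`` column is accepted even when %C/%N are absent; when both
    percentages are present the ratio is recomputed and a consistency warning
    is emitted if it disagrees with a supplied value by more than ``cn_tol``.
    Adds ``cn`` (if derivable), ``d13c_normalized`` and ``lipid_corrected``.
    """
    df = df.copy()
    has_pct = "pct_c" in df.columns and "pct_n" in df.columns
    if has_pct:
        valid = df["pct_n"].notna() & (df["pct_n"] > 0) & df["pct_c"].notna()
        recomputed = pd.Series(np.nan, index=df.index, dtype=float)
        recomputed[valid] = df.loc[valid, "pct_c"] / df.loc[valid, "pct_n"]
        if "cn" in df.columns:
            both = valid & df["cn"].notna()
            diff = (recomputed[both] - df.loc[both, "cn"]).abs()
            n_bad = int((diff > cn_tol).sum())
            if n_bad:
                warnings.warn(
                    f"{n_bad} samples have supplied C:N inconsistent with %C/%N "
                    f"by more than {cn_tol}",
                    stacklevel=2,
                )
            df["cn"] = df["cn"].where(df["cn"].notna(), recomputed)
        else:
            df["cn"] = recomputed
    elif "cn" not in df.columns:
        raise ValueError("need either a cn column or both pct_c and pct_n")
    ok = df["cn"].notna() & df["d13c"].notna()
    norm = pd.Series(np.nan, index=df.index, dtype=float)
    flag = pd.Series(False, index=df.index)
    if ok.any():
        vals, corr = lipid_normalize_d13c(df.loc[ok, "d13c"].to_numpy(), df.loc[ok, "cn"].to_numpy())
        norm[ok] = vals
        flag[ok] = corr
    df["d13c_normalized"] = norm
    df["lipid_corrected"] = flag
    return df
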