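"""Otolith ageing QC, von Bertalanffy growth fitting and Kmax standardization.

Ages come from otolith increment counts: annual band counts are accepted
when two independent counts agree (a third read resolves disagreements);
daily-increment ages are the mean of three counts, with the whole sample
excluded when any count deviates from the median by more than 10% of the
median.  Length-at-age per site-depth cell is fitted with the von
Bertalanffy growth function

    L_t = L∞ · [1 − e^(−k(t−t₀))]

and the curvature coefficient k is standardized to the species' maximum
reported size via K_max = k · (L_max/L∞)^{s_L} (default s_L = −2, the
classical growth-performance slope), enabling growth-rate comparison across
cells that differ in asymptotic size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "AgeResult",
    "resolve_age",
    "VonBertalanffyModel",
    "VBGFResults",
    "fit_vbgf",
    "predict_length",
    "KmaxResult",
    "compute_kmax",
    "age_fish_table",
    "fit_site_depth_growth",
]

DAYS_PER_YEAR = 365.0


@dataclass
class AgeResult:
    """Outcome of the ageing decision rule for one otolith."""

    fish_id: str
    age: Optional[float]  # years; None when excluded
    method: str
    excluded: bool
    reason: str = ""


def resolve_age(fish_id: str, method: str, counts: Sequence[int]) -> AgeResult:
    """Apply the ageing quality-control rules to a set of increment counts.

    annuli
        Two counts that agree fix the age.  If the first two disagree a third
        count must be present; the age is the value shared by any two counts,
        and the fish is excluded when no two counts agree.
    daily_increments
        Exactly three counts.  If any count deviates from the median by more
        than 10% of the median the whole sample is excluded; otherwise the
        age is the mean of the three counts divided by 365.
    """
    counts = list(counts)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if method == "annuli":
        if len(counts) < 2:
            raise ValueError("annuli ageing requires at least two counts")
        if counts[0] == counts[1]:
            return AgeResult(fish_id, float(counts[0]), method, excluded=False)
        if len(counts) < 3:
            return AgeResult(fish_id, None, method, excluded=True,
                             reason="first two counts disagree and no third count")
        for i in range(len(counts)):
            for j in range(i + 1, len(counts)):
                if counts[i] == counts[j]:
                    return AgeResult(fish_id, float(counts[i]), method, excluded=False)
        return AgeResult(fish_id, None, method, excluded=True,
                         reason="no two counts agree")
    if method == "daily_increments":
        if len(counts) != 3:
            raise ValueError("daily-increment ageing requires exactly three counts")
        med = float(np.median(counts))
        if med == 0 or any(abs(c - med) > 0.10 * med for c in counts):
            return AgeResult(fish_id, None, method, excluded=True,
                             reason="count outside 10% of median")
        return AgeResult(fish_id, float(np.mean(counts)) / DAYS_PER_YEAR, method,
                         excluded=False)
    raise ValueError(f"unknown ageing method {method!r}")


def age_fish_table(otoliths: pd.DataFrame) -> pd.DataFrame:
    """Vector version of :func:`resolve_age` over an otolith-count table.

    Expects columns ``fish_id``, ``method`` and ``count1..count3`` (count3
    optional/NaN for two-read annuli).  Returns fish_id, age (years),
    excluded flag and reason.
    """
    rows = []
    for rec in otoliths.itertuples(index=False):
        counts = [int(c) for c in (rec.count1, rec.count2, getattr(rec, "count3", np.nan))
                  if pd.notna(c)]
        res = resolve_age(rec.fish_id, rec.method, counts)
        rows.append({"fish_id": res.fish_id, "age": res.age,
                     "excluded": res.excluded, "reason": res.reason})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# von Bertalanffy growth


def vbgf(age, l_inf, k, t0):
    """Von Bertalanffy length-at-age, L_t = L∞(1 − exp(−k(t−t₀)))."""
    return l_inf * (1.0 - np.exp(-k * (np.asarray(age, dtype=float) - t0)))


@dataclass
class VBGFResults:
    """Fitted von Bertalanffy parameters for one site-depth cell."""

    l_inf: float  # asymptotic fork length, cm
    k: float      # curvature coefficient, per year
    t0: float     # hypothetical age at zero length, years
    n: int
    converged: bool
    rss: float    # residual sum of squares, cm^2
    label: str = ""

    def predict(self, age) -> np.ndarray:
        """Predicted fork length (cm) at age (years)."""
        return vbgf(age, self.l_inf, self.k, self.t0)

    def kmax(self, l_max: float, s_l: float = -2.0) -> "KmaxResult":
        return compute_kmax(self, l_max=l_max, s_l=s_l)

    def summary(self) -> str:
        return "\n".join([
            f"VBGF fit {self.label} (n={self.n}, converged={self.converged})",
            f"  L_inf  {self.l_inf:.4f} cm",
            f"  k      {self.k:.4f} / yr",
            f"  t0     {self.t0:.4f} yr",
            f"  RSS    {self.rss:.6f} cm^2",
        ])


class VonBertalanffyModel:
    """Nonlinear least-squares VBGF model for length-at-age pairs.

    Ages in years, fork lengths in cm.  Fits refuse (converged=False) when
    the optimizer fails or the solution sits on a parameter bound; cells
    with fewer than ``min_n`` fish yield a no-fit result, mirroring field
    datasets where some site-depth cells cannot support a growth curve.
    """

    #: default parameter bounds: L∞ ∈ (0, 3·max FL], k ∈ (0, 10], t₀ ∈ [−2, 1]
    K_MAX_BOUND = 10.0
    T0_BOUNDS = (-2.0, 1.0)

    def __init__(self, age, fl, label: str = "", min_n: int = 5):
        self.age = np.asarray(age, dtype=float)
        self.fl = np.asarray(fl, dtype=float)
        if self.age.shape != self.fl.shape:
            raise ValueError("age and fl must have equal length")
        self.label = label
        self.min_n = min_n

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, age: str = "age", fl: str = "fl_cm",
                       label: str = "", min_n: int = 5):
        sub = df.dropna(subset=[age, fl])
        return cls(sub[age].to_numpy(), sub[fl].to_numpy(), label=label, min_n=min_n)

    def fit(self, init=None, bounds=None) -> VBGFResults:
        n = len(self.age)
        if n < self.min_n or np.ptp(self.age) <= 0:
            return VBGFResults(np.nan, np.nan, np.nan, n, converged=False,
                               rss=np.nan, label=self.label)
        max_fl = float(self.fl.max())
        x0 = np.asarray(init if init is not None else (1.1 * max_fl, 1.0, 0.0), float)
        if bounds is None:
            lo = np.array([1e-8, 1e-8, self.T0_BOUNDS[0]])
            hi = np.array([3.0 * max_fl, self.K_MAX_BOUND, self.T0_BOUNDS[1]])
        else:
            lo, hi = (np.asarray(b, dtype=float) for b in bounds)
        x0 = np.clip(x0, lo, hi)

        def resid(p):
            return vbgf(self.age, *p) - self.fl

        sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-10, ftol=1e-12,
                            gtol=1e-12)
        rss = float(np.sum(sol.fun ** 2))
        # a solution pinned to a bound is not a trusted growth curve
        at_bound = bool(np.any(np.isclose(sol.x, lo, rtol=0, atol=1e-8) |
                               np.isclose(sol.x, hi, rtol=0, atol=1e-8)))
        converged = bool(sol.success) and not at_bound
        return VBGFResults(float(sol.x[0]), float(sol.x[1]), float(sol.x[2]),
                           n, converged=converged, rss=rss, label=self.label)


def fit_vbgf(pairs, init=None, bounds=None, label: str = "", min_n: int = 5) -> VBGFResults:
    """Fit the VBGF to (age, fork length) pairs; functional shorthand."""
    arr = np.asarray(pairs, dtype=float)
    return VonBertalanffyModel(arr[:, 0], arr[:, 1], label=label,
                               min_n=min_n).fit(init=init, bounds=bounds)


def predict_length(fit: VBGFResults, age):
    """Predicted fork length (cm) at age (years) for a converged fit."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    return fit.predict(age)


# ---------------------------------------------------------------------------
# Kmax standardization


@dataclass
class KmaxResult:
    """Growth coefficient standardized to the species' maximum size.

    log₁₀ K_max = Ø + s_L · log₁₀ L_max with Ø = log₁₀ k − s_L · log₁₀ L∞,
    i.e. K_max = k · (L_max / L∞)^{s_L}.
    """

    kmax: float   # per year
    phi: float    # growth performance index Ø
    s_l: float    # slope of the log k – log L∞ relationship
    l_max: float  # maximum reported species fork length, cm


def compute_kmax(fit: VBGFResults, l_max: float, s_l: float = -2.0) -> KmaxResult:
    """Standardize a fitted k to the expected growth coefficient at L_max."""
    if not fit.converged:
        raise ValueError("Kmax requires a converged VBGF fit")
    if fit.k <= 0:
        raise ValueError("Kmax requires k > 0")
    if l_max <= 0:
        raise ValueError("l_max must be positive")
    phi = np.log10(fit.k) - s_l * np.log10(fit.l_inf)
    kmax = 10.0 ** (phi + s_l * np.log10(l_max))
    return KmaxResult(kmax=float(kmax), phi=float(phi), s_l=float(s_l),
                      l_max=float(l_max))


def fit_site_depth_growth(fish: pd.DataFrame, l_max: float, s_l: float = -2.0,
                          min_n: int = 5) -> pd.DataFrame:
    """Per-site-depth VBGF fits and Kmax on an aged-fish table.

    Expects columns site_id, depth, age (years), fl_mm or fl_cm.  Lengths
    recorded in mm are converted to cm to match the growth equation's units.
    Returns one row per cell with the fit parameters, convergence flag and
    kmax (NaN when no growth curve could be fitted).
    """
    fish = fish.copy()
    if "fl_cm" not in fish.columns:
        fish["fl_cm"] = fish["fl_mm"] / 10.0
    rows = []
    for (site, depth), sub in fish.groupby(["site_id", "depth"], observed=True):
        sub = sub.dropna(subset=["age", "fl_cm"])
        label = f"{site}_{depth}"
        fit = VonBertalanffyModel.from_dataframe(sub, label=label, min_n=min_n).fit()
        row = {"site_id": site, "depth": depth, "n": fit.n,
               "converged": fit.converged, "l_inf": fit.l_inf, "k": fit.k,
               "t0": fit.t0, "rss": fit.rss, "kmax": np.nan}
        if fit.converged and fit.k > 0:
            row["kmax"] = compute_kmax(fit, l_max=l_max, s_l=s_l).kmax
        rows.append(row)
    return pd.DataFrame(rows)
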