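"""Isotopic niche estimation: standard ellipse areas in δ¹³C–δ¹⁵N space.

The standard ellipse of a bivariate point cloud is the 1-standard-deviation
ellipse of its fitted bivariate normal; its area (SEA = π·√(λ₁λ₂), with λᵢ
the sample-covariance eigenvalues) is a point estimate of isotopic niche
width.  SEA_c applies the small-sample correction (n−1)/(n−2).  The Bayesian
variant (SEA_b) samples covariance matrices from a conjugate
normal–inverse-Wishart posterior under a vague prior and propagates them to
a posterior distribution of ellipse areas; group comparisons use the
fraction of paired posterior draws for which one group's area exceeds the
other's, with significance declared when that fraction reaches 95% on
either side.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InsufficientDataError",
    "StandardEllipseModel",
    "EllipseResults",
    "PosteriorSEA",
    "SEAComparison",
    "compare_sea",
    "ellipse_boundary",
    "fit_standard_ellipse",
    "sample_posterior_sea",
    "niche_analysis",
    "NicheAnalysis",
]


class InsufficientDataError(ValueError):
    """Fewer points than the minimum (3) required for an ellipse fit."""


def _sea_from_cov(cov: np.ndarray) -> float:
    # area of the 1-sd ellipse: pi * sqrt(lambda1 * lambda2) = pi * sqrt(det)
    det = float(np.linalg.det(cov))
    return float(np.pi * np.sqrt(max(det, 0.0)))


@dataclass
class EllipseResults:
    """Maximum-likelihood standard ellipse for one group of isotope points.

    Attributes
    ----------
    group_label : str
    mean : ndarray, shape (2,)
        Centroid in (δ¹³C, δ¹⁵N) per-mil coordinates.
    cov : ndarray, shape (2, 2)
        Sample covariance (denominator n−1).
    n : int
    sea : float
        Standard ellipse area, ‰².
    sea_c : float
        Small-sample corrected area, sea × (n−1)/(n−2).
    degenerate : bool
        True when the points are (numerically) collinear and the area is 0.
    """

    group_label: str
    mean: np.ndarray
    cov: np.ndarray
    n: int
    sea: float
    sea_c: float
    degenerate: bool = False

    def boundary(self, coverage: float = None, n_points: int = 100) -> np.ndarray:
        """Boundary ring of the ellipse; see :func:`ellipse_boundary`."""
        return ellipse_boundary(self, coverage=coverage, n_points=n_points)

    def summary(self) -> str:
        lines = [
            f"Standard ellipse: {self.group_label}",
            f"  n            {self.n}",
            f"  centroid     ({self.mean[0]:.3f}, {self.mean[1]:.3f}) permil",
            f"  SEA          {self.sea:.4f} permil^2",
            f"  SEA_c        {self.sea_c:.4f} permil^2",
        ]
        if self.degenerate:
            lines.append("  (degenerate: collinear points)")
        return "\n".join(lines)


class StandardEllipseModel:
    """Bivariate isotopic-niche model for one group of (δ¹³C, δ¹⁵N) points.

    ``fit()`` gives the maximum-likelihood ellipse (:class:`EllipseResults`);
    ``fit_bayes()`` draws the SEA_b posterior (:class:`PosteriorSEA`).
    """

    def __init__(self, points, label: str = ""):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (d13c, d15n)")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        if pts.shape[0] < 3:
            raise InsufficientDataError(
                f"need at least 3 points for group {label!r}, got {pts.shape[0]}"
            )
        self.points = pts
        self.label = label
        self.n = pts.shape[0]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x: str = "d13c_normalized",
                       y: str = "d15n", label: str = ""):
        sub = df.dropna(subset=[x, y])
        return cls(np.column_stack([sub[x].to_numpy(), sub[y].to_numpy()]), label=label)

    def fit(self) -> EllipseResults:
        mean = self.points.mean(axis=0)
        cov = np.cov(self.points, rowvar=False, ddof=1)
        sea = _sea_from_cov(cov)
        # collinear clouds have a (numerically) zero eigenvalue
        eigvals = np.linalg.eigvalsh(cov)
        scale = max(eigvals.max(), 1.0)
        degenerate = bool(eigvals.min() <= 1e-12 * scale)
        if degenerate:
            sea = 0.0
        sea_c = sea * (self.n - 1) / (self.n - 2)
        return EllipseResults(
            group_label=self.label, mean=mean, cov=cov, n=self.n,
            sea=sea, sea_c=sea_c, degenerate=degenerate,
        )

    def fit_bayes(self, iterations: int = 10_000, seed=None) -> "PosteriorSEA":
        """Sample the SEA_b posterior.

        Conjugate normal–inverse-Wishart posterior under a vague prior
        (μ₀ = sample mean, κ₀ = 10⁻³, ν₀ = 2, Λ₀ = 10⁻³·I): covariance draws
        are inverse-Wishart(ν₀+n, Λ₀+S+κ shrinkage term), each mapped to its
        standard-ellipse area.
        """
        rng = np.random.default_rng(seed)
        x = self.points
        n = self.n
        xbar = x.mean(axis=0)
        s = (x - xbar).T @ (x - xbar)
        kappa0, nu0 = 1e-3, 2.0
        lambda0 = 1e-3 * np.eye(2)
        mu0 = xbar
        kappan = kappa0 + n
        nun = nu0 + n
        dm = (xbar - mu0).reshape(2, 1)
        lambdan = lambda0 + s + (kappa0 * n / kappan) * (dm @ dm.T)
        draws = np.empty(iterations)
        covs = stats.invwishart.rvs(df=nun, scale=lambdan, size=iterations, random_state=rng)
        dets = covs[:, 0, 0] * covs[:, 1, 1] - covs[:, 0, 1] * covs[:, 1, 0]
        draws[:] = np.pi * np.sqrt(np.clip(dets, 0.0, None))
        return PosteriorSEA(draws=draws, group_label=self.label, seed=seed)


def fit_standard_ellipse(points, label: str = "") -> EllipseResults:
    """Functional shorthand for ``StandardEllipseModel(points, label).fit()``."""
    return StandardEllipseModel(points, label).fit()


def sample_posterior_sea(points, iterations: int = 10_000, seed=None,
                         label: str = "") -> "PosteriorSEA":
    """Functional shorthand for ``StandardEllipseModel(...).fit_bayes(...)``."""
    return StandardEllipseModel(points, label).fit_bayes(iterations=iterations, seed=seed)


def ellipse_boundary(ellipse: EllipseResults, coverage: float = None,
                     n_points: int = 100) -> np.ndarray:
    """Points on the ellipse boundary {x : (x−μ)ᵀ Σ⁻¹ (x−μ) = q}.

    ``coverage`` is the bivariate-normal probability mass enclosed; q is the
    chi-square(2 df) quantile at that coverage.  ``coverage=None`` gives the
    standard (1-sd) ellipse, q = 1, which encloses 1 − e^(−1/2) ≈ 39.35% —
    the quantity conventionally drawn as the "40%" ellipse.  Returns a closed
    ring (first point repeated last).
    """
    if ellipse.degenerate:
        raise ValueError("degenerate covariance: no ellipse boundary")
    if coverage is None:
        q = 1.0
    else:
        if not 0.0 < coverage < 1.0:
            raise ValueError("coverage must be in (0, 1)")
        q = float(stats.chi2.ppf(coverage, df=2))
    eigvals, eigvecs = np.linalg.eigh(ellipse.cov)
    theta = np.linspace(0.0, 2.0 * np.pi, n_points)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    pts = circle * np.sqrt(q * eigvals) @ eigvecs.T + ellipse.mean
    return pts


@dataclass
class PosteriorSEA:
    """Posterior distribution of standard ellipse area (SEA_b) for one group."""

    draws: np.ndarray
    group_label: str = ""
    seed: object = None

    @property
    def mode(self) -> float:
        """Posterior mode via Gaussian KDE (Silverman bandwidth) over draws."""
        kde = stats.gaussian_kde(self.draws, bw_method="silverman")
        grid = np.linspace(self.draws.min(), self.draws.max(), 512)
        return float(grid[np.argmax(kde(grid))])

    def credible_interval(self, level: float) -> tuple:
        """Highest-density interval at the given level (0 < level < 1)."""
        x = np.sort(self.draws)
        n = len(x)
        k = max(int(np.ceil(level * n)), 2)
        widths = x[k - 1:] - x[: n - k + 1]
        i = int(np.argmin(widths))
        return float(x[i]), float(x[i + k - 1])

    @property
    def credible_intervals(self) -> dict:
        """HDIs at the conventional 50/75/95% levels."""
        return {lev: self.credible_interval(lev) for lev in (0.50, 0.75, 0.95)}

    def summary(self) -> str:
        ci = self.credible_intervals
        return "\n".join(
            [
                f"SEA_b posterior: {self.group_label} ({len(self.draws)} draws)",
                f"  mode   {self.mode:.4f} permil^2",
                f"  mean   {self.draws.mean():.4f} permil^2",
            ]
            + [f"  {int(l*100)}% HDI  ({lo:.4f}, {hi:.4f})" for l, (lo, hi) in ci.items()]
        )


@dataclass
class SEAComparison:
    """Posterior comparison of two groups' ellipse areas."""

    group_a: str
    group_b: str
    p_a_greater: float
    significant: bool


def compare_sea(a: PosteriorSEA, b: PosteriorSEA) -> SEAComparison:
    """P(SEA_a > SEA_b) as the fraction of index-paired posterior draws.

    Ties count 0.5.  Significant when the probability is ≥ 0.95 or ≤ 0.05
    (at least 95% of draws for one group smaller than the other).
    """
    if len(a.draws) != len(b.draws):
        raise ValueError(
            f"draw counts differ ({len(a.draws)} vs {len(b.draws)}); refusing to truncate"
        )
    gt = np.count_nonzero(a.draws > b.draws)
    ties = np.count_nonzero(a.draws == b.draws)
    p = (gt + 0.5 * ties) / len(a.draws)
    return SEAComparison(
        group_a=a.group_label,
        group_b=b.group_label,
        p_a_greater=float(p),
        significant=bool(p >= 0.95 or p <= 0.05),
    )


# ---------------------------------------------------------------------------
# grouped analysis


@dataclass
class NicheAnalysis:
    """Per-group ellipses, posteriors, pairwise comparisons and letter codes."""

    ellipses: dict
    posteriors: dict
    comparisons: list
    letters: dict

    def comparison_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "p_a_greater": c.p_a_greater,
                    "significant": c.significant,
                }
                for c in self.comparisons
            ]
        )

    def ellipse_table(self) -> pd.DataFrame:
        rows = []
        for label, e in self.ellipses.items():
            rows.append(
                {
                    "group": label,
                    "n": e.n,
                    "mean_d13c": e.mean[0],
                    "mean_d15n": e.mean[1],
                    "sea": e.sea,
                    "sea_c": e.sea_c,
                    "sea_b_mode": self.posteriors[label].mode,
                    "letters": self.letters.get(label, ""),
                }
            )
        return pd.DataFrame(rows)


def _letter_codes(labels, comparisons) -> dict:
    """Compact letter display: non-significant pairs share at least one letter,
    significant pairs share none.  Letters are maximal cliques of the
    non-significance graph (insert–absorb construction)."""
    nonsig = {l: {l} for l in labels}
    for c in comparisons:
        if not c.significant:
            nonsig[c.group_a].add(c.group_b)
            nonsig[c.group_b].add(c.group_a)
    cliques: list = []
    for l in labels:
        placed = False
        for cl in cliques:
            if all(l in nonsig[m] for m in cl):
                cl.add(l)
                placed = True
        if not placed:
            cliques.append({l})
    # ensure every non-significant pair shares a clique
    for c in comparisons:
        if c.significant:
            continue
        a, b = c.group_a, c.group_b
        if not any(a in cl and b in cl for cl in cliques):
            new = {a, b}
            for m in labels:
                if m in (a, b):
                    continue
                if all(m in nonsig[x] and x in nonsig[m] for x in new):
                    new.add(m)
            cliques.append(new)
    # drop cliques fully contained in another
    cliques = [cl for i, cl in enumerate(cliques)
               if not any(i != j and cl < other for j, other in enumerate(cliques))]
    letters = {l: "" for l in labels}
    for letter, cl in zip(string.ascii_lowercase, cliques):
        for l in sorted(cl):
            letters[l] += letter
    return letters


def combine_taxa(tissue: pd.DataFrame, baselines: pd.DataFrame) -> pd.DataFrame:
    """Stack fish tissue and POM/zooplankton baselines into one taxon frame.

    Fish points use the lipid-normalized δ¹³C; baseline filters are not
    lipid-corrected, so their raw δ¹³C is carried into the same column.
    """
    fish = pd.DataFrame({
        "taxon": "fish",
        "d13c_normalized": tissue["d13c_normalized"]
        if "d13c_normalized" in tissue.columns else tissue["d13c"],
        "d15n": tissue["d15n"],
    })
    base = pd.DataFrame({
        "taxon": baselines["kind"],
        "d13c_normalized": baselines["d13c"],
        "d15n": baselines["d15n"],
    })
    return pd.concat([fish, base], ignore_index=True)


_GROUPINGS = {
    "taxon": ["taxon"],
    "atoll": ["atoll"],
    "depth": ["depth"],
    "atoll_depth": ["atoll", "depth"],
}


def niche_analysis(samples: pd.DataFrame, grouping: str, iterations: int = 10_000,
                   seed=None, x: str = "d13c_normalized", y: str = "d15n",
                   min_n: int = 3) -> NicheAnalysis:
    """Fit ellipses and SEA_b posteriors per group and compare all pairs.

    ``grouping`` is one of ``taxon``, ``atoll``, ``depth``, ``atoll_depth``
    (``atoll×depth``).  Groups below ``min_n`` points are skipped with a
    warning.  Each group gets an independent posterior seed spawned from
    ``seed``; comparisons pair draws by index.
    """
    grouping = grouping.replace("×", "_").replace("x", "_") if grouping in (
        "atoll×depth", "atollxdepth") else grouping
    if grouping not in _GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}")
    cols = _GROUPINGS[grouping]
    for col in cols + [x, y]:
        if col not in samples.columns:
            raise KeyError(f"samples table lacks column {col!r}")
    ellipses, posteriors = {}, {}
    seeds = np.random.SeedSequence(seed).spawn(samples.groupby(cols, observed=True).ngroups)
    for (key, sub), ss in zip(samples.groupby(cols, observed=True), seeds):
        label = key if isinstance(key, str) else "_".join(str(k) for k in key)
        sub = sub.dropna(subset=[x, y])
        if len(sub) < min_n:
            warnings.warn(f"group {label!r} has n={len(sub)} < {min_n}; skipped",
                          stacklevel=2)
            continue
        model = StandardEllipseModel.from_dataframe(sub, x=x, y=y, label=label)
        ellipses[label] = model.fit()
        posteriors[label] = model.fit_bayes(iterations=iterations,
                                            seed=np.random.default_rng(ss))
    labels = list(ellipses)
    comparisons = [
        compare_sea(posteriors[a], posteriors[b])
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
    ]
    letters = _letter_codes(labels, comparisons)
    return NicheAnalysis(ellipses=ellipses, posteriors=posteriors,
                         comparisons=comparisons, letters=letters)
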