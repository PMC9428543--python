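"""Pre-registered hypothesis battery: GLMs, effect sizes, FDR, block permutations.

Each response (δ¹⁵N, δ¹³C, C:N, Kmax) is modelled at site-depth level with a
generalized linear model containing atoll and depth factors, site
chlorophyll-a and reef slope covariates, and the three two-way interactions
depth:slope, depth:chl and slope:chl (gaussian-identity for the isotope and
condition responses, gamma-log for Kmax).  The twenty GLM coefficient
hypotheses (H1–H20) are judged jointly under Benjamini–Hochberg FDR control
at q = 0.10; four depth-difference hypotheses (H21–H24) use site-block
permutation tests at α = 0.05.  Verdicts are a pure function of the FDR
decision and the coefficient sign relative to the pre-registered direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelSpec",
    "ResponseGLM",
    "GLMFit",
    "partial_eta_squared",
    "bh_adjust",
    "PermutationResult",
    "block_permutation_test",
    "HYPOTHESES",
    "HypothesisBattery",
    "BatteryResults",
    "build_cell_table",
]

logger = logging.getLogger(__name__)

#: model terms of the pre-registered design, in reporting order
TERMS = ["atoll", "depth", "slope", "chl", "depth:slope", "depth:chl", "slope:chl"]

_FAMILIES = {
    ("gaussian", "identity"): lambda: sm.families.Gaussian(sm.families.links.Identity()),
    ("gaussian", "log"): lambda: sm.families.Gaussian(sm.families.links.Log()),
    ("gamma", "log"): lambda: sm.families.Gamma(sm.families.links.Log()),
    ("gamma", "identity"): lambda: sm.families.Gamma(sm.families.links.Identity()),
    ("gamma", "inverse"): lambda: sm.families.Gamma(sm.families.links.InversePower()),
}

#: response → (family, link) per the registered design
RESPONSE_FAMILY = {
    "d15n": ("gaussian", "identity"),
    "d13c": ("gaussian", "identity"),
    "cn": ("gaussian", "identity"),
    "kmax": ("gamma", "log"),
}


@dataclass
class ModelSpec:
    """One response's GLM specification."""

    response: str
    family: str = None
    link: str = None
    terms: tuple = tuple(TERMS)

    def __post_init__(self):
        if self.family is None:
            self.family, default_link = RESPONSE_FAMILY.get(
                self.response, ("gaussian", "identity"))
            if self.link is None:
                self.link = default_link
        elif self.link is None:
            self.link = "log" if self.family == "gamma" else "identity"
        if (self.family, self.link) not in _FAMILIES:
            raise ValueError(f"unsupported family/link {self.family}/{self.link}")


def _term_formula(term: str) -> str:
    return ":".join("C(atoll)" if v == "atoll" else v for v in term.split(":"))


def _build_formula(response: str, terms) -> str:
    rhs = " + ".join(_term_formula(t) for t in terms) if terms else "1"
    return f"{response} ~ {rhs}"


@dataclass
class GLMFit:
    """Coefficient table and fit statistics for one response GLM."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # index: term; estimate, se, t, p
    loglik: float
    aic: float
    deviance: float
    n_obs: int
    converged: bool
    sm_results: object = field(repr=False, default=None)

    def coef(self, term: str) -> pd.Series:
        if term not in self.coefficients.index:
            raise KeyError(f"term {term!r} not in model")
        return self.coefficients.loc[term]

    def summary(self) -> str:
        head = (f"GLM {self.spec.response} ({self.spec.family}/{self.spec.link}), "
                f"n={self.n_obs}, loglik={self.loglik:.3f}, aic={self.aic:.3f}")
        return head + "\n" + self.coefficients.to_string(float_format="%.4f")


class ResponseGLM:
    """GLM of one site-depth response on the registered design.

    Thin modelling surface over statsmodels' IRLS fitter; the data frame must
    carry the response column plus atoll, depth (0 = shallow, 1 = moderate),
    slope and chl.  Rows with missing covariates or response are dropped with
    a log entry.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        needed = {spec.response, "atoll", "depth", "slope", "chl"}
        missing = needed - set(data.columns)
        if missing:
            raise KeyError(f"model frame lacks columns {sorted(missing)}")
        before = len(data)
        self.data = data.dropna(subset=sorted(needed)).reset_index(drop=True)
        dropped = before - len(self.data)
        if dropped:
            logger.info("response %s: dropped %d rows with missing covariates",
                        spec.response, dropped)
        self.formula = _build_formula(spec.response, spec.terms)

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, family="gaussian",
                     link=None):
        response = formula.split("~")[0].strip()
        spec = ModelSpec(response=response, family=family, link=link)
        obj = cls.__new__(cls)
        obj.spec = spec
        obj.data = data.dropna().reset_index(drop=True)
        obj.formula = formula
        return obj

    def fit(self, maxiter: int = 100, tol: float = 1e-10) -> GLMFit:
        family = _FAMILIES[(self.spec.family, self.spec.link)]()
        model = smf.glm(self.formula, data=self.data, family=family)
        rank = np.linalg.matrix_rank(model.exog)
        if rank < model.exog.shape[1]:
            aliased = _aliased_columns(model.exog, model.exog_names)
            raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
        res = model.fit(maxiter=maxiter, tol=tol)
        coefs = pd.DataFrame({
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        })
        return GLMFit(
            spec=self.spec, coefficients=coefs, loglik=float(res.llf),
            aic=float(res.aic), deviance=float(res.deviance),
            n_obs=int(res.nobs), converged=bool(res.converged), sm_results=res,
        )


def _aliased_columns(exog: np.ndarray, names) -> list:
    aliased = []
    kept: list = []
    for j in range(exog.shape[1]):
        trial = exog[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            aliased.append(names[j])
    return aliased


def partial_eta_squared(data: pd.DataFrame, spec: ModelSpec, term: str) -> float:
    """Deviance-based partial eta² for one model term (Type-II deletion).

    The term is compared against the model containing every term that does
    not include it (Type-II): pη² = (D_reduced − D_full) / D_reduced, where
    D is residual deviance — for gaussian models this is exactly
    SS_term / (SS_term + SS_resid).
    """
    if term not in spec.terms:
        raise KeyError(f"term {term!r} not in model spec")
    tset = set(term.split(":"))
    base = [t for t in spec.terms if t != term and not tset < set(t.split(":"))]
    full_terms = base + [term]
    d_full = ResponseGLM(data, ModelSpec(spec.response, spec.family, spec.link,
                                         tuple(full_terms))).fit().deviance
    d_red = ResponseGLM(data, ModelSpec(spec.response, spec.family, spec.link,
                                        tuple(base))).fit().deviance
    num = max(d_red - d_full, 0.0)
    if num + d_full == 0:
        return 1.0
    return float(num / (num + d_full))


def bh_adjust(p_values, q: float = 0.10):
    """Benjamini–Hochberg step-up FDR control.

    Returns (reject, p_adjusted): reject all hypotheses with rank ≤
    max{i : p(i) ≤ i·q/m}; adjusted p-values are monotone in raw rank.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# block permutation


@dataclass
class PermutationResult:
    """Two-sided site-block permutation test of a depth difference."""

    statistic_observed: float  # mean(moderate blocks) − mean(shallow blocks)
    p: float
    n_perm: int
    exact: bool
    seed: object = None


def block_permutation_test(blocks: pd.DataFrame, value: str = "value",
                           n_perm: int = 9999, seed=None,
                           method: str = "auto") -> PermutationResult:
    """Permute whole site blocks between depths and test the depth difference.

    ``blocks`` holds one row per site-depth block (columns site_id, depth,
    and the value column); fish stay within their block, so within-site
    correlation is preserved under the null.  Each site's depth labels are
    swapped independently with probability ½; when the full swap space
    2^(#sites) fits inside ``n_perm`` the null is enumerated exactly
    (``method='auto'``; force one path with 'exact' or 'sampled').
    The p-value is two-sided with add-one correction for sampled nulls.
    """
    for col in ("site_id", "depth", value):
        if col not in blocks.columns:
            raise KeyError(f"blocks table lacks column {col!r}")
    sub = blocks.dropna(subset=[value])
    if sub.groupby(["site_id", "depth"], observed=True).size().max() > 1:
        raise ValueError("each site may contribute at most one block per depth")
    vals = sub[value].to_numpy(dtype=float)
    depth01 = (sub["depth"].astype(str) == "moderate").to_numpy(dtype=int)
    if depth01.sum() == 0 or depth01.sum() == len(depth01):
        raise ValueError("both depth groups must be non-empty")
    sites = pd.factorize(sub["site_id"])[0]
    n_sites = sites.max() + 1

    def stat(labels):
        # labels: (..., n_blocks) 0/1 arrays
        labels = np.atleast_2d(labels)
        n_mod = labels.sum(axis=1)
        n_sha = labels.shape[1] - n_mod
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (labels @ vals) / n_mod - ((1 - labels) @ vals) / n_sha
        return t

    t_obs = float(stat(depth01)[0])
    if method == "auto":
        exact = bool(2 ** n_sites <= n_perm)
    elif method in ("exact", "sampled"):
        exact = method == "exact"
    else:
        raise ValueError(f"unknown method {method!r}")
    if exact:
        patterns = ((np.arange(2 ** n_sites)[:, None] >> np.arange(n_sites)) & 1)
    else:
        rng = np.random.default_rng(seed)
        patterns = rng.integers(0, 2, size=(n_perm, n_sites))
    labels = depth01[None, :] ^ patterns[:, sites]
    t_null = stat(labels)
    ok = np.isfinite(t_null)
    eps = 1e-12 * max(abs(t_obs), 1.0)
    exceed = np.abs(t_null[ok]) >= abs(t_obs) - eps
    if exact:
        p = float(exceed.mean())
        n_used = int(ok.sum())
    else:
        p = float((1 + exceed.sum()) / (ok.sum() + 1))
        n_used = int(ok.sum())
    return PermutationResult(statistic_observed=t_obs, p=p, n_perm=n_used,
                             exact=exact, seed=seed)


# ---------------------------------------------------------------------------
# the registered battery

_RESP_ORDER = ["kmax", "cn", "d15n", "d13c"]

#: H1–H24: (response, test kind, model term or None, pre-registered sign)
#: sign +1/−1 encodes the registered direction on the model's scale
#: (slope stored as negative angle, so "more gradual" = larger slope value);
#: 0 means the registered hypothesis is two-sided ("is influenced by").
HYPOTHESES = pd.DataFrame(
    [
        ("H1", "kmax", "glm", "chl", +1),
        ("H2", "cn", "glm", "chl", +1),
        ("H3", "d15n", "glm", "chl", -1),
        ("H4", "d13c", "glm", "chl", -1),
        ("H5", "kmax", "glm", "slope", +1),
        ("H6", "cn", "glm", "slope", +1),
        ("H7", "d15n", "glm", "slope", +1),
        ("H8", "d13c", "glm", "slope", -1),
        ("H9", "kmax", "glm", "depth:chl", 0),
        ("H10", "cn", "glm", "depth:chl", 0),
        ("H11", "d15n", "glm", "depth:chl", 0),
        ("H12", "d13c", "glm", "depth:chl", 0),
        ("H13", "kmax", "glm", "depth:slope", 0),
        ("H14", "cn", "glm", "depth:slope", 0),
        ("H15", "d15n", "glm", "depth:slope", 0),
        ("H16", "d13c", "glm", "depth:slope", 0),
        ("H17", "kmax", "glm", "slope:chl", 0),
        ("H18", "cn", "glm", "slope:chl", 0),
        ("H19", "d15n", "glm", "slope:chl", 0),
        ("H20", "d13c", "glm", "slope:chl", 0),
        ("H21", "kmax", "perm", None, +1),
        ("H22", "cn", "perm", None, +1),
        ("H23", "d15n", "perm", None, -1),
        ("H24", "d13c", "perm", None, -1),
    ],
    columns=["id", "response", "kind", "term", "expected_sign"],
)


def build_cell_table(cell_means: dict, covariates: pd.DataFrame,
                     slope_transform: str = "radians") -> pd.DataFrame:
    """Join site-depth response means to site covariates into one model frame.

    ``cell_means`` maps response name → DataFrame(site_id, depth, mean) as
    produced by :func:`reefiso.isotopes.aggregate_site_depth` (for kmax, a
    table with a ``kmax`` column is also accepted).  ``covariates`` must have
    site_id, slope_deg, chl_mean.  ``slope_transform`` maps the stored angle
    (degrees) onto the modelling scale: 'radians' (default), 'degrees', or
    'z' (standardized).  Depth is coded 0 = shallow, 1 = moderate.
    """
    frames = []
    for resp, df in cell_means.items():
        df = df.copy()
        if "mean" in df.columns:
            df = df.rename(columns={"mean": resp})
        elif resp not in df.columns:
            raise KeyError(f"cell table for {resp!r} lacks a mean/{resp} column")
        frames.append(df[["site_id", "depth", resp]])
    out = frames[0]
    for df in frames[1:]:
        out = pd.merge(out, df, on=["site_id", "depth"], how="outer")
    cov = covariates.copy()
    if slope_transform == "radians":
        cov["slope"] = np.deg2rad(cov["slope_deg"])
    elif slope_transform == "degrees":
        cov["slope"] = cov["slope_deg"]
    elif slope_transform == "z":
        s = cov["slope_deg"]
        cov["slope"] = (s - s.mean()) / s.std(ddof=1)
    else:
        raise ValueError(f"unknown slope_transform {slope_transform!r}")
    cov = cov.rename(columns={"chl_mean": "chl"})
    keep = ["site_id", "slope", "chl"] + (["atoll"] if "atoll" in cov.columns else [])
    out = pd.merge(out, cov[keep], on="site_id", how="left")
    if "atoll" not in out.columns:
        raise KeyError("covariates (or cell tables) must provide an atoll column")
    out["depth_label"] = out["depth"].astype(str)
    out["depth"] = (out["depth_label"] == "moderate").astype(int)
    return out


@dataclass
class BatteryResults:
    """Verdict table and per-response fits for the registered battery."""

    table: pd.DataFrame
    glm_fits: dict
    permutations: dict
    q: float
    alpha: float

    def coefficient_matrix(self) -> pd.DataFrame:
        """Table of coefficient (se) strings, one column per response."""
        cols = {}
        for resp, fit in self.glm_fits.items():
            cols[resp] = fit.coefficients.apply(
                lambda r: f"{r['estimate']:.3f} ({r['se']:.3f})", axis=1)
        return pd.DataFrame(cols)

    def summary(self) -> str:
        cols = ["id", "response", "term", "estimate", "p_raw", "p_adj",
                "rejected", "verdict"]
        return self.table[cols].to_string(index=False, float_format="%.4f")


class HypothesisBattery:
    """The registered H1–H24 battery on a site-depth model frame.

    ``cells`` is the joined frame from :func:`build_cell_table` with columns
    site_id, depth (0/1), depth_label, atoll, slope, chl and the four
    response columns (d15n, d13c, cn, kmax).  BH FDR at ``q`` applies jointly
    to the twenty GLM p-values; the permutation hypotheses are judged at
    ``alpha`` without FDR.
    """

    _COEF_NAMES = {
        "depth": "depth",
        "slope": "slope",
        "chl": "chl",
        "depth:slope": "depth:slope",
        "depth:chl": "depth:chl",
        "slope:chl": "slope:chl",
    }

    def __init__(self, cells: pd.DataFrame, q: float = 0.10, alpha: float = 0.05,
                 n_perm: int = 9999, seed=None,
                 hypotheses: pd.DataFrame = HYPOTHESES):
        self.cells = cells
        self.q = q
        self.alpha = alpha
        self.n_perm = n_perm
        self.seed = seed
        self.hypotheses = hypotheses

    def fit(self, compute_eta: bool = False) -> BatteryResults:
        missing = [r for r in _RESP_ORDER if r not in self.cells.columns]
        if missing:
            raise ValueError(f"battery inputs incomplete; absent responses: {missing}")
        glm_fits = {}
        for resp in _RESP_ORDER:
            glm_fits[resp] = ResponseGLM(self.cells, ModelSpec(resp)).fit()
        perm_seeds = np.random.SeedSequence(self.seed).spawn(len(_RESP_ORDER))
        permutations = {}
        for resp, ss in zip(_RESP_ORDER, perm_seeds):
            blocks = self.cells.dropna(subset=[resp])[
                ["site_id", "depth_label", resp]
            ].rename(columns={"depth_label": "depth", resp: "value"})
            permutations[resp] = block_permutation_test(
                blocks, n_perm=self.n_perm, seed=np.random.default_rng(ss))
        rows = []
        for h in self.hypotheses.itertuples(index=False):
            if h.kind == "glm":
                coef = glm_fits[h.response].coef(self._COEF_NAMES[h.term])
                est, se, p = coef["estimate"], coef["se"], coef["p"]
                stat = coef["t"]
            else:
                pr = permutations[h.response]
                est, se, p, stat = pr.statistic_observed, np.nan, pr.p, np.nan
            eta = np.nan
            if compute_eta and h.kind == "glm":
                eta = partial_eta_squared(self.cells, ModelSpec(h.response), h.term)
            rows.append({"id": h.id, "response": h.response, "kind": h.kind,
                         "term": h.term, "estimate": est, "se": se, "stat": stat,
                         "p_raw": p, "expected_sign": h.expected_sign,
                         "partial_eta_sq": eta})
        table = pd.DataFrame(rows)
        is_glm = table["kind"] == "glm"
        reject = np.zeros(len(table), dtype=bool)
        p_adj = np.full(len(table), np.nan)
        rej_glm, adj_glm = bh_adjust(table.loc[is_glm, "p_raw"].to_numpy(), q=self.q)
        reject[is_glm.to_numpy()] = rej_glm
        p_adj[is_glm.to_numpy()] = adj_glm
        reject[~is_glm.to_numpy()] = table.loc[~is_glm, "p_raw"] <= self.alpha
        p_adj[~is_glm.to_numpy()] = table.loc[~is_glm, "p_raw"]
        table["p_adj"] = p_adj
        table["rejected"] = reject
        sign_ok = (table["expected_sign"] == 0) | (
            np.sign(table["estimate"]) == table["expected_sign"])
        table["direction_match"] = sign_ok
        verdict = np.where(
            ~reject, "not supported",
            np.where(sign_ok, "supported", "not supported (direction reversed)"))
        table["verdict"] = verdict
        return BatteryResults(table=table, glm_fits=glm_fits,
                              permutations=permutations, q=self.q, alpha=self.alpha)
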