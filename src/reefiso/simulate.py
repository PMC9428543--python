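"""Synthetic-data generator for the full pipeline.

Emulates the study design the pipeline targets: 3 atolls × 6 seaward-slope
sites × 2 depth strata (shallow ≈ 10 m, moderate ≈ 17.5 m) × ~10
planktivorous fish per cell.  Site chlorophyll-a is right-skewed
(log-normal bulk between roughly 0.05 and 0.17 mg m⁻³ with a rare
"hotspot" multiplier); reef slopes are uniform between −70° and −16°.
Fish lengths follow cell-level von Bertalanffy growth with Gaussian noise;
δ¹³C, δ¹⁵N and C:N respond to chlorophyll-a, slope, depth and their
two-way interactions through configurable linear predictors, with an
additional growth-rate (Kmax) effect depleting δ¹⁵N.  POM and zooplankton
baselines sit below the fish in the isoscape by configurable trophic
offsets.

All randomness flows from one root seed through named SeedSequence spawns,
so every table is reproducible independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from reefiso.growth import vbgf

__all__ = [
    "SimConfig",
    "generate_sites",
    "generate_fish",
    "generate_baselines",
    "generate_transects",
    "generate_chl_grids",
    "write_dataset",
]

ATOLLS = ["EG", "PB", "SA"]
DEPTHS = ["shallow", "moderate"]

#: registered-design effect coefficients for the "paper-like" preset, one map
#: per response: keys depth, slope, chl, depth:slope, depth:chl, slope:chl.
#: Signs follow the study-like world (e.g. negative chl effect on δ¹³C,
#: positive depth:chl effect on C:N); slope enters in radians.
PAPER_LIKE_EFFECTS = {
    "d15n": {"const": 9.831, "depth": 0.086, "slope": -0.771, "chl": -9.446,
             "depth:slope": -0.120, "depth:chl": -1.690, "slope:chl": -38.602},
    "d13c": {"const": -18.622, "depth": 0.039, "slope": -0.503, "chl": -5.289,
             "depth:slope": 0.032, "depth:chl": -1.340, "slope:chl": -20.149},
    "cn": {"const": 3.259, "depth": 0.001, "slope": -0.044, "chl": -0.204,
           "depth:slope": 0.037, "depth:chl": 1.104, "slope:chl": -0.352},
    # kmax predictor is on the log scale (gamma-log response)
    "kmax": {"const": 0.733, "depth": -0.038, "slope": -0.292, "chl": -3.727,
             "depth:slope": -0.007, "depth:chl": 1.069, "slope:chl": -15.214},
}

ZERO_EFFECTS = {
    resp: {k: (v if k == "const" else 0.0) for k, v in eff.items()}
    for resp, eff in PAPER_LIKE_EFFECTS.items()
}


@dataclass
class SimConfig:
    """The stated synthetic world.  Defaults emulate the study's design.

    Chlorophyll: log-normal with median 0.10 mg m⁻³ and σ_log = 0.30 puts
    ~95% of sites between 0.055 and 0.18 mg m⁻³; a hotspot site (probability
    per site) is multiplied by ``hotspot_multiplier`` to mimic the rare
    high-production tail.  Slopes are uniform in (−70°, −16°).  Growth uses a
    cell-level Kmax drawn from a gamma distribution around the linear
    predictor, mapped back to k through the maximum-size standardization.
    """

    n_atolls: int = 3
    sites_per_atoll: int = 6
    fish_per_cell: int = 10
    chl_mu_log: float = float(np.log(0.10))
    chl_sigma_log: float = 0.30
    hotspot_probability: float = 1.0 / 18.0
    hotspot_multiplier: float = 3.0
    slope_range: tuple = (-70.0, -16.0)
    # growth world
    l_inf_cm: float = 6.5
    l_inf_sd: float = 0.15
    t0: float = -0.1
    l_max_cm: float = 7.0
    s_l: float = -2.0
    kmax_dispersion: float = 0.05
    length_noise_sd_cm: float = 0.25
    age_range_yr: tuple = (0.2, 3.0)
    reader_error_cv: float = 0.03
    # response world
    effects: dict = field(default_factory=lambda: {r: dict(v) for r, v in
                                                   PAPER_LIKE_EFFECTS.items()})
    noise_sds: dict = field(default_factory=lambda: {"d15n": 0.5, "d13c": 0.35,
                                                     "cn": 0.12})
    cn_floor: float = 2.5
    growth_d15n_slope: float = -1.5  # per-mil per unit Kmax
    # baseline world (per-trophic-level offsets below fish)
    trophic_d15n_offset: float = 3.4  # conventional literature default
    trophic_d13c_offset: float = 0.8
    pom_per_site: int = 1
    zoo_per_site: int = 2
    baseline_sd: tuple = (0.6, 0.5)  # (d13c, d15n) within-group sd
    seed: int = 0

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "SimConfig":
        """Named presets: 'paper-like' (study-sign effects) or 'null'
        (all covariate effects zero)."""
        if name == "paper-like":
            return cls(seed=seed)
        if name == "null":
            return cls(effects={r: dict(v) for r, v in ZERO_EFFECTS.items()},
                       growth_d15n_slope=0.0, seed=seed)
        raise ValueError(f"unknown preset {name!r}")


def _spawn(seed, key: str) -> np.random.Generator:
    # named, order-independent stream split from the root seed
    root = np.random.SeedSequence(seed)
    streams = {"sites": 0, "fish": 1, "baselines": 2, "transects": 3, "grids": 4}
    return np.random.default_rng(root.spawn(len(streams))[streams[key]])


def generate_sites(config: SimConfig, seed=None) -> pd.DataFrame:
    """Site covariate table: site_id, atoll, chl_mean, chl_sd, slope_deg."""
    rng = _spawn(config.seed if seed is None else seed, "sites")
    rows = []
    for atoll in ATOLLS[: config.n_atolls]:
        for i in range(config.sites_per_atoll):
            chl = float(rng.lognormal(config.chl_mu_log, config.chl_sigma_log))
            hotspot = bool(rng.random() < config.hotspot_probability)
            if hotspot:
                chl *= config.hotspot_multiplier
            slope = float(rng.uniform(*config.slope_range))
            rows.append({
                "site_id": f"{atoll}-{i + 1}",
                "atoll": atoll,
                "chl_mean": chl,
                "chl_sd": abs(rng.normal(0.1, 0.03)) * chl,
                "slope_deg": slope,
                "hotspot": hotspot,
            })
    return pd.DataFrame(rows)


def _linear_predictor(eff: dict, depth01: float, slope_rad: float, chl: float) -> float:
    return (eff["const"] + eff["depth"] * depth01 + eff["slope"] * slope_rad
            + eff["chl"] * chl + eff["depth:slope"] * depth01 * slope_rad
            + eff["depth:chl"] * depth01 * chl + eff["slope:chl"] * slope_rad * chl)


def generate_fish(config: SimConfig, sites: pd.DataFrame, seed=None):
    """Per-fish tissue and otolith tables for every site-depth cell.

    Returns (tissue, otoliths): tissue has the pipeline's input columns
    (fish_id, site_id, atoll, depth, fl_mm, tl_mm, d13c, d15n, pct_c, pct_n,
    cn); otoliths carry three-read daily increment counts consistent with the
    true age plus multiplicative reader error.  The tissue δ¹³C column is the
    *untreated* value: the generator works backwards from the target
    normalized value for fish whose C:N exceeds the lipid threshold, so the
    pipeline's own correction step reproduces the intended isoscape.
    """
    rng = _spawn(config.seed if seed is None else seed, "fish")
    tissue_rows, oto_rows = [], []
    for s in sites.itertuples(index=False):
        slope_rad = float(np.deg2rad(s.slope_deg))
        for depth in DEPTHS:
            depth01 = 1.0 if depth == "moderate" else 0.0
            eta_kmax = _linear_predictor(config.effects["kmax"], depth01,
                                         slope_rad, s.chl_mean)
            mu_kmax = float(np.exp(eta_kmax))
            shape = 1.0 / config.kmax_dispersion
            cell_kmax = float(rng.gamma(shape, mu_kmax / shape))
            l_inf = float(max(rng.normal(config.l_inf_cm, config.l_inf_sd), 3.0))
            # invert the maximum-size standardization to get the cell's k
            cell_k = cell_kmax / (config.l_max_cm / l_inf) ** config.s_l
            cell_means = {
                resp: _linear_predictor(config.effects[resp], depth01, slope_rad,
                                        s.chl_mean)
                for resp in ("d15n", "d13c", "cn")
            }
            # growth–δ¹⁵N coupling acts on the cell's Kmax *residual*, so the
            # registered covariate coefficients on δ¹⁵N stay interpretable
            cell_means["d15n"] += config.growth_d15n_slope * (cell_kmax - mu_kmax)
            for j in range(config.fish_per_cell):
                fish_id = f"{s.site_id}_{depth[0]}{j + 1:02d}"
                age = float(rng.uniform(*config.age_range_yr))
                fl_cm = float(vbgf(age, l_inf, cell_k, config.t0)
                              + rng.normal(0.0, config.length_noise_sd_cm))
                fl_cm = max(fl_cm, 0.5)
                cn = max(cell_means["cn"] + rng.normal(0.0, config.noise_sds["cn"]),
                         config.cn_floor)
                d15n = cell_means["d15n"] + rng.normal(0.0, config.noise_sds["d15n"])
                d13c_norm = cell_means["d13c"] + rng.normal(0.0, config.noise_sds["d13c"])
                # store the untreated value so the pipeline's lipid correction
                # lands on the intended normalized isoscape
                d13c_raw = d13c_norm + 3.32 - 0.99 * cn if cn > 3.5 else d13c_norm
                pct_n = float(rng.normal(13.0, 0.8))
                pct_c = cn * pct_n
                tissue_rows.append({
                    "fish_id": fish_id, "site_id": s.site_id, "atoll": s.atoll,
                    "depth": depth, "fl_mm": round(fl_cm * 10.0, 1),
                    "tl_mm": round(fl_cm * 10.0 * 1.08, 1),
                    "d13c": round(d13c_raw, 3), "d15n": round(d15n, 3),
                    "pct_c": round(pct_c, 2), "pct_n": round(pct_n, 2),
                    "cn": round(cn, 4), "true_age": age,
                })
                days = age * 365.0
                counts = np.rint(days * (1.0 + rng.normal(
                    0.0, config.reader_error_cv, size=3))).astype(int)
                counts = np.maximum(counts, 1)
                oto_rows.append({"fish_id": fish_id, "method": "daily_increments",
                                 "count1": counts[0], "count2": counts[1],
                                 "count3": counts[2]})
    return pd.DataFrame(tissue_rows), pd.DataFrame(oto_rows)


def generate_baselines(config: SimConfig, sites: pd.DataFrame, seed=None) -> pd.DataFrame:
    """POM and zooplankton baseline isotope samples per site.

    Zooplankton sit one trophic level below fish, POM two levels below, via
    the configured per-level δ¹⁵N and δ¹³C offsets.
    """
    rng = _spawn(config.seed if seed is None else seed, "baselines")
    fish_d15n = config.effects["d15n"]["const"]
    fish_d13c = config.effects["d13c"]["const"]
    sd_c, sd_n = config.baseline_sd
    rows = []
    for s in sites.itertuples(index=False):
        for kind, levels, n_rep in (("zooplankton", 1, config.zoo_per_site),
                                    ("POM", 2, config.pom_per_site)):
            for rep in range(n_rep):
                rows.append({
                    "kind": kind,
                    "site_id": s.site_id,
                    "replicate": rep + 1,
                    "d13c": round(fish_d13c - levels * config.trophic_d13c_offset
                                  + rng.normal(0.0, sd_c), 3),
                    "d15n": round(fish_d15n - levels * config.trophic_d15n_offset
                                  + rng.normal(0.0, sd_n), 3),
                })
    return pd.DataFrame(rows)


def generate_transects(config: SimConfig, sites: pd.DataFrame, seed=None,
                       n_readings: int = 12) -> pd.DataFrame:
    """Georeferenced depth transects whose fitted slope recovers each site's
    slope_deg (small depth noise, readings from ~5 m down to the 70 m
    transponder limit)."""
    rng = _spawn(config.seed if seed is None else seed, "transects")
    rows = []
    lat0, lon0 = -5.3, 71.8  # nominal atoll region
    for i, s in enumerate(sites.itertuples(index=False)):
        grade = np.tan(np.deg2rad(-s.slope_deg))  # depth gain per metre, > 0
        span_m = (70.0 - 5.0) / grade
        dists = np.linspace(0.0, span_m, n_readings)
        lat_site = lat0 + 0.02 * i
        # eastward track: metres → degrees longitude at this latitude
        dlon = dists / (EARTH_M_PER_DEG * np.cos(np.deg2rad(lat_site)))
        depths = 5.0 + grade * dists + rng.normal(0.0, 0.4, size=n_readings)
        for d, lon_off, z in zip(dists, dlon, depths):
            rows.append({"site_id": s.site_id, "lat": lat_site,
                         "lon": lon0 + lon_off, "depth_m": round(max(z, 0.5), 2)})
    return pd.DataFrame(rows)


EARTH_M_PER_DEG = 6_371_000.0 * np.pi / 180.0


def generate_chl_grids(config: SimConfig, sites: pd.DataFrame, seed=None):
    """3×3 chlorophyll pixel boxes + bathymetry per site.

    Pixel values scatter around the site chl mean; the inshore edge of each
    box is shallower than the 30 m isobath so masking is exercised.
    Returns a dict site_id → (values 3×3, bathymetry 3×3).
    """
    rng = _spawn(config.seed if seed is None else seed, "grids")
    grids = {}
    for s in sites.itertuples(index=False):
        vals = rng.normal(s.chl_mean, 0.08 * s.chl_mean, size=(3, 3))
        vals = np.clip(vals, 0.01, None)
        bathy = np.full((3, 3), 60.0) + rng.normal(0.0, 5.0, size=(3, 3))
        bathy[:, 0] = rng.uniform(10.0, 25.0, size=3)  # inshore column masked
        grids[s.site_id] = (vals, bathy)
    return grids


def write_dataset(config: SimConfig, out_dir, seed=None) -> dict:
    """Generate every pipeline input CSV into ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    sites = generate_sites(config, seed)
    tissue, otoliths = generate_fish(config, sites, seed)
    baselines = generate_baselines(config, sites, seed)
    transects = generate_transects(config, sites, seed)
    grids = generate_chl_grids(config, sites, seed)
    paths = {}
    for name, df in (("sites", sites), ("tissue", tissue), ("otoliths", otoliths),
                     ("baselines", baselines), ("transects", transects)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    grid_rows = []
    for site_id, (vals, bathy) in grids.items():
        for r in range(3):
            for c in range(3):
                grid_rows.append({"site_id": site_id, "row": r, "col": c,
                                  "chl": vals[r, c], "depth_m": bathy[r, c]})
    p = out / "chl_grids.csv"
    pd.DataFrame(grid_rows).to_csv(p, index=False)
    paths["chl_grids"] = str(p)
    return paths
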