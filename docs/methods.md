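# Methods notes

This note records the models `reefiso` implements, the defaults it ships,
the choices made where the underlying methodology is genuinely open, and
what the synthetic-data tests do and do not establish.

## Isotope processing

Delta values are carried in per mil throughout; raw heavy/light ratios are
accepted (`compute_delta`) but optional, since deposited datasets normally
ship delta values directly. The C:N condition proxy is the **mass-percent**
ratio (a molar switch exists but is off by default). Lipid normalization of
δ¹³C uses the linear correction δ¹³C − 3.32 + 0.99·C:N with a **strict**
threshold: C:N = 3.5 exactly is not corrected. The correction is
discontinuous at the threshold by construction (jump of −3.32 + 0.99·3.5 =
+0.145‰); downstream analyses always use the normalized column, including
for fish whose values were never corrected. A supplied C:N is trusted even
without %C/%N; when both percentages are present the ratio is recomputed and
disagreement beyond 0.01 triggers a warning, not an error — mass-spec
exports frequently round differently.

## Isotopic niche (SEA, SEA_c, SEA_b)

The standard ellipse is the 1-sd ellipse of the fitted bivariate normal;
its area is π√(det Σ̂) with Σ̂ the n−1 sample covariance, and SEA_c applies
the (n−1)/(n−2) small-sample factor. The "40%" ellipse drawn in figures is
the chi-square(2) quantile contour at the standard ellipse's true coverage
1 − e^(−1/2) ≈ 39.35% (q = 1); area statistics always refer to the 1-sd
ellipse.

The Bayesian posterior replaces an MCMC sampler with the **conjugate
normal–inverse-Wishart** posterior under a vague prior (μ₀ = sample mean,
κ₀ = 10⁻³, ν₀ = 2, Λ₀ = 10⁻³·I). This is a deliberate substitution for the
common Gibbs-sampling implementations of the same target quantity: the
posterior is available in closed form, needs no convergence diagnostics,
and coincides with the sampling-based posterior as n grows. The guard is a
large-n consistency test (500 standard-normal points → posterior mean
within 5% of π). With three or four fish in a group the prior's vagueness
matters and SEA_b is wide — as it should be.

The posterior mode is estimated by Gaussian KDE with Silverman bandwidth
over the draws; credible intervals are highest-density intervals at
50/75/95%. Group comparisons pair draws by index (independent seeds per
group); ties count 0.5; "significant" means P(A > B) ≥ 0.95 or ≤ 0.05.
Letter codes in grouped output are maximal cliques of the non-significance
graph, so two groups share a letter iff their areas are statistically
indistinguishable.

## Growth and K_max

Ageing rules: annual counts need two agreeing reads (a third read breaks
ties; no agreement excludes the fish); daily-increment ages are the mean of
three counts ÷ 365 (365.25 would change ages by < 0.07%, immaterial at ages
under 3 yr), and **the whole sample** is excluded when any count deviates
from the median by more than 10% of the median — the rule operates on
samples, not individual counts.

VBGF fitting is bounded trust-region least squares: initialization
L∞ = 1.1×max FL, k = 1, t₀ = 0; bounds L∞ ∈ (0, 3×max FL], k ∈ (0, 10],
t₀ ∈ [−2, 1]; step tolerance 1e−10. A solution pinned to a bound is
reported with `converged = False` — growth curves resting on box edges are
artefacts of sparse age coverage, and cells with fewer than 5 aged fish are
refused outright. Lengths recorded in mm are converted to cm before
fitting so parameters are in the equation's conventional units.

The maximum-size standardization uses K_max = k·(L_max/L∞)^{s_L} with
s_L = −2 by default — the classical slope of the log k ~ log L∞
growth-performance relationship. Both s_L and L_max are explicit arguments
because their canonical values are species-specific and maintained outside
this package; the identity K_max = k at L∞ = L_max holds for any s_L.

## Site covariates

Slope comes from a single OLS fit of depth on cumulative haversine
along-track distance (Earth radius 6 371 000 m) — no piecewise or spline
fitting, since transects are short and run perpendicular to the reef; the
reported r² flags profiles where a single angle is a poor summary. Readings
deeper than 70 m (hand-held transponder limit) are dropped first. The sign
convention is negative-down, so seaward-descending reefs give angles in
(−90°, 0).

The 30 m isobath mask uses a strict inequality: a pixel at exactly 30 m is
kept (configurable). Chlorophyll summaries are the mean and n−1 sd of the
unmasked pixels of the 3×3 box; one surviving pixel yields a mean with a
missing sd, zero surviving pixels a missing covariate. Raw satellite
processing (Level-1→2, habitat classification) is out of scope: the module
consumes a pre-gridded chlorophyll field plus bathymetry.

## Hypothesis battery

Responses are modelled at **site-depth mean level** (30–36 rows), not per
fish: the registered design treats the cell as the experimental unit and
within-cell fish as pseudo-replicates. Families: gaussian-identity for
δ¹⁵N, δ¹³C and C:N; gamma for K_max with a **log link** (the canonical
inverse link is numerically fragile at these dispersions; the link is
configurable). Factors are treatment-coded with shallow depth and the
alphabetically first atoll as references.

The slope covariate is stored in degrees but enters the models (and the
synthetic generator) in **radians** by default. The angle unit used in the
registered analyses of this design is not standardized across studies;
radians put slope coefficient magnitudes on a scale comparable to the other
covariates, and the transform is a config switch (`degrees`, `radians`,
`z`). Chlorophyll enters in mg m⁻³ untransformed; an optional z-scoring
switch exists because covariate scaling conventions differ between groups.

Partial η² is deviance-based with Type-II term deletion:
pη² = (D_reduced − D_full)/D_reduced, where the reduced model omits the
term and every higher-order term containing it. For gaussian models this is
exactly SS_term/(SS_term + SS_resid). Type-III and per-fish variants would
give different values; since the convention is ambiguous the effect sizes
are reported as descriptive, not inferential, quantities.

BH FDR at q = 0.10 is applied **jointly across the twenty GLM coefficient
p-values H1–H20** (one battery-wide family); the four permutation
hypotheses H21–H24 are judged at α = 0.05 without FDR correction. The
family definition is the main open choice in this design; it is exposed as
the battery's `q`/`alpha` parameters and the hypothesis table itself is an
injectable argument.

The permutation scheme swaps each site's shallow/moderate **blocks**
independently with probability ½, keeping fish within blocks so
within-site correlation survives under the null. When 2^(#sites) ≤ n_perm
the null is enumerated exactly; otherwise 9999 sampled permutations with
the add-one two-sided p-value. The alternative — permuting depth labels
across the pooled block list — is available via the `method` argument's
building blocks but not default, as independent per-site swaps are the
natural exchangeability structure for paired depths.

Registered directions: verdicts are a pure function of the FDR/α decision
and the coefficient's sign against the pre-registered direction
(`supported`, `not supported`, `not supported (direction reversed)`).
Interaction hypotheses (H9–H20) are registered two-sided ("is influenced
by"), so any significant sign supports them. The expected sign for the
chl-a effect on δ¹³C (H4) is encoded **negative** (depletion with
increasing production, consistent with reliance on deep-water-derived
production); the expected-sign table is user-replaceable for designs that
register the opposite.

## The synthetic world

Defaults state the emulated design: 3 atolls × 6 sites × 2 depths × 10
fish (360 fish). Site chlorophyll-a is log-normal (median 0.10 mg m⁻³,
σ_log = 0.30, putting ~95% of sites in 0.055–0.18 mg m⁻³) with a
per-site 1/18 probability of a ×3 "hotspot", mirroring a domain where one
site in eighteen sat far in the right tail. Slopes are uniform(−70°, −16°).
Growth: cell K_max is gamma-distributed (dispersion 0.05) around a log-link
linear predictor; k follows by inverting the maximum-size standardization
(L∞ ≈ 6.5 cm, L_max = 7 cm); fork lengths add 0.25 cm Gaussian noise; ages
are uniform(0.2, 3) yr; otolith triplets multiply true age in days by 3%
reader error. Response noise sds (fish level) are 0.5‰ (δ¹⁵N), 0.35‰
(δ¹³C), 0.12 (C:N) — the C:N value reproduces a cell-level residual sd of
≈ 0.037 at n = 10, the scale typical of registered designs of this kind.
The "paper-like" preset's effect coefficients carry the study-like signs
(negative chl-a on δ¹³C, positive depth:chl on C:N, …); magnitudes are
plain configuration. δ¹⁵N is additionally coupled to the cell's K_max
**residual** (−1.5‰ per unit K_max), so faster-growing cells are depleted
in δ¹⁵N without distorting the registered covariate structure. Trophic
baselines sit 3.4‰ (δ¹⁵N) and 0.8‰ (δ¹³C) per level below fish — the 3.4‰
per-level shift is the conventional literature default, not an estimate.

What a green synthetic test establishes: that each stage implements its
stated rule, that the battery recovers injected effects at realistic power,
and that the chain is deterministic under a seed. What it does not
establish: anything about real tissue chemistry (no instrument drift, no
within-run error structure), real satellite fields (no cloud masks,
no spatial autocorrelation), or real growth (no seasonal banding ambiguity,
no size-selective sampling).

## Numerical choices

- Ellipse degeneracy: smallest covariance eigenvalue ≤ 1e−12 × largest ⇒
  area 0 with a degenerate flag, rather than a tiny spurious area.
- Inverse-Wishart sampling via scipy; areas of draws are strictly positive
  because posterior scale matrices are positive definite (Λ₀ > 0).
- Permutation p-values compare |T*| ≥ |T_obs| with a 1e−12 relative
  tolerance so exact ties (e.g. the identity permutation) always count.
- GLM rank deficiency raises an error naming the aliased columns instead of
  silently dropping them.
- All randomness descends from one root seed through named
  `SeedSequence` spawns (simulation streams: sites/fish/baselines/
  transects/grids; pipeline stages: niche/battery), so single stages can be
  re-run reproducibly.

## Known limitations

- The normal–inverse-Wishart SEA_b is exchangeable with sampler-based
  implementations only up to prior choice; with n < 10 per group the two
  can differ visibly.
- Partial η² for gamma models uses the deviance analogue, which has no
  unique finite-sample definition.
- The battery assumes independent site-depth cells; spatial autocorrelation
  between nearby sites is not modelled.
- The slope estimate compresses a possibly non-linear reef profile into one
  angle; r² is the only non-linearity diagnostic.
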