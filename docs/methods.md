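# Methods

## Moisture ratio and the drying-model layer

All drying-model work happens on the dimensionless moisture ratio
MR = (X − Xe)/(X0 − Xe), with dry-basis decimal moisture and time in
hours (rate constants in h⁻¹); conversion to seconds happens only at
the diffusivity boundary. A `DryingCurve` enforces strictly increasing
time starting at 0, moisture in (0, 1), and a first sample equal to the
stated initial moisture X0.

The equilibrium moisture Xe is ideally supplied by the user (measured
or taken from a sorption isotherm). When absent, the package falls back
to Xe = 0.9 · min(X) with a warning — a pragmatic floor that keeps MR
well defined without asserting an isotherm model. Noisy tail samples at
or below Xe are clipped to MR = 0 with a warning rather than rejected,
since real curves routinely dip below the nominal equilibrium.

Eleven closed-form thin-layer models are registered. Default parameter
boxes are k, k₀, k₁ ∈ (10⁻⁶, 10³) h⁻¹, n ∈ (10⁻⁶, 10), and
a, b, c ∈ (−50, 50): wide enough to bracket any plausible fitted value
for grain drying at 80–120 °C with ample margin, tight enough to keep
the optimiser and the grid oracle on a bounded box.

## Fitting engine

`fit_model` minimises the sum of squared residuals with scipy's bounded
trust-region-reflective least squares rather than a quasi-Newton
search; on these smooth low-dimensional problems both find the same
minimiser, and TRF handles box bounds natively. The contract is "global
SSE minimum within bounds", not a named algorithm. Determinism: given
(data, model, init, n_starts, seed) the result is reproducible.

Initialisation is model-aware: rate-type parameters (k, k₀, k₁) start
from the log-linear slope of −ln MR against t when the data support it
(staggered ×0.6/×1.6 for multi-rate models, to break term symmetry);
shape and amplitude parameters start at their registry defaults (a ≈ 1,
n = 1, b, c ≈ 0). Multi-start (default 8) applies seeded multiplicative
jitter U(0.5, 2) per parameter; the best SSE wins. Total failure of
every start raises; non-convergence flags the result instead.

Fit statistics follow drying-literature conventions: R² as a
percentage, mean relative error P = (100/n)Σ|Y−Ŷ|/Y (undefined, and
reported as NaN inside `fit_model`, when an observation is zero — the
standalone function raises instead), and average estimated error
SE = √(SSE/GLR) with GLR = n − p. Jacobian-based asymptotic standard
errors and t statistics for the coefficients are computed and reported
but deliberately excluded from the ranking, since there is no reference
scale to compare them against.

### Residual classification

Residual "randomness" is judged by a runs test on residual signs, with
zeros inheriting the preceding sign and an all-zero vector (perfect
fit) random by convention. The test is **one-sided**: a fit is
*tendentious* when the number of runs is significantly too small
(systematic drift, p = P(R ≤ r_obs) < 0.05 under the exact conditional
runs distribution). An excess of runs — over-alternation — is not
evidence of trend, so it never penalises a model; a two-sided rule
would flag a strictly alternating residual pattern as non-random, which
is the opposite of what residual diagnostics ask here. The exact
combinatorial distribution is used at every n (no normal
approximation), computed stably through log-binomials.

### Ranking and verdicts

Models are ordered lexicographically: (1) random residuals first,
(2) P below the acceptability threshold (default 10 %, the customary
drying-literature cutoff; configurable), (3) smallest SE, (4) largest
R². Verdicts: *rejected* for tendentious residuals, *marginal* for
P at or above threshold, otherwise *acceptable*.

### Grid oracle

`brute_force_fit` is a testing oracle for ≤ 2-parameter models: a full
grid over the parameter box, repeatedly re-gridded onto a ±10-cell
window around the incumbent best until the step is below the requested
resolution. The wide window matters: on ridge-shaped SSE surfaces
(strongly correlated parameters such as intercept/slope pairs) the best
coarse-grid point can sit several cells from the continuous minimiser
along the ridge. The oracle shares nothing with the trust-region path
beyond the model closed forms.

## Shrinkage

Grain volume is the ellipsoid approximation V = πabc/6 from the three
calliper axes; unit shrinkage divides each volume by the first. Six
empirical ψ(X) forms are registered with coefficients in (−50, 50).
The Lang & Sokhansanj slope β₁ is fitted as a single free scalar (one
slope per drying condition, matching how such coefficients are
reported); its full covariate expansion a + b·UR + c·T is out of scope.
Rahman and the linear model are exact re-parameterisations of each
other (a_line = a_rahman − β₂X0, b_line = β₂), which the tests use as an
internal consistency check.

Published shrinkage coefficient sets are sometimes internally
inconsistent (an intercept implying ψ(X0) ≈ 0.27 rather than 1);
`ShrinkageSeries.validate_physical` therefore *warns* on ψ outside
(0, 1.2] or ψ(X0) far from 1 instead of raising, so such sets remain
usable for parameter-recovery work. The Corrêa form 1/(a + b·eˣ) maps
its invalid region (denominator ≤ 0) to a large finite penalty inside
the optimiser and raises a domain error only at the public evaluation
surface.

## Effective diffusivity

The Fick-sphere series is truncated at N terms; at t = 0 the
truncation error is bounded by (6/π²)Σ_{n>N}1/n² < 6/(π²N) and decays
geometrically for t > 0. Defaults: N = 1000 for generating data near
t = 0, N = 50 for fitting — at N = 50 the t = 0 deficit is ≈ 0.012 and
negligible one sample later at drying-relevant D/R².

The method of slopes regresses ln MR on t(s) restricted to
0 < MR < 0.6 (configurable); the window keeps the regression inside the
first-term regime, where ln MR is linear with slope −Dπ²/R². The
series fit minimises the SSE of the truncated series over
D ∈ [10⁻¹³, 10⁻⁷] m² s⁻¹ in log₁₀ space with a bounded scalar
minimiser (tolerance 10⁻¹⁰ in log-units, i.e. ≪ 0.01 % in D).

The equivalent sphere radius is not usually reported; the default
policy derives it from the grain axes as the volume-preserving
geometric mean (abc)^{1/3}/2, configurable wherever a radius is
accepted. The Arrhenius stage is an ordinary regression of ln D on
1/T: E = −slope·R_gas (reported in kJ kmol⁻¹, R_gas = 8314 J kmol⁻¹
K⁻¹), A = exp(intercept). Identical D at all temperatures short-circuits
to E = 0, A = D.

## Storage multivariate stage

The clustered objects are treatment means (one row per factor
combination, averaging replicates) over the five quality variables —
dendrogram leaves label treatments, so means rather than replicates are
the natural unit. Variables are standardised to zero mean and unit
sample SD (ddof = 1); a constant column is a contract error naming the
column. Clustering is agglomerative Ward in the squared-Euclidean
minimum-variance ("Ward.D2"-equivalent) dialect via
scipy.cluster.hierarchy; dialects differ between packages, so the
choice is stated here. The number of groups k is user-specified
(default 4); no automatic cut criterion is invented. Per-group Pearson
correlations are computed on the *raw* (unstandardised) treatment
means; clusters with fewer than three members, and variables constant
within a cluster, yield NaN entries rather than zeros.

Tukey compact letters: one-way ANOVA/Tukey HSD (statsmodels) followed
by a hand-implemented insert-and-absorb compact-letter display; levels
sharing a letter do not differ at the chosen α (0.05 and 0.01
supported, as factorial storage tables conventionally report both).
The all-identical edge case short-circuits to a single shared letter.

## Synthetic data

Generators are pure functions of (configuration, seed) using numpy's
`default_rng`. Noise is additive Gaussian on the measured scale,
independent across samples — the simplest defensible error model in the
absence of replicate-level error structure; SDs are configurable.

The drying generator inverts MR to moisture (X = Xe + MR·(X0 − Xe)),
leaves the t = 0 sample noise-free so the curve starts exactly at X0,
and clips to (Xe, X0]. Because the curve contract pins the first sample
to X0, generator parameter sets must satisfy MR(0) = 1; non-normalised
published sets are exercised through direct closed-form fits instead.

The storage generator plants a known group structure: the six (storage
temperature, package) cells map to four severity tiers —
{15 °C·P, 15 °C·PL} best, {23 °C·PL}, {23 °C·P, 30 °C·PL}, {30 °C·P}
worst — with additive tier effects on all five variables (conductivity
and acidity rise, oil and protein fall with severity). Baselines are
the reference-treatment values of a real storage trial (oil 25.89 %,
protein 35.69 %, acidity 5.54 mL, conductivity 191 µS cm⁻¹ g⁻¹,
moisture 10.31 % d.b.), and the drying-temperature and harvest offsets
keep the sign and ordering observed in such trials. Two deliberate
departures from realism: (1) severity effects are present from month 0
(in a real trial storage effects accumulate from zero), so that the
planted partition is a well-defined labelling of all 144 treatments;
(2) secondary effects (monthly trends, drying-temperature and harvest
offsets) are compressed to roughly a quarter to a half of realistic
month-8 spreads, because all effects push along the same degradation
direction and paper-scale secondary spreads would overlap adjacent
severity tiers. Passing cluster-recovery tests therefore demonstrates
that the pipeline recovers a separable planted structure — not that
real storage data cluster this cleanly. Correlation-sign checks
(conductivity negative against oil/protein, oil–protein positive) are
robust to this compression since every systematic effect is
sign-aligned with the degradation direction.

## Problem sizes and numerical choices

Recovery tests use 11–12-point curves (a 15-min sampling grid over a
2.6 h drying run), 12-point shrinkage series over 0.23 → 0.11 d.b.,
32-point diffusion curves (5-min grid over 2.6 h), and the full
432-record storage factorial; the oracle-equivalence suite draws 20
random noiseless datasets round-robin across the twelve 1–2-parameter
models at grid step 10⁻³. Tolerances: printed-parameter refits to
≤ 10⁻³ relative; series-fit diffusivity to ≤ 0.01 %, slopes to ≤ 1 %
(the slopes method carries a small first-term-truncation bias by
construction); statistic formulas to 10⁻¹²  against literal
re-implementations.

## Known limitations

- No sorption-isotherm modelling: Xe is an input, and the fallback
  policy is a heuristic.
- No moisture-dependent or shrinkage-coupled diffusivity; the sphere
  series assumes constant D, isotropic geometry and negligible external
  resistance.
- Weighted or autocorrelation-robust regression is out of scope; all
  fits are ordinary least squares.
- The runs-test α (0.05) and the P-acceptability threshold (10 %) are
  conventions, exposed as parameters.
- The storage generator is additive with independent Gaussian noise; it
  does not model deterioration kinetics, variance heterogeneity, or
  replicate correlation.
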