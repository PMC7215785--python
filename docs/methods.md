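# Methods

## Model

Severity is a three-level ordered outcome.  The latent propensity of crash
*i* on segment *m* is z_i = β·x_i + φ_m + ε_i with a standard logistic
residual; the observed level is 1 (light) if z ≤ 0, 2 (medium) if
0 < z ≤ μ2_i, and 3 (severe) otherwise, with μ2_i = exp(α·z_i) > 0.  Fixing
the lower threshold at 0 while the intercept stays in β identifies the
location; the exponential link keeps the threshold positive without
constraining α.  Integrating the logistic residual gives closed-form
category probabilities

    p1 = logistic(−η),  p3 = logistic(η − μ2),  p2 = 1 − p1 − p3,   η = β·x + φ_m.

p2 is computed by complement rather than by the equivalent product form:
the two are algebraically identical (the product form is kept as a test
oracle) but the complement avoids exp(exp(·)) overflow.  Linear predictors
are clipped at ±30 — probabilities are saturated to machine precision far
inside that range — and per-record probabilities are floored at 1e−300
before the log.  Both guards log a warning once per process.

The non-spatial model is the φ = 0 special case and is fitted by the same
machinery; with a constant-only threshold the model further reduces to a
standard proportional-odds logit, which the test suite exploits as an
independent maximum-likelihood cross-check (statsmodels `OrderedModel`).

## CAR prior and identification

Segment effects follow the intrinsic CAR prior: conditionally,
φ_m | φ_−m ~ N(mean of neighbours, 1/(τφ · degree)); jointly, up to a
constant,

    log p(φ | τφ) = (df/2)·log τφ − (τφ/2)·Σ_edges (φ_m − φ_n)²,

where df = Σ_components (size − 1) accounts for the rank deficiency (the
density is flat along each component's constant direction).  Getting df
right matters: it enters the Gamma full conditional of τφ.

Identification convention: the intercept stays in β and the field is
recentred to mean zero (over non-island segments) after every sweep, with
the intercept absorbing the removed level so the likelihood is untouched.
On connected graphs — the default chain adjacency of a linear corridor —
this pins the field completely.  On disconnected user graphs the
between-component contrasts are identified only through the likelihood;
reported results should then be restricted to identified quantities
(β, α, sd(φ)).  Degree-0 segments ("islands") have no defined CAR
conditional; their φ is pinned at 0, they are excluded from df, and the
spatial model refuses to fit crashes assigned to an island (the recentring
compensation would otherwise alter their likelihood contribution).

sd(φ), the per-draw sample standard deviation of the field, is the
reported summary of spatial-correlation strength: unlike τφ it is an
identified, directly interpretable quantity on the propensity scale.

## Priors and chain protocol

Coefficients: Normal(0, 10⁴).  Spatial precision: Gamma(0.01, 0.01).  The
reference protocol is a single chain of 60,000 sweeps with the first 50,000
discarded (`McmcConfig()` defaults; `--full-protocol` in the CLI).  Desk
work — including the package's own acceptance experiments — uses 10,000
sweeps with 5,000 burn-in, the CLI default, which the convergence
diagnostics below justify at the default study scale (n = 1424, M = 154).

## Sampler

Adaptive Metropolis-within-Gibbs.  One sweep:

1. each β then α coordinate: Gaussian random-walk Metropolis, per-coordinate
   step sizes adapted toward 0.44 acceptance during burn-in only;
2. one joint random-walk update of the full coefficient vector using the
   empirical covariance accumulated during burn-in (scaled 2.38²/d, target
   0.25) — coordinate-wise moves alone crawl along the correlated
   propensity/threshold-intercept direction;
3. spatial model: φ updated in graph-colour blocks (no two neighbours
   simultaneously, so the block update is a valid set of independent
   single-site Metropolis moves), each segment's ratio combining its crashes'
   likelihood terms with the local CAR contribution;
4. recentring (level into the intercept), then a multiplicative field
   rescale φ → sφ with log-symmetric s and Jacobian s^df.  The order is
   load-bearing: rescaling *before* recentring would scale the flat level
   direction, which is inconsistent with the s^df Jacobian and measurably
   biases the field (caught by the dense-grid oracle test);
5. Gibbs draw of τφ from Gamma(a + df/2, b + ½Σ(Δφ)²), followed by a joint
   ridge move (φ, τφ) → (sφ, τφ/s²) along which the CAR prior is invariant,
   so only the likelihood and the Gamma prior enter its ratio.

Internally the sampler works in covariate-centred coordinates: slopes are
unchanged, the intercept maps back exactly (β0 = β0ᶜ − x̄·β), the likelihood
is identical, and the prior is still evaluated on the original
coefficients — but the intercept decorrelates from the slopes, which is
what makes the coordinate-wise moves mix (EMS response time, with mean
≈ 19 min, would otherwise tie its coefficient tightly to the intercept).

Initialisation is all-zero (inside the support, reproducible); all
adaptation freezes at the end of burn-in, preserving the stationary
distribution of the retained draws.  All randomness flows from one integer
seed; fits are bit-reproducible.

Correctness evidence: on a 5-record, 2-segment toy problem the sampler's
posterior means match a dense-grid quadrature of the exact posterior (with
τφ integrated analytically) within Monte-Carlo error; an empty dataset
reproduces the prior; the proportional-odds special case matches the
maximum-likelihood fit.

## Convergence reporting

Monte-Carlo error uses batch means with ⌊√N⌋-sized batches; the reported
diagnostic is the ratio of MC error to posterior SD with the conventional
0.05 rule of thumb.  The rule is applied to the identified reported
quantities — β, α and sd(φ).  τφ itself mixes more slowly (it is informed
only through the latent field) and its ratio is ≈ 0.08 at the desk
protocol; since all reporting is in terms of sd(φ), which passes, τφ is
displayed but not gated.  Equal-tailed 90% and 95% credible intervals are
reported, with significance flagged when an interval excludes zero.

## Assessment

DIC = D̄ + pD with pD = D̄ − D(θ̄), the plug-in deviance at the posterior
means of all sampled quantities including φ (Spiegelhalter's construction).
Gaps above 10 are treated as decisive, strictly ( |Δ| = 10 is
indeterminate).  Classification accuracy is the share of crashes whose
modal posterior-mean category probability equals the observed level, ties
resolved toward the less severe level (conservative).  CA is invariant to
monotone transformations of the probabilities and is reported rounded to
whole percent in CLI summaries, full precision in JSON.

## Marginal effects

Continuous variable x with propensity coefficient βx and threshold
coefficient αx (zero where absent):

    ∂p1/∂x = βx·p1(p1 − 1)
    ∂p3/∂x = (βx − αx·μ2)·p3(1 − p3)
    ∂p2/∂x = −∂p1/∂x − ∂p3/∂x.

Indicators use the 0→1 probability difference.  For mutually exclusive
indicator groups (crash type, time of day) the sibling indicators are held
at zero in *both* counterfactuals, so the contrast is "this level vs the
reference level" and no impossible covariate row is evaluated; the
alternative of zeroing siblings only in the switched-on scenario would
contaminate threshold-only indicators with their siblings' propensity
effects and destroy the structural zero on the light category.  Per-crash
effects are evaluated at plug-in posterior means (matching the single
point estimates conventional in this literature) and averaged over the
dataset; tables are in percentage points.  Structural consequence, used as
an acceptance check: a variable with βx = 0 has exactly zero effect on the
light share, and its medium and severe effects cancel.

## Synthetic data generator

The generator emulates the targeted study design, not any real corridor:

- 1424 crashes assigned uniformly at random to 154 chained segments
  (exposure weights optional; the source study does not report per-segment
  exposure);
- binary covariates from the published shares (professional driver 0.039,
  non-local vehicle 0.284, …); crash type and time of day as single
  categorical draws per group (rear-end 0.383, angle 0.162; morning 0.222,
  afternoon 0.372, evening 0.222) so indicator rows are never impossible;
  vehicle-type indicators stay independent Bernoulli — their published
  shares overlap, so they are not exclusive in the source data either;
- continuous covariates as normals at the published mean/SD, truncated at
  physical bounds (0 for wind, precipitation, visibility, EMS time and
  geometry; [0, 100] for humidity).  Truncation shifts realised moments;
  only marginal plausibility is claimed.  Hourly precipitation is heavily
  zero-inflated in reality (SD ≫ mean); a zero-inflated-exponential option
  (80% dry hours, matching overall mean) exercises the model under
  realistic skew;
- the spatial field drawn exactly from the intrinsic CAR on the
  sum-to-zero subspace (eigen-decomposition per component), with the
  default precision calibrated by linear algebra — τφ = tr(L⁺)/(M·sd²) —
  so the field sd is 0.5, the reported magnitude of the segment effect;
- outcomes from the exact generative mechanism with true coefficients set
  to the spatial model's published posterior means; the two intercepts
  (−0.15, 1.37) were calibrated once, by large-sample simulation, so the
  implied severity composition matches the published 53.1/43.6/3.3% split.

What the generator does **not** emulate: the real joint correlation
structure of weather and geometry covariates (only marginals and group
exclusivity), per-segment exposure differences, and measurement error in
covariates.  Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the model's own assumptions — not
robustness to the misspecifications real data would add.

## Acceptance experiment sizes

Parameter recovery runs 20 replicates at the full study scale with the
desk protocol; recovery is summarised as the fraction of
coefficient-replicate pairs whose true value falls in the 95% interval
(observed ≈ 95%, gate at 90%, with a per-coefficient floor of 80% — the
per-coefficient binomial noise at 20 replicates makes a hard per-coefficient
95% gate meaningless).  The DIC comparison reuses the same 20 replicates
(spatial wins in all) plus three no-signal replicates (field sd 0.005),
where the two models' DICs agree within the decisiveness threshold and the
non-spatial pD lands within 30% of the 18 sampled coefficients.

## Limitations

- Exactly three severity levels; no alternative links (probit, cloglog).
- Intrinsic CAR only; no proper-CAR ρ parameter, no multivariate CAR.
- Single-chain convergence assessment by the MC-error rule plus optional
  trace export; no cross-chain R̂ by default.
- Marginal-effect uncertainty is not propagated by default (plug-in
  posterior means); averaging effects over draws is available in the
  library but not surfaced in the CLI tables.
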