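# carlogit

Bayesian spatial generalized ordered logit models for freeway crash severity.

Crash severity on a freeway is an ordered outcome — light, medium, severe —
driven by weather at the hour of the crash, driver and vehicle attributes,
roadway geometry and emergency-response time, and it is spatially correlated:
crashes on adjacent roadway segments share unobserved conditions (terrain,
lighting, surface state).  `carlogit` is for safety researchers and
biostatisticians who want to estimate such models, compare the spatial and
non-spatial variants, and translate coefficients into interpretable changes
in category probabilities.

## The model

For crash *i* on segment *m*, the latent severity propensity is

    z_i = β·x_i + φ_m + ε_i,        ε_i ~ Logistic(0, 1)

with observed severity y = 1 if z ≤ 0, y = 2 if 0 < z ≤ μ2, y = 3 otherwise.
Unlike a standard ordered logit, the upper threshold varies with covariates,

    μ2_i = exp(α·z_i),

so a variable may shift probability between the medium and severe levels
without touching the light share — and a variable in both functions can move
the lightest and most severe categories in the *same* direction, which fixed
thresholds cannot express.

The segment effects φ carry an intrinsic conditional autoregressive (CAR)
prior over the binary first-order adjacency of the corridor: each φ_m, given
the rest, is Gaussian around its neighbours' average with precision τφ ×
(neighbour count).  Estimation is single-chain adaptive
Metropolis-within-Gibbs under diffuse priors (Normal(0, 10⁴) coefficients,
Gamma(0.01, 0.01) precision).  Models are assessed by DIC = D̄ + pD and by
classification accuracy, and interpreted through dataset-average marginal
effects (derivatives for continuous variables, 0→1 switches for indicators).

A synthetic-data generator reproduces the study design this package targets —
1424 crashes on 154 consecutive homogeneous segments, realistic covariate
marginals, a CAR field with sd ≈ 0.5 — so the entire pipeline runs and is
tested without any external data.

## Worked example

```python
from carlogit import simulate as sim
from carlogit.estimators import SpatialGeneralizedOrderedLogit

config = sim.study_config(seed=7)          # 1424 crashes, 154 segments
dataset, truth = sim.simulate_dataset(config)
frame = dataset.to_frame()
y = frame.pop("severity")

model = SpatialGeneralizedOrderedLogit(
    propensity_cols=list(config.propensity_cols),
    threshold_cols=list(config.threshold_cols),
    n_iter=10_000, burn_in=5_000, seed=1,
).fit(frame, y)

print(model.summary_.loc[["beta[precipitation]", "alpha[precipitation]", "sd_phi"],
                         ["mean", "sd", "q2.5", "q97.5", "sig95"]].round(3))
report = model.assess()
print(f"DIC {report.dic:.0f}  CA {100*report.classification_accuracy:.0f}%")
print(model.marginal_effects({"precipitation": "continuous",
                              "afternoon": "indicator"},
                             exclusive_groups=sim.DEFAULT_EXCLUSIVE_GROUPS).round(2))
```

Output (this exact run):

```
                       mean     sd   q2.5  q97.5  sig95
parameter
beta[precipitation]   0.029  0.029 -0.027  0.086  False
alpha[precipitation]  0.099  0.026  0.048  0.152   True
sd_phi                0.431  0.066  0.305  0.565   True
DIC 1824  CA 73%
                     kind  light  medium  severe
variable
precipitation  continuous   -0.5    1.35   -0.86
afternoon       indicator    0.0    5.30   -5.30
```

Reading it: precipitation significantly widens the medium band (positive
threshold coefficient), so one extra millimetre of hourly rain shifts about
0.5 percentage points of probability out of light crashes and 0.9 out of
severe crashes, into medium ones — the same-direction movement of the extreme
categories that motivates the flexible threshold.  `sd_phi` is the posterior
spread of the segment field; its interval excluding small values indicates
genuine spatial correlation.  Afternoon enters only the threshold, so its
effect on the light share is exactly zero.

The same pipeline is available from the shell:

```bash
carlogit run-study --seed 7 --out-dir study_out          # simulate → fit both
carlogit run-study --seed 7 --full-protocol ...            # 60k/50k chains
```

which writes coefficient tables for both models, the marginal-effect table,
a DIC comparison verdict and a run manifest.

## Layout

| module | contents |
| --- | --- |
| `carlogit.data_model` | crash records, severity coding, segment graphs, CSV I/O |
| `carlogit.simulate` | synthetic covariates, CAR field draws, outcome generation |
| `carlogit.likelihood` | thresholds, category probabilities, log-likelihood |
| `carlogit.car` | intrinsic CAR prior: conditionals, joint density, recentring |
| `carlogit.mcmc` | adaptive Metropolis-within-Gibbs, summaries, MC errors |
| `carlogit.assessment` | DIC, classification accuracy, model comparison |
| `carlogit.marginal_effects` | continuous/indicator effects, averaged tables |
| `carlogit.estimators` | scikit-learn-style `fit`/`predict_proba` wrappers |
| `carlogit.cli` | `simulate`, `fit`, `assess`, `compare`, `me`, `run-study` |

See `docs/methods.md` for modelling assumptions, identification conventions,
sampler design and known limitations.
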