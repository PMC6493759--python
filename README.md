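# gllvmpy

Likelihood-based estimation of **generalized linear latent variable models
(GLLVMs)** for multivariate abundance data — site × species matrices of
counts, presence–absences, or (for testing) continuous responses.

Each species' response is a GLM whose linear predictor is augmented with a
small number of shared latent site scores,

```
g(mu_ij) = alpha_i + beta0_j + x_i' beta_j + u_i' gamma_j,
u_i ~ N_d(0, I),  alpha_i ~ N(0, sigma^2)  (optional row effect),
```

which induces parsimonious cross-species correlation and doubles as a
model-based ordination. The latent-variable integral has no closed form for
non-normal responses; the package maximizes two closed-form approximations:

* **Laplace approximation (`la`)** — per-site Newton maximization of the
  joint log-density plus a log-determinant curvature correction; outer
  maximization over the model parameters with warm-started inner solves.
* **Variational approximation (`va`)** — a normal variational density per
  site; the Jensen lower bound is maximized jointly over model and
  variational parameters with analytic gradients (closed-form expectation
  for Poisson, Gauss–Hermite for Bernoulli and negative-binomial terms).

Families: `poisson` (log), `negative_binomial` (log, Var = μ + φμ²),
`bernoulli` (probit or logit), plus an internal `gaussian` family for which
both approximations are exact (used heavily as a test oracle).

Also included:

* **Data-driven starting values** (`res`): per-species GLM fits, randomized
  quantile (Dunn–Smyth) residuals, and a factor analysis of the residual
  matrix; `res3` (jittered multi-start), `zero`, and `random` variants.
* **Wald inference**: Hessian-based standard errors (block inverse over the
  joint parameter vector for VA), confidence intervals, latent-variable
  prediction errors.
* **Evaluation tools**: full-Procrustes error for latent scores/loadings,
  variation explained (VE) against an intercept-only null, and a
  resumable simulation-study harness (bias / RMSE / coverage / CI width).

## CLI

```sh
# simulate a dataset from a generated model
gllvmpy simulate --family poisson --num-lv 2 --n 100 --m 20 --k 2 --seed 1 --out sim/

# fit it (variational engine, res starting values)
gllvmpy fit --y sim/Y.csv --x sim/X.csv --family poisson --num-lv 2 \
    --method va --start res --seed 1 --out fit/

# compare starting-value strategies
gllvmpy starts --y sim/Y.csv --family poisson --num-lv 1 --out starts/

# run a simulation study from a design file
gllvmpy simstudy --design design.json --reps 50 --out study/ --resume
```

`fit` writes `estimates.csv` (estimate / SE / Wald interval per parameter),
`parameters.json`, `latents.csv`, `latent_sd.csv` and a reproducibility
`manifest.json`. Input matrices are delimited text with sites in rows, a
site-identifier first column and species names in the header; covariates are
aligned by site identifier (`--transpose` accepts species-in-rows files).

## Python API

```python
import gllvmpy as gv

spec = gv.ModelSpec(family="negative_binomial", n_lv=2)
data = gv.read_abundance("Y.csv", "X.csv", family="negative_binomial")
fit = gv.fit_model(data, spec, method="va", start="res", seed=1)
report = gv.standard_errors(fit)
latent, cov = gv.predict_latents_va(fit)
```

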