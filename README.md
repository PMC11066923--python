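# mbdecoda

Debiased differential-abundance testing for microbiome count tables.

## The problem

Sequencing counts are compositional: each sample's reads reflect its taxa's
absolute abundances only up to an unknown sample-specific sampling fraction.
A taxon can therefore look "differentially abundant" between groups purely
because the sampling fractions differ between groups. On top of that,
microbiome tables are sparse — many zeros are *structural* (the taxon is
absent) rather than undetected — and over-dispersed relative to a Poisson
model. Tests that ignore either effect lose power or inflate the false
discovery rate.

`mbdecoda` addresses both. Each count `Y_ik` (sample `i`, taxon `k`) follows
a zero-inflated negative binomial (ZINB) model

```
Z_ik ~ Bernoulli(eta_ik)            logit(eta_ik) = U_i' alpha_k
Y_ik | Z_ik = 1  = 0
Y_ik | Z_ik = 0  ~ NB(mu_ik, phi_k)  log(mu_ik) = d_i + X_i Delta_k + V_i' beta_k
```

where `d_i` is the sample-specific compositional offset, `X` the variable of
interest (binary or continuous), `U`/`V` optional covariate designs and
`Delta_k` the log fold change per unit of `X`. An EM algorithm (exact E-step
for the structural-zero posterior; fractional-response logistic and weighted
negative binomial block maximizations) estimates all parameters. Because
`d_i` and `Delta_k` are confounded along `X`, the fitted effects
`Delta_tilde_k` share one unknown additive bias `gamma`. Under sparse
signals, the null taxa cluster around `gamma`, so the **minimum coverage
interval (MCI)** — the shortest window containing `ceil(rho*K)` of the sorted
estimates (default `rho = 0.5`) — locates the cluster; its mean `gamma_hat`
estimates the bias and `Delta_hat_k = Delta_tilde_k - gamma_hat` is the
debiased effect. Each taxon is then tested with the modified t-statistic

```
t_k = Delta_hat_k / sqrt( var(Delta_tilde_k) + var(gamma_hat) )
```

with two-sided normal p-values and Benjamini–Hochberg FDR control.

The package also ships the simulation framework used to validate these
operating characteristics (gamma-mixture baseline abundances, sparse
symmetric fold changes, group-confounded offsets, ZINB or ZIP counts), so
power and empirical FDR are testable end to end without any external data.

## Worked example

Generate a synthetic study (50 samples, 100 taxa, 20% true signals, 30%
zero-inflation) and analyse it:

```
$ mbdecoda simulate --n 50 --k 100 --pi 0.2 --eta 0.3 --seed 7 --outdir demo
wrote counts.tsv, metadata.tsv, truth.tsv to demo

$ mbdecoda run --counts demo/counts.tsv --metadata demo/metadata.tsv \
      --variable group --output demo/results.tsv
tested 100 taxa, 19 significant at FDR 0.05 (gamma_hat = -0.5240); results in demo/results.tsv

$ head -4 demo/results.tsv
taxon  delta_tilde     delta_hat       se              t               pvalue          qvalue          significant
T1     -1.22222345727  -0.698205248779 0.199770014659  -3.08298250517  0.00204937202569 0.0136624801713 True
T2     -1.60467892987  -1.08066072139  0.185159781651  -5.05705062875  4.25790227395e-07 4.25790227395e-06 True
T3     -2.75105776014  -2.22703955166  0.216794605449  -9.21706840827  3.053337455e-20 7.63334363751e-19 True
```

`delta_tilde` is the raw (biased) log-fold-change estimate, `delta_hat` the
debiased one: here the MCI placed the null cluster at `gamma_hat = -0.524`
(window of 50 estimates spanning [-0.685, -0.345]), so roughly half a log
unit of apparent depletion in every taxon was compositional artefact, not
biology. At the 5% FDR all 19 discoveries in this run are true signals
(compare `demo/truth.tsv`). A JSON sidecar (`results.tsv.meta.json`) records
the configuration, `gamma_hat`, the MCI endpoints and iteration counts.

The same pipeline is available in Python:

```python
from mbdecoda import SimulationDesign, simulate, run_mbdecoda, evaluate

data = simulate(SimulationDesign(n=50, K=100, pi=0.2, eta=0.3, seed=7))
res = run_mbdecoda(data.table, data.cov)
power, fdr, n_disc = evaluate(res, data)
```

and `mbdecoda benchmark --config design.yaml --reps 100 --seed 1` runs a
full Monte-Carlo power/FDR study.

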