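# canidiv

Macroevolutionary analysis of dense fossil occurrence records, built around
the North American canid radiation (~40 Ma to present): ecomorphological
classification of fossil predators, time-sliced survivor–victim tests of
extinction selectivity, and Bayesian fossil birth–death estimation of
diversification rates with trait and temperature covariates. A ground-truth
simulator generates synthetic fossil records so that every inference stage
can be validated end to end without any data download.

It is intended for paleobiologists who have (1) occurrence tables with
interval-censored ages (taxon, min Ma, max Ma), (2) dental/mandibular
morphometrics, and optionally (3) a time-continuous environmental proxy such
as a benthic δ¹⁸O series.

## The models

**Ecomorphology.** Body mass is estimated from lower first molar (m1) length
through a log₁₀–log₁₀ extant-canid regression; typical prey mass from jaw
depth via `log10(prey kg) = 5.583 · log10(jaw mm) − 6.482`; carnivory as
m1BS, the carnassial blade length relative to dentary length. A species is a
*large hypercarnivore* when m1BS ≥ 0.107 and it is either ≥ 20 kg or takes
prey at least as large as itself.

**Extinction selectivity.** On a timescale of NALMA-subdivision intervals,
species present in interval *i* are survivors or victims according to their
presence in *i + 1* (Lazarus gaps are range-through filled). Per slice:
a rank-based permutational MANOVA on (log₁₀ mass, m1BS), AICc Akaike weights
of the logistic models `extinction ~ m1BS`, `~ mass`, `~ mass * m1BS`, and a
resampled 2×2 contingency test of extinction against the binary
large-hypercarnivore category — with Benjamini–Hochberg control at FDR 0.2
per test family across slices.

**Diversification.** A joint Bayesian model of preservation and
diversification on occurrence data: per-species latent origination/extinction
times (ts, te), a time-variable Poisson preservation rate *q* conditioned on
each species being sampled at least once, and piecewise-constant birth–death
rates

```
log L = Σᵢ log λ(tsᵢ) + Σ_extinct log μ(teᵢ) − Σᵢ ∫_{teᵢ}^{tsᵢ} (λ + μ) dt
```

with the number and times of rate shifts sampled by reversible-jump MCMC
(Poisson shift-count prior; per-bin shift frequencies reported against
log-Bayes-factor thresholds 2 and 6). Extensions: per-lineage trait effects
`λᵢ = λ₀ · m_class(i) · exp(α_λ xᵢ)` (discrete carnivory class × continuous
mean-centered mass) and covariate links `λ(t) = λ₀ · exp(γ_λ z(t))` for a
proxy curve z(t). Significance of α and γ is judged by whether the 95% HPD
excludes 0.

## Worked example

Benjamini–Hochberg control on the published survivor–victim statistics for
North American fossil canids (17 time slices, shipped as a worked-example
table):

```python
from canidiv.selectivity import bh_adjust, canid_survivor_victim_table
t = canid_survivor_victim_table()
t["BH_sig"] = bh_adjust(t["P"], fdr=0.2)
t["chi2_BH"] = bh_adjust(t["chi2_P"], fdr=0.2)
print(t[["slice_ma", "F", "P", "BH_sig", "chi2", "chi2_P", "chi2_BH"]].tail(4))
```

```
 slice_ma      F     P BH_sig  chi2  chi2_P chi2_BH
     4.70  0.219 0.667  False 0.020   0.891   False
     1.70  0.053 0.887  False 0.625   0.547   False
     0.45  1.099 0.309  False 0.627   0.586   False
     0.01 14.716 0.011   True 4.688   0.041   False
```

Only the end-Pleistocene slice (0.01 Ma, P = 0.011) survives FDR control —
the single episode of size- and carnivory-selective extinction; no
contingency P (minimum 0.041) does.

The same pipeline end to end on a synthetic clade (truth: λ = 0.3, μ = 0.2
events·lineage⁻¹·My⁻¹, preservation q = 1.5 occurrences·lineage⁻¹·My⁻¹):

```bash
canidiv simulate --seed 11 --out demo/sim
# simulated 152 sampled species (968 occurrences) -> demo/sim
canidiv divrates --occurrences demo/sim/occurrences.csv \
    --extant demo/sim/extant.txt --seed 11 --iterations 20000 --out demo/rates
# 1800 posterior samples -> demo/rates
```

`demo/rates/model_probabilities.csv` then holds the posterior probabilities
of the k-rate models, correctly favouring the constant-rate (1-rate) model
for both origination and extinction:

```
 model  origination  extinction  origination_best  extinction_best
1-rate        0.696       0.851              True             True
2-rate        0.246       0.141             False            False
3-rate        0.049       0.009             False            False
```

and `rates_through_time.csv` the mean and 95% HPD of λ(t), μ(t) and net
diversification on a time grid, e.g. at 19.8 Ma: λ = 0.236 (0.175–0.290),
μ = 0.149 (0.117–0.178). Estimates sit somewhat below the generating rates
because species that never fossilize are invisible to the likelihood; see
`docs/methods.md` for the quantitative analysis of this effect.

Passing `--subset large_hyper --traits <profiles.csv>` restricts the run to
the large-hypercarnivore partition and reports extinction rates only, since
origination cannot be attributed within a taxon subset. The `covar` and
`covariate` subcommands fit the trait-effect and temperature-proxy models
and print the α / γ posteriors with their HPD-versus-0 verdicts.

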