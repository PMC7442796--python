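# Methods

This note records the models implemented in `canidiv`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Occurrence data model

A fossil occurrence is a taxon name with an interval-censored age
`[min_age, max_age]` in Ma. Dating uncertainty is propagated by drawing a
point age uniformly inside each interval; the default of 100 randomized
replicates follows common practice for occurrence-based diversification
analyses. Species ranges take `ts` = oldest and `te` = youngest point age;
extant species are encoded `te = 0` **only** via an explicit extant-taxon
list — a young last occurrence never silently implies survival, because that
misclassification is irreversible downstream (it deletes an extinction
event and plants a spurious one at the present).

Time intervals are half-open in Ma with an age exactly on a boundary
assigned to the *older* interval; one convention, applied by a single
function (`TimeScale.bin_index`) everywhere. The default timescale
subdivides the last 40 My into 18 unequal NALMA-scale intervals whose 17
interior edges (32.2 … 0.01 Ma) are the survivor–victim slice ages; the
exact published subdivision table is not reproduced here, so the edges are
fully overridable by configuration. Presence follows the range-through
rule: a species is present in every interval overlapped by `[te, ts]`, so
Lazarus gaps are closed by construction and presence is always one
contiguous block.

## Ecomorphology

All regressions are log₁₀–log₁₀ lines applied on the raw scale
(`y = 10^(slope·log10 x + intercept)`); base-10 throughout, matching the
printed prey-mass equation and conventional allometric practice.

* Body mass from m1 length ships with the extant-canid allometry of
  Van Valkenburgh (1990) (`slope 2.97, intercept −2.27`) as a documented,
  overridable default — the coefficients are configuration, not code.
* Dentary length, needed for m1BS when no dentary is preserved, uses
  within-subfamily regressions. No published coefficients ship; the
  defaults (`slope 1, intercept 1`, i.e. dentary ≈ 10 × m1) are synthetic
  placeholders flagged as such, and a measured dentary always takes
  precedence over any regression.
* Prey mass from jaw depth uses the published extant-canid line
  `log10(prey) = 5.583·log10(jaw) − 6.482`.
* m1BS = carnassial blade length / dentary length; values ≥ 1 are accepted
  with a warning (they indicate a measurement problem, not a code error).

Classification thresholds are inclusive (≥): hypercarnivory at
m1BS ≥ 0.107 (the minimum observed in extant large hypercarnivorous
canids), "large" at ≥ 20 kg, and the prey-size supplement admits a
hypercarnivorous species under 20 kg whose estimated prey is at least its
own mass — the rescue is deliberately conditional on hypercarnivory, since
the category is *large hypercarnivore*, not merely *large*. The
three-level carnivory coding needs a hypocarnivory cut for which no
published value exists; the shipped 0.07 is a placeholder that real
analyses must override.

## Survivor–victim selectivity

For the slice between intervals *i* and *i+1*, the test set is every
species present in *i*; survivors are those also present in *i+1*.

**Rank permutational MANOVA.** Each trait column (log₁₀ mass, m1BS) is
mid-rank transformed over the pooled slice sample and an ANOVA-type
pseudo-F on rank means is computed; the reference distribution comes from
random label permutations. The rank transform buys invariance to any
strictly monotone rescaling of the traits, and permutation gives exact
finite-sample validity. The literature on nonparametric multivariate
comparison offers several statistics; the rank pseudo-F was chosen as the
simplest permutation-valid member of that family, and no claim is made of
reproducing any specific published F value. A with-replacement
("bootstrap") null is available behind `null="bootstrap"` for comparison.

**Logistic models.** `extinction ~ m1BS`, `~ mass`, `~ mass * m1BS`
(maximum likelihood via statsmodels Newton iterations), compared by AICc
`= −2ℓ + 2k + 2k(k+1)/(n−k−1)` and Akaike weights. Complete separation is
detected (non-convergence or divergent coefficients) and resolved by a
weakly ridge-penalized refit (penalty 10⁻³·‖β‖²/2), flagged in the result —
the alternative, dropping the slice, would discard exactly the strongest
signals.

**Contingency test.** The 2×2 chi-square (no continuity correction) of
extinction against the binary large-hypercarnivore category; the null
distribution is generated by random reassignment of the category labels,
which makes the occupied cell hypergeometric and is sampled as such.

All Monte-Carlo p-values use `(b+1)/(B+1)` with B = 10,000 resamples by
default, so p is never exactly zero. Benjamini–Hochberg control at
FDR = 0.2 is applied *per family* (MANOVA family; contingency family)
across slices; BH rather than Bonferroni because the slices are few and the
fossil record noisy, so controlling the false-discovery proportion is more
appropriate than the family-wise error rate. Slices where a test is
impossible (one survivor, no large hypercarnivores, one-class outcome)
yield NA with a reason string and are excluded from the BH family size.

## Fossil birth–death engine

**Likelihood.** Ranges: every species contributes `log λ(ts)` (including
the clade's oldest — no tree topology is used, so the root is treated like
any origination), extinct species contribute `log μ(te)`, and each lineage
is exposed to `λ + μ` over `[te, ts]`, integrated segment-exactly for
piecewise-constant rates. Preservation is a time-variable Poisson process
(TPP): per-bin sampling rates q, per-species conditioning on ≥ 1
occurrence via `−log(1 − e^{−∫q})`. Optional among-lineage rate
heterogeneity uses a discretized mean-1 gamma with 4 equal-probability
categories (bounded cost, standard practice); the sampler itself runs the
homogeneous TPP, heterogeneity being available in the standalone
likelihood.

**Latent ranges.** True origination precedes the first fossil, so ts/te
are latent with flat priors, bounded by the occurrence extremes (and te
fixed at 0 for extant species). They are updated by per-species independent
sliding-window Metropolis steps — valid because both likelihood components
decompose as sums over species — which updates all ~150 latent pairs in one
vectorized move.

**Priors and proposals.** Gamma(1.1, 1) on every λ/μ segment and every q
bin; Poisson(mean 1) on the shift count (capped at 10); shift times uniform
over the observed span; Normal(0, 1) on α and γ. Rate updates are
log-multiplier proposals; shift times move in a ±3 My window with
rejection at the neighbouring shifts. These are vague, positive-support
defaults; all are configuration.

**Reversible jump.** Shift birth: a new change point u uniform on the
span splits its segment's rate r into
`r_old = r·e^{v·f₂}, r_young = r·e^{−v·f₁}` with `v ~ N(0, σ_RJ)` and
f₁, f₂ the fractional segment lengths, preserving the length-weighted
geometric mean; death merges by the same weighting. The Green acceptance
ratio includes the Jacobian `r·e^{v(f₂−f₁)}` and the *normalized* Gamma
prior density — the normalizing constant matters because the move changes
the number of rate parameters. Correctness is checked by the
flat-likelihood test: with the likelihood silenced the sampled shift-count
distribution must reproduce the Poisson prior (chi-square goodness of
fit), and does so invariantly of σ_RJ.

**Summaries.** Posterior rate curves are recorded on a 101-point age grid;
credible bands are 95% highest-posterior-density intervals computed by the
shortest-sorted-window algorithm (cross-checked against ArviZ). The k-rate
model probability is the posterior frequency of k−1 shifts. Shift-time
histograms use 1-My bins; each bin's log Bayes factor is the natural-log
posterior-to-prior odds of the bin containing ≥ 1 shift, with the prior
occupancy `1 − e^{−ν·w/T}` implied by the Poisson(ν) count prior and
uniform times. Shift histograms in this framework are conventionally read
against logBF = 2 (positive) and 6 (strong evidence); the prior-odds
construction behind those thresholds is not standardized, and the
Poisson-uniform construction above is the one used here.
Frequencies are clipped away from 0/1 by half a sample before forming odds.
Effective sample sizes (ArviZ) are reported for the log-likelihood and
mid-grid rate traces; convergence is the user's responsibility, as is usual
for this class of samplers.

**Taxon subsets.** Analyses of a subset (e.g. large hypercarnivores vs all
other canids) report extinction rates only: a subset member's ancestor need
not belong to the subset, so origination and net rates are not
interpretable and are suppressed with an explanatory note.

**Trait effects (two-trait).** `λᵢ = λ₀·m_class(i)·exp(α_λ·(xᵢ − x̄))` with
x = log₁₀ mass mean-centered internally, and analogously for μ; baseline
rates are constant through time (the model estimates one overall
trait–rate relationship, not its temporal variation). Separate class
multipliers are estimated for λ and μ with the mesocarnivore class fixed
at 1; a single shared set would force the discrete trait to affect both
rates identically, which the data have no reason to obey. α is in units of
"per log₁₀-kg", not per SD. Constant trait columns are detected and warned
about; the α posterior then simply reproduces its prior.

**Covariate link.** `λ(t) = λ₀·e^{γ_λ z(t)}` (exponential) or
`λ₀·(1 + γ_λ z(t))` (linear; proposals driving any rate non-positive are
rejected, never raised). z is linearly interpolated between curve points
and mean-centered by its time-average over the clade span so that γ
decouples from the baseline. Integrals of the time-varying rates use
cumulative trapezoids on a 600-point grid — the one deliberate numerical
approximation in the engine, accurate to far below posterior noise for
smooth proxy curves.

## Synthetic-data generator

The generator mirrors the inference model stage by stage: exact
event-driven birth–death simulation (piecewise-exponential inversion,
segment-walk) from one lineage at the root age; traits fixed per species at
origination (no anagenetic change, matching the species-mean trait usage
throughout); Poisson fossil sampling under the true q with zero-occurrence
species silently unobservable (mirroring the ≥ 1-occurrence conditioning);
and interval censoring of every point age to its timescale bin, emulating
NALMA dating. Trait-dependent diversification is generated exactly as the
Covar model assumes (per-lineage rate multipliers `e^{α·x}`); covariate
coupling rescales the true rates through a 200-segment piecewise
approximation of the curve.

Default study conditions: λ = 0.3, μ = 0.2 events·lineage⁻¹·My⁻¹, q = 1.5
occurrences·lineage⁻¹·My⁻¹, root age 40 Ma, ≥ 120 sampled species — a
clade of roughly the size, span and preservation density of the North
American canid record (~130+ species, ~3700 occurrences over 40 My).
Because the process is supercritical, conditioning only from below
occasionally accepts clades of 1000+ species; an optional
`max_sampled_species` window cap (tests use 400) keeps runs desk-scale.
Whole clades are resimulated until the window is met — preservation is
never redrawn alone, so accepted histories are genuine conditional draws.

What the generator does **not** emulate: taxonomic error and synonymy,
geographically structured sampling, body-size-biased preservation,
anagenetic trait drift, and correlated dating errors across occurrences of
a locality. Passing recovery tests therefore demonstrate correctness of
the inference machinery under the model's own assumptions, not robustness
to these real-data pathologies.

The planted-selectivity benchmark deserves a note. With a strong true
positive present, BH at FDR 0.2 will co-flag an *honest null* slice with
probability ≈ 1 − (1 − 2·0.2/m)^(m−1) ≈ 0.3 — that is what an FDR of 0.2
means — so a benchmark demanding that *only* the planted slice be flagged
cannot include background extinction, of either the trait-independent kind
(null co-flags) or the hypercarnivore-sparing kind (which enriches late
survivor pools with large hypercarnivores and creates genuine secondary
signal). The planted mode therefore has all non-planted species survive to
the final interval; false-discovery behaviour is measured separately by
the generator's all-null mode.

## Known limitations

The central one: the range likelihood is written over the *sampled*
species, and species that never fossilize — disproportionately short-lived
ones — are invisible to it. At the default preservation (q = 1.5, mean
duration 5 My) some 12–18% of simulated species go unsampled, and the
sampled subset's realized event rates sit ~10–15% below the generating
rates; the posterior tracks the realized rates of the data it sees (the
acceptance run quantifies this: posterior means match the sampled-subset
rates to within ~3%, and HPD coverage of the *generating* λ falls short of
nominal, 14/20 at these conditions, while being nominal at q = 20). This
is a property of the occurrence-based likelihood itself, shared by the
standard tools in this framework, and is worth remembering when reading
absolute rate levels — shift detection, trait and covariate effects, which
compare rates against themselves, are unaffected (their null/recovery
checks pass 10/10).

Other limitations: one chain, no parallel tempering, so rate-shift
posteriors for weakly informative data can mix slowly; desk-scale default
iteration counts (200k; production-scale 10M-iteration settings remain
valid configuration); no phylogenetic likelihood, no "hump-shaped"
(NHPP) preservation variant, no Bonferroni mode, no multi-level extinction
outcomes.

## Problem sizes used by the acceptance script

Worked examples are instantaneous. The demonstration RJMCMC chain runs
200,000 iterations on a ≥ 120-species clade; replicate batteries (coverage,
planted shift, trait/covariate nulls and recovery) use 30–50k iterations
per replicate, 10–20 replicates per check — chain-length choices based on
the effective-sample-size diagnostics of pilot chains, whose posteriors for
these constant-or-one-shift models stabilize well within that budget. The
permutation type-I check uses 500 null datasets of n = 40 with 499
permutations each. The full script completes in roughly five minutes on
one CPU.
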