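# Methods

This note describes the statistical machinery implemented in `antpath`,
the assumptions behind each stage, the defaults and why they were chosen,
and what the synthetic-data experiments do and do not establish.

## The scientific question

Ant colonies differ enormously in size (a handful to over ten million
workers) and in non-reproductive division of labour, measured either as
the number of discrete physical worker castes (1–4) or as the continuous
coefficient of variation (CV) of worker head width.  The size–complexity
hypothesis holds that large colony size precedes and enables the
evolution of greater worker specialisation.  Competing explanations give
the causal role to queen mating frequency (via within-colony relatedness)
or reverse the direction (complexity enabling larger colonies).  The
package implements a triangulated comparative test of these hypotheses on
a time-calibrated phylogeny: trait correlations (phylogenetic mixed
models), phylogenetic path analysis, discrete correlated-evolution
models, and ancestral-state reconstruction with an ancestral-value
contrast.

## Trait curation (`antpath.traits`)

Species-level values aggregate repeated observations:

- **Effective queen mating frequency** — harmonic mean, because low
  frequencies have disproportionate effects on within-colony relatedness;
  always ≥ 1, point mass at strict monandry.
- **Colony size** — arithmetic mean weighted by the number of colonies
  behind each estimate; estimates without a sample size weigh 1.
- **Worker-size variation** — CV of worker head width (sd/mean, unitless
  and scale-invariant).  The sample standard deviation (n−1) is used; the
  convention is configurable (`ddof`).  At least two workers are
  required.
- **Caste number** — morphometric criteria: limited size variation or
  monophasic allometry → one caste; non-allometric scaling → the number
  of distinct scaling relationships; otherwise the direct literature
  count.

Species with derived life histories (supercoloniality, social parasitism
other than temporary, thelytoky, gamergate reproduction, hybrid caste
determination) are excluded because they represent secondary reorganisations
of colony life under different selection pressures.  Missing data are kept
as missing; every analysis takes its own maximal complete-case subset
rather than deleting rows globally.

Analysis scales: log10 for colony size, mating frequency and queen
number; square root for the worker-size CV.  Two-class codings for the
transition-rate stage split colony size at the median of the analysis
subset (≤ median → small; sensitivity variants use the 40th and 60th
percentiles) and mating frequency at two mates (≤ 2 → low), the
relatedness midpoint between full-sib and half-sib dominated colonies.
Ties go to the lower class.

## Trees and covariance (`antpath.treeio`)

Rooted, time-calibrated trees (Newick or Nexus) are handled by dendropy
and indexed into flat arrays for the likelihood kernels.  Pruning to a
taxon subset collapses unifurcations additively, preserving root-to-tip
depths; species names match tips case-insensitively with spaces and
underscores interchangeable.  Polytomies and zero-length branches are
accepted as-is.  The phylogenetic covariance has entries equal to the
shared root-to-MRCA path length; Pagel's λ multiplies off-diagonal
entries only, and the node-inclusive variant (tips ∪ internal nodes)
backs the ancestral-value model.  Dataset species absent from the tree
are dropped and reported.

## Discrete coevolution (`antpath.coevolution`)

Two binary traits (e.g. small/large colonies and single/multiple castes)
evolve on a four-state chain ordered (0,0), (0,1), (1,0), (1,1).  The
independent model has four rates (each trait's gain and loss, regardless
of the partner trait); the dependent model conditions each single-trait
rate on the partner's current state (eight rates).  Simultaneous
double transitions have rate zero.  The likelihood is computed by
Felsenstein pruning with a numba-compiled kernel; transition matrices
come from the eigendecomposition of the generator with a
scaling-and-squaring fallback for near-defective cases (verified against
brute-force enumeration and `scipy.linalg.expm` in the test suite).  The
root uses a uniform prior over the four states (configurable to the
stationary distribution).  Ambiguous tips (one trait missing) carry
likelihood one across compatible states.

**Priors.**  Rates are exponential with a mean drawn uniform(0, 100) — a
hyper-prior whose range matches the spread of maximum-likelihood rate
estimates; a gamma variant (mean uniform(0, 100), shape uniform(0.1, 10))
is retained for prior-sensitivity checks.  For this range to be
meaningful the tree must be scaled so rates are order 1–100; analyses
rescale branch lengths (the same reasoning behind the conventional
×0.001 branch scaling for empirical time-calibrated trees, which keeps
rates away from hard-to-search small values).  The recovery experiments
rescale trees to height 0.05, putting ML rates around 10–40.

**Reversible-jump MCMC** explores rate vectors with a point mass at zero:
each sweep updates the hyper mean (prior-ratio Metropolis), proposes
zero/revive toggles per rate (revival draws from the prior, so prior and
proposal cancel and the acceptance is the likelihood ratio), and makes
multiplicative random-walk moves (sd 0.5 on the log scale, with the
Jacobian).  The posterior probability that a transition is absent is the
fraction of retained samples with that rate exactly zero.  An optional
tree-resampling mode draws one tree per iteration from a posterior
sample by a Metropolis move (uniform tree prior); the stepping-stone
sampler below works on a fixed tree only — mixing marginal likelihoods
across trees would estimate a different quantity.

**Marginal likelihoods** use stepping-stone sampling over the
fixed-dimension model (all rates free): 24 power stones spaced
(k/K)^(1/0.4), 100 kept iterations per stone after 40 burn-in, warm
starts between stones, and one full Metropolis scan (every rate, one
prior redraw, the hyper mean) per iteration.  The estimator is the
standard sum of log-mean-exponentiated likelihood increments.  Accuracy
is validated against the closed-form Beta-Bernoulli marginal likelihood
(|error| < 0.05), and run-to-run spread on 200-tip problems is about one
log unit — adequate for Bayes factors read against thresholds at 2, 5
and 10.  The Bayes factor is 2·(log ml_dependent − log ml_independent);
values above 2 are positive evidence, above 5 strong, above 10 very
strong.

## Phylogenetic mixed models (`antpath.bpmm`)

The BPMM is `y = Xb + a + e` with `a ~ N(0, V_A·A)` (A the covariance
scaled to unit leading diagonal, so variance components are on the trait
scale) and `e ~ N(0, V_R·I)`.  Gaussian responses use a blocked Gibbs
sampler in the eigenbasis of A: fixed effects are drawn from their
marginal with the random effect integrated out, the transformed random
effects are conditionally independent (diagonal draw), and variances
follow inverse-gamma full conditionals.  Poisson log-link responses add
a site-wise Metropolis update of the latent log rate, making the
residual an observation-level overdispersion term.  Missing responses
(used for ancestral nodes) are imputed by data augmentation; the smooth
fitted value (without residual noise) is stored per draw.

Priors follow the inverse-Wishart (V = 1, ν = 0.002) convention for both
variances, with parameter-expanded alternatives — Fisher
(V = 1, ν = 1, α.μ = 0, α.V = 1000) and χ² (V = 1, ν = 1000, α.μ = 0,
α.V = 1) — for poorly mixing discrete-response models; fixed effects get
a diffuse normal (variance 1e8).  Default test-scale chains are 4,000
iterations (500 burn-in, thinning 5); the full-scale setting
(1.1 M/100 k/1 k) is available through the workflow configuration but is
never exercised by the test suite.  Factor predictors can drop the
global intercept to estimate one mean per level.

Summaries report the posterior mode (kernel density peak, refined by a
quadratic fit to the log-density across the peak region) with 95%
highest-density intervals; phylogenetic heritability is
V_A/(V_A+V_R)×100 per draw; marginal R² (Gaussian only) is
var(Xb)/(var(Xb)+V_A+V_R) per draw, with the across-trees median
reported both as the median of per-tree medians and the pooled-draw
median.  pMCMC between factor levels is the smaller one-sided proportion
of paired draws (ties split).  Convergence diagnostics (effective sample
size, split R-hat, lag-1 autocorrelation) come from arviz, with a
warning gate at ESS < 300.  Multi-tree analyses fit per tree and
concatenate posteriors with per-draw tree provenance.

## Path analysis (`antpath.pathmodel`)

Four causal hypotheses over {complexity, colony size, mating frequency,
queen number} — every model contains queen number → mating frequency and
colony size → mating frequency; they differ in whether colony size,
mating frequency, both, or reversed causation explains complexity.  The
d-separation basis set has one claim per non-adjacent vertex pair,
conditioned on the union of both parents' sets; the regression response
is the topologically later vertex (ties alphabetical).  Continuous
responses use PGLS with Pagel's λ profiled by maximum likelihood in
[0, 1] (λ = 0 reduces exactly to OLS); the binary caste vertex uses a
penalised-quasi-likelihood phylogenetic logistic regression whose random
effect variance is chosen on a grid by an approximate REML criterion
(σ² = 0 recovers the ordinary statsmodels logistic fit; complete
separation is detected and handled with a small ridge, flagged).
Continuous variables are z-scored so path coefficients are standardized.

Fisher's C = −2Σln p over the k claims is χ² with 2k degrees of freedom
under the model; p < 0.05 rejects it.  Models are ranked by
CICc = C + 2qn/(n−1−q) with q the number of edges (the vertex-variance
count is constant across the candidate set and cancels in differences);
ΔCICc < 2 defines the supported set, weights are ω ∝ exp(−Δ/2), and the
averaged model renormalises ω over the supported set with absent paths
contributing coefficient and variance zero, CIs by normal approximation.

A structural caveat worth knowing: the size→complexity and
complexity→size candidates share a skeleton and v-structure set (they
are Markov equivalent), so on data exactly faithful to either one the
d-sep ranking between them is decided by finite-sample noise; only the
claims involving the exogenous queen-number vertex differ, and those
hold under both.  Empirically the correct-direction model tops the
ranking in roughly 40% of replicates, with its equivalence partner and
the supermodel splitting the rest.  Discrimination in real data rests on
departures from exact faithfulness, not on the test's asymptotics.

## Ancestral reconstruction (`antpath.ancestral`)

Hidden rate models expand each observed state across 1–3 latent rate
classes; within a class, observed transitions follow equal-rates,
symmetric, or all-rates-different structure (class-specific rates), a
single shared rate switches classes, and simultaneous state+class moves
are forbidden.  Fitting is multi-start L-BFGS on log rates over the
expanded-state pruning likelihood; model selection uses AICc
(−2lnL + 2k + 2k(k+1)/(n−k−1)) per tree across a tree sample, the winner
being the model with the lowest AICc on the largest fraction of trees
(ties to fewer parameters).  Rate-class detection from a single binary
character is weak — the 2-class model beats the 1-class model on
aggregate across replicates but not reliably per replicate; this is an
intrinsic information limit, not an optimiser failure.

Marginal ancestral probabilities combine post-order and pre-order
partial likelihoods (validated against brute-force enumeration), with
hidden classes summed out.  Nodes take their argmax state (exact ties go
to the single-caste state with a warning) and are classified: (1) single
with all descendants single, (2) single with at least one multiple
descendant, (3) multiple with all descendants multiple, (4) multiple
with at least one single descendant.  An origin is an edge from a
single-state parent to a multiple-state child; the count is reported as
a lower-bound-style summary on the argmax assignments and cross-checked
against the parent–child transition tally.

**Ancestral-value contrast.**  The continuous trait (log10 colony size
or mating frequency) is modelled over tips plus latent internal nodes
with the node-inclusive covariance in an intercept-only BPMM; each
posterior draw provides every node's ancestral value (intercept + node
effect), and per-draw means over the nodes of each category give the
category estimates, their HPD intervals, and the category-1 vs 2 pMCMC
— the trait level in ancestors that went on to evolve multiple castes.
This is the identified reading of a node-category factor model: a
fixed-effect coefficient attached only to latent responses drops out of
the observed-data likelihood entirely (its posterior is its prior), so
category levels must be functionals of the reconstructed values rather
than free regression coefficients.  When only one category is populated
its estimate reduces to the phylogenetic GLS mean of the tip data.
Because the contrast is a descriptive comparison of realized
reconstructions, its pMCMC is conditioned on the data: random node
regroupings can genuinely differ (≈40% reach pMCMC < 0.05 with no
planted signal, symmetrically in both directions); interpretation should
lean on the direction and magnitude of the contrast alongside the
pMCMC, which is how it is used here.  Back-transformed (10^x) estimates
are available for reporting on the measurement scale.

## Synthetic data (`antpath.simulate`)

Yule (pure-birth) trees with exponential waiting times; the generator's
defaults emulate the empirical distribution shapes: Brownian log10
colony size recentred so the median is exactly 300 (range a few workers
to ~10^6–10^7 over a BM variance of 1.44 per unit height); mating
frequency and queen number are censored-at-one exponentiated Brownian
latents giving point masses at monandry/monogyny with long right tails
(maxima ~26 mates, ~70 queens); caste counts are 1 for most species with
multiple-caste species at 2–4.  Causal presets: `size_complexity_true`
(gain of multiple castes has rate exactly zero on branches whose
Brownian log-size midpoint is below the median — the hard-zero regime —
plus a colony-size effect on mating frequency and a CV–size link),
`mating_frequency_true` (gains conditioned on the mating latent
instead), `null` (everything independent), and `paper_like` (alias of
the size-driven preset at the default calibration).  Observation-level
rows (1–3 colony-size and mating estimates, ~6 head widths per species
with multiplicative noise) round-trip through the curation module, and a
truth record carries every generating parameter, the per-species latent
values and the planted origin count.  Discrete traits evolve by exact
Gillespie simulation along branches with full event logs, never by time
discretisation.

What the generator does **not** emulate: real ant taxonomy or the
empirical tree shape (posterior samples over 14k species with
genus-level uncertainty), non-Brownian trait evolution (bursts, trends,
bounded scales), correlated observation effort, or literature-driven
missingness patterns.  Recovery on these synthetic studies therefore
demonstrates correctness of the estimators under their assumed models at
desk scale, not robustness to empirical model violations.

## Desk-scale study conditions

Recovery experiments (shared by the test suite and
`scripts/acceptance.py`) use 100–300-tip trees and 20 replicates:
correlated-evolution truth has colony-class gain/loss 0.75/0.75, caste
gain 2.0 in large colonies, 0 in small, loss 0.4 (per unit tree height);
Bayes factors then land around 10–40, the same order as empirical
reports.  BPMM recovery plants heritability 0.7 and slope 0.17.  The
ancestral contrast plants origins above the size median and redraws
degenerate replicates (multiple-caste fraction outside 5–45% or fewer
than three origins) so the planted regime actually holds.  The d-sep
type-I calibration uses the continuous response mode, where the claim
p-values are exactly χ²-calibrated.  These sizes keep the full
validation suite within tens of minutes on one CPU; all randomness is
seeded and every experiment is reproducible bit-for-bit from its seed.

## Numerical choices

- Transition matrices: eigendecomposition when the eigenvector matrix is
  well conditioned (cond < 1e8), otherwise scaling-and-squaring Taylor
  (order 12) per edge; rows clipped at zero and renormalised; zero
  branch lengths give the identity exactly.
- Pruning uses per-node rescaling to avoid underflow; impossible data
  return −inf (ML) or raise (marginals).
- ML fits run 3–5 starts of L-BFGS-B on log rates bounded [e−14, e9];
  boundary fits (a rate < 1e−5, or a constant trait) are flagged, never
  silently accepted.
- Eigenvalues of covariance matrices are clipped at 1e−10 (the root row
  of a node-inclusive covariance is structurally zero).
- The posterior mode uses a quadratic fit to the log-kernel-density peak
  region, stable to ~0.01 on flat-topped posteriors where a raw argmax
  jitters by ~0.1.
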