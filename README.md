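# antpath

Comparative-phylogenetic analyses of the **size–complexity hypothesis**
in ants: does large colony size precede and enable the evolution of
non-reproductive division of labour (multiple physical worker castes,
greater worker-size variation), or does causality run the other way — or
through queen mating frequency and within-colony relatedness?

`antpath` is aimed at evolutionary biologists running species-level
comparative analyses on time-calibrated phylogenies.  It provides the
full workflow as tested, reusable library code:

1. **Trait curation** — species-level aggregation of colony size
   (sample-size-weighted mean), effective queen mating frequency
   (harmonic mean), worker head-width CV, caste counts from morphometric
   criteria, exclusion of derived life histories, log10/√ analysis
   scales and binary recodings.
2. **Phylogenetic mixed models (BPMMs)** — Gaussian and Poisson-log
   responses with a phylogenetic random effect, MCMC estimation,
   inverse-Wishart and parameter-expanded priors, phylogenetic
   heritability *h*² = V_A/(V_A+V_R)·100, marginal *R*², pMCMC, ESS and
   Gelman–Rubin diagnostics, posterior pooling across tree samples.
3. **Phylogenetic path analysis** — four causal models over
   {complexity, colony size, mating frequency, queen number}, d-sep
   tests (PGLS with Pagel's λ; phylogenetic logistic regression for the
   binary caste variable), Fisher's C = −2Σln *p* ~ χ²(2k),
   CICc = C + 2qn/(n−1−q) ranking, ω weights and full model averaging.
4. **Discrete coevolution** — independent (4-rate) vs dependent (8-rate)
   continuous-time Markov models for paired binary traits, maximum
   likelihood, reversible-jump MCMC with exponential rate priors seeded
   by a uniform(0, 100) hyper-prior, stepping-stone marginal likelihoods
   and Bayes factors BF = 2·(log ml_dep − log ml_ind).
5. **Ancestral reconstruction** — hidden rate models (1–3 rate classes ×
   equal-rates/symmetric/all-rates-different), AICc selection across
   trees, marginal ancestral states, the four-way node classification,
   origin counts, and the ancestral-value contrast (colony size in
   ancestors that did vs did not go on to evolve multiple castes).
6. **Synthetic studies** — Yule trees plus trait generators with known
   causal structure (`size_complexity_true`, `mating_frequency_true`,
   `null`, `paper_like`) so every stage is validated by parameter
   recovery.

Model classes follow the statsmodels idiom: construct from data, call
`fit()`, work with the Results object (`summary()`, draws,
diagnostics).

## Worked example

Simulate a 300-species study in which multiple worker castes can only be
gained in large colonies, then run the correlational stage and the
transition-rate test:

```python
from antpath import generate_species_table, DiscretePairCoevolution, bayes_factor
from antpath.traits import binarize_traits
from antpath.workflow import run_correlations

study = generate_species_table("size_complexity_true", n_species=300, seed=7)
table, tree = study.analysis_table, study.tree

corr = run_correlations(table, tree, scale="test", seed=1)

coded = binarize_traits(table)   # colony size split at the median (302.9)
states = {r["species"]: (int(r["colony_size_class"] == "large"),
                         int(r["castes"] > 1))
          for _, r in coded.iterrows()}
ptree = tree.prune_to_taxa(list(states))
ptree = ptree.scale_branches(0.05 / ptree.height())

pair = DiscretePairCoevolution(ptree, states)
ss = dict(n_stones=24, iters_per_stone=100, burn_per_stone=40)
dep = pair.stepping_stone("dependent", seed=2, **ss)
ind = pair.stepping_stone("independent", seed=3, **ss)
print(bayes_factor(dep.log_ml, ind.log_ml))
```

Output for this seed (excerpt of the correlation table, then the
coevolution test):

```
              response              predictor  beta_mode  ci_lower  ci_upper  significant
     log10_colony_size log10_mating_frequency      1.217     0.912     1.462         True
        sqrt_worker_cv      log10_colony_size      0.126     0.116     0.142         True
        sqrt_worker_cv log10_mating_frequency      0.202     0.137     0.254         True
        sqrt_worker_cv     log10_queen_number     -0.110    -0.405     0.184        False

log ml dependent = -258.37, independent = -262.19
BF = 7.63 (strong)
P(caste gain rate in small colonies = 0) = 0.95
```

Reading the numbers: worker-size variation rises with colony size
(β = 0.126, CI excluding zero) as planted by the generator; the
dependent model of colony-size/caste coevolution is strongly preferred
(BF = 7.63 > 5), and 95% of reversible-jump posterior samples set the
caste-gain rate in small colonies to exactly zero — recovering the
generator's hard-zero rule that multiple castes only arise in large
colonies.  Caste *count* regressions are honestly weak at this scale:
the phylogenetic random effect absorbs most of the threshold-driven
association, which is why the causal stages (path analysis, transition
rates, ancestral reconstruction) carry the inferential weight.

A full run (correlations → causality → sensitivity) from one config:

```sh
antpath run --config run.cfg      # keys: preset/trait_table, trees, scale, seed, ...
```

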