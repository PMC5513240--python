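# niche-coexist

Quantitative niche analysis for co-occurring stream fishes: unified
habitat niche overlap across mixed data types, trait x environment
Poisson mixed models, and bivariate stable-isotope trophic-niche
analysis with a Bayesian mixing model.

## The problem

When closely related species share a stream reach, coexistence theory
offers competing explanations: niche partitioning (species divide
habitat or food), habitat filtering (the environment selects convergent
traits), or differentiation at the trophic level only.  Telling these
apart needs three quantitative ingredients measured on the same
community, and this package implements all three:

1. **Habitat niche overlap (NO)** following the mixed-data-type
   framework: occurrence in pools vs riffles is Bernoulli data
   (overlap = p_i p_j + (1-p_i)(1-p_j)), substratum association is
   electivity data (Manly's alpha compared by the Schoener index), and
   abundance along the depth gradient is count data (nonparametric
   Poisson-mixture densities compared by sum of minima).  The unified
   overlap is the mean across axes,

       NO_ij = (1/T) sum_t NO_ijt,   NO in [0, 1],

   tested against a permutation null that reassigns species labels to
   individual fish (small p = less overlap than chance = niche
   differentiation).

2. **Trait x environment GLMMs**: counts y_ij per site i and species j
   follow

       y_ij ~ Poisson(exp(a0 + a1 X_i + b1 Z_j + b2 X_i Z_j
                          + eps_j + gam_i)),

   with crossed species/site random intercepts, fitted by
   Laplace-approximate maximum likelihood and compared by AIC, Akaike
   weights and likelihood ratio tests; c_beta reports the share of
   between-species variance explained by the trait terms.  Allometric
   size correction (common log-log slope) and Moran/Geary spatial
   screening are included.

3. **Isotopic trophic niches**: Layman metrics (CR, NR, CD, MNND,
   SDNND), standard ellipse areas SEA = pi sqrt(det Sigma) with
   small-sample correction SEAc, a conjugate Normal-Inverse-Wishart
   posterior giving SEA_B, directional niche-region overlap
   probabilities at alpha = 95%, and a Dirichlet-prior mixing model
   with trophic discrimination factors (1 +/- 0.5 and 3 +/- 0.5 per
   mil) estimating dietary source proportions with 50/75/95%
   credibility intervals.

A synthetic-data module generates surveys with known ground truth at
the scale of a real short-term survey (37 fyke-net sites, 3 species,
~10 isotope samples per consumer, triplicate sources), which is what
the tests use for parameter-recovery checks.

## Worked example

```python
from niche_coexist import habitat, simulate

ds, truth = simulate.gen_habitat_dataset(
    simulate.default_habitat_config(), seed=1)
for res in habitat.pairwise_overlap(ds, n_perm=199, seed=2):
    a, b = res.species_pair
    print(f"{a} vs {b}: unified NO = {res.unified_no:.3f} "
          f"(p = {res.p_value:.3f})")
```

prints

```
P_burchelli vs P_skeltoni: unified NO = 0.596 (p = 0.340)
P_burchelli vs S_capensis: unified NO = 0.587 (p = 0.265)
P_skeltoni vs S_capensis: unified NO = 0.470 (p = 0.085)
```

Each line is one species pair: the unified overlap averages the
habitat-type, substratum and depth axes, and the permutation p tests
whether overlap is *lower* than expected by chance.  Here no pair
falls below the null (all p > 0.05), i.e. these synthetic species
co-occur without detectable habitat niche segregation — the depth axis
scores low only because the species differ strongly in abundance.

The `examples/` directory has one short script per capability
(survey simulation, habitat overlap, trait x environment GLMMs,
isotope niches, the mixing model); each prints its numbers with a note
on what they mean.  `docs/methods.md` documents the models,
assumptions and numerical choices.

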