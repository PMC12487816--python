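# Methods

## Recalibration model

Let FC_g be a gene's log fold change from a standard DE analysis and V_g
its genetic dosage variance — the estimated variance of the gene's
expression across the population that is attributable to cis-regulatory
genetic variation, expressed in squared log-fold-change units (the unit
of allelic fold change). The recalibrated fold change is

    FC_bar_g = FC_g / sqrt(V_g)

i.e. the observed change in units of the standard deviation of natural
genetic dosage variation. The transformation assumes that FC and V share
one log base; the package never converts bases and treats the base as the
caller's responsibility. Recalibration is a post-significance step: only
genes already significant at the configured FDR cutoff are rescaled and
reranked (a missing adjusted p-value counts as non-significant), and
genes without a V^G estimate are excluded. The direction of regulation is
never changed, and the vg map is required to be strictly positive.

Rankings use descending absolute value with ties broken by ascending gene
id, so outputs are deterministic. Two selectors are exposed because both
conventions are useful: `select_top_n` (a fixed head count) and
`select_top_half_rounded` (half the significant genes rounded to the
nearest 100, half-up, floored at 100 and capped at the table size — the
floor exists because a literal 50% of a small table would round to an
empty selection).

## Cross-tissue V^G inference

Tissue-specific estimates from allelic expression are undefined wherever
a gene lacks usable allelic reads, which concentrates missingness in
lowly expressed genes. The inference fills a (gene g, tissue t) cell from
tissues with correlated variance profiles:

1. **Pseudocount.** E_bar = E + min{E > 0}, the smallest positive TPM
   anywhere in the matrix, so logs are defined at zero expression. The
   pseudocount is computed over present cells; missing expression stays
   missing.
2. **Per-tissue fit.** OLS of log(E_bar_t) on log(V_t) over genes with
   both defined gives (beta0_t, beta1_t). Natural logarithms are used;
   beta1 is invariant to a common change of base, so the adjustment
   factors below are base-independent. The regression direction
   (expression on variance) and the use of beta1 — rather than its
   reciprocal — as the exponent in steps 3 and 7 follow the method's
   published formulation exactly. A degenerate tissue whose log(V) is
   constant gets beta1 = 0 (no adjustment); a tissue with fewer than 3
   usable genes cannot be fitted and blocks inference only for itself.
3. **Adjust to mean expression.** V_hat_{g,t} = V_{g,t} *
   (mean_r E_bar_{g,r} / E_bar_{g,t}) ^ beta1_t, the variance expected if
   the tissue expressed the gene at its cross-tissue mean. The mean is
   taken over tissues with present expression for that gene (the divisor
   is the count of present tissues). A cell with measured V but missing
   expression carries V through unadjusted — adjustment needs the cell's
   own expression, and dropping the measurement entirely would discard
   real data.
4. **Tissue similarity.** rho(t1, t2) is the Spearman correlation of the
   raw V columns over genes measured in both tissues
   (pairwise-complete). Pairs with fewer than 3 shared genes get a
   missing similarity and are never neighbours. Similarity is computed on
   raw V, not V_hat, per the published formulation.
5. **Neighbour selection.** For each cell, the k = 5 (configurable)
   tissues s ≠ t with the highest rho(t, s) among tissues where V_{g,s}
   is measured and rho is defined and positive; if fewer than k qualify,
   all of them. Equal similarities are broken by ascending tissue id.
   Negative-similarity tissues are never used: with mixed-sign weights a
   weighted mean can leave the convex hull of its inputs and produce
   non-positive variances.
6. **Weighted mean.** V_dot_{g,t} = sum_s rho(t,s) V_hat_{g,s} /
   sum_s rho(t,s) over the neighbours — the neighbours' values, each
   standardised to mean expression level by step 3, averaged with
   similarity weights.
7. **Readjust.** V_tilde_{g,t} = (E_bar_{g,t} / mean_r E_bar_{g,r}) ^
   beta1_t * V_dot_{g,t}, the exact multiplicative inverse of step 3 at
   the target tissue. Cells with missing target expression cannot be
   readjusted and stay missing.

The combined matrix keeps measured values where present and falls back to
inferred ones. V_tilde is computed for *every* cell with a qualifying
neighbour, including measured ones, which is what makes held-out
validation (mask, infer, compare) possible. The whole pipeline is
deterministic — identical inputs give bit-identical outputs.

Two exact limits are useful checks: if a gene's expression is constant
across tissues, steps 3 and 7 are identities and V_tilde is exactly the
similarity-weighted mean of the neighbours' raw values; and step 3
followed by step 7 at the same tissue with the same fit is the identity
map.

**Aggregation.** One V^G per gene is the weighted harmonic mean
sum_t w / sum_t (w / V) over tissues where both the estimate and a
positive weight are present, with per-tissue TPM as the weight. The
harmonic mean is dominated by the most constrained (smallest-variance)
tissues and always lies between the per-tissue minimum and maximum.
Genes with no usable tissue are omitted rather than given a default.

**Tissue-specific constraint test.** Each gene is assigned the tissue
where its combined V^G is lowest (ties: ascending tissue id); whether a
gene group concentrates its lowest-variance tissue in a focal set (e.g.
brain tissues) is tested with a one-sided binomial upper tail at
p0 = |focal| / n_tissues.

## Enrichment comparison

The engine is a one-sided hypergeometric upper tail P[X >= overlap] per
term with Benjamini-Hochberg adjustment across tested terms. Term
membership is intersected with the analysis universe (the genes with
expression and V^G) before term sizes are computed, so background and
foreground are consistent. Comparing two selections takes the union of
terms enriched (adjusted p <= 0.05 by default) in either, imputing an
adjusted p of 1 on the side where a term was not enriched; keyword
grouping assigns each term to the first keyword (in user order) that is a
case-insensitive substring of its name — first-match-wins is a declared
convention for terms matching several keywords — and summarises each
group by the geometric mean of adjusted p-values per side. BH was chosen
as the multiple-testing correction because it is the standard, published
procedure; the comparison logic (imputation, union, grouping) is
independent of that choice. Functional-label assignment for genes with
several labels picks the least frequent label overall (ties: ascending
label), which favors specific over generic categories.

## Synthetic data generator

The generator emulates the joint structure the method assumes, at desk
scale. Defaults (all configurable through `SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| n_genes, n_tissues | 2000, 10 | matrix size of a small study |
| log_vg_mean, log_vg_sd | ln 0.01, 1.0 | lognormal per-gene variance: typical V^G ~ 0.01, heavy right tail |
| tissue_block_count | 2 | tissue blocks sharing per-gene effects (correlated tissue families) |
| tissue_effect_sd, cell_noise_sd | 0.3, 0.3 | block effect and per-cell noise on log V^G |
| beta0, beta1, expr_noise_sd | 2.0, -0.5, 0.3 | log TPM = beta0 + beta1 log V^G + noise: lowly expressed genes are more variable |
| missing_rate | 0.2 | expected masked fraction of V^G cells |
| low_expr_missing_boost | 2.0 | bottom expression quartile is twice as likely to be masked (missing-not-at-random), base rate renormalised so the overall expectation stays at missing_rate |
| frac_drivers, frac_responders | 0.05, 0.15 | driver genes drawn from the bottom V^G quartile, responders from the top |
| fc_scale | 1.0 | responder fold-change scale |

The DE table gives drivers |log_fc| ~ |Normal(0.3, 0.1)|, responders
|log_fc| = fc_scale * sqrt(vg_g) * |Normal(1, 0.3)| (vg_g being the
TPM-weighted harmonic mean of the gene's true tissue variances), and null
genes Normal(0, 0.05); adjusted p-values are assigned (uniform below
0.001 for drivers/responders, uniform on (0.1, 1) for nulls) rather than
computed from a test, because the package consumes DE tables and never
re-derives significance. All draws come from one seeded generator in a
fixed order, so outputs are bit-identical across runs.

A separate constructor, `generate_equalization_sets`, builds the paired
contrast used to demonstrate equalization: two 300-gene sets whose
lognormal V^G medians differ 4-fold and whose absolute fold changes are
sqrt(vg) times independent |Normal(1, 0.3)| noise — nominally very
different, identically distributed after recalibration.

What the generator does **not** emulate: count-level noise and
dispersion (no read counts are simulated), real GTEx tissue identities
and their similarity structure, correlated missingness between tissues,
batch effects, and any dependence of the DE table on the expression
matrix beyond base_mean. Passing tests therefore demonstrate that the
algorithms implement their definitions and behave correctly under the
assumed generative structure — not that real resources satisfy that
structure.

## Numerical choices

* Ties in rankings, neighbour selection, lowest-tissue assignment and
  label assignment are always broken lexicographically, never arbitrarily.
* Mann-Whitney comparisons use the exact null distribution when the
  combined sample is ≤ 20 without ties, otherwise the normal
  approximation with tie correction.
* Bootstrap CIs are percentile intervals, default 1000 resamples at the
  95% level, seeded.
* Scale equivariance of recalibration (V -> c²V implies FC_bar ->
  FC_bar/c) is exact in IEEE arithmetic when c is a power of two and
  holds to rounding (~1e-15 relative) otherwise.
* Matrix round trips through TSV are bit-exact: floats are written as
  shortest-repr decimals and parsed back with correctly rounded
  conversion; missing cells are the literal `NA` (empty accepted on
  read) and are never coerced to 0.
* The held-out recovery evaluation masks a fraction of observed cells
  uniformly at random, infers from the rest, and scores Spearman
  correlation on the held-out cells; its baseline copies each held-out
  cell's value from the single most similar tissue where the gene is
  measured — the first inference neighbour without adjustment or
  averaging.

## Problem sizes

The test suite and the acceptance script run at the generator's default
scale (2000 genes x 10 tissues) for recovery evaluation, 500 x 8 for the
per-cell oracle comparison, and 10,000 random pairs for the exactness
checks; the complete suite finishes in a few seconds on one CPU.

## Known limitations

* V^G uncertainty is not propagated into recalibration; estimates are
  treated as exact. Incorporating noise estimates is a natural extension.
* The inference assumes a log-linear expression-variance relationship
  per tissue and positive inter-tissue similarity; tissues unlike every
  other tissue (no positive similarity) receive no inferred values.
* Recalibrated values for individual genes inherit all the noise of the
  underlying V^G estimate; conclusions are most robust at the gene-set
  level.
* The enrichment engine is a plain hypergeometric/BH ORA; it does not
  model term overlap or the GO graph structure.
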