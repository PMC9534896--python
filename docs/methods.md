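# Methods

## The problem

Microbial extracellular vesicles (EVs) circulating in serum carry
bacterial DNA whose 16S profile can be read as a genus-level taxa
count table. Such tables are hard to model directly: most cells are
exact zeros (a genus detected in one subject is often below detection
in the next), many taxa are only assigned at a rank above genus, and
read depth varies by an order of magnitude across samples. This
package implements a feature-coding and classification pipeline for
such tables, together with a synthetic cohort generator so every
stage is testable without access to clinical data.

## Taxonomic hierarchical accumulation

Counts are first summarized to genus level, transformed as
`log2(count + 1)` and scaled so each sample's transformed values sum
to one; the result is the relative abundance `V_G` of each genus
feature. Each feature is then coded as

```
V_ACC = V_G + k1*V_F + k2*V_O + k3*V_C + k4*V_P + k5*V_K,   k_i = 10^-(1+i)
```

where `V_F … V_K` are the per-sample sums of `V_G` over all genus
features sharing the genus's family, order, class, phylum and kingdom
(weights 0.01, 0.001, 1e-4, 1e-5, 1e-6). Because each rank sum lies
in [0, 1], the coded value is bounded by
`V_G <= V_ACC <= V_G + 0.011111`, and a genus with `V_G = 0` whose
relatives are detected receives a small positive value — the coding's
zero-mitigation property, verified exhaustively in the tests.

Numerical choices:

* **Pseudocount.** `log2(count + 1)` preserves zeros as exact zeros
  and the ordering of counts. Zeros must survive the transform for
  the zero-mitigation property to be meaningful.
* **Order of operations.** Summarize → log2 → sum-to-one, in that
  order (not log2 of proportions).
* **Rank grouping.** Rank sums are grouped by the full ancestor path
  from kingdom down, so same-named nodes on different branches never
  pool. Placeholder pseudo-genera (parenthesized = assigned at the
  next verified rank, bracketed = unverified suggestion) are distinct
  features; they contribute to every verified ancestor rank they have
  and stand in for themselves at ranks they lack.
* **Kingdom term.** Included exactly as the formula states even
  though `V_K ≈ 1` for single-kingdom data, where it is a
  near-constant offset of `1e-6`.
* **Coverage.** `V_ACC` is computed for every feature in every
  sample, including genera absent from a sample — the only reading
  consistent with the zero-mitigation motivation.
* The family-rank term uses the family sum by symmetry with the other
  rank terms.

## QC filters

Reads shorter than 350 bp, longer than 550 bp, or with mean Phred
below 20 are discarded; the thresholds themselves are retained (only
strict violations are dropped). Samples with fewer than 1000 OTUs are
removed; when per-sample OTU counts are not supplied as metadata, the
number of nonzero features stands in (the synthetic path does not
model pre-summarization OTUs). Both filters are idempotent, and
genus summarization conserves per-sample totals.

## Alpha diversity

Observed richness, Chao1 (bias-corrected,
`S_obs + F1(F1-1)/(2(F2+1))`), ACE (rare-abundance cutoff 10),
Shannon (natural log) and Simpson (reported as the diversity
`1 - sum p^2`). The estimators are delegated to
`skbio.diversity.alpha`; when every rare taxon is a singleton, where
ACE is undefined, the bias-corrected Chao1 value is substituted
(the EstimateS convention). The closed forms
(`shannon = ln S` for uniform-over-S, `chao1 = 4.5` for counts
(1,1,2,3)) are asserted independently in the tests.

## Classification suite

Five methods are compared on coded features with 0/1 labels
(1 = disease):

* **glm_all** — unpenalized logistic regression on all features.
* **glm_selected** — logistic regression on features passing a
  per-feature two-sided Wilcoxon rank-sum test (normal approximation
  with tie correction) with Bonferroni adjustment
  (`min(1, p * n_features) < 0.05`), recomputed on each training
  split.
* **gbm** — gradient-boosted regression trees on the 0/1 labels
  (learning rate 0.01, 3000 trees, depth 10), scores clipped to
  [0, 1].
* **ann** — a five-layer feed-forward network (hidden widths
  256/128/64/16, relu, linear output), MSE loss on the labels,
  RMSProp optimizer (lr 1e-3, rho 0.9), L1 weight penalty 1e-4,
  200 epochs, minibatch 32, inputs standardized with training-set
  statistics; scores clipped to [0, 1]. The network is a compact
  numpy implementation so the loss/optimizer/penalty combination is
  exactly as specified; no output nonlinearity is added beyond
  clipping.
* **ensemble** — the elementwise mean of the GBM and ANN scores.

Evaluation is by repeated stratified 70/30 hold-out: iteration *i*
splits with seed `base_seed + i`, trains on 70%, scores the held-out
30%, and records the AUC (midrank Mann–Whitney; ties get half
credit) and ROC curve; 30 iterations at full scale. Stratification
is used because unstratified splits of imbalanced cohorts can lose a
class from a partition. The **desk-scale profile** (300 trees,
50 epochs, 10 iterations) is the package's default problem size for
its own end-to-end tests and benchmark scripts; the full-scale
settings remain the defaults of `ModelSpec`.

## Permutation feature importance

Importance of a feature is the mean drop in held-out AUC over
repeated seeded shuffles of that feature's column (30 repeats by
default), computed on the held-out partition — the statistically
defensible reading when train/test is available. Each
(repeat, feature) pair uses an independent seeded stream, so results
do not depend on feature order; a constant column scores exactly
zero, and importances are reported in absolute AUC units with no
normalization (they need not sum to anything).

## Synthetic cohort generator

The generator emulates the statistical shape of serum microbial-EV
genus tables, not any particular cohort:

* **Taxonomy.** `n_phyla × families_per_phylum × genera_per_family`
  genus leaves with one class and order per phylum; the first four
  phyla are named Firmicutes, Proteobacteria, Actinobacteria and
  Bacteroidetes and carry geometrically decaying base-abundance
  factors (decay 0.6), emulating the dominance structure of serum EV
  profiles.
* **Counts.** Per taxon, log-normal with `mean_log = 3.0` and
  `sd_log = 1.2` (natural scale). The spread corresponds to a
  one-sigma ratio of ~3.3×, i.e. about half a decade — the scale of
  across-subject genus-level variation typical of 16S surveys. The
  location parameter is immaterial after rescaling.
* **Read depth.** Each sample's counts are rescaled to a total drawn
  log-uniformly from [1e4, 1e5], so read totals span four to five
  orders of magnitude as observed in serum EV sequencing.
* **Zero-inflation.** An independent Bernoulli mask per
  (sample, taxon). Detection is abundance-coupled: the zero
  probability is `zero_fraction` divided by the taxon's fold-change
  in that sample's group (capped at 1). Dropout thus behaves like a
  sampling zero — more template, proportionally fewer dropouts — and
  an enriched taxon is both more abundant and more consistently
  detected. Masked-in taxa are floored at count 1 after rescaling,
  so the realized zero proportion equals the Bernoulli rate.
* **Planted effects.** `(node, group, fold)` triples multiply the
  expected counts of every genus under `node` in the given group
  before masking; an effect on a phylum therefore lifts all its
  genera coherently.
* **Seeding.** One master seed; sample *s* uses stream
  `seed + s`, so tables are reproducible under sample subsetting and
  bit-identical across runs.

What the generator does **not** model: compositional correlation
between taxa beyond taxonomy-shared effects, sequencing error or
chimeras, batch effects, covariate structure (age, sex), and
realistic OTU-level granularity (counts are generated directly at
genus level). Passing end-to-end tests therefore demonstrates that
the pipeline recovers planted, independent, log-normal signals — not
that it attains any particular performance on clinical data.

## Benchmark study conditions

The canonical benchmark (`taxaccum.study`) uses 200 genus features,
100 samples per group, background zero fraction 0.5, and 10 genera
enriched 8-fold in the disease group, evaluated with the desk-scale
profile over 10 hold-out iterations; the null benchmark permutes the
labels of the same cohort. Under these conditions the ensemble
reliably exceeds mean AUC 0.9 while every method stays within
[0.4, 0.6] under permuted labels. One caveat is documented
deliberately: with ten strong independent planted features, the
selected-feature GLM is close to the Bayes rule and can exceed the
ensemble — the weak-GLM/strong-ensemble gap seen on real clinical
tables arises from many weak correlated features, a regime this
generator intentionally does not model.

## Known limitations

* The ANN is trained as a regressor on 0/1 labels; scores are
  interpretable as ranking scores, not calibrated probabilities.
* Unpenalized logistic regression on separable training sets stops
  at the optimizer's iteration cap; scores remain valid for ranking.
* ACE is undefined for samples whose rare taxa are all singletons;
  the Chao1 substitution is a convention, not an estimate of the
  same quantity.
* The 1000-OTU sample filter counts nonzero features when OTU
  metadata is absent, which understates true OTU counts for data
  summarized upstream.
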