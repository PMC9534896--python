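# taxaccum

Taxonomic hierarchical accumulation coding and machine-learning
classification for serum microbial extracellular-vesicle (EV)
metagenomes.

Genus-level 16S taxa tables from circulating microbial EVs are
heavily zero-inflated — a genus detected in one subject is often
below detection in the next — and many taxa are only assignable at a
rank above genus. This package implements a feature coding that
addresses both problems, the downstream classification suite that
turns coded tables into disease-prediction models, and a synthetic
cohort generator so the whole pipeline is testable end to end. It is
aimed at microbiome-ML researchers who want the coding and the
evaluation protocol as reusable, tested components.

## The coding

After summarizing counts to genus level, transforming as
`log2(count + 1)` and scaling each sample to sum to one (the relative
abundance `V_G`), every genus feature is augmented with geometrically
down-weighted abundance sums of its ancestor ranks:

```
V_ACC = V_G + k1·V_F + k2·V_O + k3·V_C + k4·V_P + k5·V_K,   k_i = 10^−(1+i)
```

where `V_F…V_K` are the per-sample sums of `V_G` under the genus's
family, order, class, phylum and kingdom. Every coded value obeys
`V_G ≤ V_ACC ≤ V_G + 0.011111`, and a genus absent from a sample
inherits a small positive value from its detected relatives — zeros
stop being uninformative. Imprecisely assigned taxa (parenthesized
placeholder names such as `g__(Fimbriimonadaceae)`, or bracketed
unverified suggestions) stay distinct features and are weighted
through the verified part of their lineage.

The classification suite compares five methods — all-feature
logistic GLM, Wilcoxon/Bonferroni-selected GLM, a gradient boosting
machine (learning rate 0.01, 3000 trees, depth 10), a five-layer
relu ANN trained with MSE/RMSProp/L1, and the GBM+ANN score-average
ensemble — by AUC over repeated stratified 7:3 hold-out splits, with
permutation feature importance (held-out AUC drop over 30 seeded
shuffles) to rank features.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
synthetic cohort (200 genus features across 8 phyla, 100 samples per
group, background zero fraction 0.5, 10 genera enriched 8-fold in
the disease group):

```
$ python analysis/01_simulate_cohort.py
cohort: 200 genera x 200 samples, seed 7
zero fraction (empirical): 0.486
read totals span 10145-99316
read QC fixture: 4497/10000 reads pass 350-550 bp / Phred>=20

$ python analysis/02_qc_and_code.py
kept 200/200 samples; 200 genus features
zero cells: 48.6% of raw counts, 0.0% after coding
coded value range: [3.87e-05, 0.031] -> results/cohort/coded.tsv

$ python analysis/04_fit_models.py
mean AUC over 10 stratified 7:3 splits (and label-permuted control):
              mean_auc  sd_auc  null_mean_auc
glm_all         0.9992  0.0013         0.4908
glm_selected    0.9998  0.0004         0.5000
gbm             0.9093  0.0553         0.4759
ann             0.9078  0.0533         0.4884
ensemble        0.9563  0.0285         0.4776
```

Half the raw count cells are zeros; after accumulation coding none
are, because absent genera inherit weight from their relatives. The
ensemble recovers the planted signal (mean AUC 0.956) and every
method collapses to chance when labels are permuted — the pipeline
finds planted structure and nothing else.
`analysis/03_alpha_diversity.py` reports per-sample
observed/Chao1/ACE/Shannon/Simpson, and
`analysis/05_feature_importance.py` ranks features by held-out AUC
drop; on this cohort 8 of the top 10 ranks are planted genera.

A thin CLI mirrors the same steps
(`taxaccum simulate|qc|code|diversity|evaluate|importance`); see
`taxaccum --help`.

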