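# Methods

## Model and assumptions

`gsmpath` implements grouping–scoring–modeling (G–S–M) feature selection
for two-class expression data. The underlying assumption is biological:
disease-relevant transcriptional change is coordinated within pathways, so
a *set* of genes should be judged as a unit by its joint ability to
separate the classes, rather than gene by gene. Pathways are treated as
plain gene sets — topology, direction and stoichiometry are deliberately
ignored — and set membership is matched to expression columns by exact,
case-sensitive symbol equality (no identifier translation is attempted;
inputs are assumed to be gene-level, not probe-level).

The score of a set is an *embedded* criterion: the cross-validated accuracy
of a classifier trained on the set's sub-dataset. This measures multivariate
separability (a set of individually weak but jointly informative genes can
score high) at the price of classifier variance, which the protocol
addresses by repetition and averaging everywhere.

## Protocol and parameters

| parameter | default | meaning |
|---|---|---|
| `k_folds` | 10 | outer Monte Carlo CV iterations |
| `train_frac` | 0.8 | outer stratified train fraction |
| `inner_r` | 5 | inner scoring repeats per group |
| `inner_train_frac` | 0.8 | inner stratified train fraction |
| `j_max` | 10 | largest number of top groups pooled into a model |
| `min_group_size` | 3 | smallest group kept after intersection with the data |
| `n_trees` | 100 | random-forest ensemble size (depth unlimited) |
| `top_genes` | off | optional t-test pre-filter of the gene universe |

Defaults mirror the established G–S–M practice for expression data:
tenfold MCCV with 80/20 splits, five inner repeats, and a 100-tree
unlimited-depth random forest. `min_group_size=3` exists because a one- or
two-gene "pathway" cannot be meaningfully cross-validated.

Design choices made where the protocol was genuinely open:

* **Inner split ratio** — inner scoring reuses the outer 80/20 ratio, and
  inner splits are stratified; both are configurable.
* **Under-sampling order** — the majority class is under-sampled once per
  outer iteration (a fresh random subset each time), *before* the 80/20
  split, so the test split is balanced and ACC/SE/SP are comparable across
  datasets. `undersample="train_only"` instead balances only the training
  split and evaluates on the imbalanced remainder; metrics are then
  reported on that imbalanced test set.
* **t-test role** — Welch's unequal-variance test is the default (safer for
  expression data than pooled-variance Student's t, which remains available
  via `equal_var_ttest`). Statistics are always computed per fold on
  training data; by default they only annotate the output, and `top_genes=n`
  additionally restricts the gene universe to the n smallest p-values
  before grouping.
* **Tie-breaking** — group ranking orders by score, then mean sensitivity,
  then fewer genes (parsimony), then set id; gene rankings break p-value
  ties by larger |t| then symbol. Fully specified orders make reports
  reproducible byte for byte.
* **Aggregation** — cross-fold means are taken per j over folds with
  defined metrics; AUC is the mean of per-fold AUCs, not a pooled-score
  AUC. The aggregated pathway list averages per-fold scores; a set dropped
  by restriction in some fold contributes that fold's minimum score and
  worst rank there, so absence is penalised rather than ignored. The mean
  rank is reported alongside for transparency.

## Numerical and degenerate-case choices

* SE, SP and AUC are undefined when their denominator class is absent from
  a test split; such folds return an explicit `None`, are excluded from
  means, and their count is logged. Stratified splitting makes this rare.
* AUC uses the rank-based Mann–Whitney formulation with midranks for ties,
  exactly equal to pair counting (ties count one half).
* Stratified splits put `round(train_frac * n_class)` samples of each class
  in training, clamped so both parts keep at least one sample per class.
* Genes with zero variance in both classes get `t=0, p=1` (not NaN) so
  sorting stays total; this is applied even in the pathological case of two
  different within-class constants.
* Every random draw is seeded from a `SeedSequence` over
  `(master seed, fold, group, repeat, ...)`, so any single group score or
  split can be reproduced in isolation and identical configurations yield
  byte-identical reports.

## Synthetic data

`synthetic.generate` emulates the study design the pipeline targets: a
samples × genes matrix of unit-variance Gaussian noise, two classes, and a
gene-set collection in which a few *informative* sets have a fraction of
their genes mean-shifted by `effect_size` standard deviations in the
positive class. Adjacent sets share `overlap_fraction` of their genes,
mimicking genes that act in multiple pathways; informative sets are placed
non-adjacently so the planted genes of different sets are distinct and the
ground truth is unambiguous. Gaussian noise is the simplest model
satisfying the t-test's assumptions; heavier-tailed noise, realistic
intensity distributions, batch effects and probe-level structure are *not*
modelled. Passing tests therefore demonstrate correctness of the algorithm
and calibration under clean conditions, not robustness to the artefacts of
real microarray or RNA-seq data.

Default generator conditions used by the end-to-end checks: 30+30 samples,
400 genes, 30 sets × 12 genes with 20% adjacent overlap, 3 informative sets
with half their genes shifted by Δ = 2. An effect of 2 within-class SDs is
a strong but realistic differential-expression signal; with half a set's
genes carrying it, single informative sets are learnable while noise sets
stay near chance. The imbalance scenario uses 157 positive vs 23 negative
samples, the most skewed class ratio among typical public expression
datasets of this kind.

## Problem sizes of the shipped checks

The test suite runs the planted-recovery and null-calibration experiments
at the geometry above with 5 outer folds, r = 5, 100-tree forests and five
master seeds each (the package default of 10 folds is used by
`scripts/acceptance.py`, which runs three planted and two null tenfold
experiments plus the imbalance and exactness checks). These sizes are the
package's chosen benchmark conditions; recovery is judged by all three
planted sets appearing in the aggregated top five (chance probability
≈ 0.1% for 30 sets), mean AUC of the top-3 model ≥ 0.90, and null-data mean
AUC within [0.40, 0.60] with mean group scores within 0.5 ± 0.05.

## Known limitations

* Groups are scored independently; shared genes let signal bleed into
  overlapping neighbour sets (visible in the worked example, where a set
  overlapping a planted one ranks third). The ranking identifies
  *discriminative* pathways, not causally dysregulated ones.
* Scores are classifier-based, not enrichment p-values; no multiple-testing
  machinery applies and none is provided.
* With hundreds of sets the S stage dominates runtime
  (`k_folds × k × r` forest fits); forest size and `inner_r` are the
  practical levers.
* Accuracy-based scoring assumes the balanced folds produced by
  under-sampling; with `undersample="train_only"` score and ACC become
  prevalence-dependent.
* On signal-free data the held-out AUC can fall slightly *below* 0.5 rather
  than sitting exactly at it: within one finite dataset, a gene whose
  chance correlation with the labels is high in the training subsample must
  be correspondingly low in the complementary test subsample, so selecting
  groups on training accuracy mildly anti-selects for the test split. This
  is a property of any selection-inside-resampling scheme on a fixed
  sample, not of this implementation; the calibration checks therefore use
  a band around 0.5 rather than a point value.
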