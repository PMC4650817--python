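# Methods

## Feature encoding

Each gene is a point in a 10-dimensional space, one coordinate per upstream
method.

* **Gene-level methods** (five): the method's raw P-value. Raw scale (not
  −log10) is used because the missing-value default of 1 is the natural
  "no evidence" extreme only on the raw scale. A gene absent from a
  method's output is imputed as P = 1 and flagged in `imputed_mask`.
* **Ranked-list method** (FLN-style): the mean network edge weight between
  the gene and the method's top-100 genes. The mean divides by the full
  top-list length k, with non-edges contributing 0; averaging over edges
  present instead is the other defensible reading, and dividing by k was
  chosen because it preserves monotonicity in the number of supporting
  links.
* **Module-count methods** (three, NetBox/MEMo/Dendrix-style): the number
  of interaction-network links L from the gene into module-interior genes,
  doubled when the gene is itself interior. The interior/exterior weights
  (2 and 1) are applied as a multiplier on the target gene's link count —
  the most literal reading of "exterior genes are assigned a weight of 1;
  interior genes are assigned a weight of 2". Modules from one method are
  merged by set union before the interior/exterior determination. Genes
  absent from the network score 0.
* **Module-weight method** (FLNP-style): the mean weighted-network edge
  weight between the gene and all module-interior genes (excluding the gene
  itself from the divisor), non-edges contributing 0.

Gene identifiers are upper-cased symbols; alias resolution across methods
is the caller's responsibility.

## Mutation statistics

Only three MAF columns are consumed (`Hugo_Symbol`, `Tumor_Sample_Barcode`,
`Variant_Classification`). "Silent" is the only silent class; every other
classification counts as non-silent. A gene's mutation rate is the number
of cohort samples carrying ≥ 1 non-silent mutation in it divided by the
cohort size, which is always an explicit parameter (the number of sequenced
patients can exceed the number of samples that appear in the MAF). Display
rounding is 4 decimals.

Negative training candidates are universe genes mutated in **at most one
sample** and absent from every annotation catalog. Per-sample counting is
the default (per-record available via `count_records=True`). By default a
gene must have at least one MAF record to qualify — negatives should be
demonstrably sequenced — with `require_observed=False` to relax.

## DECORATE

The committee starts from one base learner trained on the original data.
Each iteration draws ⌈`artificial_size`·n⌉ artificial examples
attribute-wise from independent per-attribute Gaussians fitted to the
training columns (all ten features are numeric, so no nominal branch is
needed), labels them oppositionally — p(class) ∝ 1 / max(committee
posterior, 10⁻³), normalized, sampled — trains a candidate on original +
artificial data, and accepts it iff the committee's 0/1 error on the
original data does not increase. Building stops at `desired_size` members
or `num_iterations` iterations. Defaults: artificial fraction 1, committee
size 15, 50 iterations.

Base learners are scikit-learn stand-ins for the classic Weka workbench
implementations, documented as approximations: Gaussian naive Bayes; a
linear SVC with a Platt sigmoid fitted to its training decision values (an
SMO-style probabilistic SVM); an entropy-split decision tree (C4.5-style);
and a 10-tree random forest (the classic Weka default forest size, and a
deliberately small forest — committee building trains up to 50 candidate
forests per run, and 10 trees on a 10-feature, ~100-example problem is
already saturated). Bit-exact Weka replication is a non-goal.

Four committees (one per base learner) are trained from one seeded
generator; the ensemble posterior Prb is their uniform mean. The reading
"one DECORATE committee per base learner, averaged at the end" is the one
most consistent with averaging the posterior probabilities of four base
classifiers; a single mixed committee is the alternative reading and is not
implemented. Classification is driver iff Prb > 0.5, with the tie at
exactly 0.5 resolved to passenger (conservative call).

## Trials and screening

Each trial samples negatives uniformly without replacement to match the
positive count, trains the ensemble, and estimates sensitivity/specificity
by stratified 10-fold cross-validation (stratification is a choice; the
held-out predictions of the ten folds are pooled within a trial). A
`single_split` flag evaluates one 10% hold-out instead of the full
rotation; `cv_folds=0` skips CV when only the ranking is needed.
Per-trial seeds are master seed + trial index. After training, every
universe gene outside the trial's training set is scored; final Prb is the
per-gene mean over trials, and the final ranking excludes the positives
and the union of all sampled negatives (strict reading of "excluding the
training sets" — no gene in the ranking was ever seen by any trained
model). Rank ties are broken lexicographically by symbol. Genes with fully
imputed feature rows are still scored.

## Evaluation

Enrichment is the hypergeometric upper tail, identical to the one-sided
Fisher exact test, computed with `scipy.stats.hypergeom` (verified against
an exact rational-arithmetic tail sum to ~10⁻¹⁵ relative error even at
P ≈ 10⁻²¹). DAVID's EASE-modified score and its curated background are a
different statistic and are not reproduced. Rank-sum meta-ranking uses the
shared-minimum convention for ties on each criterion (so a double first
scores 2). FDR control is Benjamini–Hochberg via statsmodels.

## Synthetic cohorts

The generator plants `n_drivers` drivers among `n_genes` genes. Gene-level
methods report each gene with probability `detection_prob`; driver
P-values follow Beta(shape, 1) with shape 0.1 (concentrated near 0),
passengers are Uniform[0,1]. Modules are built by partitioning drivers
into groups of 4 and padding with passenger fillers to size 10; each
module method retains a driver member with probability `module_recall`
(0.8) and a filler with probability `filler_retention` (0.3), so module
membership — like real module methods — enriches for drivers without being
pure. Networks are planted-partition graphs: driver–driver intra-module
edges are frequent (0.9) and heavy (0.7–1.0), filler-touching intra-module
edges sparser (0.4) and lighter (0.2–0.6), on a weak background of density
`network_density` (0.005, weights 0.01–0.3). The MAF gives drivers a
per-sample non-silent mutation probability of 0.05 and passengers 0.002
(≈ 1 expected mutation per passenger in a 500-sample cohort, which makes
the ≤ 1-sample negative rule bite realistically); 15% of records are
Silent.

`planted_separability` is the expected fraction of drivers visible to at
least one method, 1 − (1−detection)⁵(1−recall)⁵ ≈ 1 at the defaults; the
ensemble's CV sensitivity is compared against it.

The **rare-driver scenario** reassigns a subset of drivers to the
passenger mutation rate and to non-significant gene-level P-values
(Uniform[0.3, 1] when reported at all) while forcing their module
membership — the regime where per-gene statistics fail but network context
persists. Rare drivers are excluded from the training positives (they are
"not yet annotated") and included in the annotation catalog used by the
negative rule, so an unknown true driver is never drawn as a training
negative. What passing tests show: the ensemble recovers module-supported
rare drivers that all five P-value methods miss. What they do not show:
performance under realistic mutational processes, miscalibrated upstream
P-values, correlated method errors, or annotation noise — none of which
the generator emulates.

## Problem sizes

The study-scale checks run a 2000-gene / 40-driver / 500-sample cohort
with 50 balanced trials and full 10-fold CV (≈ 6–8 minutes on one CPU);
the rare-driver replicate check uses 20 seeds at 600 genes / 2 trials with
CV disabled, trading per-seed depth for replicate count. The acceptance
script uses 1000-gene cohorts with 10 CV trials and a 4-trial rare-driver
screen for the same reason. These sizes are the package's own choices for
routine verification; all defaults remain at the values above.

## Known limitations

* Base learners approximate, not replicate, the original Weka classifiers;
  absolute Prb values are not comparable across toolchains.
* The committee-error acceptance rule uses the 0/1 loss at Prb > 0.5;
  probabilistic (log-loss) acceptance is not offered.
* Cross-method identifier mapping (aliases, retired symbols) is out of
  scope; inputs must share a symbol namespace.
* The interior/exterior multiplier reading of the module-count feature is
  one of two defensible interpretations; the per-link weighting variant is
  not implemented.
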