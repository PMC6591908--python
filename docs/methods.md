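# Methods

This note documents the statistical and cheminformatic choices behind
`metaboclust`, the knobs that matter, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Data model and preprocessing

An `IntensityTable` is a sample × metabolite matrix of non-negative raw
abundances with per-sample metadata (a binary trait plus covariates) and a
processing-state flag. The flag enforces the pipeline order

    raw → imputed → normalized → logged → (autoscaled | covariate_adjusted)

so that, for example, log2 can never be applied before normalization.
Missing cells model non-detects; zeros are detected values. Panel
alignment retains exactly the metabolites that have a parsed structure and
are detected (non-missing in ≥ 1 sample) in every cohort, mirroring the
common-panel requirement of multi-cohort designs.

* **Half-minimum imputation** assumes non-detects are left-censored: each
  missing cell becomes 0.5 × the metabolite's minimum observed intensity.
* **Total-quantity normalization** divides each sample by its own total and
  rescales by the mean total. The rescaling constant is a presentation
  choice only — it cancels after log2 and centering — but keeps values on
  an interpretable intensity scale. The operation is idempotent.
* **Autoscaling** uses the n−1 standard deviation. Zero-variance
  metabolites are centered, flagged, and left unscaled.
* **Covariate adjustment** replaces each (logged) profile by OLS residuals
  on an intercept plus covariates; categorical covariates are 0/1
  indicator-encoded against the first-seen level. Constant covariates are
  dropped with a warning; rank-deficient designs fall back to the
  least-norm solution. Adjustment operates on logged, not autoscaled,
  values: the differential-testing path never rescales per metabolite.
* **Variance decomposition** reports BSS, WSS and BSS/(BSS+WSS) for any
  grouping of autoscaled profiles; BSS + WSS equals the total sum of
  squares about the grand mean by construction.

## Differential analysis

Each metabolite's covariate-adjusted residuals are tested with an unpaired
Welch *t* statistic under a Monte-Carlo permutation null: trait labels are
reassigned uniformly at random and the two-sided p-value uses the add-one
convention p = (1 + #{|t*| ≥ |t_obs|}) / (B + 1), which is a valid p-value
for any B and never returns zero (the attainable floor is 1/(B+1)). The
default B is 100,000; the package's own simulation studies use 999–4,999
(see problem sizes below). Degenerate cases: zero variance with zero mean
difference gives t = 0 and p = 1; zero variance with a non-zero difference
is treated as infinite |t|.

Implementation notes that matter for reproducibility and symmetry:

* each metabolite receives an independent permutation stream spawned from
  the single analysis seed, so p-values are mutually independent under the
  null and runs are bit-reproducible;
* permutations are drawn over the sorted pooled sample and always select
  the smaller group's positions, which makes the p-value exactly invariant
  to swapping the group labels;
* values are centered before the sums-of-squares pass to avoid
  cancellation at raw-intensity magnitudes.

Multiple testing uses Benjamini–Hochberg step-up q-values
(q_(i) = min_{j≥i} m·p_(j)/j, capped at 1); a metabolite is significant at
q ≤ 0.075, the threshold used for selecting classifier inputs. Because
permutation p-values are bounded below by 1/(B+1), BH at small target
levels is conservative for small B: with B = 999 and 100 metabolites a
rank-1 rejection needs p ≤ 7.5×10⁻⁴ < 1/1000, so under a global null
rejections require joint small p-values at higher ranks and the realized
false-discovery proportion sits well below the nominal level. This is a
property of discrete Monte-Carlo p-values, not a defect of the step-up.

Fold changes reported for display are ratios of back-transformed
normalized group means when a normalized table is supplied; significance
is always decided on the residual scale.

## Enrichment statistics

Cluster enrichment asks whether significant metabolites (or members of a
given pathway) are over-represented inside a structure cluster: a
one-sided (greater) Fisher exact test on the 2×2 table
{in/out cluster} × {hit/miss}, BH-corrected across clusters. A cluster
covering the whole population is reported with p = 1 and a warning.
Pathway over-representation uses the upper-tail hypergeometric
P(X ≥ k) with population N (the aligned panel), K pathway members in the
population, n significant metabolites and overlap k, BH-corrected across
pathways at FDR 0.05. Pathways with no members in the population are
skipped with a warning.

## Structure fingerprints and distances

Structures are parsed from SMILES (or SDF) with RDKit and canonicalized;
unparseable entries go to a rejects list and must be resolved (or
explicitly ignored) before fingerprinting. Each metabolite is a 166-bit
MACCS key vector (RDKit's unused bit 0 dropped).

Redundant keys are removed in two deterministic steps: constant keys first
(Pearson r is undefined on them), then a greedy scan in ascending key
order that drops any key with |r| > 0.9 against an already-retained key —
so the lower-numbered key of a correlated pair always survives. The filter
is fit once on the full aligned panel and reused for the
significant-subset clustering, keeping the two dendrograms in the same
feature space.

Soergel distance, d = 1 − |intersection|/|union| of the bit sets, is one
minus Tanimoto similarity and a true metric on binary vectors; an all-zero
pair is assigned d = 0 by convention (the 0/0 case is undefined). The
structure-free alternative is 1 − |Spearman ρ| between covariate-adjusted
profiles; zero-variance profiles get correlation 0 (distance 1) with a
warning.

## Clustering and the number of clusters

Average linkage (UPGMA-style) merges the pair of clusters with the
smallest mean inter-cluster dissimilarity, maintained exactly by the
Lance–Williams update; ties break lexicographically on cluster indices so
results are identical across platforms. Cutting the tree at k labels
clusters by first appearance in input order.

k is chosen to maximize the average silhouette width over k ∈ [2, n−1]
(the values for which the silhouette is defined), ties toward smaller k.
Members of singleton clusters get s(i) = 0, the standard convention.  Two
consequences are documented deliberately:

* a partition whose best ASW is ≤ 0 carries no better-than-chance
  structure; `cluster_significant` then returns all singletons (no
  multi-metabolite bins) rather than an arbitrary cut;
* because k = 1 is not evaluable, a significant set consisting of one
  homogeneous chemical family cannot be reported as a single cluster; the
  realistic regime — one coherent module among chemically scattered hits —
  is exactly where the criterion works well.

Dendrograms are exported as Newick with branch lengths from merge heights.

## Classifiers

Single-metabolite models are logistic regressions with a tiny ridge term
(1e−8) so separable inputs keep finite coefficients. Multi-metabolite
families: RBF SVM (cost grid {0.25, 0.5, 1, 2, 4}, kernel width from the
median pairwise-distance heuristic), PLS-DA (1..min(5, p) components),
random forest (500 trees, mtry grid 1..p), gradient-boosted trees (depth
{1,2,3}, rounds {50,150}, learning rate 0.3). Margin-based families (SVM,
PLS-DA) emit probabilities through a logistic link fitted to their decision
values within each training fold, because threshold selection operates on
probabilities and these families do not produce them natively.

Internal validation is leave-one-out: sample i is predicted by a model fit
on all others. The probability threshold is chosen from the LOOCV
predictions: candidates are midpoints of adjacent sorted unique
probabilities plus guards toward 0 and 1 (so both constant classifiers are
reachable); the threshold maximizing accuracy wins, ties going to higher
specificity and then the lower threshold. AUC is the Mann–Whitney rank
statistic with ties counted half. The grid point with the best LOOCV
accuracy (first in declared order on ties) is refit on all training
samples and paired with its frozen threshold for external validation.
Thresholds and hyperparameters are functions of the training cohort only.

The external cohort is preprocessed independently — its own totals for
normalization and its own covariate residualization — matching the
symmetric treatment of separately collected studies; per-metabolite
centering by residualization is also what removes additive (log-scale)
batch offsets. Labels are encoded case = 1; sensitivity is case recall.

The comparison suite contains one logistic model per significant
metabolite, each ML family on each multi-member cluster of significant
metabolites, and each family on the all-metabolite and all-significant
baselines. `select_best` ranks by internal LOOCV accuracy (ties: internal
AUC, then smaller panel) and never consults external metrics.

## The synthetic-data generator

`simulate_cohort_pair` produces a training cohort and an independently
sampled, batch-shifted test cohort with known ground truth:

* per-metabolite log2 intensities ~ Normal(μ_m, σ_m), with μ_m uniform in
  [10, 16] and σ_m log-uniform in [0.3, 0.8] (a ~64-fold abundance range
  and 20–75% coefficients of variation). The ranges are deliberately
  moderate so that no metabolite dominates sample totals: a trait effect
  on a dominant metabolite would propagate through total-quantity
  normalization into spurious associations everywhere — a real phenomenon
  this generator controls by design rather than emulates;
* chemical identity from a bundled library of 70 real metabolite SMILES in
  8 chemically coherent families (amino acids, sugars, organic acids,
  nucleosides, fatty acids, sterols, phosphates, amines);
* the default signal plants a 2-SD mean shift on a 5-member saturated
  fatty-acid module plus two chemically distant singleton hits (one
  nucleoside down, one amine up), 40 cases vs 40 controls per cohort.
  Directions alternate within the module, as with substrate/product pairs,
  which also keeps total signal approximately trait-neutral. The module is
  chemically homogeneous on purpose: silhouette-based selection will
  legitimately split a family that itself contains subfamilies;
* binary covariates (gender, smoking) with per-metabolite coefficients
  ~ Normal(0, 0.3·σ_m);
* left-censored non-detects: per metabolite a Binomial(n, missing_rate)
  number of cells is deleted from the low-intensity pool (default censor
  quantile 0.4, rate 0.1);
* the test cohort is multiplied per metabolite by 2^Normal(0, 1) before
  censoring — order-of-magnitude batch shifts like those seen between
  independently processed studies.

All randomness derives from the single config seed. The ground-truth
record (signal ids and effects, family labels, module membership, batch
factors) suffices to score recall of the planted signal, adjusted-Rand
recovery of the module, and external-accuracy gaps without external data.
Module recovery is scored as the ARI between "in the module's cluster" and
"member of the planted family" over the clustered significant set, so a
same-family false positive that joins the cluster does not spuriously fail
the check, while any foreign metabolite inside the module's cluster does.

What the generator does **not** emulate: correlated metabolite co-regulation
(intensities are independent given the trait and covariates), retention-time
or spectral-annotation ambiguity, missingness that depends on batch, and
drifting covariate distributions between cohorts. Passing the recovery
studies therefore demonstrates the machinery is correct under the stated
model, not that real cohorts will behave as cleanly.

## Problem sizes used by the built-in studies

The library default of 100,000 permutations is impractical to repeat across
dozens of simulations, so the packaged studies scale it down; everything
else runs at the stated study conditions (40/40 per cohort, 70-metabolite
panel, FDR 0.075, bit cutoff 0.9):

* null calibration: 1,000 metabolites × 999 permutations, one cohort;
* null FDR: 50 seeded simulations, 100 metabolites × 999 permutations;
* module recovery: 50 seeded simulations at 2,999 permutations;
* cluster-vs-single comparison: 25 seeded simulations at 999 permutations,
  SVM family for cluster models;
* pipeline demonstration: 4,999 permutations, SVM + PLS-DA families.

## Known limitations

* Structures must be supplied explicitly; there is no name-to-structure
  resolution, standardization pipeline, or InChI support.
* MACCS keys are coarse: stereochemistry is invisible, and homologous
  series (e.g. fatty acids differing by chain length) can be nearly or
  exactly indistinguishable. That coarseness is also what makes family
  recovery work.
* The silhouette criterion cannot return k = 1 and undervalues partitions
  with many singletons; both conventions (singleton s = 0, ASW ≤ 0 →
  singletons) are configurable only by clustering manually.
* Model objects are not serialized; external validation happens in the
  same process as training (`run_all`, `metaboclust train --test`).
* LOOCV is exhaustive (n fits per grid point); for cohorts much larger
  than a few hundred samples a k-fold scheme would be preferable.
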