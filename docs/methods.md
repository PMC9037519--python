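# Methods

`gutmint` reimplements an integrated fecal microbiome–metabolome analysis
for a two-class case-control cohort (IBS patients vs healthy controls) as a
tested, reusable library. It has three analytical engines — a supervised
linear-SVM ensemble, an unsupervised kernel-t-SNE consensus subtyping
pipeline with phenotype screening, and a host+microbiome metabolic
reaction-network builder — plus a synthetic cohort generator that makes
every stage testable without access to the controlled cohort data.

## Supervised discrimination: resampled linear SVM with RFE

Models are linear support-vector classifiers (L2-regularized hinge-loss
family; scikit-learn's `LinearSVC`) trained on auto-scaled features:
each feature is mean-centered and divided by its **population** SD
(ddof = 0), with statistics estimated on the training portion only;
zero-variance training features map to 0. The protocol per resample:

1. draw a random stratified 80:20 train/test split. Splits are *tracked*:
   a `SplitPlan` carries an identity hash and every model being compared
   must run on the same plan (enforced at comparison time);
2. tune the cost parameter C over 13 candidates, 0.001 · 10^k for
   k = 0..12, by stratified 5-fold cross-validated accuracy, ties toward
   the smallest cost (balanced accuracy available by flag);
3. fit, record the test AUC (*pre-RFE*). AUC is the probability that a
   random positive outscores a random negative, ties counting ½ — equal to
   U/(n₊n₋) of the Mann–Whitney statistic;
4. recursive feature elimination on the training data: repeatedly drop the
   ⌈10% of remaining⌉ features with smallest |weight| (at least one per
   step) down to a single feature; the retained subset is the survivor
   prefix maximizing internal 5-fold CV AUC, ties toward the smaller
   subset;
5. re-tune C on the selected subset, refit, record post-RFE test AUC,
   signed weights (sign = class association) and test decision scores.

Test samples never influence scaling, tuning or selection; the suite
asserts this by corrupting test rows and checking that every fitted
parameter is unchanged.

Per-resample AUCs of two models on one plan are compared with the paired
Wilcoxon signed-rank test (zero differences dropped, midranks, normal
approximation with continuity correction); family-wise adjustment across
model comparisons is Bonferroni. `rank_scan` aggregates a species table to
each taxonomic rank (summing abundances within the rank group, conserving
per-sample totals) and runs the full protocol per rank on the shared plan.

Phenotype association models reuse the identical machinery: binary
variables run the classification path on relabeled data; continuous
variables swap in an epsilon-insensitive linear regressor (`LinearSVR`,
ε = 0.1) with Pearson r replacing both the CV tuning objective and the
test metric (the regression quality metric is not prescribed by the
original analysis; r is the natural scale-free choice for relative
intensities). Samples missing the phenotype are dropped before splitting;
fewer than 20 non-missing samples is an error (80:20 splitting plus
stratified 5-fold CV is not meaningful below that).

## Unsupervised subtyping: kernel-t-SNE consensus clustering

"Kernel t-SNE" is realized as a standard 2-D t-SNE embedding plus a
Gaussian-kernel regression map from input space to the embedding: with
kernel matrix `K` (bandwidth = `bandwidth_factor` × median pairwise
distance), the coefficients solve `K c = Y` by least squares, giving an
out-of-sample projection that reproduces training embeddings up to the
least-squares residual and maps duplicate inputs identically.

Numerical choices: perplexity 30 and 1,000 gradient iterations by default;
**random** (not PCA) initialization, so that the ensemble members explore
different cluster arrangements — the elbow statistic below is computed on
the across-model mean WSS curve and benefits from averaging over
arrangements; exact-gradient t-SNE below 500 samples (faster than
Barnes–Hut at that size and removes the tree approximation). Embeddings at
fewer than ~500 iterations are unusable: scikit-learn spends the first 250
iterations in early exaggeration.

The ensemble runs `n_models` embeddings (seeds spawned from one master
seed; 1,000 at full scale). Per model, k-means (10 restarts) is run for
k = 1..10 on the 2-D coordinates and the within-cluster sum of squared
errors (WSS) recorded. The optimal k* maximizes the second-order
difference WSS(k−1) − 2·WSS(k) + WSS(k+1) of the mean curve over
k ∈ [2, 9], ties toward the smallest k. For each k, a proximity matrix
holds the fraction of models in which each sample pair co-clusters;
average-linkage hierarchical clustering on 1 − proximity cut at k groups
gives consensus labels, and any group below the minimum size (default 5)
is merged into the group with highest average proximity to it, repeated
until all groups qualify (the final group count may be below k and is
reported). Complete linkage is available by flag.

## Phenotype screening

Each phenotype variable is tested against the consensus clusters on its
non-missing samples (pairwise-complete; no imputation): Kruskal–Wallis
(midrank tie correction, χ² p-value with k−1 df) when k > 2, Mann–Whitney
for k = 2, with binary variables encoded 0/1 into the same rank tests and
nominal categorical variables falling back to a χ² contingency test
(flagged distinctly). All identical values give H = 0, p = 1 by
convention. Raw p-values are adjusted by the Hommel step-up procedure
(equivalent to closed testing with Simes local tests; verified against an
exhaustive-subset oracle in the suite). The correction family defaults to
one family per cluster configuration spanning all variables, switchable
to a single global family across configurations. For k > 2, all cluster
pairs additionally get raw pairwise Mann–Whitney p-values for reporting.

Mann–Whitney p-values are exact (distribution enumeration) when both
groups are small (min n ≤ 20) and tie-free, and otherwise use the normal
approximation with midrank tie correction and continuity correction.

## Diversity and outlier screening

Simpson's evenness of an abundance vector is the inverse Simpson index
divided by observed richness, E = (1/Σpᵢ²)/S over the S taxa with pᵢ > 0;
it is 1 exactly for a uniform community, invariant to rescaling, and the
alternative 1 − Σp² was rejected as being Simpson diversity rather than
evenness. Prevalence summaries report the per-group fraction of samples
in which each taxon is present, compared between groups by Mann–Whitney.

The Hotelling T² screen computes T² = Σₐ tₐ²/λₐ on the leading
`n_components` (default 2) principal-component scores. The threshold is
the F-form a(n−1)/(n−a)·F₁₋α′(a, n−a) with α′ = α/n by default: α then
bounds the probability of flagging *any* sample of a clean table, which is
what an exclusion screen needs (a per-sample 1−α limit flags ~α·n clean
samples by construction; it remains available as `familywise=False`).
Screening is iterative: all samples over the threshold are removed and the
PCA refitted until none remain — gross outliers inflate the leading
eigenvalues enough to mask one another in a single pass, and after
removing one of two coincident spikes the contaminated direction can even
drop out of the top components, so batch removal per pass is used.
Intensity tables should be log-transformed before screening (the CLI does
this by default): on the raw scale, log-normal intensities put ~1% of
clean samples past even the family-wise threshold.

A 2-component screen can only see a contaminated direction whose variance
exceeds the bulk of the eigenvalue spectrum — roughly (1 + √(p/n))² for
uncorrelated features. Real spectral data concentrate variance in few
components and easily clear this bar; the generator's iid features make it
the binding constraint, which is why the synthetic spike is enormous and
why screening conditions with p approaching n (many features, few samples)
can hide even such a spike. Raising `n_components` is the remedy when a
known contaminant fails to surface.

## Metabolic reaction network

The catalog is a flat-file snapshot of KEGG-style records: reactions
(metabolite pair, main-reactant-pair flag, enzyme EC and name), enzyme →
organism gene links, and organism → family assignments with *Homo sapiens*
mapping to the host. Two metabolites are associated iff some reaction
marks them as the main reactant pair **and** its enzyme has at least one
gene link to the host or to an organism whose family is in the included
set. Qualifying enzymes contribute family–enzyme, host–enzyme and
enzyme–metabolite edges; reaction directionality is not modeled, so
metabolite–metabolite edges are undirected. Families and metabolites carry
optional direction annotations (increased in cases vs controls), from
which `families_with_enzyme` counts an enzyme's family support per
direction and `concordance_report` flags enzymes whose incident annotated
metabolites all share one direction. Exports: GraphML, a lossless TSV edge
list (with a node sidecar), and a tripartite JSON in
families | enzymes | metabolites column order.

A hand-transcribed toy catalog ships with the package covering seven
narrated enzymes (propionate CoA-transferase; the aspartoacylase class
represented by N-formylaspartate amidohydrolase; alanine–lactate ligase;
lactate 2-monooxygenase; valine N-monooxygenase; carnosine synthase;
beta-alanine–histidine dipeptidase) with their direction annotations.
Family names not given in the narration are synthetic placeholders
(`ToyHCxx`/`ToyIBSxx`) present only to reach the narrated family counts;
the full reaction network of the original study depends on a KEGG snapshot
that cannot be reconstructed and is out of scope.

## Synthetic cohorts

The generator emulates the structure of the study data: compositional
species abundances with a family lineage, positively skewed metabolite
intensities, ~200 mixed-type phenotype variables, two diagnosis classes
and latent case subgroups. All randomness flows from one seed through
spawned generators, so equal configs give bit-identical outputs.

* **Microbiome** — species log-abundances are N(μⱼ, 1) with base means
  μⱼ ~ N(0, 2²) (wide abundance range with a heavy right tail after
  exponentiation); class effects add ±`effect_size` (in within-group SD
  units) on the log scale for the informative species *before* a Bernoulli
  sparsity mask (default 30% zeros per cell) and closure of each row to
  sum 1. With `n_informative_families` set, the generator switches to a
  family-structured mode: the class effect acts on *family log-totals*
  (one sign per family) and member-species abundances are the family
  total times a per-sample Dirichlet composition
  (`family_concentration = 3` scaled by member count around heavy-tailed
  base weights). Species-level variation is then within-family
  replacement that cancels on aggregation — the natural model of
  family-level biology with species-level noise (functional redundancy),
  and the regime in which rank aggregation genuinely helps. Shifting each
  member species individually instead plants signal at both ranks and
  lets a species-level model win by sheer feature count.
* **Metabolome** — log-normal intensities (log-SD 1); same class-effect
  mechanism; the last feature is a polymer contaminant which, in the
  designated outlier samples, is set `spike_sd` (default 5000) within-group
  SDs above its mean — a PEG-dominated spectrum is orders of magnitude
  above the metabolites, and on the log scale this still amounts to only
  ~9 SD.
* **Subgroups** — only case samples carry subgroup labels (balanced
  assignment). The subgroup-signature features (disjoint from the
  class-informative set; defaults 20 taxa / 16 metabolites) are split
  round-robin into one exclusive marker block per subgroup, and members of
  subgroup g gain `subgroup_shift` SD on block g: subtype-specific marker
  signatures whose centroids are symmetric. (Random ± patterns were
  considered and rejected: they give irregular between-subgroup distances,
  and the second-difference elbow then prefers merging the closest pair —
  a property of the geometry, not of the estimator.)
* **Phenotypes** — continuous variables are standard normal; binary
  variables Bernoulli with per-variable base rates in [0.25, 0.75]. A
  linked continuous variable gains g·`subgroup_shift` for cases in
  subgroup g; a linked binary variable shifts its log-odds by the centered
  version of the same pattern. Missing cells are inserted completely at
  random at `missing_rate`.

What the generator does **not** emulate: taxon–taxon correlation beyond
closure, overdispersion/zero-inflation structure tied to sequencing depth,
metabolite–taxon cross-correlations, longitudinal sampling, or raw
NMR/sequencing artifacts. Passing tests therefore demonstrate that the
pipeline recovers planted structure under a clean generative model, not
performance on real cohorts.

## Problem sizes in the test suite and acceptance script

Library defaults follow the full-scale analysis (1,000 resamples, 1,000
kt-SNE models); the test suite and `scripts/acceptance.py` run the same
code at desk scale as the package's own choice of problem size: 50–100
resamples per ensemble, 100 kt-SNE models for the subtype-recovery check
and 20 models per master seed for the elbow-stability check (fewer models
make the mean WSS curve noisier, so this is the conservative direction),
with t-SNE at 500 iterations.

Null calibration pools resamples across independent null cohorts: a single
finite null cohort carries a spurious class signature, so its conditional
mean test AUC over resamples scatters around 0.5 with SD ≈ 0.06 (measured
0.43–0.59 across seeds); pooling 10 cohorts × 10 resamples tests the same
hypothesis with SD ≈ 0.02. The acceptance script reports the pooled value.

## Known limitations

* The cost grid upper end (C = 10⁹) can hit the liblinear iteration cap on
  noise-like folds; convergence warnings are suppressed and the affected
  candidates simply score what the capped solver achieves.
* Hommel adjustment is delegated to statsmodels; the exhaustive
  closed-testing construction lives in the test suite as the oracle.
* `consensus_groups` merges undersized groups greedily (smallest first);
  other repair orders are possible and can differ on adversarial proximity
  matrices.
* The reaction network treats an EC number as one enzyme; organism-level
  isoenzyme differences within a family are not represented.
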