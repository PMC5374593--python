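# Methods

## Model

The core object is a first-order dependence tree over discrete variables
X₁…Xₙ (SNP minor-allele dosages with 3 states; demographic variables
with k ≥ 2 states), conditioned on a binary class C (0 = control,
1 = case).  The joint is approximated as

P(X₁,…,Xₙ | C) = ∏ᵢ P(Xᵢ | X_{mᵢ}, C),

with mᵢ the tree parent (the root has none and is conditioned on C
alone).  Edge weights are plug-in (MLE) estimates of the
class-conditional mutual information

Î(X, Y | C) = ∑_c P̂(c) ∑_{x,y} P̂(x,y|c) · log[ P̂(x,y|c) / (P̂(x|c) P̂(y|c)) ]

in natural log, with 0·log 0 ≡ 0, computed on pairwise-complete samples
(missing genotypes are a distinct state at I/O time and are dropped
per-pair here).  The maximum-weight spanning tree over this matrix is
also the maximum-likelihood dependence tree, a fact the test suite
verifies exhaustively for small n by enumerating all labeled trees via
Prüfer sequences.

Because every node also has C as a parent, the model is a
tree-augmented naive Bayes classifier.  The score of a sample is the
log-likelihood ratio ∑ᵢ [log P̂(xᵢ|x_{mᵢ}, case) − log P̂(xᵢ|x_{mᵢ},
control)]; a factor whose child or parent value is missing is skipped in
both sums, keeping scores comparable across samples.  The class prior is
excluded by default — the classification rule compares the bare
products — and can be enabled (`use_prior=True`).

## Numerical choices

* **Kruskal tie-breaks.** Edges of equal weight are taken in
  lexicographic (i, j) order; with all weights equal this yields the
  star rooted at the first node.  Deterministic structure for
  deterministic input.
* **Root selection.** The node with the largest total incident tree
  weight, ties to the lower node index.  Any root yields the same joint
  distribution; the choice only fixes the direction of edges in the
  serialized network.
* **CPT smoothing.** P̂(Xᵢ=a | X_{mᵢ}=b, C=c) = (n_abc + α) /
  (n_bc + α·kᵢ) with Laplace α = 1 by default, so every factor of the
  classification product is strictly positive and scores are finite.
  Edge weights always use the unsmoothed MLE.  A never-observed parent
  cell at α = 0 is filled uniformly; it can never be hit when scoring
  the data the table was fitted on.
* **Root invariance vs smoothing.** The factorization is exactly
  root-invariant at the MLE (α = 0 on complete data), and the suite
  checks scores agree to 1e-9 across all roots there.  With α > 0 the
  per-factor smoothing is applied in the directed parameterization, so
  different roots give (very slightly) different smoothed models; this
  is why the root is fixed deterministically rather than left free.
* **Discretization.** Continuous demographics are quantile-binned
  (default 4 bins); ties go to the lower bin, equal quantiles are
  merged, missing stays missing.
* **Degenerate inputs.** Monomorphic SNPs get association p = 1, not an
  error; CMH strata with a zero margin are dropped with a warning; a
  SNP monomorphic on complete pairs has LD r² defined as 0;
  cross-chromosome r² is 0 by definition (bins never span chromosomes).

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `hwe` | 1e-4 | exact HWE p-value threshold, per race stratum; a SNP fails if it is below the threshold in **any** stratum |
| `maf` | 0.01 | minor allele frequency floor (all samples, non-missing calls) |
| `call_rate` | 0.98 | SNP call-rate floor (strict <  removes) |
| `sample_rate` | 0.98 | sample genotyping-rate floor (strict > keeps) |
| `p_threshold` | 5e-4 | CMH candidate threshold for network construction |
| `step` | 50 | SNPs removed (largest CMH p) per backward iteration |
| `r2` | 0.4 | LD threshold for Carlson tag-SNP binning |
| `k_folds` | 3 | stratified CV folds for every AUC used in ranking |
| `B` | 1000 | permutation networks per null distribution |
| `alpha` | 1 | Laplace pseudocount for CPTs |

The CMH test runs on 2×2 allele-count tables (case/control ×
minor/major) stratified by race, matching standard GWAS practice; the
stratifying covariate is configurable.  The HWE test is the exact
(enumeration-based) two-sided test — the sum of probabilities of all
heterozygote counts no more likely than the observed one — computed via
log-gamma in the package and validated against an exact-rational
enumeration in the tests.  The Cochran–Armitage trend statistic uses
linear scores (0, 1, 2) and the exact finite-population (hypergeometric)
variance with the (N−1) factor.

## Network search and composition

Backward elimination evaluates the candidate set plus **all**
demographic variables, removes the `step` SNPs with the largest CMH
p-values, and repeats until ≤ `step` SNPs remain (final set still
evaluated); the best network is the one with the highest CV AUC, ties
to fewer SNPs.  The LD branch first collapses candidates to tag SNPs
(greedy Carlson binning: repeatedly bin the SNP with the most unbinned
partners at r² ≥ threshold; the tag must reach r² ≥ threshold to every
bin member, ties to the smallest CMH p).  Between the two branches, ties
go to the smaller network, then to the plain backward branch.  Because
candidate selection uses the full data, CV AUCs are ranking metrics
only, and are reported as such.

Composition analysis scores each gene/pathway as the CV AUC of a fresh
tree on its SNPs plus race and sex (so race- or sex-specific SNPs can
show their effect), and each demographic factor or edge as the decline
in resubstitution AUC on removal — resubstitution because CV noise
swamps the small declines.  On node removal, orphaned children are
re-attached to the class node alone (CPT refit as P̂(X|C)).  Null
distributions come from random same-size SNP sets drawn from the
background (default: the candidate set that entered network
construction; configurable to the full post-QC set), with race and sex
always included; p = (r + 1)/(B + 1), never zero, flagged at the
non-adjusted 0.05 level.  A null distribution depends on an item only
through its sub-network size, so nulls are cached per distinct size
rather than redrawn per item.

## Synthetic data

The generator emulates the cohort structure this framework targets:
two ancestry groups mixed 0.30/0.70 whose allele frequencies differ by
per-SNP Gaussian offsets (sd 0.08), 15 interview-style demographic
variables (income with 9 levels, education with 4, five-level childhood
home, binary trauma/abuse items, continuous age/weight/height/
attendance — the continuous ones quantile-binned downstream), uniform
missingness (1%), and LD blocks built by copying a founder SNP with 5%
flip noise.  Genetic signal comes in three flavors: a planted dependence
tree sampled ancestrally with class-conditional CPTs (a child copies its
parent with probability 1 − ε, ε = 0.25, and the case-conditional table
is shifted by a total-variation `edge_effect`, default 0.15); a
contiguous block of strongly associated "causal gene" SNPs
(case–control allele-frequency difference 0.25); and a polygenic
background of weakly associated SNPs (difference 0.12).  The polygenic
background is there on purpose: it makes the candidate set entering the
network larger than the causal gene itself, which is what the
permutation null assumes, and it mirrors the many-small-effects premise
of the application domain.  Tree components share their founder's
allele frequency so epistatic SNPs remain in Hardy–Weinberg
proportions and survive QC.

Desk-scale defaults (500 samples per class, 200 SNPs) keep every test
and the full pipeline fast; the structure-recovery experiments use
5,000 samples per class, at which size the learned tree recovers
essentially all planted edges.  What the generator does **not** emulate:
coalescent-realistic haplotype structure, liability-threshold
phenotypes, genotyping batch effects, or relatedness.  Passing tests
therefore demonstrate correctness of the machinery and calibration
under the stated generative model, not performance on real cohorts.

## Known limitations

* The dependence-tree assumption is a modeling convenience; nothing
  guarantees biological dependencies are tree-shaped.  The model is the
  maximum-likelihood *tree*, not the maximum-likelihood graph.
* LD r² is the composite (genotype-dosage correlation) version, not an
  EM haplotype-phase estimate; at the sample sizes involved the two are
  close, but phased r² can differ for rare variants.
* Ordinal demographics (income, education) are treated as nominal in
  the CPTs; their ordering is only used by discretization.
* X-chromosome hemizygous males arrive as homozygous calls in text PED
  and are coded 0/2 like everyone else.
* p-values from B permutations resolve no finer than 1/(B + 1), and the
  0.05 flags are non-adjusted by design.
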