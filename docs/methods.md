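# Methods

## Model and procedure

`netprog` predicts a binary prognosis label from tumour gene expression by
using overlapping protein-interactome modules as the feature units. The
pipeline is:

1. **Label derivation.** From censored follow-up records, a patient is *bad*
   (y = 1) if the event (death or metastasis) occurred within the cutoff k
   years and *good* (y = 0) if followed event-free to at least k. Patients
   censored before k carry no usable outcome and are excluded: labelling them
   good would contaminate the good class with patients who may have had early
   events. This makes the good label monotone in k (good at k ⇒ good at every
   k′ ≤ k), a property the tests enforce.
2. **Module filtering.** Modules are consumed as files (the output of an
   overlapping-cluster tool run on the interactome); module detection itself
   is out of scope. A module is kept only if at least 1/3 of its genes have
   expression rows — the boundary is inclusive — and kept modules are
   restricted to their measured members, so the module size s_m used in
   averages is the measured member count (unmeasured genes cannot contribute
   to an expression average).
3. **Class standardization.** Per gene, means and SDs of expression are
   computed separately over good- and bad-labelled *training* patients;
   P (good-standardized) and Q (bad-standardized) values follow. SDs use the
   sample (n−1) convention. Genes with fewer than two observations or zero
   variance in either class are flagged and excluded rather than
   epsilon-floored — flooring a zero SD would manufacture unbounded
   standardized signal out of a degenerate gene.
4. **Features.** "Averaged" mode: two features per module, G (mean P over the
   module's usable genes) and B (mean Q); a patient's missing values are
   skipped, the denominator being that patient's observed-gene count.
   "Expanded" mode: all per-gene P/Q values per module. A value that cannot
   be computed at all (expanded-mode missing entry, or an averaged module
   where a patient observes no member gene) is set to 0, the class mean on
   the standardized scale — the least-informative imputation. "auto" picks
   the better mode by inner-CV AUC on the training fold.
5. **Regression.** The 0/1 label is fitted by Gaussian least squares with the
   elastic-net penalty in the unscaled convention RSS + λ·Σ[((1−α)/2)β² +
   α|β|]. The printed objective is Gaussian even though the outcome is
   binary; a binomial-family variant exists but is off by default. Features
   are already class-standardized by construction, so no internal
   re-standardization is applied (it would double-scale G/B).
6. **Clinical arm.** Clinical covariates are low-dimensional, so they get a
   maximum-likelihood logistic fit with a small L2 guard (default 0.01,
   coefficients only) against separation; categorical covariates are one-hot
   encoded in sorted category order. The final score is Y = k·Y₁ + (1−k)·Y₂,
   k grid-searched on inner-CV AUC (default grid 0:0.01:1; ties prefer the
   smaller k). With no clinical table the model degenerates to k = 1.
7. **Evaluation.** Stratified 5-fold CV repeated 50 times from one master
   seed (derived child seeds < 2³¹), so competing configurations see
   identical splits. One AUC per repeat pools the five test folds' scores;
   per-fold AUCs and coefficient vectors are kept for stability analysis.
   AUC is the midrank (tie-aware) formulation; accuracy is reported at the
   accuracy-optimal ROC point (with symmetric costs the optimal slope is
   S = N/P, equivalently minimise FP+FN; threshold ties prefer higher
   sensitivity) and at the strictest threshold reaching 90% sensitivity.
   AUC sets are compared by a two-sided Mann–Whitney U test — exact when both
   sets are small (min n ≤ 8) and tie-free, otherwise the tie-corrected
   normal approximation.
8. **Biomarkers.** Each module's coefficient is the larger-magnitude of its
   G/B (or per-gene) coefficients. Modules in the top and bottom q% of the
   coefficient distribution are significant; q = 2 by default with q = 10 as
   a supported alternative, both recorded in outputs. Tail size is
   round(q·n/100) (at least 1), ties broken lexicographically by module id so
   degenerate coefficient vectors still select deterministically. The
   consensus set across CV fits contains modules significant in ≥ 50% of
   fits. Enrichment uses unique gene sets: Ef = C/T over all filtered-module
   genes, Of = X/N over significant-module genes, En = Of/Ef, and
   p = P[Binomial(N, Ef) ≥ X]. Stability is the Spearman correlation of
   shared significant-module coefficients over all pairs of fits (pairs
   sharing < 2 modules are skipped and counted).

## Numerical choices

* Optimisation is scikit-learn coordinate descent. The unscaled objective is
  mapped onto sklearn's 1/(2N)-scaled convention by alpha_skl = λ/(2N),
  l1_ratio = α; every model records this in its `scaling` tag. At α = 0 the
  fit therefore solves (XᵀX + (λ/2)I)β = Xᵀy on centered data, which the test
  suite checks against the closed form to 1e−6 relative error.
* Grids: α ∈ {0.05, 0.10, …, 1.0}; λ is a 50-point log grid per α from
  λ_max = 2·max|X_cᵀy_c|/α (the smallest all-zeroing λ) down four decades.
  (α, λ) minimise inner-CV mean squared prediction error (3 inner folds);
  ties prefer the sparser model — smallest α, then largest λ.
* Selection paths run warm-started with a precomputed Gram matrix and a
  capped iteration budget (they only need ranking accuracy); the refit at the
  chosen pair re-runs the warm-started path at tolerance 1e−4 and raises,
  naming (α, λ), if the duality gap refuses to close even at a 10× budget.
* Percentile CIs for the median AUC are the 2.5/97.5 percentiles of the
  per-repeat AUC distribution (the CI construction for this quantity is a
  design choice; no canonical form exists for pooled repeated-CV AUCs).
* Edge deletion removes round-half-up(fraction·|E|) edges uniformly without
  replacement from the sorted edge list; the node set is unchanged, so
  modules are later restricted to nodes still incident to an edge before the
  coverage filter is re-applied.

## The synthetic-data generator

The generator emulates the structure the method assumes: a gene universe with
overlapping module blocks, an interactome densified within modules (edge
probability 0.6) over sparse background edges, and expression equal to a
per-gene baseline + the mean latent activity of the gene's modules + Gaussian
noise. *Planted* modules shift their latent mean between classes, so member
genes are differentially co-expressed as a block; the shift is calibrated so
a single-module planted gene's class-mean gap is `effect_size` within-class
SDs. Defaults: 1,000 genes, 200 patients, 50 modules (sizes 5–15, overlap
probability 0.2), 5 planted modules at effect size 2, noise SD 1, bad-class
prevalence 0.35, 10% of patients censored before the 5-year cutoff, 1%
missing expression entries, one weakly informative numeric clinical covariate
(strength 0.8) plus one uninformative categorical one. Event times are
truncated-exponential within the cutoff for the bad class and
cutoff + exponential for the good class.

Structural randomness (module membership, network, gene baselines, which
modules are planted) derives from a seed built from the structural config
fields alone, while patient-level randomness follows the master seed: two
cohorts with different master seeds share their "disease biology" and differ
only in patients, which is what makes cross-cohort prediction a meaningful
synthetic experiment.

What the generator does **not** emulate: microarray probe effects, batch and
platform differences, heavy-tailed or heteroscedastic noise, correlated
censoring, and module catalogues that disagree with the expression signal.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of block-structured signal — not expected AUC levels on real
cohorts, which depend on dataset quality.

## Problem sizes used in tests and the acceptance script

CV-based checks run at 5 folds × 10 repeats on the 200-patient default cohort
(null calibration and signal recovery) and at 2–3 folds/repeats on a compact
100-patient cohort for harness-level checks (cutoff sweep over k = 3…14,
network robustness, determinism); these sizes give stable medians for the
properties asserted while keeping the suite quick on a single CPU.

## Known limitations

* The Gaussian least-squares objective on a 0/1 outcome is a linear
  probability model; scores are not calibrated probabilities (the combined
  model mixes them with logistic probabilities on the k-weighted scale).
* Expanded mode multiplies features by the mean module size and is
  correspondingly slower; with very small cohorts its inner-CV mode selection
  is noisy.
* The exact-vs-asymptotic switch in the Mann–Whitney comparison follows
  sample size and tie structure, so p-values for small tied samples are
  approximate.
* Module coefficients from averaged mode collapse G/B pairs by magnitude; a
  module whose G and B coefficients are large with opposite signs is reported
  by its dominant arm only.
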