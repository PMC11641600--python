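# Methods

## The model

`edgemarker` selects a small set of *edge* (gene-pair) and *node* (single
gene) biomarkers that separate two or more sample classes in an expression
matrix, using information from a protein-protein interaction (PPI) network.

**Edge features.** For a PPI between genes u and v, the law of mass action
gives the concentration of the u:v complex as proportional to
`alpha * [u]^a * [v]^b`. With reaction constant and stoichiometric
coefficients set to 1 (the defaults; mRNA taken as a proxy for protein
concentration), the per-sample interaction affinity of edge i = (u, v) is
the product `a_ji = x_ju * x_jv`. Each edge also carries a co-expression
weight `B_uv`, the Spearman rank correlation of the two genes across
samples, zeroed below a cutoff `k` (default 0.5): an edge only counts as a
functional interaction in contexts where its partners are actually
co-expressed. Edges with zero thresholded weight are dropped from the
feature system — their model coefficients would vanish identically.

**Node features.** Plain expression columns, one per candidate gene
(default: every gene that survived filtering).

**The selection LP.** Sample classes are modelled as ellipsoids around
their centroids. With feature weights `w` in [0, 1] and deviation
constants

    d_jik = B_i * (a_ji - a_ik)^2      (edge feature i)
    d_jik = (x_ji - x_ik)^2            (node feature i)

where `a_ik`, `x_ik` are class-k means, the LP is

    min  sum_edges w_i + lambda * sum_nodes w_i
         + alpha * sum_k (Z1_k - Z2_k) + C * sum_{j,k} eta_jk
    s.t. sum_i w_i d_jik <= Z1_k + eta_jk     (j in class k)
         sum_i w_i d_jik >= Z2_k - eta_jk     (j not in class k)
         0 <= Z1_k <= Z2_k,  0 <= w_i <= 1,  eta_jk >= 0.

`Z1_k`/`Z2_k` are the inner/outer radius of class k's ellipsoid; in-class
samples must fall inside `Z1`, others outside `Z2`, up to penalized slack.
Minimizing the weight sum keeps the biomarker set small; `alpha` rewards
the radius gap; `C` charges classification errors. Features with optimal
`w_i >= weight_tol` (default 1e-6) are reported. The all-zero point is
always feasible with objective 0, so the optimum is never positive, and a
sufficiently small `alpha` (or large `C`) yields the *trivial solution* —
no biomarkers. The formulation generalizes verbatim to C > 2 classes
(every out-of-class pair gets an outer-radius row); this is implemented
and tested at three classes, though typical applications are binary.

Solved with HiGHS (`scipy.optimize.linprog`), deterministic for fixed
inputs; primal feasibility is re-verified at 1e-8 (scaled) before a
solution is accepted. The test suite cross-checks optima against an
independently written dense Bland's-rule simplex.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `lambda_` | 1 | node cost relative to edge cost; 1 treats genes and interactions as equally expensive biomarkers |
| `alpha` | 0.1 | reward per unit of inner/outer radius gap |
| `penalty_C` | 100 | cost per unit slack (classification error) |
| `coexpression_cutoff` (k) | 0.5 | minimum B for an edge to enter the model |
| `weight_tol` | 1e-6 | minimum optimal weight to count a feature as selected |

`alpha` and `penalty_C` are *data-scale dependent* (deviations are squared
expression units; no standardization is applied, though an optional
z-scoring flag exists on the evaluation side). They are therefore
determined per dataset by grid search over `alpha in {0.02, 0.1, 0.5, 1}`
and `C in {0.1, 1, 10, 100}`; the default rule keeps non-trivial cells and
prefers the largest `C`, then the smallest `alpha` (few errors, few
biomarkers). A `cv_auc` rule that maximizes cross-validated AUC is also
available. Qualitatively — and asserted as a regression property — the
biomarker count is non-decreasing in `alpha` and the total slack
non-increasing in `C`. The end-to-end recovery experiments in the
acceptance harness run this full protocol (grid search, then selection at
the chosen pair), since the fixed pair (0.1, 100) sits exactly at the
trivial-solution boundary on a minority of synthetic replicates.

## Co-expression: formula and scope

Two deliberate choices, both exposed:

* **Denominator.** The standard rank-difference denominator `m(m^2 - 1)`
  is the default (`formula_mode="standard"`, values guaranteed in
  [-1, 1]). A `legacy` mode with denominator `m(m - 1)` exists for
  replicating published variants that print it that way; for m >= 3 it
  leaves the unit interval (m = 3, reversed ranks gives -7), so it is not
  the default. Ties get average ranks.
* **Scope.** `spearman_coexpression` defaults to the pooled all-sample
  coefficient, which is what the rank-difference formula literally
  computes. The *selection pipeline*, however, defaults to
  `scope="per_class_max"`: B computed within each class, maximum kept.
  Rationale: the cutoff exists to impose context specificity, and the very
  signal edge biomarkers carry — differential co-expression, e.g. +0.8 in
  one class and -0.8 in the other — pools to a correlation near zero, so
  the pooled coefficient would discard exactly the edges the model is
  built to find. An edge strongly co-expressed in at least one context
  survives. The pooled scope remains one flag away. Strongly
  *anti*-correlated edges are zeroed by the one-sided cutoff by default;
  `absolute=True` thresholds |B| instead and uses |B| as the multiplier
  (keeping the LP's deviation constants non-negative).

## Gene filters

* **Missing values**: any gene with a missing entry is dropped.
* **Entropy**: per gene, expression is discretized into `n_bins` (default
  10) equal-width bins between the gene's min and max; genes whose
  Shannon entropy (bits) falls below `min_entropy` are dropped. A constant
  gene has entropy 0. Without an explicit threshold the lowest-entropy 10%
  is dropped — note this relative mode is not idempotent (each application
  removes another decile); the threshold mode is.
* **Replicate ratio**: a gene is dropped if, within any replicate group,
  (max + pseudocount)/(min + pseudocount) > 100 (the conventional TPM
  reproducibility rule). Pseudocount defaults to 0; an all-zero group
  counts as ratio 1.

Gene identifiers match by exact string comparison after whitespace
stripping; alias resolution is out of scope.

## Evaluation

Sensitivity, specificity and accuracy come from the pooled out-of-fold
confusion table (score threshold 0.5, configurable), computed in exact
rational arithmetic; AUC is the rank-based Mann-Whitney estimator with tie
correction. The classifier is a binomial GLM (logistic regression with
intercept) on the selected features — node features as expression, edge
features as B-weighted expression products — with train-fold
standardization and a small L2 ridge (1e-4) so perfect separation cannot
diverge. Folds are stratified by class and seeded. Two protocols:
`mode="preselect"` selects features once on the full dataset (the protocol
conventionally reported with selectors of this family; it leaks), and
`mode="nested"` re-selects inside each training fold. On
exchangeable-class data the preselect-mode AUC exceeds the nested-mode AUC by
≈0.3 on average in our harness — the size of the leakage. The Welch
(unequal-variance) two-sample t-test at p < 5e-5 serves as the node-only
baseline selector.

## Synthetic data

The generator draws log-normal expression (non-negative, TPM-like):
background genes i.i.d. with identical distributions in both classes.
Defaults, fixed once: baseline log-mean 2.0 and log-SD 0.5 (median ≈ 7.4,
a plausible scale for filtered expressed genes), 200 genes, 30 + 30
samples, 120 background PPI edges.

* **Node plants** (default 5): class-2 log-mean shift of 2 log-SD — a
  classical DEG.
* **Edge plants** (default 5): the pair is bivariate normal on the log
  scale with correlation +0.8 in class 1 and -0.8 in class 2, identical
  marginals. Neither gene shifts, but for jointly log-normal X, Y,
  `E[XY] = exp(2 mu + sigma^2 (1 + rho))`, so the pair's affinity mean is
  class-dependent. Node-based selectors are provably blind to these pairs;
  this is the cleanest testbed for the claim that edge information helps.

What the generator does *not* emulate: microarray probe effects, batch
effects, library-size variation, count noise, heavy-tailed outliers beyond
log-normality, or realistic PPI topology (background edges are uniform
random pairs). Passing recovery tests therefore show the machinery works
under its own model of the data, not that it will recover biology from any
particular real cohort.

Under the null design (no plants) the default pipeline returns the trivial
solution in ≥ 90% of replicates — a regression property of the defaults.
Under the planted design, the full protocol recovers on average ≥ 98% of
node plants and ≈ two-thirds of edge plants, while the t-test baseline
finds ≈ 0% of edge-plant genes.

## TSS signal normalization

Per gene, the window [TSS - flank, TSS + flank) is tiled by `n_bins`
half-open 0-based bins (standard layouts: 5 kb/100 bins and 3 kb/60 bins,
both 100 bp). Bins are ordered 5'→3' in transcript orientation (reversed
for minus-strand genes). Fragments are counted by the midpoint rule
(boundary midpoints go to the right bin); depth is the total fragment
count of the sample's BED file. Normalization:
`H = h * 1e9 / (depth * L_j)`, averaged across samples. Windows crossing
position 0 are clipped with the lost-bin count recorded. Exact invariances
(asserted as tests): joint scaling of counts and depth; bin-width halving
of a uniform signal; averaging of identical replicates.

## Numerical and degenerate-input choices

* Constant genes: co-expression undefined → B set to 0 with a warning
  record; entropy 0; never selected by the t-test (p treated as 1).
* Biomarker report ordering: descending weight, ties broken by feature
  index — deterministic output.
* Trivial solution: reported as an empty set with an explicit flag (CLI
  exit code 3), never silently.
* Oracle instances for the LP cross-check are drawn with
  `penalty_C >= 1 >= alpha`, which guarantees boundedness (if
  `alpha > C * m_out` for some class, the outer radius plus slack is a
  negative-cost ray).
* Recovery/leakage experiment sizes (20 and 50 replicates, 200- and
  100-gene matrices) were chosen as the package's standard benchmark
  sizes; all derive their seeds deterministically from one base seed.

## Known limitations

* The LP is scale-sensitive: `alpha`/`C` must be re-searched per dataset,
  and very differently scaled feature blocks (squared products vs squared
  expression) can make edge features dominate. The optional z-scoring in
  evaluation does not change the selection itself.
* With large `alpha` the solution is not sparse (many weights hit the
  upper bound); sparsity is only obtained near the trivial boundary.
* Gene-level entropy filtering parameters are stand-ins, not a
  reconstruction of any published threshold.
* The per-class co-expression scope requires ≥ 3 samples per class.
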