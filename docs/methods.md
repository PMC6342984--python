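# Methods

## The deconvolution model

A bulk RNA-seq profile of a solid tissue is modeled as a mixture of
cell-type-specific expression programs measured in single cells. With
θ<sub>jg</sub><sup>k</sup> the relative abundance of gene *g* in cell
type *k* of subject *j* (pooled counts over that subject's type-*k*
cells, normalized to sum one over genes) and S<sup>k</sup> the average
library size of a type-*k* cell (the observable proxy for cell size),
the bulk relative abundance satisfies

    Y_g = C · ( Σ_k p_k S^k θ_g^k + ε_g ),      ε_g ~ N(0, δ_g²),

with p the cell-type proportions (non-negative, summing to one) and C
an unidentifiable normalizing constant. Identifiability rests on three
assumptions: (A1) reference and bulk subjects are draws from one
population, so θ<sub>jg</sub><sup>k</sup> has a common mean
θ<sub>g</sub><sup>k</sup> and variance σ²<sub>gk</sub> across subjects;
(A2) cell-size *ratios* between types are conserved across subjects;
(A3′) library-size ratios equal cell-size ratios (equal capture
efficiency across types). When A3′ fails — efficiencies γ<sup>k</sup>
differ by type — the proportion estimate is predictably biased toward
normalize(p/γ) while the RNA-fraction vector q ∝ p·S is still
consistently estimated; both are therefore reported, and the generator's
efficiency knob reproduces exactly this bias (it is asserted in the
test suite).

## Estimation

The regression is run on the θ columns over the genes shared between
bulk and reference, after rescaling bulk and design to mean one over
those genes (this fixes the scale on which the damping constant ν and
the variance term live; the estimate itself is scale-invariant). The
raw non-negative coefficients q ∝ C·p·S<sup>k</sup> are the RNA
fractions up to scale; proportions are recovered as
p = normalize(q/S̃<sup>k</sup>), which absorbs C and enforces the
sum-to-one constraint.

Marginalizing over cross-subject signature variability gives
Var[Y_g|p] = δ_g² + Σ_k (p_k S^k)² σ²_gk = 1/w_g. Since δ is unknown,
weights are estimated iteratively from the fit itself:

    w_g = 1 / ( ν + r_g² + Σ_k q_k² σ²_gk ),

with r the current residual vector and q the current coefficients, both
on the regression's own scale so that C cancels. Iteration starts from
the unweighted NNLS solution (a uniform-proportions start is available
and converges to the same fixed point — asserted to 1e-6 in the
acceptance suite) and stops when the L1 change of p drops below `tol`.

Numerical choices: `tol = 1e-4` (L1 on p), `max_iter = 1000`,
`ν = 1e-4` on the mean-one scale (guards against zero denominators;
when residuals, variances and ν are all zero every weight hits a common
floor, so the scheme degenerates exactly to unweighted NNLS). The inner
solver is the Lawson–Hanson NNLS; weights enter by row-scaling with
√w. A bulk vector whose NNLS solution is identically zero yields
uniform proportions with `converged=False` and a warning, never NaNs.
An all-zero shared-gene intersection is an error. TPM input is rejected:
without per-type library sizes the cell-size factors cannot be formed.

The optional `center` switch removes a multiplicative gene-specific
offset shared across cell types (a crude protocol-bias correction); it
is experimental and off by default.

## Tree-guided recursion

Closely related cell types give nearly collinear design columns, and
the error of the flat fit concentrates along the poorly identified
directions. The recursive mode takes a user-supplied partition of the
cell types (normally read off the dendrogram produced by
`cluster_cell_types`; an automatic cut helper exists but is never
applied silently) and proceeds in two stages:

1. **Cluster proportions.** Each cluster is collapsed to a
   representative column (unweighted mean of member θ columns and of
   member size factors) and the collapsed design is fit by W-NNLS on
   *cluster-consistent genes* — the `keep_fraction` of genes with the
   smallest worst-cluster within-cluster variance of θ, on the relative
   scale (variance / squared mean abundance). The relative scale keeps
   the score comparable across the orders-of-magnitude spread of gene
   expression; a singleton cluster contributes its cross-subject
   variance instead, the only within-type variability available.
2. **Within-cluster resolution.** Each non-singleton cluster is
   resolved by a *joint* W-NNLS over all cell types — restricting the
   design to one cluster's columns would be misspecified, since the
   other types' contributions to the bulk must be absorbed somewhere —
   run on the stage-2 gene set, after which the member types' relative
   proportions are rescaled to sum exactly to the cluster's stage-1
   estimate. Nested groupings recurse with the remaining types riding
   along as singletons.

Two stage-2 gene policies are implemented. The default, `complement`,
uses the expressed genes *not* selected at stage 1 — the genes that
actually discriminate within clusters. The alternative, `reselect`,
re-selects genes with low within-type (cross-subject) variance per
cluster. Under purely exchangeable cross-subject noise the re-selection
score carries no discriminating information and merely halves the gene
count, so the complement is the default.

When is the recursion worth it? Under a perfectly specified reference
the flat weighted fit is close to the efficient generalized
least-squares estimator, and no staged procedure can beat it — the
recursion's value appears when the reference is *systematically* wrong
in ways the cross-subject variance cannot flag, most importantly
per-cell-type capture bias that manufactures apparent differences
between genuinely similar types. Stage 1 is insulated from such genes
by construction (they are not cluster-consistent), so the cluster
totals stay accurate and the residual split error is confined within
clusters. The planted-collinear scenario encodes exactly this regime
(see below), and the replicated acceptance checks assert the resulting
median-RMSD ordering.

## Synthetic data generator

The generator emulates precisely the structure the estimator assumes,
plus the stressors studied:

- Base signatures per type are symmetric-Dirichlet draws (concentration
  0.3 over 1000 genes — a realistically sparse, long-tailed
  transcriptome profile).
- Cross-subject variation (A1) perturbs the base on the log scale:
  θ ∝ θ₀·exp(ε − sd²/2), ε ~ N(0, sd²), renormalized. The −sd²/2 offset
  makes the pre-normalization mean exactly θ₀, so to excellent
  approximation at 1000 genes E[θ] = θ₀ and
  Var[θ] = θ₀²(e^{sd²}−1) — closed-form targets the moment tests check.
  A Dirichlet subject law with matched mean is available.
- Cells are multinomial given Poisson totals around
  depth · S^k · γ^k (A2/A3′ knobs: per-type cell sizes, default a 4×
  geometric spread; per-type efficiencies, default uniform). An
  optional gamma multiplier on θ yields negative-binomial-style
  overdispersion.
- Dropout zeroes count entries independently at a uniform rate
  (an expression-dependent logistic variant is provided; the uniform
  one is what the tests use).
- Bulk samples mix *fresh* subjects' signatures (drawn from the same
  population as, but disjoint from, the reference subjects), scaled by
  true cell sizes, with per-gene log-normal noise (sd 0.1) and
  multinomial sampling to depth 1e5.

Default study conditions: 1000 genes, 6 types, 6 reference subjects,
50 cells per type, per-cell depth 2000, cross-subject sd 0.25, 10 bulk
samples per scenario with Dirichlet(2) mixing proportions. These sizes
keep every test and the acceptance script comfortably sub-minute while
leaving all estimated quantities well away from small-sample
degeneracy.

Named scenarios: `baseline`; `heteroscedastic` (a random 25% of genes
get cross-subject sd 1.2 vs 0.05 elsewhere — the regime where variance
weighting matters); `collinear_pair` (two planted pairs of types with
base-signature correlation ≈0.995, and a per-type gene-wise capture
bias exp(N(0,0.3)) applied to the *reference* counts only, identical
across subjects so that cross-subject variance cannot flag it);
`missing_celltype` (a ~5% cell type present in the bulk but removed
from the reference; accuracy is scored over the reference's types with
the truth renormalized, since the estimator cannot emit an unseen
type); `mismatched_composition` (reference cell counts per type
strongly skewed relative to the bulk mixing); `biased_theta` (gene-wise
multiplicative reference bias shared by all types); `dropout` (rate
0.3).

What passing these tests does **not** show: the generator draws
independent genes (no co-expression modules), a single batch, no
ambient RNA or doublets, no gene-length effects, and read/UMI counts as
faithful molecule proxies. Real-data performance additionally depends
on annotation quality of the single-cell labels, which are taken as
given here.

## Benchmarking and metrics

Artificial (pseudo-)bulk samples are built by summing each subject's
single-cell counts per gene, so the true proportions are the
cell-count fractions; with leave-one-out holdout, each subject's
pseudo-bulk is deconvolved against a reference built from the other
subjects only (provenance is recorded and audited in tests). Cells
with sentinel labels ("NA", "unclassified") are excluded from both the
bulk and the truth, and counted.

Estimates are scored by Pearson correlation R, RMSD = √avg(p−p̂)² and
mAD = avg|p−p̂|, computed on the flattened samples × types matrix
("overall") or per sample / per cell type. An undefined correlation
(constant truth, e.g. equal cell counts everywhere) is reported as
missing, never coerced to zero.

## Design choices that were genuinely open

- **Variance estimator** for σ²_gk: sample variance (n−1) by default
  (two-subject references are common and n−1 is the conventional
  unbiased choice); population variance available.
- **Subject averaging**: unweighted across subjects (exchangeable
  subjects), with cell-count weighting as an option.
- **Absent (subject, type) pairs** are excluded from the pooled mean
  and variance, not imputed as zeros — imputation would fabricate
  cross-subject variance.
- **Genes**: the reference keeps all genes (zero-count genes carry
  θ = σ² = 0 and get no weight); intersection with the bulk happens at
  fit time. No marker pre-selection anywhere.
- **keep_fraction** defaults to 0.5 per recursion stage.
- **Stage-1 representative column**: unweighted member mean. A
  split-weighted collapse was evaluated and does not improve cluster
  sums enough to justify the extra coupling between stages.

## Known limitations

- Only count-scale input is supported; RPKM/TPM conversion is out of
  scope (TPM is rejected with an explanatory error).
- Proportions are relative; absolute cell counts are not estimable.
- The protocol-bias centering option is a heuristic and off by default.
- The recursion requires a user-chosen grouping; no automatic choice of
  recursion stages is attempted.
- With a single reference subject the cross-subject variance is zero
  and the method degenerates (with a warning) to unweighted NNLS on
  that subject's signatures.
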