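# Methods

## The problem

Bulk RNA-seq measures the average expression of a mixed cell population.
Given a labelled single-cell reference from the same tissue, reference-based
deconvolution estimates, for each bulk sample j, the vector of cell-type
proportions p_j = (p_j1, …, p_jK) on the simplex (p_jk ≥ 0, Σ_k p_jk = 1).
Two obstacles dominate in practice: (i) single-cell and bulk protocols have
different capture characteristics, so the reference and the mixtures live in
systematically shifted expression distributions; (ii) marker information is
unevenly spread over genes, and selecting a small marker panel throws most
of it away. This package addresses (i) with kernel-mean-matching domain
adaptation and (ii) with a per-gene specificity score that lets the whole
common gene set participate in the fit, weighted by how exclusively each
gene marks a type.

## Pipeline

1. **Gene intersection.** Reference and bulk are restricted to their common
   genes G (|G| = d), in the bulk row order.
2. **Per-column normalization.** Every cell and every bulk sample is scaled
   to 10 000 total counts (`target_sum`, default 10 000). All downstream
   algebra is on the linear scale; no log transform is used anywhere,
   because the mixing model is linear in expression.
3. **KMM transformation** (optional, on by default) of the bulk samples
   toward the reference distribution.
4. **Signature construction** from the labelled reference: cosine scores,
   mean expression per type, cell-size factors.
5. **Constrained regression** per bulk sample: relative abundance →
   (weighted) non-negative least squares → renormalization to the simplex.

## Kernel mean matching

Bulk samples x_i (i = 1…n_bulk) and reference cells x_j (j = 1…n_sc) are
points in R^d over the common genes, after per-column normalization. KMM
estimates weights β_i ≈ p_sc(x_i)/p_bulk(x_i) by minimizing the empirical
squared Maximum Mean Discrepancy between the β-weighted bulk cloud and the
cell cloud in the RKHS of the RBF kernel κ(x, x′) = exp(−‖x−x′‖²/(2σ²)):

    min_β  ½ βᵀ K_bb β − (n_bulk/n_sc) βᵀ K_bs 1
    s.t.   0 ≤ β_i ≤ B,   |mean(β) − 1| ≤ ε

Defaults: B = 1000; ε = (n_bulk − 1)/n_bulk; σ = median pairwise Euclidean
distance over the pooled (bulk ∪ cells) point set. The median heuristic is
computed over the pooled set because the bandwidth must be meaningful for
both the bulk–bulk and bulk–cell Gram matrices. The problem is a convex QP
of dimension n_bulk; it is solved with SLSQP using the analytic gradient,
with K_bb symmetrized and jittered by 1e-10·I so near-duplicate samples
cannot make it indefinite, and the mean constraint written as two linear
inequalities. On failure ε is doubled once (`solver_status =
"infeasible_relaxed"`), then the solve errors out. `mmd_before` (β ≡ 1) and
`mmd_after` are reported; β ≡ 1 is always feasible, so `mmd_after ≤
mmd_before` up to solver tolerance.

Two deliberate edge-case policies:

- **n_bulk = 1.** ε defaults to 0 and the mean constraint pins the single
  weight to 1; the solve is skipped and β = (1) returned with a warning.
- **β_j = 0 downstream.** The transformed bulk is Y = β·x_bulk (each column
  scaled by its weight). Because each sample is subsequently reduced to
  relative abundance (divided by its own sum), the proportion estimate for
  sample j is *constant in β_j* for every β_j > 0. When bulk samples are
  near-duplicates at the kernel scale (e.g. replicate pseudobulks of one
  mixture), K_bb ≈ 11ᵀ and the QP optimum legitimately concentrates all
  weight on one sample, zeroing the others. The pipeline resolves those
  zero columns by continuity (as if β_j = 1) rather than dropping samples.
  A corollary worth stating plainly: on a per-sample solver, the per-sample
  scalar β changes the estimates only through quantities that couple
  samples; the KMM step is a distribution diagnostic and a no-op for the
  per-sample fit. It is retained (and on by default) because it implements
  the published transformation exactly and reports the MMD gap.

## Signature matrix

For gene g (cell-space vector over the N reference cells, normalized
matrix) and cell type k with m_k cells, the ideal vector v_k is the 0/1
membership indicator. The cosine similarity

    cos(g, v_k) = (Σ_{j ∈ C_k} x_jg) / (‖g‖₂ √m_k)

is scale-free in the gene's abundance. The contribution score is

    r(g, k) = cos(g, v_k)⁵ / (μ Σ_{t ≠ k} cos(g, v_t)² + 1)
    score(g, k) = ln(1 / (1 − r)),   r clipped to ≤ 1 − clip_delta

with μ ≥ 0 (default 1) the off-target penalty and clip_delta = 1e-10
guarding the singularity so a perfectly exclusive marker receives the large
finite weight ln(1e10) ≈ 23.03. The score is 0 for a gene silent in type k,
strictly increasing in the target cosine, and weakly decreasing in μ and in
every off-target cosine. All-zero genes get cosine 0 by convention so the
algebra stays total.

θ_gk is the mean normalized expression of g over cells of type k, and the
stored signature is S = θ ⊙ score. Cell sizes S_k — the per-type mean raw
library size rescaled to mean 1 — convert RNA-content fractions into
cell-count fractions, so the returned proportions are proportions of
*cells*, not of RNA.

## Proportion estimation

Each bulk sample's relative abundance y (y_g = Y_g/Σ Y_g′) follows

    y_g ∝ Σ_k p_k S_k θ_gk.

The scores enter this regression as **per-gene weights**: gene g's equation
is multiplied by ω_g = max_k score(g, k) on both sides. This was a genuinely
open design point. Folding the per-(gene, type) scores into the design
matrix alone (regressing y on θ⊙score directly) changes the linear model
per type and is measurably biased — on noiseless 60/30/10 pseudobulks it
misallocates ~10 percentage points of mass per type — whereas two-sided
per-gene weighting is ordinary weighted least squares: unbiased, while still
letting type-specific genes dominate by factors of 10²–10⁵ over
housekeeping-like genes. The literal elementwise variant remains available
as `SolverConfig(score_weighting="elementwise")` for sensitivity analysis,
and `design_matrix()` still exposes S·diag(S_k) as an object.

Non-negativity is enforced by Lawson–Hanson NNLS; the sum-to-one constraint
is applied afterwards by renormalizing the raw weights (the mixing model is
proportional, so a single normalization constant absorbs the scale). The
default solver adds MuSiC-style iterative gene reweighting on top of ω:
starting from the plain NNLS fit, each iteration solves NNLS on
(√w·A, √w·y) with

    w_g = 1 / (ν_g + r_g² + τ),   τ = 1e-8,

where ν_g is the variance across types of the solution-scaled design row
(cross-cell-type variation) and r_g the current residual (misfit). The
iteration stops when the solution moves less than `tol` (1e-6) in max-norm
or after `max_iter` (100) rounds. The published framework this follows does
not print its recursion; this scheme realizes its stated principle and is
isolated behind `SolverConfig` so an alternative can be swapped in.

Genes whose signature row is all zero (or whose ω_g = 0) are dropped at
solver assembly only, keeping the earlier stages composable. A design
matrix with column rank < K triggers an "unidentifiable" warning — e.g. a
reference in which every gene is expressed uniformly across types yields
identical signature columns and cannot be deconvolved.

## Synthetic benchmark generator

The simulator emulates the pseudobulk benchmark design: per-type expression
programs with planted markers, counts with realistic noise, pools of
labelled cells summed at known proportions, and a cross-protocol bias
between the reference and the bulk side.

- **Programs.** Gene base means are log-normal (meanlog 1, sdlog 1, i.e.
  median ≈ e ≈ 2.7 counts); each type's mean vector multiplies the base by
  a mild log-normal heterogeneity (sdlog 0.15) so types differ beyond
  markers; each of `markers_per_type` (default 50) planted exclusive
  markers is elevated `marker_fold`-fold (default 5, a typical scRNA-seq
  marker effect size) in its own type only.
- **Counts.** Negative binomial with var = μ + φμ², φ = `nb_dispersion`
  (default 0.1, 10x-like); per-cell library factors are log-normal with
  sdlog `libsize_lognorm_sigma` (default 0.3), centred to mean 1 so
  empirical type means converge to the programmed means.
- **Protocol shift.** Each gene row of the bulk side is multiplied by a
  fixed log-normal(0, `shift_sigma`²) capture factor and re-rounded;
  `shift_sigma` = 0 is the identity. This is the simplest mechanism that
  produces the reference/bulk distribution gap KMM targets.
- **Pseudobulks.** Per type, ⌊p_k·n_cells + ½⌋ cells are drawn (without
  replacement when possible) from a pool *disjoint* from the reference
  cells, and raw counts are summed ("pooling reads"). The ground truth
  recorded is the realized, post-rounding composition, so rounding cannot
  bias the evaluation. Mixing proportions are Dirichlet(1,…,1) or fixed;
  defaults are n_cells = 500 and 3 types (benchmark tissues in this setting
  span 3–9).

What the generator does **not** emulate: doublets, ambient RNA, dropout
beyond NB sampling, cell-type-correlated library sizes, batch structure
within the reference, or mis-labelled cells. Passing tests therefore show
correctness of the algorithm under its own model assumptions plus moderate
count noise and gene-wise capture bias — not robustness to every failure
mode of real tissue data.

## Metrics

- **Mean L1 error** = (1/K) Σ_k |est_k − truth_k|, reported in percentage
  points (×100) by default; aggregated as mean over types per sample, then
  mean over samples.
- **JSD** with log base 2 (so the range is exactly [0, 1]); inputs are
  normalized to probability vectors internally; computed via the squared
  Jensen–Shannon distance.
- **PCC**, the standard Pearson correlation.

## Numerical choices

- QP: SLSQP, ftol 1e-12, 500 iterations max, analytic gradient; Gram jitter
  1e-10.
- NNLS: scipy's Lawson–Hanson implementation (deterministic); verified in
  the tests against exhaustive active-set enumeration for K ≤ 4.
- Score clip: r ≤ 1 − 1e-10. Float64 cancellation near the clip limits the
  perfect-marker score to ~1e-8 relative accuracy, which the tests reflect.
- Proportions are validated to sum to 1 within 1e-8; written at 6
  significant digits and renormalized on read so round-trips stay on the
  simplex.
- Duplicate gene ids are summed on read (count-preserving); gene matching
  is exact string match after whitespace stripping.

## Problem sizes

The bundled benchmarks run at 2000 genes, 3–6 types, 300 reference cells
per type, 3 pseudobulk samples per replicate and 500–1000 pooled cells per
pseudobulk — small enough to iterate on a laptop, large enough that the
estimator operates in its intended regime (n ≫ K, markers in the hundreds).
Under these conditions the noiseless (shift-free) benchmark inverts
mixtures with mean L1 error well under 1 percentage point, and the 60/30/10
three-component design recovers the dominant component within a fraction of
a point of 60%.

## Known limitations

- The per-sample scalar KMM weights cannot alter per-sample estimates (see
  above); correcting gene-wise protocol bias would require a gene-level
  transformation, which is a different method family and out of scope.
- The W-NNLS recursion is a faithful stand-in, not a port of the original.
- Proportions come with no uncertainty quantification.
- Readers for HDF5/AnnData-native formats and 10x directories are not
  provided; MTX + sidecars and delimited tables are.
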