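# Methods

This note records the models implemented in `distimpute`, the defaults and
why they were chosen, the numerical decisions taken where the design was
genuinely open, and what the synthetic benchmarks do and do not establish.

## Data model

A `MaskedDistanceMatrix` couples an N×N symmetric non-negative matrix
(zero diagonal) with a symmetric boolean mask; `True` marks a missing
unordered pair, of which there can be 0 … N(N−1)/2. Cells under the mask
may retain hidden ground-truth values so benchmarks can score imputations,
but the writer always emits the marker token for them. One on-disk dialect
is supported (square, relaxed-PHYLIP, `NA` marker, full-precision values);
lower-triangular input is deliberately rejected to keep round trips
bit-exact and unambiguous.

## Distance estimators

Both estimators use pairwise deletion: for each pair, only columns where
both sequences carry an unambiguous character count. IUPAC ambiguity codes
are treated as missing characters, the simplest defensible rule.

**TN93.** The closed-form Tamura–Nei (1993) estimator from the observed
transition proportions P1 (A↔G), P2 (C↔T), transversion proportion Q, and
base frequencies π pooled over *both* sequences at the shared sites.
Pooling makes the estimate exactly symmetric in its arguments, which the
rest of the pipeline assumes. This is the textbook moment estimator, not
MEGA's composite-likelihood variant ("MLCompositeTN93"), whose internals
are not published; on the simulations used here the two agree in the
regime where distances are defined at all. A distance is *missing* when no
sites are shared, a required frequency product is zero, or a logarithm
argument is non-positive (saturation).

**LogDet.** d = −ln det F with F the 4×4 (or 20×20 for amino acids)
site-pattern proportion matrix, implemented literally — no −¼-type
normalization, so the value is a matrix property rather than a
per-site rate. The arguments are put in canonical order before the
determinant so floating-point symmetry is bit-exact (det Fᵀ = det F holds
only approximately in floating point). Singular F (e.g. a base absent
from both sequences) gives a missing value.

A pair is also masked when it shares fewer than `min_shared` sites
(default 1). Marginally negative finite-sample estimates are floored at 0.

## Matrix factorization imputer

R ≈ X·Yᵀ with X, Y ∈ ℝ^{N×K}. Defaults: K = N, learning rate α = 0.002,
regularization β = 0.02, stop when the epoch's total squared error E over
observed lower-triangular entries falls below 10⁻⁶, cap 10,000 epochs.

Decisions worth recording:

* **E is a sum of squared errors.** Signed residuals could cancel; the
  squared form is the quantity the gradient actually descends.
* **Per-entry objective.** The regularizer is implemented as
  (β/2)(‖x_i‖² + ‖y_j‖²) per observed entry — exactly the function whose
  gradient reproduces the update rules above. A finite-difference test
  pins this correspondence to 10⁻⁶ relative accuracy.
* **Simultaneous update.** Within one entry update, e_ij is computed once
  and both coordinate updates use the pre-update values.
* **Fixed sweep order.** One epoch visits the observed lower-triangular
  entries in row-major order, not shuffled: determinism is worth more
  here than the marginal stochasticity of reshuffling.
* **Initialization** is Uniform[0, 1) from a mandatory seed; identical
  seed + input ⇒ bit-identical output.
* **"Iterations" count epochs** (full sweeps), not single-entry updates.
* Negative predictions are clamped to 0 (distances are non-negative), and
  observed entries are never overwritten.
* Training errors exceeding 10¹² or going non-finite raise a divergence
  error rather than returning garbage.
* The epoch loop is JIT-compiled with numba; this changes nothing about
  the arithmetic, only its speed.

## Autoencoder imputer

Rows of the scaled matrix are the training samples (an N-vector in, an
N-vector out). Architecture: three ReLU hidden layers, default widths
(N, ⌈N/2⌉, N), sigmoid output. The sigmoid forces a scaling step:
distances are divided by 1.05 × the largest observed entry (values then
lie in [0, 1/1.05]), and multiplied back on output. If every observed
entry is zero the scale is undefined and unit scale is used with a
warning.

Training interleaves learning and imputation: missing cells start as
seeded Uniform[0, max-scaled-observed) values; each iteration takes one
Adam step (step size 10⁻³) on all rows as a batch against the masked loss
L(R,R′) = Σ_{non-missing} (R_i − R′_i)², then blends the *deterministic*
(dropout-free) predictions into the missing cells, x′ = (1 − w)x + wp with
w = 0.5. Stops at L < 10⁻⁶ or 10,000 iterations.

Decisions:

* **Dropout 0.75** on hidden activations, training passes only, inverted
  scaling (kept units divided by 0.25). At default widths the expected
  active hidden width is N/4 ≤ N/2 — the capacity constraint that makes
  the autoencoder undercomplete in effect, not just in shape.
* **The loss is the printed sum**, not a mean, and the 10⁻⁶ threshold is
  applied to that sum. One "iteration" is one full pass over all rows.
* **Diagonal zeros are observed cells** and participate in the loss; they
  anchor the output scale.
* All stochasticity (weight init, dropout masks, random fill) flows from
  one seed, so runs are exactly reproducible; predictions used for
  blending are dropout-free for the same reason.
* The network output need not be symmetric; imputed cells are symmetrized
  by averaging (i,j) and (j,i) at the end. Observed cells are restored
  verbatim, so only imputed cells are touched.
* A complete input skips training entirely and is returned unchanged
  (both imputers).

## Trees and comparison

Neighbor joining uses the standard Q-criterion agglomeration with ties
broken at the lowest (row, column) pair and negative branch lengths
clamped to 0 — deterministic, and provably exact on additive matrices
(verified over 50 random trees in the suite). NJ stands in for FastME's
balanced minimum evolution: it is compiled-dependency-free and
well-specified, and the matrix writer emits files FastME can consume for
users who prefer it. RF evaluation is builder-agnostic.

The RF rate is |B1 △ B2| / (|B1| + |B2|) over non-trivial splits, each
canonicalized as the side not containing the smallest leaf label. The
denominator equals the usual 2(n−3) when both trees are binary and
degrades gracefully for multifurcations; n ≤ 3 (no internal edges) gives
rate 0. dendropy backs newick parsing/serialization and path-length
matrices; bipartition extraction, the rate itself and NJ are native, with
dendropy's NJ used as an independent cross-check in the tests.

## Synthetic data

`random_tree` draws a uniformly random unrooted binary topology by
sequential random edge attachment, with i.i.d. Uniform[0.05, 0.5]
branch lengths by default. `simulate_alignment` evolves i.i.d. sites down
the tree under HKY (rate matrix exponentials, root at stationarity; JC is
κ = 1 with uniform frequencies); the default is a two-gene concatenated
alignment of 500 + 500 sites, mirroring the two-mitochondrial-gene design
(COI + CytB) the indirect missingness mechanism models.
`perturbed_matrix` multiplies each additive distance by (1 + ε),
ε ~ N(0, σ²) truncated positive.

The indirect-count benchmarks (37- and 201-taxon two-gene alignments) use
milder branch lengths — Uniform[0.01, 0.1] and Uniform[0.002, 0.03]
respectively, 800 sites/gene — chosen so that pairwise divergence stays in
the comfortably estimable range (maximum true distance ≈ 1
substitution/site), as in real intrafamilial mitochondrial data. That is
what makes the missing-entry count a pure property of the removal design
(n1 × n2) rather than of estimator saturation; under the default
deep-divergence lengths additional pairs saturate and are masked too,
which is correct behavior but a different experiment.

No coalescent/ILS gene-tree discordance is simulated: species-tree-scale
noise is emulated by the multiplicative matrix perturbation instead.
Consequences for interpretation: passing benchmarks show the imputers
recover *additive or near-additive* structure from partial matrices; they
do not certify performance under gene-tree conflict, alignment error, or
compositional heterogeneity, which real data add on top.

## Benchmark scales and pipeline

The shipped benchmarks run at desk scale — 20-taxon matrices with 5% of
pairs deleted (10 replicates) for tree-accuracy comparisons, an 8×8
complete matrix for the MF interpolation check, 201 taxa only for the
missingness-count identity — sizes at which the full default training
budgets (10,000 epochs/iterations) complete in seconds per run while
exercising every code path. The pipeline derives per-replicate seeds as
master + replicate index (masking) and master + 1000 + index (imputer
init), reports mean RF and standard error (sample SD/√r), and embeds all
seeds in the report rows. The reference tree is the model tree for
synthetic input and the NJ tree on the complete matrix for file input.

## Known limitations

* TN93 here is the closed-form estimator, not MEGA's composite-likelihood
  one; absolute distances can differ slightly near saturation.
* The AE loss with dropout 0.75 is noisy; the stopping rule on the raw
  sum effectively means the iteration cap is what usually terminates
  training. The blend loop still converges in practice because the
  deterministic predictions stabilize much earlier.
* MF with K = N has O(N²) parameters and O(N²·K) work per epoch; beyond a
  few hundred taxa the AE is the cheaper of the two, consistent with its
  better scaling behavior.
* Imputed matrices are generally not additive; NJ on them is a heuristic
  whose quality degrades with the fraction missing, steeply so past ~50%.
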