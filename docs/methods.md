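# Methods

This note documents the model, the numerical conventions, the synthetic
data-generating process, and the design decisions taken where the design
was genuinely open. It states no empirical result beyond what the test
suite and `scripts/acceptance.py` compute at run time.

## Feature derivation

**Functional connectivity.** Pearson correlation across ROI time-series
columns, symmetrized, diagonal pinned to 1, then min-max scaled over the
off-diagonal entries (diagonal re-pinned to 1). A zero-variance ROI column
is an error naming the ROI — the correlation is undefined, and silently
imputing it would corrupt the graph.

**Intrinsic neural timescale (INT).** For ROI signal y with mean ȳ,

    r(k) = Σ_{t=k+1..T} (y_t−ȳ)(y_{t−k}−ȳ) / Σ_t (y_t−ȳ)²,
    INT = TR · Σ_{k=1..N} r(k)

with N the lag immediately preceding the first negative r. Conventions:
if r(1) < 0 then INT = 0; if r never turns negative the sum runs to the
largest retained lag, T−2. (For this autocovariance estimator the lags sum
to −1/2, so a fully nonnegative prefix is an edge case that essentially
only arises for tiny T; the fallback keeps the estimator total.) The
estimator uses the shared mean ȳ and the full sum of squares in the
denominator — not a per-lag re-centered variant. INT is computed directly
per ROI from ROI-level time series; pipelines that average voxel-wise
estimates within a parcel use the identical estimator one level down, and
ingesting voxel data is out of scope. This is a deliberate, documented
approximation.

**SC normalization.** `raw(i,j)/√(V_i·V_j)` corrects the streamline count
for the sizes of the connected regions (larger parcels accumulate more
streamlines), followed by min-max scaling of the off-diagonal entries.
Zeros are preserved whenever any zero entry exists (the off-diagonal
minimum is then 0), which holds for any realistically sparse SC.

**Min-max of a constant array** is defined as all zeros: it avoids 0/0 and
keeps degenerate inputs inside [0,1].

**Structure–function coupling.** Spearman rank correlation (average ranks
for ties, via `scipy.stats.spearmanr`) between ROI q's SC row and FC row,
restricted to off-diagonal entries with SC > 0 — coupling is evaluated
over a region's existing white-matter connections, the convention in the
structure–function coupling literature. ROIs with fewer than 3 nonzero SC
entries (or a constant row on the support) get coupling 0. Because
Spearman is invariant under strictly monotone transforms, it is irrelevant
whether the scaled or unscaled FC enters.

**Anatomical table.** Column order is fixed: the nine morphology columns
(vertex count, surface area, gray-matter volume, mean/sd cortical
thickness, mean curvature, Gaussian curvature, intrinsic curvature index,
folding index), then INT, then coupling — d_c = 11. Each column is
log1p-transformed (plain log available for strictly positive columns) and
min-max scaled; columns that can be negative (curvatures, coupling) are
shifted to their minimum first so the log is defined — min-max scaling
retains only within-column order anyway, which the shift preserves.

**Scaling scope.** All min-max scaling is within subject (per matrix, per
column). Nothing in the protocol pins this down; within-subject scaling
needs no cohort pass and makes subjects exchangeable. Cohort-level scaling
would preserve between-subject level differences at the cost of a global
pass; the within-subject choice means any *global* per-subject offset in a
feature is invisible to the model, which the synthetic generator respects
(see below).

## Graph construction

Per node, the k largest off-diagonal entries strictly above the edge
threshold (0.001) are selected; the edge set is the **union** of the
selections (an edge survives if either endpoint picked it), so degrees may
exceed k; nodes with no supra-threshold connection simply keep whatever
they have — possibly nothing, in which case the self-loop added inside the
model keeps them alive. Union rather than intersection keeps sparse SC
graphs connected; intersection is available behind a flag. Edge weights
are the scaled connectivity values (binary adjacency behind a flag); the
symmetric normalization inside the model then rescales them. FC defines
the topology for multimodal runs, SC for SC-only runs. Node features are
connectivity-profile rows (FC row ‖ SC row, d₀ = 2Q; Q for single-modality
ablations) — the common convention in this literature for "features
amalgamated at the nodal level".

**Top-k at desk scale.** The reference protocol keeps the top 30 of 359
possible neighbors (~8%) at Q = 360. At the package's desk scale (Q = 40)
the same absolute k would keep 30 of 39 neighbors and make the graph
near-complete, destroying the sparsification's purpose. `desk_config`
therefore uses k = 8 (~20% of 39), preserving the spirit — a sparse graph
whose edges the mask can meaningfully rank — while leaving `RunConfig`'s
default at the protocol value k = 30.

## Model

Two masked GCN layers share one free matrix V (initialized at 0, so the
mask starts flat at 0.5); M = sigmoid(V + Vᵀ) is symmetric with entries in
(0,1) by construction. The filter is F = (M + I) ⊙ S with
S = D̃^{-1/2}(A+I)D̃^{-1/2}: the Hadamard product means the mask only
modulates edges that exist (plus self-loops), and the +I term guarantees
an identity path even at M = 0. The learned M also has a diagonal,
redundant with +I; it is trained but ignored by interpretation. Hidden
widths d₁ = d₂ = 64 and a 32-unit dense hidden layer before the linear
output are package choices (unreported upstream); activations are ReLU on
the graph layers and the readout hidden layer, identity on the output.
Pooling is mean over nodes — it preserves permutation invariance and keeps
edge saliency in the mask rather than the pooling; sum/max are flags.
Dropout is omitted: regularization comes from weight decay, the mask
penalties and the manifold term, and omitting it keeps the forward pass
deterministic.

Classification uses two logits with softmax cross-entropy; AUC ranks by
the logit difference, and Grad-CAM differentiates the selected class
logit (standard practice; probability-space gradients only rescale).

Everything is numpy. The backward pass is derived analytically (including
the route from both layers' filters back to V and the Grad-RAM gradient
with respect to the fused AS block) and validated against central finite
differences for every parameter tensor in the tests.

## Objective and training

L = L_e + α·L_manifold + L_mask.

- **L_manifold** = trace(Hᵀ L H) on the *last* layer's embeddings, with L
  the unnormalized Laplacian of the **binary** support of the subject's
  adjacency. This is the only reading under which the double-sum form
  ½ΣΣ‖h_q−h_j‖² and the trace form are identical (unit weights over
  neighborhoods); both forms are checked against each other in the tests.
  Batch value is the mean over subjects.
- **L_mask** = λ₁‖M‖₁ + λ₂‖M‖²_F + λ₃‖MMᵀ−I‖_F, computed once per step
  (the mask is population-level). The prose orthonormality conditions
  (unit-norm, zero-mean rows) are not enforced as hard constraints —
  sigmoid-range entries cannot have zero mean — only this soft penalty is
  applied. The unsquared Frobenius term uses subgradient 0 at MMᵀ = I.
- Defaults λ₁ = λ₂ = 1e-3, λ₃ = 1e-4, α = 1e-5 were fixed once to balance
  the terms' magnitudes against a unit-variance prediction loss at Q = 40
  (‖M‖₁ ≈ Q²/2 at init; the manifold trace is O(Q·degree·d₂)); the
  upstream protocol tunes these by random search and reports no values.

Training: Adam (lr 0.005, weight decay 1e-6 on layer/readout weights —
V has its own penalties, biases are exempt), batch size 32, 50 epochs,
ReduceLROnPlateau (factor 0.5, patience 10) on validation total loss,
best-validation checkpointing. Regression targets are standardized on the
training split and predictions mapped back, so errors are reported on the
original score scale. The **manifold monitor** guards against embedding
collapse: if the epoch's batch-mean manifold loss falls below a floor
(default 1e-3), α is halved and the event logged — the corrective action
is unspecified upstream ("monitored with a predefined threshold"); halving
is gentle and reversible in effect. Divergence (non-finite loss) aborts
with diagnostics. Splits are 70/10/20, stratified by label for
classification (protecting extreme-group designs). Bootstrap evaluation
re-draws splits and re-seeds training per repetition (what is resampled is
ambiguous upstream; re-drawn splits measure the pipeline variance that the
reported mean ± sd is meant to capture); model comparisons use Welch's
two-sample t-test.

## Interpretation

**Mask thresholding.** Retained entries satisfy M_ij > t strictly, on the
(0,1) sigmoid scale. The published rule as printed applies a second
sigmoid to M, which would compress (0,1) into (0.5, 0.731); thresholds
near 0.52 are consistent with either reading, so the direct comparison is
the default and the double-sigmoid reading is behind a flag. The diagonal
is excluded from reporting. The mask penalties shrink all entries during
training, so the absolute scale of a trained mask depends on λ and epoch
count; the visualization threshold is meant to be adjusted per run (the
edge *ranking*, which the recovery analyses use, is threshold-free).

**Grad-RAM / Grad-CAM.** a = softmax(mean_q ReLU(G_q ⊙ C_q)) per subject,
then the mean over subjects (per-group means for classification).
Averaging after the per-subject softmax keeps every subject's attribution
on a common simplex so no subject dominates; the alternative order is not
pinned down upstream.

**Network aggregation.** Mean retained weight per network pair is computed
over retained edges only; density is retained/possible pairs. Unlabeled
ROIs belong in an "Others" network by convention of the caller's label
file.

## Synthetic cohort

The generator emulates the statistical structure the method assumes, with
every ground-truth ingredient returned for scoring:

1. Q ROIs in near-equal contiguous blocks; base correlation ρ_in = 0.35
   within, ρ_out = 0.05 between; per-subject jitter (sd 0.04) projected to
   the nearest valid correlation matrix (eigenvalue clipping at 1e-4 +
   diagonal renormalization).
2. Time series from x_t = φ ⊙ x_{t−1} + e_t with cov(e) the subject
   correlation and per-ROI AR(1) coefficients φ ~ U[0, 0.6] — giving INT
   genuine regional heterogeneity to recover. The implied stationary
   correlation corr_ij = R_ij·√((1−φ_i²)(1−φ_j²))/(1−φ_iφ_j) is stored as
   ground truth; sample FC converges to it entrywise as T grows (tested).
3. Raw SC: Poisson counts with rate 15 within-block vs 0.3 between (sparse,
   nonnegative, integer, symmetric, zero diagonal), log-normal subject and
   edge jitter; so SC shares the FC community structure.
4. Gray-matter volumes and the nine morphology columns log-normal at
   parcel-plausible scales.
5. Target: y = β_e·z(Σ_{(i,j)∈E*} FC_ij·SC_ij) + β_a·z(Σ_{c∈S*} mean_q
   AS_qc) + ε, with E* 5% of within-block pairs, S* three of the nine
   morphology columns, both components measured **on the very features the
   model ingests** (so the planted signal is exactly expressible in the
   model's input space), z-scored so β are effect sizes in sd units;
   β_e = β_a = 1, ε ~ N(0, 0.5²) (≈ 90% of target variance is signal).
   y is rescaled to mean 100 / sd 15, a cognition-composite-like scale.
   Labels: median split by default; extreme-group quantiles optionally.
6. The informative-column effect is a *regional* shift (block-0 ROIs only)
   of the column's log-values per subject: a global shift would be erased
   by within-subject min-max scaling, a regional one survives it — and
   regionally expressed anatomical effects are the biologically meaningful
   case anyway.

Defaults (n = 300 subjects, Q = 40, 4 blocks, T = 400, TR = 0.8 s) are the
desk-scale study conditions used by the tests and the acceptance script:
minutes on one CPU while preserving the statistical regime.

**What the generator does not emulate:** hemodynamic forward models,
voxel-level structure, scanner/site effects, motion artifacts, realistic
tractography biases, or heavy-tailed score distributions. Passing recovery
tests therefore demonstrate the *method's* correctness and sensitivity
under its own assumptions, not performance on real MRI cohorts.

## Known limitations

- The backward pass is architecture-specific; changing the network shape
  means re-deriving gradients (the finite-difference harness in the tests
  makes that safe).
- Single-target and two-target regression are supported; the synthetic
  target is one-dimensional.
- The mask is population-level by design; it cannot express
  subject-specific edge saliency.
- Hyperparameter random search is available only as a documented manual
  procedure over `RunConfig`, not a subcommand.
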