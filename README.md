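# neuromask

Interpretable masked graph neural networks for multimodal brain-network
analysis.

Predicting individual cognition from neuroimaging usually draws on several
complementary views of the brain: functional connectivity (FC) from
resting-state fMRI, structural connectivity (SC) from diffusion imaging
tractography, and regional anatomy from structural MRI. `neuromask` is a
toolkit for researchers who want to fuse these modalities on a shared
cortical parcellation of Q regions of interest (ROIs), fit a single graph
neural network against cognitive scores, and — crucially — read back *which
connections* and *which anatomical features* carried the prediction.

## Method

**Features** (all per subject, on a common Q-region parcellation):

- **FC**: Pearson correlation between ROI time series, min-max scaled.
- **SC**: streamline counts normalized by regional gray-matter volume,
  `SC(i,j) / sqrt(V_GM(i) · V_GM(j))`, then min-max scaled.
- **INT** (intrinsic neural timescale): `INT = TR · Σ_{k=1..N} r(k)`, the
  repetition-time-scaled area under the initial positive phase of the
  signal autocorrelation `r(k)`; a per-ROI duration in seconds.
- **Structure–function coupling**: per-ROI Spearman correlation between the
  ROI's SC profile and FC profile over its existing connections.
- **AS** (anatomical statistics): nine surface-morphology/volumetric
  columns plus INT and coupling (d_c = 11), log-transformed and min-max
  scaled.

**Model.** Each subject is a graph: nodes are ROIs, the adjacency `A` keeps
each node's top-k supra-threshold connections (FC-defined for multimodal
runs), node features are the FC/SC connectivity-profile rows. A single
population-level **edge mask**

    M = sigmoid(V + Vᵀ) ∈ (0,1)^{Q×Q},  V trainable

reweights message passing in both layers of a GCN:

    H^{l+1} = φ( (M + I) ⊙ D̃^{-1/2} Ã D̃^{-1/2} H^l Θ^l ),   Ã = A + I

After layer 1 the node embeddings are concatenated with the AS table `C`
(`H¹ = Ĥ¹ ⊕ C`), layer 2 shares the same mask, the node axis is
mean-pooled, and a dense readout emits the prediction (scores for
regression, logits for classification).

**Objective.**

    L = L_e(ŷ, y) + α · trace(Hᵀ L H) + λ₁‖M‖₁ + λ₂‖M‖²_F + λ₃‖MMᵀ − I‖_F

prediction error plus manifold smoothness of the last-layer embeddings over
graph neighborhoods plus sparsity/orthonormality pressure on the mask.

**Interpretation.** Edges: threshold the learned mask and aggregate retained
edges by functional network. Node features: Grad-RAM / Grad-CAM — per
subject, `a = softmax( mean_q ReLU(G_q ⊙ C_q) )` with `G = ∂ŷ/∂C`, averaged
over subjects.

The whole network, including the backward pass, is implemented in numpy;
every analytic gradient is validated against finite differences in the test
suite.

Real multimodal cohorts are access-restricted, so the package ships a
first-class synthetic-cohort generator with planted, recoverable ground
truth (community-structured FC, sparse Poisson SC, log-normal morphology,
a cognition-like target driven by a planted edge set and informative
anatomical columns), which all recovery experiments use.

## Worked example

```python
import numpy as np
import neuromask as nm
from neuromask.training import prepare_inputs, train, evaluate
from neuromask.interpret import edge_recovery_auc, grad_attribution

cohort = nm.generate_cohort(nm.SyntheticSpec(seed=1))   # 300 subjects, Q=40
config = nm.desk_config(seed=1)                         # protocol defaults, top-8 graph
data = prepare_inputs(cohort, config)
result = train(data, config)

print(evaluate(result, data))
print("edge-recovery AUC:",
      round(edge_recovery_auc(result.model.mask(), cohort.planted_edges), 3))
scores = grad_attribution(result, data)["scores"]
inf = cohort.informative_columns
print("attribution, informative vs rest:",
      round(scores[inf].mean(), 4), "vs",
      round(np.delete(scores[:9], inf).mean(), 4))
```

prints

```
{'rmse': 9.681847609992184, 'mae': 7.682901878304387}
edge-recovery AUC: 0.942
attribution, informative vs rest: 0.0932 vs 0.09
```

Read: held-out RMSE 9.7 on a cognition-composite-like target (mean 100,
sd 15; a constant predictor scores ≈ 14.7), the planted predictive edges
rank near the top of all 780 ROI pairs under the learned mask (AUC 0.94),
and the three informative anatomical columns receive higher Grad-RAM
attribution than the six uninformative ones.

The same pipeline is available from the shell:

```bash
neuromask simulate --out cohort/ --seed 1
neuromask train --manifest cohort/manifest.csv --checkpoint model.npz --metrics history.csv
neuromask interpret --checkpoint model.npz --threshold 0.25 --out-prefix interp
neuromask ablate --manifest cohort/manifest.csv --out ablation.csv
```

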