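# ckalign

Supervised metric learning by **centered kernel alignment (CKA)** for
multi-class diagnosis from morphometric feature tables, with a
generalization to layer-wise pretraining of feed-forward networks.

The intended setting is computer-aided dementia diagnosis: each MRI scan is
summarized by a few hundred FreeSurfer-style morphometric features (region
volumes in mm³, surface areas in mm², cortical thickness statistics in mm)
and labeled healthy control (HC), mild cognitive impairment (MCI), or
Alzheimer's disease (AD). Off-the-shelf distance-based classifiers struggle
because the features mix units and scales and most dimensions are
uninformative. `ckalign` learns a linear projection that makes distances
mean something for the diagnosis task, and feeds it to k-nn, kernel SVM,
and neural-network classifiers.

## The statistic

For a feature matrix **X** ∈ ℝ^(N×P) with labels *l*, build two N×N
kernels: a Gaussian kernel on linearly projected features,

    κ_X(x, x′) = exp( −(x − x′) W Wᵀ (x − x′)ᵀ / 2σ² ),   W ∈ ℝ^(P×d),

and the class-indicator label kernel κ_L(l, l′) = 1[l = l′]. With
K̄ = H K H the double-centered kernel (H = I − 11ᵀ/N), the empirical CKA is

    ρ̂(K̄_X, K̄_L) = ⟨K̄_X, K̄_L⟩_F / √(⟨K̄_X, K̄_X⟩_F ⟨K̄_L, K̄_L⟩_F) ∈ [0, 1],

an HSIC-style measure of how well feature-space similarity mirrors class
structure. The projection is learned by minimizing −log ρ̂ with full-batch
gradient descent (analytic gradient, backtracking line search; minibatch
SGD optional), initialized from the principal components of the z-scored
features, with σ set by the median heuristic on projected distances.

The multi-layer generalization pretrains each hidden layer of a sigmoid
feed-forward network, sequentially, by maximizing the alignment between
the Gaussian kernel on that layer's representation h^m = ϑ(h^(m−1) W^m),
ϑ(z) = (tanh z + 1)/2, and the label kernel; the pretrained stack then
initializes backpropagation on cross-entropy with a softmax output.

Evaluation follows the usual diagnosis-study protocol: subject-grouped
70/30 split and 5-fold grid search (no subject ever spans a fold),
accuracy and per-class true-positive fractions τ_c with 1,000-resample
bootstrap 95% CIs, the balance measure std_τ, per-class one-vs-rest AUC,
and a one-sided Welch t-test at 1% comparing each classifier with its
CKA-enhanced version.

## Worked example

No clinical data ships with the package; `ckalign.simulate` generates
tables with the relevant statistical structure. The "scale-confounded"
family has one unit-scale discriminative feature buried under nine noise
features with ~100× larger variance:

```python
import numpy as np
from ckalign import FitConfig, fit_metric, knn_classify, make_fixture, subject_split

data, meta = make_fixture("scale-confounded")
tr, te = subject_split(data, test_fraction=0.3, seed=0)
train, test = data.subset(tr), data.subset(te)
model = fit_metric(train, FitConfig(seed=0, max_iters=80))
```

Running `python examples/02_fit_linear_metric.py` prints:

```
alignment rho: 0.322 (PCA init) -> 0.953 after 80 accepted steps
projection row norms: signal feature 5.77, largest noise row 0.85 (ratio 6.8x)
5-nn test accuracy baseline: 0.278
5-nn test accuracy with learned metric: 1.000
```

The alignment climbs from the PCA start to near 1; the learned projection
concentrates on the informative feature (row norm 6.8× any noise row); and
k-nn goes from chance (three classes) to perfect on held-out subjects.
The other scripts in `examples/` walk through the alignment statistic
itself, layer-wise pretraining on a nonlinearly separable (XOR) family,
and a full baseline-versus-enhanced study with bootstrap CIs.

There is also a thin CLI mirroring the library
(`ckalign simulate | fit-metric | pretrain | classify | evaluate | run`).

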