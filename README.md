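# hemamil

Weakly supervised classification of hematological malignancies from bone
marrow smears, using attention-based multiple-instance learning (MIL).

A whole-slide image or a set of micrograph fields carries one diagnostic
label — AML, ALL, CML, CLL or MM — but no annotation of *where* the
diagnostic cells are. `hemamil` treats each slide as a bag of 256×256
patches: patches are encoded into fixed-length feature vectors h_k, and a
gated-attention network with one branch per class pools them into
class-specific slide representations

    a_{i,k} = softmax_k( P_i · (tanh(W₁ h_k) ⊙ σ(W₂ h_k)) )
    h_slide,i = Σ_k a_{i,k} h_k,      s_i = W_c,i · h_slide,i

with slide probabilities softmax(s). An auxiliary instance-clustering
task pseudo-labels each bag's B most-attended patches positive and B
least-attended negative within the true class's branch and scores a
linear instance classifier on them with a smooth top-1 SVM loss; the
training objective is `0.7·CE(bag) + 0.3·L(instances)`. The learned
attention doubles as interpretation: overlap-averaged, min–max-normalized
attention heatmaps localize the evidence the model used.

The package provides the full pipeline — Otsu foreground segmentation at
16× downsample, stride tiling, pluggable frozen patch encoders, the MIL
classifier (pure NumPy, analytic gradients, Adam, early stopping), Monte
Carlo cross-validation with macro one-vs-rest AUC / balanced error /
confidence / PCA reporting, heatmap rendering — plus a synthetic-data
generator with known per-instance ground truth so everything is testable
at desk scale. It is aimed at computational-pathology researchers who
want a transparent, dependency-light reference implementation of
clustering-constrained gated-attention MIL.

## Worked example

```python
import numpy as np
from hemamil import SyntheticBagSpec, generate_feature_bags, GatedAttentionMIL
from hemamil.training import evaluate

# five classes; 10% of each bag's 30-70 instances carry class evidence
# displaced 6 noise-sd from the shared background
spec = SyntheticBagSpec(n_classes=5, feature_dim=256, separation=6.0,
                        evidence_fraction=0.1, seed=1)
train, val, test = generate_feature_bags(spec, split_sizes=(25, 8, 8))

unpack = lambda s: ([b.features for b, _ in s],
                    np.array([b.label for b, _ in s]))
X_tr, y_tr = unpack(train); X_va, y_va = unpack(val); X_te, y_te = unpack(test)

clf = GatedAttentionMIL(n_classes=5, B=8, learning_rate=2e-4,
                        max_epochs=200, patience=20, random_state=1)
clf.fit(X_tr, y_tr, val_X=X_va, val_y=y_va)
report, _ = evaluate(clf, X_te, y_te)
print(f"macro one-vs-rest AUC: {report.macro_ovr_auc:.3f}")
print(f"balanced error:        {report.balanced_error:.3f}")
```

prints, after a few minutes of training (62 epochs before early
stopping):

```
macro one-vs-rest AUC: 1.000
balanced error:        0.000
```

i.e. the five synthetic classes are recovered perfectly on the 40
held-out bags — the expected outcome at this class separation, where the
per-instance Bayes error is ≈ 1.3×10⁻³. `clf.attention(bag)` returns the
N×K attention distributions; ranking instances by the true class's row
against the generator's evidence flags gives a localization AUC of 0.999,
meaning the attention lands almost exclusively on the instances that
actually carry the class signal. With `separation=0.0` (a null dataset)
the same pipeline yields macro AUC ≈ 0.51 — chance, as it must.

A CLI covers the image pipeline end to end: `hemamil synth`,
`hemamil preprocess`, `hemamil extract`, `hemamil train`, `hemamil eval`,
`hemamil heatmap` (see `hemamil --help`).

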