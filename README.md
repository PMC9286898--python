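# cdrscreen

Predicting compound–disease relationships (CDRs) from fused descriptor
images, for computational drug-repositioning and natural-product screening.

## The problem and the method

Curated databases record which compounds treat, mark, or mechanistically
relate to which diseases, but the space of untested pairs is vast. This
package implements a screening strategy that describes each side of a pair
numerically — a compound by a dense vector of molecular descriptors
`V_C = [b_1, …, b_Dc]` (topological indices, ring counts, 3D shape
descriptors, …) and a disease by a sparse non-negative vector of symptom
weights `V_D = [a_1, …, a_Dd]` derived from literature co-occurrence — and
fuses the two into a single two-dimensional matrix

```
M[r, c] = (b_r + a_c) / 2        r = 1..Dc,  c = 1..Dd
```

after per-feature min–max normalization to [0, 1]. `M` maps directly onto an
8-bit grayscale image (`pixel = round(255·M)`), so every compound–disease
pair becomes a picture in which rows are molecular descriptors and columns
are symptom descriptors. A convolutional network trained on images of known
positive pairs and sampled negative pairs then scores any unknown pair with
a probability of relationship.

Around that core the package provides:

- **Benchmark assembly** — negative sampling from the unlabeled complement
  of the positive set, positive:negative ratio series (1:1 … 1:5) with
  75/25 splits, and *disease-held-out* / *compound-held-out* splits that
  guarantee no test disease (or compound) was seen in training.
- **Classifiers** — a `tiny` CNN for desk-scale work plus width-reduced
  `alexnet_like` (5 conv + 3 dense) and `inception_like` (parallel
  1×1/3×3/5×5/pool branches) architectures, trained with SGD
  (momentum 0.9) on 2-class cross-entropy. The stack is pure numpy and
  bit-reproducible from a seed.
- **Evaluation** — Acc, Sen, Pre, F-measure, MCC from confusion counts,
  trapezoidal ROC/AUC, and the relative-improvement / relative-drop
  calculators used to compare classifiers and test regimes.
- **Screening** — filter a compound library (QC flag, blood-detectable
  flag, or oral bioavailability > 30%), enumerate unknown pairs against a
  disease panel, rank by probability, and flag candidates above a 0.9 cut.
- **Feature ranking** — linear-SVM recursive feature elimination
  (`F_i = w_i²`, remove the smallest each round) to find which structural
  and ADME descriptors separate candidate actives from the background.
- **Synthetic data** — a generator that plants a latent-factor rule
  `P(positive | c, d) = σ(s·⟨u_c, v_d⟩ + offset)` beneath realistic-shaped
  descriptor tables, so the whole pipeline is testable without external
  databases.

## Worked example

`examples/train_and_evaluate.py` simulates a 120-compound × 24-disease
world, draws a balanced 800-pair benchmark, trains the tiny CNN on the
64×32 pair images, and prints:

```
train pairs: 600, test pairs: 200
final train loss 0.314, train accuracy 0.867
  acc        0.810
  sen        0.890
  pre        0.767
  f_measure  0.824
  mcc        0.628
  auc        0.906
```

Sen = 0.890 means 89% of true relationships in the held-out set were
recovered; AUC = 0.906 is threshold-free ranking quality (0.5 would be
chance — which is exactly what the generator's zero-signal control
produces). `examples/screen_library.py` continues the workflow: of 120
library compounds, 82 pass the QC/blood/OB>30% filter, 1672 unknown pairs
are scored, 342 are predicted positive at the 0.5 threshold and 14 exceed
the 0.9 candidate cut. `examples/encode_pair.py` and
`examples/rank_features.py` demonstrate the image encoding and SVM-RFE.

A thin CLI mirrors the workflow
(`cdrscreen simulate | encode | build | train | predict | screen`); run
`cdrscreen --help`.

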