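# Methods

## The encoding

A pair (compound, disease) is represented by the additive matrix
`M[r, c] = (b_r + a_c) / 2` over the compound's molecular-descriptor vector
`b` (rows) and the disease's symptom-descriptor vector `a` (columns). Both
vectors are first min–max normalized per feature, so `M ∈ [0, 1]` and maps
onto 8-bit grayscale by `pixel = round(255·M)` (round half away from zero;
the quantization error is at most 1/510 per cell).

Properties that follow from the construction, and that the test suite
verifies: every 2×2 sub-matrix has equal diagonal sums (the matrix is
rank-2, a sum of a row profile and a column profile); raising one compound
feature raises exactly its row; swapping the vectors transposes the matrix;
row/column means recover the centred halves of the source vectors. The
encoding carries the two vectors side by side — it does **not** form
products of compound and disease features — so any interaction between the
two sides must be learned by the classifier from the joint picture.

Orientation: descriptions of the source method place disease features on
rows, yet state the matrix size as (number of compound features) × (number
of disease features). We follow the stated size — compound features as rows
— and expose a `transpose` flag for the other reading.

The CNN input geometry is not fixed by the method; desk-scale networks
consume the unresized `D_c × D_d` image, and `render_for_cnn` provides a
deterministic align-corners bilinear resize (default target 224×224) for
the larger architectures.

## Normalization

"Normalized separately" is implemented as per-feature min–max over the
reference (training) table, because the encoding averages raw feature
values and the grayscale rendering needs a bounded range; z-scoring is
unbounded and was rejected. Constant features map to 0 rather than being
dropped so the image geometry never changes. The fitted (min, max) pairs
are frozen and re-applied to screened compounds (`apply_normalization`,
clipping to [0, 1]), so a screening library is encoded on exactly the
training scale. Missing cells are an error by default; column-median fill
is an explicit opt-in, since silent imputation changes images invisibly.
A per-entity-vector reading of "normalized separately" is conceivable but
is not implemented; per-feature scaling is the standard QSAR practice.

## Benchmark assembly

Negatives are drawn uniformly without replacement from the complement of
the positive set over the full compound × disease grid. Ratio-series
datasets draw `floor(size/(1+r))` positives and the remainder negatives,
then split 75/25 with the class ratio preserved in both partitions; repeat
`k` uses seed `seed + k`.

Held-out splits grow the training set one whole disease (or compound) at a
time, in seeded random order, until the positive-count target is crossed;
the overshoot is kept, because truncating mid-group would reintroduce
leakage. The test set is then sampled from the untouched groups, and the
same procedure runs independently for negatives. Disjointness is enforced
within each label class (matching the stepwise definition of the
procedure); any cross-class group overlap is reported in the split's
provenance rather than forbidden. Realized counts are always recorded — a
split that targets 7500 training positives typically lands slightly above.

## Classifiers

The network stack is written on numpy (im2col convolution, max pooling,
dense layers, softmax cross-entropy, SGD with classical momentum) so that
training is single-threaded, dependency-light, and bit-reproducible from a
seed. Three architectures share the training loop:

- `tiny` — conv(8)+pool, conv(16)+pool, dense(64), dense(2); the test and
  experiment workhorse for unresized small encodings.
- `alexnet_like` — five convolutions and three dense layers with ReLU, a
  width-reduced re-expression of the classical eight-layer design for
  224×224 inputs.
- `inception_like` — a stem plus two inception blocks (1×1, 1×1→3×3,
  1×1→5×5, pool→1×1 branches concatenated on channels), global average
  pooling, dense head.

Reference training settings are the defaults: SGD momentum 0.9, learning
rate 1e-4, 20 epochs, batch 20, no weight decay or schedule. A freshly
initialized tiny network at desk scale barely moves at lr 1e-4 within 20
epochs, so `TrainConfig.desk_scale()` pins the tiny-network variant at
lr 0.01 (He initialization, float32); this is a property of network scale,
not of the data. Labels use a strict `p > 0.5` rule, so a probability of
exactly 0.5 is negative. Iterations per epoch follow from the actual
training-set size and batch size. Training is from scratch; no pretrained
weights are involved.

## Metrics

Acc, Pre, Sen, F and MCC are computed from TP/FP/TN/FN; a vanishing
denominator yields NaN ("undefined"), never a silent 0. The standard
Matthews coefficient (with the square root and all four factors) is the
default; a `legacy_mcc` flag reproduces a non-standard printed variant
(no root, missing (TN+FP) factor) for auditing only — published benchmark
values are consistent with the standard formula. AUC is the trapezoidal
area over the full threshold sweep with tied scores collapsed into single
sweep steps, which equals the rank-averaged Mann–Whitney statistic. The
comparison calculators report *relative* differences
(`100·(new−baseline)/baseline` and `100·(orig−new)/orig`) rounded to
3 decimals, matching how published model comparisons are quoted.

## Screening and feature ranking

A library compound survives filtering if it is a QC (quality-control)
compound OR is blood-detectable OR has oral bioavailability strictly above
30% (a missing OB value fails that clause); an AND mode exists for
sensitivity analysis. Pairs already labeled in the benchmark are excluded
from enumeration by default. Ranking is by descending probability with
ties broken by (compound_id, disease_id); "predicted positive" (p > 0.5)
and "candidate" (p > 0.9) are reported as distinct counts.

SVM-RFE fits a linear SVC (C = 1.0, z-scored features — the linear kernel
makes weights scale-dependent) and removes the single feature with the
smallest `w_i²` per round, ties broken by column order; the reported score
is the weight at elimination time, since a feature has no weight after it
is removed. A `step` option allows chunked removal on wide matrices, at
the cost of departing from strict one-at-a-time elimination. Labels are
supplied explicitly (e.g. screened candidates for a tumor indication vs
the remaining screened compounds); no reweighting is applied by default.
Structural and ADME descriptors may be ranked jointly or in separate runs.

## Synthetic worlds

The generator emulates the statistical shape of the real inputs: dense
Gaussian-mixed descriptor vectors for compounds, sparse non-negative
mixed-and-clipped symptom vectors for diseases, and a planted rule
`P(positive|c,d) = σ(s·⟨u_c, v_d⟩ + offset)` over latent factors
(`n_latent = 4`), with the offset root-solved on the realized grid so the
expected positive fraction equals `positive_rate`. Defaults: 200×40 grid,
64/32 feature dimensions, signal strength 5, noise SD 0.5, positive rate
0.15. The rate is higher than real curated collections (roughly 7% of the
reference grid) because a 200×40 desk-scale grid must still yield enough
absolute positives to build ratio-series benchmarks; the grid and feature
dimensions are config-reachable up to reference scale (5270/322).

What passing synthetic tests shows: the pipeline is wired correctly end to
end, the classifier can extract a planted cross-side interaction from the
additive image, and the imbalance/held-out behaviors have the expected
signatures. What it does not show: performance on real descriptor
distributions (Dragon descriptors are heavy-tailed and highly collinear;
symptom weights have database-specific sparsity), nor the absolute metric
levels reported for the full-scale curated benchmark — no molecular
chemistry is simulated.

## Experiment sizes and numerical choices

Desk-scale experiment sizes: learnability uses a balanced 2000-pair sample
(1500 train / 500 test) and 12 training epochs; the imbalance series uses
2400-pair samples at ratios 1:1 … 1:5, three repeats per ratio with
averaged test metrics, mirroring the triplicate design of the original
imbalance experiment; SVM-RFE recovery uses 100 seeded runs of a
5-feature, 200-sample planted design (2σ effect). With these sizes the
strong-signal tiny CNN reaches held-out AUC above 0.9 while the
zero-signal control stays at chance, and sensitivity/MCC fall steeply
across the ratio series while accuracy stays nearly flat.

Numerical details: float32 network arithmetic; He-initialized weights;
mean cross-entropy with an explicit non-finite-loss guard; quantization
rounds half away from zero; bilinear resizing uses align-corners
coordinates; all samplers take `numpy.random.default_rng` seeds and
derived seeds stay below 2³¹.

## Known limitations

- The additive encoding is rank-2; a model that only pools the image
  globally sees little more than the two mean profiles, so classifier
  capacity (flatten + dense, or spatially local features) matters.
- One-at-a-time RFE on thousands of descriptors is O(D²) SVM fits; use
  `step` for wide matrices.
- The alexnet_like and inception_like architectures are functional
  re-expressions at reduced width, provided for full-scale runs; they are
  not trained in the test suite and no claim is made that they reproduce
  published full-scale metric levels.
- Screening candidate counts depend on the trained model and library
  composition; only their internal consistency (candidate ⊆ predicted
  positive ⊆ scored) is guaranteed.
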