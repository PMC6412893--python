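# sdaehar

Human activity recognition (HAR) from smartphone inertial sensors:
unsupervised **stacked denoising autoencoder (SDAE)** feature extraction per
sensor, followed by a **Boosting K-Fold** ensemble of gradient-boosted
decision trees.

## Who this is for

Researchers and engineers working on wearable / mobile sensing who want a
tested, dataset-free reference implementation of the SDAE + boosted-tree HAR
pipeline — including its preprocessing, class-separability diagnostics,
comparison baselines, and a synthetic inertial-signal generator that lets
every stage run at desk scale.

## The method

Raw recordings from N sensors (accelerometer, gyroscope, magnetometer,
optionally barometer) are cut into sliding windows of w samples with stride
s (floor((T − w)/s) + 1 windows per recording), flattened to vectors
x ∈ ℝ^(w·d_k), and min–max scaled per column with extrema learned from the
training partition only.

**Feature extraction.** Each sensor gets an independent SDAE. One layer
corrupts its input by Bernoulli zero-masking at rate θ (dropout 0.4 by
default), encodes h = σ(Wx̃ + b), decodes r = σ(W′h + b′), and is trained to
minimise the mean squared reconstruction error ‖r − x‖² against the *clean*
input. Layers are pretrained greedily (layer l+1 on the clean encodings of
layer l), then the unrolled encoder–decoder chain is fine-tuned end-to-end
on the same unsupervised objective. At inference the encoder composition
e(x) = f_enc(… f_enc(x; θ¹) …; θⁿ) yields the features, concatenated across
sensors: e(x) = e¹(x) | e²(x) | … | e^N(x).

**Classification.** Stratified k-fold (k = 5) is run *sequentially*: every
sample misclassified in fold f's validation set is duplicated once into fold
f+1's training set (replaced each fold, not accumulated), then the k
LightGBM models vote; ties break toward the smallest class index.

**Diagnostics.** Within-class scatter S_W = Σ P(Ω_i)·(1/N_i)Σ(x−m_i)(x−m_i)ᵀ
and between-class scatter S_B = ½ Σ_i Σ_j P(Ω_i)P(Ω_j)(m_i−m_j)(m_i−m_j)ᵀ;
their traces measure class compactness and separation before vs. after
feature extraction.

**Metrics.** Confusion matrix plus macro-averaged P_k = TP/(TP+FP),
R_k = TP/(TP+FN), F1_k = 2·P_k·R_k/(P_k+R_k), and accuracy.

Two baselines are included: the pretrained SDAE with a softmax head trained
by cross-entropy (gradients flow into the encoders), and a classical
hand-crafted feature table (gravity-axis decomposition statistics,
modulus-series statistics with spectral terms, inter-axis correlations,
barometric change features) fed to xgboost.

## Worked example

```python
import sdaehar as sh

# 6-class synthetic dataset: 20 recordings/class, 10 s at 50 Hz
recs, _ = sh.generate_dataset(sh.SimConfig(recordings_per_class=20, seed=0))

cfg = sh.PipelineConfig(
    window=sh.WindowConfig(128, 128),                     # 2.56 s windows
    sdae=sh.SDAEConfig(n_hidden=(100, 30), epochs=15, seed=0),
    k=5,
)
res = sh.run_pipeline(recs, sh.default_schema(), cfg)
print("test accuracy", res.report.accuracy)
print(res.divergence.totals())
```

prints

```
test accuracy 1.0
                         raw  features
inner_class_trace  44.318963  5.376002
outer_class_trace  45.549337  6.677686
```

Held-out windows of the six postures/gaits are classified perfectly, and the
learned 90-dimensional features shrink the within-class scatter trace about
8-fold relative to the raw scaled windows — the direction the method is
designed to produce (classes become tighter while staying separated).

The same flow is available from the shell:

```bash
har simulate --out data --seed 0
har preprocess --config prep.yaml --in data --out samples
har pretrain  --config sdae.yaml --samples samples.train.h5 --out stacks.h5
har train     --samples samples.train.h5 --stacks stacks.h5 --k 5 --out model
har evaluate  --model model --samples samples.test.h5 --stacks stacks.h5 --out metrics.json
har diagnose  --raw samples.test.h5 --stacks stacks.h5 --out report.csv
har baseline  --method handcrafted-gbdt --train-samples samples.train.h5 \
              --test-samples samples.test.h5 --window-len 128 --out xgb.json
```

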