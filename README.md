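# mdlink

Microbe–disease association prediction with a dual graph-embedded
fusion model.

Imbalances in the human microbiota are implicated in a wide range of
diseases, but experimentally testing individual microbe–disease links
is slow; curated association databases cover only a sparse sample of
the true interaction structure. `mdlink` is for computational
biologists who want to rank the *unobserved* pairs of a curated
association table by their likelihood of being true associations, and
to evaluate such rankings honestly under cross-validation.

## Model

From a binary association matrix **A** ∈ {0,1}^(Nm×Nd), the package
builds integrated similarity matrices per side — the mean of a
Gaussian interaction profile (GIP) kernel
`exp(−λ‖p_i − p_j‖²)`, cosine similarity of the same association
profiles, and an optional functional view (gene-set similarity over a
scored gene-interaction net for diseases; DAG semantic similarity of
associated disease sets for microbes) — and stacks everything into one
heterogeneous network

    Y = [[w·MS, A], [Aᵀ, w·DS]],   w = similarity weight (default 6).

Two parallel encoders read the normalized network
`D̂^(−1/2)(Y+I)D̂^(−1/2)`: a graph convolutional channel
`H^{l+1} = ReLU(D̂^(−1/2)ÂD̂^(−1/2) H^l W^l)` and a graph attention
channel with per-edge softmax coefficients
`α_ij ∝ exp(LeakyReLU(aᵀ[Wh_i ‖ Wh_j]))`. Their outputs are
concatenated, refined by a bidirectional LSTM along the node axis, and
decoded into association probabilities
`ŷ_ij = σ(z_mi · z_dj + b0)` by a fully connected projection. Training
minimizes cross-entropy against the known matrix plus an L2 penalty,
`L = L_CE + λ Σ_k ‖W_k‖²`, with Adam. See `docs/methods.md` for the
full treatment.

## Worked example

```python
from mdlink import (
    FixtureSpec, MicrobeDiseaseGraphModel, ModelConfig, TrainConfig,
    gen_association,
)

adjacency = gen_association(FixtureSpec(seed=1))   # 60 microbes x 20 diseases
model = MicrobeDiseaseGraphModel(
    adjacency, config=ModelConfig(embed_dim=32, seed=1)
)
results = model.fit(TrainConfig(epochs=300, seed=1))
print(results.summary())
print(results.rankings("disease_000", top_k=3))
```

prints

```
Dual graph-embedded fusion model: fit summary
==============================================
nodes:            60 microbes, 20 diseases
known positives:  151
encoders:         L=2, k=32
sequence layer:   BiLSTM, width 128
parameters:       77473
epochs:           300
final loss:       0.327880
score range:      [0.0000, 0.7968]
   rank      microbe     score
0     1  microbe_024  0.583657
1     2  microbe_004  0.536689
2     3  microbe_048  0.488942
```

The summary reports the trained configuration and final training loss;
the ranking lists the highest-scoring microbes *not* already known to
associate with `disease_000` — on this synthetic fixture the top
candidates are same-block microbes whose association was masked by the
generator's sparsity, exactly what a practitioner would shortlist for
validation. Cross-validated evaluation of the same pipeline:

```python
from mdlink import cross_validate
report = cross_validate(adjacency, ModelConfig(embed_dim=32, seed=1),
                        TrainConfig(epochs=500, repeats=1, seed=1))
print(report.summary())
```

```
Cross-validation report
==========================================
5 evaluations (1 repeats x 5 folds)
auc          0.8922 +/- 0.0041
accuracy     0.9470 +/- 0.0075
specificity  0.9689 +/- 0.0100
```

Each fold hides a fifth of the known positives, rebuilds all
similarities from the masked matrix (no leakage), retrains, and ranks
the hidden positives against every unknown pair; mean AUC ≈ 0.89 means
hidden true associations outrank random unknown pairs ~89% of the
time.

The same operations are available from a shell:

```
mdlink simulate --seed 1 --outdir fixture
mdlink cv --associations fixture/associations.tsv --embed-dim 32 \
          --epochs 500 --folds 5 --repeats 1 --seed 1 --outdir cv_out
```

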