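# latentreplay

Privacy-aware **domain-incremental continual learning** over frozen-backbone
latent features, built for settings like single-cell white-blood-cell (WBC)
classification where datasets arrive sequentially from different clinical
sites (different scanners, stains, tissues) and raw images from earlier
sites cannot be stored or shared.

## The problem and the method

In the domain-incremental setting a model must learn *T* tasks
{D¹, …, Dᵀ} in order. The class set (here a monocyte / eosinophil /
lymphocyte analogue) is the same in every task, but the input distribution
shifts between tasks. Fine-tuning a classifier on each new task in turn
destroys performance on earlier ones — catastrophic forgetting.

`latentreplay` counters forgetting with two complementary mechanisms that
never store raw past data:

1. **KDE-based generative latent replay (GLR).** After training on task
   *t*, its latent vectors z are compressed by K-means to K cluster
   centers (default K = 10); *only the centers are retained*. The centers
   of all tasks so far form the support of a Gaussian kernel density
   estimate whose per-dimension bandwidth follows Silverman's rule,

       h_j = σ_j · (4 / ((d + 2) m))^(1/(d+4)),

   recomputed whenever the support set grows. Sampling this KDE yields
   synthetic latents that mimic every past domain. During task *t* each
   mini-batch is a 50/50 hybrid: half current-task rows with ground-truth
   labels, half freshly sampled replay rows labelled by the previous
   model's predictions (pseudo-labels).

2. **Knowledge distillation (DST).** The student model Mᵗ is initialised
   from the frozen previous model Mᵗ⁻¹ (the teacher) and trained with

       loss = (1 − α) · loss_CE + α · loss_KLD,   α ∈ [0, 1]

   where loss_KLD is the KL divergence between the teacher's and
   student's output distributions.

The trainable model is a small fully connected head (default widths
[512, 256, 128, 64, 32]) over latents from a *frozen* feature extractor;
freezing the backbone is what keeps the latent generator valid across
tasks. Evaluation fills the T×T train-test matrix P (cell p_ij = accuracy
on task j after session i) and summarises it with the standard
continual-learning metrics **ACC** (mean of the last row), **BWT**
(average signed backward transfer; negative = forgetting) and **ILM**
(mean over the lower triangle).

A synthetic benchmark generator ships with the package: 4 domains sharing
3 classes in a 16-dimensional latent space, with controllable mean
translation, scaling and rotation between domains, so the whole method is
testable without any images or pretrained backbones. An optional plug-in
boundary (`latentreplay.features.extract_features`) accepts any callable
mapping an image array to a feature vector for real-data use.

## Worked example

```python
from latentreplay import ContinualExperiment, RunConfig
from latentreplay.datasets import default_benchmark_specs

specs = default_benchmark_specs(base_seed=0)          # 4 shifted domains
res = ContinualExperiment.from_specs(
    specs, RunConfig(strategy="proposed", n_repeats=3)).fit()
print(res.summary())
```

```
         Continual Learning Experiment Results
==========================================================
Strategy:       proposed
Tasks:          4  (domain1, domain2, domain3, domain4)
Repeats:        3   base seed: 0
alpha: 0.2   K/task: 10   batch: 64   epochs: 20
----------------------------------------------------------
ACC  (%)          85.61 +/- 1.75
BWT  (%)           0.14 +/- 0.90
ILM  (%)          87.80 +/- 1.87
----------------------------------------------------------
Train-test matrix P, repeat 0 (rows: after session i):
    92.00   60.67   83.33   46.67
    92.00   90.00   82.00   52.67
    92.67   87.33   88.00   52.67
    91.33   90.67   87.33   80.00
==========================================================
```

Read the matrix row by row: after session 1 the model is good on domain 1
(92.0) and poor on unseen domains; after session 4 it is accurate on *all*
domains — column 1 ends at 91.3, essentially where it started, so nothing
was forgotten (BWT ≈ 0). The same sequence under `strategy="naive"` gives
ACC 68.1 and BWT −31.2: without replay and distillation, early domains
collapse as later ones are learned. `strategy="joint"` (all tasks pooled,
the upper bound) reaches ACC 87.2.

The same experiment from the shell:

```sh
latent-replay simulate --out seq/            # default 4-domain benchmark
latent-replay run seq/ --strategy proposed --out out/
latent-replay metrics out/P_repeat0.tsv
```

Strategies: `naive`, `joint`, `proposed` (GLR + DST), `dst_only`,
`glr_only`, and `gmm_replay` (per-task Gaussian-mixture generator instead
of the KDE).

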