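# Methods

## Setting and model

The package targets domain-incremental continual learning on latent
features: T labelled datasets with a common class set but shifted input
distributions are learned strictly in sequence, with no access to earlier
raw data during later sessions. The classifier is a fully connected head
over features from a frozen extractor; only the head trains. At session t
the student is initialised from the trained session-(t−1) model, whose
frozen copy acts as teacher.

Two mechanisms counter forgetting:

- **Generative latent replay.** Each session's latents are compressed by
  K-means; only the K cluster centers are retained. The cumulative center
  set supports a Gaussian product-kernel KDE. During session t > 1 every
  mini-batch is half current data (true labels) and half fresh KDE samples
  labelled by the teacher's argmax predictions.
- **Distillation.** The objective is
  `(1 − α)·CE + α·KL(softmax(teacher/T) ‖ softmax(student/T))`, both terms
  batch means.

Privacy is structural: the persisted generator state is O(m·d) numbers
(m = ΣK_t centers plus a bandwidth vector), independent of the amount of
data seen, and a center is a cluster mean rather than an individual
sample (a singleton cluster is the only degenerate exception).

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| α | 0.2 | CE/KLD balance; small values preserve plasticity while distilling. The grid {0.01, 0.1, 0.2, 0.3, 0.4, 0.5} is the intended search range. |
| K per task | 10 | retained centers per domain → 40 support points after 4 tasks. `k="auto"` switches to BIC selection instead. |
| batch size | 64 | hybrid batches therefore hold 32 current + 32 replay rows. |
| head widths | [512, 256, 128, 64, 32] | ReLU between layers, linear output; He init. |
| bandwidth | Silverman per dimension | `h_j = σ_j (4/((d+2)m))^{1/(d+4)}`, σ_j the ddof=1 column SD, floored at 1e−6 so zero-variance columns stay sampleable. |
| GMM components | 10 per domain | the parametric replay alternative (`gmm_replay`), full covariances. |
| optimizer | Adam, lr 1e−3, 20 epochs | fixed budget, no scheduler or early stopping; exposed in `RunConfig`. |
| repeats | 5 (`n_repeats`) | metrics reported as mean ± sample (ddof=1) SD across seeds `base_seed + r`. |

## Design choices where the design was open

- **BIC for K-means.** K-means has no likelihood, so BIC uses the implied
  spherical-Gaussian mixture: cluster occupancies as mixing weights, one
  pooled MLE variance, parameter count p = K·d + K + 1, and
  BIC = p·ln n − 2·ln L. This is the standard X-means-style construction;
  it is deterministic given the K-means seed and ties break toward smaller
  K. Fixed K = 10 is the default; BIC selection is the `k="auto"` mode.
- **Distillation details.** Temperature 1, direction KL(teacher‖student),
  hard pseudo-labels (argmax) for replay rows. In the combined strategy the
  KLD term covers **all** rows of the hybrid batch (`kld_scope="all"`);
  the `dst_only` ablation computes CE and KLD on current-task data only
  (`kld_scope="current_only"`, no replay), and `glr_only` uses CE alone on
  hybrid batches.
- **Support points are unweighted.** Cluster mass is discarded when
  centers are retained; weighting by cluster size would leak occupancy
  information and is deliberately not a default.
- **Short final batch.** The last batch of an epoch keeps the 50/50 ratio
  by shrinking symmetrically: r leftover current rows are paired with r
  replay rows.
- **Session order.** Within session t the model replays generator state
  G^{t−1}; task t's centers are merged only after the session finishes,
  and the trained model becomes the next teacher. Task 1 trains with plain
  CE (no teacher, no replay).
- **Evaluation.** After every session the model is evaluated on all T test
  sets, giving a full T×T matrix; ACC/BWT/ILM only read cells with j ≤ i,
  future-task cells are stored for completeness. The joint strategy trains
  once on pooled data and reports a single accuracy row — BWT/ILM are null
  for it since there is no sequence.
- **Seeding.** Every run derives head-init, shuffling, replay-draw and
  generator seeds from one repeat seed via spawned `SeedSequence` streams,
  so any matrix is bit-reproducible from (config, seed).

## The synthetic benchmark

`default_benchmark_specs` builds 4 domains × 3 classes in d = 16: class
centroids 4.0 apart on the coordinate axes, per-class isotropic scale
1.5 + 0.15·t, and per-domain shift of norm 8.0 in a random direction plus
a rotation of t·π/8 in the first two coordinates. 100 training and 50
test rows per class per domain. These sizes keep the complete test suite
and the acceptance script around a minute on one CPU while leaving the
learning problem non-trivial: accuracies land in the 60–90 % band, naive
sequential training forgets heavily (BWT ≈ −31), replay restores early
domains, and the upper-bound joint strategy stays within ~2 points of the
combined method.

What the generator does *not* emulate: real backbone feature geometry
(latents here are Gaussian by construction, so the KDE's non-parametric
flexibility is not stress-tested against skewed or multi-modal
class-conditionals), label noise, class imbalance across sites, and
dimensionalities in the 512–2048 range. Passing the synthetic suite shows
the machinery is correct and the forgetting/replay dynamics behave as
designed — not that any particular accuracy transfers to real imaging
data.

## Numerical notes

- KDE sampling: uniform support-point choice plus diagonal Gaussian
  noise; exact mixture sampling, no approximation.
- If a task has fewer than K distinct latent rows, K is clamped to the
  distinct count with a warning.
- Losses are computed through `log_softmax`/`softmax` from scipy for
  stability; a non-finite training loss aborts the session with a
  diagnostic rather than continuing.
- Accuracy ties (equal logits) resolve to the lowest class index,
  matching the argmax convention used for pseudo-labels.

## Known limitations

- The head trains with a fixed epoch budget; no convergence criterion.
- The KDE is label-free by design — class information re-enters only
  through teacher pseudo-labels, so a poorly trained teacher propagates
  label noise into replay.
- `gmm_replay` stores one mixture per task, so its state grows linearly
  in T with a larger constant than the KDE variant.
- No GPU path; everything is NumPy on CPU, sized for latent-space heads
  rather than backbone training.
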