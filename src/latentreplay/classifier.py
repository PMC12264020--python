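"""Trainable head over frozen features, and the teacher-student mechanics.

The classifier is a small fully connected network applied to latent vectors
produced by a frozen feature extractor; only these FC layers ever train.
At task t the student is initialised from the trained model of task t-1,
whose frozen snapshot simultaneously serves as teacher: it pseudo-labels
synthetic replay latents and supplies the distillation target.  The
training objective blends cross-entropy with ground-truth (or pseudo)
labels and the KL divergence between teacher and student output
distributions:

    loss = (1 - alpha) * CE + alpha * KL(teacher || student)

with alpha in [0, 1] trading plasticity against retention.

The network, Adam optimiser and backpropagation are implemented directly
on NumPy arrays: the head is a few dense layers, so an explicit
reverse-mode pass is short, fast on CPU and exactly reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.special import log_softmax, softmax

from .datasets import LatentDataset, ValidationError
from .generator import GeneratorState, sample as generator_sample

DEFAULT_HIDDEN_WIDTHS = (512, 256, 128, 64, 32)


class ContractError(RuntimeError):
    """A call violated an inter-module contract (e.g. missing teacher)."""


@dataclass(frozen=True)
class HeadSpec:
    """Architecture of the FC head: input_dim -> hidden widths -> n_classes."""

    input_dim: int
    n_classes: int
    hidden_widths: tuple[int, ...] = DEFAULT_HIDDEN_WIDTHS
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if self.input_dim < 1:
            raise ValidationError("input_dim must be positive")
        if any(w <= 0 for w in self.hidden_widths):
            raise ValidationError("all hidden widths must be positive")
        if self.activation != "relu":
            raise ValidationError(f"unsupported activation {self.activation!r}")
        object.__setattr__(self, "hidden_widths", tuple(self.hidden_widths))

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        widths = [self.input_dim, *self.hidden_widths, self.n_classes]
        return list(zip(widths[:-1], widths[1:]))


class ClassifierModel:
    """FC head with explicit forward/backward passes.

    ``mode`` is 'student' (trainable) or 'teacher' (a frozen deep copy used
    for pseudo-labels and distillation targets; its parameters are never
    updated by any training session).
    """

    def __init__(self, spec: HeadSpec, mode: str = "student"):
        self.spec = spec
        self.mode = mode
        rng = np.random.default_rng(spec.seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in spec.layer_dims:
            # He initialisation, suited to the ReLU hidden layers
            self.weights.append(
                rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            )
            self.biases.append(np.zeros(fan_out))

    # -- inference -----------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Return (n, C) logits for an (n, d) batch."""
        return self._forward_cached(x)[0]

    def _forward_cached(self, x: np.ndarray):
        x = np.asarray(x, float)
        if x.ndim != 2 or x.shape[1] != self.spec.input_dim:
            raise ValidationError(
                f"expected (n, {self.spec.input_dim}) input, got {x.shape}"
            )
        activations = [x]
        n_layers = len(self.weights)
        h = x
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < n_layers - 1:
                h = np.maximum(h, 0.0)
            activations.append(h)
        return activations[-1], activations

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax class per row; ties resolve to the lowest class index."""
        return np.argmax(self.forward(x), axis=1)

    # -- training plumbing ----------------------------------------------

    def backward(self, activations: list[np.ndarray], grad_logits: np.ndarray):
        """Gradients of a scalar loss wrt all parameters, given d(loss)/d(logits)."""
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        delta = grad_logits
        for i in range(len(self.weights) - 1, -1, -1):
            grads_w[i] = activations[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[i].T) * (activations[i] > 0)
        return grads_w, grads_b

    def copy(self, mode: str | None = None) -> "ClassifierModel":
        clone = ClassifierModel.__new__(ClassifierModel)
        clone.spec = self.spec
        clone.mode = mode or self.mode
        clone.weights = [w.copy() for w in self.weights]
        clone.biases = [b.copy() for b in self.biases]
        return clone

    def as_teacher(self) -> "ClassifierModel":
        return self.copy(mode="teacher")

    def param_hash(self) -> str:
        h = hashlib.sha256()
        for w, b in zip(self.weights, self.biases):
            h.update(np.ascontiguousarray(w).tobytes())
            h.update(np.ascontiguousarray(b).tobytes())
        return h.hexdigest()


def init_head(spec: HeadSpec) -> ClassifierModel:
    """Deterministically initialise a student head from its spec."""
    return ClassifierModel(spec, mode="student")


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LossConfig:
    """Balancing factor, distillation temperature and KLD scope.

    ``kld_scope='all'`` applies the distillation term to every row of the
    hybrid batch (the combined strategy); ``'current_only'`` restricts it to
    current-task rows (the distillation-only ablation).
    """

    alpha: float = 0.2
    kd_temperature: float = 1.0
    kld_scope: str = "all"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")
        if self.kd_temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.kld_scope not in ("all", "current_only"):
            raise ValidationError(f"unknown kld_scope {self.kld_scope!r}")


def _ce_and_grad(logits: np.ndarray, labels: np.ndarray):
    n = logits.shape[0]
    logp = log_softmax(logits, axis=1)
    ce = -logp[np.arange(n), labels].mean()
    grad = softmax(logits, axis=1)
    grad[np.arange(n), labels] -= 1.0
    return ce, grad / n


def _kld_and_grad(student_logits, teacher_logits, temperature: float):
    n = student_logits.shape[0]
    t = temperature
    p_teacher = softmax(teacher_logits / t, axis=1)
    logp_teacher = log_softmax(teacher_logits / t, axis=1)
    logp_student = log_softmax(student_logits / t, axis=1)
    kld = (p_teacher * (logp_teacher - logp_student)).sum(axis=1).mean()
    grad = (softmax(student_logits / t, axis=1) - p_teacher) / (n * t)
    return kld, grad


def combined_loss(
    student_logits: np.ndarray,
    teacher_logits: np.ndarray | None,
    labels: np.ndarray,
    cfg: LossConfig,
) -> tuple[float, float, float]:
    """(1 - alpha) * CE + alpha * KL(teacher || student), batch means.

    Returns (total, ce, kld).  When alpha > 0 a teacher is mandatory.
    """
    student_logits = np.asarray(student_logits, float)
    labels = np.asarray(labels, int)
    if student_logits.shape[0] != labels.shape[0]:
        raise ValidationError("logits/labels row mismatch")
    if np.any(labels < 0) or np.any(labels >= student_logits.shape[1]):
        raise ValidationError("label outside class range")
    ce, _ = _ce_and_grad(student_logits, labels)
    if cfg.alpha == 0.0:
        return ce, ce, 0.0
    if teacher_logits is None:
        raise ContractError("alpha > 0 requires teacher logits")
    teacher_logits = np.asarray(teacher_logits, float)
    if teacher_logits.shape != student_logits.shape:
        raise ValidationError("teacher/student logits shape mismatch")
    kld, _ = _kld_and_grad(student_logits, teacher_logits, cfg.kd_temperature)
    return (1 - cfg.alpha) * ce + cfg.alpha * kld, ce, kld


def pseudo_label(teacher: ClassifierModel, latents: np.ndarray) -> np.ndarray:
    """Teacher argmax predictions for unlabelled (synthetic) latents."""
    return teacher.predict(latents)


# ---------------------------------------------------------------------------
# Hybrid mini-batches: 50% current task (true labels), 50% freshly sampled
# replay latents (teacher pseudo-labels).
# ---------------------------------------------------------------------------

def make_hybrid_batches(
    current: LatentDataset,
    gen: GeneratorState,
    teacher: ClassifierModel,
    batch_size: int,
    seed: int,
) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """One epoch of hybrid batches (features, labels, is_replay flags).

    Current-task rows are an epoch-wise shuffle without replacement; replay
    rows are freshly drawn from the generator for each batch.  The trailing
    short batch keeps the 50/50 ratio by shrinking symmetrically (r current
    + r replay rows).
    """
    if batch_size % 2 != 0 or batch_size <= 0:
        raise ValidationError("batch_size must be a positive even number")
    if gen is None or gen.n_support == 0:
        raise ContractError("hybrid batches need a non-empty generator")
    if teacher is None:
        raise ContractError("hybrid batches need a teacher for pseudo-labels")
    rng = np.random.default_rng(seed)
    half = batch_size // 2
    order = rng.permutation(len(current))
    for start in range(0, len(order), half):
        cur_idx = order[start : start + half]
        n_replay = len(cur_idx)
        replay = generator_sample(gen, n_replay, int(rng.integers(0, 2**31)))
        features = np.vstack([current.features[cur_idx], replay])
        labels = np.concatenate(
            [current.labels[cur_idx], pseudo_label(teacher, replay)]
        )
        flags = np.zeros(len(labels), dtype=bool)
        flags[n_replay:] = True
        yield features, labels, flags


def _plain_batches(current: LatentDataset, batch_size: int, seed: int):
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(current))
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        flags = np.zeros(len(idx), dtype=bool)
        yield current.features[idx], current.labels[idx], flags


# ---------------------------------------------------------------------------
# Optimiser and the training session
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OptConfig:
    """Adam hyperparameters and session length."""

    learning_rate: float = 1e-3
    epochs: int = 20
    batch_size: int = 64
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


class Adam:
    def __init__(self, params: list[np.ndarray], cfg: OptConfig):
        self.cfg = cfg
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = c.beta1 * self.m[i] + (1 - c.beta1) * g
            self.v[i] = c.beta2 * self.v[i] + (1 - c.beta2) * g * g
            m_hat = self.m[i] / (1 - c.beta1**self.t)
            v_hat = self.v[i] / (1 - c.beta2**self.t)
            p -= c.learning_rate * m_hat / (np.sqrt(v_hat) + c.eps)


def train_session(
    student: ClassifierModel,
    teacher: ClassifierModel | None,
    current: LatentDataset,
    gen: GeneratorState | None,
    loss_cfg: LossConfig,
    opt_cfg: OptConfig,
    seed: int,
    trace: list | None = None,
) -> ClassifierModel:
    """One training session (one task) of mini-batch Adam on the combined loss.

    Replay batches are used iff a generator is supplied; the distillation
    term is active iff a teacher is supplied and alpha > 0.  With neither
    (the first task, or the naive strategy) this reduces to plain
    cross-entropy on the current task.  The teacher is never modified.
    """
    if gen is not None and teacher is None:
        raise ContractError("replay requires a teacher for pseudo-labels")
    alpha = loss_cfg.alpha if teacher is not None else 0.0
    rng = np.random.default_rng(seed)
    params = student.weights + student.biases
    opt = Adam(params, opt_cfg)
    for epoch in range(opt_cfg.epochs):
        epoch_seed = int(rng.integers(0, 2**31))
        if gen is not None:
            batches = make_hybrid_batches(
                current, gen, teacher, opt_cfg.batch_size, epoch_seed
            )
        else:
            batches = _plain_batches(current, opt_cfg.batch_size, epoch_seed)
        for step, (x, y, is_replay) in enumerate(batches):
            logits, acts = student._forward_cached(x)
            ce, grad = _ce_and_grad(logits, y)
            grad *= 1 - alpha
            kld = 0.0
            if alpha > 0:
                t_logits = teacher.forward(x)
                if loss_cfg.kld_scope == "current_only":
                    mask = ~is_replay
                else:
                    mask = np.ones(len(y), dtype=bool)
                if mask.any():
                    kld, kgrad = _kld_and_grad(
                        logits[mask], t_logits[mask], loss_cfg.kd_temperature
                    )
                    grad[mask] += alpha * kgrad
            total = (1 - alpha) * ce + alpha * kld
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step}: "
                    f"ce={ce}, kld={kld}"
                )
            gw, gb = student.backward(acts, grad)
            opt.step(params, gw + gb)
            if trace is not None:
                trace.append(
                    {"epoch": epoch, "step": step, "loss_ce": ce,
                     "loss_kld": kld, "loss_total": total}
                )
    return student
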