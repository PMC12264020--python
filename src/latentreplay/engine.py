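"""Sequential training orchestration and the experiment-level API.

`ContinualExperiment` is the user-facing entry point: build it from a task
sequence plus a `RunConfig`, call :meth:`ContinualExperiment.fit`, and read
the resulting `ExperimentResults` (train-test matrices, ACC/BWT/ILM with
cross-repeat mean and standard deviation, a `summary()` table).  The
lower-level functions `run_strategy` / `run_experiment` / `evaluate` do the
actual work and remain available for scripting.

Strategies
----------
naive       sequential fine-tuning, no forgetting control (lower bound)
joint       one session on all tasks pooled (upper bound)
proposed    KDE generative latent replay + KL distillation
dst_only    distillation on current-task data only, no replay
glr_only    KDE replay with plain cross-entropy (no distillation)
gmm_replay  replay from per-task Gaussian mixtures instead of the KDE
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np

from . import generator as gen_mod
from . import metrics as metrics_mod
from .classifier import (
    ClassifierModel,
    DEFAULT_HIDDEN_WIDTHS,
    HeadSpec,
    LossConfig,
    OptConfig,
    init_head,
    train_session,
)
from .datasets import DomainSpec, LatentDataset, ValidationError, make_sequence

STRATEGIES = ("naive", "joint", "proposed", "dst_only", "glr_only", "gmm_replay")
#: Strategies that replay synthetic latents from a generator.
REPLAY_STRATEGIES = ("proposed", "glr_only", "gmm_replay")
#: Strategies whose loss includes the distillation term.
DISTILL_STRATEGIES = ("proposed", "dst_only", "gmm_replay")


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs: strategy, loss, generator and budget settings."""

    strategy: str = "proposed"
    alpha: float = 0.2
    k: int | str = 10  # centers retained per task, or 'auto' for BIC selection
    k_candidates: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 8, 10, 12, 15)
    gmm_components: int = 10
    batch_size: int = 64
    epochs: int = 20
    learning_rate: float = 1e-3
    n_repeats: int = 5
    base_seed: int = 0
    hidden_widths: tuple[int, ...] = DEFAULT_HIDDEN_WIDTHS
    kd_temperature: float = 1.0
    kld_scope: str = "all"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValidationError(
                f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}"
            )
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")
        if self.k != "auto" and (not isinstance(self.k, int) or self.k < 1):
            raise ValidationError("k must be a positive integer or 'auto'")

    def loss_config(self) -> LossConfig:
        if self.strategy == "dst_only":
            return LossConfig(self.alpha, self.kd_temperature, "current_only")
        if self.strategy in DISTILL_STRATEGIES:
            return LossConfig(self.alpha, self.kd_temperature, self.kld_scope)
        return LossConfig(0.0, self.kd_temperature, self.kld_scope)

    def opt_config(self) -> OptConfig:
        return OptConfig(
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
        )


@dataclass
class TrainTestMatrix:
    """T x T accuracy matrix P on the 0-100 scale.

    Cell (i, j) is test accuracy on task j after completing training session
    i.  The joint strategy produces a single row (one pooled session
    evaluated on every task).
    """

    values: np.ndarray
    task_names: list[str]
    repeat_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise ValidationError("accuracies must lie in [0, 100]")

    @property
    def T(self) -> int:
        return self.values.shape[1]


def evaluate(model: ClassifierModel, test: LatentDataset) -> float:
    """Percent accuracy of argmax predictions on a test split."""
    if len(test) == 0:
        raise ValidationError("cannot evaluate on an empty test set")
    return float(100.0 * (model.predict(test.features) == test.labels).mean())


def _choose_k(cfg: RunConfig, latents: np.ndarray, seed: int) -> int:
    if cfg.k == "auto":
        candidates = [k for k in cfg.k_candidates if k <= latents.shape[0]]
        return gen_mod.select_k_bic(latents, candidates, seed)
    return min(cfg.k, latents.shape[0])


def run_strategy(
    sequence: Sequence[tuple[LatentDataset, LatentDataset]],
    cfg: RunConfig,
    repeat_seed: int,
    collect_traces: bool = False,
) -> tuple[TrainTestMatrix, dict]:
    """Train through the sequence under one strategy and fill the matrix P.

    For the replay strategies the order per session t is: train the student
    on task t (replaying the generator state accumulated over tasks < t),
    then fold task t's latents into the generator and snapshot the trained
    model as the next teacher.
    """
    if not sequence:
        raise ValidationError("empty task sequence")
    trains = [p[0] for p in sequence]
    tests = [p[1] for p in sequence]
    t_total = len(sequence)
    dim = trains[0].dim
    n_classes = max(int(tr.labels.max()) for tr in trains) + 1
    task_names = [tr.domain_id for tr in trains]

    ss = np.random.SeedSequence(repeat_seed)
    head_seed, train_seed_root, gen_seed_root = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)
    )
    head_spec = HeadSpec(dim, n_classes, cfg.hidden_widths, seed=head_seed)
    loss_cfg = cfg.loss_config()
    opt_cfg = cfg.opt_config()
    artifacts: dict = {"traces": [], "generators": [], "models": []}

    if cfg.strategy == "joint":
        pooled = LatentDataset(
            "joint",
            "train",
            np.vstack([tr.features for tr in trains]),
            np.concatenate([tr.labels for tr in trains]),
        )
        model = init_head(head_spec)
        trace: list | None = [] if collect_traces else None
        train_session(model, None, pooled, None, loss_cfg, opt_cfg,
                      train_seed_root, trace=trace)
        row = np.array([[evaluate(model, te) for te in tests]])
        artifacts["models"].append(model)
        if collect_traces:
            artifacts["traces"].append(trace)
        return TrainTestMatrix(row, task_names), artifacts

    use_replay = cfg.strategy in REPLAY_STRATEGIES
    use_teacher = cfg.strategy in REPLAY_STRATEGIES + ("dst_only",)
    gen_state = (
        gen_mod.empty_state("gmm" if cfg.strategy == "gmm_replay" else "kde")
        if use_replay
        else None
    )
    p = np.zeros((t_total, t_total))
    model: ClassifierModel | None = None
    for t, current in enumerate(trains):
        teacher = model.as_teacher() if (model is not None and use_teacher) else None
        student = model.copy(mode="student") if model is not None else init_head(head_spec)
        session_gen = (
            gen_state if (use_replay and t > 0 and gen_state.n_support > 0) else None
        )
        session_teacher = teacher if t > 0 else None
        trace = [] if collect_traces else None
        train_session(
            student,
            session_teacher,
            current,
            session_gen if session_teacher is not None else None,
            loss_cfg,
            opt_cfg,
            train_seed_root + t,
            trace=trace,
        )
        model = student
        if use_replay:
            if cfg.strategy == "gmm_replay":
                n_comp = min(cfg.gmm_components, len(current))
                gen_state = gen_mod.append_gmm_task(
                    gen_state, current.features, n_comp, gen_seed_root + t
                )
            else:
                k = _choose_k(cfg, current.features, gen_seed_root + t)
                centers = gen_mod.fit_kmeans(
                    current.features, k, gen_seed_root + t
                )
                gen_state = gen_mod.update_generator(gen_state, centers)
            artifacts["generators"].append(gen_state)
        p[t] = [evaluate(model, te) for te in tests]
        artifacts["models"].append(model)
        if collect_traces:
            artifacts["traces"].append(trace)
    return TrainTestMatrix(p, task_names), artifacts


@dataclass
class ExperimentResults:
    """Fitted results: per-repeat matrices and aggregated CL metrics.

    ACC/BWT/ILM are reported as (mean, sample std) across repeats, on the
    0-100 percent scale.  The joint strategy has no sequential structure, so
    its ``bwt`` and ``ilm`` are None.
    """

    config: RunConfig
    matrices: list[TrainTestMatrix]
    acc: tuple[float, float]
    bwt: tuple[float, float] | None
    ilm: tuple[float, float] | None
    artifacts: list[dict] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.matrices)

    def to_report(self) -> dict:
        def pair(x):
            return None if x is None else {"mean": x[0], "std": x[1]}

        return {
            "strategy": self.config.strategy,
            "n_repeats": self.n_repeats,
            "T": self.matrices[0].T,
            "acc": pair(self.acc),
            "bwt": pair(self.bwt),
            "ilm": pair(self.ilm),
        }

    def summary(self) -> str:
        cfg = self.config
        t = self.matrices[0].T
        lines = [
            "         Continual Learning Experiment Results",
            "=" * 58,
            f"Strategy:       {cfg.strategy}",
            f"Tasks:          {t}  ({', '.join(self.matrices[0].task_names)})",
            f"Repeats:        {self.n_repeats}   base seed: {cfg.base_seed}",
            f"alpha: {cfg.alpha}   K/task: {cfg.k}   batch: {cfg.batch_size}"
            f"   epochs: {cfg.epochs}",
            "-" * 58,
            f"ACC  (%)        {self.acc[0]:7.2f} +/- {self.acc[1]:.2f}",
        ]
        if self.bwt is not None:
            lines.append(f"BWT  (%)        {self.bwt[0]:7.2f} +/- {self.bwt[1]:.2f}")
            lines.append(f"ILM  (%)        {self.ilm[0]:7.2f} +/- {self.ilm[1]:.2f}")
        else:
            lines.append("BWT  (%)              --  (joint strategy)")
            lines.append("ILM  (%)              --  (joint strategy)")
        lines.append("-" * 58)
        lines.append("Train-test matrix P, repeat 0 (rows: after session i):")
        for row in self.matrices[0].values:
            lines.append("   " + "  ".join(f"{v:6.2f}" for v in row))
        lines.append("=" * 58)
        return "\n".join(lines)


def run_experiment(
    sequence: Sequence[tuple[LatentDataset, LatentDataset]],
    cfg: RunConfig,
    collect_traces: bool = False,
) -> ExperimentResults:
    """Repeat run_strategy with seeds base_seed + r and aggregate the metrics."""
    matrices, artifacts = [], []
    accs, bwts, ilms = [], [], []
    for r in range(cfg.n_repeats):
        matrix, art = run_strategy(
            sequence, cfg, cfg.base_seed + r, collect_traces=collect_traces
        )
        matrix.repeat_index = r
        matrices.append(matrix)
        artifacts.append(art)
        if cfg.strategy == "joint":
            accs.append(float(matrix.values[0].mean()))
        else:
            accs.append(metrics_mod.acc(matrix.values))
            if matrix.T >= 2:
                bwts.append(metrics_mod.bwt(matrix.values))
            ilms.append(metrics_mod.ilm(matrix.values))
    return ExperimentResults(
        config=cfg,
        matrices=matrices,
        acc=metrics_mod.aggregate(accs),
        bwt=metrics_mod.aggregate(bwts) if bwts else None,
        ilm=metrics_mod.aggregate(ilms) if ilms else None,
        artifacts=artifacts,
    )


class ContinualExperiment:
    """Model-style wrapper: a task sequence plus a run configuration.

    Examples
    --------
    >>> from latentreplay.datasets import default_benchmark_specs
    >>> specs = default_benchmark_specs(base_seed=0)
    >>> exp = ContinualExperiment.from_specs(specs, RunConfig(strategy="proposed",
    ...                                                       n_repeats=3))
    >>> res = exp.fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        sequence: Sequence[tuple[LatentDataset, LatentDataset]],
        config: RunConfig | None = None,
    ):
        if not sequence:
            raise ValidationError("empty task sequence")
        self.sequence = list(sequence)
        self.config = config or RunConfig()

    @classmethod
    def from_specs(
        cls, specs: Sequence[DomainSpec], config: RunConfig | None = None
    ) -> "ContinualExperiment":
        return cls(make_sequence(specs), config)

    @classmethod
    def from_directory(
        cls, seq_dir, config: RunConfig | None = None
    ) -> "ContinualExperiment":
        from .datasets import read_sequence

        return cls(read_sequence(seq_dir), config)

    def fit(self, collect_traces: bool = False) -> ExperimentResults:
        return run_experiment(self.sequence, self.config,
                              collect_traces=collect_traces)
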