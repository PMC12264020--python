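"""Privacy-aware generative latent replay: the KDE-over-centers generator.

The generator is the only persisted trace of past tasks.  After each task,
its training latents are compressed by K-means to K cluster centers; only
the centers are retained (no raw vectors, so nothing resembling an
individual sample survives unless a cluster is a singleton).  The centers
from all tasks so far form the support set of a Gaussian kernel density
estimate whose diagonal bandwidth is recomputed by Silverman's rule at
every update.  Sampling the KDE yields synthetic latents that mimic every
past domain at once; state size is O(m*d) with m = sum of per-task K,
independent of how much data was seen.

A parametric alternative — one Gaussian mixture model per task — is
provided for comparison with GMM-based generative replay.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .datasets import ValidationError

#: Lower bound on every bandwidth entry, so zero-variance support columns
#: still admit sampling.
BANDWIDTH_FLOOR = 1e-6


@dataclass
class TaskGMM:
    """Parameters of one task's fitted Gaussian mixture."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d) full covariances


@dataclass
class GeneratorState:
    """Cumulative generator over all tasks seen so far.

    ``kind='kde'`` stores retained cluster centers (``support_points``) plus
    a per-dimension Gaussian bandwidth; ``kind='gmm'`` stores one fitted
    mixture per task.
    """

    support_points: np.ndarray  # (m, d)
    per_task_counts: list[int]
    bandwidth: np.ndarray | None  # (d,), kde only, None while m < 2
    kind: str = "kde"
    gmms: list[TaskGMM] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.support_points = np.atleast_2d(np.asarray(self.support_points, float))
        if self.n_support != sum(self.per_task_counts):
            raise ValidationError(
                f"m={self.n_support} support points but per_task_counts sum to "
                f"{sum(self.per_task_counts)}"
            )
        if self.bandwidth is not None:
            self.bandwidth = np.asarray(self.bandwidth, float)
            if np.any(self.bandwidth <= 0):
                raise ValidationError("bandwidth entries must be > 0")

    @property
    def n_support(self) -> int:
        return 0 if self.support_points.size == 0 else self.support_points.shape[0]

    @property
    def dim(self) -> int:
        return self.support_points.shape[1]

    @property
    def n_tasks(self) -> int:
        return len(self.per_task_counts)


def empty_state(kind: str = "kde") -> GeneratorState:
    return GeneratorState(np.empty((0, 0)), [], None, kind=kind)


def fit_kmeans(latents: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Compress latents to K cluster centers (k-means++, 10 restarts).

    If the data holds fewer than K distinct rows, K is clamped with a
    warning so every center remains the mean of a nonempty cluster.
    """
    latents = np.asarray(latents, float)
    n = latents.shape[0]
    if k < 1:
        raise ValidationError("k must be positive")
    if k > n:
        raise ValidationError(f"k={k} exceeds n={n} samples")
    n_distinct = np.unique(latents, axis=0).shape[0]
    if k > n_distinct:
        warnings.warn(
            f"only {n_distinct} distinct rows; clamping k={k} to {n_distinct}",
            stacklevel=2,
        )
        k = n_distinct
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, tol=1e-4,
                random_state=seed)
    km.fit(latents)
    return km.cluster_centers_


def _kmeans_bic(latents: np.ndarray, k: int, seed: int) -> float:
    """BIC of the spherical-Gaussian mixture implied by a K-means fit.

    Components share one pooled variance (MLE of the mean squared residual
    per coordinate); mixing weights are the cluster occupancies.  Parameter
    count p = K*d + K + 1 (means, mixing, pooled variance);
    BIC = p*ln(n) - 2*lnL.
    """
    latents = np.asarray(latents, float)
    n, d = latents.shape
    centers = fit_kmeans(latents, k, seed)
    k = centers.shape[0]  # may have been clamped
    d2 = ((latents[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    rss = d2[np.arange(n), assign].sum()
    counts = np.bincount(assign, minlength=k).astype(float)
    sigma2 = max(rss / (n * d), 1e-12)
    nonzero = counts > 0
    log_mix = float((counts[nonzero] * np.log(counts[nonzero] / n)).sum())
    loglik = log_mix - 0.5 * n * d * (np.log(2 * np.pi * sigma2) + 1.0)
    p = k * d + k + 1
    return p * np.log(n) - 2.0 * loglik


def select_k_bic(latents: np.ndarray, k_candidates: list[int], seed: int) -> int:
    """Pick the cluster count minimising the K-means BIC; ties favour smaller K."""
    if not k_candidates:
        raise ValidationError("empty candidate list")
    latents = np.asarray(latents, float)
    n = latents.shape[0]
    for k in k_candidates:
        if k < 1 or k > n:
            raise ValidationError(f"candidate k={k} outside [1, {n}]")
    best_k, best_bic = None, np.inf
    for k in sorted(k_candidates):
        bic = _kmeans_bic(latents, k, seed)
        if bic < best_bic:  # strict: ties keep the smaller k
            best_k, best_bic = k, bic
    return best_k


def silverman_bandwidth(
    points: np.ndarray, floor: float = BANDWIDTH_FLOOR
) -> np.ndarray:
    """Per-dimension Silverman plug-in bandwidth for a Gaussian product kernel.

    h_j = sigma_j * (4 / ((d + 2) * m)) ** (1 / (d + 4)), with sigma_j the
    sample (ddof=1) standard deviation of column j, floored at ``floor`` so
    degenerate columns stay sampleable.
    """
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValidationError("bandwidth needs at least 2 support points")
    m, d = points.shape
    sigma = points.std(axis=0, ddof=1)
    factor = (4.0 / ((d + 2) * m)) ** (1.0 / (d + 4))
    return np.maximum(sigma * factor, floor)


def update_generator(
    prev: GeneratorState | None, new_centers: np.ndarray
) -> GeneratorState:
    """Merge a task's retained centers into the cumulative KDE generator.

    Support set is the row concatenation of the previous support set and the
    new centers; the bandwidth is recomputed on the combined set so the
    kernel adapts as domains accumulate.
    """
    new_centers = np.atleast_2d(np.asarray(new_centers, float))
    if prev is None:
        prev = empty_state()
    if prev.kind != "kde":
        raise ValidationError("update_generator applies to kde generators")
    if prev.n_support:
        if new_centers.shape[1] != prev.dim:
            raise ValidationError(
                f"dimension mismatch: state d={prev.dim}, centers "
                f"d={new_centers.shape[1]}"
            )
        support = np.vstack([prev.support_points, new_centers])
    else:
        support = new_centers
    counts = list(prev.per_task_counts) + [new_centers.shape[0]]
    bw = silverman_bandwidth(support) if support.shape[0] >= 2 else None
    return GeneratorState(support, counts, bw, kind="kde")


def sample(state: GeneratorState, n: int, seed: int) -> np.ndarray:
    """Draw n synthetic latents mimicking all past tasks.

    kde: uniformly pick a support point, add diagonal Gaussian noise with
    the stored bandwidth.  gmm: pick a task uniformly, then a component by
    weight, then draw from that component.  Deterministic given seed.
    """
    if n < 0:
        raise ValidationError("n must be non-negative")
    rng = np.random.default_rng(seed)
    if state.kind == "kde":
        if state.n_support < 2 or state.bandwidth is None:
            raise ValidationError("kde sampling needs >= 2 support points")
        if n == 0:
            return np.empty((0, state.dim))
        idx = rng.integers(0, state.n_support, size=n)
        noise = rng.standard_normal((n, state.dim)) * state.bandwidth
        return state.support_points[idx] + noise
    if state.kind == "gmm":
        if not state.gmms:
            raise ValidationError("gmm generator holds no fitted mixtures")
        d = state.gmms[0].means.shape[1]
        if n == 0:
            return np.empty((0, d))
        out = np.empty((n, d))
        task_idx = rng.integers(0, len(state.gmms), size=n)
        for i, t in enumerate(task_idx):
            g = state.gmms[t]
            comp = rng.choice(len(g.weights), p=g.weights)
            out[i] = rng.multivariate_normal(g.means[comp], g.covariances[comp])
        return out
    raise ValidationError(f"unknown generator kind {state.kind!r}")


def fit_gmm_generator(
    latents_per_task: list[np.ndarray], n_components: int, seed: int
) -> GeneratorState:
    """Fit one full-covariance GMM per seen task (parametric replay variant)."""
    if not latents_per_task:
        raise ValidationError("need at least one task")
    gmms, support_blocks, counts = [], [], []
    for t, latents in enumerate(latents_per_task):
        latents = np.asarray(latents, float)
        if n_components > latents.shape[0]:
            raise ValidationError(
                f"n_components={n_components} exceeds task {t} size "
                f"{latents.shape[0]}"
            )
        gm = GaussianMixture(
            n_components=n_components,
            covariance_type="full",
            random_state=seed + t,
            reg_covar=1e-6,
            n_init=1,
        )
        gm.fit(latents)
        gmms.append(TaskGMM(gm.weights_.copy(), gm.means_.copy(),
                            gm.covariances_.copy()))
        support_blocks.append(gm.means_.copy())
        counts.append(n_components)
    return GeneratorState(
        np.vstack(support_blocks), counts, None, kind="gmm", gmms=gmms
    )


def append_gmm_task(
    prev: GeneratorState, latents: np.ndarray, n_components: int, seed: int
) -> GeneratorState:
    """Incrementally add one task's mixture to a gmm generator."""
    if prev.kind != "gmm":
        raise ValidationError("append_gmm_task applies to gmm generators")
    addition = fit_gmm_generator([latents], n_components, seed)
    if prev.n_support == 0:
        return addition
    return GeneratorState(
        np.vstack([prev.support_points, addition.support_points]),
        list(prev.per_task_counts) + addition.per_task_counts,
        None,
        kind="gmm",
        gmms=prev.gmms + addition.gmms,
    )


# ---------------------------------------------------------------------------
# Serialization: support points as TSV, the rest as a JSON sidecar, so the
# privacy claim (centers only, no raw vectors) is auditable by eye.
# ---------------------------------------------------------------------------

def save_state(state: GeneratorState, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(prefix.with_suffix(".tsv"), state.support_points, delimiter="\t")
    meta = {
        "kind": state.kind,
        "per_task_counts": state.per_task_counts,
        "bandwidth": None if state.bandwidth is None else state.bandwidth.tolist(),
        "gmms": [
            {
                "weights": g.weights.tolist(),
                "means": g.means.tolist(),
                "covariances": g.covariances.tolist(),
            }
            for g in state.gmms
        ],
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_state(prefix: str | Path) -> GeneratorState:
    prefix = Path(prefix)
    support = np.atleast_2d(np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    gmms = [
        TaskGMM(
            np.asarray(g["weights"]), np.asarray(g["means"]),
            np.asarray(g["covariances"]),
        )
        for g in meta["gmms"]
    ]
    bw = None if meta["bandwidth"] is None else np.asarray(meta["bandwidth"])
    return GeneratorState(support, meta["per_task_counts"], bw,
                          kind=meta["kind"], gmms=gmms)
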