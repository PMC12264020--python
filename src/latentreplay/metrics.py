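"""Continual-learning metrics over the train-test accuracy matrix.

All metrics read a T x T matrix P whose cell p[i, j] is the accuracy (in
percent) on task j's test set after completing training session i.  The
matrix uses 0-based storage; the conventional 1-based task indices map to
rows/columns by subtracting 1, and that mapping is confined to this module.

ACC  = mean of the last row — average accuracy once the sequence is done.
BWT  = mean over columns j < T of the average drop p[i, j] - p[j, j] over
       later sessions i > j — signed backward transfer (negative values
       quantify forgetting).
ILM  = mean over the lower triangle including the diagonal (the
       2 / (T (T + 1)) normalisation) — incremental-learning quality over
       the whole run, not just the end state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ValidationError


@dataclass(frozen=True)
class CLMetrics:
    acc: float
    bwt: float | None
    ilm: float
    T: int


def _as_matrix(p) -> np.ndarray:
    values = np.asarray(getattr(p, "values", p), dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1] or values.size == 0:
        raise ValidationError(f"expected a nonempty square matrix, got {values.shape}")
    return values


def acc(p) -> float:
    """Mean accuracy over all tasks after the final training session."""
    return float(_as_matrix(p)[-1].mean())


def bwt(p) -> float:
    """Average backward transfer; undefined (error) for a single task."""
    values = _as_matrix(p)
    t = values.shape[0]
    if t < 2:
        raise ValidationError("BWT needs at least 2 tasks")
    outer = 0.0
    for j in range(t - 1):
        later = values[j + 1 :, j]  # sessions i > j
        outer += float((later - values[j, j]).mean())
    return outer / (t - 1)


def ilm(p) -> float:
    """Mean accuracy over the lower triangle (incl. diagonal) of P."""
    values = _as_matrix(p)
    t = values.shape[0]
    mask = np.tril(np.ones((t, t), dtype=bool))
    return float(values[mask].sum() * 2.0 / (t * (t + 1)))


def compute_all(p) -> CLMetrics:
    values = _as_matrix(p)
    t = values.shape[0]
    return CLMetrics(
        acc=acc(values),
        bwt=bwt(values) if t >= 2 else None,
        ilm=ilm(values),
        T=t,
    )


def aggregate(values: list[float]) -> tuple[float, float]:
    """Mean and sample (ddof=1) standard deviation; std is 0 for one value."""
    if not values:
        raise ValidationError("nothing to aggregate")
    arr = np.asarray(values, float)
    mean = float(arr.mean())
    std = 0.0 if arr.size == 1 else float(arr.std(ddof=1))
    return mean, std
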