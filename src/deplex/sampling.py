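"""Class rebalancing on encoded posts: random under-sampling and SMOTE.

SMOTE here operates directly on padded token-index vectors: a synthetic
minority row is ``a + lam * (b - a)`` with ``lam ~ U(0, 1)`` and ``b`` one of
``a``'s k nearest minority neighbours (Euclidean distance in index space),
rounded to the nearest valid index.  Interpolating index vectors is exactly
what corrupts reserved boundary markers ([CLS]/[SEP]-style begin/end tokens):
a marker present at different positions in ``a`` and ``b`` is averaged into an
ordinary index, so synthetic rows can carry zero or duplicated markers and a
downstream transformer head sees malformed sequences.  The
``guard_special_tokens`` switch copies every position where either parent
holds a pad or boundary index verbatim from ``a``, which provably preserves
each row's marker multiset; with the guard off the pathology is reproducible
on purpose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .features import FeatureMatrix

logger = logging.getLogger(__name__)


class SingleClassError(ValueError):
    """Resampling needs both classes present."""


@dataclass(frozen=True)
class SamplingConfig:
    mode: str = "normal"  # normal | under | over
    k_neighbors: int = 5
    seed: int = 0
    guard_special_tokens: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("normal", "under", "over"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class SmoteTrace:
    """Per-synthetic-row provenance: base row a, neighbour b, lam, raw point.

    ``raw`` is the pre-rounding interpolation ``a + lam * (b - a)``, kept so
    tests can verify every synthetic point is a convex combination of two
    minority rows.
    """

    base_rows: np.ndarray
    neighbor_rows: np.ndarray
    lam: np.ndarray
    raw: np.ndarray


def _check_two_classes(y: np.ndarray) -> tuple[int, int]:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise SingleClassError("resampling requires both classes in y")
    order = np.argsort(counts, kind="stable")
    minority = int(classes[order[0]])
    majority = int(classes[order[-1]])
    return minority, majority


def undersample(X: np.ndarray, y: np.ndarray, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Randomly subsample the majority class (without replacement) down to the
    minority count; minority rows pass through untouched."""
    X, y = np.asarray(X), np.asarray(y)
    minority, majority = _check_two_classes(y)
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y == majority)
    rng = np.random.default_rng(seed)
    keep_maj = np.sort(rng.choice(maj_idx, size=len(min_idx), replace=False))
    keep = np.sort(np.concatenate([min_idx, keep_maj]))
    return X[keep], y[keep]


def smote(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
    guard_special_tokens: bool = True,
    special_indices: tuple[int, ...] = (),
    pad_index: int = 0,
    vocab_size: Optional[int] = None,
    return_trace: bool = False,
):
    """SMOTE over integer token-index rows; balances classes exactly.

    With the guard on, ``special_indices`` (boundary markers) and the pad
    index are never interpolated: wherever either parent row holds one of
    those indices, the synthetic row copies ``a``'s value verbatim.
    """
    X = np.asarray(X, dtype=np.int64)
    y = np.asarray(y)
    minority, majority = _check_two_classes(y)
    min_rows = X[y == minority]
    n_min, n_maj = len(min_rows), int((y == majority).sum())
    if n_min <= k_neighbors:
        raise ValueError(
            f"SMOTE needs more minority samples ({n_min}) than k_neighbors "
            f"({k_neighbors}); lower sampling.k_neighbors or gather more data"
        )
    n_new = n_maj - n_min
    rng = np.random.default_rng(seed)

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(min_rows.astype(np.float64))
    # column 0 is the point itself
    neighbor_idx = nn.kneighbors(min_rows.astype(np.float64), return_distance=False)[:, 1:]

    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_neighbors, size=n_new)
    lam = rng.random(n_new)
    a = min_rows[base]
    b = min_rows[neighbor_idx[base, pick]]
    raw = a + lam[:, None] * (b - a)
    synth = np.rint(raw).astype(np.int64)
    if vocab_size is not None:
        synth = np.clip(synth, 0, vocab_size - 1)
    if guard_special_tokens and (special_indices or pad_index is not None):
        reserved = set(special_indices) | {pad_index}
        mask = np.isin(a, list(reserved)) | np.isin(b, list(reserved))
        synth[mask] = a[mask]

    X_out = np.concatenate([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    if return_trace:
        return X_out, y_out, SmoteTrace(a, b, lam, raw)
    return X_out, y_out


def apply_sampling(dataset: FeatureMatrix, config: SamplingConfig) -> FeatureMatrix:
    """Dispatch normal (identity) / under / over; meant for the training split
    only — resampling evaluation data would bias every reported metric."""
    before = dataset.class_counts()
    if config.mode == "normal":
        out = dataset
    elif config.mode == "under":
        X, y = undersample(dataset.X, dataset.y, seed=config.seed)
        out = FeatureMatrix(X, y, dataset.vocab_size, dataset.pad_index, dataset.boundary_indices)
    else:
        X, y = smote(
            dataset.X,
            dataset.y,
            k_neighbors=config.k_neighbors,
            seed=config.seed,
            guard_special_tokens=config.guard_special_tokens,
            special_indices=dataset.boundary_indices,
            pad_index=dataset.pad_index,
            vocab_size=dataset.vocab_size,
        )
        out = FeatureMatrix(X, y, dataset.vocab_size, dataset.pad_index, dataset.boundary_indices)
    logger.info("sampling mode=%s class counts %s -> %s", config.mode, before, out.class_counts())
    return out
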