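"""Distance kernels and the greedy max-min (Kennard-Stone style) splitter.

The splitter seeds the training set with the globally most distant pair,
then repeatedly appends the candidate whose distance to its nearest
already-selected training sample is maximal.  Supported metrics: Euclidean,
Mahalanobis (covariance estimated on all rows, inverted by pseudo-inverse,
optional ridge term) and 1 - Tanimoto for bit vectors.  Optionally the
binary class label is appended as an extra coordinate before distances are
computed.

All ties are broken by lowest row index so a split is a pure function of its
inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceConfig",
    "SplitResult",
    "pairwise_distances",
    "kennard_stone",
]

_METRICS = ("euclidean", "mahalanobis", "tanimoto_complement")


@dataclass(frozen=True)
class DistanceConfig:
    metric: str = "euclidean"
    include_labels: bool = False
    covariance_regularization: float = 0.0

    def __post_init__(self):
        if self.metric not in _METRICS:
            raise InputError(f"metric must be one of {_METRICS}")
        if self.covariance_regularization < 0:
            raise InputError("covariance_regularization must be >= 0")


@dataclass
class SplitResult:
    train_ids: List[str]  # in selection order
    test_ids: List[str]
    metric: str
    train_fraction: float
    selection_distances: List[float] = field(default_factory=list)


def _tanimoto_complement(X: np.ndarray) -> np.ndarray:
    if not np.isin(X, (0, 1)).all():
        raise InputError("tanimoto_complement requires binary (0/1) data")
    Xb = X.astype(np.float64)
    inter = Xb @ Xb.T
    counts = Xb.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    d = 1.0 - tc
    np.fill_diagonal(d, 0.0)
    return d


def pairwise_distances(
    X: np.ndarray,
    config: DistanceConfig = DistanceConfig(),
    labels: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Symmetric zero-diagonal distance matrix under the configured metric."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("X must be a 2-D matrix with at least 2 rows")
    if config.include_labels:
        if labels is None:
            raise InputError("include_labels set but no labels supplied")
        y = np.asarray(labels, dtype=float).reshape(-1, 1)
        if y.shape[0] != X.shape[0]:
            raise InputError("labels length mismatch")
        X = np.hstack([X, y])

    if config.metric == "euclidean":
        d = cdist(X, X, metric="euclidean")
    elif config.metric == "mahalanobis":
        cov = np.cov(X, rowvar=False)
        cov = np.atleast_2d(cov)
        if config.covariance_regularization > 0:
            cov = cov + config.covariance_regularization * np.eye(cov.shape[0])
        vi = np.linalg.pinv(cov)
        # cdist requires VI symmetric positive-semidefinite; pinv of a
        # symmetric matrix is symmetric up to rounding
        vi = (vi + vi.T) / 2.0
        d = cdist(X, X, metric="mahalanobis", VI=vi)
    else:
        d = _tanimoto_complement(X)

    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def kennard_stone(
    X: np.ndarray,
    train_size: int,
    config: DistanceConfig = DistanceConfig(),
    labels: Optional[Sequence[int]] = None,
    ids: Optional[Sequence[str]] = None,
) -> SplitResult:
    """Greedy max-min split: train covers the feature space, remainder is test.

    The first two training samples are a pair at maximal mutual distance
    (lowest indices on ties); each further sample maximises the distance to
    its nearest training sample.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not (2 <= train_size < n):
        raise InputError(f"train_size must be in [2, {n - 1}], got {train_size}")
    id_list = [str(i) for i in (ids if ids is not None else range(n))]
    if len(id_list) != n:
        raise InputError("ids length mismatch")

    D = pairwise_distances(X, config, labels=labels)
    if D.max() == 0.0:
        logger.warning("all points identical: selection degenerates to index order")

    # initial pair: maximal distance, ties -> lexicographically lowest (i, j)
    iu = np.triu_indices(n, k=1)
    flat = D[iu]
    best = int(np.argmax(flat))  # argmax returns first max: lowest (i, j)
    i0, j0 = int(iu[0][best]), int(iu[1][best])

    selected = [i0, j0]
    sel_dist = [float(D[i0, j0]), float(D[i0, j0])]
    in_train = np.zeros(n, dtype=bool)
    in_train[[i0, j0]] = True
    # distance of every candidate to its nearest training sample
    nearest = np.minimum(D[:, i0], D[:, j0])

    while len(selected) < train_size:
        cand = np.where(~in_train)[0]
        # argmax over candidates; first occurrence = lowest index tie-break
        pick = cand[int(np.argmax(nearest[cand]))]
        selected.append(int(pick))
        sel_dist.append(float(nearest[pick]))
        in_train[pick] = True
        nearest = np.minimum(nearest, D[:, pick])

    test = [i for i in range(n) if not in_train[i]]
    return SplitResult(
        train_ids=[id_list[i] for i in selected],
        test_ids=[id_list[i] for i in test],
        metric=config.metric,
        train_fraction=train_size / n,
        selection_distances=sel_dist,
    )
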