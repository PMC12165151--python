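"""Reduction of continuous multichannel recordings to N = 9 binary state series.

Two routes are supported:

* brain route — a 9-channel (network-averaged) series is binarized against
  the whole-recording average signal: by default, node i is +1 at time t iff
  its signal exceeds the across-node mean signal at t (a per-timepoint
  global-mean threshold; a per-node temporal-mean threshold is available as
  a config switch).
* LLM route — a high-dimensional hidden-state series is first restricted to
  an iteration window (to drop the prompt-dominated start and the frozen
  tail), its nodes are z-normalized and k-means-clustered into nine
  clusters, and each cluster-mean time course is binarized against its own
  temporal average.  For multi-layer recordings each layer is processed
  independently and layer 1 (which merely encodes the input tokens) is
  excluded.

Ties at a threshold are resolved by the strictly-greater convention:
value > threshold → +1, else −1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

N_CLUSTERS = 9
DEFAULT_WINDOW = (10_000, 60_000)  # iteration window retained for analysis


@dataclass
class BinaryStateSeries:
    """T x N matrix of ±1 activities with provenance annotations."""

    values: np.ndarray
    node_labels: list[str] = field(default_factory=list)
    source: str = "unknown"  # "brain-route" | "llm-route" | generator name
    layer: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x N matrix")
        if not np.isin(self.values, (-1, 1)).all():
            raise ValueError("entries must be -1 or +1")
        if not self.node_labels:
            self.node_labels = [f"n{i + 1}" for i in range(self.values.shape[1])]

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        arr = self.values
        if dtype is not None:
            arr = arr.astype(dtype)
        return np.array(arr, copy=True) if copy else arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class LLMSeriesMeta:
    """Shape annotations of a hidden-state recording (layers are 1-based)."""

    n_hidden: int
    n_layers: int
    n_iterations: int
    window_start: int = DEFAULT_WINDOW[0]
    window_end: int = DEFAULT_WINDOW[1]
    n_tokens: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.window_start < self.window_end <= self.n_iterations):
            raise ValueError(
                f"window [{self.window_start}, {self.window_end}) outside "
                f"0..{self.n_iterations}"
            )


@dataclass
class ClusterAssignment:
    """Column → cluster map; cluster ids run 1..k and every cluster is non-empty."""

    labels: np.ndarray  # (n_columns,) of int in 1..k
    k: int = N_CLUSTERS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError(f"expected exactly {self.k} non-empty clusters 1..{self.k}")

    @property
    def counts(self) -> dict[int, int]:
        lab, cnt = np.unique(self.labels, return_counts=True)
        return {int(a): int(c) for a, c in zip(lab, cnt)}

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def _validate_continuous(series: np.ndarray, name: str = "series") -> np.ndarray:
    X = np.asarray(series, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix")
    if np.isnan(X).any():
        rows = np.flatnonzero(np.isnan(X).any(axis=1))
        cols = np.flatnonzero(np.isnan(X).any(axis=0))
        raise ValueError(
            f"{name} contains NaN entries (rows {rows[:10].tolist()}, columns {cols.tolist()})"
        )
    return X


def binarize_brain_route(
    series: np.ndarray,
    threshold_mode: str = "per_timepoint_global_mean",
) -> BinaryStateSeries:
    """Binarize a 9-channel series against the whole-brain average signal.

    ``per_timepoint_global_mean`` (default): node i is +1 at t iff its value
    strictly exceeds the across-node mean at t.  ``per_node_temporal_mean``:
    threshold is instead each node's own temporal mean.
    """
    X = _validate_continuous(series)
    if X.shape[1] != N_CLUSTERS:
        raise ValueError(f"brain route expects exactly {N_CLUSTERS} columns, got {X.shape[1]}")
    if threshold_mode == "per_timepoint_global_mean":
        thr = X.mean(axis=1, keepdims=True)
    elif threshold_mode == "per_node_temporal_mean":
        thr = X.mean(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    vals = np.where(X > thr, 1, -1).astype(np.int8)
    return BinaryStateSeries(values=vals, source="brain-route")


def select_iteration_window(
    series: np.ndarray,
    window_start: int = DEFAULT_WINDOW[0],
    window_end: int = DEFAULT_WINDOW[1],
) -> np.ndarray:
    """Rows [window_start, window_end) of the iteration axis (half-open)."""
    X = np.asarray(series)
    if not (0 <= window_start < window_end <= X.shape[0]):
        raise ValueError(
            f"window [{window_start}, {window_end}) outside series of length {X.shape[0]}"
        )
    return X[window_start:window_end]


def znormalize_columns(series: np.ndarray) -> np.ndarray:
    """Per-column temporal z-normalization; constant columns become all-zero (logged)."""
    X = _validate_continuous(series)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    # relative tolerance: a numerically constant column has sd at rounding level
    constant = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if constant.any():
        logger.warning(
            "z-normalization: %d constant column(s) set to zero: %s",
            int(constant.sum()),
            np.flatnonzero(constant)[:10].tolist(),
        )
    sd_safe = np.where(constant, 1.0, sd)
    Z = (X - mean) / sd_safe
    Z[:, constant] = 0.0
    return Z


def cluster_nodes(
    series: np.ndarray,
    k: int = N_CLUSTERS,
    seed: int = 0,
    restarts: int = 10,
) -> ClusterAssignment:
    """K-means partition of the columns by their z-normalized time courses.

    Best of ``restarts`` seeded initializations by within-cluster sum of
    squares; deterministic given ``seed``.
    """
    X = _validate_continuous(series)
    if X.shape[1] < k:
        raise ValueError(f"need at least {k} columns to form {k} clusters, got {X.shape[1]}")
    Z = znormalize_columns(X)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(Z.T)
    return ClusterAssignment(labels=labels + 1, k=k)


def reduce_and_binarize(
    series: np.ndarray,
    clusters: ClusterAssignment,
    normalize: bool = True,
) -> BinaryStateSeries:
    """Cluster-mean time courses binarized against each cluster's temporal average.

    With ``normalize`` (default) the cluster means are taken over the same
    z-normalized node time courses the clustering used; either way an entry
    is +1 iff the cluster activity at t strictly exceeds that cluster's
    temporal average.
    """
    X = _validate_continuous(series)
    if clusters.labels.shape[0] != X.shape[1]:
        raise ValueError(
            f"cluster assignment covers {clusters.labels.shape[0]} columns, series has {X.shape[1]}"
        )
    Z = znormalize_columns(X) if normalize else X
    out = np.empty((X.shape[0], clusters.k), dtype=np.int8)
    for c in range(1, clusters.k + 1):
        members = clusters.members(c)
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        activity = Z[:, members].mean(axis=1)
        out[:, c - 1] = np.where(activity > activity.mean(), 1, -1)
    return BinaryStateSeries(values=out, source="llm-route")


def per_layer_series(
    stacked: dict[int, np.ndarray] | np.ndarray,
    meta: LLMSeriesMeta,
    seed: int = 0,
    restarts: int = 10,
) -> list[BinaryStateSeries]:
    """Window → cluster → binarize each layer independently; layer 1 excluded.

    ``stacked`` is either a dict {layer (1-based): T x n_hidden matrix} or a
    (n_layers, T, n_hidden) array.  The first layer's states merely encode
    the input tokens, so layers 2..n_layers are returned.
    """
    if meta.n_layers < 2:
        raise ValueError("need at least 2 layers (layer 1 is excluded from analysis)")
    if isinstance(stacked, dict):
        layers = {int(l): np.asarray(m) for l, m in stacked.items()}
    else:
        arr = np.asarray(stacked)
        layers = {l + 1: arr[l] for l in range(arr.shape[0])}
    missing = set(range(1, meta.n_layers + 1)) - set(layers)
    if missing:
        raise ValueError(f"missing layers {sorted(missing)}")

    out: list[BinaryStateSeries] = []
    for layer in range(2, meta.n_layers + 1):
        windowed = select_iteration_window(layers[layer], meta.window_start, meta.window_end)
        # a distinct, deterministic clustering seed per layer
        assignment = cluster_nodes(windowed, seed=seed + layer, restarts=restarts)
        series = reduce_and_binarize(windowed, assignment)
        series.layer = layer
        out.append(series)
    return out
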