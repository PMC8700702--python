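"""State-space clustering of windowed features and Markov transition maps.

The four dyad channels' windowed recurrence profiles are z-scored and
clustered with k-means; consecutive window labels are then counted into a
row-stochastic transition matrix whose stationary distribution and
self-transition diagonal identify attractor states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eig
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "FeatureStream",
    "StateSequence",
    "TransitionModel",
    "assemble_features",
    "cluster_states",
    "select_k",
    "estimate_transitions",
    "attractor_report",
]

DEFAULT_FEATURES = ("RR", "DET")
DEFAULT_SEED = 20211125


@dataclass
class FeatureStream:
    """Window-aligned, z-scored multichannel feature matrix."""

    t: np.ndarray
    X: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.t.size:
            raise ValueError("X must be (n_windows, n_features) aligned with t")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column labels must match feature count")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_windows(self) -> int:
        return int(self.X.shape[0])


@dataclass
class StateSequence:
    labels: np.ndarray
    k: int
    centroids: np.ndarray  # (k, n_features), z-score space

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("labels out of range")

    def occupancy(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k) / self.labels.size


@dataclass
class TransitionModel:
    P: np.ndarray
    counts: np.ndarray
    pi: np.ndarray
    k: int = field(init=False)

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.counts = np.asarray(self.counts)
        self.pi = np.asarray(self.pi, dtype=float)
        self.k = self.P.shape[0]
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("stationary distribution must sum to 1")

    @property
    def self_p(self) -> np.ndarray:
        return np.diag(self.P)

    def as_dict(self) -> dict:
        return {
            "k": int(self.k),
            "P": self.P.tolist(),
            "counts": self.counts.astype(int).tolist(),
            "pi": self.pi.tolist(),
        }


def assemble_features(
    profiles: dict[str, pd.DataFrame],
    features: tuple[str, ...] = DEFAULT_FEATURES,
) -> FeatureStream:
    """Join per-channel windowed profiles into one z-scored matrix.

    All channels must share the window grid (same number of windows);
    timestamps are taken from the first channel. Zero-variance columns
    are dropped with a warning since they carry no clustering signal.
    """
    if not profiles:
        raise ValueError("no channels given")
    names = list(profiles)
    n = len(profiles[names[0]])
    for name in names:
        if len(profiles[name]) != n:
            raise ValueError(
                f"channel {name!r} has {len(profiles[name])} windows, expected {n}"
            )
    t = profiles[names[0]]["t_center"].to_numpy(dtype=float)

    cols, data = [], []
    for name in names:
        df = profiles[name]
        for feat in features:
            if feat not in df.columns:
                raise KeyError(f"channel {name!r} lacks feature {feat!r}")
            cols.append(f"{name}:{feat}")
            data.append(df[feat].to_numpy(dtype=float))
    X = np.column_stack(data)

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"dropping zero-variance feature columns: {dropped}", stacklevel=2)
    if not keep.any():
        raise ValueError("all feature columns have zero variance")
    Xz = (X[:, keep] - mu[keep]) / sd[keep]
    return FeatureStream(t=t, X=Xz, columns=[c for c, k in zip(cols, keep) if k])


def cluster_states(
    f: FeatureStream,
    k: int,
    n_init: int = 10,
    seed: int = DEFAULT_SEED,
) -> StateSequence:
    """k-means clustering of the feature stream.

    Standard Euclidean k-means with k-means++ seeding, best of ``n_init``
    restarts; states are renumbered by descending occupancy so label 0 is
    always the most visited state.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if f.n_windows < max(2, k):
        raise ValueError(f"need at least {max(2, k)} windows to fit k={k} states")
    for attempt in range(10):
        km = KMeans(
            n_clusters=k, n_init=n_init, random_state=seed + attempt, init="k-means++"
        ).fit(f.X)
        counts = np.bincount(km.labels_, minlength=k)
        if counts.min() > 0:
            break
    else:
        raise RuntimeError("k-means produced an empty cluster in 10 attempts")
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return StateSequence(
        labels=remap[km.labels_], k=k, centroids=km.cluster_centers_[order]
    )


def select_k(
    f: FeatureStream,
    k_range: range = range(2, 9),
    n_init: int = 10,
    seed: int = DEFAULT_SEED,
) -> int:
    """Silhouette-selected state count over ``k_range``."""
    best_k, best_score = None, -np.inf
    for k in k_range:
        if f.n_windows < 5 * k:
            continue
        s = cluster_states(f, k=k, n_init=n_init, seed=seed)
        score = silhouette_score(f.X, s.labels)
        if score > best_score:
            best_k, best_score = k, score
    if best_k is None:
        raise ValueError("too few windows for any k in range")
    return best_k


def estimate_transitions(
    s: StateSequence | np.ndarray,
    smoothing: float = 0.0,
    k: int | None = None,
) -> TransitionModel:
    """Count consecutive label pairs into a transition model.

    ``P = (counts + smoothing)`` row-normalized; the stationary
    distribution is the leading left eigenvector (power iteration as a
    fallback for defective cases).
    """
    labels = s.labels if isinstance(s, StateSequence) else np.asarray(s, dtype=int)
    if labels.size < 2:
        raise ValueError("need at least 2 windows to estimate transitions")
    if k is None:
        k = s.k if isinstance(s, StateSequence) else int(labels.max()) + 1
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")

    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (labels[:-1], labels[1:]), 1)

    row = counts.sum(axis=1).astype(float) + smoothing * k
    if np.any(row == 0):
        dead = np.flatnonzero(counts.sum(axis=1) == 0)
        raise ValueError(
            f"states {dead.tolist()} have no outgoing transitions; "
            "use smoothing > 0 to regularize"
        )
    P = (counts + smoothing) / row[:, None]
    pi = _stationary(P)
    return TransitionModel(P=P, counts=counts, pi=pi)


def _stationary(P: np.ndarray) -> np.ndarray:
    vals, vecs = eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    pi = pi / pi.sum()
    # refine by power iteration; also covers near-defective matrices
    for _ in range(10_000):
        nxt = pi @ P
        if np.max(np.abs(nxt - pi)) < 1e-14:
            pi = nxt
            break
        pi = nxt
    return pi / pi.sum()


def attractor_report(
    m: TransitionModel,
    s: StateSequence,
    top: int | None = None,
) -> pd.DataFrame:
    """Rank states by self-transition probability (attractor strength).

    Ties break by occupancy. Each state's centroid features are labeled
    low/medium/high by terciles of that feature's values across states.
    """
    occ = s.occupancy()
    order = sorted(range(m.k), key=lambda i: (-m.self_p[i], -occ[i]))
    if top is not None:
        order = order[:top]

    tercile_labels = np.empty((m.k, s.centroids.shape[1]), dtype=object)
    for j in range(s.centroids.shape[1]):
        col = s.centroids[:, j]
        lo, hi = np.quantile(col, [1 / 3, 2 / 3])
        for i in range(m.k):
            tercile_labels[i, j] = (
                "low" if col[i] <= lo else ("high" if col[i] > hi else "medium")
            )

    rows = []
    for rank, i in enumerate(order):
        row = {
            "rank": rank,
            "state": i,
            "self_p": float(m.self_p[i]),
            "occupancy": float(occ[i]),
            "pi": float(m.pi[i]),
        }
        # feature centroid values and qualitative levels
        for j in range(s.centroids.shape[1]):
            row[f"f{j}"] = float(s.centroids[i, j])
            row[f"f{j}_level"] = tercile_labels[i, j]
        rows.append(row)
    return pd.DataFrame(rows)
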