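"""Shared-component analysis of paired physiological channels.

PCA across simultaneously recorded dyad channels separates a *shared*
component — one on which the two subjects' corresponding channels load
with the same sign and non-trivial magnitude — from individual
components. The shared score can be summarized per session and regressed
on an outcome, or discretized into symbols for Markov analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from syncmap.embedding import SymbolSeries

__all__ = [
    "ComponentDecomposition",
    "decompose",
    "outcome_regression",
    "symbolize_component",
]

DEFAULT_LOADING_FLOOR = 0.3


@dataclass
class ComponentDecomposition:
    loadings: np.ndarray       # (channels, components)
    scores: np.ndarray         # (time, components)
    explained_var: np.ndarray  # fractions, non-increasing
    shared_idx: int | None
    channel_names: list[str]
    rank: int

    def reconstruct(self) -> np.ndarray:
        """Centered input reproduced from scores and loadings."""
        return self.scores @ self.loadings.T

    @property
    def shared_score(self) -> np.ndarray:
        if self.shared_idx is None:
            raise ValueError("no shared component was identified")
        return self.scores[:, self.shared_idx]


def decompose(
    X: np.ndarray,
    channel_names: list[str] | None = None,
    pairs: list[tuple[int, int]] | None = None,
    loading_floor: float = DEFAULT_LOADING_FLOOR,
    zscore: bool = True,
) -> ComponentDecomposition:
    """PCA of a (time, channels) matrix with shared-component tagging.

    Channels are z-scored by default so each contributes unit variance.
    ``pairs`` lists index pairs of corresponding channels across the two
    subjects (default: channel i of the first half pairs with channel i
    of the second half). The shared component is the first one whose
    loadings agree in sign and exceed ``loading_floor`` in magnitude on
    every pair; ``shared_idx`` is None when no component qualifies.
    Loadings beyond the numerical rank are flagged by ``rank``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a (time, channels) matrix with >= 2 channels")
    n, c = X.shape
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(c)]
    if pairs is None:
        if c % 2:
            raise ValueError("odd channel count: specify pairs explicitly")
        half = c // 2
        pairs = [(i, i + half) for i in range(half)]

    Xc = X - X.mean(axis=0)
    if zscore:
        sd = Xc.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("zero-variance channel cannot be z-scored")
        Xc = Xc / sd

    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * max(n, c) * np.finfo(float).eps)) if S.size else 0
    loadings = Vt.T                       # (channels, components), orthonormal
    scores = U * S                        # (time, components)
    var = S**2
    explained = var / var.sum() if var.sum() > 0 else var

    # deterministic sign: largest-magnitude loading positive per component
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    shared_idx = None
    for j in range(min(rank, loadings.shape[1])):
        ok = all(
            loadings[a, j] * loadings[b, j] > 0
            and abs(loadings[a, j]) >= loading_floor
            and abs(loadings[b, j]) >= loading_floor
            for a, b in pairs
        )
        if ok:
            shared_idx = j
            break

    return ComponentDecomposition(
        loadings=loadings,
        scores=scores,
        explained_var=explained,
        shared_idx=shared_idx,
        channel_names=list(channel_names),
        rank=rank,
    )


def outcome_regression(score: np.ndarray, outcome: np.ndarray) -> dict:
    """OLS of a per-session outcome on a per-session shared-score summary."""
    x = np.asarray(score, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.size != y.size:
        raise ValueError("predictor and outcome must pair up")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0:
        raise ValueError("zero-variance predictor")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "n": int(x.size),
    }


def symbolize_component(score: np.ndarray, m: int = 3) -> SymbolSeries:
    """Equal-frequency discretization of a score series into ``m`` symbols.

    Ties are broken by rank order (first occurrence gets the lower rank).
    A constant series is degenerate — every observation would land in one
    bin — and is rejected.
    """
    x = np.asarray(score, dtype=float)
    if m < 2:
        raise ValueError("need at least 2 bins")
    if x.size < m:
        raise ValueError(f"need at least {m} points for {m} bins")
    if np.ptp(x) == 0:
        raise ValueError("constant series cannot be meaningfully binned (degenerate)")
    ranks = stats.rankdata(x, method="ordinal") - 1  # 0..n-1, stable ties
    codes = (ranks * m // x.size).astype(np.int64)
    alphabet = {str(i): i for i in range(m)}
    return SymbolSeries(codes=codes, alphabet=alphabet)
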