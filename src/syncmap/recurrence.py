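"""Recurrence plots and quantification measures.

Auto- and cross-recurrence matrices for symbolic (exact match) and
continuous (radius threshold) embedded series, plus the standard
line-based quantifiers: recurrence rate (RR), determinism (DET),
diagonal line entropy (ENT, bits), longest diagonal (Lmax) and
laminarity (LAM). Formulas follow the Webber–Zbilut conventions with a
minimum line length ``lmin`` (default 2) and a Theiler band around the
line of identity for auto-recurrence (default width 1, i.e. the main
diagonal itself is excluded from all counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from syncmap.embedding import EmbeddedSeries, SymbolSeries, embed

__all__ = [
    "RecurrencePlot",
    "RQAProfile",
    "rp_symbolic",
    "rp_continuous",
    "rp_cross",
    "rqa_measures",
    "radius_for_target_rr",
    "cross_recurrence_rate",
    "permutation_null_cross_rr",
    "windowed_rqa",
    "rp_to_sparse_df",
]

DEFAULT_LMIN = 2
DEFAULT_THEILER = 1
DEFAULT_TARGET_RR = 0.05


@dataclass
class RecurrencePlot:
    """Binary (cross-)recurrence matrix."""

    matrix: np.ndarray
    kind: str  # "auto" | "cross"
    theiler_w: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.ndim != 2:
            raise ValueError("recurrence matrix must be 2-D")
        if self.kind not in ("auto", "cross"):
            raise ValueError("kind must be 'auto' or 'cross'")
        if self.kind == "auto" and self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("auto-recurrence matrix must be square")
        if self.theiler_w < 0:
            raise ValueError("theiler_w must be >= 0")


@dataclass
class RQAProfile:
    """Scalar recurrence quantifiers of one plot (or one window)."""

    RR: float
    DET: float
    ENT: float
    Lmax: int
    LAM: float
    n_points: int
    degenerate: bool = field(default=False)

    def as_dict(self) -> dict[str, float]:
        return {
            "RR": self.RR,
            "DET": self.DET,
            "ENT": self.ENT,
            "Lmax": float(self.Lmax),
            "LAM": self.LAM,
        }


def _as_embedded(e) -> EmbeddedSeries:
    if isinstance(e, EmbeddedSeries):
        return e
    raise TypeError("expected an EmbeddedSeries (use syncmap.embedding.embed)")


def rp_symbolic(e: EmbeddedSeries, theiler_w: int = DEFAULT_THEILER) -> RecurrencePlot:
    """Auto-recurrence of a symbolic embedding: exact row identity."""
    e = _as_embedded(e)
    keys = _row_keys(e.rows)
    m = keys[:, None] == keys[None, :]
    return RecurrencePlot(matrix=m, kind="auto", theiler_w=theiler_w)


def rp_continuous(
    e: EmbeddedSeries,
    radius: float,
    norm: str = "euclidean",
    theiler_w: int = DEFAULT_THEILER,
) -> RecurrencePlot:
    """Auto-recurrence of a real-valued embedding under a distance radius."""
    e = _as_embedded(e)
    if radius <= 0:
        raise ValueError("radius must be > 0")
    rows = np.asarray(e.rows, dtype=float)
    if not np.all(np.isfinite(rows)):
        raise ValueError("embedding contains non-finite values")
    d = cdist(rows, rows, metric=norm)
    return RecurrencePlot(matrix=d <= radius, kind="auto", theiler_w=theiler_w)


def rp_cross(
    ea: EmbeddedSeries,
    eb: EmbeddedSeries,
    radius: float | None = None,
    norm: str = "euclidean",
) -> RecurrencePlot:
    """Cross-recurrence between two embeddings.

    Exact row identity when ``radius`` is None (symbolic data), distance
    threshold otherwise. Both embeddings must share ``p`` and ``lag``.
    """
    ea, eb = _as_embedded(ea), _as_embedded(eb)
    if ea.p != eb.p or ea.lag != eb.lag:
        raise ValueError(
            f"embedding parameters differ: (p={ea.p}, lag={ea.lag}) vs "
            f"(p={eb.p}, lag={eb.lag})"
        )
    if radius is None:
        ka, kb = _row_keys(ea.rows), _row_keys(eb.rows)
        m = ka[:, None] == kb[None, :]
    else:
        if radius <= 0:
            raise ValueError("radius must be > 0")
        a = np.asarray(ea.rows, dtype=float)
        b = np.asarray(eb.rows, dtype=float)
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("embedding contains non-finite values")
        m = cdist(a, b, metric=norm) <= radius
    return RecurrencePlot(matrix=m, kind="cross")


def _row_keys(rows: np.ndarray) -> np.ndarray:
    """Hash integer embedding rows to single comparable keys.

    Falls back to a structured-view comparison key for non-integer data.
    """
    rows = np.asarray(rows)
    if not np.issubdtype(rows.dtype, np.integer):
        raise ValueError("symbolic recurrence requires integer-coded rows")
    base = int(rows.max()) + 1 if rows.size else 1
    p = rows.shape[1]
    if base**p < 2**62:
        weights = base ** np.arange(p, dtype=np.int64)
        return rows.astype(np.int64) @ weights
    # rare: huge alphabets — use void view
    c = np.ascontiguousarray(rows)
    return c.view([("", c.dtype)] * p).ravel()


def _valid_mask(rp: RecurrencePlot) -> np.ndarray:
    n, m = rp.matrix.shape
    if rp.kind == "cross" or rp.theiler_w == 0:
        return np.ones((n, m), dtype=bool)
    i, j = np.indices((n, m), sparse=True)
    return np.abs(i - j) >= rp.theiler_w


def _diag_offsets(rp: RecurrencePlot):
    n, m = rp.matrix.shape
    lo, hi = -(n - 1), m - 1
    excl = rp.theiler_w if rp.kind == "auto" else 0
    for off in range(lo, hi + 1):
        if rp.kind == "auto" and abs(off) < excl:
            continue
        yield off


def _run_lengths(line: np.ndarray) -> np.ndarray:
    """Lengths of runs of True in a 1-D boolean array."""
    if line.size == 0 or not line.any():
        return np.empty(0, dtype=np.int64)
    padded = np.empty(line.size + 2, dtype=bool)
    padded[0] = padded[-1] = False
    padded[1:-1] = line
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def rqa_measures(rp: RecurrencePlot, lmin: int = DEFAULT_LMIN) -> RQAProfile:
    """Compute RR, DET, ENT, Lmax and LAM of one recurrence plot.

    For auto plots the Theiler band (|i-j| < theiler_w) is excluded from
    every count: the denominator of RR, the diagonal histogram, and the
    vertical-line scan. With zero recurrent points the profile is flagged
    ``degenerate`` and the line measures report 0.
    """
    if lmin < 2:
        raise ValueError("lmin must be >= 2")
    valid = _valid_mask(rp)
    rec = rp.matrix & valid
    total = int(valid.sum())
    n_rec = int(rec.sum())
    rr = n_rec / total if total else 0.0
    if n_rec == 0:
        return RQAProfile(RR=0.0, DET=0.0, ENT=0.0, Lmax=0, LAM=0.0, n_points=0,
                          degenerate=True)

    # diagonal line histogram (Theiler-excluded offsets for auto)
    lengths = []
    lmax_all = 0
    for off in _diag_offsets(rp):
        runs = _run_lengths(np.diagonal(rec, offset=off))
        if runs.size:
            lengths.append(runs)
            lmax_all = max(lmax_all, int(runs.max()))
    lengths = np.concatenate(lengths) if lengths else np.empty(0, dtype=np.int64)
    long_lines = lengths[lengths >= lmin]
    det = float(long_lines.sum()) / n_rec if n_rec else 0.0

    if long_lines.size:
        _, counts = np.unique(long_lines, return_counts=True)
        probs = counts / counts.sum()
        ent = float(-(probs * np.log2(probs)).sum()) + 0.0  # avoid -0.0
    else:
        ent = 0.0

    # vertical lines on the masked matrix
    v_lengths = []
    for col in range(rec.shape[1]):
        runs = _run_lengths(rec[:, col])
        if runs.size:
            v_lengths.append(runs)
    v_lengths = np.concatenate(v_lengths) if v_lengths else np.empty(0, dtype=np.int64)
    lam = float(v_lengths[v_lengths >= lmin].sum()) / n_rec if n_rec else 0.0

    return RQAProfile(RR=rr, DET=det, ENT=ent, Lmax=lmax_all, LAM=lam,
                      n_points=n_rec)


def radius_for_target_rr(
    e: EmbeddedSeries,
    target_rr: float = DEFAULT_TARGET_RR,
    norm: str = "euclidean",
    theiler_w: int = DEFAULT_THEILER,
) -> float:
    """Distance radius whose auto-RP hits approximately the target RR.

    Chosen as the ``target_rr`` quantile of the pairwise distances outside
    the Theiler band; makes windows of nonstationary data comparable.
    """
    if not 0 < target_rr < 1:
        raise ValueError("target_rr must be in (0, 1)")
    rows = np.asarray(e.rows, dtype=float)
    n = rows.shape[0]
    if theiler_w <= 1:
        d = pdist(rows, metric=norm)
    else:
        dm = cdist(rows, rows, metric=norm)
        i, j = np.triu_indices(n, k=theiler_w)
        d = dm[i, j]
    if d.size == 0:
        raise ValueError("not enough points to choose a radius")
    r = float(np.quantile(d, target_rr))
    return r if r > 0 else float(np.min(d[d > 0], initial=1e-12))


def cross_recurrence_rate(
    a: SymbolSeries | np.ndarray,
    b: SymbolSeries | np.ndarray,
    p: int = 3,
    lag: int = 1,
) -> float:
    """Cross-RR of two symbol streams without materializing the matrix.

    For exact matching the cross-recurrence count is the sum over state
    types of the product of their occurrence counts in each stream, so the
    rate follows from two histograms in O(n) instead of O(n_a * n_b).
    """
    ea, eb = embed(a, p=p, lag=lag), embed(b, p=p, lag=lag)
    ka, kb = _row_keys(ea.rows), _row_keys(eb.rows)
    allk, inv = np.unique(np.concatenate([ka, kb]), return_inverse=True)
    ca = np.bincount(inv[: ka.size], minlength=allk.size)
    cb = np.bincount(inv[ka.size :], minlength=allk.size)
    return float((ca * cb).sum()) / (ka.size * kb.size)


def permutation_null_cross_rr(
    a: SymbolSeries,
    b: SymbolSeries,
    p: int = 3,
    lag: int = 1,
    n_shuffles: int = 200,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """Observed cross-RR and its shuffle-null distribution.

    The second stream's symbols are permuted (destroying sequential
    structure while keeping the marginal symbol frequencies) and the
    cross-RR recomputed for each shuffle.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    observed = cross_recurrence_rate(a, b, p=p, lag=lag)
    codes_b = b.codes.copy()
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(codes_b)
        null[s] = cross_recurrence_rate(
            a, SymbolSeries(codes=perm, alphabet=b.alphabet), p=p, lag=lag
        )
    return observed, null


def windowed_rqa(
    series,
    window: int,
    step: int,
    mode: str = "symbolic",
    p: int = 3,
    lag: int = 1,
    lmin: int = DEFAULT_LMIN,
    theiler_w: int = DEFAULT_THEILER,
    radius: float | None = None,
    target_rr: float = DEFAULT_TARGET_RR,
    t0: float = 0.0,
    dt: float = 1.0,
) -> pd.DataFrame:
    """Sliding-window RQA of one channel.

    ``series`` is a :class:`SymbolSeries` (mode ``"symbolic"``) or a 1-D
    real array (mode ``"continuous"``). Windows are ``window`` samples
    long, advanced by ``step``; each yields one profile timestamped at the
    window center (``t0 + dt * center_index``). In continuous mode the
    radius is re-chosen per window to hit ``target_rr`` unless ``radius``
    is fixed. Windows too short to embed are skipped with a warning.
    """
    if mode not in ("symbolic", "continuous"):
        raise ValueError("mode must be 'symbolic' or 'continuous'")
    x = series.codes if isinstance(series, SymbolSeries) else np.asarray(series)
    if step < 1:
        raise ValueError("step must be >= 1")
    min_len = (p - 1) * lag + 1
    if window < min_len:
        raise ValueError(f"window {window} shorter than minimum embeddable length {min_len}")

    records = []
    start = 0
    n = x.size
    while start + window <= n:
        seg = x[start : start + window]
        e = embed(seg, p=p, lag=lag)
        if mode == "symbolic":
            rp = rp_symbolic(e, theiler_w=theiler_w)
        else:
            r = radius if radius is not None else radius_for_target_rr(
                e, target_rr=target_rr, theiler_w=theiler_w
            )
            rp = rp_continuous(e, radius=r, theiler_w=theiler_w)
        prof = rqa_measures(rp, lmin=lmin)
        center = start + (window - 1) / 2
        records.append({"t_center": t0 + dt * center, **prof.as_dict()})
        start += step
    if not records:
        raise ValueError(
            f"no complete window of {window} samples fits a series of length {n}"
        )
    leftover = n - (start - step + window)
    if leftover >= min_len:
        warnings.warn(
            f"{leftover} trailing samples do not fill a window and were skipped",
            stacklevel=2,
        )
    return pd.DataFrame.from_records(records)


def rp_to_sparse_df(rp: RecurrencePlot) -> pd.DataFrame:
    """Export a plot as 0-based sparse (i, j) coordinates."""
    i, j = np.nonzero(rp.matrix)
    return pd.DataFrame({"i": i, "j": j})
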