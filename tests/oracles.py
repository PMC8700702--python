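"""Independent brute-force reference implementations for RQA measures.

Pure-Python double loops, deliberately sharing no code path with the
package: recurrence matrices are built cell by cell and line histograms
by walking every diagonal/column with an explicit run counter.
"""

from __future__ import annotations

import math
from collections import Counter


def brute_symbolic_matrix(rows_a, rows_b=None):
    """Cell-by-cell exact-match recurrence matrix (lists of tuples)."""
    rows_a = [tuple(r) for r in rows_a]
    rows_b = rows_a if rows_b is None else [tuple(r) for r in rows_b]
    return [[1 if ra == rb else 0 for rb in rows_b] for ra in rows_a]


def brute_continuous_matrix(rows_a, radius, rows_b=None):
    """Cell-by-cell Euclidean-threshold recurrence matrix."""
    rows_a = [list(map(float, r)) for r in rows_a]
    rows_b = rows_a if rows_b is None else [list(map(float, r)) for r in rows_b]
    out = []
    for ra in rows_a:
        line = []
        for rb in rows_b:
            d = math.sqrt(sum((x - y) ** 2 for x, y in zip(ra, rb)))
            line.append(1 if d <= radius else 0)
        out.append(line)
    return out


def brute_rqa(matrix, kind="auto", theiler_w=1, lmin=2):
    """RR/DET/ENT/Lmax/LAM by explicit scanning.

    Returns a dict; all counts honor the Theiler band for auto plots
    exactly as the package contract states.
    """
    n = len(matrix)
    m = len(matrix[0])
    excl = theiler_w if kind == "auto" else 0

    def valid(i, j):
        return kind == "cross" or abs(i - j) >= excl

    total = sum(1 for i in range(n) for j in range(m) if valid(i, j))
    n_rec = sum(
        1 for i in range(n) for j in range(m) if valid(i, j) and matrix[i][j]
    )
    rr = n_rec / total if total else 0.0
    if n_rec == 0:
        return {"RR": 0.0, "DET": 0.0, "ENT": 0.0, "Lmax": 0.0, "LAM": 0.0}

    # diagonal lines
    lengths = []
    lmax = 0
    for off in range(-(n - 1), m):
        if kind == "auto" and abs(off) < excl:
            continue
        run = 0
        i0 = max(0, -off)
        for i in range(i0, n):
            j = i + off
            if j < 0 or j >= m:
                break
            if matrix[i][j] and valid(i, j):
                run += 1
            else:
                if run:
                    lengths.append(run)
                    lmax = max(lmax, run)
                run = 0
        if run:
            lengths.append(run)
            lmax = max(lmax, run)

    long_pts = sum(l for l in lengths if l >= lmin)
    det = long_pts / n_rec

    hist = Counter(l for l in lengths if l >= lmin)
    tot = sum(hist.values())
    ent = 0.0
    for c in hist.values():
        p = c / tot
        ent -= p * math.log2(p)

    # vertical lines
    v_lengths = []
    for j in range(m):
        run = 0
        for i in range(n):
            if matrix[i][j] and valid(i, j):
                run += 1
            else:
                if run:
                    v_lengths.append(run)
                run = 0
        if run:
            v_lengths.append(run)
    lam = sum(l for l in v_lengths if l >= lmin) / n_rec

    return {"RR": rr, "DET": det, "ENT": ent, "Lmax": float(lmax), "LAM": lam}


def brute_cross_rr(codes_a, codes_b, p=3, lag=1):
    """Cross recurrence rate of two symbol streams by direct comparison."""
    rows_a = [tuple(codes_a[i + k * lag] for k in range(p))
              for i in range(len(codes_a) - (p - 1) * lag)]
    rows_b = [tuple(codes_b[i + k * lag] for k in range(p))
              for i in range(len(codes_b) - (p - 1) * lag)]
    hits = sum(1 for ra in rows_a for rb in rows_b if ra == rb)
    return hits / (len(rows_a) * len(rows_b))
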