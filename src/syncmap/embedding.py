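"""Orthographic cleaning and lagged embedding of symbol streams.

Text is folded to a fixed alphabet (lowercase a-z plus space by default)
and coded as integers; the embedding stacks ``p`` lagged copies of the
coded stream so each row is one ``p``-symbol state vector. The default
``p=3`` window makes the state a letter trigram — a mesoscopic unit
between single characters and whole words.
"""

from __future__ import annotations

import string
import unicodedata
from dataclasses import dataclass

import numpy as np

__all__ = ["SymbolSeries", "EmbeddedSeries", "clean_text", "embed", "DEFAULT_ALPHABET"]

DEFAULT_ALPHABET = string.ascii_lowercase + " "


@dataclass
class SymbolSeries:
    """Integer-coded symbol stream with its alphabet map."""

    codes: np.ndarray
    alphabet: dict[str, int]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.size < 1:
            raise ValueError("symbol series must be non-empty")
        if self.codes.min() < 0 or self.codes.max() >= len(self.alphabet):
            raise ValueError("codes out of alphabet range")

    @property
    def n(self) -> int:
        return int(self.codes.size)

    def decode(self) -> str:
        """Inverse-map codes back to their symbols (for audit export)."""
        inv = {c: s for s, c in self.alphabet.items()}
        return "".join(inv[int(c)] for c in self.codes)


@dataclass
class EmbeddedSeries:
    """Lagged embedding matrix: row i = codes[i], codes[i+lag], ..."""

    rows: np.ndarray
    p: int
    lag: int

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows)
        if self.rows.ndim != 2 or self.rows.shape[1] != self.p:
            raise ValueError("rows must be 2-D with p columns")
        if self.rows.shape[0] < 1:
            raise ValueError("embedding has no rows")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")

    @property
    def n_rows(self) -> int:
        return int(self.rows.shape[0])


def _fold(ch: str) -> str:
    """Strip combining marks so accented letters fold to ASCII."""
    return "".join(
        c for c in unicodedata.normalize("NFKD", ch) if not unicodedata.combining(c)
    )


def clean_text(
    text_or_doc,
    alphabet: str = DEFAULT_ALPHABET,
    keep_space: bool = True,
) -> SymbolSeries:
    """Lower-case, fold diacritics, drop out-of-alphabet characters and
    collapse whitespace runs to single spaces.

    Raises ``ValueError`` when nothing survives cleaning.
    """
    text = getattr(text_or_doc, "raw_text", text_or_doc)
    if not text:
        raise ValueError("empty text")
    if not keep_space:
        alphabet = alphabet.replace(" ", "")
    amap = {s: i for i, s in enumerate(alphabet)}

    folded = _fold(text.lower())
    out: list[int] = []
    space_code = amap.get(" ")
    for ch in folded:
        if ch.isspace():
            ch = " "
        code = amap.get(ch)
        if code is None:
            continue
        if code == space_code and out and out[-1] == space_code:
            continue  # collapse space runs
        out.append(code)
    # trim leading/trailing space
    if space_code is not None:
        while out and out[0] == space_code:
            out.pop(0)
        while out and out[-1] == space_code:
            out.pop()
    if not out:
        raise ValueError("no symbols survive cleaning")
    return SymbolSeries(codes=np.array(out, dtype=np.int64), alphabet=amap)


def embed(s, p: int = 3, lag: int = 1) -> EmbeddedSeries:
    """Build the lagged embedding matrix of a 1-D series.

    Accepts a :class:`SymbolSeries` or any 1-D array (real-valued series
    embed the same way). Row count is ``n - (p - 1) * lag``.
    """
    x = s.codes if isinstance(s, SymbolSeries) else np.asarray(s)
    if x.ndim != 1:
        raise ValueError("input must be 1-D")
    if p < 1:
        raise ValueError("embedding dimension p must be >= 1")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    n = x.size
    min_n = (p - 1) * lag + 1
    if n < min_n:
        raise ValueError(
            f"series of length {n} too short to embed with p={p}, lag={lag}; "
            f"minimum length is {min_n}"
        )
    n_rows = n - (p - 1) * lag
    idx = np.arange(n_rows)[:, None] + lag * np.arange(p)[None, :]
    return EmbeddedSeries(rows=x[idx], p=p, lag=lag)
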