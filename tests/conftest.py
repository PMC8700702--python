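import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from syncmap.embedding import DEFAULT_ALPHABET, SymbolSeries


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_symbols(text: str) -> SymbolSeries:
    """Build a SymbolSeries directly from already-clean text."""
    amap = {s: i for i, s in enumerate(DEFAULT_ALPHABET)}
    return SymbolSeries(codes=np.array([amap[c] for c in text]), alphabet=amap)


def random_symbols(rng, n: int, n_symbols: int = 27) -> SymbolSeries:
    amap = {s: i for i, s in enumerate(DEFAULT_ALPHABET[:n_symbols])}
    return SymbolSeries(codes=rng.integers(0, n_symbols, size=n), alphabet=amap)


@pytest.fixture
def tiny_dyad_dir(tmp_path):
    """A small on-disk synthetic dyad for IO/CLI tests."""
    from syncmap.synthetic import DyadSpec, generate_dyad, write_dyad

    spec = DyadSpec(n_windows=30, seed=7)
    paths = write_dyad(generate_dyad(spec), tmp_path / "dyad")
    return paths
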