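"""Synthetic dyads with known ground truth.

Generates a two-person "session": two letter streams seeded with shared
recurring trigram motifs, two GSR-like series (AR(1) tonic drift plus
exponentially decaying phasic bursts), and a hidden two-regime Markov
process that switches both the motif density/echo probability and the
burst rate/shared-burst fraction. Every generator is a pure function of
(spec, seed), so the full pipeline can be validated end-to-end against
the planted regime labels.
"""

from __future__ import annotations

import json
import string
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from syncmap.embedding import clean_text
from syncmap.io_ingest import PhysioSeries, write_physio

__all__ = ["DyadSpec", "gen_regimes", "gen_speech_pair", "gen_gsr_pair",
           "generate_dyad", "write_dyad"]

_LETTERS = string.ascii_lowercase


@dataclass
class DyadSpec:
    """Ground-truth parameters of a synthetic dyad session."""

    n_windows: int = 200
    window_symbols: int = 300
    window_seconds: float = 60.0
    gsr_rate_hz: float = 4.0
    regime_P: tuple = ((0.9, 0.1), (0.15, 0.85))
    #: per-regime probability that a motif uttered by A is echoed by B
    motif_coupling: tuple = (0.05, 0.6)
    #: per-regime expected motif emissions by speaker A per window
    motif_rate: tuple = (2.0, 16.0)
    motif_bank: tuple = ("aba", "tik", "son", "rem")
    #: per-regime fraction of burst arrivals shared by both subjects
    gsr_shared_frac: tuple = (0.1, 0.9)
    #: per-regime phasic burst arrival rate (events per second)
    gsr_burst_rate: tuple = (0.02, 0.2)
    ar_coeff: float = 0.95
    ar_sd: float = 0.02
    burst_amp: float = 0.6
    burst_tau: float = 2.0
    noise_sd: float = 0.02
    seed: int = 20211125

    def __post_init__(self) -> None:
        P = np.asarray(self.regime_P, dtype=float)
        if P.shape != (2, 2) or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("regime_P must be a 2x2 row-stochastic matrix")
        for c in self.motif_coupling:
            if not 0 <= c <= 1:
                raise ValueError("motif coupling must be in [0, 1]")
        if not -1 < self.ar_coeff < 1:
            raise ValueError("AR(1) coefficient must be in (-1, 1)")
        if any(len(m) != 3 for m in self.motif_bank):
            raise ValueError("motifs must be 3 letters long")


def gen_regimes(spec: DyadSpec, seed: int | None = None) -> np.ndarray:
    """Sample the hidden regime label per window (Markov chain, start 0)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    P = np.asarray(spec.regime_P, dtype=float)
    labels = np.empty(spec.n_windows, dtype=int)
    state = 0
    for w in range(spec.n_windows):
        labels[w] = state
        state = int(rng.random() >= P[state, 0])
    return labels


_BLOCK = 6  # implant slot width: a 3-letter motif doubled


def _implant(window: np.ndarray, motifs: list[str], rng: np.random.Generator) -> None:
    """Overwrite non-overlapping 6-char slots with doubled motifs.

    Doubling makes two occurrences of the same motif share a run of
    consecutive identical trigram states, which is what produces diagonal
    (DET) lines rather than isolated recurrence points.
    """
    n_slots = window.size // _BLOCK
    use = min(len(motifs), n_slots)
    slots = rng.choice(n_slots, size=use, replace=False)
    for slot, motif in zip(slots, motifs[:use]):
        block = motif + motif
        codes = [_LETTERS.index(c) for c in block]
        window[slot * _BLOCK : slot * _BLOCK + _BLOCK] = codes


def gen_speech_pair(
    spec: DyadSpec, regimes: np.ndarray, seed: int | None = None
) -> tuple[str, str]:
    """Two coupled letter streams (speaker A and B) as raw text.

    Background letters are i.i.d.; per window speaker A implants
    Poisson-many doubled motifs from the bank, each of which is echoed
    into B's window with the regime's coupling probability. B utters no
    motifs of its own: at zero coupling B's stream is exchangeable, so
    the cross-recurrence symbol-permutation null is exact — and the
    asymmetry mirrors a leading/entraining speaker versus a partner
    whose stream carries only echoed patterns. Windows are exactly
    ``window_symbols`` characters so downstream windowing aligns with the
    planted regimes.
    """
    rng = np.random.default_rng(
        (spec.seed if seed is None else seed) + 1_000_003
    )
    bank = list(spec.motif_bank)
    out_a, out_b = [], []
    for w, r in enumerate(regimes):
        rate = spec.motif_rate[r]
        couple = spec.motif_coupling[r]
        win_a = rng.integers(0, 26, size=spec.window_symbols)
        win_b = rng.integers(0, 26, size=spec.window_symbols)

        n_a = rng.poisson(rate)
        motifs_a = [bank[i] for i in rng.integers(0, len(bank), size=n_a)]
        # echo coupling: A's motifs resound in B's stream
        motifs_b = [m for m in motifs_a if rng.random() < couple]
        _implant(win_a, motifs_a, rng)
        _implant(win_b, motifs_b, rng)

        out_a.append("".join(_LETTERS[i] for i in win_a))
        out_b.append("".join(_LETTERS[i] for i in win_b))
    return "".join(out_a), "".join(out_b)


def _burst_train(
    n: int, rate_hz: float, arrivals: np.ndarray, amps: np.ndarray, tau: float
) -> np.ndarray:
    impulses = np.zeros(n)
    idx = arrivals[arrivals < n]
    np.add.at(impulses, idx, amps[: idx.size] if amps.size else amps)
    decay = np.exp(-1.0 / (tau * rate_hz))
    return lfilter([1.0], [1.0, -decay], impulses)


def gen_gsr_pair(
    spec: DyadSpec, regimes: np.ndarray, seed: int | None = None
) -> tuple[PhysioSeries, PhysioSeries]:
    """Two GSR-like series with regime-switched burst coupling.

    Each subject is tonic AR(1) drift plus phasic bursts (Poisson
    arrivals, exponential decay). A shared arrival stream drives both
    subjects; its per-regime fraction sets the cross-correlation level.
    """
    rng = np.random.default_rng(
        (spec.seed if seed is None else seed) + 2_000_039
    )
    rate = spec.gsr_rate_hz
    n_per_w = int(round(spec.window_seconds * rate))
    n = spec.n_windows * n_per_w
    t = np.arange(n) / rate

    # regime-dependent arrival streams
    shared_idx, shared_amp = [], []
    ind_idx = ([], [])
    ind_amp = ([], [])
    for w, r in enumerate(regimes):
        lam = spec.gsr_burst_rate[r] * spec.window_seconds
        f = spec.gsr_shared_frac[r]
        base = w * n_per_w
        for count, sink_i, sink_a in (
            (rng.poisson(lam * f), shared_idx, shared_amp),
            (rng.poisson(lam * (1 - f)), ind_idx[0], ind_amp[0]),
            (rng.poisson(lam * (1 - f)), ind_idx[1], ind_amp[1]),
        ):
            if count:
                sink_i.extend(base + rng.integers(0, n_per_w, size=count))
                sink_a.extend(spec.burst_amp * rng.exponential(1.0, size=count))

    shared = _burst_train(
        n, rate, np.asarray(shared_idx, dtype=int),
        np.asarray(shared_amp, dtype=float), spec.burst_tau,
    )

    series = []
    for subj, sid in enumerate(("a", "b")):
        own = _burst_train(
            n, rate, np.asarray(ind_idx[subj], dtype=int),
            np.asarray(ind_amp[subj], dtype=float), spec.burst_tau,
        )
        tonic = lfilter([1.0], [1.0, -spec.ar_coeff],
                        rng.normal(0, spec.ar_sd, size=n))
        v = tonic + shared + own + rng.normal(0, spec.noise_sd, size=n)
        series.append(PhysioSeries(subject_id=f"subject_{sid}", t=t.copy(), v=v))
    return series[0], series[1]


def generate_dyad(spec: DyadSpec, seed: int | None = None) -> dict:
    """Full synthetic session: regimes, texts, symbol series, GSR pair."""
    base = spec.seed if seed is None else seed
    regimes = gen_regimes(spec, seed=base)
    text_a, text_b = gen_speech_pair(spec, regimes, seed=base)
    gsr_a, gsr_b = gen_gsr_pair(spec, regimes, seed=base)
    return {
        "spec": spec,
        "seed": base,
        "regimes": regimes,
        "text_a": text_a,
        "text_b": text_b,
        "symbols_a": clean_text(text_a),
        "symbols_b": clean_text(text_b),
        "gsr_a": gsr_a,
        "gsr_b": gsr_b,
    }


def write_dyad(dyad: dict, outdir: str | Path) -> dict[str, str]:
    """Write a generated dyad in the pipeline's input formats.

    Produces speaker_a.txt, speaker_b.txt, gsr_a.csv, gsr_b.csv and
    ground_truth.json; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "text_a": outdir / "speaker_a.txt",
        "text_b": outdir / "speaker_b.txt",
        "gsr_a": outdir / "gsr_a.csv",
        "gsr_b": outdir / "gsr_b.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    paths["text_a"].write_text(dyad["text_a"], encoding="utf-8")
    paths["text_b"].write_text(dyad["text_b"], encoding="utf-8")
    write_physio(dyad["gsr_a"], paths["gsr_a"])
    write_physio(dyad["gsr_b"], paths["gsr_b"])
    truth = {
        "seed": dyad["seed"],
        "regimes": dyad["regimes"].tolist(),
        "spec": asdict(dyad["spec"]),
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=2), encoding="utf-8")
    return {k: str(v) for k, v in paths.items()}
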