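"""End-to-end dyad analysis: channels -> windowed RQA -> states -> transitions.

The staged functions here are pure (inputs in, artifacts out) so they can
run either from the CLI on files or in-memory on synthetic dyads.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from syncmap.config import RunConfig, config_hash
from syncmap.embedding import SymbolSeries, clean_text
from syncmap.io_ingest import PhysioSeries, read_physio, read_transcript
from syncmap.recurrence import windowed_rqa
from syncmap.state_dynamics import (
    FeatureStream,
    assemble_features,
    attractor_report,
    cluster_states,
    estimate_transitions,
    select_k,
)

__all__ = ["dyad_features", "analyze_features", "run_pipeline"]

log = logging.getLogger("syncmap")


def dyad_features(
    symbols_a: SymbolSeries,
    symbols_b: SymbolSeries,
    gsr_a: PhysioSeries,
    gsr_b: PhysioSeries,
    cfg: RunConfig,
) -> FeatureStream:
    """Windowed RQA of the four dyad channels on one window grid.

    Speech channels are windowed in symbols, physiology in seconds; all
    four profiles are truncated to the shortest channel so every window
    row spans the same stretch of the session.
    """
    rate = gsr_a.rate_hz
    n_per_w = int(round(cfg.window_seconds * rate))
    step_w = int(round(cfg.step_seconds * rate))
    profiles = {
        "speech_a": windowed_rqa(
            symbols_a, cfg.window_symbols, cfg.step_symbols, mode="symbolic",
            p=cfg.p, lag=cfg.lag, lmin=cfg.lmin, theiler_w=cfg.theiler_w,
        ),
        "speech_b": windowed_rqa(
            symbols_b, cfg.window_symbols, cfg.step_symbols, mode="symbolic",
            p=cfg.p, lag=cfg.lag, lmin=cfg.lmin, theiler_w=cfg.theiler_w,
        ),
        "gsr_a": windowed_rqa(
            gsr_a.v, n_per_w, step_w, mode="continuous",
            p=cfg.p, lag=cfg.lag, lmin=cfg.lmin, theiler_w=cfg.theiler_w,
            radius=cfg.radius, target_rr=cfg.target_rr,
            t0=float(gsr_a.t[0]), dt=1.0 / rate,
        ),
        "gsr_b": windowed_rqa(
            gsr_b.v, n_per_w, step_w, mode="continuous",
            p=cfg.p, lag=cfg.lag, lmin=cfg.lmin, theiler_w=cfg.theiler_w,
            radius=cfg.radius, target_rr=cfg.target_rr,
            t0=float(gsr_b.t[0]), dt=1.0 / rate,
        ),
    }
    n_min = min(len(df) for df in profiles.values())
    profiles = {k: df.iloc[:n_min].reset_index(drop=True) for k, df in profiles.items()}
    return assemble_features(profiles, features=cfg.features)


def analyze_features(f: FeatureStream, cfg: RunConfig) -> dict:
    """Cluster windows into states and estimate the transition model."""
    k = select_k(f, seed=cfg.seed, n_init=cfg.n_init) if cfg.k == "auto" else int(cfg.k)
    states = cluster_states(f, k=k, n_init=cfg.n_init, seed=cfg.seed)
    model = estimate_transitions(states, smoothing=cfg.smoothing)
    report = attractor_report(model, states)
    return {"k": k, "states": states, "model": model, "report": report}


def run_pipeline(
    transcript_a: str | Path,
    transcript_b: str | Path,
    gsr_a: str | Path,
    gsr_b: str | Path,
    outdir: str | Path,
    cfg: RunConfig | None = None,
) -> dict:
    """File-to-file pipeline producing the standard artifact set.

    Writes features.csv, states.csv, transitions.json, attractors.csv and
    report.md (with stage timings and the config hash) into ``outdir``.
    """
    cfg = cfg or RunConfig()
    chash = config_hash(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: list[tuple[str, float]] = []

    def _stage(name):
        t0 = time.perf_counter()

        def done():
            dt = time.perf_counter() - t0
            timings.append((name, dt))
            log.info("stage=%s elapsed=%.2fs seed=%d", name, dt, cfg.seed)

        return done

    done = _stage("ingest")
    try:
        doc_a = read_transcript(transcript_a)
        doc_b = read_transcript(transcript_b)
        sa = clean_text(doc_a, keep_space=cfg.keep_space)
        sb = clean_text(doc_b, keep_space=cfg.keep_space)
        ga = read_physio(gsr_a, max_gap_s=cfg.max_gap_s)
        gb = read_physio(gsr_b, max_gap_s=cfg.max_gap_s)
    except Exception as exc:
        raise RuntimeError(f"stage 'ingest' failed: {exc}; check input paths/formats") from exc
    done()

    done = _stage("features")
    try:
        f = dyad_features(sa, sb, ga, gb, cfg)
    except Exception as exc:
        raise RuntimeError(
            f"stage 'features' failed: {exc}; check window sizes against session length"
        ) from exc
    done()

    done = _stage("states")
    try:
        res = analyze_features(f, cfg)
    except Exception as exc:
        raise RuntimeError(f"stage 'states' failed: {exc}; try smaller k or more windows") from exc
    done()

    states, model, report = res["states"], res["model"], res["report"]

    feat = pd.DataFrame(f.X, columns=f.columns)
    feat.insert(0, "t_center", f.t)
    feat.to_csv(outdir / "features.csv", index=False, float_format="%.10f")
    pd.DataFrame({"t_center": f.t, "label": states.labels}).to_csv(
        outdir / "states.csv", index=False, float_format="%.10f"
    )
    attractors = report[report["self_p"] > 0.5]["state"].tolist()
    payload = {
        **model.as_dict(),
        "attractors": attractors,
        "config_hash": chash,
        "seed": cfg.seed,
    }
    (outdir / "transitions.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8"
    )
    report.to_csv(outdir / "attractors.csv", index=False, float_format="%.10f")

    lines = [
        "# syncmap session report",
        "",
        f"- config hash: `{chash}`",
        f"- seed: {cfg.seed}",
        f"- windows: {f.n_windows}, features: {len(f.columns)}, states: {res['k']}",
        "",
        "## Stage timings",
        "",
    ]
    lines += [f"- {name}: {dt:.2f}s" for name, dt in timings]
    lines += ["", "## Attractor ranking", "", report.to_string(index=False)]
    (outdir / "report.md").write_text("\n".join(lines) + "\n", encoding="utf-8")

    return {"outdir": str(outdir), "config_hash": chash, **res, "features": f}
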