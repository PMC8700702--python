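# syncmap

Synchronization mapping of dyadic human interaction. The package turns a
two-person session — two speech transcripts plus two physiological (GSR-like)
series — into a discrete state-space model of the dyad:

1. **Symbolic embedding** (`syncmap.embedding`): transcripts are cleaned to a
   letters-plus-space alphabet and embedded as overlapping 3-letter states.
2. **Recurrence analysis** (`syncmap.recurrence`): auto- and cross-recurrence
   plots for symbolic (exact trigram identity) and continuous (distance
   radius) data, with the standard quantifiers RR, DET, ENT (bits), Lmax and
   LAM, windowed over the session. Cross-recurrence significance is assessed
   against a symbol-permutation null.
3. **State dynamics** (`syncmap.state_dynamics`): the four channels' windowed
   profiles are z-scored, clustered with k-means, and the window-label
   sequence is compiled into a row-stochastic Markov transition matrix with a
   stationary distribution; states with high self-transition probability are
   reported as attractors.
4. **Shared component** (`syncmap.shared_component`): PCA across simultaneous
   dyad channels tags a *shared* component (same-sign loadings above a
   magnitude floor on both subjects' corresponding channels), supports an
   outcome regression on per-session summaries, and discretizes the shared
   score for Markov analysis.
5. **Oscillator models** (`syncmap.oscillators`): RK4 integration of the
   mean-field Kuramoto system and of a ring of identical, nonlocally coupled
   phase oscillators with a phase-lag parameter; local order parameters
   segment coherent from incoherent groups and detect chimaera states.
6. **Synthetic dyads** (`syncmap.synthetic`): fully seeded generator of
   coupled letter streams (shared trigram motifs echoed across speakers),
   GSR-like series (AR(1) tonic drift plus shared phasic bursts), and a
   hidden two-regime Markov process switching the coupling — the ground
   truth every pipeline stage is validated against.

## Test

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, the binding property-based
battery (brute-force RQA oracle equivalence, Markov estimator recovery,
end-to-end regime recovery over 20 seeds, Kuramoto mean-field limits,
chimaera coexistence, permutation-null sanity, shared-component recovery at
a calibrated effect size). The full run takes several minutes on one CPU.

## CLI

```sh
# generate a synthetic session with ground truth
syncmap simulate-dyad --seed 1 --out session/

# full pipeline: windowed RQA -> k-means states -> transition matrix
syncmap run --transcript-a session/speaker_a.txt --transcript-b session/speaker_b.txt \
            --gsr-a session/gsr_a.csv --gsr-b session/gsr_b.csv \
            --k 2 --out results/

# individual stages
syncmap rqa session/speaker_a.txt --out rqa_a.csv
syncmap crqa session/speaker_a.txt session/speaker_b.txt
syncmap states results/features.csv --k 2 --out states.csv
syncmap transitions states.csv --out transitions.json
syncmap components gsr_a.csv gsr_b.csv --out components/
syncmap oscillators --model ring --preset chimaera-kb --out ring/
```

`run` writes `features.csv`, `states.csv`, `transitions.json`,
`attractors.csv` and `report.md`; outputs embed the config hash and seed so
runs are reproducible byte-for-byte. Configuration is a single-mapping YAML
file (`--config`); unknown keys are rejected. All defaults live in
`syncmap.config.RunConfig`.

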