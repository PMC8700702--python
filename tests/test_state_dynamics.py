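import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from syncmap.state_dynamics import (
    FeatureStream,
    StateSequence,
    assemble_features,
    attractor_report,
    cluster_states,
    estimate_transitions,
    select_k,
)


def _profiles(n=10, channels=("a", "b"), feats=("RR",), rng=None):
    rng = rng or np.random.default_rng(0)
    out = {}
    for ch in channels:
        data = {"t_center": np.arange(n, dtype=float)}
        for f in feats:
            data[f] = rng.random(n)
        out[ch] = pd.DataFrame(data)
    return out


class TestAssembleFeatures:
    def test_shape(self):
        f = assemble_features(_profiles(n=10), features=("RR",))
        assert f.X.shape == (10, 2)
        assert f.columns == ["a:RR", "b:RR"]

    def test_zscore(self):
        f = assemble_features(_profiles(n=50, feats=("RR", "DET")),
                              features=("RR", "DET"))
        assert np.all(np.abs(f.X.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(f.X.std(axis=0) - 1) < 1e-9)

    def test_constant_column_dropped_with_warning(self):
        profs = _profiles(n=10, feats=("RR", "DET"))
        profs["a"]["DET"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            f = assemble_features(profs, features=("RR", "DET"))
        assert "a:DET" not in f.columns
        assert f.X.shape == (10, 3)

    def test_mismatched_grids_error(self):
        profs = _profiles(n=10)
        profs["b"] = profs["b"].iloc[:5]
        with pytest.raises(ValueError, match="windows"):
            assemble_features(profs, features=("RR",))


def _blobs(rng, k=2, n_per=40, sep=10.0, d=3):
    centers = rng.normal(size=(k, d)) * sep
    X = np.vstack([centers[i] + rng.normal(size=(n_per, d)) for i in range(k)])
    y = np.repeat(np.arange(k), n_per)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


class TestClusterStates:
    def test_separated_blobs_perfect_ari(self, rng):
        X, y = _blobs(rng)
        f = FeatureStream(t=np.arange(len(y), dtype=float), X=X,
                          columns=[f"f{i}" for i in range(X.shape[1])])
        s = cluster_states(f, k=2, seed=0)
        assert adjusted_rand_score(y, s.labels) == 1.0

    def test_k1_all_zero(self, rng):
        X, _ = _blobs(rng)
        f = FeatureStream(t=np.arange(len(X), dtype=float), X=X,
                          columns=["f0", "f1", "f2"])
        s = cluster_states(f, k=1, seed=0)
        assert set(s.labels) == {0}

    def test_labels_ordered_by_occupancy(self, rng):
        X, _ = _blobs(rng, k=3, n_per=30)
        extra = X[:20] + 0.01  # inflate one cluster
        f = FeatureStream(t=np.arange(len(X) + 20, dtype=float),
                          X=np.vstack([X, extra]), columns=["f0", "f1", "f2"])
        s = cluster_states(f, k=3, seed=0)
        occ = s.occupancy()
        assert np.all(np.diff(occ) <= 0)

    def test_multirestart_near_optimal(self, rng):
        X, _ = _blobs(rng, k=5, n_per=30, sep=4.0)
        f = FeatureStream(t=np.arange(len(X), dtype=float), X=X,
                          columns=["f0", "f1", "f2"])

        def wcss(labels, k):
            return sum(
                ((X[labels == i] - X[labels == i].mean(axis=0)) ** 2).sum()
                for i in range(k)
            )

        s = cluster_states(f, k=5, n_init=10, seed=123)
        best = min(
            wcss(cluster_states(f, k=5, n_init=1, seed=seed).labels, 5)
            for seed in range(50)
        )
        assert wcss(s.labels, 5) <= best * 1.01

    def test_select_k_two_blobs(self, rng):
        X, _ = _blobs(rng, k=2, n_per=50)
        f = FeatureStream(t=np.arange(len(X), dtype=float), X=X,
                          columns=["f0", "f1", "f2"])
        assert select_k(f, k_range=range(2, 6), seed=0) == 2


class TestEstimateTransitions:
    def test_hand_count(self):
        m = estimate_transitions(np.array([0, 0, 1, 1, 0]))
        np.testing.assert_array_equal(m.counts, [[1, 1], [1, 1]])
        np.testing.assert_allclose(m.P, [[0.5, 0.5], [0.5, 0.5]])
        np.testing.assert_allclose(m.pi, [0.5, 0.5])

    def test_deterministic_cycle(self):
        m = estimate_transitions(np.array([0, 1] * 10))
        np.testing.assert_allclose(m.P, [[0, 1], [1, 0]])
        np.testing.assert_allclose(m.pi, [0.5, 0.5])

    def test_known_chain_recovery(self):
        rng = np.random.default_rng(7)
        P = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.25, 0.25, 0.5]])
        labels = np.empty(5000, dtype=int)
        state = 0
        for i in range(5000):
            labels[i] = state
            state = rng.choice(3, p=P[state])
        m = estimate_transitions(labels)
        assert np.max(np.abs(m.P - P)) <= 0.05
        assert np.max(np.abs(m.pi @ m.P - m.pi)) < 1e-9

    def test_dead_state_needs_smoothing(self):
        labels = np.array([0, 0, 1])  # state 1 has no outgoing transition
        with pytest.raises(ValueError, match="smoothing"):
            estimate_transitions(labels)
        m = estimate_transitions(labels, smoothing=1.0)
        np.testing.assert_allclose(m.P.sum(axis=1), 1.0)

    def test_row_stochastic_and_stationary_invariants(self, rng):
        labels = rng.integers(0, 4, size=500)
        m = estimate_transitions(labels)
        np.testing.assert_allclose(m.P.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(m.pi @ m.P, m.pi, atol=1e-9)
        assert m.pi.sum() == pytest.approx(1.0)

    def test_label_permutation_leaves_spectrum(self, rng):
        labels = rng.integers(0, 3, size=400)
        m1 = estimate_transitions(labels)
        perm = np.array([2, 0, 1])
        m2 = estimate_transitions(perm[labels])
        ev1 = np.sort(np.abs(np.linalg.eigvals(m1.P)))
        ev2 = np.sort(np.abs(np.linalg.eigvals(m2.P)))
        np.testing.assert_allclose(ev1, ev2, atol=1e-9)
        np.testing.assert_allclose(np.sort(m1.pi), np.sort(m2.pi), atol=1e-9)


class TestAttractorReport:
    def _model_states(self, diag, occ_labels):
        m = estimate_transitions(np.asarray(occ_labels), smoothing=0.5)
        k = m.k
        s = StateSequence(labels=np.asarray(occ_labels), k=k,
                          centroids=np.arange(k * 2, dtype=float).reshape(k, 2))
        return m, s

    def test_self_p_ranking(self):
        rng = np.random.default_rng(0)
        # state 0 sticky, others noisy
        labels = []
        state = 0
        for _ in range(300):
            labels.append(state)
            if state == 0:
                state = 0 if rng.random() < 0.9 else 1
            else:
                state = rng.integers(0, 3)
        m, s = self._model_states(None, labels)
        rep = attractor_report(m, s)
        assert rep.iloc[0]["state"] == 0

    def test_uniform_ties_break_by_occupancy(self):
        labels = np.array([0, 1, 0, 1, 0, 0, 1, 0])  # state 0 more occupied
        m, s = self._model_states(None, labels)
        rep = attractor_report(m, s)
        assert list(rep["state"]) == sorted(
            range(m.k), key=lambda i: (-m.self_p[i], -s.occupancy()[i])
        )

    def test_tercile_levels_present(self):
        labels = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 0])
        m, s = self._model_states(None, labels)
        rep = attractor_report(m, s)
        assert set(rep["f0_level"]) <= {"low", "medium", "high"}
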