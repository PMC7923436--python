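"""Clustering, PCA validation, stratified splitting and the SVM transfer
classifier, checked against brute-force linkage and eigendecomposition
oracles and the planted synthetic subtypes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import cpgpairs as cp


def brute_force_complete_linkage(dist: np.ndarray, k: int) -> list[set]:
    """Exhaustive agglomeration: repeatedly merge the two clusters whose
    maximum inter-point distance is smallest, until k clusters remain."""
    clusters = [{i} for i in range(len(dist))]
    while len(clusters) > k:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return clusters


def _partition_sets(labels: pd.Series) -> set[frozenset]:
    return {frozenset(g) for _, g in labels.groupby(labels).groups.items()}


class TestHierarchicalCluster:
    def test_duplicated_blocks_separate_perfectly(self):
        rng = np.random.default_rng(0)
        block_a = rng.integers(0, 2, size=(30, 1))
        block_b = 1 - block_a
        scores = pd.DataFrame(
            np.hstack([np.repeat(block_a, 5, axis=1), np.repeat(block_b, 5, axis=1)]),
            index=[f"p{i}" for i in range(30)],
            columns=[f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)],
        )
        labels = cp.hierarchical_cluster(scores, k=2)
        assert labels[[f"A{i}" for i in range(5)]].nunique() == 1
        assert labels[[f"B{i}" for i in range(5)]].nunique() == 1
        assert labels["A0"] != labels["B0"]

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_six_samples_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = pd.DataFrame(
            rng.integers(0, 2, size=(25, 6)),
            index=[f"p{i}" for i in range(25)],
            columns=[f"s{i}" for i in range(6)],
        )
        labels = cp.hierarchical_cluster(scores, k=3)
        x = scores.to_numpy().T
        dist = (x[:, None, :] != x[None, :, :]).mean(axis=2)
        oracle = brute_force_complete_linkage(dist, k=3)
        oracle_sets = {
            frozenset(scores.columns[i] for i in c) for c in oracle
        }
        assert _partition_sets(labels) == oracle_sets

    def test_sample_permutation_invariance(self, pipeline):
        scores = pipeline.scores
        rng = np.random.default_rng(5)
        perm = rng.permutation(scores.columns)
        labels_perm = cp.hierarchical_cluster(scores[perm], k=3)
        assert _partition_sets(labels_perm) == _partition_sets(pipeline.labels)

    def test_pair_order_invariance(self, pipeline):
        scores = pipeline.scores
        shuffled = scores.sample(frac=1.0, random_state=4)
        labels = cp.hierarchical_cluster(shuffled, k=3)
        assert _partition_sets(labels) == _partition_sets(pipeline.labels)

    def test_labels_canonicalized_by_size(self, pipeline):
        counts = pipeline.labels.value_counts()
        assert list(counts.index) == sorted(counts.index)  # 1..k present
        assert (counts.sort_index(ascending=True).diff().dropna() <= 0).all()

    def test_planted_subtypes_recovered(self, pipeline):
        truth = pipeline.truth.sample_subtype[pipeline.labels.index]
        assert adjusted_rand_score(truth, pipeline.labels) > 0.8

    def test_consensus_wrapper_agrees_on_clear_structure(self, pipeline):
        labels = cp.hierarchical_cluster(
            pipeline.scores, k=3, consensus=True, n_resamples=30, seed=1
        )
        ari = adjusted_rand_score(pipeline.labels, labels)
        assert ari > 0.8

    @pytest.mark.parametrize("k", [1, 500])
    def test_bad_k_raises(self, pipeline, k):
        with pytest.raises(ValueError):
            cp.hierarchical_cluster(pipeline.scores, k=k)


class TestPcaEmbed:
    def test_identical_samples_identical_coordinates(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 2, size=20)
        other = rng.integers(0, 2, size=(20, 3))
        scores = pd.DataFrame(
            np.column_stack([col, col, other]),
            columns=["dup1", "dup2", "x1", "x2", "x3"],
        )
        coords = cp.pca_embed(scores)
        assert np.allclose(coords.loc["dup1"], coords.loc["dup2"])

    def test_explained_variance_conserved(self, pipeline):
        scores = pipeline.scores
        x = scores.to_numpy(dtype=float).T
        total = x.var(axis=0, ddof=1).sum()
        ev = cp.subtypes.explained_variance(scores, n_components=min(x.shape) - 1)
        assert np.isclose(ev.sum(), total, rtol=1e-8)

    def test_toy_matrix_matches_eigendecomposition(self):
        x = np.array(
            [[2.0, 0.5, 1.0], [0.1, 1.2, 0.3], [1.5, 2.2, 0.8], [0.3, 0.4, 2.4]]
        )
        scores = pd.DataFrame(x.T, columns=["a", "b", "c", "d"])
        coords = cp.pca_embed(scores, n_components=2)
        centered = x - x.mean(axis=0)
        cov = centered.T @ centered / (len(x) - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        v = v[:, order]
        expected = centered @ v[:, :2]
        for i in range(2):
            got = coords.iloc[:, i].to_numpy()
            assert np.allclose(got, expected[:, i]) or np.allclose(
                got, -expected[:, i]
            )

    def test_constant_matrix_raises(self):
        scores = pd.DataFrame(np.ones((5, 4)), columns=list("abcd"))
        with pytest.raises(ValueError, match="variance"):
            cp.pca_embed(scores)


class TestSplitTrain:
    def _labels(self, sizes):
        samples, labs = [], []
        for c, n in sizes.items():
            for i in range(n):
                samples.append(f"c{c}s{i:03d}")
                labs.append(c)
        return pd.Series(labs, index=samples)

    def test_balanced_100_gives_75_25(self):
        labels = self._labels({1: 40, 2: 40, 3: 20})
        a, b = cp.split_train(labels, seed=0)
        assert len(a) == 75 and len(b) == 25

    def test_deterministic_under_seed(self):
        labels = self._labels({1: 40, 2: 40, 3: 20})
        assert cp.split_train(labels, seed=3) == cp.split_train(labels, seed=3)
        assert cp.split_train(labels, seed=3) != cp.split_train(labels, seed=4)

    def test_stratification_within_one_sample(self):
        labels = self._labels({1: 41, 2: 37, 3: 22})
        a, _ = cp.split_train(labels, seed=1)
        a_labels = labels[a]
        for c in (1, 2, 3):
            expected = 0.75 * (labels == c).sum()
            assert abs((a_labels == c).sum() - expected) <= 1

    def test_small_cluster_raises(self):
        labels = self._labels({1: 10, 2: 3})
        with pytest.raises(ValueError, match="stratify"):
            cp.split_train(labels)


@pytest.fixture(scope="module")
def split_model(pipeline):
    a, b = cp.split_train(pipeline.labels, seed=0)
    model = cp.fit_svm_grid(pipeline.scores[a], pipeline.labels[a], seed=0)
    return a, b, model


class TestSvm:
    def test_separable_data_cv_accuracy_high(self, split_model):
        _, _, model = split_model
        assert model.cv_accuracy >= 0.95

    def test_holdout_within_ten_points_of_cv(self, split_model, pipeline):
        _, b, model = split_model
        pred = cp.predict_subtype(model, pipeline.scores[b])
        acc = float((pred == pipeline.labels[b]).mean())
        assert acc >= 0.9
        assert abs(acc - model.cv_accuracy) <= 0.10

    def test_training_labels_recovered(self, split_model, pipeline):
        a, _, model = split_model
        pred = cp.predict_subtype(model, pipeline.scores[a])
        assert (pred == pipeline.labels[a]).mean() >= 0.95

    def test_single_point_grid_returned(self, pipeline):
        a, _ = cp.split_train(pipeline.labels, seed=0)
        model = cp.fit_svm_grid(
            pipeline.scores[a],
            pipeline.labels[a],
            C_grid=[10.0],
            gamma_grid=[0.1],
            seed=0,
        )
        assert model.C == 10.0 and model.gamma == 0.1

    def test_permuted_labels_give_chance_accuracy(self, pipeline):
        rng = np.random.default_rng(0)
        labels = pipeline.labels.copy()
        labels[:] = rng.permutation(labels.to_numpy())
        model = cp.fit_svm_grid(
            pipeline.scores, labels, C_grid=[1.0], gamma_grid=["scale"], seed=0
        )
        prior = labels.value_counts(normalize=True).max()
        assert model.cv_accuracy <= prior + 0.15

    def test_single_sample_prediction(self, split_model, pipeline):
        _, b, model = split_model
        one = pipeline.scores[[b[0]]]
        pred = cp.predict_subtype(model, one)
        assert len(pred) == 1

    def test_pair_mismatch_raises(self, split_model, pipeline):
        _, b, model = split_model
        bad = pipeline.scores[b].iloc[:-3]
        with pytest.raises(ValueError, match="mismatch"):
            cp.predict_subtype(model, bad)

    def test_single_class_raises(self, pipeline):
        labels = pipeline.labels.copy()
        labels[:] = 1
        with pytest.raises(ValueError):
            cp.fit_svm_grid(pipeline.scores, labels)

    def test_shifted_twins_get_same_labels(self, split_model, pipeline):
        _, b, model = split_model
        twin = cp.platform_shift(pipeline.tumor[b], shift=0.05)
        scores_twin = cp.score_new_samples(twin, model.pairs)
        pred_twin = cp.predict_subtype(model, scores_twin)
        pred_orig = cp.predict_subtype(model, pipeline.scores[b])
        assert (pred_twin == pred_orig).all()
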