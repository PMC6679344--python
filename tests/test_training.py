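import numpy as np
import pytest

from bipathnet.data_io import RunConfig, ValidationError
from bipathnet.features import embedding_matrix
from bipathnet.training import (batch_losses, build_pair_batch,
                                forward_batch, gather_parameters,
                                init_model, losses, make_folds, pair_scores,
                                sample_negatives, score_pairs, train)


class TestSampleNegatives:
    def test_toy_matrix_yields_disjoint_negatives(self, toy_network):
        neg = sample_negatives(toy_network.A, 4, seed=0)
        assert len(neg) == len(set(neg)) == 4
        assert all(toy_network.A[i, j] == 0 for i, j in neg)

    def test_same_seed_reproducible(self, toy_network):
        assert sample_negatives(toy_network.A, 4, seed=5) == \
            sample_negatives(toy_network.A, 4, seed=5)

    def test_insufficient_zeros_rejected(self):
        A = np.ones((2, 2))
        A[0, 0] = 0
        with pytest.raises(ValidationError):
            sample_negatives(A, 2, seed=0)

    def test_uniform_selection_frequencies(self):
        """Each of the 8 zero cells of a 3x3 matrix with one positive is
        drawn with frequency ~ 1/8 over many single-negative samples."""
        A = np.zeros((3, 3))
        A[1, 1] = 1
        rng = np.random.default_rng(0)
        counts = {}
        n = 1000
        for _ in range(n):
            (pair,) = sample_negatives(A, 1, rng)
            counts[pair] = counts.get(pair, 0) + 1
        p = 1 / 8
        sigma = np.sqrt(n * p * (1 - p))
        for c in counts.values():
            assert abs(c - n * p) < 3.5 * sigma


class TestMakeFolds:
    def pairs(self, n):
        return [(i, 0) for i in range(n)]

    def test_balanced_fold_sizes(self):
        tset = make_folds(self.pairs(10), self.pairs(10), 5, seed=0)
        counts = np.bincount(tset.pos_folds, minlength=5)
        assert (counts == 2).all()

    def test_folds_partition_input(self):
        pos = self.pairs(13)
        tset = make_folds(pos, self.pairs(13), 5, seed=1)
        seen = []
        for fold in range(5):
            _, _, test_pos = tset.fold_split(fold)
            seen.extend(test_pos)
        assert sorted(seen) == sorted(pos)

    def test_distinct_partitions_across_seeds(self):
        partitions = {tuple(make_folds(self.pairs(20), self.pairs(20), 5,
                                       seed=s).pos_folds)
                      for s in range(20)}
        assert len(partitions) > 15  # distinct with high probability

    def test_too_few_positives_rejected(self):
        with pytest.raises(ValidationError):
            make_folds(self.pairs(3), self.pairs(3), 5, seed=0)


class TestScoresAndLosses:
    def make_state(self, toy_network, tiny_config):
        rng = np.random.default_rng(0)
        E = embedding_matrix(toy_network)
        return init_model(E.shape[1], tiny_config, rng), E

    @pytest.mark.parametrize("lam, expect", [(1.0, "s_n"), (0.0, "s_p")])
    def test_lambda_limits(self, toy_network, tiny_config, lam, expect):
        state, E = self.make_state(toy_network, tiny_config)
        state.combine_weight = lam
        rng = np.random.default_rng(1)
        vn = rng.random(state.Wn.shape[0])
        vp = rng.random(state.Wp_head.shape[0])
        state.Wn.data = rng.normal(size=state.Wn.shape)
        state.Wp_head.data = rng.normal(size=state.Wp_head.shape)
        s_n, s_p, s = pair_scores(state, vn, vp)
        np.testing.assert_allclose(s, s_n if expect == "s_n" else s_p)

    def test_combined_score_is_distribution(self, toy_network, tiny_config):
        state, _ = self.make_state(toy_network, tiny_config)
        rng = np.random.default_rng(2)
        state.Wn.data = rng.normal(size=state.Wn.shape)
        state.Wp_head.data = rng.normal(size=state.Wp_head.shape)
        for lam in (0.0, 0.12, 0.5, 1.0):
            state.combine_weight = lam
            _, _, s = pair_scores(state, rng.random(state.Wn.shape[0]),
                                  rng.random(state.Wp_head.shape[0]))
            assert s.sum() == pytest.approx(1.0)
            assert (s >= 0).all()

    def test_pathless_pair_scored_by_cnn_branch_only(self, toy_network,
                                                     tiny_config):
        state, _ = self.make_state(toy_network, tiny_config)
        rng = np.random.default_rng(3)
        state.Wp_head.data = rng.normal(size=state.Wp_head.shape)
        s_n, _, s = pair_scores(state, rng.random(state.Wn.shape[0]),
                                np.zeros(state.Wp_head.shape[0]),
                                has_paths=False)
        np.testing.assert_allclose(s, s_n)

    def test_perfect_prediction_near_zero_loss(self):
        s = np.array([[0.0, 1.0], [1.0, 0.0]])
        y = np.array([[0.0, 1.0], [1.0, 0.0]])
        loss_n, loss_p = losses(s, s, y)
        assert loss_n <= 1e-9 and loss_p <= 1e-9

    def test_uniform_prediction_is_log2_per_sample(self):
        s = np.full((4, 2), 0.5)
        y = np.zeros((4, 2)); y[:, 1] = 1
        loss_n, _ = losses(s, s, y)
        assert loss_n == pytest.approx(4 * np.log(2))

    def test_batch_loss_matches_per_sample_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            B = 5
            z = rng.normal(size=(B, 2))
            s = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
            labels = rng.integers(0, 2, B)
            y = np.zeros((B, 2)); y[np.arange(B), labels] = 1
            mask = rng.random(B) < 0.8
            expect_n = -sum(np.log(s[b, labels[b]]) for b in range(B))
            expect_p = -sum(np.log(s[b, labels[b]]) for b in range(B)
                            if mask[b])
            got_n, got_p = losses(s, s, y, path_mask=mask)
            assert got_n == pytest.approx(expect_n)
            assert got_p == pytest.approx(expect_p)


class TestTrainingLoop:
    def small_train_setup(self, small_world, epochs=4):
        net = small_world["net"]
        cfg = RunConfig(epochs=epochs, batch_size=32, lstm_hidden_size=8,
                        conv1_channels=4, conv2_channels=4, seed=11)
        rng = np.random.default_rng(11)
        pos = [(int(i), int(j)) for i, j in zip(*np.nonzero(net.A))]
        neg = sample_negatives(net.A, len(pos), rng)
        pairs = pos + neg
        labels = np.array([1] * len(pos) + [0] * len(neg))
        return net, cfg, pairs, labels

    def test_loss_decreases_on_planted_signal(self, small_world):
        net, cfg, pairs, labels = self.small_train_setup(small_world)
        state, history = train(net, pairs, labels,
                               cfg, np.random.default_rng(0))
        assert history[-1, 2] < history[0, 2]

    def test_fixed_seed_reproduces_loss_trajectory(self, small_world):
        net, cfg, pairs, labels = self.small_train_setup(small_world, 2)
        _, h1 = train(net, pairs, labels, cfg, np.random.default_rng(5))
        _, h2 = train(net, pairs, labels, cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(h1, h2)

    def test_score_pairs_shapes_and_range(self, small_world):
        net, cfg, pairs, labels = self.small_train_setup(small_world, 1)
        state, _ = train(net, pairs, labels, cfg, np.random.default_rng(0))
        raw = score_pairs(state, net, pairs[:10], cfg)
        assert raw.shape == (10, 3)
        s = raw[:, 2]
        assert ((s >= 0) & (s <= 1)).all()

    def test_no_path_of_masked_edge_survives(self, small_world):
        """Leakage audit: after masking a test fold, no enumerated
        training path traverses a held-out association edge."""
        net = small_world["net"]
        cfg = RunConfig(lstm_hidden_size=4)
        pos = [(int(i), int(j)) for i, j in zip(*np.nonzero(net.A))]
        test_pos = pos[::5]
        net_fold = net.masked(test_pos)
        held_out = set(test_pos)
        nr = net.n_drugs
        batch = build_pair_batch(net_fold, pos[:40] , cfg)
        for L, paths in batch.path_groups.items():
            for p in paths:
                for a, b in zip(p[:-1], p[1:]):
                    lo, hi = min(a, b), max(a, b)
                    if lo < nr <= hi:  # an association edge
                        assert (lo, hi - nr) not in held_out

    def test_gradients_flow_to_every_parameter_family(self, toy_network,
                                                      tiny_config):
        rng = np.random.default_rng(0)
        E = embedding_matrix(toy_network)
        state = init_model(E.shape[1], tiny_config, rng)
        # heads start at zero by design; gradients reach the branches only
        # once the heads are nonzero, as after the first optimizer step
        state.Wn.data = rng.normal(size=state.Wn.shape)
        state.Wp_head.data = rng.normal(size=state.Wp_head.shape)
        pairs = [(0, 3), (0, 1), (1, 0), (2, 3)]
        batch = build_pair_batch(toy_network, pairs, tiny_config, E)
        logits_n, logits_p = forward_batch(state, batch, E)
        loss_n, loss_p = batch_losses(logits_n, logits_p,
                                      np.array([1, 1, 0, 0]),
                                      batch.has_paths)
        (loss_n + loss_p).backward()
        grads = {k: t.grad for k, t in gather_parameters(state).items()}
        for family in ("conv.W1", "lstm.forward.Wg", "lstm.backward.Wc",
                       "attn.up", "head_n.W", "head_p.W"):
            assert grads[family] is not None, family
            assert np.abs(grads[family]).sum() > 0, family
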