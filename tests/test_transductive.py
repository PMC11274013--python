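"""TIM machinery: prototypes, posteriors, information objective, inference."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import SMALL_ENCODER
from timsed.backbone import build_encoder
from timsed.transductive import (ClassifierState, Episode, PosteriorMatrix,
                                 TimConfig, init_prototypes,
                                 make_gaussian_episode, mutual_information,
                                 posterior, prototype_posterior,
                                 query_accuracy, support_cross_entropy,
                                 tim_gradient, tim_infer, tim_loss)


def brute_force_mi(P):
    """Double-sum evaluation of the information objective (oracle)."""
    n, K = P.shape
    marginal = [sum(P[i][k] for i in range(n)) / n for k in range(K)]
    h_marg = -sum(m * math.log(m) for m in marginal if m > 0)
    h_cond = -sum(P[i][k] * math.log(P[i][k])
                  for i in range(n) for k in range(K) if P[i][k] > 0) / n
    return h_marg - h_cond


def simple_episode():
    sup = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 4.0]])
    y = np.array([0, 0, 1])
    qry = np.array([[1.0, 1.0], [0.0, 3.0]])
    return Episode(sup, y, qry, n_way=2)


class TestPrototypes:
    def test_means_per_class(self):
        cs = init_prototypes(simple_episode())
        assert np.allclose(cs.W, [[1.0, 0.0], [0.0, 4.0]])

    def test_one_shot_prototype_is_the_embedding(self):
        ep = Episode(np.array([[1.0, 2.0], [3.0, 4.0]]), np.array([0, 1]),
                     np.array([[0.0, 0.0]]), n_way=2)
        assert np.allclose(init_prototypes(ep).W, ep.support_z)

    def test_missing_class_support_rejected(self):
        with pytest.raises(ValueError, match="needs support"):
            Episode(np.array([[1.0, 0.0]]), np.array([0]),
                    np.array([[0.0, 0.0]]), n_way=2)


class TestPosterior:
    def test_zero_weights_give_uniform_rows(self):
        cs = ClassifierState(np.zeros((4, 3)))
        pm = posterior(cs, np.random.default_rng(0).random((5, 3)))
        assert np.allclose(pm.P, 0.25)

    def test_single_class_rows_are_one(self):
        cs = ClassifierState(np.ones((1, 3)))
        pm = posterior(cs, np.random.default_rng(0).random((4, 3)))
        assert np.allclose(pm.P, 1.0)

    def test_scalar_softmax_value(self):
        # logits (1, 0) -> (e/(e+1), 1/(e+1))
        cs = ClassifierState(np.array([[1.0], [0.0]]))
        pm = posterior(cs, np.array([[1.0]]))
        assert np.allclose(pm.P[0], [0.73105857, 0.26894143], atol=1e-6)

    def test_rows_sum_to_one_and_marginal_is_column_mean(self, rng):
        cs = ClassifierState(rng.standard_normal((5, 7)))
        pm = posterior(cs, rng.standard_normal((20, 7)))
        assert np.allclose(pm.P.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(pm.marginal, pm.P.mean(axis=0), atol=1e-9)


class TestMutualInformation:
    def test_uniform_rows_give_zero(self):
        P = np.full((6, 4), 0.25)
        assert abs(mutual_information(PosteriorMatrix(P, P.mean(0)))) < 1e-12

    def test_balanced_one_hot_gives_log_k(self):
        P = np.eye(4)
        mi = mutual_information(PosteriorMatrix(P, P.mean(0)))
        assert np.isclose(mi, math.log(4))

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(50):
            n, K = int(rng.integers(1, 12)), int(rng.integers(2, 6))
            P = rng.random((n, K)) + 1e-9
            P /= P.sum(axis=1, keepdims=True)
            mi = mutual_information(PosteriorMatrix(P, P.mean(0)))
            assert abs(mi - brute_force_mi(P)) <= 1e-10

    @settings(max_examples=200, derandomize=True)
    @given(arrays(np.float64, (7, 3),
                  elements=st.floats(1e-6, 1.0, allow_nan=False)))
    def test_information_bounds(self, raw):
        P = raw / raw.sum(axis=1, keepdims=True)
        mi = mutual_information(PosteriorMatrix(P, P.mean(0)))
        assert -1e-12 <= mi <= math.log(3) + 1e-12


class TestSupportCrossEntropy:
    def test_confident_correct_posterior_near_zero(self):
        ep = simple_episode()
        cs = ClassifierState(np.array([[50.0, -50.0], [-50.0, 50.0]]))
        ep2 = Episode(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([0, 1]),
                      ep.query_z, n_way=2)
        assert support_cross_entropy(cs, ep2) < 1e-6

    def test_uniform_posterior_gives_log_k(self):
        ep = simple_episode()
        cs = ClassifierState(np.zeros((2, 2)))
        assert np.isclose(support_cross_entropy(cs, ep), math.log(2))

    def test_hand_computed_value(self):
        # basis embeddings pick columns of W as logits: item 1 (label 0)
        # sees (ln.8, ln.2) -> p_true = 0.8; item 2 (label 1) sees
        # (ln.5, ln.5) -> p_true = 0.5; CE = -(ln .8 + ln .5)/2
        W = np.array([[math.log(0.8), math.log(0.5)],
                      [math.log(0.2), math.log(0.5)]])
        ep = Episode(np.eye(2), np.array([0, 1]), np.eye(2), n_way=2)
        got = support_cross_entropy(ClassifierState(W), ep)
        assert np.isclose(got, -(math.log(0.8) + math.log(0.5)) / 2, atol=1e-9)


class TestTimLoss:
    def test_lambda_zero_is_negative_information(self):
        ep = simple_episode()
        cs = init_prototypes(ep)
        cfg = TimConfig(lambda_ce=0.0)
        assert np.isclose(tim_loss(cs, ep, cfg),
                          -mutual_information(posterior(cs, ep.query_z)))

    def test_equals_manual_composition(self, rng):
        ep, _ = make_gaussian_episode(3, 2, 6, 5, 1.0, 1.0, rng=rng)
        cs = init_prototypes(ep)
        manual = support_cross_entropy(cs, ep) \
            - mutual_information(posterior(cs, ep.query_z))
        assert np.isclose(tim_loss(cs, ep, TimConfig()), manual)

    def test_gradient_matches_finite_differences(self):
        ep, _ = make_gaussian_episode(3, 2, 5, 4, 1.0, 1.0, rng=2)
        cs = init_prototypes(ep)
        cfg = TimConfig()
        _, dW = tim_gradient(cs, ep, cfg)
        eps = 1e-6
        for i in range(cs.W.shape[0]):
            for j in range(cs.W.shape[1]):
                Wp, Wm = cs.W.copy(), cs.W.copy()
                Wp[i, j] += eps
                Wm[i, j] -= eps
                num = (tim_loss(ClassifierState(Wp), ep, cfg)
                       - tim_loss(ClassifierState(Wm), ep, cfg)) / (2 * eps)
                assert abs(num - dW[i, j]) < 1e-7


class TestTimInfer:
    def test_separable_clusters_classified_perfectly(self):
        ep, yq = make_gaussian_episode(2, 5, 20, 8, 3.0, 0.1, rng=0)
        pm, _, trace = tim_infer(None, ep, TimConfig())
        assert query_accuracy(pm, yq) == 1.0
        assert all(trace[i + 1] <= trace[i] + 1e-6 for i in range(len(trace) - 1))

    def test_single_class_posterior_all_ones(self):
        ep = Episode(np.ones((2, 3)), np.zeros(2, dtype=int),
                     np.ones((4, 3)), n_way=1)
        pm, _, trace = tim_infer(None, ep, TimConfig())
        assert np.allclose(pm.P, 1.0)
        assert len(trace) == 1

    def test_improves_over_prototypes_on_overlapping_clusters(self):
        from timsed.benchmark import tim_vs_prototype
        res = tim_vs_prototype(n_episodes=10, center_scale=1.0, sigma=1.0, seed=3)
        assert res["tim_accuracy"] >= res["prototype_accuracy"] - 1e-9

    def test_last_block_scope_runs_on_tiny_encoder(self, rng):
        enc = build_encoder(SMALL_ENCODER, seed=0)
        sup = rng.random((6, 8, 32))
        qry = rng.random((10, 8, 32))
        sup[:3, :, 20:26] += 2.0   # crude class structure
        ep = Episode(enc.embed(sup), np.array([0] * 3 + [1] * 3),
                     enc.embed(qry), n_way=2,
                     support_patches=sup, query_patches=qry)
        cfg = TimConfig(update_scope="classifier+last_block", n_iters=5)
        pm, cs, trace = tim_infer(enc, ep, cfg)
        assert pm.P.shape == (10, 2)
        assert np.all(np.isfinite(trace))

    def test_prototype_posterior_uses_distances(self):
        # a far-but-large-norm prototype must not win under Euclidean softmax
        ep = Episode(np.array([[10.0, 0.0], [0.0, 1.0]]), np.array([0, 1]),
                     np.array([[0.0, 0.9]]), n_way=2)
        pm = prototype_posterior(ep)
        assert pm.P[0, 1] > 0.99
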