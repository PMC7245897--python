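"""The neural core: attention, classifiers, CRF decoding, input windows."""

import itertools

import numpy as np
import pytest

from kbrelex import nn
from kbrelex.corpus import EntityMention, TAGS
from kbrelex.model import (
    ModelConfig,
    RelationNetwork,
    TaggerNetwork,
    attentive_pool,
    build_relation_input,
    classify,
    crf_decode,
    kb_attention,
    load_checkpoint,
    save_checkpoint,
)

from conftest import make_sentence


def attention_oracle(h, V, U, P=None):
    """Direct exp/normalize enumeration of the bilinear attention."""
    logits = np.array([v @ U @ h for v in V])
    w = np.exp(logits - logits.max())
    alpha = w / w.sum()
    s = sum(a * v for a, v in zip(alpha, V))
    bridged = s if P is None else P @ s
    return alpha, s, h + bridged


class TestKbAttention:
    def test_empty_v_returns_h_exactly(self):
        h = np.random.default_rng(0).normal(size=6)
        out = kb_attention(h, np.zeros((0, 3)), np.zeros((3, 6)))
        assert np.array_equal(out.h_prime, h)
        assert out.alpha.size == 0 and np.array_equal(out.s, np.zeros(3))

    def test_singleton_v_forces_weight_one(self, rng):
        v = rng.normal(size=(1, 4))
        h = rng.normal(size=4)
        out = kb_attention(h, v, rng.normal(size=(4, 4)))
        assert np.allclose(out.alpha, [1.0])
        assert np.allclose(out.s, v[0])

    def test_worked_two_vector_example(self):
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = kb_attention(np.array([1.0, 0.0]), V, np.eye(2))
        e = np.e
        assert np.allclose(out.alpha, [e / (1 + e), 1 / (1 + e)], atol=1e-4)
        assert np.allclose(out.s, out.alpha)
        assert np.allclose(out.h_prime, np.array([1.0, 0.0]) + out.s)

    def test_oracle_equivalence_random_instances(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 8))
            dv, dh = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            V = rng.normal(size=(m, dv))
            h = rng.normal(size=dh)
            U = rng.normal(size=(dv, dh))
            P = rng.normal(size=(dh, dv))
            out = kb_attention(h, V, U, P)
            alpha, s, hp = attention_oracle(h, V, U, P)
            assert np.abs(out.alpha - alpha).max() < 1e-9
            assert np.abs(out.s - s).max() < 1e-9
            assert np.abs(out.h_prime - hp).max() < 1e-9

    def test_permutation_equivariance(self, rng):
        V = rng.normal(size=(5, 3))
        h = rng.normal(size=3)
        U = rng.normal(size=(3, 3))
        perm = rng.permutation(5)
        a = kb_attention(h, V, U)
        b = kb_attention(h, V[perm], U)
        assert np.abs(a.alpha[perm] - b.alpha).max() < 1e-9
        assert np.abs(a.s - b.s).max() < 1e-9

    def test_logit_shift_invariance(self, rng):
        # adding a constant to every logit leaves the weights unchanged;
        # realised here by shifting h along a direction in U's null space
        V = np.ones((4, 2)) * rng.normal(size=(4, 1))
        h = rng.normal(size=2)
        U = rng.normal(size=(2, 2))
        base = kb_attention(h, V, U)
        scaled_logits = V @ (U @ h) + 123.456
        w = np.exp(scaled_logits - scaled_logits.max())
        assert np.abs(base.alpha - w / w.sum()).max() < 1e-9

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            kb_attention(rng.normal(size=4), rng.normal(size=(2, 3)),
                         rng.normal(size=(3, 5)))
        with pytest.raises(ValueError):
            kb_attention(rng.normal(size=4), rng.normal(size=(2, 3)),
                         rng.normal(size=(3, 4)))  # needs P, none given


class TestClassify:
    def test_zero_weights_uniform(self):
        out = classify(np.ones(3), np.zeros((4, 3)))
        assert np.allclose(out.probs, 0.25)

    def test_closed_form_two_way(self):
        W = np.array([[np.log(2.0)], [0.0]])
        out = classify(np.ones(1), W)
        assert np.allclose(out.probs, [2 / 3, 1 / 3])

    def test_probs_sum_to_one(self, rng):
        out = classify(rng.normal(size=5), rng.normal(size=(7, 5)))
        assert abs(out.probs.sum() - 1.0) < 1e-9

    def test_tie_breaks_to_lowest_index(self):
        out = classify(np.zeros(2), np.zeros((3, 2)))
        assert out.argmax == 0

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            classify(rng.normal(size=4), rng.normal(size=(3, 5)))


class TestCrfDecode:
    def brute_force(self, em, trans, start, stop):
        T, K = em.shape
        return max(
            itertools.product(range(K), repeat=T),
            key=lambda p: start[p[0]]
            + sum(em[t, p[t]] for t in range(T))
            + sum(trans[p[t - 1], p[t]] for t in range(1, T))
            + stop[p[-1]],
        )

    def test_single_step(self, rng):
        em = rng.normal(size=(1, 4))
        tags = crf_decode(em, np.zeros((4, 4)))
        assert tags == [TAGS[int(np.argmax(em[0]))]]

    def test_zero_transitions_reduce_to_argmax(self, rng):
        em = rng.normal(size=(6, 4))
        tags = crf_decode(em, np.zeros((4, 4)))
        assert tags == [TAGS[i] for i in np.argmax(em, axis=1)]

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            T = int(rng.integers(1, 7))
            em = rng.normal(size=(T, 4))
            trans = rng.normal(size=(4, 4))
            start = rng.normal(size=4)
            stop = rng.normal(size=4)
            decoded = crf_decode(em, trans, start, stop)
            best = self.brute_force(em, trans, start, stop)
            assert decoded == [TAGS[i] for i in best]


class TestRelationInput:
    def make(self, n=10):
        sent = make_sentence(" ".join(f"w{i}" for i in range(n)))
        def ent(i, eid):
            t = sent.tokens[i]
            return EntityMention(eid, "Gene", t.char_start, t.char_end, t.surface)
        return sent, ent

    def test_between_entities_with_expansion(self):
        sent, ent = self.make(10)
        window = build_relation_input(
            sent, (ent(2, "T1"), ent(7, "T2")), "between_entities", 2
        )
        assert [t.surface for t in window] == [f"w{i}" for i in range(10)]

    def test_clamped_at_boundaries(self):
        sent, ent = self.make(10)
        window = build_relation_input(
            sent, (ent(0, "T1"), ent(9, "T2")), "between_entities", 2
        )
        assert len(window) == 10

    def test_whole_sentence_ignores_pair(self):
        sent, ent = self.make(10)
        window = build_relation_input(
            sent, (ent(4, "T1"), ent(5, "T2")), "whole_sentence", 2
        )
        assert len(window) == 10

    def test_entity_outside_sentence_raises(self):
        sent, ent = self.make(5)
        outside = EntityMention("T9", "Gene", 900, 905, "XXXXX")
        with pytest.raises(ValueError):
            build_relation_input(sent, (ent(0, "T1"), outside),
                                 "between_entities", 2)


class TestPooling:
    def test_identical_states_return_the_state(self, rng):
        state = rng.normal(size=4)
        states = np.tile(state, (6, 1))
        merged, beta = attentive_pool(states, rng.normal(size=4))
        assert np.allclose(merged, state)
        assert abs(beta.sum() - 1.0) < 1e-12

    def test_single_state(self, rng):
        state = rng.normal(size=(1, 4))
        merged, beta = attentive_pool(state, rng.normal(size=4))
        assert np.allclose(merged, state[0]) and np.allclose(beta, [1.0])


class TestEncoderAndNetworks:
    CFG = dict(embed_dim=6, lstm_state=4, num_relation_labels=3, seed=0)

    def test_bilstm_shape_and_determinism(self, rng):
        from kbrelex.autodiff import Tensor

        params = nn.bilstm_parameters(np.random.default_rng(0), 6, 4)
        xs = [Tensor(rng.normal(size=(2, 6))) for _ in range(5)]
        hs1 = nn.bilstm_run(params, xs)
        hs2 = nn.bilstm_run(params, xs)
        assert len(hs1) == 5 and hs1[0].shape == (2, 8)
        for a, b in zip(hs1, hs2):
            assert np.array_equal(a.data, b.data)

    def test_backward_stream_mirrors_reversed_forward(self, rng):
        from kbrelex.autodiff import Tensor

        params = nn.lstm_parameters(np.random.default_rng(0), 3, 2, "l")
        xs = [Tensor(rng.normal(size=(1, 3))) for _ in range(4)]
        backward = nn.lstm_run(params, "l", xs, reverse=True)
        forward_on_reversed = nn.lstm_run(params, "l", xs[::-1])
        for t in range(4):
            assert np.allclose(
                backward[t].data, forward_on_reversed[3 - t].data
            )

    def test_relation_network_kb_off_equals_empty_memory(self, rng):
        X = rng.normal(size=(3, 5, 6))
        masks = np.zeros((3, 5, 2))
        cfg_on = ModelConfig(use_kb=True, **self.CFG)
        cfg_off = ModelConfig(use_kb=False, **self.CFG)
        net_on = RelationNetwork(cfg_on, np.random.default_rng(1))
        net_off = RelationNetwork(cfg_off, np.random.default_rng(1))
        empty = np.zeros((3, 0, 6))
        a = net_on.forward(X, masks, empty, np.zeros((3, 0)))
        b = net_off.forward(X, masks, empty, np.zeros((3, 0)))
        assert np.array_equal(a.data, b.data)

    def test_untrained_tagger_emits_valid_length(self, rng):
        cfg = ModelConfig(use_crf=True, **self.CFG)
        net = TaggerNetwork(cfg, np.random.default_rng(0))
        X = rng.normal(size=(1, 7, 6))
        em = net.emissions(X, np.zeros((1, 0, 6)), np.zeros((1, 0)))
        tags = net.decode(em.data[0])
        assert len(tags) == 7 and set(tags) <= set(TAGS)

    def test_type_head_symmetric_weights_uniform(self):
        cfg = ModelConfig(**self.CFG)
        net = TaggerNetwork(cfg, np.random.default_rng(0))
        net.params["type.W"].data[:] = 0.0
        net.params["type.b"].data[:] = 0.0
        logits = net.type_logits(np.ones((1, 6)), np.zeros((1, 0, 6)),
                                 np.zeros((1, 0)))
        probs = np.exp(logits.data[0]) / np.exp(logits.data[0]).sum()
        assert np.allclose(probs, 0.5)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = ModelConfig(**self.CFG)
        net = RelationNetwork(cfg, np.random.default_rng(3))
        save_checkpoint(tmp_path / "m.npz", cfg, net.params, {"task": "relation"})
        cfg2, params, extra = load_checkpoint(tmp_path / "m.npz")
        assert cfg2 == cfg and extra == {"task": "relation"}
        for name, value in params.items():
            assert np.array_equal(value, net.params[name].data)
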