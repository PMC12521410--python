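"""Seq2seq model: structure, determinism, attention properties, retrieval
rule, generation, the attention/context-reinstatement equivalence, and
checkpoint round-trips."""

import numpy as np
import pytest

from memsearch import (
    CMRParams,
    Seq2SeqConfig,
    Seq2SeqModel,
    StudyList,
    attention_equivalence_check,
    build_model,
    encode_list,
)
from memsearch import autodiff as ad
from memsearch.autodiff import Tensor
from memsearch.seq2seq import attend_core


@pytest.fixture
def cfg():
    return Seq2SeqConfig(hidden_dim=12, vocab_size=10, embed_dim=6, seed=3)


@pytest.fixture
def model(cfg):
    return build_model(cfg)


def gru_param_count(input_dim, d):
    return 3 * d * input_dim + 3 * d * d + 6 * d


class TestBuildModel:
    def test_seeded_builds_are_identical(self, cfg):
        m1, m2 = build_model(cfg), build_model(cfg)
        for k in m1.params.names():
            assert np.array_equal(m1.params[k].data, m2.params[k].data)

    def test_no_attention_has_smaller_mixing_layer(self):
        base = dict(hidden_dim=8, vocab_size=10, embed_dim=6, seed=0)
        with_attn = build_model(Seq2SeqConfig(**base, attention=True))
        without = build_model(Seq2SeqConfig(**base, attention=False))
        assert with_attn.params["mix.W"].shape == (16, 8)
        assert without.params["mix.W"].shape == (8, 8)

    def test_parameter_count_scales_with_hidden_dim(self):
        counts = {}
        for d in (32, 128):
            cfg = Seq2SeqConfig(hidden_dim=d, vocab_size=10, embed_dim=6, seed=0)
            m = build_model(cfg)
            expected = (
                10 * 6 + 2 * 6  # item + special embeddings
                + 2 * gru_param_count(6, d)  # encoder + decoder
                + d  # learned initial encoder state
                + 2 * d * d  # mixing layer
                + d + 1  # EOS head
                + 10 * d  # output embeddings
                + d + 1  # value head
            )
            counts[d] = m.params.n_parameters()
            assert counts[d] == expected
        assert counts[128] > counts[32]

    def test_pretrained_requires_embeddings(self):
        cfg = Seq2SeqConfig(
            hidden_dim=8, vocab_size=10, embed_dim=6,
            embedding_source="pretrained", seed=0,
        )
        with pytest.raises(ValueError, match="pretrained"):
            build_model(cfg)

    def test_pretrained_uses_pool_vectors(self, pool16):
        cfg = Seq2SeqConfig(
            hidden_dim=8, vocab_size=16, embed_dim=6,
            embedding_source="pretrained", seed=0,
        )
        m = build_model(cfg, wordpool=pool16)
        assert np.array_equal(m.params["emb.items"].data, pool16.embeddings)
        assert not m.params["emb.items"].requires_grad


class TestEncodeSequence:
    def test_single_item_trace(self, model):
        trace = model.encode_sequence(StudyList((4,)))
        assert trace.H.shape == (1, 12)
        assert np.array_equal(trace.final_state, trace.H[0])

    def test_deterministic_forward(self, model):
        study = StudyList((1, 5, 3))
        t1 = model.encode_sequence(study)
        t2 = model.encode_sequence(study)
        assert np.array_equal(t1.H, t2.H)

    def test_order_sensitivity(self, model):
        a = model.encode_sequence(StudyList((1, 5, 3)))
        b = model.encode_sequence(StudyList((3, 5, 1)))
        assert not np.allclose(a.final_state, b.final_state)

    def test_empty_list_rejected(self, model):
        with pytest.raises(ValueError):
            model.encode_sequence(StudyList(()))


class TestAttention:
    def test_identical_states_give_uniform_weights(self):
        h = np.ones((1, 4))
        Hmat = Tensor(np.repeat(h[:, None, :], 5, axis=1))
        w, _ = attend_core(Tensor(h), Hmat)
        assert np.allclose(w.data, 0.2)

    def test_hand_softmax_two_orthonormal_states(self):
        h1 = np.array([1.0, 0.0])
        h2 = np.array([0.0, 1.0])
        Hmat = Tensor(np.stack([h1, h2])[None, :, :])
        w, alpha = attend_core(Tensor(h1[None, :]), Hmat)
        e = np.e
        assert np.allclose(w.data[0], [e / (e + 1), 1 / (e + 1)])
        assert np.allclose(alpha.data[0], w.data[0, 0] * h1 + w.data[0, 1] * h2)

    def test_weights_on_simplex(self, model, rng):
        study = StudyList(tuple(rng.permutation(10)[:6]))
        res = model.generate_recall(study, mode="sample", max_steps=8,
                                    rng=np.random.default_rng(0))
        w = res.attention.weights
        assert np.all(w >= 0)
        assert np.allclose(w.sum(axis=1), 1.0)

    def test_no_attention_model_rejects_attend(self):
        cfg = Seq2SeqConfig(hidden_dim=8, vocab_size=10, embed_dim=6,
                            attention=False, seed=0)
        m = build_model(cfg)
        with pytest.raises(ValueError):
            m.attend(Tensor(np.zeros((1, 8))), Tensor(np.zeros((1, 2, 8))))

    def test_no_attention_model_records_empty_weights(self):
        cfg = Seq2SeqConfig(hidden_dim=8, vocab_size=10, embed_dim=6,
                            attention=False, seed=0)
        m = build_model(cfg)
        res = m.generate_recall(StudyList((0, 1, 2)), mode="greedy", max_steps=4)
        assert res.attention.weights.shape[1] == 3
        assert res.attention.weights.shape[0] == 0


class TestOutputDistribution:
    def test_in_list_mode_zero_mass_off_list(self, model, rng):
        study = StudyList((2, 7, 4))
        res = model.generate_recall(study, mode="sample", max_steps=6,
                                    rng=np.random.default_rng(1))
        # outcomes are the 3 studied items + EOS only
        assert res.step_distributions.shape[1] == 4
        assert np.allclose(res.step_distributions.sum(axis=1), 1.0, atol=1e-9)
        assert all(t in (2, 7, 4, model.eos) for t in res.tokens)

    def test_full_vocab_mode_can_express_intrusions(self):
        cfg = Seq2SeqConfig(hidden_dim=8, vocab_size=10, embed_dim=6,
                            output_mode="full-vocab", seed=0)
        m = build_model(cfg)
        study = StudyList((0, 1, 2))
        res = m.generate_recall(study, mode="sample", max_steps=6,
                                rng=np.random.default_rng(2))
        assert res.step_distributions.shape[1] == 11
        assert np.allclose(res.step_distributions.sum(axis=1), 1.0, atol=1e-9)

    def test_first_decode_step_starts_from_final_encoder_state(self, model):
        # the first decoder GRU step must receive h_L, not zeros
        study = StudyList((1, 2, 3))
        trace = model.encode_sequence(study)
        with ad.no_grad():
            enc = model.encode_batch(np.array([study.positions]))
            hhat, h1, _ = model.decode_step(np.array([model.sos]), enc.final, enc)
            x = model.embed(np.array([model.sos]))
            expected = model.decoder(x, Tensor(trace.final_state[None, :]))
        assert np.allclose(h1.data, expected.data)

    def test_hhat_in_tanh_range(self, model, rng):
        study = StudyList(tuple(rng.permutation(10)[:5]))
        with ad.no_grad():
            enc = model.encode_batch(np.array([study.positions]))
            hhat, _, _ = model.decode_step(np.array([model.sos]), enc.final, enc)
        assert np.all(np.abs(hhat.data) < 1.0)


class TestGenerateRecall:
    def test_greedy_deterministic(self, model):
        study = StudyList((0, 3, 5, 7))
        r1 = model.generate_recall(study, mode="greedy", max_steps=6)
        r2 = model.generate_recall(study, mode="greedy", max_steps=6)
        assert r1.recall.outputs == r2.recall.outputs

    def test_seeded_sampling_reproducible(self, model):
        study = StudyList((0, 3, 5, 7))
        r1 = model.generate_recall(study, "sample", 6, np.random.default_rng(5))
        r2 = model.generate_recall(study, "sample", 6, np.random.default_rng(5))
        assert np.array_equal(r1.tokens, r2.tokens)

    def test_max_steps_one_emits_at_most_one(self, model):
        res = model.generate_recall(StudyList((0, 1)), mode="greedy", max_steps=1)
        assert len(res.tokens) <= 1

    def test_untrained_sampling_near_chance(self):
        # untrained in-list policy picks uniformly-ish among L+1 outcomes,
        # so studied-item recall runs at chance, far below perfect recall
        cfg = Seq2SeqConfig(hidden_dim=8, vocab_size=30, embed_dim=6, seed=9)
        m = build_model(cfg)
        rng = np.random.default_rng(17)
        n_correct, n_total = 0, 0
        for _ in range(300):
            study = StudyList(tuple(rng.permutation(30)[:5]))
            res = m.generate_recall(study, "sample", 6, rng)
            n_correct += len(set(res.recall.outputs) & set(study.positions))
            n_total += 1
        mean_correct = n_correct / n_total
        assert 0.5 < mean_correct < 4.0  # chance-like, not degenerate


class TestEquivalence:
    def test_equivalence_sweep(self, rng):
        # attention context == expected CMR reinstatement for matched probes
        for _ in range(100):
            N = int(rng.integers(4, 33))
            L = int(rng.integers(2, min(9, N)))
            study = StudyList(tuple(rng.permutation(N)[:L]))
            params = CMRParams(beta_enc=float(rng.uniform(0, 1)))
            state = encode_list(params, study, N=N)
            for k in (0.5, 1.0, 5.0):
                assert attention_equivalence_check(state, k) < 1e-9

    def test_k_zero_uniform_average(self, rng):
        study = StudyList((0, 2, 4))
        state = encode_list(CMRParams(beta_enc=0.5), study, N=6)
        assert attention_equivalence_check(state, 0.0) < 1e-12


class TestCheckpoints:
    def test_round_trip_bit_exact(self, tmp_path, model):
        study = StudyList((0, 3, 5))
        before = model.generate_recall(study, mode="greedy", max_steps=5)
        model.save_checkpoint(tmp_path / "ckpt", provenance={"step": 7})
        loaded = Seq2SeqModel.load_checkpoint(tmp_path / "ckpt")
        after = loaded.generate_recall(study, mode="greedy", max_steps=5)
        assert np.array_equal(before.step_distributions, after.step_distributions)
        for k in model.params.names():
            assert np.array_equal(model.params[k].data, loaded.params[k].data)

    def test_sidecar_preserves_config(self, tmp_path, cfg, model):
        model.save_checkpoint(tmp_path / "c")
        loaded = Seq2SeqModel.load_checkpoint(tmp_path / "c")
        assert loaded.config == cfg
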