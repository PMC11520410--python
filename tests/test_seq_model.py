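"""End-to-end network contracts: encoding toggles, decoder causality,
loss additivity, gradient flow, training determinism and checkpoints."""

import numpy as np
import pytest

from retrocap.nn import Tensor, no_grad
from retrocap.seq_model import (
    ABLATIONS, ModelConfig, RetrosynthesisModel, apply_ablation,
    build_sample, load_checkpoint, prepare_samples, train,
    vocabulary_from_reactions,
)


@pytest.fixture(scope="module")
def tiny_setup(small_reaction_set):
    rxns = [g.reaction for g in small_reaction_set[:10]]
    vocab = vocabulary_from_reactions(rxns)
    cfg = ModelConfig.small(dropout=0.0)
    samples = prepare_samples(rxns, vocab, cfg)
    return rxns, vocab, cfg, samples


@pytest.fixture(scope="module")
def tiny_model(tiny_setup):
    _, vocab, cfg, _ = tiny_setup
    model = RetrosynthesisModel(cfg, vocab, np.random.default_rng(3))
    model.set_training(False)
    return model


class TestEncoder:
    def test_single_token_sequence(self, tiny_model):
        H = tiny_model.uni_view_encode(np.array([5]))
        assert H.shape == (1, tiny_model.cfg.d_model)

    def test_pad_mask_leaves_real_positions_unchanged(self, tiny_setup):
        _, vocab, cfg, samples = tiny_setup
        model = RetrosynthesisModel(cfg, vocab, np.random.default_rng(4))
        model.set_training(False)
        ids = samples[0].src_ids
        H_plain = model.uni_view_encode(ids)
        padded = np.concatenate([ids, [vocab.pad_id] * 3])
        mask = np.array([True] * len(ids) + [False] * 3)
        H_padded = model.uni_view_encode(padded, pad_mask=mask)
        assert np.allclose(H_plain.data, H_padded.data[: len(ids)], atol=1e-9)

    def test_different_writings_give_different_embeddings(self, tiny_model, tiny_setup):
        _, vocab, _, _ = tiny_setup
        from retrocap.chem_io import tokenize
        a = np.asarray(vocab.encode(tokenize("CCO").tokens))
        b = np.asarray(vocab.encode(tokenize("OCC").tokens))
        Ha = tiny_model.uni_view_encode(a)
        Hb = tiny_model.uni_view_encode(b)
        assert not np.allclose(Ha.data, Hb.data)

    def test_sequence_too_long_raises(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.uni_view_encode(np.ones(500, dtype=np.intp))


class TestToggles:
    def test_ablation_table_has_four_variants(self):
        assert set(ABLATIONS) == {"transformer", "smiles-graph", "no-captioner", "full"}

    def test_no_graph_equals_plain_encoder(self, tiny_setup):
        """With the graph disabled, the dual stack degenerates to plain
        encoder layers and H must equal that plain output bitwise."""
        _, vocab, cfg, samples = tiny_setup
        cfg_t = apply_ablation(cfg, "transformer")
        model = RetrosynthesisModel(cfg_t, vocab, np.random.default_rng(5))
        model.set_training(False)
        enc = model.encode(samples[0].src_ids, None)
        H_s = model.uni_view_encode(samples[0].src_ids)
        z = model.dual_view_encode(H_s, None)
        assert np.array_equal(enc.H.data, z.data)

    @pytest.mark.parametrize("name", list(ABLATIONS))
    def test_every_variant_computes_a_loss(self, tiny_setup, name):
        rxns, vocab, cfg, _ = tiny_setup
        cfg_v = apply_ablation(cfg, name)
        samples = prepare_samples(rxns[:2], vocab, cfg_v)
        model = RetrosynthesisModel(cfg_v, vocab, np.random.default_rng(6))
        model.set_training(False)
        lb = model.total_loss(samples[0])
        assert np.isfinite(lb.to_floats()["total"])
        if not cfg_v.use_captioner:
            assert lb.to_floats()["captioner"] == 0.0
        if not cfg_v.use_graph:
            assert lb.to_floats()["cl"] == 0.0

    def test_single_node_graph_cross_attention_is_value_projection(self, tiny_setup):
        """Softmax over one key is 1, so every query position receives
        exactly that node's value vector."""
        rxns, vocab, cfg, _ = tiny_setup
        from retrocap.chem_io import parse_reaction
        rxn = parse_reaction("[CH4:1]>>[CH4:1]")
        sample = build_sample(rxn, vocab, cfg)
        model = RetrosynthesisModel(cfg, vocab, np.random.default_rng(7))
        model.set_training(False)
        layer = model.dual[0]
        with no_grad():
            enc0 = model.uni_view_encode(sample.src_ids)
            gemb, _ = model.graph_encoder(sample.graph)
            wg = model.captioner.caption_weights(gemb.H_g, enc0)
            out, _ = layer.cross(layer.ln_x(enc0), wg.H_w)
            v = layer.cross.wv(wg.H_w)
            per_head = v.data.reshape(1, layer.cross.heads, -1)
            merged = per_head.reshape(1, -1)
            expected = layer.cross.wo(Tensor(np.tile(merged, (enc0.shape[0], 1))))
        assert np.allclose(out.data, expected.data, atol=1e-9)


class TestDecoder:
    def test_step_logprobs_normalize(self, tiny_model, tiny_setup):
        _, _, _, samples = tiny_setup
        enc = tiny_model.encode(samples[0].src_ids, samples[0].graph)
        logp = tiny_model.decode_step(enc, np.array([tiny_model.vocab.bos_id]))
        assert np.exp(logp).sum() == pytest.approx(1.0)

    def test_causality_future_tokens_do_not_leak(self, tiny_model, tiny_setup):
        _, vocab, _, samples = tiny_setup
        enc = tiny_model.encode(samples[0].src_ids, samples[0].graph)
        prefix = np.array([vocab.bos_id, 8, 9, 10], dtype=np.intp)
        logits1, _ = tiny_model.decode(enc, prefix)
        altered = prefix.copy()
        altered[3] = 11
        logits2, _ = tiny_model.decode(enc, altered)
        assert np.allclose(logits1.data[:3], logits2.data[:3], atol=1e-12)


class TestLosses:
    def test_total_is_sum_of_parts(self, tiny_setup):
        _, vocab, cfg, samples = tiny_setup
        model = RetrosynthesisModel(cfg, vocab, np.random.default_rng(8))
        model.set_training(False)
        lb = model.total_loss(samples[0])
        parts = lb.to_floats()
        assert parts["total"] == pytest.approx(
            parts["lm"] + parts["ag"] + parts["cl"] + parts["captioner"], abs=1e-6)

    def test_alignment_loss_uniform_attention_is_log_L(self, tiny_model):
        L = 8
        attn = Tensor(np.full((5, L), 1.0 / L))
        pairs = [(1, 2), (2, 3), (3, 0)]
        loss = tiny_model.alignment_loss([attn], pairs)
        assert float(loss.data) == pytest.approx(np.log(L), abs=1e-9)

    def test_alignment_loss_one_hot_attention_is_zero(self, tiny_model):
        attn = np.full((4, 6), 1e-12)
        pairs = [(0, 1), (2, 4)]
        for t, s in pairs:
            attn[t, s] = 1.0
        loss = tiny_model.alignment_loss([Tensor(attn)], pairs)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-6)

    def test_alignment_loss_hand_case(self, tiny_model):
        attn = Tensor(np.array([[0.5, 0.3, 0.2],
                                [0.1, 0.8, 0.1],
                                [0.25, 0.25, 0.5]]))
        pairs = [(0, 0), (1, 1), (2, 2)]
        expected = -(np.log(0.5) + np.log(0.8) + np.log(0.5)) / 3
        assert float(tiny_model.alignment_loss([attn], pairs).data) == \
            pytest.approx(expected, abs=1e-9)

    def test_empty_alignment_returns_zero(self, tiny_model):
        assert float(tiny_model.alignment_loss([], []).data) == 0.0

    def test_gradient_reaches_graph_encoder(self, tiny_setup):
        """Generative feedback must backpropagate into the graph encoder."""
        _, vocab, cfg, samples = tiny_setup
        model = RetrosynthesisModel(cfg, vocab, np.random.default_rng(9))
        model.set_training(False)
        model.zero_grad()
        model.total_loss(samples[0]).total.backward()
        g = model.graph_encoder.node_init.fc1.weight.grad
        assert g is not None and np.abs(g).max() > 0


class TestTraining:
    def test_loss_decreases_on_smoke_fixture(self, tiny_setup):
        _, vocab, cfg, samples = tiny_setup
        hist = []
        train(samples, cfg, vocab, seed=11, epochs=3, batch_size=2,
              callback=lambda e, m, _: hist.append(m["total"]))
        assert hist[-1] < hist[0]

    def test_same_seed_identical_checkpoints(self, tiny_setup, tmp_path):
        _, vocab, cfg, samples = tiny_setup
        m1 = train(samples[:4], cfg, vocab, seed=21, epochs=2, batch_size=2)
        m2 = train(samples[:4], cfg, vocab, seed=21, epochs=2, batch_size=2)
        s1, s2 = m1.state_dict(), m2.state_dict()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)

    def test_checkpoint_roundtrip_and_resume(self, tiny_setup, tmp_path):
        _, vocab, cfg0, samples = tiny_setup
        cfg = ModelConfig.from_dict(cfg0.to_dict())
        cfg.ema_decay = 0.0   # resume must continue the exact same weights
        out = tmp_path / "ckpt"
        train(samples[:4], cfg, vocab, seed=31, epochs=2, batch_size=2,
              out_dir=out)
        model, _, epoch, _ = load_checkpoint(out)
        assert epoch == 2
        hist_resumed = []
        train(samples[:4], cfg, vocab, seed=31, epochs=1, batch_size=2,
              resume_from=out,
              callback=lambda e, m, _: hist_resumed.append((e, m["total"])))
        hist_full = []
        train(samples[:4], cfg, vocab, seed=31, epochs=3, batch_size=2,
              callback=lambda e, m, _: hist_full.append((e, m["total"])))
        # identical third-epoch loss whether resumed or uninterrupted:
        # optimizer moments, LR-schedule position and shuffling RNG are all
        # restored from the checkpoint
        assert hist_resumed[0][0] == 2
        assert hist_resumed[0][1] == pytest.approx(hist_full[2][1], abs=1e-12)

    def test_divergence_aborts(self, tiny_setup, monkeypatch):
        """A non-finite loss must abort training with diagnostics."""
        _, vocab, cfg, samples = tiny_setup
        original = RetrosynthesisModel.total_loss

        def poisoned(self, sample):
            lb = original(self, sample)
            lb.total.data = np.array(np.nan)
            return lb

        monkeypatch.setattr(RetrosynthesisModel, "total_loss", poisoned)
        with pytest.raises(FloatingPointError, match="diverged"):
            train(samples[:2], cfg, vocab, seed=41, epochs=1, batch_size=1)


class TestSamplePreparation:
    def test_alignment_pairs_cover_mapped_atoms(self, small_reaction_set, tiny_setup):
        _, vocab, cfg, _ = tiny_setup
        gen = small_reaction_set[0]
        sample = build_sample(gen.reaction, vocab, cfg)
        assert len(sample.align_pairs) == len(gen.reaction.atom_map)
        L_src = len(sample.src_ids)
        T = len(sample.tgt_ids) + 1
        for t, s in sample.align_pairs:
            assert 0 <= s < L_src
            assert 1 <= t < T + 1

    def test_augmented_samples_share_canonical_product(self, tiny_setup):
        rxns, vocab, cfg, _ = tiny_setup
        samples = prepare_samples(rxns[:3], vocab, cfg, augment=2, seed=7)
        assert len(samples) > 3
        from retrocap.chem_io import canonicalize
        for i in range(0, len(samples)):
            assert canonicalize(samples[i].product) == samples[i].product

    def test_labels_follow_rewritten_atom_order(self, small_reaction_set, tiny_setup):
        """RC labels re-indexed into the rooted writing must still mark a
        single bond with both endpoints."""
        _, vocab, cfg, _ = tiny_setup
        gen = small_reaction_set[1]
        for root in range(min(3, gen.reaction.product.num_atoms)):
            s = build_sample(gen.reaction, vocab, cfg, product_root=root)
            assert s.labels.bond_labels.sum() == 1
            assert s.labels.atom_labels.sum() == 2
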