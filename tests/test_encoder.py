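"""Encoder stack: masking, forward contracts, training behaviour, embeddings."""

import copy

import numpy as np
import pytest

from ehrclust.encoder import (
    Batch,
    EHRDebertaEmbedder,
    ModelConfig,
    collate,
    contrastive_loss,
    diffcse_finetune,
    dynamic_mask,
    embed_patients,
    init_model,
    load_checkpoint,
    rtd_pretrain,
    save_checkpoint,
    token_embeddings,
)
from ehrclust import nn
from ehrclust.sequences import SPECIAL_TOKENS, TokenSequence, Vocabulary


def make_vocab(n_tokens=10):
    tokens = {t: i for i, t in enumerate(SPECIAL_TOKENS)}
    for j in range(n_tokens):
        tokens[f"T{j:02d}"] = len(tokens)
    return Vocabulary(tokens, {t: 100 for t in tokens}, min_patient_count=1)


def make_sequences(vocab, n=20, length=8, seed=0, gender="female"):
    rng = np.random.default_rng(seed)
    nonspecial = [vocab.token_to_id[t] for t in vocab.nonspecial_tokens()]
    seqs = []
    for i in range(n):
        toks = rng.choice(nonspecial, size=length).tolist()
        ages = sorted(rng.integers(50, 90, size=length).tolist())
        seqs.append(
            TokenSequence(
                patient_id=f"p{i}",
                gender=gender,
                token_ids=toks,
                age_years=ages,
                calendar_year=[2000 + a - 50 for a in ages],
                visit_number=list(range(1, length + 1)),
            )
        )
    return seqs


def small_config(vocab, **kw):
    defaults = dict(
        vocab_size=len(vocab),
        hidden_size=16,
        attention_heads=2,
        discriminator_layers=2,
        generator_layers=1,
        pretrain_epochs=2,
        diffcse_epochs=2,
        batch_size=16,
        seed=0,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestModelConfig:
    def test_heads_must_divide_hidden_size(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(vocab_size=20, hidden_size=10, attention_heads=3)

    def test_mask_rate_bounds(self):
        with pytest.raises(ValueError):
            ModelConfig(vocab_size=20, mask_rate=0.0)
        with pytest.raises(ValueError):
            ModelConfig(vocab_size=20, mask_rate=1.0)

    def test_generator_not_deeper_than_discriminator(self):
        with pytest.raises(ValueError):
            ModelConfig(vocab_size=20, generator_layers=4, discriminator_layers=2)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(vocab_size=20, diffcse_lambda=-0.1)


class TestInitAndForward:
    def test_same_seed_gives_identical_initial_parameters(self):
        vocab = make_vocab()
        cfg = small_config(vocab)
        g1, d1 = init_model(cfg)
        g2, d2 = init_model(cfg)
        for a, b in zip(g1.params(), g2.params()):
            assert np.array_equal(a.data, b.data)
        for a, b in zip(d1.params(), d2.params()):
            assert np.array_equal(a.data, b.data)

    def test_forward_shape_contract(self):
        vocab = make_vocab()
        cfg = small_config(vocab, max_len=64)
        seqs = make_sequences(vocab, n=3, length=64)
        gen, _ = init_model(cfg)
        batch = collate(seqs, vocab, cfg)
        hidden = gen.forward(batch)
        # per-token states for all 64 events plus the leading CLS position
        assert hidden.shape == (3, 65, cfg.hidden_size)
        assert np.isfinite(hidden.data).all()

    def test_discriminator_token_table_is_gradient_disentangled(self):
        vocab = make_vocab()
        cfg = small_config(vocab)
        gen, disc = init_model(cfg)
        seqs = make_sequences(vocab, n=4, length=6)
        batch = collate(seqs, vocab, cfg)
        out = disc.rtd_logits(disc.forward(batch)).sum()
        out.backward()
        # shared generator table receives no gradient through the discriminator
        assert gen.emb.tok.grad is None
        assert disc.emb.tok.grad is not None


class TestDynamicMask:
    def test_rate_zero_rejected(self):
        vocab = make_vocab()
        cfg = small_config(vocab)
        batch = collate(make_sequences(vocab, n=2), vocab, cfg)
        with pytest.raises(ValueError):
            dynamic_mask(batch, rate=0.0, rng=np.random.default_rng(0))

    def test_mean_masked_fraction_near_rate(self):
        vocab = make_vocab()
        cfg = small_config(vocab, max_len=64)
        seqs = make_sequences(vocab, n=2000, length=64, seed=1)
        batch = collate(seqs, vocab, cfg)
        sel = dynamic_mask(batch, rate=0.15, rng=np.random.default_rng(2))
        frac = sel.sum() / batch.maskable.sum()
        se = np.sqrt(0.15 * 0.85 / batch.maskable.sum())
        assert abs(frac - 0.15) < 3 * se

    def test_length_one_sequence_gets_its_position_masked(self):
        vocab = make_vocab()
        cfg = small_config(vocab)
        seqs = make_sequences(vocab, n=5, length=1, seed=3)
        batch = collate(seqs, vocab, cfg)
        sel = dynamic_mask(batch, rate=0.15, rng=np.random.default_rng(4))
        assert (sel.sum(axis=1) == 1).all()

    def test_masking_never_touches_special_positions(self):
        vocab = make_vocab()
        cfg = small_config(vocab)
        seqs = make_sequences(vocab, n=10, length=5, seed=5)
        batch = collate(seqs, vocab, cfg)
        for trial in range(20):
            sel = dynamic_mask(batch, rate=0.5, rng=np.random.default_rng(trial))
            assert not sel[:, 0].any()  # CLS
            assert not sel[~batch.maskable].any()  # PAD and any special ids


class TestRTDPretraining:
    def test_empty_corpus_rejected(self):
        vocab = make_vocab()
        with pytest.raises(ValueError):
            rtd_pretrain([], vocab, small_config(vocab))

    def test_loss_improves_on_tiny_corpus(self):
        vocab = make_vocab()
        cfg = small_config(vocab, pretrain_epochs=4)
        seqs = make_sequences(vocab, n=40, length=8, seed=6)
        _, _, report = rtd_pretrain(seqs, vocab, cfg)
        assert report.total_loss[-1] < report.total_loss[0]

    def test_uncorrupted_batch_labels_are_all_original(self):
        # replaced labels derive from corrupted != original; with no
        # corruption every label is "original" and the loss equals BCE
        # against the all-original labelling by construction
        vocab = make_vocab()
        cfg = small_config(vocab)
        seqs = make_sequences(vocab, n=4, length=6)
        batch = collate(seqs, vocab, cfg)
        corrupted = batch.token_ids.copy()
        replaced = (corrupted != batch.token_ids).astype(float)
        assert not replaced.any()
        _, disc = init_model(cfg)
        logits = disc.rtd_logits(disc.forward(batch))
        event_pos = batch.pad_mask.copy()
        event_pos[:, 0] = False
        loss = nn.binary_cross_entropy_with_logits(
            logits, replaced, weights=event_pos.astype(float)
        )
        expected = nn.binary_cross_entropy_with_logits(
            logits, np.zeros_like(replaced), weights=event_pos.astype(float)
        )
        assert np.isclose(float(loss.data), float(expected.data))

    def test_generator_beats_majority_class_on_two_token_vocabulary(self):
        vocab = make_vocab(n_tokens=2)
        cfg = small_config(vocab, pretrain_epochs=6)
        rng = np.random.default_rng(7)
        ids = [vocab.token_to_id[t] for t in vocab.nonspecial_tokens()]
        # 70/30 token mix: majority-class accuracy baseline is 0.7
        seqs = []
        for i in range(60):
            toks = rng.choice(ids, size=8, p=[0.7, 0.3]).tolist()
            ages = sorted(rng.integers(50, 80, size=8).tolist())
            seqs.append(
                TokenSequence(
                    patient_id=f"p{i}", gender="male", token_ids=toks,
                    age_years=ages, calendar_year=[2010] * 8,
                    visit_number=list(range(1, 9)),
                )
            )
        gen, _, _ = rtd_pretrain(seqs, vocab, cfg)
        batch = collate(seqs, vocab, cfg)
        sel = dynamic_mask(batch, 0.15, np.random.default_rng(8))
        masked = batch.token_ids.copy()
        masked[sel] = vocab.mask_id
        mb = Batch(masked, batch.age, batch.year, batch.visit, batch.gender,
                   batch.pad_mask, batch.maskable)
        logits = gen.lm_logits(gen.forward(mb)).data
        pred = logits[sel].argmax(axis=-1)
        acc = (pred == batch.token_ids[sel]).mean()
        assert acc >= 0.7 - 0.1  # approaches or beats the majority baseline


class TestDiffCSE:
    def test_negative_lambda_rejected(self):
        vocab = make_vocab()
        cfg = small_config(vocab)
        gen, _ = init_model(cfg)
        with pytest.raises(ValueError):
            diffcse_finetune(gen, make_sequences(vocab), vocab, lambda_=-1.0)

    def test_lambda_zero_reduces_to_pure_contrastive(self):
        vocab = make_vocab()
        cfg = small_config(vocab)
        seqs = make_sequences(vocab, n=24, length=6, seed=9)
        gen, _ = init_model(cfg)
        _, report = diffcse_finetune(gen, seqs, vocab, lambda_=0.0, epochs=2, seed=1)
        # total loss trace equals the contrastive component exactly
        assert np.allclose(report.total_loss, report.generator_loss)

    def test_duplicate_sequences_have_maximal_view_similarity(self):
        vocab = make_vocab()
        cfg = small_config(vocab)
        seqs = make_sequences(vocab, n=6, length=6, seed=10)
        seqs[1] = TokenSequence(
            patient_id="dup", gender=seqs[0].gender,
            token_ids=list(seqs[0].token_ids), age_years=list(seqs[0].age_years),
            calendar_year=list(seqs[0].calendar_year),
            visit_number=list(seqs[0].visit_number),
        )
        gen, _ = init_model(cfg)
        _, emb = embed_patients(gen, seqs, vocab)
        unit = emb / np.linalg.norm(emb, axis=1, keepdims=True)
        sim = unit @ unit.T
        # the duplicate pair is the most similar off-diagonal pair
        off = sim - np.eye(len(seqs)) * 10
        assert np.unravel_index(off.argmax(), off.shape) in [(0, 1), (1, 0)]
        assert np.isclose(off[0, 1], 1.0)

    def test_loss_decreases_over_epochs(self):
        vocab = make_vocab()
        cfg = small_config(vocab)
        seqs = make_sequences(vocab, n=32, length=6, seed=11)
        gen, _ = init_model(cfg)
        _, report = diffcse_finetune(gen, seqs, vocab, epochs=5, seed=2)
        assert report.total_loss[-1] <= report.total_loss[0]

    def test_contrastive_loss_matches_manual_computation(self, rng):
        z1 = nn.Tensor(rng.normal(size=(4, 8)))
        z2 = nn.Tensor(rng.normal(size=(4, 8)))
        t = 0.05
        a = z1.data / np.linalg.norm(z1.data, axis=1, keepdims=True)
        b = z2.data / np.linalg.norm(z2.data, axis=1, keepdims=True)
        sim = a @ b.T / t
        log_probs = sim - np.log(np.exp(sim).sum(axis=1, keepdims=True))
        expected = -np.mean(np.diag(log_probs))
        assert np.isclose(float(contrastive_loss(z1, z2, t).data), expected)


class TestEmbeddings:
    def test_embedding_determinism_and_row_count(self):
        vocab = make_vocab()
        cfg = small_config(vocab)
        seqs = make_sequences(vocab, n=7, length=5, seed=12)
        gen, _ = init_model(cfg)
        ids1, e1 = embed_patients(gen, seqs, vocab)
        ids2, e2 = embed_patients(gen, seqs, vocab)
        assert ids1 == ids2 == [s.patient_id for s in seqs]
        assert e1.shape == (7, cfg.hidden_size)
        assert np.array_equal(e1, e2)

    def test_empty_sequences_are_skipped(self):
        vocab = make_vocab()
        cfg = small_config(vocab)
        seqs = make_sequences(vocab, n=3, length=5, seed=13)
        seqs.append(
            TokenSequence(
                patient_id="empty", gender="female", token_ids=[],
                age_years=[], calendar_year=[], visit_number=[],
            )
        )
        gen, _ = init_model(cfg)
        ids, emb = embed_patients(gen, seqs, vocab)
        assert "empty" not in ids and emb.shape[0] == 3

    def test_gender_channel_changes_the_embedding(self):
        vocab = make_vocab()
        cfg = small_config(vocab)
        f = make_sequences(vocab, n=1, length=5, seed=14, gender="female")[0]
        m = TokenSequence(
            patient_id="m", gender="male", token_ids=list(f.token_ids),
            age_years=list(f.age_years), calendar_year=list(f.calendar_year),
            visit_number=list(f.visit_number),
        )
        gen, _ = init_model(cfg)
        _, emb = embed_patients(gen, [f, m], vocab)
        assert not np.allclose(emb[0], emb[1])

    def test_token_embeddings_cover_vocabulary(self):
        vocab = make_vocab(n_tokens=9)
        cfg = small_config(vocab)
        gen, _ = init_model(cfg)
        tokens, vecs = token_embeddings(gen, vocab)
        assert len(tokens) == 9 and vecs.shape == (9, cfg.hidden_size)
        unit = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
        assert np.allclose(np.sum(unit * unit, axis=1), 1.0)  # self-cosine is 1

    def test_checkpoint_roundtrip(self, tmp_path):
        vocab = make_vocab()
        cfg = small_config(vocab)
        gen, _ = init_model(cfg)
        seqs = make_sequences(vocab, n=4, length=5, seed=15)
        _, before = embed_patients(gen, seqs, vocab)
        save_checkpoint(gen, vocab, tmp_path / "ck.npz")
        loaded, vocab2 = load_checkpoint(tmp_path / "ck.npz")
        _, after = embed_patients(loaded, seqs, vocab2)
        assert np.allclose(before, after)


def test_estimator_fit_transform_interface(small_sequences, tiny_model_config):
    seqs, vocab = small_sequences
    sub = [s for s in seqs if not s.is_empty][:40]
    est = EHRDebertaEmbedder(vocab=vocab, config=tiny_model_config)
    emb = est.fit_transform(sub)
    assert emb.shape == (len(sub), tiny_model_config.hidden_size)
    assert np.isfinite(emb).all()
    params = est.get_params()
    assert "vocab" in params and "config" in params
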