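"""Covariate-aware disentangled-attention encoder for EHR token sequences.

The encoder reads a patient's chronological token sequence together with four
paired covariate channels (age at event, calendar year, gender, visit
number), each contributing its own embedding to the input representation.
Attention is disentangled: each position is represented by separate content
and relative-position vectors, and the attention score sums content-content,
content-to-position and position-to-content terms; absolute position
embeddings are additionally added at the input.

Training follows a two-stage recipe:

1. Replaced-token detection (RTD) pretraining: a small generator predicts
   dynamically masked events (15% masking rate, re-drawn every epoch); its
   sampled predictions corrupt the sequence, and a discriminator classifies
   every position as original or replaced.  Both models train jointly and the
   discriminator's token table is gradient-disentangled from the generator's
   (it sees the shared table as a constant and learns an additive delta).
2. Difference-based contrastive fine-tuning of the pretrained generator: two
   dropout views of each sequence are pulled together against in-batch
   negatives (temperature-scaled cosine similarity), plus a lambda-weighted
   conditional replaced-token-detection term on generator-edited sequences,
   which keeps the embedding sensitive to edits that change the trajectory.

Patient embeddings are the mean of the final hidden states over real event
positions (padding and the leading CLS position excluded), computed in
evaluation mode (no dropout), one vector per patient.  Mean pooling keeps
the patient vector anchored to the event content; a single pooled position
is much more easily dominated by the sequence-level covariate embeddings at
small hidden sizes.
"""

from __future__ import annotations

import copy
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ehrclust import nn
from ehrclust.nn import Tensor
from ehrclust.sequences import TokenSequence, Vocabulary

logger = logging.getLogger(__name__)

_GENDER_IDX = {"female": 0, "male": 1}


@dataclass
class ModelConfig:
    """Encoder and training hyperparameters.

    Defaults are desk-scale (hidden 64, 2 discriminator + 1 generator
    layers) so the full pipeline runs on one CPU in minutes; see
    :func:`paper_scale_config` for the published configuration (hidden 768,
    6 + 3 layers, 100 pretraining epochs), which is documented but far
    beyond desk-scale budgets.
    """

    vocab_size: int
    hidden_size: int = 64
    discriminator_layers: int = 2
    generator_layers: int = 1
    attention_heads: int = 2
    max_len: int = 64
    max_age: int = 110
    year_min: int = 1900
    year_max: int = 2035
    visit_cap: int = 512
    max_relative_positions: int = 16
    ffn_multiplier: int = 2
    dropout: float = 0.1
    mask_rate: float = 0.15
    rtd_loss_weight: float = 50.0
    pretrain_epochs: int = 20
    diffcse_temperature: float = 0.05
    diffcse_lambda: float = 0.005
    diffcse_epochs: int = 5
    batch_size: int = 32
    learning_rate: float = 1e-3
    finetune_learning_rate: float = 2e-4  # fine-tuning uses a reduced step size
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mask_rate < 1.0:
            raise ValueError("mask_rate must be in (0, 1)")
        if self.hidden_size % self.attention_heads != 0:
            raise ValueError("hidden_size must be divisible by attention_heads")
        if self.generator_layers > self.discriminator_layers:
            raise ValueError("generator_layers must be <= discriminator_layers")
        if self.diffcse_lambda < 0:
            raise ValueError("diffcse_lambda must be >= 0")
        if self.vocab_size < 6:
            raise ValueError("vocab_size must include the 5 special tokens")

    @property
    def n_years(self) -> int:
        return self.year_max - self.year_min + 1


def paper_scale_config(vocab_size: int) -> ModelConfig:
    """The published configuration: not exercised by the test suite."""
    return ModelConfig(
        vocab_size=vocab_size,
        hidden_size=768,
        discriminator_layers=6,
        generator_layers=3,
        attention_heads=12,
        pretrain_epochs=100,
        batch_size=256,
    )


# ---------------------------------------------------------------------------
# Batching


@dataclass
class Batch:
    """Padded numpy arrays for one minibatch (CLS prepended at position 0)."""

    token_ids: np.ndarray  # (B, L) int
    age: np.ndarray  # (B, L) int
    year: np.ndarray  # (B, L) int
    visit: np.ndarray  # (B, L) int
    gender: np.ndarray  # (B,) int
    pad_mask: np.ndarray  # (B, L) bool, True at real positions
    maskable: np.ndarray  # (B, L) bool, True where masking is allowed

    @property
    def n(self) -> int:
        return self.token_ids.shape[0]

    @property
    def length(self) -> int:
        return self.token_ids.shape[1]


def collate(seqs: Sequence[TokenSequence], vocab: Vocabulary, config: ModelConfig) -> Batch:
    """Pad sequences to a common length and prepend the CLS position."""
    if not seqs:
        raise ValueError("cannot collate an empty list of sequences")
    L = 1 + min(max(len(s) for s in seqs), config.max_len)
    B = len(seqs)
    ids = np.full((B, L), vocab.pad_id, dtype=np.int64)
    age = np.zeros((B, L), dtype=np.int64)
    year = np.zeros((B, L), dtype=np.int64)
    visit = np.zeros((B, L), dtype=np.int64)
    gender = np.zeros(B, dtype=np.int64)
    pad = np.zeros((B, L), dtype=bool)
    special = vocab.special_ids
    maskable = np.zeros((B, L), dtype=bool)
    for b, s in enumerate(seqs):
        toks = s.token_ids[-config.max_len :]
        ages = s.age_years[-config.max_len :]
        yrs = s.calendar_year[-config.max_len :]
        vis = s.visit_number[-config.max_len :]
        n = len(toks)
        ids[b, 0] = vocab.cls_id
        ids[b, 1 : n + 1] = toks
        a0 = ages[0] if ages else 0
        age[b, 0] = min(max(a0, 0), config.max_age)
        age[b, 1 : n + 1] = np.clip(ages, 0, config.max_age)
        y0 = yrs[0] if yrs else config.year_min
        year[b, 0] = np.clip(y0 - config.year_min, 0, config.n_years - 1)
        year[b, 1 : n + 1] = np.clip(np.asarray(yrs) - config.year_min, 0, config.n_years - 1)
        visit[b, 0] = 0
        visit[b, 1 : n + 1] = np.clip(vis, 0, config.visit_cap)
        gender[b] = _GENDER_IDX[s.gender]
        pad[b, : n + 1] = True
        maskable[b, 1 : n + 1] = [t not in special for t in toks]
    return Batch(ids, age, year, visit, gender, pad, maskable)


# ---------------------------------------------------------------------------
# Model components


class _InputEmbedding:
    """Sum of token, age, year, gender, visit and absolute-position embeddings."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        H = config.hidden_size
        self.config = config
        self.tok = nn.parameter(rng, config.vocab_size, H)
        self.age = nn.parameter(rng, config.max_age + 1, H)
        self.year = nn.parameter(rng, config.n_years, H)
        self.gender = nn.parameter(rng, 2, H)
        self.visit = nn.parameter(rng, config.visit_cap + 1, H)
        self.pos = nn.parameter(rng, config.max_len + 1, H)
        self.ln_g = nn.ones(H)
        self.ln_b = nn.zeros(H)
        # Gradient-disentangled sharing: when `shared_tok` is set (the
        # discriminator case) the shared table enters as a constant and
        # `tok` acts as a trainable additive delta on top of it.
        self.shared_tok: Tensor | None = None

    def named_params(self, prefix: str = "") -> dict[str, Tensor]:
        return {
            f"{prefix}{k}": v
            for k, v in vars(self).items()
            if isinstance(v, Tensor) and v.requires_grad
        }

    def token_table(self) -> Tensor:
        if self.shared_tok is None:
            return self.tok
        return Tensor(self.shared_tok.data) + self.tok

    def forward(self, batch: Batch, rng: np.random.Generator | None) -> Tensor:
        L = batch.length
        tok_part = nn.embedding(self.tok, batch.token_ids)
        if self.shared_tok is not None:
            tok_part = tok_part + Tensor(self.shared_tok.data[batch.token_ids])
        h = (
            tok_part
            + nn.embedding(self.age, batch.age)
            + nn.embedding(self.year, batch.year)
            + nn.embedding(self.gender, batch.gender).reshape(batch.n, 1, -1)
            + nn.embedding(self.visit, batch.visit)
            + nn.embedding(self.pos, np.arange(L))
        )
        h = nn.layer_norm(h, self.ln_g, self.ln_b)
        return nn.dropout(h, self.config.dropout, rng)


class _EncoderLayer:
    """Disentangled self-attention plus feed-forward, post-layernorm residuals."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        H = config.hidden_size
        F = H * config.ffn_multiplier
        self.config = config
        self.Wq = nn.parameter(rng, H, H)
        self.Wk = nn.parameter(rng, H, H)
        self.Wv = nn.parameter(rng, H, H)
        self.Wo = nn.parameter(rng, H, H)
        self.bq, self.bk, self.bv, self.bo = (nn.zeros(H) for _ in range(4))
        self.Wqr = nn.parameter(rng, H, H)  # position->content projection
        self.Wkr = nn.parameter(rng, H, H)  # content->position projection
        self.ln1_g, self.ln1_b = nn.ones(H), nn.zeros(H)
        self.W1 = nn.parameter(rng, H, F)
        self.b1 = nn.zeros(F)
        self.W2 = nn.parameter(rng, F, H)
        self.b2 = nn.zeros(H)
        self.ln2_g, self.ln2_b = nn.ones(H), nn.zeros(H)

    def named_params(self, prefix: str = "") -> dict[str, Tensor]:
        return {
            f"{prefix}{k}": v
            for k, v in vars(self).items()
            if isinstance(v, Tensor) and v.requires_grad
        }

    def _heads(self, x: Tensor, B: int, L: int) -> Tensor:
        nh = self.config.attention_heads
        dh = self.config.hidden_size // nh
        return x.reshape(B, L, nh, dh).transpose(0, 2, 1, 3)

    def forward(
        self,
        h: Tensor,
        rel_emb: Tensor,
        rel_idx: np.ndarray,
        pad_mask: np.ndarray,
        rng: np.random.Generator | None,
    ) -> Tensor:
        cfg = self.config
        B, L = pad_mask.shape
        nh = cfg.attention_heads
        dh = cfg.hidden_size // nh

        q = self._heads(h @ self.Wq + self.bq, B, L)
        k = self._heads(h @ self.Wk + self.bk, B, L)
        v = self._heads(h @ self.Wv + self.bv, B, L)

        scores = q @ k.swapaxes(-1, -2)  # content -> content

        # Relative-position terms: rel_emb is (R, H) over clipped offsets.
        R = rel_emb.shape[0]
        r_k = (rel_emb @ self.Wkr).reshape(R, nh, dh).transpose(1, 2, 0)  # (nh, dh, R)
        r_q = (rel_emb @ self.Wqr).reshape(R, nh, dh).transpose(1, 2, 0)
        c2p = nn.gather_last(q @ r_k, rel_idx)  # A[i,j] += Qc[i] . Kr[d(i,j)]
        p2c = nn.gather_last(k @ r_q, rel_idx).swapaxes(-1, -2)  # Kc[j] . Qr[d(j,i)]
        scores = (scores + c2p + p2c) * (1.0 / math.sqrt(3.0 * dh))

        bias = np.where(pad_mask, 0.0, -1e9)[:, None, None, :]
        attn = nn.softmax(scores + Tensor(bias), axis=-1)
        attn = nn.dropout(attn, cfg.dropout, rng)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, cfg.hidden_size)
        out = nn.dropout(ctx @ self.Wo + self.bo, cfg.dropout, rng)
        h = nn.layer_norm(h + out, self.ln1_g, self.ln1_b)

        ffn = nn.gelu(h @ self.W1 + self.b1) @ self.W2 + self.b2
        ffn = nn.dropout(ffn, cfg.dropout, rng)
        return nn.layer_norm(h + ffn, self.ln2_g, self.ln2_b)


class DebertaEncoder:
    """Stack of input embeddings and disentangled-attention layers."""

    def __init__(
        self,
        config: ModelConfig,
        n_layers: int,
        rng: np.random.Generator,
        shared_tok: Tensor | None = None,
    ):
        self.config = config
        self.emb = _InputEmbedding(config, rng)
        self.emb.shared_tok = shared_tok
        k = config.max_relative_positions
        self.rel_emb = nn.parameter(rng, 2 * k + 1, config.hidden_size)
        self.layers = [_EncoderLayer(config, rng) for _ in range(n_layers)]

    def named_params(self) -> dict[str, Tensor]:
        params = self.emb.named_params("emb.")
        params["rel_emb"] = self.rel_emb
        for i, layer in enumerate(self.layers):
            params.update(layer.named_params(f"layer{i}."))
        return params

    def params(self) -> list[Tensor]:
        return list(self.named_params().values())

    def _rel_index(self, L: int) -> np.ndarray:
        k = self.config.max_relative_positions
        i = np.arange(L)
        return np.clip(i[:, None] - i[None, :], -k, k) + k

    def forward(self, batch: Batch, rng: np.random.Generator | None = None) -> Tensor:
        """Per-position hidden states of shape (B, L, hidden); L includes CLS."""
        h = self.emb.forward(batch, rng)
        rel_idx = self._rel_index(batch.length)
        for layer in self.layers:
            h = layer.forward(h, self.rel_emb, rel_idx, batch.pad_mask, rng)
        return h


class Generator(DebertaEncoder):
    """Masked-event predictor; its input token table is the shared table."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__(config, config.generator_layers, rng)
        self.lm_bias = nn.zeros(config.vocab_size)

    def named_params(self) -> dict[str, Tensor]:
        p = super().named_params()
        p["lm_bias"] = self.lm_bias
        return p

    def lm_logits(self, hidden: Tensor) -> Tensor:
        """Tied-embedding LM head: hidden (B, L, H) -> logits (B, L, V)."""
        return hidden @ self.emb.tok.transpose(1, 0) + self.lm_bias


class Discriminator(DebertaEncoder):
    """Original-vs-replaced classifier with gradient-disentangled token table."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator, shared_tok: Tensor):
        super().__init__(config, config.discriminator_layers, rng, shared_tok=shared_tok)
        self.head_w = nn.parameter(rng, config.hidden_size, 1)
        self.head_b = nn.zeros(1)

    def named_params(self) -> dict[str, Tensor]:
        p = super().named_params()
        p["head_w"] = self.head_w
        p["head_b"] = self.head_b
        return p

    def rtd_logits(self, hidden: Tensor) -> Tensor:
        B, L, _ = hidden.shape
        return (hidden @ self.head_w + self.head_b).reshape(B, L)


def init_model(config: ModelConfig) -> tuple[Generator, Discriminator]:
    """Seeded initialisation of the generator/discriminator pair."""
    rng = np.random.default_rng(config.seed)
    generator = Generator(config, rng)
    discriminator = Discriminator(config, rng, shared_tok=generator.emb.tok)
    return generator, discriminator


# ---------------------------------------------------------------------------
# Dynamic masking


def dynamic_mask(
    batch: Batch, rate: float = 0.15, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Independent per-position masking, re-drawn on every call.

    Each maskable (non-special, non-pad) position is selected with
    probability ``rate``; every sequence with at least one maskable position
    gets at least one mask.  Returns a boolean (B, L) selection array.
    """
    if not 0.0 < rate < 1.0:
        raise ValueError("masking rate must be in (0, 1)")
    rng = rng if rng is not None else np.random.default_rng()
    sel = (rng.random(batch.token_ids.shape) < rate) & batch.maskable
    for b in range(batch.n):
        if not sel[b].any() and batch.maskable[b].any():
            choices = np.flatnonzero(batch.maskable[b])
            sel[b, rng.choice(choices)] = True
    return sel


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainingReport:
    """Per-epoch loss traces."""

    total_loss: list[float] = field(default_factory=list)
    generator_loss: list[float] = field(default_factory=list)
    discriminator_loss: list[float] = field(default_factory=list)

    @property
    def improved(self) -> bool:
        return len(self.total_loss) >= 2 and self.total_loss[-1] < self.total_loss[0]


def _iter_batches(
    order: np.ndarray, seqs: list[TokenSequence], batch_size: int
) -> list[list[TokenSequence]]:
    return [
        [seqs[i] for i in order[start : start + batch_size]]
        for start in range(0, len(order), batch_size)
    ]


def _sample_replacements(
    logits: np.ndarray, rng: np.random.Generator, special_ids: frozenset[int]
) -> np.ndarray:
    """Categorical sampling from generator softmax (temperature 1)."""
    logits = logits.copy()
    logits[:, list(special_ids)] = -1e9  # never corrupt with special tokens
    shifted = logits - logits.max(axis=-1, keepdims=True)
    p = np.exp(shifted)
    p /= p.sum(axis=-1, keepdims=True)
    cum = np.cumsum(p, axis=-1)
    u = rng.random((p.shape[0], 1))
    return (u > cum).sum(axis=-1)


def rtd_pretrain(
    sequences: Sequence[TokenSequence],
    vocab: Vocabulary,
    config: ModelConfig,
) -> tuple[Generator, Discriminator, TrainingReport]:
    """Joint replaced-token-detection pretraining of generator + discriminator.

    The generator is trained on masked-code prediction at dynamically masked
    positions; its sampled predictions build the corrupted sequence on which
    the discriminator learns per-position original/replaced labels.  Both
    models update at every step; the combined loss is the generator
    cross-entropy plus ``rtd_loss_weight`` times the discriminator binary
    cross-entropy.
    """
    seqs = [s for s in sequences if not s.is_empty]
    if not seqs:
        raise ValueError("rtd_pretrain requires a non-empty corpus")
    generator, discriminator = init_model(config)
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(
        generator.params() + discriminator.params(), lr=config.learning_rate
    )
    report = TrainingReport()
    for _ in range(config.pretrain_epochs):
        order = rng.permutation(len(seqs))
        g_tot = d_tot = t_tot = 0.0
        n_batches = 0
        for chunk in _iter_batches(order, seqs, config.batch_size):
            batch = collate(chunk, vocab, config)
            sel = dynamic_mask(batch, config.mask_rate, rng)
            masked = batch.token_ids.copy()
            masked[sel] = vocab.mask_id
            gen_batch = Batch(
                masked, batch.age, batch.year, batch.visit, batch.gender,
                batch.pad_mask, batch.maskable,
            )
            hidden = generator.forward(gen_batch, rng)
            logits = generator.lm_logits(hidden)
            flat = logits.reshape(-1, config.vocab_size)
            gen_loss = nn.cross_entropy(
                flat, batch.token_ids.reshape(-1), weights=sel.reshape(-1).astype(float)
            )

            sampled = _sample_replacements(
                flat.data[sel.reshape(-1)], rng, vocab.special_ids
            )
            corrupted = batch.token_ids.copy()
            corrupted[sel] = sampled
            replaced = (corrupted != batch.token_ids).astype(float)
            disc_batch = Batch(
                corrupted, batch.age, batch.year, batch.visit, batch.gender,
                batch.pad_mask, batch.maskable,
            )
            d_hidden = discriminator.forward(disc_batch, rng)
            d_logits = discriminator.rtd_logits(d_hidden)
            event_pos = batch.pad_mask.copy()
            event_pos[:, 0] = False  # CLS carries no original/replaced label
            disc_loss = nn.binary_cross_entropy_with_logits(
                d_logits, replaced, weights=event_pos.astype(float)
            )

            loss = gen_loss + disc_loss * config.rtd_loss_weight
            opt.zero_grad()
            loss.backward()
            opt.step()
            g_tot += float(gen_loss.data)
            d_tot += float(disc_loss.data)
            t_tot += float(loss.data)
            n_batches += 1
        report.generator_loss.append(g_tot / n_batches)
        report.discriminator_loss.append(d_tot / n_batches)
        report.total_loss.append(t_tot / n_batches)
    return generator, discriminator, report


def discriminator_loss_on_batch(
    discriminator: Discriminator, batch: Batch, labels: np.ndarray
) -> float:
    """Evaluation-mode discriminator BCE against given per-position labels."""
    hidden = discriminator.forward(batch, rng=None)
    logits = discriminator.rtd_logits(hidden)
    event_pos = batch.pad_mask.copy()
    event_pos[:, 0] = False
    return float(
        nn.binary_cross_entropy_with_logits(
            logits, labels, weights=event_pos.astype(float)
        ).data
    )


class _ConditionalRTDHead:
    """Per-position replaced/original classifier conditioned on the patient vector."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        H = config.hidden_size
        self.tok = nn.parameter(rng, config.vocab_size, H)
        self.Wz = nn.parameter(rng, H, H)
        self.W1 = nn.parameter(rng, H, H)
        self.b1 = nn.zeros(H)
        self.W2 = nn.parameter(rng, H, 1)
        self.b2 = nn.zeros(1)

    def params(self) -> list[Tensor]:
        return [self.tok, self.Wz, self.W1, self.b1, self.W2, self.b2]

    def logits(self, edited_ids: np.ndarray, z: Tensor) -> Tensor:
        B, L = edited_ids.shape
        h = nn.embedding(self.tok, edited_ids) + (z @ self.Wz).reshape(B, 1, -1)
        h = nn.gelu(h @ self.W1 + self.b1)
        return (h @ self.W2 + self.b2).reshape(B, L)


def _normalize_rows(z: Tensor) -> Tensor:
    norm = ((z * z).sum(axis=-1, keepdims=True) + 1e-12) ** 0.5
    return z / norm


def contrastive_loss(z1: Tensor, z2: Tensor, temperature: float) -> Tensor:
    """In-batch NT-Xent over two views: cosine similarities scaled by temperature."""
    sim = (_normalize_rows(z1) @ _normalize_rows(z2).transpose(1, 0)) * (1.0 / temperature)
    n = sim.shape[0]
    return nn.cross_entropy(sim, np.arange(n))


def diffcse_finetune(
    encoder: Generator,
    sequences: Sequence[TokenSequence],
    vocab: Vocabulary,
    temperature: float = 0.05,
    lambda_: float = 0.005,
    epochs: int = 5,
    seed: int = 0,
) -> tuple[Generator, TrainingReport]:
    """Contrastive fine-tuning with a conditional replaced-token term.

    ``encoder`` (the pretrained generator) is updated in place.  The edit
    generator — a frozen copy of the encoder taken at entry — masks and
    re-samples 15% of events; a conditional discriminator head receives the
    patient vector of the unedited view and classifies each edited position,
    adding ``lambda_`` times its loss to the contrastive term.
    """
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    seqs = [s for s in sequences if not s.is_empty]
    if not seqs:
        raise ValueError("diffcse_finetune requires a non-empty corpus")
    config = encoder.config
    editor = copy.deepcopy(encoder)  # frozen edit generator
    rng = np.random.default_rng(seed + 2)
    head = _ConditionalRTDHead(config, rng)
    opt = nn.Adam(encoder.params() + head.params(), lr=config.finetune_learning_rate)
    report = TrainingReport()
    for _ in range(epochs):
        order = rng.permutation(len(seqs))
        tot = ctot = dtot = 0.0
        n_batches = 0
        for chunk in _iter_batches(order, seqs, config.batch_size):
            if len(chunk) < 2:
                continue  # contrastive term needs in-batch negatives
            batch = collate(chunk, vocab, config)
            h1 = encoder.forward(batch, rng)
            h2 = encoder.forward(batch, rng)  # second dropout view
            z1 = _pooled_state(h1, batch)
            z2 = _pooled_state(h2, batch)
            loss_cl = contrastive_loss(z1, z2, temperature)

            sel = dynamic_mask(batch, config.mask_rate, rng)
            masked = batch.token_ids.copy()
            masked[sel] = vocab.mask_id
            ed_batch = Batch(
                masked, batch.age, batch.year, batch.visit, batch.gender,
                batch.pad_mask, batch.maskable,
            )
            ed_logits = editor.lm_logits(editor.forward(ed_batch, rng=None))
            sampled = _sample_replacements(
                ed_logits.data.reshape(-1, config.vocab_size)[sel.reshape(-1)],
                rng,
                vocab.special_ids,
            )
            edited = batch.token_ids.copy()
            edited[sel] = sampled
            replaced = (edited != batch.token_ids).astype(float)
            event_pos = batch.pad_mask.copy()
            event_pos[:, 0] = False
            logits = head.logits(edited, z1)
            loss_rtd = nn.binary_cross_entropy_with_logits(
                logits, replaced, weights=event_pos.astype(float)
            )

            loss = loss_cl + loss_rtd * lambda_
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot += float(loss.data)
            ctot += float(loss_cl.data)
            dtot += float(loss_rtd.data)
            n_batches += 1
        report.total_loss.append(tot / max(n_batches, 1))
        report.generator_loss.append(ctot / max(n_batches, 1))
        report.discriminator_loss.append(dtot / max(n_batches, 1))
    return encoder, report


def _pooled_state(hidden: Tensor, batch: Batch) -> Tensor:
    """Masked mean of hidden states over event positions, (B, L, H) -> (B, H)."""
    mask = batch.pad_mask.copy()
    mask[:, 0] = False  # CLS carries no event content
    w = mask.astype(float)
    w = w / np.maximum(w.sum(axis=1, keepdims=True), 1.0)
    B, L, H = hidden.shape
    return (hidden.swapaxes(1, 2) @ Tensor(w[:, :, None])).reshape(B, H)


# ---------------------------------------------------------------------------
# Embedding extraction


def embed_patients(
    encoder: DebertaEncoder,
    sequences: Sequence[TokenSequence],
    vocab: Vocabulary,
    batch_size: int = 64,
) -> tuple[list[str], np.ndarray]:
    """One deterministic evaluation-mode vector per patient (mean pooling).

    Empty sequences are reported and skipped.
    """
    ids: list[str] = []
    chunks: list[np.ndarray] = []
    todo = []
    for s in sequences:
        if s.is_empty:
            logger.warning("patient %s has an empty sequence; skipped", s.patient_id)
            continue
        todo.append(s)
    for start in range(0, len(todo), batch_size):
        chunk = todo[start : start + batch_size]
        batch = collate(chunk, vocab, encoder.config)
        hidden = encoder.forward(batch, rng=None)
        chunks.append(_pooled_state(hidden, batch).data)
        ids.extend(s.patient_id for s in chunk)
    if not chunks:
        return [], np.zeros((0, encoder.config.hidden_size))
    return ids, np.vstack(chunks)


def token_embeddings(
    encoder: DebertaEncoder, vocab: Vocabulary
) -> tuple[list[str], np.ndarray]:
    """Input-embedding-table vectors for every non-special token."""
    tokens = vocab.nonspecial_tokens()
    table = encoder.emb.token_table().data
    rows = np.array([table[vocab.token_to_id[t]] for t in tokens])
    return tokens, rows


# ---------------------------------------------------------------------------
# Checkpointing (runtime artifacts)


def save_checkpoint(encoder: Generator, vocab: Vocabulary, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {k.replace(".", "__"): v.data for k, v in encoder.named_params().items()}
    np.savez(path, **arrays)
    meta = {"config": asdict(encoder.config), "vocab": vocab.token_to_id,
            "counts": vocab.patient_counts, "min_patient_count": vocab.min_patient_count}
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def load_checkpoint(path: str | Path) -> tuple[Generator, Vocabulary]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig(**meta["config"])
    vocab = Vocabulary(
        {k: int(v) for k, v in meta["vocab"].items()},
        {k: int(v) for k, v in meta["counts"].items()},
        min_patient_count=meta["min_patient_count"],
    )
    encoder = Generator(config, np.random.default_rng(config.seed))
    data = np.load(path if path.suffix else path.with_suffix(".npz"))
    for k, p in encoder.named_params().items():
        p.data = data[k.replace(".", "__")]
    return encoder, vocab


# ---------------------------------------------------------------------------
# Estimator interface


class EHRDebertaEmbedder(BaseEstimator, TransformerMixin):
    """Patient-embedding transformer: RTD pretraining + contrastive fine-tuning.

    ``fit`` pretrains a generator/discriminator pair with replaced-token
    detection and then fine-tunes the generator contrastively; ``transform``
    maps token sequences to one embedding vector per patient.  Follows the
    scikit-learn estimator conventions, so it composes with pipelines and
    model selection.

    Parameters
    ----------
    vocab : Vocabulary
        Token vocabulary the sequences were encoded with.
    config : ModelConfig, optional
        Full hyperparameter block; built from ``vocab`` with desk-scale
        defaults when omitted.
    seed : int
        Overrides ``config.seed`` when given.
    """

    def __init__(self, vocab: Vocabulary, config: ModelConfig | None = None, seed: int | None = None):
        self.vocab = vocab
        self.config = config
        self.seed = seed

    def _resolved_config(self) -> ModelConfig:
        cfg = self.config if self.config is not None else ModelConfig(vocab_size=len(self.vocab))
        if cfg.vocab_size != len(self.vocab):
            raise ValueError("config.vocab_size must match the vocabulary size")
        if self.seed is not None:
            cfg = ModelConfig(**{**asdict(cfg), "seed": self.seed})
        return cfg

    def fit(self, X: Sequence[TokenSequence], y=None) -> "EHRDebertaEmbedder":
        cfg = self._resolved_config()
        generator, discriminator, pre_report = rtd_pretrain(X, self.vocab, cfg)
        encoder, ft_report = diffcse_finetune(
            generator,
            X,
            self.vocab,
            temperature=cfg.diffcse_temperature,
            lambda_=cfg.diffcse_lambda,
            epochs=cfg.diffcse_epochs,
            seed=cfg.seed,
        )
        self.encoder_ = encoder
        self.discriminator_ = discriminator
        self.pretrain_report_ = pre_report
        self.finetune_report_ = ft_report
        self.n_features_out_ = cfg.hidden_size
        return self

    def transform(self, X: Sequence[TokenSequence]) -> np.ndarray:
        if not hasattr(self, "encoder_"):
            raise RuntimeError("EHRDebertaEmbedder must be fitted before transform")
        _, emb = embed_patients(self.encoder_, X, self.vocab)
        return emb

    def patient_embeddings(self, X: Sequence[TokenSequence]) -> tuple[list[str], np.ndarray]:
        return embed_patients(self.encoder_, X, self.vocab)

    def token_embeddings(self) -> tuple[list[str], np.ndarray]:
        return token_embeddings(self.encoder_, self.vocab)
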