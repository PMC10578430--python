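"""Encoder–decoder condition-prediction model.

A bidirectional self-attention encoder embeds the tokenized reaction
SMILES; a 6-step causal decoder with cross-attention emits one
classification per step — catalyst, solvent1, solvent2, reagent1,
reagent2, then an end token — over a shared union label vocabulary with
per-step admissibility masking.  Previously decoded labels are embedded
and fed back as decoder inputs, so later conditions are predicted in the
context of earlier ones.  A feed-forward head pools the encoder memory
and the six decoder states to regress the reaction temperature.

The training objective is the sum over the six decoder positions of the
cross-entropy within each position's admissible label set, plus
``alpha`` times the squared temperature error (omitted when the dataset
carries no temperatures)::

    loss = sum_i CE(c_i, c_hat_i) + alpha * (t - t_hat)^2
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .chem import ConditionVocabulary
from .nn import DTYPE, NEG_INF, Module
from .tokenizer import TokenVocabulary

#: fixed decoder target length: five condition slots plus the end token
TARGET_LEN = 6


@dataclass
class ModelConfig:
    d_model: int = 64
    d_ff: int = 128
    enc_layers: int = 2
    enc_heads: int = 4
    dec_layers: int = 3
    dec_heads: int = 4
    alpha: float = 0.001
    max_len: int = 96
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.d_model % self.enc_heads or self.d_model % self.dec_heads:
            raise ValueError("attention heads must divide d_model")


@dataclass
class AttentionBundle:
    """Attention weights of one forward pass on a single reaction.

    ``encoder_self[l][h, q, k]`` are encoder self-attention weights;
    ``cross[l][h, step, k]`` are decoder→encoder cross-attention weights
    for decoder steps 0..5.  Rows over non-PAD keys sum to 1.
    """

    encoder_self: list[np.ndarray]
    cross: list[np.ndarray]
    n_tokens: int


class ReactionEncoder(Module):
    def __init__(self, cfg: ModelConfig, vocab_size: int, rng: np.random.Generator):
        self.token_emb = nn.Embedding(vocab_size, cfg.d_model, rng)
        self.pos_emb = nn.Embedding(cfg.max_len, cfg.d_model, rng)
        self.layers = [
            nn.EncoderLayer(cfg.d_model, cfg.enc_heads, cfg.d_ff, cfg.dropout, rng)
            for _ in range(cfg.enc_layers)
        ]
        self.norm = nn.LayerNorm(cfg.d_model)

    def __call__(self, ids, mask, training, rng):
        b, t = ids.shape
        x = self.token_emb(ids) + self.pos_emb(np.arange(t)[None, :].repeat(b, axis=0))
        attn_weights = []
        for layer in self.layers:
            x, w = layer(x, mask, training, rng)
            attn_weights.append(w)
        return self.norm(x), attn_weights


class ConditionTransformer(Module):
    """Full model: reaction encoder, condition decoder, temperature head."""

    def __init__(
        self,
        config: ModelConfig,
        token_vocab: TokenVocabulary,
        cond_vocab: ConditionVocabulary,
    ):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.token_vocab = token_vocab
        self.cond_vocab = cond_vocab
        self.encoder = ReactionEncoder(config, len(token_vocab), rng)
        self.cond_emb = nn.Embedding(len(cond_vocab), config.d_model, rng)
        self.dec_pos = nn.Embedding(TARGET_LEN, config.d_model, rng)
        self.dec_layers = [
            nn.DecoderLayer(config.d_model, config.dec_heads, config.d_ff, config.dropout, rng)
            for _ in range(config.dec_layers)
        ]
        self.dec_norm = nn.LayerNorm(config.d_model)
        self.out_head = nn.Linear(config.d_model, len(cond_vocab), rng)
        d = config.d_model
        self.temp_net_a = nn.Linear(d, d, rng)
        self.temp_net_b = nn.Linear(d, d, rng)
        self.temp_net_c1 = nn.Linear(2 * d, d, rng)
        self.temp_net_c2 = nn.Linear(d, 1, rng)
        # temperature standardization (train mean/sd), set by the trainer
        self.temp_mean = 0.0
        self.temp_sd = 1.0
        self.training = False
        self._drop_rng = np.random.default_rng(config.seed + 1)
        # (6, V) admissibility mask; position 5 admits only EOS
        self.slot_masks = np.stack(
            [cond_vocab.slot_mask(s) for s in range(TARGET_LEN)]
        )

    def train(self, mode: bool = True) -> "ConditionTransformer":
        self.training = mode
        return self

    def eval(self) -> "ConditionTransformer":
        return self.train(False)

    def reseed_dropout(self, seed: int) -> None:
        self._drop_rng = np.random.default_rng(seed)

    # -- forward pieces ----------------------------------------------------
    def encode(self, ids: np.ndarray, mask: np.ndarray) -> tuple[Tensor, list[np.ndarray]]:
        """Memory states (B, T, d) and per-layer encoder self-attention."""
        if ids.shape[1] > self.config.max_len:
            raise ValueError(
                f"sequence length {ids.shape[1]} exceeds max_len {self.config.max_len}"
            )
        return self.encoder(ids, mask, self.training, self._drop_rng)

    def decode_conditions(
        self, memory: Tensor, memory_mask: np.ndarray, decoder_input_ids: np.ndarray
    ) -> tuple[Tensor, list[np.ndarray], Tensor]:
        """Masked per-step logits (B, 6, V), cross-attention, decoder states.

        ``decoder_input_ids`` is (B, 6): BOS followed by the five (teacher
        or previously decoded) slot labels.  Step ``p`` logits are masked
        to the slot-``p`` admissible set; the causal self-attention makes
        them independent of later prefix entries.
        """
        b = decoder_input_ids.shape[0]
        if decoder_input_ids.shape[1] != TARGET_LEN:
            raise ValueError(f"decoder input must have length {TARGET_LEN}")
        for p in range(1, TARGET_LEN):
            bad = ~np.isin(decoder_input_ids[:, p], self.cond_vocab.slot_ids(p - 1))
            pad_ok = decoder_input_ids[:, p] == self.cond_vocab.pad_id
            if np.any(bad & ~pad_ok):
                raise ValueError(f"decoder prefix id outside slot {p - 1} admissible set")
        x = self.cond_emb(decoder_input_ids) + self.dec_pos(
            np.arange(TARGET_LEN)[None, :].repeat(b, axis=0)
        )
        cross_weights = []
        for layer in self.dec_layers:
            x, w = layer(x, memory, memory_mask, self.training, self._drop_rng)
            cross_weights.append(w)
        states = self.dec_norm(x)
        logits = self.out_head(states)
        bias = (~self.slot_masks).astype(DTYPE) * NEG_INF
        return logits + bias[None], cross_weights, states

    def predict_temperature(
        self, memory: Tensor, memory_mask: np.ndarray, decoder_states: Tensor
    ) -> Tensor:
        """Scalar temperature (standardized units) per batch row.

        Mean-pools the non-PAD memory states through net A and the six
        decoder states through net B, then concatenates through net C.
        """
        if decoder_states is None:
            raise ValueError("decoder states required for temperature prediction")
        m = memory_mask.astype(DTYPE)[:, :, None]
        counts = np.maximum(m.sum(axis=1), 1.0)
        pooled_mem = ad.mul(ad.tsum(ad.mul(memory, m), axis=1), 1.0 / counts)
        pooled_dec = ad.tmean(decoder_states, axis=1)
        a = ad.tanh(self.temp_net_a(pooled_mem))
        b = ad.tanh(self.temp_net_b(pooled_dec))
        h = ad.tanh(self.temp_net_c1(ad.concat([a, b], axis=-1)))
        return ad.reshape(self.temp_net_c2(h), (-1,))

    def forward(
        self, ids: np.ndarray, mask: np.ndarray, decoder_input_ids: np.ndarray
    ):
        memory, enc_attn = self.encode(ids, mask)
        logits, cross, states = self.decode_conditions(memory, mask, decoder_input_ids)
        return memory, enc_attn, logits, cross, states

    def attention_bundle(self, ids: np.ndarray, mask: np.ndarray,
                         decoder_input_ids: np.ndarray) -> AttentionBundle:
        """Single-record forward pass collecting all attention weights."""
        memory, enc_attn, _, cross, _ = self.forward(ids, mask, decoder_input_ids)
        n = int(mask[0].sum())
        return AttentionBundle(
            encoder_self=[w[0] for w in enc_attn],
            cross=[w[0] for w in cross],
            n_tokens=n,
        )

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "config": asdict(self.config),
            "cond_vocab": self.cond_vocab.to_dict(),
            "token_vocab": self.token_vocab.tokens,
            "temp_mean": self.temp_mean,
            "temp_sd": self.temp_sd,
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "ConditionTransformer":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        token_vocab = TokenVocabulary.__new__(TokenVocabulary)
        token_vocab.tokens = meta["token_vocab"]
        token_vocab.index = {t: i for i, t in enumerate(token_vocab.tokens)}
        model = cls(
            ModelConfig(**meta["config"]),
            token_vocab,
            ConditionVocabulary.from_dict(meta["cond_vocab"]),
        )
        model.load_state_dict(state)
        model.temp_mean = meta["temp_mean"]
        model.temp_sd = meta["temp_sd"]
        return model


def compute_loss(
    step_logits,
    targets: np.ndarray,
    t_pred: Optional[Tensor] = None,
    t_true: Optional[np.ndarray] = None,
    alpha: float = 0.001,
) -> Tensor:
    """Training loss: summed per-position cross-entropy plus weighted MSE.

    ``step_logits`` is (B, 6, V) or (6, V) — already admissibility-masked;
    the cross-entropy at each of the six positions uses natural log over
    the admissible set.  The regression term ``alpha * (t - t_hat)^2`` is
    included only when both temperatures are given; with ``alpha = 0`` the
    loss is invariant to the temperature prediction.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    logits = step_logits if isinstance(step_logits, Tensor) else Tensor(np.asarray(step_logits))
    targets = np.asarray(targets)
    if logits.ndim == 2:
        logits = ad.reshape(logits, (1, *logits.shape))
        targets = targets[None, :]
    b = logits.shape[0]
    if logits.shape[1] != TARGET_LEN or targets.shape != (b, TARGET_LEN):
        raise ValueError("expected 6 logit rows and matching targets")
    logp = ad.log_softmax(logits, axis=-1)
    batch_idx = np.repeat(np.arange(b), TARGET_LEN)
    step_idx = np.tile(np.arange(TARGET_LEN), b)
    picked = ad.getitem(logp, (batch_idx, step_idx, targets.reshape(-1)))
    loss = ad.mul(ad.tsum(picked), -1.0 / b)
    if alpha > 0 and t_pred is not None and t_true is not None:
        t_pred = t_pred if isinstance(t_pred, Tensor) else Tensor(np.asarray(t_pred, dtype=float))
        diff = t_pred - np.asarray(t_true, dtype=float).reshape(t_pred.shape)
        loss = loss + ad.tmean(ad.mul(diff, diff)) * alpha
    return loss
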