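"""Masked-token pretraining of the reaction encoder.

Two corruption procedures over condition-free reactions
(``reactants>>products``):

* masked language modeling (LM): every maskable token is selected
  independently with the base probability (default 0.15);
* masked reaction-center modeling (RCM): reaction-center atom tokens are
  selected at an elevated probability (default 0.5) while all other
  maskable tokens keep the base probability, injecting reaction-center
  knowledge into the encoder.

Selected positions follow the standard masked-LM replacement recipe
(80% mask token / 10% random atom token / 10% kept); BOS, EOS, PAD and
the ``>>`` separator are never selected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from . import nn
from .chem import ReactionCenter, strip_atom_maps_keep_center
from .model import ModelConfig, ReactionEncoder
from .nn import Module
from .tokenizer import (
    TokenVocabulary,
    TokenizedReaction,
    mark_center_tokens,
    tokenize_reaction,
)

IGNORE_LABEL = -100
SEPARATOR = ">>"


@dataclass
class MaskingPolicy:
    base_rate: float = 0.15
    center_rate: float = 0.5
    mask_frac: float = 0.8
    random_frac: float = 0.1
    keep_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.base_rate, self.center_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("masking rates must lie in [0, 1]")
        if abs(self.mask_frac + self.random_frac + self.keep_frac - 1.0) > 1e-9:
            raise ValueError("replacement fractions must sum to 1")


def corrupt(
    tok: TokenizedReaction,
    policy: MaskingPolicy,
    mode: str,
    vocab: TokenVocabulary,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One corruption draw: (input ids, label ids, corrupted positions).

    Labels carry the original token id at selected positions and
    ``IGNORE_LABEL`` elsewhere.  Mode ``"RCM"`` requires center flags.
    """
    if mode not in ("LM", "RCM"):
        raise ValueError(f"unknown corruption mode {mode!r}")
    if mode == "RCM" and not any(tok.center_flags):
        raise ValueError("RCM corruption requires center-flagged tokens")
    rng = rng if rng is not None else np.random.default_rng(policy.seed)
    n = len(tok)
    ids = np.array([vocab.index.get(t, vocab.unk_id) for t in tok.tokens], dtype=np.int64)
    maskable = np.array(
        [t not in (SEPARATOR, *_specials(vocab)) for t in tok.tokens], dtype=bool
    )
    rates = np.where(maskable, policy.base_rate, 0.0)
    if mode == "RCM":
        rates = np.where(np.asarray(tok.center_flags), policy.center_rate, rates)
    selected = rng.random(n) < rates
    labels = np.where(selected, ids, IGNORE_LABEL)
    out = ids.copy()
    atom_ids = vocab.atom_token_ids()
    draws = rng.random(n)
    for pos in np.flatnonzero(selected):
        if draws[pos] < policy.mask_frac:
            out[pos] = vocab.mask_id
        elif draws[pos] < policy.mask_frac + policy.random_frac:
            out[pos] = atom_ids[int(rng.integers(len(atom_ids)))]
        # else: keep original token
    return out, labels, np.flatnonzero(selected)


def _specials(vocab: TokenVocabulary) -> tuple[str, ...]:
    from .tokenizer import SPECIALS

    return SPECIALS


class MaskedLMModel(Module):
    """Reaction encoder plus a token-classification head."""

    def __init__(self, config: ModelConfig, vocab: TokenVocabulary):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.vocab = vocab
        self.encoder = ReactionEncoder(config, len(vocab), rng)
        self.head = nn.Linear(config.d_model, len(vocab), rng)
        self._drop_rng = np.random.default_rng(config.seed + 1)
        self.training = False

    def loss_on_batch(
        self, ids: np.ndarray, mask: np.ndarray, labels: np.ndarray
    ) -> ad.Tensor:
        memory, _ = self.encoder(ids, mask, self.training, self._drop_rng)
        logits = self.head(memory)
        logp = ad.log_softmax(logits, axis=-1)
        rows, cols = np.nonzero(labels != IGNORE_LABEL)
        if len(rows) == 0:
            return ad.Tensor(np.zeros(()), requires_grad=False)
        picked = ad.getitem(logp, (rows, cols, labels[rows, cols]))
        return ad.mul(ad.tsum(picked), -1.0 / len(rows))

    def save(self, path) -> None:
        import json as _json

        meta = {"config": self.config.__dict__, "tokens": self.vocab.tokens}
        np.savez(
            path,
            __meta__=np.frombuffer(_json.dumps(meta).encode(), dtype=np.uint8),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "MaskedLMModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        vocab = TokenVocabulary.__new__(TokenVocabulary)
        vocab.tokens = meta["tokens"]
        vocab.index = {t: i for i, t in enumerate(vocab.tokens)}
        model = cls(ModelConfig(**meta["config"]), vocab)
        model.load_state_dict(state)
        return model


def tokenize_corpus(
    reactions: Sequence[str],
    centers: Optional[Sequence[Optional[ReactionCenter]]] = None,
) -> list[TokenizedReaction]:
    """Tokenize condition-free reactions; mark centers when provided.

    ``reactions`` may carry ``:n`` atom maps: maps are stripped (with the
    center renumbered to the stripped atom order) so the pretraining
    surface matches the fine-tuning inputs.
    """
    out = []
    for i, rxn in enumerate(reactions):
        center = centers[i] if centers is not None else None
        if center is not None:
            rxn, center = strip_atom_maps_keep_center(rxn, center)
        tok = tokenize_reaction(rxn)
        if center is not None:
            tok = mark_center_tokens(tok, center)
        out.append(tok)
    return out


def pretrain(
    model: MaskedLMModel,
    corpus: Sequence[TokenizedReaction],
    policy: MaskingPolicy,
    mode: str,
    steps: int,
    batch_size: int = 16,
    lr: float = 1e-3,
    seed: int = 0,
    checkpoint_path=None,
) -> tuple[MaskedLMModel, list[float]]:
    """Run masked-token pretraining; returns the model and per-step losses.

    Zero steps leave the model bit-identical.  Deterministic given
    ``seed`` on one device.
    """
    if len(corpus) == 0:
        raise ValueError("empty pretraining corpus")
    rng = np.random.default_rng(seed)
    model.training = True
    model._drop_rng = np.random.default_rng(seed + 1)
    opt = nn.AdamW(model.parameters(), lr=lr)
    losses: list[float] = []
    for _ in range(steps):
        idx = rng.integers(len(corpus), size=batch_size)
        batch = [corpus[int(i)] for i in idx]
        max_len = max(len(t) for t in batch)
        ids = np.zeros((batch_size, max_len), dtype=np.int64)
        mask = np.zeros((batch_size, max_len), dtype=np.int64)
        labels = np.full((batch_size, max_len), IGNORE_LABEL, dtype=np.int64)
        for j, tok in enumerate(batch):
            cids, clabels, _ = corrupt(tok, policy, mode, model.vocab, rng)
            ids[j, : len(cids)] = cids
            labels[j, : len(clabels)] = clabels
            mask[j, : len(cids)] = 1
        opt.zero_grad()
        loss = model.loss_on_batch(ids, mask, labels)
        loss.backward()
        opt.step()
        losses.append(loss.item())
    model.training = False
    if checkpoint_path is not None:
        model.save(checkpoint_path)
    return model, losses


def masked_ce(
    model: MaskedLMModel,
    corpus: Sequence[TokenizedReaction],
    policy: MaskingPolicy,
    mode: str,
    seed: int = 0,
    center_tokens_only: bool = False,
) -> float:
    """Mean masked cross-entropy of the model over one corruption pass."""
    rng = np.random.default_rng(seed)
    model.training = False
    total, count = 0.0, 0
    for tok in corpus:
        ids, labels, _ = corrupt(tok, policy, mode, model.vocab, rng)
        if center_tokens_only:
            flags = np.asarray(tok.center_flags)
            labels = np.where(flags, labels, IGNORE_LABEL)
        if not np.any(labels != IGNORE_LABEL):
            continue
        loss = model.loss_on_batch(
            ids[None, :], np.ones((1, len(ids)), dtype=np.int64), labels[None, :]
        )
        n = int(np.sum(labels != IGNORE_LABEL))
        total += loss.item() * n
        count += n
    return total / max(count, 1)
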