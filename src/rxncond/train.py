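"""Supervised fine-tuning on reaction-condition datasets.

The trainer teacher-forces the 6-step decoder against the target label
sequence (five slots then the end token), optimizes the combined
classification + weighted temperature-regression loss with AdamW under
linear warmup, tracks per-epoch train/validation loss and validation
strict top-1 accuracy, and retains the best-validation parameters.
Temperatures are standardized with the training mean/sd inside the
regression head and de-standardized for reporting, which keeps the
default loss weight usable across datasets; the raw-°C behaviour is
recovered by ``standardize_temperature=False``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .chem import ConditionVocabulary, ReactionRecord, augment_reaction, strip_atom_maps
from .model import TARGET_LEN, ConditionTransformer, ModelConfig, compute_loss
from .pretrain import MaskedLMModel
from .tokenizer import TokenVocabulary, encode, tokenize_reaction


@dataclass
class TrainConfig:
    epochs: int = 40
    batch_size: int = 50
    lr: float = 2e-3
    weight_decay: float = 0.01
    warmup_steps: int = 30
    patience: Optional[int] = None  # epochs without val improvement; None = off
    seed: int = 0
    standardize_temperature: bool = True


@dataclass
class EncodedDataset:
    """Records encoded once: token ids, masks, targets, temperatures."""

    ids: np.ndarray  # (N, T)
    mask: np.ndarray  # (N, T)
    targets: np.ndarray  # (N, 6)
    temperatures: Optional[np.ndarray]  # (N,) or None when any is absent


def encode_dataset(
    records: Sequence[ReactionRecord],
    token_vocab: TokenVocabulary,
    cond_vocab: ConditionVocabulary,
    max_len: int,
) -> EncodedDataset:
    n = len(records)
    ids = np.zeros((n, max_len), dtype=np.int64)
    mask = np.zeros((n, max_len), dtype=np.int64)
    targets = np.zeros((n, TARGET_LEN), dtype=np.int64)
    temps = np.zeros(n)
    have_temps = True
    for i, rec in enumerate(records):
        tok = tokenize_reaction(strip_atom_maps(rec.rxn_smiles))
        ids[i], mask[i] = encode(tok, token_vocab, max_len)
        targets[i] = cond_vocab.encode_conditions(rec.conditions)
        if rec.temperature is None:
            have_temps = False
        else:
            temps[i] = rec.temperature
    return EncodedDataset(ids, mask, targets, temps if have_temps else None)


def teacher_inputs(targets: np.ndarray, cond_vocab: ConditionVocabulary) -> np.ndarray:
    """Decoder inputs: BOS followed by the first five target labels."""
    bos = np.full((targets.shape[0], 1), cond_vocab.bos_id, dtype=np.int64)
    return np.concatenate([bos, targets[:, : TARGET_LEN - 1]], axis=1)


def greedy_decode(
    model: ConditionTransformer, ids: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Batched greedy top-1 decode; returns (slot label ids (B,5), temps)."""
    memory, _ = model.encode(ids, mask)
    b = ids.shape[0]
    prefix = np.full((b, TARGET_LEN), model.cond_vocab.pad_id, dtype=np.int64)
    prefix[:, 0] = model.cond_vocab.bos_id
    states = None
    for p in range(TARGET_LEN - 1):
        logits, _, states = model.decode_conditions(memory, mask, prefix)
        choice = logits.data[:, p, :].argmax(axis=-1)
        if p + 1 < TARGET_LEN:
            prefix[:, p + 1] = choice
    logits, _, states = model.decode_conditions(memory, mask, prefix)
    labels = np.stack(
        [logits.data[:, p, :].argmax(axis=-1) for p in range(TARGET_LEN - 1)], axis=1
    )
    t = model.predict_temperature(memory, mask, states).data
    temps = t * model.temp_sd + model.temp_mean
    return labels, temps


def _batch_loss(model, data: EncodedDataset, idx: np.ndarray, use_temp: bool):
    ids, mask = data.ids[idx], data.mask[idx]
    tmax = int(mask.sum(axis=1).max())  # trim PAD-only tail
    ids, mask = ids[:, :tmax], mask[:, :tmax]
    targets = data.targets[idx]
    dec_in = teacher_inputs(targets, model.cond_vocab)
    memory, _, logits, _, states = model.forward(ids, mask, dec_in)
    t_pred = t_true = None
    alpha = model.config.alpha
    if use_temp and data.temperatures is not None and alpha > 0:
        t_pred = model.predict_temperature(memory, mask, states)
        t_true = (data.temperatures[idx] - model.temp_mean) / model.temp_sd
    return compute_loss(logits, targets, t_pred, t_true, alpha)


def strict_top1_accuracy(
    model: ConditionTransformer, data: EncodedDataset, batch_size: int = 128
) -> float:
    """Fraction of records whose greedy decode matches all five slots."""
    hits = 0
    for lo in range(0, len(data.ids), batch_size):
        sl = slice(lo, lo + batch_size)
        tmax = int(data.mask[sl].sum(axis=1).max())
        labels, _ = greedy_decode(model, data.ids[sl, :tmax], data.mask[sl, :tmax])
        hits += int((labels == data.targets[sl, : TARGET_LEN - 1]).all(axis=1).sum())
    return hits / len(data.ids)


def init_from_pretrained(model: ConditionTransformer, checkpoint) -> None:
    """Copy encoder weights from a masked-token pretraining checkpoint."""
    lm = checkpoint if isinstance(checkpoint, MaskedLMModel) else MaskedLMModel.load(checkpoint)
    if lm.vocab.tokens != model.token_vocab.tokens:
        extra = set(lm.vocab.tokens) ^ set(model.token_vocab.tokens)
        raise ValueError(f"token vocabulary mismatch with checkpoint: {sorted(extra)}")
    enc_state = {
        k[len("encoder."):]: v for k, v in lm.state_dict().items() if k.startswith("encoder.")
    }
    model.encoder.load_state_dict(enc_state)


def train(
    model: ConditionTransformer,
    train_records: Sequence[ReactionRecord],
    val_records: Sequence[ReactionRecord],
    cfg: TrainConfig,
    init_checkpoint=None,
    log_path=None,
) -> tuple[ConditionTransformer, list[dict]]:
    """Teacher-forced fine-tuning; returns the best-validation model.

    ``init_checkpoint`` may be a MaskedLMModel (or path) whose encoder
    weights initialize the model; otherwise the random initialization of
    the model's own seed is kept.  Deterministic given ``cfg.seed``.
    """
    if init_checkpoint is not None:
        init_from_pretrained(model, init_checkpoint)
    data = encode_dataset(
        train_records, model.token_vocab, model.cond_vocab, model.config.max_len
    )
    val = encode_dataset(
        val_records, model.token_vocab, model.cond_vocab, model.config.max_len
    )
    if cfg.standardize_temperature and data.temperatures is not None:
        model.temp_mean = float(np.mean(data.temperatures))
        model.temp_sd = float(np.std(data.temperatures) + 1e-8)
    history: list[dict] = []
    if cfg.epochs == 0:
        return model, history
    rng = np.random.default_rng(cfg.seed)
    model.train(True)
    model.reseed_dropout(cfg.seed + 1)
    opt = nn.AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    step = 0
    best_acc, best_state, since_best = -1.0, None, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_records))
        epoch_losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            step += 1
            opt.lr = cfg.lr * min(1.0, step / max(cfg.warmup_steps, 1))
            opt.zero_grad()
            loss = _batch_loss(model, data, idx, use_temp=True)
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        model.train(False)
        val_loss = _batch_loss(model, val, np.arange(len(val_records)), use_temp=True).item()
        val_acc = strict_top1_accuracy(model, val)
        model.train(True)
        entry = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "val_top1_strict": val_acc,
        }
        history.append(entry)
        if log_path is not None:
            with open(log_path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(entry) + "\n")
        if val_acc > best_acc:
            best_acc, best_state, since_best = val_acc, model.state_dict(), 0
        else:
            since_best += 1
            if cfg.patience is not None and since_best > cfg.patience:
                break
        if val_acc >= 0.999:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.train(False)
    return model, history


def enhanced_finetune(
    model: ConditionTransformer,
    train_records: Sequence[ReactionRecord],
    val_records: Sequence[ReactionRecord],
    factor: int = 5,
    epochs: int = 2,
    lr: float = 1e-6,
    seed: int = 0,
) -> tuple[ConditionTransformer, list[dict]]:
    """Continue training on a SMILES-augmented copy of the training set.

    The training set is expanded ``factor``-fold with random-rooted
    SMILES and shuffled molecule order, then trained for exactly
    ``epochs`` passes at the (low) learning rate ``lr``.
    """
    if factor < 1:
        raise ValueError("augmentation factor must be >= 1")
    if epochs == 0:
        return model, []
    augmented: list[ReactionRecord] = []
    for i, rec in enumerate(train_records):
        augmented.extend(augment_reaction(rec, factor, seed=seed + i))
    cfg = TrainConfig(epochs=epochs, lr=lr, warmup_steps=1, seed=seed)
    return train(model, augmented, val_records, cfg)
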