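"""Top-k combination inference and the strict/relaxed evaluation protocol.

Inference decodes greedily slot by slot conditioned on the running top-1
prefix, keeps the top-k_p candidates per slot, enumerates the Cartesian
product of the per-slot candidate sets, and ranks every combination by
the product of its per-slot softmax probabilities.  With the standard
portfolio — top-1 catalyst, top-3 solvent1, top-1 solvent2, top-5
reagent1, top-1 reagent2 — that yields exactly 15 ranked combinations.

Evaluation strictly matches all five labels (Null included); the relaxed
protocol instead matches solvents and reagents at the level of
substitutability categories (catalysts stay strict).  Test sets are
stratified into Alpha (no catalyst) and Beta (catalyst present), each
with its own portfolio.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem import NULL_LABEL, SLOTS, ConditionVocabulary, ReactionRecord, strip_atom_maps
from .model import TARGET_LEN, ConditionTransformer
from .tokenizer import encode as encode_tokens, tokenize_reaction

TOP_KS = (1, 3, 5, 10, 15)


@dataclass(frozen=True)
class BeamWidths:
    """Per-slot candidate counts (catalyst, solvent1, solvent2, reagent1, reagent2)."""

    widths: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.widths) != 5 or any(w < 1 for w in self.widths):
            raise ValueError("need 5 widths, each >= 1")

    @property
    def n_combinations(self) -> int:
        return int(np.prod(self.widths))


#: portfolio used for catalyst-bearing USPTO-style evaluation
USPTO_WIDTHS = BeamWidths((1, 3, 1, 5, 1))
#: stratum portfolios: Alpha = no catalyst, Beta = catalyst present
ALPHA_WIDTHS = BeamWidths((1, 3, 1, 5, 1))
BETA_WIDTHS = BeamWidths((2, 3, 1, 5, 1))


@dataclass
class ConditionPrediction:
    """Ranked condition combinations for one reaction."""

    ranked: list[tuple[tuple[str, str, str, str, str], float]]
    slot_candidates: list[list[tuple[str, float]]]
    temperature: Optional[float] = None


def _slot_topk(probs: np.ndarray, slot_ids: list[int], k: int) -> list[tuple[int, float]]:
    p = probs[slot_ids]
    order = np.argsort(-p, kind="stable")[:k]
    return [(slot_ids[int(i)], float(p[int(i)])) for i in order]


def enumerate_combinations(
    candidates: Sequence[Sequence[tuple[str, float]]],
) -> list[tuple[tuple[str, ...], float]]:
    """Cartesian product of per-slot candidates ranked by probability product.

    Ties break by slot-wise candidate rank order, first slot first.
    """
    combos = []
    for ranks in itertools.product(*[range(len(c)) for c in candidates]):
        labels = tuple(candidates[s][r][0] for s, r in enumerate(ranks))
        score = float(np.prod([candidates[s][r][1] for s, r in enumerate(ranks)]))
        combos.append((ranks, labels, score))
    combos.sort(key=lambda c: (-c[2], c[0]))
    return [(labels, score) for _, labels, score in combos]


def predict_conditions(
    model: ConditionTransformer,
    record: ReactionRecord | str,
    widths: BeamWidths = USPTO_WIDTHS,
) -> ConditionPrediction:
    """Ranked condition combinations plus the top-1-sequence temperature.

    Slot ``p`` candidates are the top-k_p labels conditioned on the top-1
    prefix; combination scores multiply per-slot probabilities and ties
    break by slot-wise candidate rank (catalyst first).
    """
    vocab = model.cond_vocab
    for s, w in enumerate(widths.widths):
        if w > len(vocab.per_slot_labels[s]):
            raise ValueError(f"width {w} exceeds {SLOTS[s]} vocabulary size")
    rxn = record.rxn_smiles if isinstance(record, ReactionRecord) else record
    tok = tokenize_reaction(strip_atom_maps(rxn))
    ids, mask = encode_tokens(tok, model.token_vocab, model.config.max_len)
    ids, mask = ids[None], mask[None]
    model.train(False)
    memory, _ = model.encode(ids, mask)
    prefix = np.full((1, TARGET_LEN), vocab.pad_id, dtype=np.int64)
    prefix[0, 0] = vocab.bos_id
    candidates: list[list[tuple[int, float]]] = []
    states = None
    for p in range(5):
        logits, _, states = model.decode_conditions(memory, mask, prefix)
        probs = _softmax(logits.data[0, p])
        cands = _slot_topk(probs, vocab.slot_ids(p), widths.widths[p])
        candidates.append(cands)
        if p + 1 < TARGET_LEN:
            prefix[0, p + 1] = cands[0][0]
    _, _, states = model.decode_conditions(memory, mask, prefix)
    t = model.predict_temperature(memory, mask, states).data[0]
    temperature = float(t * model.temp_sd + model.temp_mean)
    slot_candidates = [
        [(vocab.union_labels[i], prob) for i, prob in c] for c in candidates
    ]
    return ConditionPrediction(
        ranked=enumerate_combinations(slot_candidates),  # type: ignore[arg-type]
        slot_candidates=slot_candidates,
        temperature=temperature,
    )


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def _match_strict(pred: Sequence[str], truth: Sequence[str], slots: Sequence[int]) -> bool:
    return all(pred[s] == truth[s] for s in slots)


def strict_topk_accuracy(
    predictions: Sequence[ConditionPrediction],
    truths: Sequence[Sequence[str]],
    k: int,
    slots: Sequence[int] = (0, 1, 2, 3, 4),
) -> float:
    """Fraction of records with an exact match in the first ``k`` combinations."""
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = sum(
        any(_match_strict(labels, truth, slots) for labels, _ in pred.ranked[:k])
        for pred, truth in zip(predictions, truths)
    )
    return hits / len(predictions)


def slot_topk_accuracy(
    predictions: Sequence[ConditionPrediction],
    truths: Sequence[Sequence[str]],
    slot: int,
    k: int,
) -> float:
    """Per-slot accuracy over that slot's own candidate list (capped at its width)."""
    hits = sum(
        truth[slot] in [lab for lab, _ in pred.slot_candidates[slot][:k]]
        for pred, truth in zip(predictions, truths)
    )
    return hits / len(predictions)


def _match_relaxed(
    pred: Sequence[str], truth: Sequence[str], category_map: dict[str, str],
    slots: Sequence[int],
) -> bool:
    for s in slots:
        a, b = pred[s], truth[s]
        if s == 0:  # catalysts always strict
            if a != b:
                return False
            continue
        if (a == NULL_LABEL) != (b == NULL_LABEL):
            return False
        if a == b == NULL_LABEL:
            continue
        for lab in (a, b):
            if lab not in category_map:
                raise KeyError(f"label {lab!r} missing from category map")
        if category_map[a] != category_map[b]:
            return False
    return True


def relaxed_topk_accuracy(
    predictions: Sequence[ConditionPrediction],
    truths: Sequence[Sequence[str]],
    k: int,
    category_map: dict[str, str],
    slots: Sequence[int] = (0, 1, 2, 3, 4),
) -> float:
    """Category-level top-k accuracy: solvent/reagent slots match when their
    categories agree; catalysts are strict and Null matches only Null."""
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = sum(
        any(
            _match_relaxed(labels, truth, category_map, slots)
            for labels, _ in pred.ranked[:k]
        )
        for pred, truth in zip(predictions, truths)
    )
    return hits / len(predictions)


def temperature_mae(
    predictions: Sequence[ConditionPrediction], truths: Sequence[Optional[float]]
) -> float:
    """Mean absolute temperature error (°C) over records with ground truth."""
    pairs = [
        (p.temperature, t) for p, t in zip(predictions, truths) if t is not None
    ]
    if not pairs:
        raise ValueError("no ground-truth temperatures present")
    return float(np.mean([abs(a - b) for a, b in pairs]))


@dataclass
class PortfolioConfig:
    """Per-stratum beam widths and the slots entering the overall accuracy."""

    alpha_widths: BeamWidths = ALPHA_WIDTHS
    beta_widths: BeamWidths = BETA_WIDTHS
    alpha_overall_slots: tuple[int, ...] = (1, 3)  # solvent1, reagent1
    beta_overall_slots: tuple[int, ...] = (0, 1, 3)  # + catalyst
    top_ks: tuple[int, ...] = TOP_KS


def evaluate_split(
    model: ConditionTransformer,
    records: Sequence[ReactionRecord],
    portfolio: PortfolioConfig = PortfolioConfig(),
    category_map: Optional[dict[str, str]] = None,
) -> dict:
    """Catalyst-stratified evaluation report.

    Records are partitioned into Alpha (catalyst = Null) and Beta
    (catalyst present); each stratum is scored with its portfolio:
    per-slot and overall strict top-k accuracies, optional relaxed
    accuracies, and temperature MAE.  Empty strata are absent from the
    report rather than zero.
    """
    report: dict = {"n_records": len(records)}
    strata = {
        "alpha": ([r for r in records if r.conditions[0] == NULL_LABEL],
                  portfolio.alpha_widths, portfolio.alpha_overall_slots),
        "beta": ([r for r in records if r.conditions[0] != NULL_LABEL],
                 portfolio.beta_widths, portfolio.beta_overall_slots),
    }
    for name, (subset, widths, overall_slots) in strata.items():
        if not subset:
            continue
        preds = [predict_conditions(model, rec, widths) for rec in subset]
        report[name] = score_stratum(
            preds, subset, widths, overall_slots, portfolio.top_ks, category_map
        )
    return report


def score_stratum(
    preds: Sequence[ConditionPrediction],
    subset: Sequence[ReactionRecord],
    widths: BeamWidths,
    overall_slots: Sequence[int],
    top_ks: Sequence[int] = TOP_KS,
    category_map: Optional[dict[str, str]] = None,
) -> dict:
    """Score one stratum given its predictions (see :func:`evaluate_split`)."""
    truths = [rec.conditions for rec in subset]
    ks = [k for k in top_ks if k <= widths.n_combinations] or [1]
    entry: dict = {
        "n": len(subset),
        "widths": list(widths.widths),
        "overall_slots": [SLOTS[s] for s in overall_slots],
        "per_slot": {
            SLOTS[s]: {k: slot_topk_accuracy(preds, truths, s, k) for k in ks}
            for s in range(5)
        },
        "overall_strict": {
            k: strict_topk_accuracy(preds, truths, k, overall_slots) for k in ks
        },
    }
    if category_map is not None:
        entry["overall_relaxed"] = {
            k: relaxed_topk_accuracy(preds, truths, k, category_map, overall_slots)
            for k in ks
        }
    temps = [rec.temperature for rec in subset]
    if all(t is not None for t in temps):
        entry["temperature_mae"] = temperature_mae(preds, temps)
    return entry


def render_report(report: dict) -> str:
    """Plain-text table of an evaluate_split report."""
    lines = [f"records: {report['n_records']}"]
    for name in ("alpha", "beta"):
        if name not in report:
            lines.append(f"[{name}] absent (no records)")
            continue
        entry = report[name]
        ks = sorted(entry["overall_strict"])
        lines.append(
            f"[{name}] n={entry['n']} widths={tuple(entry['widths'])} "
            f"overall={'+'.join(entry['overall_slots'])}"
        )
        header = f"  {'condition':<10}" + "".join(f"top-{k:<4}" for k in ks)
        lines.append(header)
        for slot in SLOTS:
            accs = entry["per_slot"][slot]
            lines.append(
                f"  {slot:<10}" + "".join(f"{accs[k]:<8.4f}" for k in ks)
            )
        lines.append(
            f"  {'overall':<10}"
            + "".join(f"{entry['overall_strict'][k]:<8.4f}" for k in ks)
        )
        if "temperature_mae" in entry:
            lines.append(f"  temperature MAE: {entry['temperature_mae']:.2f} degC")
    return "\n".join(lines)
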