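"""Attention-based interpretability: reaction-center recovery and
fragment-condition attention score maps.

Three routes recover reaction-center atoms from a trained model's
attention weights:

1. *Cross-attention thresholding*: the decoder's cross-attention row for
   one condition slot, restricted to atom tokens and renormalized
   separately over the reactant and product sides, marks an atom active
   when its weight is at least ``mean + k * std`` (population std, per
   side).  Layer, head, k and the condition slot are chosen on a
   validation set by maximizing mean overlap score minus mean false
   positive rate.
2. *Self-attention / template route*: an atom mapper (ground-truth
   passthrough on synthetic data, or a greedy encoder-attention mapper)
   yields a reactant→product atom map from which the changed-atom
   template core is extracted.
3. *Combined*: the union of the cross route (threshold rule ∪ top-n
   atoms by weight) with the template-matched atoms.

The overlap score is OS = TP / |center|; the false positive rate is, in
its literal form, FPR = |active Δ center| / |active| (symmetric
difference), which can exceed 1 when the center is much larger than the
active set — ``fp_mode="strict"`` uses |active \\ center| instead.

The attention score map (ASM) aggregates, over a corpus, the mean
per-atom cross-attention each BRICS fragment receives under each
condition label: a hit ``e`` of fragment G contributes
``S_e = (sum of atom weights) / n_atoms(G)`` and the cell value is the
mean over all E hits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS

from .chem import (
    ReactionCenter,
    ReactionRecord,
    extract_reaction_center,
    parse_reaction,
    side_atoms,
    strip_atom_maps,
    strip_atom_maps_with_order,
)
from .model import TARGET_LEN, AttentionBundle, ConditionTransformer
from .tokenizer import TokenizedReaction, encode as encode_tokens, tokenize_reaction

AtomSet = frozenset[tuple[str, int]]
SLOT_NAMES = ("catalyst", "solvent1", "solvent2", "reagent1", "reagent2")


@dataclass(frozen=True)
class AttentionSearchParams:
    layer: int
    head: int
    k: float
    slot: int  # condition slot C in 0..4
    n: int = 0  # top-n count, combined route only

    def __post_init__(self) -> None:
        if self.slot not in range(5) or self.n < 0:
            raise ValueError("slot must be 0..4 and n >= 0")


@dataclass
class OverlapMetrics:
    tp: int
    fp: int
    os: float
    fpr: float
    active: AtomSet
    center: AtomSet


def prepare_record(
    record: ReactionRecord, center: Optional[ReactionCenter] = None
) -> tuple[ReactionRecord, Optional[ReactionCenter]]:
    """Re-express a record (and optionally its center) in map-stripped
    atom order, keeping the atom map as an explicit index dict.

    Interpretability functions index atoms in the order of the SMILES the
    model actually reads; this prepares atom-mapped records accordingly.
    """
    stripped, r_map, p_map = strip_atom_maps_with_order(record.rxn_smiles)
    atom_map = record.atom_map
    if atom_map is None:
        from .chem import atom_map_from_smiles

        parsed = atom_map_from_smiles(record.rxn_smiles)
        atom_map = parsed or None
    new_map = (
        {r_map[k]: p_map[v] for k, v in atom_map.items()} if atom_map else None
    )
    new_center = (
        ReactionCenter(
            frozenset(r_map[i] for i in center.reactant_atoms),
            frozenset(p_map[i] for i in center.product_atoms),
        )
        if center is not None
        else None
    )
    return replace(record, rxn_smiles=stripped, atom_map=new_map), new_center


def bundle_for_record(
    model: ConditionTransformer, record: ReactionRecord
) -> tuple[AttentionBundle, TokenizedReaction]:
    """Forward pass on the (map-stripped, teacher-forced) record.

    Records without ``:n`` annotations are tokenized verbatim, so atom
    indices of the returned tokenization match the record's own indexing
    (see :func:`prepare_record`).
    """
    import re as _re

    rxn = record.rxn_smiles
    if _re.search(r":\d+\]", rxn):
        rxn = strip_atom_maps(rxn)
    tok = tokenize_reaction(rxn)
    ids, mask = encode_tokens(tok, model.token_vocab, model.config.max_len)
    targets = model.cond_vocab.encode_conditions(record.conditions)
    dec_in = np.concatenate([[model.cond_vocab.bos_id], targets[: TARGET_LEN - 1]])
    model.train(False)
    bundle = model.attention_bundle(ids[None], mask[None], dec_in[None])
    return bundle, tok


def _per_side_weights(
    bundle: AttentionBundle, tok: TokenizedReaction, layer: int, head: int, slot: int
) -> dict[tuple[str, int], float]:
    """Atom-token cross-attention of one slot, renormalized per side."""
    row = bundle.cross[layer][head, slot, :]
    weights: dict[tuple[str, int], float] = {}
    for side in ("reactant", "product"):
        pos = [
            (i, ta) for i, ta in enumerate(tok.token_atom) if ta is not None and ta[0] == side
        ]
        vals = np.array([row[i] for i, _ in pos], dtype=float)
        total = vals.sum()
        if total > 0:
            vals = vals / total
        for (i, ta), v in zip(pos, vals):
            weights[ta] = float(v)
    return weights


def cross_attention_active_atoms(
    bundle: AttentionBundle,
    tok: TokenizedReaction,
    params: AttentionSearchParams,
) -> AtomSet:
    """Atoms whose per-side weight is >= mean + k * std (population, per side)."""
    weights = _per_side_weights(bundle, tok, params.layer, params.head, params.slot)
    active: set[tuple[str, int]] = set()
    for side in ("reactant", "product"):
        items = [(ta, w) for ta, w in weights.items() if ta[0] == side]
        if not items:
            continue
        vals = np.array([w for _, w in items])
        threshold = vals.mean() + params.k * vals.std()
        active |= {ta for ta, w in items if w >= threshold}
    return frozenset(active)


def top_n_atoms(
    bundle: AttentionBundle,
    tok: TokenizedReaction,
    params: AttentionSearchParams,
) -> AtomSet:
    """The n highest-weighted atoms (per-side renormalized weights, both sides)."""
    weights = _per_side_weights(bundle, tok, params.layer, params.head, params.slot)
    ranked = sorted(weights.items(), key=lambda kv: -kv[1])
    return frozenset(ta for ta, _ in ranked[: params.n])


def overlap_metrics(
    active: AtomSet, center: AtomSet, fp_mode: str = "symmetric"
) -> OverlapMetrics:
    """TP/FP/OS/FPR of an active-atom set against the ground-truth center.

    ``fp_mode="symmetric"`` (literal definition) counts |active Δ center|
    as FP; ``"strict"`` counts |active \\ center|.  0/0 ratios are 0.
    """
    active, center = frozenset(active), frozenset(center)
    tp = len(active & center)
    if fp_mode == "symmetric":
        fp = len(active ^ center)
    elif fp_mode == "strict":
        fp = len(active - center)
    else:
        raise ValueError(f"unknown fp_mode {fp_mode!r}")
    os_ = tp / len(center) if center else 0.0
    fpr = fp / len(active) if active else 0.0
    return OverlapMetrics(tp, fp, os_, fpr, active, center)


def optimize_attention_params(
    model: ConditionTransformer,
    records: Sequence[ReactionRecord],
    centers: dict[str, ReactionCenter],
    layers: Sequence[int],
    heads: Sequence[int],
    ks: Sequence[float],
    slots: Sequence[int] = range(5),
    fp_mode: str = "symmetric",
    bundle_fn: Optional[Callable] = None,
) -> tuple[AttentionSearchParams, float, float]:
    """Grid search maximizing mean OS − mean FPR on a validation set.

    Deterministic and invariant to record order; ties resolve to the
    lexicographically smallest (layer, head, k, slot).  Returns the
    winning parameters with their achieved mean OS and mean FPR.
    ``bundle_fn(model, record)`` may replace the model forward pass.
    """
    grid = list(itertools.product(layers, heads, ks, slots))
    if not grid:
        raise ValueError("empty parameter grid")
    bundle_fn = bundle_fn or bundle_for_record
    bundles = [bundle_fn(model, rec) for rec in records]
    truth = [centers[rec.record_id].as_pairs() for rec in records]
    best = None
    for layer, head, k, slot in grid:
        params = AttentionSearchParams(layer, head, k, slot)
        os_vals, fpr_vals = [], []
        for (bundle, tok), center in zip(bundles, truth):
            active = cross_attention_active_atoms(bundle, tok, params)
            m = overlap_metrics(active, center, fp_mode)
            os_vals.append(m.os)
            fpr_vals.append(m.fpr)
        score = float(np.mean(os_vals) - np.mean(fpr_vals))
        key = (-score, layer, head, k, slot)
        if best is None or key < best[0]:
            best = (key, params, float(np.mean(os_vals)), float(np.mean(fpr_vals)))
    return best[1], best[2], best[3]


# ---------------------------------------------------------------------------
# self-attention / template route
# ---------------------------------------------------------------------------

Mapper = Callable[[ReactionRecord, AttentionBundle, TokenizedReaction], dict[int, int]]


def ground_truth_mapper(
    record: ReactionRecord, bundle: AttentionBundle, tok: TokenizedReaction
) -> dict[int, int]:
    """Passthrough mapper: the record's own atom map (synthetic data)."""
    if record.atom_map is None:
        raise ValueError("record has no atom map")
    return record.atom_map


def make_greedy_attention_mapper(layer: int, head: int) -> Mapper:
    """Greedy encoder-attention mapper: pair product atoms to reactant
    atoms by descending self-attention weight, subject to element
    agreement and a one-to-one constraint.  Unmappable atoms stay
    unmapped.  A deliberate simplification of neighborhood-propagation
    attention mappers."""

    def mapper(
        record: ReactionRecord, bundle: AttentionBundle, tok: TokenizedReaction
    ) -> dict[int, int]:
        attn = bundle.encoder_self[layer][head]
        reactants, products = parse_reaction(tok.smiles)
        r_sym = [a.GetSymbol() for a in side_atoms(reactants)]
        p_sym = [a.GetSymbol() for a in side_atoms(products)]
        r_pos = {ta[1]: i for i, ta in enumerate(tok.token_atom) if ta and ta[0] == "reactant"}
        p_pos = {ta[1]: i for i, ta in enumerate(tok.token_atom) if ta and ta[0] == "product"}
        pairs = []
        for p_idx, pi in p_pos.items():
            for r_idx, ri in r_pos.items():
                if p_sym[p_idx] == r_sym[r_idx]:
                    w = float(attn[pi, ri] + attn[ri, pi])
                    pairs.append((w, r_idx, p_idx))
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_r: set[int] = set()
        used_p: set[int] = set()
        mapping: dict[int, int] = {}
        for _, r_idx, p_idx in pairs:
            if r_idx in used_r or p_idx in used_p:
                continue
            mapping[r_idx] = p_idx
            used_r.add(r_idx)
            used_p.add(p_idx)
        return mapping

    return mapper


def self_attention_active_atoms(
    bundle: AttentionBundle,
    tok: TokenizedReaction,
    record: ReactionRecord,
    mapper: Mapper = ground_truth_mapper,
) -> AtomSet:
    """Template-matched atoms from a mapper-derived atom map.

    The mapping feeds the changed-atom extraction, whose atoms (both
    sides) are returned.  An identity reaction yields the empty set.
    """
    mapping = mapper(record, bundle, tok)
    if not mapping:  # nothing mappable: no template, no active atoms
        return frozenset()
    center = extract_reaction_center(replace(record, rxn_smiles=tok.smiles, atom_map=mapping))
    return center.as_pairs()


def combined_active_atoms(
    bundle: AttentionBundle,
    tok: TokenizedReaction,
    record: ReactionRecord,
    params_cross: AttentionSearchParams,
    mapper: Mapper = ground_truth_mapper,
) -> AtomSet:
    """Union route: (threshold rule ∪ top-n by weight) ∪ template-matched atoms."""
    cross = cross_attention_active_atoms(bundle, tok, params_cross) | top_n_atoms(
        bundle, tok, params_cross
    )
    return frozenset(cross | self_attention_active_atoms(bundle, tok, record, mapper))


def center_accuracy(
    results: Sequence[tuple[AtomSet, AtomSet]], criterion: str = "half"
) -> float:
    """Fraction of records whose active atoms hit the center.

    ``"half"``: |active ∩ center| >= |center| / 2;
    ``"at_least_2"``: |active ∩ center| >= min(2, |center|), so singleton
    centers need their single atom.
    """
    if criterion not in ("half", "at_least_2"):
        raise ValueError(f"unknown criterion {criterion!r}")
    hits = 0
    for active, center in results:
        overlap = len(frozenset(active) & frozenset(center))
        need = len(center) / 2 if criterion == "half" else min(2, len(center))
        hits += overlap >= need
    return hits / len(results)


# ---------------------------------------------------------------------------
# BRICS fragment library and attention score maps
# ---------------------------------------------------------------------------

@dataclass
class Fragment:
    smiles: str  # BRICS fragment with dummy attachment points
    query: Chem.Mol  # dummy-stripped substructure query
    n_atoms: int
    count: int


@dataclass
class FragmentLibrary:
    fragments: list[Fragment]

    def __len__(self) -> int:
        return len(self.fragments)


def _strip_dummies(frag_smiles: str) -> Optional[Chem.Mol]:
    mol = Chem.MolFromSmiles(frag_smiles)
    if mol is None:
        return None
    rw = Chem.RWMol(mol)
    for idx in sorted(
        (a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0), reverse=True
    ):
        rw.RemoveAtom(idx)
    mol = rw.GetMol()
    if mol.GetNumAtoms() == 0:
        return None
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def build_fragment_library(
    records: Sequence[ReactionRecord], target_size: int = 103
) -> FragmentLibrary:
    """BRICS-fragment all reactant/product molecules and keep the
    ``target_size`` most frequent fragments (counts per molecule
    appearance; ties alphabetical)."""
    if not records:
        raise ValueError("need at least one reaction")
    counts: dict[str, int] = {}
    for rec in records:
        for mols in parse_reaction(strip_atom_maps(rec.rxn_smiles)):
            for mol in mols:
                for frag in BRICS.BRICSDecompose(mol):
                    counts[frag] = counts.get(frag, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    fragments = []
    for smi, count in ranked:
        query = _strip_dummies(smi)
        if query is None:
            continue
        fragments.append(Fragment(smi, query, query.GetNumAtoms(), count))
        if len(fragments) == target_size:
            break
    return FragmentLibrary(fragments)


@dataclass
class AttentionScoreMap:
    """Fragments × condition-labels matrix of mean per-atom attention.

    ``values[i, j]`` is NaN (absent) when fragment i was never matched
    under condition j; ``hits[i, j]`` counts the matches E.
    """

    fragment_smiles: list[str]
    condition_labels: list[str]
    values: np.ndarray
    hits: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=self.fragment_smiles, columns=self.condition_labels
        )


def _mean_head_layer_weights(
    bundle: AttentionBundle, tok: TokenizedReaction, slot: int
) -> dict[tuple[str, int], float]:
    """a_e: per-atom cross-attention to slot C, averaged over heads of all
    decoder layers, then per-side renormalized."""
    stacked = np.mean([layer[:, slot, :] for layer in bundle.cross], axis=(0, 1))
    weights: dict[tuple[str, int], float] = {}
    for side in ("reactant", "product"):
        pos = [(i, ta) for i, ta in enumerate(tok.token_atom) if ta and ta[0] == side]
        vals = np.array([stacked[i] for i, _ in pos], dtype=float)
        if vals.sum() > 0:
            vals = vals / vals.sum()
        for (_, ta), v in zip(pos, vals):
            weights[ta] = float(v)
    return weights


def compute_asm(
    model: ConditionTransformer,
    records: Sequence[ReactionRecord],
    library: FragmentLibrary,
    slot: int = 0,
    condition_source: str = "truth",
    weight_fn: Optional[Callable] = None,
) -> AttentionScoreMap:
    """Attention score map for one condition slot over a corpus.

    For every record and fragment match (hit e), S_e is the mean over
    matched atoms of the head/layer-averaged cross-attention toward the
    record's condition (ground-truth labels by default, or the model's
    greedy prediction with ``condition_source="predicted"``).
    ``weight_fn(record, slot)`` may replace the attention-derived per-atom
    weights; the model may then be None.
    """
    if condition_source not in ("truth", "predicted"):
        raise ValueError("condition_source must be 'truth' or 'predicted'")
    labels = sorted(
        {rec.conditions[slot] for rec in records}
        | (set(model.cond_vocab.per_slot_labels[slot]) if model is not None else set())
    )
    col = {lab: j for j, lab in enumerate(labels)}
    sums = np.zeros((len(library), len(labels)))
    hits = np.zeros((len(library), len(labels)), dtype=int)
    for rec in records:
        if condition_source == "predicted":
            from .inference import BeamWidths, predict_conditions

            pred = predict_conditions(model, rec, BeamWidths((1, 1, 1, 1, 1)))
            label = pred.ranked[0][0][slot]
        else:
            label = rec.conditions[slot]
        if label not in col:
            continue
        j = col[label]
        if weight_fn is not None:
            tok = tokenize_reaction(strip_atom_maps(rec.rxn_smiles))
            weights = weight_fn(rec, slot)
        else:
            bundle, tok = bundle_for_record(model, rec)
            weights = _mean_head_layer_weights(bundle, tok, slot)
        reactants, products = parse_reaction(tok.smiles)
        for side, mols in (("reactant", reactants), ("product", products)):
            offset = 0
            for mol in mols:
                for i, frag in enumerate(library.fragments):
                    for match in mol.GetSubstructMatches(frag.query):
                        s_e = (
                            sum(weights.get((side, a + offset), 0.0) for a in match)
                            / frag.n_atoms
                        )
                        sums[i, j] += s_e
                        hits[i, j] += 1
                offset += mol.GetNumAtoms()
    with np.errstate(invalid="ignore"):
        values = np.where(hits > 0, sums / np.maximum(hits, 1), np.nan)
    return AttentionScoreMap([f.smiles for f in library.fragments], labels, values, hits)
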