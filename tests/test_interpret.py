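"""Attention interpretability: overlap metrics, active-atom routes, ASM."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import BRICS

from rxncond.chem import NULL_LABEL, ReactionRecord, parse_reaction, strip_atom_maps
from rxncond.interpret import (
    AttentionSearchParams,
    Fragment,
    FragmentLibrary,
    build_fragment_library,
    bundle_for_record,
    center_accuracy,
    combined_active_atoms,
    compute_asm,
    cross_attention_active_atoms,
    ground_truth_mapper,
    make_greedy_attention_mapper,
    optimize_attention_params,
    overlap_metrics,
    prepare_record,
    self_attention_active_atoms,
    top_n_atoms,
)
from rxncond.model import AttentionBundle
from rxncond.tokenizer import tokenize_reaction


def bundle_with_cross_row(tok, row, n_layers=1, n_heads=1, layer=0, head=0):
    """Bundle whose cross-attention row for every decoder step is ``row``."""
    t = len(tok)
    cross = []
    for l in range(n_layers):
        arr = np.full((n_heads, 6, t), 1.0 / t)
        if l == layer:
            arr[head, :, :] = row
        cross.append(arr)
    enc = [np.full((n_heads, t, t), 1.0 / t) for _ in range(n_layers)]
    return AttentionBundle(encoder_self=enc, cross=cross, n_tokens=t)


@pytest.fixture()
def four_atom_case():
    # reactant atoms at token positions 1,2,4,5; product atoms at 7,8
    tok = tokenize_reaction("CC.CO>>CO")
    row = np.zeros(len(tok))
    row[[1, 2, 4, 5]] = [0.1, 0.1, 0.4, 0.4]
    row[[7, 8]] = [0.3, 0.7]
    return tok, bundle_with_cross_row(tok, row)


class TestCrossAttentionRoute:
    def test_worked_threshold_example(self, four_atom_case):
        # weights (.1,.1,.4,.4): mean .25, population std .15 -> threshold .325
        tok, bundle = four_atom_case
        active = cross_attention_active_atoms(
            bundle, tok, AttentionSearchParams(0, 0, k=0.5, slot=0)
        )
        reactant_active = {i for side, i in active if side == "reactant"}
        assert reactant_active == {2, 3}

    def test_large_k_empties_the_set(self, four_atom_case):
        tok, bundle = four_atom_case
        active = cross_attention_active_atoms(
            bundle, tok, AttentionSearchParams(0, 0, k=1e9, slot=0)
        )
        assert active == frozenset()

    def test_uniform_weights_with_k_zero_keep_all_atoms(self):
        tok = tokenize_reaction("CCO>>CCO")
        row = np.ones(len(tok))
        bundle = bundle_with_cross_row(tok, row)
        active = cross_attention_active_atoms(
            bundle, tok, AttentionSearchParams(0, 0, k=0.0, slot=0)
        )
        assert active == frozenset(
            ta for ta in tok.token_atom if ta is not None
        )

    def test_top_n_bounds(self, four_atom_case):
        tok, bundle = four_atom_case
        p0 = AttentionSearchParams(0, 0, k=0.0, slot=0, n=0)
        assert top_n_atoms(bundle, tok, p0) == frozenset()
        pall = AttentionSearchParams(0, 0, k=0.0, slot=0, n=6)
        assert top_n_atoms(bundle, tok, pall) == frozenset(
            ta for ta in tok.token_atom if ta is not None
        )


class TestOverlapMetrics:
    def test_perfect_overlap(self):
        a = frozenset({("reactant", 2), ("reactant", 3)})
        m = overlap_metrics(a, a)
        assert m.os == 1.0 and m.fpr == 0.0

    def test_set_arithmetic_example(self):
        active = frozenset({("reactant", i) for i in (1, 2, 3)})
        center = frozenset({("reactant", i) for i in (2, 3, 4)})
        m = overlap_metrics(active, center)
        assert m.os == pytest.approx(2 / 3)
        assert m.fpr == pytest.approx(2 / 3)  # |active ^ center| / |active|

    def test_degenerate_zero_over_zero(self):
        m = overlap_metrics(frozenset(), frozenset({("reactant", 1)}))
        assert m.os == 0.0 and m.fpr == 0.0

    def test_matches_independent_oracle_on_random_pairs(self):
        rng = np.random.default_rng(1)
        universe = [("reactant", i) for i in range(12)] + [("product", i) for i in range(12)]
        for _ in range(1000):
            active = frozenset(
                u for u in universe if rng.random() < 0.3
            )
            center = frozenset(u for u in universe if rng.random() < 0.3)
            m = overlap_metrics(active, center)
            inter = sum(1 for u in universe if u in active and u in center)
            sym = sum(1 for u in universe if (u in active) != (u in center))
            assert m.tp == inter
            assert m.os == (inter / len(center) if center else 0.0)
            assert m.fpr == (sym / len(active) if active else 0.0)
            strict = overlap_metrics(active, center, fp_mode="strict")
            assert strict.fp == len(active - center)

    def test_strict_mode_fpr_bounded_by_one(self):
        active = frozenset({("reactant", 0)})
        center = frozenset({("reactant", i) for i in range(9)})
        assert overlap_metrics(active, center).fpr > 1.0  # literal definition
        assert overlap_metrics(active, center, fp_mode="strict").fpr <= 1.0


class TestParameterSearch:
    def planted(self, records, centers):
        """Bundles where head 1 of layer 0 concentrates on center atoms."""

        def bundle_fn(model, rec):
            tok = tokenize_reaction(rec.rxn_smiles)
            center = centers[rec.record_id].as_pairs()
            row = np.full(len(tok), 0.01)
            for i, ta in enumerate(tok.token_atom):
                if ta in center:
                    row[i] = 5.0
            bundle = bundle_with_cross_row(tok, row, n_heads=2, layer=0, head=1)
            return bundle, tok

        return bundle_fn

    def test_single_point_grid_returned(self, untrained_model, records, centers):
        prepped = [prepare_record(r, centers[r.record_id]) for r in records[:3]]
        recs = [r for r, _ in prepped]
        cents = {r.record_id: c for r, c in prepped}
        params, _, _ = optimize_attention_params(
            untrained_model, recs, cents, layers=[0], heads=[1], ks=[0.5], slots=[2]
        )
        assert params == AttentionSearchParams(0, 1, 0.5, 2)

    def test_planted_head_is_selected(self, records, centers):
        prepped = [prepare_record(r, centers[r.record_id]) for r in records[:10]]
        recs = [r for r, _ in prepped]
        cents = {r.record_id: c for r, c in prepped}
        params, os_mean, fpr_mean = optimize_attention_params(
            None, recs, cents, layers=[0], heads=[0, 1], ks=[1.0],
            slots=[0], bundle_fn=self.planted(recs, cents),
        )
        assert params.head == 1
        assert os_mean > 0.9

    def test_exhaustive_grid_matches_brute_force(self, records, centers):
        prepped = [prepare_record(r, centers[r.record_id]) for r in records[:5]]
        recs = [r for r, _ in prepped]
        cents = {r.record_id: c for r, c in prepped}
        bundle_fn = self.planted(recs, cents)
        grid = [(l, h, k, s) for l in [0] for h in [0, 1] for k in [0.0, 1.0] for s in [0, 1]]
        # brute force oracle
        best_score, best_point = -np.inf, None
        for l, h, k, s in grid:
            oss, fprs = [], []
            for rec in recs:
                bundle, tok = bundle_fn(None, rec)
                active = cross_attention_active_atoms(
                    bundle, tok, AttentionSearchParams(l, h, k, s)
                )
                m = overlap_metrics(active, cents[rec.record_id].as_pairs())
                oss.append(m.os)
                fprs.append(m.fpr)
            score = np.mean(oss) - np.mean(fprs)
            if score > best_score + 1e-12:
                best_score, best_point = score, (l, h, k, s)
        params, os_mean, fpr_mean = optimize_attention_params(
            None, recs, cents, layers=[0], heads=[0, 1], ks=[0.0, 1.0],
            slots=[0, 1], bundle_fn=bundle_fn,
        )
        assert (params.layer, params.head, params.k, params.slot) == best_point
        assert os_mean - fpr_mean == pytest.approx(best_score)

    def test_result_invariant_to_record_order(self, records, centers):
        prepped = [prepare_record(r, centers[r.record_id]) for r in records[:6]]
        recs = [r for r, _ in prepped]
        cents = {r.record_id: c for r, c in prepped}
        bundle_fn = self.planted(recs, cents)
        a = optimize_attention_params(
            None, recs, cents, [0], [0, 1], [1.0], [0], bundle_fn=bundle_fn
        )
        b = optimize_attention_params(
            None, recs[::-1], cents, [0], [0, 1], [1.0], [0], bundle_fn=bundle_fn
        )
        assert a[0] == b[0] and a[1] == pytest.approx(b[1])

    def test_empty_grid_rejected(self, untrained_model):
        with pytest.raises(ValueError):
            optimize_attention_params(untrained_model, [], {}, [], [], [])


class TestSelfAttentionRoute:
    def test_ground_truth_mapper_recovers_generator_centers(
        self, untrained_model, records, centers
    ):
        for rec in records[:30]:
            prec, pcen = prepare_record(rec, centers[rec.record_id])
            bundle, tok = bundle_for_record(untrained_model, prec)
            active = self_attention_active_atoms(bundle, tok, prec, ground_truth_mapper)
            assert active == pcen.as_pairs()

    def test_identity_reaction_yields_empty_set(self, untrained_model):
        rec = ReactionRecord(
            "CCO>>CCO", (NULL_LABEL,) * 5, atom_map={0: 0, 1: 1, 2: 2}, record_id="id0"
        )
        bundle, tok = bundle_for_record(untrained_model, rec)
        assert self_attention_active_atoms(bundle, tok, rec, ground_truth_mapper) == frozenset()

    def test_greedy_mapper_recovers_identity_on_diagonal_fixture(self):
        rec = ReactionRecord("NCO>>NCO", (NULL_LABEL,) * 5, record_id="id1")
        tok = tokenize_reaction(rec.rxn_smiles)
        t = len(tok)
        attn = np.full((1, t, t), 1e-4)
        r_pos = {ta[1]: i for i, ta in enumerate(tok.token_atom) if ta and ta[0] == "reactant"}
        p_pos = {ta[1]: i for i, ta in enumerate(tok.token_atom) if ta and ta[0] == "product"}
        for idx in r_pos:
            attn[0, p_pos[idx], r_pos[idx]] = 1.0
        bundle = AttentionBundle([attn], [np.full((1, 6, t), 1.0 / t)], t)
        mapper = make_greedy_attention_mapper(layer=0, head=0)
        assert mapper(rec, bundle, tok) == {0: 0, 1: 1, 2: 2}
        assert self_attention_active_atoms(bundle, tok, rec, mapper) == frozenset()


class TestCombinedRoute:
    def test_reduces_to_threshold_rule_without_template_or_topn(self, four_atom_case):
        tok, bundle = four_atom_case
        rec = ReactionRecord("CC.CO>>CO", (NULL_LABEL,) * 5, record_id="x")
        params = AttentionSearchParams(0, 0, k=0.5, slot=0, n=0)
        empty_mapper = lambda record, bundle, tok: {}
        combined = combined_active_atoms(bundle, tok, rec, params, empty_mapper)
        assert combined == cross_attention_active_atoms(bundle, tok, params)

    def test_union_attains_full_overlap_when_routes_split_the_center(
        self, untrained_model, records, centers
    ):
        rec = records[0]
        prec, pcen = prepare_record(rec, centers[rec.record_id])
        center_pairs = sorted(pcen.as_pairs())
        half = center_pairs[: len(center_pairs) // 2]
        tok = tokenize_reaction(prec.rxn_smiles)
        row = np.zeros(len(tok))
        for i, ta in enumerate(tok.token_atom):
            if ta in half:
                row[i] = 10.0
            elif ta is not None:
                row[i] = 0.01
        bundle = bundle_with_cross_row(tok, row)
        params = AttentionSearchParams(0, 0, k=1.0, slot=0, n=0)

        def other_half_mapper(record, bundle, tok):
            return ground_truth_mapper(record, bundle, tok)

        combined = combined_active_atoms(bundle, tok, prec, params, other_half_mapper)
        m = overlap_metrics(combined, pcen.as_pairs())
        assert m.os == 1.0

    def test_combined_os_never_below_single_routes(
        self, untrained_model, records, centers
    ):
        params = AttentionSearchParams(0, 0, k=1.0, slot=0, n=2)
        for rec in records[:15]:
            prec, pcen = prepare_record(rec, centers[rec.record_id])
            bundle, tok = bundle_for_record(untrained_model, prec)
            cross = cross_attention_active_atoms(bundle, tok, params)
            self_route = self_attention_active_atoms(bundle, tok, prec, ground_truth_mapper)
            combined = combined_active_atoms(bundle, tok, prec, params, ground_truth_mapper)
            truth = pcen.as_pairs()
            os_cross = overlap_metrics(cross, truth).os
            os_self = overlap_metrics(self_route, truth).os
            os_comb = overlap_metrics(combined, truth).os
            assert os_comb >= max(os_cross, os_self)


class TestCenterAccuracy:
    def test_superset_hits_both_criteria(self):
        results = [
            (frozenset({("reactant", i) for i in range(6)}),
             frozenset({("reactant", i) for i in range(4)}))
        ] * 3
        assert center_accuracy(results, "half") == 1.0
        assert center_accuracy(results, "at_least_2") == 1.0

    def test_half_overlap_of_size_four_center(self):
        active = frozenset({("reactant", 0), ("reactant", 1)})
        center = frozenset({("reactant", i) for i in range(4)})
        assert center_accuracy([(active, center)], "half") == 1.0
        assert center_accuracy([(active, center)], "at_least_2") == 1.0
        smaller = frozenset({("reactant", 0)})
        assert center_accuracy([(smaller, center)], "half") == 0.0
        assert center_accuracy([(smaller, center)], "at_least_2") == 0.0

    def test_singleton_center_uses_min_convention(self):
        active = frozenset({("reactant", 3)})
        center = frozenset({("reactant", 3)})
        assert center_accuracy([(active, center)], "at_least_2") == 1.0

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            center_accuracy([(frozenset(), frozenset())], "most")


class TestFragmentLibrary:
    def test_single_benzene_corpus(self):
        rec = ReactionRecord("c1ccccc1>>c1ccccc1", (NULL_LABEL,) * 5, record_id="bz")
        lib = build_fragment_library([rec], target_size=103)
        expected = set(BRICS.BRICSDecompose(Chem.MolFromSmiles("c1ccccc1")))
        assert {f.smiles for f in lib.fragments} <= expected | {"c1ccccc1"}
        assert len(lib) >= 1

    def test_counts_non_increasing_and_match_recount(self, records):
        lib = build_fragment_library(records[:60], target_size=20)
        counts = [f.count for f in lib.fragments]
        assert counts == sorted(counts, reverse=True)
        # independent recount oracle
        recount = {}
        for rec in records[:60]:
            for mols in parse_reaction(strip_atom_maps(rec.rxn_smiles)):
                for mol in mols:
                    for frag in BRICS.BRICSDecompose(mol):
                        recount[frag] = recount.get(frag, 0) + 1
        for f in lib.fragments:
            assert recount[f.smiles] == f.count

    def test_small_corpus_returns_fewer_than_target(self, records):
        lib = build_fragment_library(records[:3], target_size=103)
        assert len(lib) < 103

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_fragment_library([])


class TestAttentionScoreMap:
    def two_atom_example(self):
        rec = ReactionRecord("OCCO>>C", ("lab", *("Null",) * 4), record_id="h")
        query = Chem.MolFromSmiles("CO")
        lib = FragmentLibrary([Fragment("CO", query, 2, 2)])
        weights = {
            ("reactant", 0): 0.2,  # O of hit 1
            ("reactant", 1): 0.4,  # C of hit 1
            ("reactant", 2): 0.1,  # C of hit 2
            ("reactant", 3): 0.1,  # O of hit 2
            ("product", 0): 0.0,
        }
        return rec, lib, weights

    def test_hand_computed_cell(self):
        rec, lib, weights = self.two_atom_example()
        asm = compute_asm(
            None, [rec], lib, slot=0, weight_fn=lambda r, s: weights
        )
        j = asm.condition_labels.index("lab")
        assert asm.hits[0, j] == 2  # S1 = 0.3, S2 = 0.1
        assert asm.values[0, j] == pytest.approx(0.2)

    def test_uniform_attention_gives_one_over_m(self):
        rec = ReactionRecord("CCCO>>C", ("lab", *("Null",) * 4), record_id="u")
        query = Chem.MolFromSmiles("CO")
        lib = FragmentLibrary([Fragment("CO", query, 2, 1)])
        m = 4  # reactant-side atoms; uniform per-side weight is 1/m
        weights = {("reactant", i): 1 / m for i in range(m)}
        weights[("product", 0)] = 1.0
        asm = compute_asm(None, [rec], lib, slot=0, weight_fn=lambda r, s: weights)
        j = asm.condition_labels.index("lab")
        assert asm.values[0, j] == pytest.approx(1 / m)

    def test_unmatched_fragment_cell_is_absent(self):
        rec, lib, weights = self.two_atom_example()
        lib.fragments.append(Fragment("N", Chem.MolFromSmiles("N"), 1, 1))
        asm = compute_asm(None, [rec], lib, slot=0, weight_fn=lambda r, s: weights)
        j = asm.condition_labels.index("lab")
        assert np.isnan(asm.values[1, j])
        assert asm.hits[1, j] == 0

    def test_model_asm_cells_lie_in_unit_interval(self, trained_model, learnability_split):
        _, _, _, _, test_set = learnability_split
        lib = build_fragment_library(test_set[:20], target_size=15)
        asm = compute_asm(trained_model, test_set[:20], lib, slot=0)
        vals = asm.values[np.isfinite(asm.values)]
        assert len(vals) > 0
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_dataframe_export_shape(self):
        rec, lib, weights = self.two_atom_example()
        asm = compute_asm(None, [rec], lib, slot=0, weight_fn=lambda r, s: weights)
        df = asm.to_dataframe()
        assert df.shape == (len(lib), len(asm.condition_labels))
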