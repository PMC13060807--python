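"""Threshold selection, exclusion hygiene, and the agreement filter."""

from __future__ import annotations

import math

import pytest

from sigmatch import (
    MatchComponents,
    ReferenceRelation,
    loocv_select_threshold,
    logrank_prioritization,
    predict_relations,
)
from sigmatch.containers import PerturbagenKind
from sigmatch.loocv import THRESHOLD_GRID, candidate_pairs, known_targets
from tests.conftest import make_signature


def mk(df1: float, t: float = 0.0) -> MatchComponents:
    """MatchComponents stub carrying only the DF1 value."""
    return MatchComponents(0, 0, 0, 0, 0, 0, 0, 0, 0, 0, df1, t)


POS_PAIRS = {  # drug_gene, DF1 > 0 => predicted inhibitory (-1)
    ("P1", "g1"): -1, ("P1", "g2"): -1, ("P2", "g3"): -1,  # correct
    ("P2", "g4"): 1, ("P3", "g5"): 1,                      # incorrect
}
NEG_PAIRS = {  # DF1 < 0 => predicted supportive (+1)
    ("P1", "g6"): 1, ("P2", "g7"): 1, ("P3", "g8"): 1,     # correct
    ("P4", "g9"): -1, ("P4", "g10"): -1,                   # incorrect
}
REFS = [
    ReferenceRelation(m, g, "drug_gene", d)
    for pairs in (POS_PAIRS, NEG_PAIRS)
    for (m, g), d in pairs.items()
]


def build_table(t_pos_best: float, t_neg_best: float,
                query_scores: dict[float, float]):
    """DF1 tables where only the given thresholds separate well.

    At ``t_pos_best`` the positively-scored reference pairs rank correct
    above incorrect; everywhere else they interleave badly.  Likewise for
    ``t_neg_best`` on the negative side.  ``query_scores`` sets the DF1 of
    the query pair ("D", "q") per threshold.
    """
    good_pos = {("P1", "g1"): 0.9, ("P1", "g2"): 0.8, ("P2", "g3"): 0.7,
                ("P2", "g4"): 0.1, ("P3", "g5"): 0.2}
    bad_pos = {("P1", "g1"): 0.1, ("P1", "g2"): 0.15, ("P2", "g3"): 0.2,
               ("P2", "g4"): 0.4, ("P3", "g5"): 0.5}
    good_neg = {("P1", "g6"): -0.9, ("P2", "g7"): -0.8, ("P3", "g8"): -0.7,
                ("P4", "g9"): -0.1, ("P4", "g10"): -0.2}
    bad_neg = {("P1", "g6"): -0.1, ("P2", "g7"): -0.15, ("P3", "g8"): -0.2,
               ("P4", "g9"): -0.4, ("P4", "g10"): -0.5}
    table = {}
    for t in THRESHOLD_GRID:
        entry = {}
        entry.update({p: mk(v, t) for p, v in
                      (good_pos if t == t_pos_best else bad_pos).items()})
        entry.update({p: mk(v, t) for p, v in
                      (good_neg if t == t_neg_best else bad_neg).items()})
        if t in query_scores:
            entry[("D", "q")] = mk(query_scores[t], t)
        table[t] = entry
    return table


class TestSelectThreshold:
    def test_separating_threshold_wins(self):
        table = build_table(0.5, 0.7, {})
        t_pos = loocv_select_threshold(("D", "q"), table, REFS, +1, "drug_gene")
        t_neg = loocv_select_threshold(("D", "q"), table, REFS, -1, "drug_gene")
        assert (t_pos, t_neg) == (0.5, 0.7)

    def test_selection_matches_direct_logrank_argmax(self):
        """Independent recomputation of the statistic at every grid point."""
        table = build_table(0.4, 0.0, {})
        best, best_z = None, -math.inf
        for t in THRESHOLD_GRID:
            correct, incorrect = [], []
            for pair, d in POS_PAIRS.items():
                df1 = table[t][pair].DF1
                (correct if d == -1 else incorrect).append(abs(df1))
            z, _ = logrank_prioritization(correct, incorrect)
            if not math.isnan(z) and z > best_z:
                best, best_z = t, z
        assert loocv_select_threshold(("D", "q"), table, REFS, +1,
                                      "drug_gene") == best == 0.4

    def test_all_ties_pick_smallest(self):
        table = {t: {p: mk(v, t) for p, v in
                     {("P1", "g1"): 0.9, ("P1", "g2"): 0.8, ("P2", "g3"): 0.7,
                      ("P2", "g4"): 0.1, ("P3", "g5"): 0.2}.items()}
                 for t in THRESHOLD_GRID}
        assert loocv_select_threshold(("D", "q"), table, REFS, +1,
                                      "drug_gene") == 0.0

    def test_undefined_when_no_evaluable_relations(self):
        table = {t: {} for t in THRESHOLD_GRID}
        assert loocv_select_threshold(("D", "q"), table, REFS, +1,
                                      "drug_gene") is None

    def test_excludes_modifier_and_its_targets(self):
        """Relations touching A or any reference target of A never enter."""
        table = build_table(0.5, 0.7, {})
        audit: dict = {}
        loocv_select_threshold(("P1", "g3"), table, REFS, +1, "drug_gene",
                               audit=audit)
        banned = {"P1"} | known_targets("P1", REFS)
        assert banned == {"P1", "g1", "g2", "g6"}
        for relations in audit.values():
            for r in relations:
                assert r.modifier_id not in banned
                assert r.target_id not in banned

    def test_small_groups_cannot_be_selected(self):
        # only one incorrect relation at every threshold: statistic undefined
        pairs = {("P1", "g1"): 0.9, ("P1", "g2"): 0.8, ("P2", "g4"): 0.1}
        table = {t: {p: mk(v, t) for p, v in pairs.items()}
                 for t in THRESHOLD_GRID}
        assert loocv_select_threshold(("D", "q"), table, REFS, +1,
                                      "drug_gene") is None


def _signature_set():
    sigs = {}
    genes = [f"g{i}" for i in range(1, 11)] + ["q"]
    for g in genes:
        sigs[g] = make_signature(g, {"x": 0.5})
    for d in ["D", "P1", "P2", "P3", "P4"]:
        sigs[d] = make_signature(d, {"x": 0.5},
                                 kind=PerturbagenKind.drug_treatment)
    return sigs


class TestPredictRelations:
    def test_agreement_filter_drops_conflicting_optima(self):
        table = build_table(0.0, 0.5, {0.0: 0.3, 0.5: -0.2})
        preds = predict_relations(_signature_set(), REFS, "drug_gene",
                                  matches_by_T=table)
        assert not any(p.modifier_id == "D" and p.target_id == "q"
                       for p in preds)

    def test_agreeing_optima_keep_prediction(self):
        table = build_table(0.0, 0.5, {0.0: 0.3, 0.5: 0.01})
        preds = predict_relations(_signature_set(), REFS, "drug_gene",
                                  matches_by_T=table)
        query = [p for p in preds if p.modifier_id == "D" and p.target_id == "q"]
        assert len(query) == 1
        pred = query[0]
        # positive DF1 on a drug-gene relation reads as inhibition
        assert pred.direction == -1
        assert pred.score == pytest.approx(0.3)
        assert (pred.T_pos, pred.T_neg) == (0.0, 0.5)

    def test_zero_at_both_optima_no_prediction(self):
        table = build_table(0.0, 0.5, {0.0: 0.0, 0.5: 0.0})
        preds = predict_relations(_signature_set(), REFS, "drug_gene",
                                  matches_by_T=table)
        assert not any(p.modifier_id == "D" and p.target_id == "q"
                       for p in preds)

    def test_every_emitted_prediction_satisfies_direction_contract(self):
        table = build_table(0.0, 0.5, {0.0: 0.3, 0.5: 0.01})
        for p in predict_relations(_signature_set(), REFS, "drug_gene",
                                   matches_by_T=table):
            assert p.direction in (1, -1) and p.score >= 0

    def test_candidate_pairs_by_class(self):
        sigs = _signature_set()
        drug_pairs = candidate_pairs(sigs, "drug_gene")
        gene_pairs = candidate_pairs(sigs, "gene_gene")
        assert all(m.startswith(("D", "P")) for m, _ in drug_pairs)
        assert all(not m.startswith(("D", "P")) for m, _ in gene_pairs)
        assert all(m != g for m, g in gene_pairs)
        covered = candidate_pairs(sigs, "drug_gene", REFS, restrict_to_refs=True)
        assert set(covered) == set(POS_PAIRS) | set(NEG_PAIRS)


class TestLowNoiseRecovery:
    def test_inhibitory_predictions_prioritize_planted_truth(self, planted_dataset):
        """Emitted inhibitory drug-gene predictions rank planted-correct
        relations above planted-incorrect ones on a strong-effect network."""
        net, _, _, signatures = planted_dataset
        refs = net.to_reference_relations()
        preds = predict_relations(signatures, refs, "drug_gene")
        truth = {(r.modifier_id, r.target_id): r.direction
                 for r in refs if r.relation_class == "drug_gene"}
        covered = [p for p in preds if p.direction == -1
                   and (p.modifier_id, p.target_id) in truth]
        correct = [p.score for p in covered
                   if truth[(p.modifier_id, p.target_id)] == -1]
        incorrect = [p.score for p in covered
                     if truth[(p.modifier_id, p.target_id)] == 1]
        z, _ = logrank_prioritization(correct, incorrect)
        assert z > 0
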