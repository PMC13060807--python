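"""Per-pair DEG-threshold selection by leave-one-out cross-validation.

For a candidate relation from modifier A to target B, the DEG threshold T
is not fixed globally: it is chosen, per pair, as the grid value whose DF1
scores best prioritize correct over incorrect reference relations (highest
signed log-rank statistic) — computed only on reference relations involving
neither A nor any of A's known targets, so the held-out pair never informs
its own threshold.  Positive and negative predictions get separate optima,
and a pair whose two optima disagree in sign is not predicted at all.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional, Sequence

from .containers import (
    MatchComponents,
    PerturbationSignature,
    PerturbagenKind,
    ReferenceRelation,
    RelationPrediction,
)
from .matching import df1_match, interpret_direction
from .stats import logrank_prioritization

logger = logging.getLogger(__name__)

#: DEG thresholds swept by the cross-validation
THRESHOLD_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(10))

MatchTable = dict[float, dict[tuple[str, str], MatchComponents]]


def compute_match_table(
    signatures: Mapping[str, PerturbationSignature],
    pairs: Iterable[tuple[str, str]],
    grid: Sequence[float] = THRESHOLD_GRID,
) -> MatchTable:
    """DF1 components for every (modifier, target) pair at every grid T."""
    table: MatchTable = {float(t): {} for t in grid}
    for a, b in pairs:
        sig_a, sig_b = signatures.get(a), signatures.get(b)
        if sig_a is None or sig_b is None:
            logger.warning("missing signature for pair (%s, %s); skipped", a, b)
            continue
        for t in grid:
            table[float(t)][(a, b)] = df1_match(sig_a, sig_b, float(t))
    return table


def known_targets(modifier: str, refs: Iterable[ReferenceRelation]) -> set[str]:
    """Targets of ``modifier`` in the reference database."""
    return {r.target_id for r in refs if r.modifier_id == modifier}


def loocv_select_threshold(
    pair: tuple[str, str],
    matches_by_T: MatchTable,
    refs: Sequence[ReferenceRelation],
    sign: int,
    relation_class: str,
    *,
    grid: Sequence[float] = THRESHOLD_GRID,
    audit: Optional[dict] = None,
) -> Optional[float]:
    """Best DEG threshold for scoring ``pair``, excluding its own evidence.

    Reference relations involving (as modifier or target) A or any known
    target of A are excluded.  At each grid T, the remaining relations whose
    DF1 carries the requested ``sign`` are split into correct and incorrect
    by whether the implied direction matches the reference; the signed
    log-rank statistic of correct vs incorrect over |DF1| ranks the
    thresholds.  A threshold whose correct or incorrect group has fewer than
    two members cannot be selected.  Ties break toward the smallest T (the
    largest DEG sets).  Returns None when no threshold is evaluable.

    ``audit``, if given, records {T: list of relations evaluated} so that
    leave-one-out hygiene can be asserted externally.
    """
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    a, _ = pair
    excluded = {a} | known_targets(a, refs)
    usable = [
        r
        for r in refs
        if r.relation_class == relation_class
        and r.modifier_id not in excluded
        and r.target_id not in excluded
    ]
    best_t: Optional[float] = None
    best_z = -math.inf
    for t in grid:
        t = float(t)
        matches = matches_by_T[t]
        correct: list[float] = []
        incorrect: list[float] = []
        evaluated: list[ReferenceRelation] = []
        for r in usable:
            mc = matches.get((r.modifier_id, r.target_id))
            if mc is None:
                continue
            df1 = mc.DF1
            if df1 == 0 or (df1 > 0) != (sign > 0):
                continue
            evaluated.append(r)
            predicted = interpret_direction(df1, relation_class)
            (correct if predicted == r.direction else incorrect).append(abs(df1))
        if audit is not None:
            audit[t] = evaluated
        z, _ = logrank_prioritization(correct, incorrect)
        if math.isnan(z):
            continue
        if z > best_z:
            best_z, best_t = z, t
    if best_t is None:
        logger.debug("pair %s: no evaluable threshold for sign %+d", pair, sign)
    return best_t


def candidate_pairs(
    signatures: Mapping[str, PerturbationSignature],
    relation_class: str,
    refs: Sequence[ReferenceRelation] = (),
    *,
    restrict_to_refs: bool = False,
) -> list[tuple[str, str]]:
    """Scorable (modifier, target) pairs for a relation class.

    Modifiers are drug signatures for drug_gene and disruption signatures
    for gene_gene; targets are always gene-disruption signatures.  With
    ``restrict_to_refs`` only reference-covered pairs are kept (the
    evaluation-run mode).
    """
    gene_sigs = [
        p for p, s in signatures.items() if s.kind is PerturbagenKind.gene_disruption
    ]
    if relation_class == "drug_gene":
        modifiers = [
            p for p, s in signatures.items() if s.kind is PerturbagenKind.drug_treatment
        ]
    else:
        modifiers = gene_sigs
    pairs = [(m, g) for m in modifiers for g in gene_sigs if m != g]
    if restrict_to_refs:
        covered = {
            (r.modifier_id, r.target_id)
            for r in refs
            if r.relation_class == relation_class
        }
        pairs = [p for p in pairs if p in covered]
    return pairs


def predict_relations(
    signatures: Mapping[str, PerturbationSignature],
    refs: Sequence[ReferenceRelation],
    relation_class: str,
    *,
    grid: Sequence[float] = THRESHOLD_GRID,
    restrict_to_refs: bool = False,
    matches_by_T: Optional[MatchTable] = None,
) -> list[RelationPrediction]:
    """Score every candidate pair with per-pair LOOCV thresholds.

    For each pair, DF1 is evaluated at the positive- and negative-optimized
    thresholds.  If the two signed values are both nonzero and disagree in
    sign the pair is dropped (directionality-agreement filter); otherwise
    the prediction carries the shared sign, the |DF1| of the optimization
    whose sign matches, and the direction implied by the relation class.
    """
    pairs = candidate_pairs(signatures, relation_class, refs,
                            restrict_to_refs=restrict_to_refs)
    if matches_by_T is None:
        ref_pairs = {
            (r.modifier_id, r.target_id)
            for r in refs
            if r.relation_class == relation_class
        }
        matches_by_T = compute_match_table(
            signatures, set(pairs) | ref_pairs, grid
        )
    predictions: list[RelationPrediction] = []
    for pair in pairs:
        t_pos = loocv_select_threshold(
            pair, matches_by_T, refs, +1, relation_class, grid=grid
        )
        t_neg = loocv_select_threshold(
            pair, matches_by_T, refs, -1, relation_class, grid=grid
        )
        df1_pos = (
            matches_by_T[t_pos][pair].DF1 if t_pos is not None
            and pair in matches_by_T[t_pos] else None
        )
        df1_neg = (
            matches_by_T[t_neg][pair].DF1 if t_neg is not None
            and pair in matches_by_T[t_neg] else None
        )
        nonzero = [v for v in (df1_pos, df1_neg) if v is not None and v != 0]
        if not nonzero:
            if df1_pos is None and df1_neg is None:
                logger.warning("pair %s: no evaluable threshold; skipped", pair)
            continue
        if len(nonzero) == 2 and (nonzero[0] > 0) != (nonzero[1] > 0):
            continue  # optima disagree on direction: no prediction
        shared = 1 if nonzero[0] > 0 else -1
        if shared > 0 and df1_pos:
            score_src = df1_pos
        elif shared < 0 and df1_neg:
            score_src = df1_neg
        else:
            score_src = nonzero[0]
        direction = interpret_direction(score_src, relation_class)
        assert direction is not None
        predictions.append(
            RelationPrediction(
                modifier_id=pair[0],
                target_id=pair[1],
                relation_class=relation_class,
                direction=direction,
                score=abs(score_src),
                provenance="df1_loocv",
                T_pos=t_pos,
                T_neg=t_neg,
            )
        )
    return predictions
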