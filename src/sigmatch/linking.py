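"""Indirect predictions: chaining DF1 matches through gene coexpression.

A direct DF1 match only relates a perturbagen A to genes whose disruption
was actually assayed.  Coexpression linking extends the reach: the signed
DF1 between A and an assayed intermediate gene B is multiplied by the
Pearson correlation r(B, C) to yield a contribution toward an end target C,
and contributions from all intermediates are aggregated with the same
conflict-penalized quadratic form the DF1 score itself uses.  The
aggregation is a pluggable strategy so alternative linking formulas can be
dropped in.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .containers import CoexpressionMatrix, RelationPrediction
from .matching import interpret_direction

logger = logging.getLogger(__name__)

Aggregator = Callable[[Sequence[float]], float]


def signed_df1_table(predictions: Sequence[RelationPrediction]) -> dict[str, dict[str, float]]:
    """Recover signed DF1 values, keyed modifier -> target, from predictions.

    Inverts :func:`sigmatch.matching.interpret_direction`: a gene-gene
    prediction's sign equals its direction, a drug-gene prediction's sign is
    the negated direction.
    """
    out: dict[str, dict[str, float]] = {}
    for p in predictions:
        sign = p.direction if p.relation_class == "gene_gene" else -p.direction
        out.setdefault(p.modifier_id, {})[p.target_id] = sign * p.score
    return out


def conflict_penalized_sum(contributions: Sequence[float]) -> float:
    """Default aggregation: 2*(pos-neg)*|pos-neg| / (pos+neg+1).

    pos and neg are the summed positive and negative contribution
    magnitudes.  Perfectly conflicting evidence cancels to exactly 0; the
    +1 keeps sparse evidence from looking confident.
    """
    arr = np.asarray(contributions, dtype=float)
    pos = float(arr[arr > 0].sum())
    neg = float(-arr[arr < 0].sum())
    return 2 * (pos - neg) * abs(pos - neg) / (pos + neg + 1)


def link_predictions(
    df1_scores: Mapping[str, Mapping[str, float]],
    coexpr: CoexpressionMatrix,
    relation_class: str,
    *,
    aggregate: Aggregator = conflict_penalized_sum,
    min_abs_df1: float = 0.0,
    min_abs_r: float = 0.0,
    provenance: str = "coexpr_link",
) -> list[RelationPrediction]:
    """Link per-modifier DF1 scores to end targets through coexpression.

    ``df1_scores[A][B]`` is the signed DF1 between modifier A and the
    disruption signature of intermediate gene B.  For every end target C in
    the coexpression matrix (C != B for each intermediate), contributions
    DF1(A, B) * r(B, C) are aggregated into one signed linked score; its
    sign is interpreted exactly like a direct DF1 of the same relation
    class.  Optional magnitude floors on |DF1| and |r| control fan-out.
    Targets or intermediates absent from the matrix are skipped.
    """
    genes = coexpr.gene_ids
    gene_index = {g: i for i, g in enumerate(genes)}
    rmat = coexpr.r.to_numpy()
    predictions: list[RelationPrediction] = []
    for modifier, inner in df1_scores.items():
        usable = [
            (b, v) for b, v in inner.items()
            if abs(v) > min_abs_df1 and b in gene_index
        ]
        skipped = [b for b in inner if b not in gene_index]
        if skipped:
            logger.warning(
                "modifier %s: %d intermediate(s) lack coexpression rows",
                modifier, len(skipped),
            )
        if not usable:
            continue
        for c in genes:
            if relation_class == "gene_gene" and c == modifier:
                continue
            contributions = []
            for b, v in usable:
                if b == c:
                    continue  # the direct match already covers B itself
                r = rmat[gene_index[b], gene_index[c]]
                if abs(r) < min_abs_r:
                    continue
                contributions.append(v * r)
            if not contributions:
                continue
            linked = aggregate(contributions)
            direction = interpret_direction(linked, relation_class)
            if direction is None:
                continue
            predictions.append(
                RelationPrediction(
                    modifier_id=modifier,
                    target_id=c,
                    relation_class=relation_class,
                    direction=direction,
                    score=abs(linked),
                    provenance=provenance,
                )
            )
    return predictions
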