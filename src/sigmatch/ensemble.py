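"""Confidence-calibrated ensemble of relation predictors.

Each predictor's raw scores mean nothing across tools, so they are mapped
to accuracy estimates (a-hat) by leave-one-out calibration: for a query
relation A -> B, every reference relation involving A or B is excluded, and
the predictor's accuracy among the remaining reference-covered predictions
at scores >= s becomes a-hat(s).  The ensemble then simply believes
whichever predictor reports the highest a-hat for the query, which lets a
confident-but-wrong tool act as a filter on the rarer direction.
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .containers import (
    AccuracyCurve,
    CalibrationMap,
    ReferenceRelation,
    RelationPrediction,
)
from .stats import accuracy_curve

__all__ = ["calibrate", "ensemble_predict", "loocv_ensemble_evaluate"]


def _ref_key(r: ReferenceRelation) -> tuple[str, str, str]:
    return (r.modifier_id, r.target_id, r.relation_class)


def calibrate(
    predictor_preds: Sequence[RelationPrediction],
    refs_heldout: Sequence[ReferenceRelation],
    *,
    predictor: str = "",
) -> dict[int, CalibrationMap]:
    """Map one predictor's scores to accuracy estimates, per direction.

    Only predictions covered by ``refs_heldout`` (which the caller must
    already have purged of the query's modifier and target) contribute.
    For each direction, the knot at score s holds the smoothed accuracy of
    covered predictions scoring >= s.  A direction with no covered
    predictions gets an empty map, meaning the predictor abstains there.
    """
    truth = {_ref_key(r): r.direction for r in refs_heldout}
    maps: dict[int, CalibrationMap] = {}
    for direction in (1, -1):
        scored: list[tuple[float, bool]] = []
        for p in predictor_preds:
            if p.direction != direction:
                continue
            key = (p.modifier_id, p.target_id, p.relation_class)
            if key not in truth:
                continue
            scored.append((p.score, truth[key] == p.direction))
        if not scored:
            maps[direction] = CalibrationMap(predictor, direction, [])
            continue
        scored.sort()
        scores = [s for s, _ in scored]
        knots = []
        for s in sorted(set(scores)):
            at = [ok for sc, ok in scored if sc >= s]
            n_corr = sum(at)
            knots.append(
                (s, n_corr / (len(at) + 1))  # smoothed accuracy at >= s
            )
        maps[direction] = CalibrationMap(predictor, direction, knots)
    return maps


def ensemble_predict(
    candidates: Mapping[str, tuple[int, float]],
    *,
    priority: Optional[Sequence[str]] = None,
) -> Optional[tuple[str, int, float]]:
    """Believe the predictor with the highest a-hat.

    ``candidates`` maps predictor name -> (direction, a_hat).  Ties break
    by ``priority`` order (default alphabetical, for determinism).  Returns
    (predictor, direction, a_hat) or None when no predictor fires.
    """
    if not candidates:
        return None
    if priority is None:
        rank = {name: i for i, name in enumerate(sorted(candidates))}
    else:
        rank = {name: i for i, name in enumerate(priority)}
        unknown = set(candidates) - set(rank)
        if unknown:
            raise ValueError(f"predictors missing from priority order: {unknown}")
    best = min(candidates.items(), key=lambda kv: (-kv[1][1], rank[kv[0]]))
    name, (direction, a_hat) = best
    return name, direction, a_hat


def loocv_ensemble_evaluate(
    predictor_tables: Mapping[str, Sequence[RelationPrediction]],
    refs: Sequence[ReferenceRelation],
    *,
    priority: Optional[Sequence[str]] = None,
    audit: Optional[Callable[[ReferenceRelation, Sequence[ReferenceRelation]], None]] = None,
) -> dict:
    """Leave-one-out evaluation of the ensemble and each predictor's worth.

    For every reference relation A -> B: calibrate each predictor on the
    references with A and B excluded, collect each predictor's (direction,
    a-hat) for the pair, and keep the most confident one.  Repeating the
    argmax with each predictor removed yields its removal effect.

    Returns a dict with:

    * ``rows`` — per-relation DataFrame of the full-roster ensemble choice;
    * ``curves`` — {(class, direction): AccuracyCurve} over a-hat for the
      full roster;
    * ``without`` — {predictor: {(class, direction): AccuracyCurve}} with
      that predictor removed;
    * ``summary`` — per (predictor, class, direction): whether the full
      roster beats the removal roster on prediction count ("coverage"), on
      maximum achieved smoothed accuracy ("accuracy"), both, or neither.
    """
    if len(refs) < 2:
        raise ValueError("need at least two reference relations")
    by_pair: dict[str, dict[tuple[str, str, str], RelationPrediction]] = {}
    for name, preds in predictor_tables.items():
        by_pair[name] = {
            (p.modifier_id, p.target_id, p.relation_class): p for p in preds
        }

    candidates_per_ref: list[tuple[ReferenceRelation, dict[str, tuple[int, float]]]] = []
    for ref in refs:
        heldout = [
            r for r in refs
            if ref.modifier_id not in (r.modifier_id, r.target_id)
            and ref.target_id not in (r.modifier_id, r.target_id)
        ]
        if audit is not None:
            audit(ref, heldout)
        cands: dict[str, tuple[int, float]] = {}
        for name, table in by_pair.items():
            pred = table.get(_ref_key(ref))
            if pred is None:
                continue
            heldout_cls = [r for r in heldout if r.relation_class == ref.relation_class]
            cal = calibrate(
                list(predictor_tables[name]), heldout_cls, predictor=name
            )[pred.direction]
            a_hat = cal.lookup(pred.score)
            if a_hat is None:
                continue  # no held-out coverage: the predictor abstains
            cands[name] = (pred.direction, a_hat)
        candidates_per_ref.append((ref, cands))

    def run(roster: Iterable[str]) -> pd.DataFrame:
        roster = set(roster)
        rows = []
        for ref, cands in candidates_per_ref:
            sub = {k: v for k, v in cands.items() if k in roster}
            choice = ensemble_predict(sub, priority=priority)
            if choice is None:
                continue
            name, direction, a_hat = choice
            rows.append(
                {
                    "modifier_id": ref.modifier_id,
                    "target_id": ref.target_id,
                    "relation_class": ref.relation_class,
                    "predictor": name,
                    "direction": direction,
                    "a_hat": a_hat,
                    "correct": direction == ref.direction,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "modifier_id", "target_id", "relation_class",
                "predictor", "direction", "a_hat", "correct",
            ],
        )

    def curves(frame: pd.DataFrame) -> dict[tuple[str, int], AccuracyCurve]:
        out = {}
        for (cls, direction), grp in frame.groupby(["relation_class", "direction"]):
            out[(cls, int(direction))] = accuracy_curve(
                grp["a_hat"].tolist(), grp["correct"].tolist()
            )
        return out

    full_frame = run(predictor_tables)
    full_curves = curves(full_frame)
    without: dict[str, dict[tuple[str, int], AccuracyCurve]] = {}
    summary_rows = []
    for name in predictor_tables:
        rest = [p for p in predictor_tables if p != name]
        frame = run(rest)
        without[name] = curves(frame)
        for key, full_curve in full_curves.items():
            cls, direction = key
            rem = without[name].get(key)
            full_n = int(full_curve.table["n_correct"].iloc[-1]
                         + full_curve.table["n_incorrect"].iloc[-1]) if len(full_curve) else 0
            rem_n = 0
            rem_max = 0.0
            if rem is not None and len(rem):
                rem_n = int(rem.table["n_correct"].iloc[-1]
                            + rem.table["n_incorrect"].iloc[-1])
                rem_max = float(rem.table["accuracy"].max())
            full_max = float(full_curve.table["accuracy"].max()) if len(full_curve) else 0.0
            summary_rows.append(
                {
                    "predictor": name,
                    "relation_class": cls,
                    "direction": direction,
                    "adds_coverage": full_n > rem_n,
                    "adds_accuracy": full_max > rem_max,
                }
            )
    summary = pd.DataFrame(
        summary_rows,
        columns=["predictor", "relation_class", "direction",
                 "adds_coverage", "adds_accuracy"],
    )
    return {
        "rows": full_frame,
        "curves": full_curves,
        "without": without,
        "summary": summary,
    }
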