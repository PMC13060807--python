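"""Readers and writers for the pipeline's tab-separated table dialects.

All tables are UTF-8 TSV (gzip transparent through the file extension);
the dense coexpression matrix additionally round-trips through an
HDF5-style container.  Schema violations are reported with the offending
column or identifier.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd

from .containers import (
    CoexpressionMatrix,
    ExpressionMatrix,
    MatchComponents,
    PerturbagenKind,
    PerturbationSignature,
    ReferenceRelation,
    RelationPrediction,
    SampleRecord,
)

PathLike = Union[str, Path]

SAMPLE_COLUMNS = [
    "sample_id", "study_id", "perturbagen_id", "kind",
    "target_gene", "control_ids", "source", "species",
]
RELATION_COLUMNS = ["modifier_id", "target_id", "relation_class", "direction", "source"]
PREDICTION_COLUMNS = [
    "modifier_id", "target_id", "relation_class", "direction",
    "score", "T_pos", "T_neg", "provenance",
]
MATCH_COLUMNS = [
    "perturbagen_a", "perturbagen_b", "T",
    "STP", "OTP", "FP", "FN",
    "SP", "OP", "SR", "OR", "SF1", "OF1", "DF1",
]
SIGNATURE_COLUMNS = ["perturbagen_id", "kind", "species", "gene_id", "consensus_z", "n_samples"]


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path: PathLike) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


# -- expression matrix --------------------------------------------------------

def read_expression(path: PathLike) -> ExpressionMatrix:
    """Genes x samples TSV: first column gene id, header row of sample ids."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(frame)


def write_expression(matrix: ExpressionMatrix, path: PathLike) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


# -- sample annotation table --------------------------------------------------

def read_samples(path: PathLike) -> list[SampleRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(frame, SAMPLE_COLUMNS, path)
    dupes = frame["sample_id"][frame["sample_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicated sample id(s): {sorted(set(dupes))}")
    records = []
    for lineno, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            records.append(
                SampleRecord(
                    sample_id=row.sample_id,
                    study_id=row.study_id,
                    perturbagen_id=row.perturbagen_id,
                    kind=PerturbagenKind(row.kind),
                    control_ids=tuple(filter(None, row.control_ids.split(";"))),
                    target_gene=row.target_gene or None,
                    source=row.source,
                    species=row.species,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_samples(samples: Iterable[SampleRecord], path: PathLike) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "study_id": s.study_id,
            "perturbagen_id": s.perturbagen_id,
            "kind": s.kind.value,
            "target_gene": s.target_gene or "",
            "control_ids": ";".join(s.control_ids),
            "source": s.source,
            "species": s.species,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, sep="\t", index=False)


# -- reference relations ------------------------------------------------------

def read_relations(path: PathLike) -> list[ReferenceRelation]:
    frame = pd.read_csv(path, sep="\t", dtype={"direction": int}, keep_default_na=False)
    _require_columns(frame, RELATION_COLUMNS, path)
    out = []
    for lineno, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            out.append(
                ReferenceRelation(
                    modifier_id=str(row.modifier_id),
                    target_id=str(row.target_id),
                    relation_class=row.relation_class,
                    direction=int(row.direction),
                    source=str(row.source),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_relations(relations: Iterable[ReferenceRelation], path: PathLike) -> None:
    rows = [
        {
            "modifier_id": r.modifier_id,
            "target_id": r.target_id,
            "relation_class": r.relation_class,
            "direction": r.direction,
            "source": r.source,
        }
        for r in relations
    ]
    pd.DataFrame(rows, columns=RELATION_COLUMNS).to_csv(path, sep="\t", index=False)


# -- predictions --------------------------------------------------------------

def read_predictions(path: PathLike) -> list[RelationPrediction]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    _require_columns(frame, PREDICTION_COLUMNS, path)
    out = []
    for lineno, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            out.append(
                RelationPrediction(
                    modifier_id=str(row.modifier_id),
                    target_id=str(row.target_id),
                    relation_class=row.relation_class,
                    direction=int(row.direction),
                    score=float(row.score),
                    provenance=str(row.provenance),
                    T_pos=float(row.T_pos) if row.T_pos != "" else None,
                    T_neg=float(row.T_neg) if row.T_neg != "" else None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_predictions(preds: Iterable[RelationPrediction], path: PathLike) -> None:
    rows = [
        {
            "modifier_id": p.modifier_id,
            "target_id": p.target_id,
            "relation_class": p.relation_class,
            "direction": p.direction,
            "score": repr(float(p.score)),
            "T_pos": "" if p.T_pos is None else p.T_pos,
            "T_neg": "" if p.T_neg is None else p.T_neg,
            "provenance": p.provenance,
        }
        for p in preds
    ]
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(path, sep="\t", index=False)


# -- pairwise match table -----------------------------------------------------

def write_matches(
    matches: Mapping[tuple[str, str], MatchComponents] | Iterable[tuple[str, str, MatchComponents]],
    path: PathLike,
) -> None:
    if isinstance(matches, Mapping):
        triples = [(a, b, mc) for (a, b), mc in matches.items()]
    else:
        triples = list(matches)
    rows = []
    for a, b, mc in triples:
        row = {"perturbagen_a": a, "perturbagen_b": b}
        row.update(mc.as_dict())
        rows.append(row)
    pd.DataFrame(rows, columns=MATCH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_matches(path: PathLike) -> list[tuple[str, str, MatchComponents]]:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, MATCH_COLUMNS, path)
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            (
                str(row.perturbagen_a),
                str(row.perturbagen_b),
                MatchComponents(
                    STP=int(row.STP), OTP=int(row.OTP),
                    FP=int(row.FP), FN=int(row.FN),
                    SP=row.SP, OP=row.OP, SR=row.SR, OR=getattr(row, "OR"),
                    SF1=row.SF1, OF1=row.OF1, DF1=row.DF1,
                    threshold=row.T,
                ),
            )
        )
    return out


# -- consensus signatures (long format) ---------------------------------------

def write_signatures(
    signatures: Mapping[str, PerturbationSignature], path: PathLike
) -> None:
    frames = []
    for sig in signatures.values():
        frames.append(
            pd.DataFrame(
                {
                    "perturbagen_id": sig.perturbagen_id,
                    "kind": sig.kind.value,
                    "species": sig.species,
                    "gene_id": sig.consensus_z.index,
                    "consensus_z": [repr(float(v)) for v in sig.consensus_z.to_numpy()],
                    "n_samples": sig.n_samples.reindex(sig.consensus_z.index).to_numpy(),
                }
            )
        )
    out = pd.concat(frames) if frames else pd.DataFrame(columns=SIGNATURE_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


def read_signatures(path: PathLike) -> dict[str, PerturbationSignature]:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "perturbagen_id": str})
    _require_columns(frame, SIGNATURE_COLUMNS, path)
    out: dict[str, PerturbationSignature] = {}
    for pid, grp in frame.groupby("perturbagen_id", sort=False):
        out[str(pid)] = PerturbationSignature(
            perturbagen_id=str(pid),
            kind=PerturbagenKind(grp["kind"].iloc[0]),
            species=str(grp["species"].iloc[0]),
            consensus_z=pd.Series(
                grp["consensus_z"].astype(float).to_numpy(), index=grp["gene_id"].tolist()
            ),
            n_samples=pd.Series(
                grp["n_samples"].astype(int).to_numpy(), index=grp["gene_id"].tolist()
            ),
        )
    return out


# -- coexpression matrix ------------------------------------------------------

def read_coexpression(path: PathLike) -> CoexpressionMatrix:
    """Square TSV with gene ids as both row labels and header."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return CoexpressionMatrix(frame)


def write_coexpression(coexpr: CoexpressionMatrix, path: PathLike) -> None:
    coexpr.r.to_csv(path, sep="\t", index_label="gene_id")


def read_coexpression_hdf5(path: PathLike) -> CoexpressionMatrix:
    """Dense HDF5 layout: datasets ``gene_ids`` (strings) and ``r``."""
    with h5py.File(path, "r") as fh:
        genes = [g.decode() if isinstance(g, bytes) else str(g) for g in fh["gene_ids"][:]]
        r = fh["r"][:]
    return CoexpressionMatrix(pd.DataFrame(r, index=genes, columns=genes))


def write_coexpression_hdf5(coexpr: CoexpressionMatrix, path: PathLike) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset(
            "gene_ids", data=np.array(coexpr.gene_ids, dtype="S")
        )
        fh.create_dataset("r", data=coexpr.r.to_numpy())
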