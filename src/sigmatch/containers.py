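"""Core in-memory containers for the signature-matching pipeline.

Expression data are carried as :class:`pandas.DataFrame` objects (genes as
rows, samples as columns); these dataclasses wrap them with the metadata and
invariants the pipeline relies on.  All identifiers are opaque strings: Entrez
IDs, gene symbols or PubChem SIDs pass through unmodified.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PerturbagenKind",
    "ExpressionMatrix",
    "SampleRecord",
    "SampleZScores",
    "PerturbationSignature",
    "DEGSet",
    "MatchComponents",
    "ReferenceRelation",
    "RelationPrediction",
    "CoexpressionMatrix",
    "AccuracyCurve",
    "CalibrationMap",
    "PlantedNetwork",
]


class PerturbagenKind(str, enum.Enum):
    """How a sample was perturbed: a gene knockout/knockdown or a compound."""

    gene_disruption = "gene_disruption"
    drug_treatment = "drug_treatment"


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of read counts or normalized expression.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    Counts must be finite and nonnegative; duplicate gene or sample
    identifiers are rejected because downstream lookups are by label.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values)


@dataclass(frozen=True)
class SampleRecord:
    """Annotation of one perturbed sample and its matched controls."""

    sample_id: str
    study_id: str
    perturbagen_id: str
    kind: PerturbagenKind
    control_ids: tuple[str, ...]
    target_gene: Optional[str] = None
    source: str = "synthetic"
    species: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.control_ids:
            raise ValueError(f"sample {self.sample_id}: control_ids is empty")
        if self.sample_id in self.control_ids:
            raise ValueError(
                f"sample {self.sample_id} listed among its own controls"
            )
        if self.kind is PerturbagenKind.gene_disruption and self.target_gene is None:
            raise ValueError(
                f"gene-disruption sample {self.sample_id} lacks a target gene"
            )
        if self.kind is PerturbagenKind.drug_treatment and self.target_gene is not None:
            raise ValueError(
                f"drug sample {self.sample_id} must not declare a target gene"
            )


@dataclass
class SampleZScores:
    """Per-gene z-scores of one perturbed sample against its controls.

    ``z`` is a Series indexed by gene id.  ``flagged`` names genes whose
    control standard deviation was degenerate (z forced to 0).
    """

    sample_id: str
    z: pd.Series
    n_controls: int
    flagged: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not np.isfinite(self.z.to_numpy()).all():
            raise ValueError(f"sample {self.sample_id}: non-finite z-scores")


@dataclass
class PerturbationSignature:
    """Consensus per-gene effect of one perturbagen across its samples.

    ``consensus_z[g]`` is a single signed, sample-size-aware estimate of the
    effect of the perturbagen on gene ``g``; ``n_samples[g]`` counts the
    samples that measured ``g``.
    """

    perturbagen_id: str
    kind: PerturbagenKind
    consensus_z: pd.Series
    n_samples: pd.Series
    species: str = "synthetic"

    def __post_init__(self) -> None:
        if not np.isfinite(self.consensus_z.to_numpy()).all():
            raise ValueError(
                f"signature {self.perturbagen_id}: non-finite consensus values"
            )
        if (self.n_samples.reindex(self.consensus_z.index) < 1).any():
            raise ValueError(
                f"signature {self.perturbagen_id}: gene with n_samples < 1"
            )

    @property
    def genes(self) -> pd.Index:
        return self.consensus_z.index


@dataclass
class DEGSet:
    """Signed differentially expressed genes of one signature at threshold T.

    ``signs`` maps gene id -> +1/-1 for every gene whose |consensus z|
    strictly exceeds ``threshold``.
    """

    perturbagen_id: str
    threshold: float
    signs: dict[str, int]

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold < 1.0:
            raise ValueError(f"threshold {self.threshold} outside [0, 1)")
        bad = {g: s for g, s in self.signs.items() if s not in (1, -1)}
        if bad:
            raise ValueError(f"non-unit signs: {bad}")

    def __len__(self) -> int:
        return len(self.signs)


@dataclass(frozen=True)
class MatchComponents:
    """DF1 decomposition of a signature pair at one DEG threshold.

    Counts: STP/OTP are shared DEGs with agreeing/conflicting direction;
    FP/FN are DEGs private to the first/second signature.  The smoothed
    ratios SP, OP (precision), SR, OR (recall) and SF1, OF1 combine into the
    conflict-penalized directional score DF1 in (-1, 1).
    """

    STP: int
    OTP: int
    FP: int
    FN: int
    SP: float
    OP: float
    SR: float
    OR: float
    SF1: float
    OF1: float
    DF1: float
    threshold: float

    def as_dict(self) -> dict[str, float]:
        return {
            "STP": self.STP, "OTP": self.OTP, "FP": self.FP, "FN": self.FN,
            "SP": self.SP, "OP": self.OP, "SR": self.SR, "OR": self.OR,
            "SF1": self.SF1, "OF1": self.OF1, "DF1": self.DF1,
            "T": self.threshold,
        }


@dataclass(frozen=True)
class ReferenceRelation:
    """A gold-standard directed relation from a manually curated database."""

    modifier_id: str
    target_id: str
    relation_class: str  # "gene_gene" | "drug_gene"
    direction: int  # +1 supportive, -1 inhibitory
    source: str = "reference"

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError(f"direction must be +1/-1, got {self.direction}")
        if self.relation_class == "gene_gene" and self.modifier_id == self.target_id:
            raise ValueError(f"self-relation {self.modifier_id}")
        if self.relation_class not in ("gene_gene", "drug_gene"):
            raise ValueError(f"unknown relation class {self.relation_class!r}")


@dataclass(frozen=True)
class RelationPrediction:
    """One predicted directed relation with its score and provenance."""

    modifier_id: str
    target_id: str
    relation_class: str
    direction: int
    score: float
    provenance: str
    T_pos: Optional[float] = None
    T_neg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError(f"direction must be +1/-1, got {self.direction}")
        if self.score < 0:
            raise ValueError("prediction score must be nonnegative")


@dataclass
class CoexpressionMatrix:
    """Symmetric gene x gene Pearson correlation matrix with unit diagonal."""

    r: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.r.to_numpy()
        if list(self.r.index) != list(self.r.columns):
            raise ValueError("row and column gene ids differ")
        if arr.size:
            if not np.allclose(arr, arr.T, atol=1e-8):
                raise ValueError("correlation matrix is not symmetric")
            if np.nanmax(np.abs(arr)) > 1 + 1e-8:
                raise ValueError("correlations outside [-1, 1]")
            if not np.allclose(np.diag(arr), 1.0, atol=1e-8):
                raise ValueError("diagonal is not 1")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.r.index)

    def corr(self, a: str, b: str) -> float:
        return float(self.r.at[a, b])


@dataclass
class AccuracyCurve:
    """Smoothed accuracy of scored predictions swept over score thresholds.

    ``table`` has one row per distinct score (descending) with columns
    ``score``, ``n_correct``, ``n_incorrect``, ``accuracy`` where accuracy is
    the smoothed proportion n_correct / (n_correct + n_incorrect + 1) among
    predictions scoring >= that row's score.
    """

    table: pd.DataFrame

    REQUIRED = ("score", "n_correct", "n_incorrect", "accuracy")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"accuracy curve missing columns {missing}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def levels(self) -> np.ndarray:
        """Distinct achieved smoothed-accuracy levels."""
        return np.unique(self.table["accuracy"].to_numpy())

    def coverage_at(self, level: float) -> int:
        """Correct-prediction count above the lowest score achieving ``level``.

        Defined as the largest correct count among thresholds whose smoothed
        accuracy is >= ``level``; 0 if the level is never achieved.
        """
        ok = self.table["accuracy"] >= level
        if not ok.any():
            return 0
        return int(self.table.loc[ok, "n_correct"].max())


@dataclass
class CalibrationMap:
    """Score -> accuracy-estimate (a-hat) lookup for one predictor/direction.

    ``knots`` is an ascending-by-score list of (score, a_hat) pairs where
    a_hat is the smoothed accuracy of the predictor's held-out reference
    predictions at scores >= that knot.
    """

    predictor: str
    direction: int
    knots: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        scores = [s for s, _ in self.knots]
        if any(b <= a for a, b in zip(scores, scores[1:])):
            raise ValueError("knot scores must be strictly increasing")
        if any(not 0.0 <= a < 1.0 for _, a in self.knots):
            raise ValueError("a-hat values must lie in [0, 1)")

    def lookup(self, score: float) -> Optional[float]:
        """Best-supported a-hat at or below ``score``.

        Every knot at a score <= the query is a valid accuracy estimate for
        it (the query clears that threshold), so the largest of them is
        reported; queries below the lowest knot clamp to it.  This keeps a
        confident query from being punished merely because few held-out
        references score as high as it does.
        """
        if not self.knots:
            return None
        eligible = [a for s, a in self.knots if s <= score]
        if not eligible:
            return self.knots[0][1]
        return max(eligible)


@dataclass
class PlantedNetwork:
    """A synthetic regulatory network used as planted ground truth.

    ``edges`` are (modifier, target, direction, effect_size) with direction
    +1 (modifier supports target) or -1 (modifier opposes target).  Drug
    edges only point at genes; self-edges are forbidden.
    """

    genes: list[str]
    drugs: list[str]
    edges: list[tuple[str, str, int, float]]
    seed: int

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        for mod, tgt, d, eff in self.edges:
            if mod == tgt:
                raise ValueError(f"self-edge on {mod}")
            if d not in (1, -1):
                raise ValueError(f"edge direction must be +1/-1, got {d}")
            if eff <= 0:
                raise ValueError("edge effect sizes must be positive")
            if tgt not in gene_set:
                raise ValueError(f"edge target {tgt} is not a gene")

    def gene_edges(self) -> list[tuple[str, str, int, float]]:
        drug_set = set(self.drugs)
        return [e for e in self.edges if e[0] not in drug_set]

    def drug_edges(self) -> list[tuple[str, str, int, float]]:
        drug_set = set(self.drugs)
        return [e for e in self.edges if e[0] in drug_set]

    def to_reference_relations(self) -> list[ReferenceRelation]:
        """Ground-truth edges as a reference relation table."""
        drug_set = set(self.drugs)
        out = []
        for mod, tgt, d, _ in self.edges:
            cls = "drug_gene" if mod in drug_set else "gene_gene"
            out.append(ReferenceRelation(mod, tgt, cls, d, source="planted"))
        return out
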