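"""Per-sample z-scores and per-perturbagen consensus signatures.

The pipeline normalizes each perturbed sample against its own study's
control samples, then collapses all samples sharing a perturbagen into one
consensus signature: for each gene, a one-sample z statistic of the
per-sample z-scores against zero, mean / (sd / sqrt(n)).  A single value per
(perturbagen, gene) pair summarizes the perturbagen's effect on that gene.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    PerturbagenKind,
    PerturbationSignature,
    SampleRecord,
    SampleZScores,
)
from .stats import binom_ci, binom_test, smoothed_proportion

logger = logging.getLogger(__name__)

#: below this, a standard deviation is treated as zero
SD_TOLERANCE = 1e-8
#: consensus magnitude assigned when >= 2 samples agree exactly (sd ~ 0)
Z_CAP = 10.0


def normalize_counts(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million then log2(CPM + 1), per sample.

    Samples with zero total count carry no usable information and are
    dropped with a warning.  Pre-log CPM columns sum to 1e6 for any sample
    with nonzero depth.
    """
    values = matrix.values
    if values.shape[1] < 1:
        raise ValueError("expression matrix has no samples")
    arr = values.to_numpy(dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError("count matrix contains negative values")
    depth = arr.sum(axis=0)
    empty = depth == 0
    if empty.any():
        dropped = [s for s, e in zip(values.columns, empty) if e]
        logger.warning("dropping %d zero-depth sample(s): %s", len(dropped), dropped)
        values = values.loc[:, ~empty]
        arr = arr[:, ~empty]
        depth = depth[~empty]
    cpm = arr / depth * 1e6
    out = pd.DataFrame(np.log2(cpm + 1.0), index=values.index, columns=values.columns)
    return ExpressionMatrix(out)


def sample_zscores(sample: SampleRecord, matrix: ExpressionMatrix) -> SampleZScores:
    """z-score one perturbed sample against its own controls, per gene.

    z = (x - mean(controls)) / sd(controls), with the n-1 (sample) standard
    deviation.  Genes whose control sd is below :data:`SD_TOLERANCE` (or
    undefined, with a single control) get z = 0 and are flagged.
    """
    cols = matrix.values.columns
    if sample.sample_id not in cols:
        raise KeyError(f"sample {sample.sample_id} not in expression matrix")
    missing = [c for c in sample.control_ids if c not in cols]
    if missing:
        raise KeyError(
            f"sample {sample.sample_id}: control column(s) missing: {missing}"
        )
    x = matrix.values[sample.sample_id].to_numpy(dtype=float)
    ctrl = matrix.values[list(sample.control_ids)].to_numpy(dtype=float)
    n_controls = ctrl.shape[1]
    mean = ctrl.mean(axis=1)
    if n_controls >= 2:
        sd = ctrl.std(axis=1, ddof=1)
    else:
        sd = np.zeros_like(mean)  # single control: spread undefined
    degenerate = sd < SD_TOLERANCE
    z = np.zeros_like(mean)
    ok = ~degenerate
    z[ok] = (x[ok] - mean[ok]) / sd[ok]
    flagged = frozenset(matrix.values.index[degenerate])
    return SampleZScores(
        sample_id=sample.sample_id,
        z=pd.Series(z, index=matrix.values.index),
        n_controls=n_controls,
        flagged=flagged,
    )


def consensus_signature(
    zs: Iterable[SampleZScores],
    perturbagen_id: str,
    kind: PerturbagenKind,
    *,
    z_cap: float = Z_CAP,
    species: str = "synthetic",
) -> PerturbationSignature:
    """Collapse sample z-scores sharing a perturbagen into one signature.

    Per gene, over the n samples that measured it:

    * n >= 2: consensus = mean(z) / (sd(z) / sqrt(n)), the one-sample z of
      the sample-z distribution against zero;
    * n == 1: the single z passes through unchanged;
    * sd below tolerance with n >= 2: sign(mean) * ``z_cap`` (0 stays 0),
      preserving direction without an infinity.

    The gene universe is the union of genes across contributing samples.
    """
    zs = list(zs)
    if not zs:
        raise ValueError(f"no samples for perturbagen {perturbagen_id}")
    frame = pd.DataFrame({s.sample_id: s.z for s in zs})
    n = frame.notna().sum(axis=1)
    mean = frame.mean(axis=1)
    sd = frame.std(axis=1, ddof=1)  # NaN where n == 1

    consensus = mean / (sd / np.sqrt(n))
    single = n == 1
    consensus[single] = mean[single]
    capped = (n >= 2) & (sd < SD_TOLERANCE)
    consensus[capped] = np.sign(mean[capped]) * z_cap

    keep = n >= 1
    return PerturbationSignature(
        perturbagen_id=perturbagen_id,
        kind=kind,
        consensus_z=consensus[keep].astype(float),
        n_samples=n[keep].astype(int),
        species=species,
    )


def build_signatures(
    samples: Iterable[SampleRecord],
    matrix: ExpressionMatrix,
    *,
    target_down: bool = False,
    source_filter: Optional[str] = None,
    species_filter: Optional[str] = None,
    z_cap: float = Z_CAP,
) -> dict[str, PerturbationSignature]:
    """Full signature stage: z-score every sample, optionally apply the
    target-down filter, then build one consensus signature per perturbagen.

    ``source_filter`` / ``species_filter`` restrict to a single read-count
    source or species (the single-source and mouse-only analysis modes);
    mixing sources is the default.
    """
    samples = list(samples)
    if source_filter is not None:
        samples = [s for s in samples if s.source == source_filter]
    if species_filter is not None:
        samples = [s for s in samples if s.species == species_filter]
    zmap = {s.sample_id: sample_zscores(s, matrix) for s in samples}
    if target_down:
        samples = target_down_filter(samples, zmap)
    by_pert: dict[tuple[str, PerturbagenKind], list[SampleZScores]] = {}
    for s in samples:
        by_pert.setdefault((s.perturbagen_id, s.kind), []).append(zmap[s.sample_id])
    out: dict[str, PerturbationSignature] = {}
    for (pid, kind), group in by_pert.items():
        out[pid] = consensus_signature(group, pid, kind, z_cap=z_cap)
    return out


def target_down_filter(
    samples: list[SampleRecord],
    zs: Mapping[str, SampleZScores],
) -> list[SampleRecord]:
    """Keep a gene-disruption sample only if its target gene went down.

    A disruption sample passes iff z(target gene) < 0 strictly; drug
    samples pass unchanged.  Samples whose target gene was not measured are
    dropped with a warning.  Idempotent.
    """
    kept: list[SampleRecord] = []
    for s in samples:
        if s.kind is not PerturbagenKind.gene_disruption:
            kept.append(s)
            continue
        z = zs[s.sample_id].z
        if s.target_gene not in z.index:
            logger.warning(
                "sample %s: target gene %s not measured; dropped",
                s.sample_id, s.target_gene,
            )
            continue
        if z[s.target_gene] < 0:
            kept.append(s)
    return kept


def validate_target_direction(
    samples: Iterable[SampleRecord],
    zs: Mapping[str, SampleZScores],
) -> dict:
    """Concordance check: do disrupted target genes go down in expression?

    Counts disruption samples whose target z is strictly negative (down) or
    strictly positive (up); z exactly 0 is not evaluable.  Returns the
    smoothed proportion down, an exact two-sided binomial p against 0.5, and
    the binomial 95% CI of the raw proportion.  A predominance of decreases
    indicates that targets and controls were annotated correctly.
    """
    n_down = n_up = 0
    for s in samples:
        if s.kind is not PerturbagenKind.gene_disruption:
            continue
        z = zs[s.sample_id].z
        if s.target_gene not in z.index:
            continue
        value = z[s.target_gene]
        if value < 0:
            n_down += 1
        elif value > 0:
            n_up += 1
    n = n_down + n_up
    if n == 0:
        return {
            "n_down": 0, "n_up": 0, "proportion_down": None,
            "p_value": None, "ci": None, "undefined": True,
        }
    lo, hi = binom_ci(n_down, n)
    return {
        "n_down": n_down,
        "n_up": n_up,
        "proportion_down": smoothed_proportion(n_down, n_up),
        "p_value": binom_test(n_down, n, 0.5),
        "ci": (lo, hi),
        "undefined": False,
    }
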