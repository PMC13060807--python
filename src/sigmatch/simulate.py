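"""Seeded synthetic datasets with a planted regulatory network.

The generator emulates the statistical structure the signature pipeline
assumes: each gene has a log-scale baseline expression; disrupting gene A
pushes A itself down and propagates signed shifts along A's outgoing
network edges; a drug that inhibits A reproduces A's disruption profile
(and an activating drug the mirror image).  Control samples scatter around
the baselines with Gaussian noise.  Every operation derives its own
sub-stream from the top-level seed, so regenerating one piece never
perturbs another.

Expression values are emitted on the log2 scale, i.e. already normalized —
the z-scoring stage consumes them directly.  Set ``as_counts=True`` to get
integer counts (2**x - 1, rounded) that exercise the CPM normalization
path instead.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .containers import (
    CoexpressionMatrix,
    ExpressionMatrix,
    PerturbagenKind,
    PlantedNetwork,
    SampleRecord,
)

__all__ = ["simulate_network", "simulate_experiments", "simulate_coexpression"]

_SUBSTREAM = {"network": 1, "experiments": 2, "coexpression": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_SUBSTREAM[stream], seed])


def simulate_network(
    n_genes: int,
    n_drugs: int,
    edge_density: float = 0.15,
    frac_negative: float = 0.5,
    seed: int = 0,
) -> PlantedNetwork:
    """Plant a random directed regulatory network.

    Every ordered gene pair and every drug -> gene pair carries an edge
    with probability ``edge_density``; a ``frac_negative`` share of edges
    is inhibitory (-1).  Each drug is guaranteed at least one target so
    every drug signature has something to recover.  Effect sizes are drawn
    uniformly from [0.5, 1.5] (multiples of the experiment-level effect
    scale).  Deterministic for a fixed seed.
    """
    if n_genes < 2:
        raise ValueError("need at least two genes")
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must lie in (0, 1]")
    if not 0 <= frac_negative <= 1:
        raise ValueError("frac_negative must lie in [0, 1]")
    rng = _rng(seed, "network")
    genes = [f"G{i:03d}" for i in range(n_genes)]
    drugs = [f"D{i:03d}" for i in range(n_drugs)]
    edges: list[tuple[str, str, int, float]] = []

    def add_edge(mod: str, tgt: str) -> None:
        direction = -1 if rng.random() < frac_negative else 1
        effect = float(rng.uniform(0.5, 1.5))
        edges.append((mod, tgt, direction, effect))

    for a in genes:
        for b in genes:
            if a != b and rng.random() < edge_density:
                add_edge(a, b)
    for d in drugs:
        targets = [g for g in genes if rng.random() < edge_density]
        if not targets:
            targets = [genes[int(rng.integers(n_genes))]]
        for g in targets:
            add_edge(d, g)
    return PlantedNetwork(genes=genes, drugs=drugs, edges=edges, seed=seed)


def _disruption_shift(
    net: PlantedNetwork, gene: str, effect_sd: float, gene_pos: dict[str, int]
) -> np.ndarray:
    """Log-scale expression shift caused by disrupting ``gene``."""
    shift = np.zeros(len(net.genes))
    shift[gene_pos[gene]] -= effect_sd  # the target itself goes down
    for mod, tgt, d, eff in net.gene_edges():
        if mod == gene:
            # losing a supporter lowers the target; losing a repressor raises it
            shift[gene_pos[tgt]] -= d * eff * effect_sd
    return shift


def simulate_experiments(
    net: PlantedNetwork,
    samples_per_perturbagen: int = 5,
    n_controls: int = 3,
    effect_sd: float = 2.0,
    noise_sd: float = 0.5,
    seed: Optional[int] = None,
    *,
    baseline_mean: float = 10.0,
    baseline_sd: float = 2.0,
    as_counts: bool = False,
) -> tuple[ExpressionMatrix, list[SampleRecord]]:
    """Simulate one perturbation study per gene and per drug.

    Each study contributes ``n_controls`` control samples plus
    ``samples_per_perturbagen`` perturbed ones, all with N(0, noise_sd)
    log-scale noise around the (shifted) baselines.  Gene studies apply the
    disruption shift of their target; drug studies apply the sum over the
    drug's planted targets of the target's disruption shift (scaled by the
    edge effect size) for inhibitory edges, or its negation for activating
    edges.  Every perturbed sample's record lists its study's controls.
    """
    rng = _rng(net.seed if seed is None else seed, "experiments")
    genes = net.genes
    gene_pos = {g: i for i, g in enumerate(genes)}
    baselines = rng.normal(baseline_mean, baseline_sd, size=len(genes))

    drug_shifts: dict[str, np.ndarray] = {d: np.zeros(len(genes)) for d in net.drugs}
    for mod, tgt, d, eff in net.drug_edges():
        target_shift = _disruption_shift(net, tgt, effect_sd, gene_pos)
        # an inhibitor mimics the target's disruption; an activator mirrors it
        drug_shifts[mod] += (-d) * eff * target_shift

    columns: dict[str, np.ndarray] = {}
    records: list[SampleRecord] = []

    def study(pid: str, kind: PerturbagenKind, shift: np.ndarray,
              target_gene: Optional[str], study_idx: int) -> None:
        study_id = f"S{study_idx:04d}"
        ctrl_ids = [f"{study_id}_C{j}" for j in range(n_controls)]
        for cid in ctrl_ids:
            columns[cid] = baselines + rng.normal(0, noise_sd, len(genes))
        for j in range(samples_per_perturbagen):
            sid = f"{study_id}_P{j}"
            columns[sid] = baselines + shift + rng.normal(0, noise_sd, len(genes))
            records.append(
                SampleRecord(
                    sample_id=sid,
                    study_id=study_id,
                    perturbagen_id=pid,
                    kind=kind,
                    control_ids=tuple(ctrl_ids),
                    target_gene=target_gene if kind is PerturbagenKind.gene_disruption else None,
                )
            )

    idx = 0
    for g in genes:
        study(g, PerturbagenKind.gene_disruption,
              _disruption_shift(net, g, effect_sd, gene_pos), g, idx)
        idx += 1
    for d in net.drugs:
        study(d, PerturbagenKind.drug_treatment, drug_shifts[d], None, idx)
        idx += 1

    frame = pd.DataFrame(columns, index=genes)
    if as_counts:
        frame = np.round(np.exp2(frame.clip(lower=0)) - 1).astype(int)
    return ExpressionMatrix(frame), records


def simulate_coexpression(
    net: PlantedNetwork,
    strength: float = 0.6,
    noise_scale: float = 0.03,
    seed: Optional[int] = None,
) -> CoexpressionMatrix:
    """Coexpression matrix consistent with the planted network.

    Gene pairs connected by a network edge get r = +/-``strength`` (sign
    following the edge direction); unconnected off-diagonal entries get
    small symmetric N(0, noise_scale) noise.  Unit diagonal, exactly
    symmetric, clipped to [-1, 1].
    """
    if not 0 < strength < 1:
        raise ValueError("strength must lie in (0, 1)")
    rng = _rng(net.seed if seed is None else seed, "coexpression")
    genes = net.genes
    n = len(genes)
    pos = {g: i for i, g in enumerate(genes)}
    noise = rng.normal(0, noise_scale, size=(n, n))
    r = np.triu(noise, 1)
    r = r + r.T
    assigned: set[tuple[int, int]] = set()
    for mod, tgt, d, _ in net.gene_edges():
        i, j = pos[mod], pos[tgt]
        # reciprocal edges with conflicting signs: first edge wins (one
        # correlation cannot carry both)
        if (min(i, j), max(i, j)) in assigned:
            continue
        assigned.add((min(i, j), max(i, j)))
        r[i, j] = r[j, i] = d * strength
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CoexpressionMatrix(pd.DataFrame(r, index=genes, columns=genes))
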