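"""Shared fixtures: tiny hand-built datasets and one mid-size synthetic one."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sigmatch import (
    ExpressionMatrix,
    PerturbagenKind,
    PerturbationSignature,
    SampleRecord,
    build_signatures,
    simulate_experiments,
    simulate_network,
)


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples: one perturbed sample, three controls."""
    frame = pd.DataFrame(
        {
            "ctrl1": [2.0, 3.0, 5.0],
            "ctrl2": [4.0, 3.0, 5.0],
            "ctrl3": [3.0, 3.0, 5.0],
            "pert": [5.0, 7.0, 5.0],
        },
        index=["g1", "g2", "g3"],
    )
    return ExpressionMatrix(frame)


@pytest.fixture
def toy_sample() -> SampleRecord:
    return SampleRecord(
        sample_id="pert",
        study_id="s1",
        perturbagen_id="g1",
        kind=PerturbagenKind.gene_disruption,
        control_ids=("ctrl1", "ctrl2", "ctrl3"),
        target_gene="g1",
    )


def make_signature(pid: str, z: dict[str, float],
                   kind=PerturbagenKind.gene_disruption) -> PerturbationSignature:
    series = pd.Series(z, dtype=float)
    return PerturbationSignature(
        perturbagen_id=pid,
        kind=kind,
        consensus_z=series,
        n_samples=pd.Series(1, index=series.index),
    )


@pytest.fixture
def signature_factory():
    return make_signature


@pytest.fixture(scope="session")
def planted_dataset():
    """One 30-gene / 10-drug replicate of the synthetic benchmark."""
    net = simulate_network(30, 10, seed=1)
    matrix, samples = simulate_experiments(net)
    signatures = build_signatures(samples, matrix)
    return net, matrix, samples, signatures
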