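"""Normalization, per-sample z-scoring, consensus, and target-direction QC."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigmatch import (
    ExpressionMatrix,
    PerturbagenKind,
    SampleRecord,
    SampleZScores,
    consensus_signature,
    normalize_counts,
    sample_zscores,
    target_down_filter,
    validate_target_direction,
)


def _matrix(data: dict, genes: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(data, index=genes))


class TestNormalizeCounts:
    def test_equal_counts_normalize_equally(self):
        m = _matrix({"s1": [1.0, 1.0]}, ["g1", "g2"])
        out = normalize_counts(m).values["s1"]
        assert out["g1"] == out["g2"]

    def test_cpm_log2_hand_arithmetic(self):
        m = _matrix({"s1": [9.0, 1.0]}, ["g1", "g2"])
        out = normalize_counts(m).values["s1"]
        assert out["g1"] == pytest.approx(math.log2(900001), rel=1e-12)
        assert out["g2"] == pytest.approx(math.log2(100001), rel=1e-12)

    def test_prelog_cpm_sums_to_million(self):
        rng = np.random.default_rng(0)
        m = _matrix({f"s{i}": rng.integers(0, 500, 20).astype(float) for i in range(3)},
                    [f"g{i}" for i in range(20)])
        out = normalize_counts(m)
        cpm = np.exp2(out.values.to_numpy()) - 1
        assert np.allclose(cpm.sum(axis=0), 1e6)

    def test_zero_depth_sample_dropped(self):
        m = _matrix({"s1": [5.0, 5.0], "s2": [0.0, 0.0]}, ["g1", "g2"])
        out = normalize_counts(m)
        assert out.sample_ids == ["s1"]

    def test_negative_counts_rejected(self):
        m = _matrix({"s1": [1.0, -1.0]}, ["g1", "g2"])
        with pytest.raises(ValueError, match="negative"):
            normalize_counts(m)


class TestSampleZScores:
    def test_sample_equal_to_control_mean_gives_zero(self, toy_matrix, toy_sample):
        g3 = sample_zscores(toy_sample, toy_matrix).z["g3"]
        assert g3 == 0.0  # g3 is constant: guarded, not NaN

    def test_hand_arithmetic_two_controls(self):
        m = _matrix({"c1": [2.0], "c2": [4.0], "p": [5.0]}, ["g1"])
        s = SampleRecord("p", "s", "g1", PerturbagenKind.gene_disruption,
                         ("c1", "c2"), target_gene="g1")
        z = sample_zscores(s, m).z["g1"]
        assert z == pytest.approx(2 / math.sqrt(2), rel=1e-12)

    def test_constant_controls_flagged(self, toy_matrix, toy_sample):
        out = sample_zscores(toy_sample, toy_matrix)
        assert "g3" in out.flagged and out.z["g3"] == 0.0
        assert "g1" not in out.flagged

    def test_missing_control_names_sample(self, toy_matrix):
        s = SampleRecord("pert", "s", "g1", PerturbagenKind.gene_disruption,
                         ("ctrl1", "nope"), target_gene="g1")
        with pytest.raises(KeyError, match="pert"):
            sample_zscores(s, toy_matrix)

    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_location_scale_invariance(self, a, b):
        """z-scores are unchanged by an affine rescaling of a gene's row."""
        base = pd.DataFrame({"c1": [2.0], "c2": [4.0], "c3": [7.0], "p": [5.0]},
                            index=["g1"])
        s = SampleRecord("p", "s", "g1", PerturbagenKind.gene_disruption,
                         ("c1", "c2", "c3"), target_gene="g1")
        z0 = sample_zscores(s, ExpressionMatrix(base)).z["g1"]
        z1 = sample_zscores(s, ExpressionMatrix(a * base + b)).z["g1"]
        assert z1 == pytest.approx(z0, rel=1e-9, abs=1e-9)


def _zs(sample_id: str, z: dict[str, float]) -> SampleZScores:
    return SampleZScores(sample_id, pd.Series(z, dtype=float), n_controls=3)


class TestConsensusSignature:
    def test_symmetric_pair_cancels(self):
        sig = consensus_signature(
            [_zs("a", {"g": -1.0}), _zs("b", {"g": 1.0})], "p",
            PerturbagenKind.gene_disruption)
        assert sig.consensus_z["g"] == 0.0

    def test_hand_arithmetic_three_samples(self):
        sig = consensus_signature(
            [_zs("a", {"g": 1.0}), _zs("b", {"g": 2.0}), _zs("c", {"g": 3.0})],
            "p", PerturbagenKind.gene_disruption)
        assert sig.consensus_z["g"] == pytest.approx(2 * math.sqrt(3), rel=1e-12)

    def test_identical_samples_hit_cap(self):
        sig = consensus_signature(
            [_zs("a", {"g": 2.0}), _zs("b", {"g": 2.0})], "p",
            PerturbagenKind.gene_disruption)
        assert sig.consensus_z["g"] == 10.0

    def test_single_sample_passes_through(self):
        sig = consensus_signature([_zs("a", {"g": -3.3})], "p",
                                  PerturbagenKind.gene_disruption)
        assert sig.consensus_z["g"] == -3.3
        assert sig.n_samples["g"] == 1

    def test_gene_universe_is_union_with_per_gene_n(self):
        sig = consensus_signature(
            [_zs("a", {"g1": 1.0, "g2": 5.0}), _zs("b", {"g1": 3.0})], "p",
            PerturbagenKind.gene_disruption)
        assert set(sig.genes) == {"g1", "g2"}
        assert sig.n_samples["g1"] == 2 and sig.n_samples["g2"] == 1
        assert sig.consensus_z["g2"] == 5.0  # pass-through for the n=1 gene

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            consensus_signature([], "p", PerturbagenKind.gene_disruption)

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_sign_symmetry(self, values):
        """Negating every sample z negates the consensus."""
        pos = consensus_signature(
            [_zs(f"s{i}", {"g": v}) for i, v in enumerate(values)], "p",
            PerturbagenKind.gene_disruption)
        neg = consensus_signature(
            [_zs(f"s{i}", {"g": -v}) for i, v in enumerate(values)], "p",
            PerturbagenKind.gene_disruption)
        assert neg.consensus_z["g"] == pytest.approx(-pos.consensus_z["g"],
                                                     rel=1e-9, abs=1e-12)


class TestTargetDownFilter:
    def _sample(self, sid, kind, target=None):
        return SampleRecord(sid, "s", "p", kind, ("c",), target_gene=target)

    def test_sign_rule_and_strict_boundary(self):
        ko_down = self._sample("down", PerturbagenKind.gene_disruption, "g")
        ko_zero = self._sample("zero", PerturbagenKind.gene_disruption, "g")
        drug = self._sample("drug", PerturbagenKind.drug_treatment)
        zs = {
            "down": _zs("down", {"g": -2.1}),
            "zero": _zs("zero", {"g": 0.0}),
            "drug": _zs("drug", {"g": 9.9}),
        }
        kept = target_down_filter([ko_down, ko_zero, drug], zs)
        assert [s.sample_id for s in kept] == ["down", "drug"]

    def test_unmeasured_target_dropped(self):
        ko = self._sample("ko", PerturbagenKind.gene_disruption, "absent")
        kept = target_down_filter([ko], {"ko": _zs("ko", {"g": -1.0})})
        assert kept == []

    def test_idempotent(self):
        samples = [
            self._sample("a", PerturbagenKind.gene_disruption, "g"),
            self._sample("b", PerturbagenKind.gene_disruption, "g"),
            self._sample("d", PerturbagenKind.drug_treatment),
        ]
        zs = {"a": _zs("a", {"g": -1.0}), "b": _zs("b", {"g": 1.0}),
              "d": _zs("d", {"g": 1.0})}
        once = target_down_filter(samples, zs)
        twice = target_down_filter(once, zs)
        assert once == twice


class TestValidateTargetDirection:
    def _dataset(self, n_down, n_up):
        samples, zs = [], {}
        for i in range(n_down + n_up):
            sid = f"s{i}"
            samples.append(SampleRecord(sid, "st", "p",
                                        PerturbagenKind.gene_disruption,
                                        ("c",), target_gene="g"))
            zs[sid] = _zs(sid, {"g": -1.0 if i < n_down else 1.0})
        return samples, zs

    def test_balanced_counts(self):
        report = validate_target_direction(*self._dataset(5, 5))
        assert report["proportion_down"] == pytest.approx(5 / 11)
        assert report["p_value"] == pytest.approx(1.0)

    def test_smoothed_undershoots_raw(self):
        report = validate_target_direction(*self._dataset(8, 2))
        assert report["proportion_down"] < 8 / 10

    def test_no_evaluable_samples_flagged(self):
        report = validate_target_direction([], {})
        assert report["undefined"] and report["proportion_down"] is None
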