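"""Corrected MAF arithmetic, null model, hit calling, plate QC, dose tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmdscreen.scoring import (
    Carrier,
    NullModel,
    PoolDesign,
    ScoringError,
    call_hits,
    control_values,
    corrected_maf,
    dose_response,
    fit_null,
    plate_qc,
    score_counts,
)


class TestCorrectedMaf:
    @pytest.mark.parametrize(
        "m, w, expected_raw, expected_corrected",
        [
            (0, 1000, 0.0, 0.0),
            (500, 1000, 1 / 3, 1.0),  # complete inhibition hits the pool maximum
            (150, 850, 0.15, 0.45),
        ],
    )
    def test_third_pool_examples(self, design, m, w, expected_raw, expected_corrected):
        rec = corrected_maf(m, w, design, "STAG2_clone2_mut")
        assert rec.raw_maf == pytest.approx(expected_raw, abs=1e-12)
        assert rec.corrected_maf == pytest.approx(expected_corrected, abs=1e-12)

    def test_heterozygous_carrier_correction(self, het_design):
        # e = 1*0.5/3 = 1/6
        rec = corrected_maf(100, 1100, het_design, "GENE_mut")
        assert rec.raw_maf == pytest.approx(0.083333, abs=1e-6)
        assert rec.corrected_maf == pytest.approx(0.5, abs=1e-12)

    def test_zero_depth_is_missing_and_low_coverage(self, design):
        rec = corrected_maf(0, 0, design, "STAG2_clone2_mut")
        assert rec.raw_maf is None and rec.corrected_maf is None
        assert rec.low_coverage

    def test_low_coverage_threshold(self, design):
        assert corrected_maf(10, 189, design, "STAG2_clone2_mut").low_coverage
        assert not corrected_maf(10, 190, design, "STAG2_clone2_mut").low_coverage

    def test_unknown_allele_rejected(self, design):
        with pytest.raises(ScoringError, match="unknown mutant allele"):
            corrected_maf(1, 1, design, "nonexistent")

    @given(m=st.integers(0, 10_000), w=st.integers(0, 10_000), c=st.integers(1, 50))
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, m, w, c):
        """Multiplying both counts by any positive integer leaves raw and
        corrected MAF unchanged exactly."""
        design = PoolDesign(n_lines=3, carriers={"a_mut": Carrier("a", 1, 1.0)})
        if m + w == 0:
            return
        base = corrected_maf(m, w, design, "a_mut")
        scaled = corrected_maf(m * c, w * c, design, "a_mut")
        assert scaled.raw_maf == base.raw_maf
        assert scaled.corrected_maf == base.corrected_maf

    def test_oracle_equivalence_random_inputs(self, design, rng):
        """Fractions recomputed from first principles agree to 1e-12 relative."""
        e = {a: design.expected_max_fraction(a) for a in design.mutant_allele_ids}
        for _ in range(500):
            a = design.mutant_allele_ids[rng.integers(3)]
            m = int(rng.integers(0, 100_000))
            w = int(rng.integers(1, 100_000))
            rec = corrected_maf(m, w, design, a)
            expect_raw = m / (m + w)
            assert math.isclose(rec.raw_maf, expect_raw, rel_tol=1e-12)
            assert math.isclose(rec.corrected_maf, expect_raw / e[a], rel_tol=1e-12)


class TestFitNull:
    def test_zero_variance_controls(self):
        null = fit_null({"a": [0.10, 0.10, 0.10]}, k=5)
        s = null.per_allele["a"]
        assert s.sd == pytest.approx(0.0, abs=1e-15)
        assert s.mean == pytest.approx(0.10, abs=1e-15)
        assert s.threshold == pytest.approx(s.mean, abs=1e-14)  # T = mean at any k when sd = 0

    def test_pooled_control_threshold(self):
        null = fit_null({"a": [0.08, 0.09, 0.10, 0.10, 0.11, 0.12]}, k=5)
        s = null.per_allele["a"]
        assert s.mean == pytest.approx(0.10, abs=1e-12)
        assert s.sd == pytest.approx(0.0141421, abs=1e-7)
        assert s.threshold == pytest.approx(0.1707107, abs=1e-7)

    def test_fixed_threshold_overrides_controls(self):
        null = fit_null({"a": [0.01, 0.02, 0.03], "b": [0.2, 0.3]}, k=5, fixed_threshold=0.46)
        assert null.threshold("a") == 0.46
        assert null.threshold("b") == 0.46

    def test_too_few_controls_is_error_without_fixed_threshold(self):
        with pytest.raises(ScoringError, match="< 2"):
            fit_null({"a": [0.1]}, k=5)
        fit_null({"a": [0.1]}, k=5, fixed_threshold=0.46)  # ok with override

    def test_oracle_equivalence_random_controls(self, rng):
        for _ in range(100):
            vals = rng.uniform(0, 0.4, size=int(rng.integers(2, 40)))
            k = float(rng.uniform(0, 8))
            null = fit_null({"a": list(vals)}, k=k)
            mean = sum(vals) / len(vals)
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
            s = null.per_allele["a"]
            assert math.isclose(s.mean, mean, rel_tol=1e-12, abs_tol=1e-15)
            assert math.isclose(s.sd, sd, rel_tol=1e-12, abs_tol=1e-15)
            assert math.isclose(s.threshold, mean + k * sd, rel_tol=1e-12, abs_tol=1e-15)

    def test_json_round_trip(self, tmp_path):
        null = fit_null({"a": [0.08, 0.12], "b": [0.2, 0.25, 0.3]}, k=5)
        null.to_json(tmp_path / "null.json")
        loaded = NullModel.from_json(tmp_path / "null.json")
        assert loaded.k == null.k
        assert loaded.per_allele == null.per_allele


def _maf_frame(design, values, plate="P01", well="A9", min_depth=200):
    """Build a MAF table row set from corrected values at comfortable depth."""
    rows = []
    for allele, corrected in values.items():
        e = design.expected_max_fraction(allele)
        raw = corrected * e
        depth = 10_000
        m = int(round(raw * depth))
        rows.append(
            {
                "plate_id": plate,
                "well_id": well,
                "allele_id": allele,
                "mutant_reads": m,
                "wildtype_reads": depth - m,
                "depth": depth,
                "raw_maf": m / depth,
                "corrected_maf": (m / depth) / e,
                "low_coverage": depth < min_depth,
            }
        )
    return pd.DataFrame(rows)


def _null_at(design, threshold):
    return fit_null(
        {a: [threshold, threshold] for a in design.mutant_allele_ids},
        k=0,
    )


def _platemap(rows):
    return pd.DataFrame(rows, columns=["plate_id", "well_id", "compound_id", "role"])


class TestCallHits:
    def test_all_alleles_above_threshold_is_hit(self, design):
        maf = _maf_frame(
            design,
            {"STAG2_clone2_mut": 0.50, "STAG2_clone8_mut": 0.48, "TP53_clone221_mut": 0.47},
        )
        null = _null_at(design, 0.46)
        pm = _platemap([("P01", "A9", "cpd1", "library")])
        hits = call_hits(maf, null, pm, design)
        assert hits.loc[0, "is_hit"]

    def test_boundary_equality_is_not_a_hit(self, design):
        """Strict inequality: an allele exactly at the threshold disqualifies."""
        maf = _maf_frame(
            design,
            {"STAG2_clone2_mut": 0.50, "STAG2_clone8_mut": 0.48, "TP53_clone221_mut": 0.46},
        )
        threshold = float(
            maf.loc[maf["allele_id"] == "TP53_clone221_mut", "corrected_maf"].iloc[0]
        )
        null = _null_at(design, threshold)
        pm = _platemap([("P01", "A9", "cpd1", "library")])
        hits = call_hits(maf, null, pm, design)
        assert not hits.loc[0, "is_hit"]

    def test_missing_allele_flags_well_and_blocks_hit(self, design):
        maf = _maf_frame(design, {"STAG2_clone2_mut": 0.50, "STAG2_clone8_mut": 0.48})
        null = _null_at(design, 0.1)
        pm = _platemap([("P01", "A9", "cpd1", "library")])
        hits = call_hits(maf, null, pm, design)
        assert not hits.loc[0, "is_hit"]
        assert "missing_allele" in hits.loc[0, "qc_flags"]

    def test_failed_plate_blocks_hit(self, design):
        maf = _maf_frame(
            design,
            {"STAG2_clone2_mut": 0.50, "STAG2_clone8_mut": 0.48, "TP53_clone221_mut": 0.47},
        )
        null = _null_at(design, 0.1)
        pm = _platemap([("P01", "A9", "cpd1", "library")])
        qc = pd.DataFrame([{"plate_id": "P01", "passed": False}])
        hits = call_hits(maf, null, pm, design, qc=qc)
        assert not hits.loc[0, "is_hit"]
        assert "failed_plate" in hits.loc[0, "qc_flags"]

    def test_monotonicity_in_mutant_count_and_k(self, design, rng):
        """More mutant reads never turns a hit into a non-hit; larger k never
        adds hits."""
        pm = _platemap([("P01", "A9", "cpd1", "library")])
        controls = {a: list(rng.uniform(0.05, 0.15, size=8)) for a in design.mutant_allele_ids}
        for _ in range(30):
            vals = {a: float(rng.uniform(0.0, 1.2)) for a in design.mutant_allele_ids}
            maf = _maf_frame(design, vals)
            k_small, k_big = sorted(rng.uniform(0, 8, size=2))
            hit_small = call_hits(maf, fit_null(controls, k=k_small), pm, design).loc[0, "is_hit"]
            hit_big = call_hits(maf, fit_null(controls, k=k_big), pm, design).loc[0, "is_hit"]
            assert hit_big <= hit_small  # raising k never adds hits
            # raise one allele's mutant count
            allele = design.mutant_allele_ids[rng.integers(3)]
            boosted = dict(vals)
            boosted[allele] = vals[allele] + float(rng.uniform(0, 0.5))
            maf_boosted = _maf_frame(design, boosted)
            hit_boosted = call_hits(maf_boosted, fit_null(controls, k=k_small), pm, design).loc[0, "is_hit"]
            assert hit_boosted >= hit_small

    def test_sorted_by_min_margin_descending(self, design):
        frames = []
        for well, top in (("A9", 0.6), ("A10", 0.9), ("A11", 0.3)):
            frames.append(
                _maf_frame(design, {a: top for a in design.mutant_allele_ids}, well=well)
            )
        maf = pd.concat(frames, ignore_index=True)
        pm = _platemap(
            [("P01", w, f"c_{w}", "library") for w in ("A9", "A10", "A11")]
        )
        hits = call_hits(maf, _null_at(design, 0.46), pm, design)
        assert list(hits["well_id"]) == ["A10", "A9", "A11"]


class TestPlateQC:
    def _qc(self, design, pos, neg, q=2.0):
        frames = []
        layout = []
        for i, v in enumerate(pos):
            well = f"A{i + 1}"
            frames.append(_maf_frame(design, {a: v for a in design.mutant_allele_ids}, well=well))
            layout.append(("P01", well, "emetine", "positive_control"))
        for i, v in enumerate(neg):
            well = f"B{i + 1}"
            frames.append(_maf_frame(design, {a: v for a in design.mutant_allele_ids}, well=well))
            layout.append(("P01", well, "DMSO", "negative_control"))
        return plate_qc(pd.concat(frames, ignore_index=True), _platemap(layout), q=q)

    def test_emetine_like_effect_passes(self, design):
        qc = self._qc(design, pos=[0.35], neg=[0.10])
        assert qc.loc[0, "pos_neg_ratio"] == pytest.approx(3.5, rel=5e-3)
        assert qc.loc[0, "passed"]

    def test_equal_means_fail(self, design):
        qc = self._qc(design, pos=[0.10], neg=[0.10])
        assert not qc.loc[0, "passed"]

    def test_zero_negative_mean_with_signal_passes(self, design):
        qc = self._qc(design, pos=[0.35], neg=[0.0])
        assert math.isinf(qc.loc[0, "pos_neg_ratio"])
        assert qc.loc[0, "passed"]

    def test_missing_controls_fail_with_reason(self, design):
        maf = _maf_frame(design, {a: 0.3 for a in design.mutant_allele_ids}, well="A1")
        pm = _platemap([("P01", "A1", "emetine", "positive_control")])
        qc = plate_qc(maf, pm)
        assert not qc.loc[0, "passed"]
        assert "missing" in qc.loc[0, "reason"]


class TestDoseResponse:
    def test_six_point_three_allele_table(self, design):
        rows = [
            {
                "concentration": c,
                "allele_id": a,
                "mutant_reads": 100 + 10 * i,
                "wildtype_reads": 900,
            }
            for i, c in enumerate((0.1, 0.3, 1.0, 3.0, 10.0, 30.0))
            for a in design.mutant_allele_ids
        ]
        out = dose_response(pd.DataFrame(rows), design)
        assert len(out) == 18

    def test_single_concentration_rejected(self, design):
        rows = [
            {"concentration": 1.0, "allele_id": a, "mutant_reads": 10, "wildtype_reads": 90}
            for a in design.mutant_allele_ids
        ]
        with pytest.raises(ScoringError, match="at least 2 concentrations"):
            dose_response(pd.DataFrame(rows), design)

    def test_duplicate_rows_rejected(self, design):
        rows = [
            {"concentration": 1.0, "allele_id": "STAG2_clone2_mut", "mutant_reads": 10, "wildtype_reads": 90},
            {"concentration": 1.0, "allele_id": "STAG2_clone2_mut", "mutant_reads": 11, "wildtype_reads": 89},
            {"concentration": 3.0, "allele_id": "STAG2_clone2_mut", "mutant_reads": 12, "wildtype_reads": 88},
        ]
        with pytest.raises(ScoringError, match="duplicate"):
            dose_response(pd.DataFrame(rows), design)

    def test_all_zero_mutant_counts_retained_as_zero_maf(self, design):
        rows = [
            {"concentration": c, "allele_id": "STAG2_clone2_mut", "mutant_reads": 0, "wildtype_reads": 500}
            for c in (1.0, 3.0)
        ]
        out = dose_response(pd.DataFrame(rows), design)
        assert len(out) == 2
        assert (out["corrected_maf"] == 0.0).all()


class TestScoreCounts:
    def test_counts_to_maf_table(self, design, panel):
        counts = pd.DataFrame(
            [
                {"plate_id": "P01", "well_id": "A9", "gene": "STAG2", "allele_id": "STAG2_wt", "count": 900},
                {"plate_id": "P01", "well_id": "A9", "gene": "STAG2", "allele_id": "STAG2_clone2_mut", "count": 50},
                {"plate_id": "P01", "well_id": "A9", "gene": "STAG2", "allele_id": "STAG2_clone8_mut", "count": 60},
                {"plate_id": "P01", "well_id": "A9", "gene": "TP53", "allele_id": "TP53_wt", "count": 800},
                {"plate_id": "P01", "well_id": "A9", "gene": "TP53", "allele_id": "TP53_clone221_mut", "count": 70},
            ]
        )
        maf = score_counts(counts, design, panel, min_depth=200)
        assert len(maf) == 3
        row = maf[maf["allele_id"] == "STAG2_clone2_mut"].iloc[0]
        # w is the gene's wild-type count, not the other clone's
        assert row.mutant_reads == 50 and row.wildtype_reads == 900
        assert row.raw_maf == pytest.approx(50 / 950)
        assert row.corrected_maf == pytest.approx((50 / 950) / (1 / 3))

    def test_absent_allele_becomes_missing_record(self, design, panel):
        counts = pd.DataFrame(
            [
                {"plate_id": "P01", "well_id": "A9", "gene": "STAG2", "allele_id": "STAG2_wt", "count": 900},
            ]
        )
        maf = score_counts(counts, design, panel)
        tp53 = maf[maf["allele_id"] == "TP53_clone221_mut"].iloc[0]
        assert pd.isna(tp53.corrected_maf) and tp53.low_coverage

    def test_control_values_exclude_low_coverage(self, design, panel):
        counts = pd.DataFrame(
            [
                {"plate_id": "P01", "well_id": "A3", "gene": g, "allele_id": a, "count": c}
                for g, a, c in [
                    ("STAG2", "STAG2_wt", 50),
                    ("STAG2", "STAG2_clone2_mut", 5),
                    ("STAG2", "STAG2_clone8_mut", 5),
                    ("TP53", "TP53_wt", 50),
                    ("TP53", "TP53_clone221_mut", 5),
                ]
            ]
        )
        maf = score_counts(counts, design, panel, min_depth=200)
        pm = _platemap([("P01", "A3", "DMSO", "negative_control")])
        vals = control_values(maf, pm)
        assert vals == {}
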