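"""Diversity metrics against hand calculations and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctcdiv.datatypes import CNASegment, MathPolicy, PatientProfile
from ctcdiv.diversity import (
    crc_driver_cna_count,
    crc_driver_mut_count,
    math_score,
    msi_classify,
    mutational_burden,
    proportion_aberrant_genome,
    recurrent_gene_status,
    restrict_to_mss,
)
from ctcdiv.errors import AnalysisError

from conftest import make_variant, variants_from_vafs


# --- independent brute-force oracles (sort-based, no numpy medians) -------

def oracle_median(xs):
    s = sorted(xs)
    n = len(s)
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2.0


def oracle_math(vafs, mad_scale):
    med = oracle_median(vafs)
    mad = oracle_median([abs(v - med) for v in vafs])
    return 100.0 * mad_scale * mad / med


class TestMutationalBurden:
    def test_snvs_per_megabase(self):
        variants = ([make_variant(pos=i) for i in range(100)]
                    + [make_variant(pos=1000 + i, ref="AT") for i in range(40)])
        assert mutational_burden(variants, 50.0) == pytest.approx(2.0)

    def test_empty(self):
        assert mutational_burden([], 50.0) == 0.0

    def test_invalid_capture_size(self):
        with pytest.raises(AnalysisError):
            mutational_burden([], 0.0)

    def test_linear_in_snv_count(self):
        base = [make_variant(pos=i) for i in range(10)]
        assert mutational_burden(base * 3, 10.0) == pytest.approx(
            3 * mutational_burden(base, 10.0))


class TestProportionAberrantGenome:
    def test_all_neutral(self):
        segs = [CNASegment("1", 1, 100, "neutral"), CNASegment("2", 1, 50, "neutral")]
        assert proportion_aberrant_genome(segs) == 0.0

    def test_all_gain(self):
        segs = [CNASegment("1", 1, 100, "gain")]
        assert proportion_aberrant_genome(segs) == 1.0

    def test_hand_arithmetic(self):
        segs = [CNASegment("1", 1, 100, "gain"), CNASegment("1", 101, 400, "neutral")]
        assert proportion_aberrant_genome(segs) == pytest.approx(100 / 400)

    def test_no_segments_is_missing_not_zero(self):
        assert proportion_aberrant_genome([]) is None

    def test_invariant_to_segment_splitting(self):
        whole = [CNASegment("1", 1, 1000, "loss"), CNASegment("1", 1001, 4000, "neutral")]
        split = [CNASegment("1", 1, 500, "loss"), CNASegment("1", 501, 1000, "loss"),
                 CNASegment("1", 1001, 2500, "neutral"),
                 CNASegment("1", 2501, 4000, "neutral")]
        assert proportion_aberrant_genome(whole) == pytest.approx(
            proportion_aberrant_genome(split))


class TestMathScore:
    def test_identical_vafs_give_zero(self):
        variants = variants_from_vafs([0.4] * 5)
        assert math_score(variants, MathPolicy(apply_depth_filter=False)) == 0.0

    def test_hand_computed_value(self):
        """VAFs {0.2,0.3,0.4,0.5,0.6}: median 0.4, MAD 0.1, scaled 0.14826,
        so MATH = 100 * 0.14826 / 0.4 = 37.065."""
        variants = variants_from_vafs([0.2, 0.3, 0.4, 0.5, 0.6])
        score = math_score(variants, MathPolicy(apply_depth_filter=False))
        assert score == pytest.approx(37.065, abs=1e-9)

    def test_depth_filter_applied_by_default(self):
        qualifying = variants_from_vafs([0.2, 0.4, 0.6], depth=100)
        shallow = [make_variant(total=20, alt=4, pos=99)]  # fails >=25/>=5
        with_noise = qualifying + shallow
        assert math_score(with_noise) == pytest.approx(math_score(qualifying))

    def test_too_few_variants_is_missing(self):
        assert math_score(variants_from_vafs([0.3, 0.5])) is None

    def test_closed_form_symmetric_triplet(self):
        """On {m-d, m, m+d} with mad_scale=1 the score is 100*d/m."""
        m, d = 0.4, 0.15
        variants = variants_from_vafs([m - d, m, m + d])
        policy = MathPolicy(mad_scale=1.0, apply_depth_filter=False)
        assert math_score(variants, policy) == pytest.approx(100 * d / m, abs=1e-9)

    @given(st.lists(st.integers(1, 999), min_size=3, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, milli_vafs):
        vafs = [v / 1000 for v in milli_vafs]
        variants = variants_from_vafs(vafs, depth=1000)
        policy = MathPolicy(apply_depth_filter=False)
        assert math_score(variants, policy) == pytest.approx(
            oracle_math(vafs, policy.mad_scale), abs=1e-9)

    @given(st.lists(st.integers(1, 999), min_size=3, max_size=20),
           st.integers(1000, 100_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_free(self, alt_counts, bigger_depth):
        """Scaling every VAF by c = 1000/bigger_depth leaves MATH unchanged
        (same alternate counts at a deeper total scale all VAFs equally)."""
        policy = MathPolicy(apply_depth_filter=False)
        base = [make_variant(total=1000, alt=a, pos=i)
                for i, a in enumerate(alt_counts)]
        scaled = [make_variant(total=bigger_depth, alt=a, pos=i)
                  for i, a in enumerate(alt_counts)]
        assert math_score(scaled, policy) == pytest.approx(
            math_score(base, policy), abs=1e-9)


class TestDriverGeneCounts:
    DRIVERS = ["APC", "TP53", "KRAS"]

    def test_hand_enumeration(self):
        variants = (
            [make_variant(pos=i, gene="APC", consequence="nonsilent") for i in range(3)]
            + [make_variant(pos=10 + i, gene="TP53", consequence="silent") for i in range(2)]
            + [make_variant(pos=20 + i, gene="OTHER", consequence="nonsilent") for i in range(4)]
        )
        assert crc_driver_mut_count(variants, self.DRIVERS) == 3

    def test_case_insensitive_matching(self):
        variants = [make_variant(gene="apc", consequence="nonsilent"),
                    make_variant(pos=2, gene=" Tp53 ", consequence="nonsilent")]
        assert crc_driver_mut_count(variants, self.DRIVERS) == 2

    def test_no_nonsilent(self):
        variants = [make_variant(gene="APC", consequence="silent")]
        assert crc_driver_mut_count(variants, self.DRIVERS) == 0

    def test_cna_pair_counting(self):
        """One gain spanning two driver genes contributes one pair per gene."""
        coords = {"APC": ("5", 100, 200), "TP53": ("5", 300, 400),
                  "KRAS": ("12", 100, 200)}
        segs = [CNASegment("5", 50, 500, "gain"),
                CNASegment("12", 1, 1000, "neutral")]
        assert crc_driver_cna_count(segs, coords) == 2

    def test_gene_hit_twice_counts_twice(self):
        coords = {"APC": ("5", 100, 500)}
        segs = [CNASegment("5", 1, 200, "loss"), CNASegment("5", 201, 600, "loh")]
        assert crc_driver_cna_count(segs, coords) == 2

    def test_neutral_overlap_does_not_count(self):
        coords = {"APC": ("5", 100, 200)}
        segs = [CNASegment("5", 1, 1000, "neutral")]
        assert crc_driver_cna_count(segs, coords) == 0


def _patient(pid, genes):
    variants = [make_variant(pos=i + 1, gene=g, consequence="nonsilent")
                for i, g in enumerate(genes)]
    return PatientProfile(patient_id=pid, variants=variants)


class TestRecurrentGeneStatus:
    def test_gene_in_exactly_min_patients_selected(self):
        cohort = [_patient(f"P{i}", ["APC"]) for i in range(4)]
        cohort.append(_patient("P9", []))
        status = recurrent_gene_status(cohort, ["APC"], min_patients=4)
        assert set(status) == {"APC"}
        assert status["APC"]["P0"] == "mutated"
        assert status["APC"]["P9"] == "unmutated"

    def test_below_threshold_not_selected(self):
        cohort = [_patient(f"P{i}", ["KRAS"]) for i in range(3)]
        assert recurrent_gene_status(cohort, ["KRAS"], min_patients=4) == {}

    def test_no_recurrent_genes_empty_map(self):
        cohort = [_patient("P0", ["X1"]), _patient("P1", ["X2"])]
        assert recurrent_gene_status(cohort, ["APC"], min_patients=1) == {}


class TestMsiClassification:
    @pytest.mark.parametrize("fraction,expected", [
        (0.0, "MSS"), (0.30, "MSS"), (0.300001, "MSI"), (0.35, "MSI"), (1.0, "MSI"),
    ])
    def test_strict_threshold(self, fraction, expected):
        assert msi_classify(fraction) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(AnalysisError):
            msi_classify(1.2)

    def test_restrict_drops_only_msi(self):
        cohort = [PatientProfile(patient_id=f"P{i}", msi_fraction=0.1)
                  for i in range(28)]
        cohort.append(PatientProfile(patient_id="P28", msi_fraction=0.6))
        kept = restrict_to_mss(cohort)
        assert len(kept) == 28
        assert all(p.msi_fraction <= 0.30 for p in kept)

    def test_all_mss_unchanged(self):
        cohort = [PatientProfile(patient_id="A", msi_fraction=0.0)]
        assert restrict_to_mss(cohort) == cohort

    def test_all_msi_empty(self):
        cohort = [PatientProfile(patient_id="A", msi_fraction=0.9)]
        assert restrict_to_mss(cohort) == []
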