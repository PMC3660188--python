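"""Pentamer classification, array segmentation and spectrum bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyz1kit import synth
from dyz1kit.core_io import SequenceRecord, read_table
from dyz1kit.digest import default_panel_path
from dyz1kit.pentamer import (
    REFERENCE_MOTIF,
    PentamerSpectrum,
    SegmentationParams,
    classify_pentamer,
    compare_spectra,
    hamming,
    segment_array,
    spectrum,
)

dna = st.text(alphabet="ACGT", min_size=5, max_size=30)


def exhaustive_min_cost(s: str, skip_penalty: int = 3, max_unit_cost: int = 5) -> int:
    """Independent oracle: enumerate every pentamer/skip tiling recursively."""

    def rec(i: int) -> int:
        if i == len(s):
            return 0
        best = skip_penalty + rec(i + 1)
        if i + 5 <= len(s):
            d = hamming(s[i : i + 5], REFERENCE_MOTIF)
            if d <= max_unit_cost:
                best = min(best, d + rec(i + 5))
        return best

    return rec(0)


class TestClassify:
    @pytest.mark.parametrize(
        "motif,distance",
        [("TTCCA", 0), ("GTCCA", 1), ("ttcca", 0), ("AGGTC", 5)],
    )
    def test_examples(self, motif, distance):
        assert classify_pentamer(motif).distance == distance

    def test_exactly_fifteen_single_base_derivatives(self):
        singles = {
            m
            for m in (
                REFERENCE_MOTIF[:i] + b + REFERENCE_MOTIF[i + 1 :]
                for i in range(5)
                for b in "ACGT"
            )
            if m != REFERENCE_MOTIF
        }
        assert len(singles) == 15
        assert all(classify_pentamer(m).distance == 1 for m in singles)

    @pytest.mark.parametrize("bad", ["TTCC", "TTCCAA", "TTCNA", "TTCUA"])
    def test_rejects(self, bad):
        with pytest.raises(ValueError):
            classify_pentamer(bad)


class TestSegmentation:
    def test_pure_array_fixed_and_dynamic(self, record):
        rec = record("TTCCA" * 10)
        for mode in ("fixed-frame", "dynamic"):
            seg = segment_array(rec, SegmentationParams(mode=mode))
            assert len(seg.units) == 10
            assert all(pc.motif == "TTCCA" for _, pc in seg.units)
            assert seg.residues == ()

    def test_trailing_residue(self, record):
        seg = segment_array(record("TTCCATTCCATT"), SegmentationParams(mode="fixed-frame"))
        assert len(seg.units) == 2
        assert [(r.start, r.end) for r in seg.residues] == [(11, 12)]

    def test_dynamic_rejoins_frame_after_insertion(self, record):
        # two bases inserted between units: dynamic mode skips them,
        # fixed-frame mode degrades every downstream tile
        rec = record("TTCCA" * 4 + "GG" + "TTCCA" * 4)
        dyn = segment_array(rec, SegmentationParams(mode="dynamic"))
        assert sum(pc.distance == 0 for _, pc in dyn.units) == 8
        assert sum(len(r) for r in dyn.residues) == 2

    def test_ambiguity_rejected(self, record):
        with pytest.raises(ValueError):
            segment_array(record("TTCCN" * 2))

    @settings(max_examples=150, derandomize=True)
    @given(dna)
    def test_dynamic_cost_matches_exhaustive_oracle(self, s):
        rec = SequenceRecord("r", s)
        assert segment_array(rec).cost == exhaustive_min_cost(s)

    @settings(max_examples=100, derandomize=True)
    @given(dna)
    def test_dynamic_cost_never_exceeds_fixed_frame(self, s):
        rec = SequenceRecord("r", s)
        dyn = segment_array(rec, SegmentationParams(mode="dynamic"))
        fixed = segment_array(rec, SegmentationParams(mode="fixed-frame"))
        assert dyn.cost <= fixed.cost

    @settings(max_examples=100, derandomize=True)
    @given(dna)
    def test_length_conservation(self, s):
        sp = spectrum(SequenceRecord("r", s))
        assert 5 * sum(sp.counts.values()) + sp.residue_bases == sp.total_length

    def test_leftmost_tie_break(self, record):
        # "TTCCATTCCA" with one unit's worth of cost tie: the unit is
        # assigned starting at position 1, not via any skipped prefix
        seg = segment_array(record("TTCCA" * 2))
        assert seg.units[0][0].start == 1


class TestSpectrum:
    def test_pure_array(self, record):
        sp = spectrum(record("TTCCA" * 3))
        assert sp.counts == {"TTCCA": 3}
        assert sp.residue_bases == 0

    def test_recovers_generator_truth(self):
        for seed in (0, 7, 123):
            rec, truth = synth.generate_array(synth.ArraySpec(n_units=300, seed=seed))
            sp = spectrum(rec)
            assert dict(sp.counts) == dict(truth.counts)
            assert sp.residue_bases == 0

    def test_aggregate_decomposition(self):
        rec, _ = synth.generate_array(synth.ArraySpec(n_units=200, seed=5))
        sp = spectrum(rec)
        agg = sp.by_distance
        for d in range(6):
            assert agg[d] == sum(
                c for m, c in sp.counts.items() if hamming(m, REFERENCE_MOTIF) == d
            )

    def test_bookkeeping_validated(self):
        with pytest.raises(ValueError):
            PentamerSpectrum(counts={"TTCCA": 2}, residue_bases=1, total_length=12)


@pytest.fixture(scope="module")
def published_spectrum_table():
    path = default_panel_path().with_name("reference_spectrum_counts.tsv")
    return read_table(path).set_index("label")


class TestPublishedCounts:
    """Internal consistency of the shipped published-spectrum table."""

    @pytest.mark.parametrize("column,expected", [("AC068123.5", 292), ("DU145", 289), ("LNCaP", 282)])
    def test_single_base_aggregate_is_sum_of_motifs(self, published_spectrum_table, column, expected):
        one_bp = [
            "ATCCA", "TACCA", "TTACA", "TTCAA", "TTTCA", "TTCTA", "TTCCT",
            "GTCCA", "TGCCA", "TTGCA", "TTCGA", "TTCCG", "CTCCA", "TCCCA", "TTCCC",
        ]
        assert sum(int(published_spectrum_table.loc[m, column]) for m in one_bp) == expected
        assert int(published_spectrum_table.loc["1bp_derivatives", column]) == expected

    @pytest.mark.parametrize("column,residue", [("AC068123.5", 14), ("DU145", 19), ("LNCaP", 15)])
    def test_published_counts_leave_small_residue(self, published_spectrum_table, column, residue):
        classes = ["TTCCA", "1bp_derivatives", "2bp_derivatives",
                   "3bp_derivatives", "4bp_derivatives", "5bp_derivatives"]
        total_units = sum(int(published_spectrum_table.loc[c, column]) for c in classes)
        assert int(published_spectrum_table.loc["actual_size_bp", column]) - 5 * total_units == residue


class TestCompare:
    def test_identical_spectra_zero(self, record):
        sp = spectrum(record("TTCCA" * 4))
        assert all(v == 0 for v in compare_spectra(sp, sp).values())

    def test_antisymmetry_and_union(self):
        a_rec, _ = synth.generate_array(synth.ArraySpec(n_units=100, seed=1))
        b_rec, _ = synth.generate_array(synth.ArraySpec(n_units=100, seed=2))
        a, b = spectrum(a_rec), spectrum(b_rec)
        d_ab, d_ba = compare_spectra(a, b), compare_spectra(b, a)
        assert set(d_ab) == set(a.counts) | set(b.counts)
        assert all(d_ab[m] == -d_ba[m] for m in d_ab)

    def test_reference_vs_sample_direction(self, record):
        a = spectrum(record("TTCCA" * 229 + "GTCCA"))
        b = spectrum(record("TTCCA" * 235 + "GTCCA"))
        assert compare_spectra(a, b)["TTCCA"] == 6

    def test_params_mismatch_rejected(self, record):
        a = spectrum(record("TTCCA" * 3), SegmentationParams(mode="dynamic"))
        b = spectrum(record("TTCCA" * 3), SegmentationParams(mode="fixed-frame"))
        with pytest.raises(ValueError):
            compare_spectra(a, b)
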