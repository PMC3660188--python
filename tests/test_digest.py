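"""Restriction-site scanning, frequency comparison, fragments and RFLP."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyz1kit.core_io import SequenceRecord, read_table, reverse_complement
from dyz1kit.digest import (
    EnzymeSpec,
    IUPAC_CODES,
    compare_frequencies,
    compile_iupac,
    default_panel_path,
    digest_fragments,
    find_sites,
    load_enzyme_panel,
    predict_rflp,
    site_frequency_table,
)


def naive_site_count(seq: str, enzyme: EnzymeSpec) -> int:
    """Independent oracle: position-by-position IUPAC comparison on both
    strands, palindromes deduplicated."""

    def matches_at(s: str, pattern: str, i: int) -> bool:
        if i + len(pattern) > len(s):
            return False
        return all(s[i + k] in IUPAC_CODES[p] for k, p in enumerate(pattern))

    def count(pattern: str) -> int:
        return sum(matches_at(seq, pattern, i) for i in range(len(seq)))

    total = count(enzyme.recognition)
    rc = reverse_complement(enzyme.recognition)
    if rc != enzyme.recognition:
        total += count(rc)
    return total


class TestCompileIupac:
    def test_degenerate_expansion(self):
        matcher = compile_iupac("CCWGG")
        assert matcher.search("CCAGG") and matcher.search("CCTGG")
        assert not matcher.search("CCGGG")

    def test_n_wildcard(self):
        assert compile_iupac("GATNNNNATC").search("GATACGTATC")

    def test_concrete_pattern(self):
        m = compile_iupac("ACGT")
        assert m.search("ACGT") and not m.search("ACGA")

    def test_illegal_letter(self):
        with pytest.raises(ValueError):
            compile_iupac("ACJT")


class TestFindSites:
    def test_palindrome_counted_once(self, record):
        hits = find_sites(record("AAGAATTCAA"), EnzymeSpec("EcoRI", "GAATTC", "5'", 1, 1))
        assert [(h.position, h.strand) for h in hits] == [(3, "forward")]

    def test_reverse_strand_hit(self, record):
        fok = EnzymeSpec("FokI", "GGATG", "5'")
        hits = find_sites(record("TTCATCCTT"), fok)
        assert [(h.position, h.strand) for h in hits] == [(3, "reverse")]

    def test_overlapping_occurrences(self, record):
        hits = find_sites(record("AAAA"), EnzymeSpec("probe", "AA", "blunt"), both_strands=False)
        assert [h.position for h in hits] == [1, 2, 3]

    @settings(max_examples=60, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=20, max_size=200), st.data())
    def test_counts_match_naive_oracle(self, seq, data):
        panel = load_enzyme_panel()
        enzyme = data.draw(st.sampled_from(panel))
        rec = SequenceRecord("r", seq)
        assert len(find_sites(rec, enzyme)) == naive_site_count(seq, enzyme)


class TestFrequencyTable:
    def test_zero_counts_included(self, record, enzyme_panel):
        table = site_frequency_table(record("TTCCA" * 10), list(enzyme_panel.values()))
        assert set(table) == set(enzyme_panel)
        assert table["EcoRI"] == 0

    def test_duplicate_names_rejected(self, record):
        e = EnzymeSpec("X", "GATC", "blunt")
        with pytest.raises(ValueError):
            site_frequency_table(record("ACGT"), [e, e])

    def test_empty_panel_rejected(self, record):
        with pytest.raises(ValueError):
            site_frequency_table(record("ACGT"), [])


class TestCompareFrequencies:
    def test_identity_is_empty(self, record, enzyme_panel):
        table = site_frequency_table(record("GGATCCTTCCA"), list(enzyme_panel.values()))
        summary = compare_frequencies(table, table)
        assert summary.lost == summary.gained == summary.changed == frozenset()

    def test_lost_gained_changed(self):
        ref = {"A": 1, "B": 0, "C": 2, "D": 1}
        sample = {"A": 0, "B": 3, "C": 5, "D": 1}
        summary = compare_frequencies(ref, sample)
        assert summary.lost == {"A"}
        assert summary.gained == {"B"}
        assert summary.changed == {"C"}

    def test_panel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_frequencies({"A": 1}, {"B": 1})


class TestFragments:
    def test_single_mid_site(self, record, rflp_enzymes):
        # FspI site placed so the blunt cut falls after base 398 of a
        # 709-base amplicon -> fragments 398 + 311
        fsp = rflp_enzymes["FspI"]
        amplicon = "T" * 395 + "TGCGCA" + "T" * 308
        assert len(amplicon) == 709
        call, frags = predict_rflp(record(amplicon), fsp)
        assert call == "cut"
        assert frags.fragments == (398, 311)

    def test_no_sites_full_length(self, record, rflp_enzymes):
        call, frags = predict_rflp(record("T" * 182), rflp_enzymes["MboI"])
        assert call == "uncut"
        assert frags.fragments == (182,)

    def test_three_fragment_pattern(self, record, rflp_enzymes):
        # two DraI sites cutting a 244-base amplicon into 122 + 73 + 49
        dra = rflp_enzymes["DraI"]
        amplicon = "G" * 119 + "TTTAAA" + "G" * 67 + "TTTAAA" + "G" * 46
        assert len(amplicon) == 244
        _, frags = predict_rflp(record(amplicon), dra)
        assert frags.fragments == (122, 73, 49)

    def test_missing_offsets_unsupported(self, record, enzyme_panel):
        with pytest.raises(NotImplementedError):
            digest_fragments(record("CTGAAG" + "A" * 20), enzyme_panel["Eco57I"])

    def test_offsite_cut_counts_but_does_not_fragment(self, record):
        # cut offset beyond the molecule end: the hit counts, no boundary
        e = EnzymeSpec("OffSite", "GGATG", "5'", cut_top=9, cut_bottom=13)
        rec = record("AAGGATG")  # cut would fall at 2 + 9 = 11 > 7
        assert len(find_sites(rec, e)) == 1
        assert digest_fragments(rec, e).fragments == (7,)

    @settings(max_examples=60, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=10, max_size=150), st.data())
    def test_fragment_sum_conservation(self, seq, data):
        path = default_panel_path().with_name("rflp_enzymes.tsv")
        enzyme = data.draw(st.sampled_from(load_enzyme_panel(path)))
        frags = digest_fragments(SequenceRecord("r", seq), enzyme)
        assert frags.total == len(seq)
        assert len(frags.fragments) >= 1


class TestPanelAssets:
    def test_panel_loads_with_site_length_semantics(self, enzyme_panel):
        assert len(enzyme_panel) == 65
        # informative-site length = non-N letters of the recognition pattern
        assert enzyme_panel["BsaBI"].site_length == 6
        assert enzyme_panel["CspCI"].site_length == 7
        assert enzyme_panel["EcoRII"].site_length == 5

    def test_published_frequency_table_consistency(self):
        # in the published virtual digest, lost/gained sets derived from
        # the frequency columns match the reported 6 (DU145) and 8 (LNCaP)
        # losses plus the single Eco57I gain
        path = default_panel_path().with_name("reference_digest_counts.tsv")
        df = read_table(path).set_index("name")
        ref = {n: int(v) for n, v in df["AC068123.5"].items()}
        for column, n_lost in [("DU145", 6), ("LNCaP", 8)]:
            sample = {n: int(v) for n, v in df[column].items()}
            summary = compare_frequencies(ref, sample)
            assert len(summary.lost) == n_lost
            assert summary.gained == {"Eco57I"}
        assert compare_frequencies(ref, {n: int(v) for n, v in df["DU145"].items()}).lost == {
            "BsaBI", "NlaIV", "BamHI", "EcoRII", "XhoII", "CspCI"
        }

    def test_rflp_assay_table_fragment_sums(self):
        # fragment patterns sum to the product size for the
        # self-consistent rows of the published assay table
        path = default_panel_path().with_name("rflp_assays.tsv")
        df = read_table(path)
        inconsistent = set()
        for row in df.itertuples(index=False):
            size = int(row.product_size)
            for col in (row.fragments_allele_a, row.fragments_allele_b):
                if sum(int(x) for x in col.split("+")) != size:
                    inconsistent.add(row.assay)
        # two assays are internally inconsistent as published
        assert inconsistent == {"GOLY-SNV_1", "DAZ-SNV_IV"}
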