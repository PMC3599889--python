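"""Raw-tag filtering and tag-to-gene mapping, with brute-force oracles."""

from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from conftest import small_config
from dgetag.mapping import (
    filter_raw_tags,
    map_tags,
    mapping_summary,
    strand_breakdown,
)
from dgetag.reference import UnigeneRecord, extract_reference_tags, percent
from dgetag.simulate import simulate_dataset

A21 = "A" * 21
G21 = "G" * 21
CCN = "CC" + "N" + "C" * 18


class TestFiltering:
    def test_three_rules_applied(self):
        raw = {A21: 3, CCN: 5, G21: 1}
        lib = filter_raw_tags(raw, min_copies=2)
        assert dict(lib.clean_counts) == {A21: 3}
        assert lib.clean_total == 3 and lib.clean_distinct == 1
        assert lib.raw_total == 9 and lib.raw_distinct == 3

    def test_identity_when_rules_disabled(self):
        raw = {A21: 1, G21: 4}
        lib = filter_raw_tags(raw, min_copies=1, drop_n=False, adapter_list=())
        assert dict(lib.clean_counts) == raw

    def test_all_singletons_filtered_with_warning(self, caplog):
        raw = {A21: 1, G21: 1}
        with caplog.at_level("WARNING"):
            lib = filter_raw_tags(raw, min_copies=2)
        assert lib.clean_total == 0
        assert any("no tags survived" in r.message for r in caplog.records)

    def test_adapter_removed(self):
        raw = {A21: 10, G21: 10}
        lib = filter_raw_tags(raw, adapter_list=[G21])
        assert dict(lib.clean_counts) == {A21: 10}

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            filter_raw_tags(["AAAA", A21])

    def test_stream_input_counted(self):
        lib = filter_raw_tags([A21, A21, G21], min_copies=2)
        assert dict(lib.clean_counts) == {A21: 2}

    @given(
        counts=st.dictionaries(
            st.text(alphabet="ACGT", min_size=21, max_size=21),
            st.integers(min_value=1, max_value=50),
            max_size=30,
        ),
        m1=st.integers(min_value=1, max_value=5),
        m2=st.integers(min_value=1, max_value=5),
    )
    @settings(max_examples=50, deadline=None)
    def test_min_copies_monotone(self, counts, m1, m2):
        lo, hi = sorted((m1, m2))
        lib_lo = filter_raw_tags(counts, min_copies=lo)
        lib_hi = filter_raw_tags(counts, min_copies=hi)
        assert lib_hi.clean_total <= lib_lo.clean_total
        assert lib_hi.clean_distinct <= lib_lo.clean_distinct


def brute_force_assign(clean_counts, reference):
    """Oracle: all-pairs comparison over every reference entry."""
    gene_all = Counter()
    gene_unambig = Counter()
    unknown = Counter()
    for tag, count in clean_counts.items():
        sense = {g for g, _, s in reference.hits.get(tag, ()) if s == "sense"}
        anti = {g for g, _, s in reference.hits.get(tag, ()) if s == "antisense"}
        genes = sense or anti
        if not genes:
            unknown[tag] = count
            continue
        for g in genes:
            gene_all[g] += count
        if len(genes) == 1:
            gene_unambig[next(iter(genes))] += count
    return gene_all, gene_unambig, unknown


class TestMapping:
    def test_unmatched_tag_is_unknown(self, toy_reference):
        lib = filter_raw_tags({G21: 5}, min_copies=1)
        res = map_tags(lib, toy_reference)
        assert res.unknown_total == 5 and res.unknown_distinct == 1
        assert res.mapped_all_total == 0

    def test_empty_reference_rejected(self, toy_unigenes):
        empty = extract_reference_tags([UnigeneRecord("g", "AAAA" * 10)])
        lib = filter_raw_tags({A21: 2}, min_copies=1)
        with pytest.raises(ValueError, match="empty"):
            map_tags(lib, empty)

    def test_tag_length_mismatch_rejected(self, toy_reference):
        lib = filter_raw_tags({"CATG" + "A" * 13: 2}, min_copies=1)
        with pytest.raises(ValueError, match="length"):
            map_tags(lib, toy_reference)

    def test_toy_counts_match_brute_force(self, toy_reference):
        shared = "CATG" + "ACGTACGTACGTACGTA"
        tags = {
            shared: 10,  # ambiguous between G1 and G2
            "CATG" + "C" * 17: 4,  # G3
            "CATGCATG" + "A" * 13: 3,  # G4 offset 0
            "CATG" + "A" * 17: 2,  # G4 offset 4
            G21: 7,  # unknown
        }
        lib = filter_raw_tags(tags, min_copies=1)
        res = map_tags(lib, toy_reference)
        oracle_all, oracle_unambig, oracle_unknown = brute_force_assign(
            lib.clean_counts, toy_reference
        )
        assert res.gene_all == oracle_all
        assert res.gene_unambig == oracle_unambig
        assert res.unknown_tags == oracle_unknown
        assert res.gene_unambig["G4"] == 5
        assert "G1" not in res.gene_unambig  # shared window: all-mapped only
        assert res.gene_all["G1"] == res.gene_all["G2"] == 10

    def test_simulation_matches_brute_force(self):
        cfg = small_config(n_genes=40, library_size=800, singleton_noise=100, seed=6)
        ds = simulate_dataset(cfg)
        for lid in ("F-1", "S-3"):
            lib = filter_raw_tags(ds.raw_libraries[lid], min_copies=1)
            res = map_tags(lib, ds.reference)
            oracle_all, oracle_unambig, oracle_unknown = brute_force_assign(
                lib.clean_counts, ds.reference
            )
            assert res.gene_all == oracle_all
            assert res.gene_unambig == oracle_unambig
            assert res.unknown_tags == oracle_unknown

    def test_conservation_identity_on_simulations(self, small_dataset):
        for lid, raw in small_dataset.raw_libraries.items():
            lib = filter_raw_tags(raw)
            res = map_tags(lib, small_dataset.reference)
            assert res.mapped_all_total + res.unknown_total == lib.clean_total
            assert res.mapped_all_distinct + res.unknown_distinct == lib.clean_distinct
            assert res.mapped_unambig_total <= res.mapped_all_total
            assert res.mapped_unambig_distinct <= res.mapped_all_distinct

    def test_one_mismatch_rescue_unique_best(self, toy_reference):
        target = "CATG" + "C" * 17
        near = "CATG" + "C" * 16 + "T"  # one substitution from G3's tag
        lib = filter_raw_tags({near: 6}, min_copies=1)
        strict = map_tags(lib, toy_reference, max_mismatch=0)
        relaxed = map_tags(lib, toy_reference, max_mismatch=1)
        assert strict.unknown_total == 6
        assert relaxed.unknown_total == 0
        assert relaxed.gene_all["G3"] == 6
        assert relaxed.mapped_all_total >= strict.mapped_all_total

    def test_one_mismatch_tie_stays_unknown(self):
        genes = [
            UnigeneRecord("a", "CATG" + "A" * 17),
            UnigeneRecord("b", "CATG" + "A" * 16 + "C"),
        ]
        ref = extract_reference_tags(genes, include_antisense=False)
        # equidistant from both reference tags
        query = "CATG" + "A" * 16 + "G"
        lib = filter_raw_tags({query: 3}, min_copies=1)
        res = map_tags(lib, ref, max_mismatch=1)
        assert res.unknown_total == 3

    def test_mismatch_mode_never_decreases_mapping(self, small_dataset):
        lib = filter_raw_tags(small_dataset.raw_libraries["F-2"])
        strict = map_tags(lib, small_dataset.reference, max_mismatch=0)
        relaxed = map_tags(lib, small_dataset.reference, max_mismatch=1)
        assert relaxed.mapped_all_total >= strict.mapped_all_total


class TestSummary:
    def test_percentages_match_printed_convention(self):
        assert percent(4_418_440, 5_766_711) == 76.62
        assert percent(66_081, 116_520) == 56.71
        assert percent(0, 10) == 0.00

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)

    def test_summary_fields(self, toy_reference):
        lib = filter_raw_tags({"CATG" + "C" * 17: 4, G21: 6}, min_copies=1)
        res = map_tags(lib, toy_reference)
        summary = mapping_summary(res, n_reference_genes=5)
        assert summary["All tag mapping to gene"]["Total number"] == 4
        assert summary["All tag mapping to gene"]["Total % of clean tags"] == 40.00
        assert summary["Unknown tags"]["Total number"] == 6
        assert summary["All tag-mapped genes"]["Number"] == 1
        assert summary["All tag-mapped genes"]["% of ref genes"] == 20.00

    def test_empty_library_summary_rejected(self, toy_reference):
        lib = filter_raw_tags({}, min_copies=1)
        res = map_tags(lib, toy_reference)
        with pytest.raises(ValueError):
            mapping_summary(res)


class TestStrandBreakdown:
    def test_partition_sums_to_one(self, small_dataset):
        lib = filter_raw_tags(small_dataset.raw_libraries["S-1"])
        res = map_tags(lib, small_dataset.reference)
        fractions = strand_breakdown(res)
        assert abs(sum(fractions.values()) - 1.0) < 1e-12

    def test_hand_classified_four_tags(self):
        # CATG is its own reverse complement, so a gene ending in CATG
        # yields an antisense reference tag at revcomp offset 0
        gene = UnigeneRecord("g", "CATG" + "ACGTACGTACGTACGTA" + "CATG")
        ref = extract_reference_tags([gene])
        anti_tag = next(t for t, hits in ref.hits.items() if hits[0][2] == "antisense")
        tags = {
            "CATG" + "ACGTACGTACGTACGTA": 5,  # sense
            anti_tag: 5,  # antisense only
            "CATG" + "T" * 17: 5,  # unknown
            "CATG" + "G" * 17: 5,  # unknown
        }
        lib = filter_raw_tags(tags, min_copies=1)
        res = map_tags(lib, ref)
        fractions = strand_breakdown(res)
        assert fractions["antisense_only"] == 0.25
        assert fractions["sense_only"] == 0.25
        assert fractions["unknown"] == 0.50
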