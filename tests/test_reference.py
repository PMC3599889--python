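"""Reference-tag extraction: CATG+17 windows, ambiguity, summaries."""

import numpy as np
import pytest
from Bio.Seq import Seq

from dgetag.reference import (
    SENSE,
    ANTISENSE,
    UnigeneRecord,
    canonical_tag,
    extract_reference_tags,
    library_summary,
    percent,
)


def brute_force_sense_tags(sequence: str, tail: int = 17) -> list[tuple[int, str]]:
    """Independent oracle: naive scan for CATG with >= tail following bases."""
    out = []
    L = 4 + tail
    for i in range(len(sequence) - L + 1):
        window = sequence[i : i + L]
        if window.startswith("CATG") and "N" not in window:
            out.append((i, window))
    return out


class TestExtraction:
    def test_single_tag_at_offset_zero(self):
        gene = UnigeneRecord("g", "CATG" + "A" * 17)
        lib = extract_reference_tags([gene], include_antisense=False)
        assert lib.hits == {"CATG" + "A" * 17: [("g", 0, SENSE)]}

    def test_overlapping_sites_yield_two_tags(self):
        gene = UnigeneRecord("g", "CATGCATG" + "A" * 17)
        lib = extract_reference_tags([gene], include_antisense=False)
        offsets = sorted(off for hits in lib.hits.values() for _, off, _ in hits)
        assert offsets == [0, 4]

    def test_no_catg_no_tags(self):
        lib = extract_reference_tags([UnigeneRecord("g", "AAAA" * 10)])
        assert len(lib) == 0
        assert lib.genes_with_catg_fraction == 0.0

    def test_window_with_n_skipped(self):
        gene = UnigeneRecord("g", "CATG" + "A" * 8 + "N" + "A" * 8)
        lib = extract_reference_tags([gene], include_antisense=False)
        assert len(lib) == 0
        # the gene still counts as CATG-containing
        assert lib.genes_with_catg == 1

    def test_truncated_tail_skipped(self):
        gene = UnigeneRecord("g", "CATG" + "A" * 16)  # only 16 bases follow
        lib = extract_reference_tags([gene], include_antisense=False)
        assert len(lib) == 0

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            extract_reference_tags([])

    def test_bad_characters_name_the_record(self):
        with pytest.raises(ValueError, match="gX"):
            UnigeneRecord("gX", "CATGRRR")

    def test_duplicate_gene_id_raises(self):
        genes = [UnigeneRecord("g", "CATG" + "A" * 17)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            extract_reference_tags(genes)

    def test_sense_tag_count_matches_naive_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=rng.integers(21, 300)))
            lib = extract_reference_tags(
                [UnigeneRecord("g", seq)], include_antisense=False
            )
            expected = brute_force_sense_tags(seq)
            got = sorted(
                (off, tag) for tag, hits in lib.hits.items() for _, off, _ in hits
            )
            assert got == sorted(expected)

    def test_reverse_complement_swaps_strands(self):
        rng = np.random.default_rng(9)
        genes = [
            UnigeneRecord(f"g{i}", "".join(rng.choice(list("ACGT"), size=200)))
            for i in range(10)
        ]
        fwd = extract_reference_tags(genes)
        rc_genes = [
            UnigeneRecord(g.gene_id, str(Seq(g.sequence).reverse_complement()))
            for g in genes
        ]
        rev = extract_reference_tags(rc_genes)

        def strand_set(lib, strand):
            return {
                (tag, g)
                for tag, hits in lib.hits.items()
                for g, _, s in hits
                if s == strand
            }

        assert strand_set(fwd, SENSE) == strand_set(rev, ANTISENSE)
        assert strand_set(fwd, ANTISENSE) == strand_set(rev, SENSE)

    def test_tag_invariants_on_random_set(self):
        rng = np.random.default_rng(13)
        genes = [
            UnigeneRecord(f"g{i}", "".join(rng.choice(list("ACGT"), size=150)))
            for i in range(30)
        ]
        lib = extract_reference_tags(genes)
        lengths = {len(g.sequence) for g in genes}.pop()
        for tag, hits in lib.hits.items():
            assert len(tag) == 21 and tag.startswith("CATG")
            for _, off, _ in hits:
                assert 0 <= off and off + 21 <= lengths


class TestAmbiguity:
    def test_shared_window_is_ambiguous(self, toy_reference):
        shared = "CATG" + "ACGTACGTACGTACGTA"
        assert not toy_reference.is_unambiguous(shared)
        assert toy_reference.sense_genes(shared) == {"G1", "G2"}

    def test_single_gene_library_all_unambiguous(self):
        lib = extract_reference_tags(
            [UnigeneRecord("g", "CATGCATG" + "A" * 17)], include_antisense=False
        )
        assert all(lib.is_unambiguous(t) for t in lib.hits)

    def test_unambiguous_count_matches_brute_force(self):
        rng = np.random.default_rng(3)
        genes = [
            UnigeneRecord(f"g{i}", "".join(rng.choice(list("ACGT"), size=120)))
            for i in range(5)
        ]
        # force one shared window between g0 and g1
        window = "CATG" + "G" * 17
        genes[0] = UnigeneRecord("g0", window + genes[0].sequence[21:])
        genes[1] = UnigeneRecord("g1", genes[1].sequence[:-21] + window)
        lib = extract_reference_tags(genes, include_antisense=False)

        tag_to_genes: dict[str, set[str]] = {}
        for g in genes:
            for _, tag in brute_force_sense_tags(g.sequence):
                tag_to_genes.setdefault(tag, set()).add(g.gene_id)
        expected = sum(1 for gs in tag_to_genes.values() if len(gs) == 1)
        assert lib.unambiguous_reference_tags == expected
        assert not lib.is_unambiguous(window)


class TestSummary:
    def test_seven_of_eight(self):
        genes = [UnigeneRecord(f"g{i}", "CATG" + "A" * 17) for i in range(7)]
        genes.append(UnigeneRecord("g7", "A" * 40))
        lib = extract_reference_tags(genes)
        assert library_summary(lib, 8)["genes_with_catg_pct"] == 87.50

    def test_no_catg_zero_percent(self):
        lib = extract_reference_tags([UnigeneRecord("g", "A" * 40)])
        assert library_summary(lib, 1)["genes_with_catg_pct"] == 0.00

    def test_zero_reference_genes_rejected(self, toy_reference):
        with pytest.raises(ValueError):
            library_summary(toy_reference, 0)

    def test_summary_matches_independent_recount(self, small_dataset):
        lib = small_dataset.reference
        summary = library_summary(lib, lib.n_genes)
        n_catg = sum(1 for u in small_dataset.unigenes if "CATG" in u.sequence)
        assert summary["genes_with_catg"] == n_catg
        assert summary["genes_with_catg_pct"] == percent(n_catg, lib.n_genes)
        # distinct-sequence counting: totals equal the number of distinct tags
        assert summary["total_reference_tags"] == len(lib.hits)

    def test_pair_counting_convention(self, toy_unigenes):
        seq_lib = extract_reference_tags(toy_unigenes, counting="sequence")
        pair_lib = extract_reference_tags(toy_unigenes, counting="pair")
        assert pair_lib.total_reference_tags == sum(
            len(h) for h in seq_lib.hits.values()
        )
        assert pair_lib.total_reference_tags > seq_lib.total_reference_tags


def test_canonical_tag_prepends_anchor():
    assert canonical_tag("A" * 17) == "CATG" + "A" * 17
    assert canonical_tag("CATG" + "A" * 17) == "CATG" + "A" * 17
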