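"""Virtual reference-tag library construction.

NlaIII-anchored digital gene expression (DGE) quantifies transcripts by
sequencing a fixed-length tag downstream of every CATG restriction site.
To map such tags back to genes one builds a *virtual* reference-tag
library: every occurrence of ``CATG`` in a reference transcript (unigene)
with at least ``tag_tail_length`` bases following it yields one 21-mer
reference tag (``CATG`` + 17 nt by default).  Because short tags can be
shared between paralogues or assembly redundancy, each tag is flagged
*unambiguous* only when all of its sense-strand hits fall in a single
gene; only unambiguous tags contribute to per-gene expression estimates
downstream.

Antisense reference tags (the same extraction applied to the reverse
complement of each unigene) are built as well, so that tags arising from
antisense transcription can be recognised and classified.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

TAG_ANCHOR = "CATG"
DEFAULT_TAIL = 17

SENSE = "sense"
ANTISENSE = "antisense"

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class UnigeneRecord:
    """A reference transcript: an identifier and its DNA sequence (ACGTN)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"unigene {self.gene_id!r} has an empty sequence")
        bad = set(self.sequence.upper()) - _VALID_BASES
        if bad:
            raise ValueError(
                f"unigene {self.gene_id!r} contains non-ACGTN characters: {sorted(bad)}"
            )


@dataclass(frozen=True)
class ReferenceTag:
    """One virtual tag: a CATG-anchored 21-mer with its gene/position/strand."""

    tag_seq: str
    gene_id: str
    offset: int  # 0-based start of CATG (revcomp coordinates for antisense)
    strand: str  # "sense" | "antisense"


@dataclass
class ReferenceTagLibrary:
    """Map from tag sequence to its reference hits, with ambiguity flags.

    ``hits`` maps each distinct tag sequence to the list of
    ``(gene_id, offset, strand)`` triples where it occurs.  A tag is
    *unambiguous* when its sense-strand hits reference exactly one gene;
    per-strand ambiguity (used during mapping) is derived on demand.
    """

    hits: dict[str, list[tuple[str, int, str]]]
    n_genes: int
    genes_with_catg: int
    tag_length: int = len(TAG_ANCHOR) + DEFAULT_TAIL
    counting: str = "sequence"  # "sequence" | "pair": convention for totals

    def __post_init__(self) -> None:
        if self.counting not in ("sequence", "pair"):
            raise ValueError(f"unknown counting convention {self.counting!r}")

    # -- totals ---------------------------------------------------------

    @property
    def total_reference_tags(self) -> int:
        if self.counting == "sequence":
            return len(self.hits)
        return sum(len(v) for v in self.hits.values())

    @property
    def unambiguous_reference_tags(self) -> int:
        return sum(1 for seq in self.hits if self.is_unambiguous(seq))

    @property
    def genes_with_catg_fraction(self) -> float:
        return self.genes_with_catg / self.n_genes if self.n_genes else 0.0

    # -- per-tag queries ------------------------------------------------

    def sense_genes(self, tag_seq: str) -> set[str]:
        return {g for g, _, s in self.hits.get(tag_seq, ()) if s == SENSE}

    def antisense_genes(self, tag_seq: str) -> set[str]:
        return {g for g, _, s in self.hits.get(tag_seq, ()) if s == ANTISENSE}

    def is_unambiguous(self, tag_seq: str) -> bool:
        """True when the tag's sense hits fall in exactly one gene."""
        return len(self.sense_genes(tag_seq)) == 1

    def genes_on_strand(self, tag_seq: str, strand: str) -> set[str]:
        return self.sense_genes(tag_seq) if strand == SENSE else self.antisense_genes(tag_seq)

    def sense_tags_of_gene(self, gene_id: str) -> list[str]:
        """All sense tag sequences of one gene, ordered by offset."""
        out = [
            (off, seq)
            for seq, hit_list in self.hits.items()
            for g, off, s in hit_list
            if g == gene_id and s == SENSE
        ]
        return [seq for _, seq in sorted(out)]

    def __len__(self) -> int:
        return len(self.hits)

    def __contains__(self, tag_seq: str) -> bool:
        return tag_seq in self.hits

    # -- I/O -------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write ``tag_seq, gene_id, offset, strand, ambiguous`` rows."""
        with open(path, "w") as fh:
            fh.write("tag_seq\tgene_id\toffset\tstrand\tambiguous\n")
            for seq in sorted(self.hits):
                amb = int(not self.is_unambiguous(seq))
                for gene_id, offset, strand in self.hits[seq]:
                    fh.write(f"{seq}\t{gene_id}\t{offset}\t{strand}\t{amb}\n")

    def summary_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(library_summary(self, self.n_genes), fh, indent=2)
            fh.write("\n")


def canonical_tag(seq: str, tag_length: int = 4 + DEFAULT_TAIL) -> str:
    """Canonicalize a tag to the anchored 21-mer form.

    17-mer inputs (the sequenced tail without its CATG anchor) are
    prefixed with CATG; full-length tags are returned unchanged.
    """
    seq = seq.upper()
    if len(seq) == tag_length - len(TAG_ANCHOR):
        return TAG_ANCHOR + seq
    return seq


def iter_unigenes_fasta(path: str | Path) -> Iterator[UnigeneRecord]:
    """Read a multi-FASTA of unigenes, validating characters per record."""
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        yield UnigeneRecord(gene_id=rec.id, sequence=str(rec.seq).upper())
    if n == 0:
        raise ValueError(f"no FASTA records found in {path}")


def _scan_sequence(seq: str, tail: int) -> Iterator[tuple[int, str]]:
    """Yield (offset, tag) for every CATG with >= tail following bases.

    Windows containing N are skipped. Overlapping CATG occurrences each
    yield a tag.
    """
    tag_len = len(TAG_ANCHOR) + tail
    start = 0
    while True:
        i = seq.find(TAG_ANCHOR, start)
        if i < 0:
            break
        window = seq[i : i + tag_len]
        if len(window) == tag_len and "N" not in window:
            yield i, window
        start = i + 1


def extract_reference_tags(
    unigenes: Iterable[UnigeneRecord],
    tag_tail_length: int = DEFAULT_TAIL,
    include_antisense: bool = True,
    counting: str = "sequence",
) -> ReferenceTagLibrary:
    """Build the virtual reference-tag library from a unigene set.

    Every CATG occurrence with at least ``tag_tail_length`` bases after it
    contributes one sense tag; with ``include_antisense`` the reverse
    complement of each unigene is scanned identically for antisense tags.

    Raises ``ValueError`` on an empty unigene set.
    """
    hits: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
    n_genes = 0
    genes_with_catg = 0
    seen_ids: set[str] = set()
    for rec in unigenes:
        if rec.gene_id in seen_ids:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r} in unigene set")
        seen_ids.add(rec.gene_id)
        n_genes += 1
        seq = rec.sequence.upper()
        n_sense = 0
        for offset, tag in _scan_sequence(seq, tag_tail_length):
            hits[tag].append((rec.gene_id, offset, SENSE))
            n_sense += 1
        if TAG_ANCHOR in seq:
            genes_with_catg += 1
        if include_antisense:
            rc = str(Seq(seq).reverse_complement())
            for offset, tag in _scan_sequence(rc, tag_tail_length):
                hits[tag].append((rec.gene_id, offset, ANTISENSE))
    if n_genes == 0:
        raise ValueError("empty unigene set")
    return ReferenceTagLibrary(
        hits=dict(hits),
        n_genes=n_genes,
        genes_with_catg=genes_with_catg,
        tag_length=len(TAG_ANCHOR) + tag_tail_length,
        counting=counting,
    )


def classify_ambiguity(library: ReferenceTagLibrary) -> dict[str, bool]:
    """Per-tag unambiguity flags (sense hits in exactly one gene)."""
    return {seq: library.is_unambiguous(seq) for seq in library.hits}


def percent(part: float, whole: float, ndigits: int = 2) -> float:
    """part/whole x 100, rounded — the report convention used throughout."""
    if whole == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(part / whole * 100.0, ndigits)


def library_summary(library: ReferenceTagLibrary, n_reference_genes: int) -> dict:
    """Headline reference-library statistics.

    Reports the fraction of reference genes containing a CATG site (as a
    percentage, 2 decimals) plus total and unambiguous reference-tag
    counts under the library's counting convention.
    """
    if n_reference_genes == 0:
        raise ValueError("n_reference_genes must be positive")
    return {
        "n_reference_genes": n_reference_genes,
        "genes_with_catg": library.genes_with_catg,
        "genes_with_catg_pct": percent(library.genes_with_catg, n_reference_genes),
        "total_reference_tags": library.total_reference_tags,
        "unambiguous_reference_tags": library.unambiguous_reference_tags,
        "counting": library.counting,
    }


def build_reference_from_fasta(
    fasta_path: str | Path,
    tag_tail_length: int = DEFAULT_TAIL,
    include_antisense: bool = True,
    counting: str = "sequence",
) -> ReferenceTagLibrary:
    """Convenience: FASTA path → ReferenceTagLibrary."""
    return extract_reference_tags(
        iter_unigenes_fasta(fasta_path),
        tag_tail_length=tag_tail_length,
        include_antisense=include_antisense,
        counting=counting,
    )
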