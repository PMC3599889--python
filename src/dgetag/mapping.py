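"""Raw-tag filtering and tag-to-gene mapping.

The raw output of a DGE lane is a stream of fixed-length tags.  Filtering
to *clean tags* removes tags with ambiguous bases, adapter sequences, and
library-wide singletons (copy number below ``min_copies``); everything
downstream counts clean tags only.

Mapping assigns each clean tag to reference genes by exact sequence match
against the virtual reference-tag library (sense hits take precedence
over antisense), with an optional unique-best one-mismatch rescue.  The
accounting mirrors the standard DGE report: *all tag-mapped* totals
(every clean tag with at least one reference hit), *unambiguous* totals
(hits confined to one gene), and *unknown* tags, with the exact
conservation identity ``mapped_all + unknown == clean`` on both total and
distinct counts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .reference import ANTISENSE, SENSE, ReferenceTagLibrary, percent

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")

# strand classes of a mapped distinct tag
SENSE_ONLY = "sense_only"
ANTISENSE_ONLY = "antisense_only"
BOTH = "both"
UNKNOWN = "unknown"


@dataclass
class TagLibrary:
    """One sample's tag counts: raw totals plus the clean-tag multiset."""

    library_id: str
    clean_counts: Counter
    raw_total: int
    raw_distinct: int
    genotype: str | None = None
    stage: str | None = None

    @property
    def clean_total(self) -> int:
        return sum(self.clean_counts.values())

    @property
    def clean_distinct(self) -> int:
        return len(self.clean_counts)


@dataclass
class MappingResult:
    """Partition of one library's clean tags into mapped and unknown.

    Per-gene counters hold total tag counts; ``all_*`` counters include
    ambiguous tags (credited to every hit gene), ``unambig_*`` counters
    only tags whose hits on the assigned strand fall in a single gene.
    """

    library_id: str
    gene_all_sense: Counter
    gene_all_antisense: Counter
    gene_unambig_sense: Counter
    gene_unambig_antisense: Counter
    mapped_all_total: int
    mapped_all_distinct: int
    mapped_unambig_total: int
    mapped_unambig_distinct: int
    unknown_total: int
    unknown_distinct: int
    clean_total: int
    clean_distinct: int
    strand_class_distinct: Counter  # distinct-tag counts per strand class
    unknown_tags: Counter
    assignments: dict[str, tuple[str, frozenset[str], bool]] = field(repr=False)
    # tag_seq -> (strand used, genes hit on that strand, unambiguous?)

    @property
    def gene_all(self) -> Counter:
        return self.gene_all_sense + self.gene_all_antisense

    @property
    def gene_unambig(self) -> Counter:
        return self.gene_unambig_sense + self.gene_unambig_antisense

    @property
    def all_mapped_genes(self) -> set[str]:
        return set(self.gene_all_sense) | set(self.gene_all_antisense)

    @property
    def unambiguous_mapped_genes(self) -> set[str]:
        return set(self.gene_unambig_sense) | set(self.gene_unambig_antisense)

    def to_gene_tsv(self, path: str | Path) -> None:
        genes = sorted(self.all_mapped_genes)
        with open(path, "w") as fh:
            fh.write("gene_id\tall_count\tunambig_count\tsense_count\tantisense_count\n")
            for g in genes:
                fh.write(
                    f"{g}\t{self.gene_all[g]}\t{self.gene_unambig[g]}"
                    f"\t{self.gene_all_sense[g]}\t{self.gene_all_antisense[g]}\n"
                )

    def to_unknown_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("tag_seq\tcount\n")
            for seq in sorted(self.unknown_tags):
                fh.write(f"{seq}\t{self.unknown_tags[seq]}\n")


def filter_raw_tags(
    raw_tags: Iterable[str] | Mapping[str, int],
    library_id: str = "library",
    min_copies: int = 2,
    drop_n: bool = True,
    adapter_list: Sequence[str] = (),
    genotype: str | None = None,
    stage: str | None = None,
) -> TagLibrary:
    """Filter a raw tag stream (or pre-counted map) to clean tags.

    Three rules, each configurable: drop tags containing non-ACGT bases
    (``drop_n``), drop tags identical to an adapter entry, and drop tags
    whose library-wide copy number is below ``min_copies``.

    Raises ``ValueError`` on mixed tag lengths.
    """
    if isinstance(raw_tags, Mapping):
        raw_counts = Counter({t.upper(): int(c) for t, c in raw_tags.items()})
    else:
        raw_counts = Counter(t.upper() for t in raw_tags)
    if raw_counts:
        lengths = {len(t) for t in raw_counts}
        if len(lengths) > 1:
            raise ValueError(f"mixed tag lengths in raw input: {sorted(lengths)}")
    raw_total = sum(raw_counts.values())
    raw_distinct = len(raw_counts)

    adapters = {a.upper() for a in adapter_list}
    clean = Counter()
    for tag, count in raw_counts.items():
        if drop_n and (set(tag) - _ACGT):
            continue
        if tag in adapters:
            continue
        if count < min_copies:
            continue
        clean[tag] = count
    if raw_total and not clean:
        logger.warning(
            "library %s: no tags survived filtering (min_copies=%d)", library_id, min_copies
        )
    return TagLibrary(
        library_id=library_id,
        clean_counts=clean,
        raw_total=raw_total,
        raw_distinct=raw_distinct,
        genotype=genotype,
        stage=stage,
    )


def _one_mismatch_neighbors(tag: str) -> Iterable[str]:
    for i, base in enumerate(tag):
        for alt in "ACGT":
            if alt != base:
                yield tag[:i] + alt + tag[i + 1 :]


def _resolve_hit(
    tag: str, ref: ReferenceTagLibrary, max_mismatch: int
) -> tuple[str | None, frozenset[str], str]:
    """Return (strand used, genes hit on that strand, strand class).

    Exact match first, sense before antisense; with ``max_mismatch=1`` an
    unmatched tag is rescued only when exactly one reference tag sequence
    lies at Hamming distance 1 (ties stay unknown).
    """
    if tag in ref:
        sense = ref.sense_genes(tag)
        anti = ref.antisense_genes(tag)
        if sense:
            cls = BOTH if anti else SENSE_ONLY
            return SENSE, frozenset(sense), cls
        return ANTISENSE, frozenset(anti), ANTISENSE_ONLY
    if max_mismatch >= 1:
        matches = [n for n in _one_mismatch_neighbors(tag) if n in ref]
        if len(matches) == 1:
            neighbor = matches[0]
            sense = ref.sense_genes(neighbor)
            anti = ref.antisense_genes(neighbor)
            if sense:
                return SENSE, frozenset(sense), BOTH if anti else SENSE_ONLY
            return ANTISENSE, frozenset(anti), ANTISENSE_ONLY
    return None, frozenset(), UNKNOWN


def map_tags(
    lib: TagLibrary, ref: ReferenceTagLibrary, max_mismatch: int = 0
) -> MappingResult:
    """Assign every clean tag of one library to reference genes.

    Ambiguous tags (several genes hit on the assigned strand) count toward
    the all-mapped tallies of every hit gene but never toward unambiguous
    tallies.  The conservation identity mapped_all + unknown == clean
    holds exactly for totals and distinct counts.

    Raises ``ValueError`` on an empty reference or a tag-length mismatch.
    """
    if len(ref) == 0:
        raise ValueError("empty reference-tag library")
    if lib.clean_counts:
        tag_len = len(next(iter(lib.clean_counts)))
        if tag_len != ref.tag_length:
            raise ValueError(
                f"tag length {tag_len} does not match reference tag length {ref.tag_length}"
            )

    gene_all_sense: Counter = Counter()
    gene_all_antisense: Counter = Counter()
    gene_unambig_sense: Counter = Counter()
    gene_unambig_antisense: Counter = Counter()
    strand_class_distinct: Counter = Counter()
    unknown_tags: Counter = Counter()
    assignments: dict[str, tuple[str, frozenset[str], bool]] = {}

    mapped_all_total = mapped_all_distinct = 0
    mapped_unambig_total = mapped_unambig_distinct = 0

    for tag, count in lib.clean_counts.items():
        strand, genes, cls = _resolve_hit(tag, ref, max_mismatch)
        strand_class_distinct[cls] += 1
        if strand is None:
            unknown_tags[tag] = count
            continue
        mapped_all_total += count
        mapped_all_distinct += 1
        unambiguous = len(genes) == 1
        assignments[tag] = (strand, genes, unambiguous)
        all_counter = gene_all_sense if strand == SENSE else gene_all_antisense
        for g in genes:
            all_counter[g] += count
        if unambiguous:
            mapped_unambig_total += count
            mapped_unambig_distinct += 1
            (gene_unambig_sense if strand == SENSE else gene_unambig_antisense)[
                next(iter(genes))
            ] += count

    return MappingResult(
        library_id=lib.library_id,
        gene_all_sense=gene_all_sense,
        gene_all_antisense=gene_all_antisense,
        gene_unambig_sense=gene_unambig_sense,
        gene_unambig_antisense=gene_unambig_antisense,
        mapped_all_total=mapped_all_total,
        mapped_all_distinct=mapped_all_distinct,
        mapped_unambig_total=mapped_unambig_total,
        mapped_unambig_distinct=mapped_unambig_distinct,
        unknown_total=sum(unknown_tags.values()),
        unknown_distinct=len(unknown_tags),
        clean_total=lib.clean_total,
        clean_distinct=lib.clean_distinct,
        strand_class_distinct=strand_class_distinct,
        unknown_tags=unknown_tags,
        assignments=assignments,
    )


def mapping_summary(
    result: MappingResult,
    clean_total: int | None = None,
    clean_distinct: int | None = None,
    n_reference_genes: int | None = None,
) -> dict:
    """Standard DGE accounting of one mapped library.

    Every percentage is part/whole x 100 rounded to 2 decimals.  Row
    labels follow the conventional per-library report: clean tags, all
    tag mapping to gene, unambiguous tag mapping to gene, tag-mapped
    genes, and unknown tags.
    """
    clean_total = result.clean_total if clean_total is None else clean_total
    clean_distinct = result.clean_distinct if clean_distinct is None else clean_distinct
    if clean_total == 0 or clean_distinct == 0:
        raise ValueError("clean totals must be positive for a mapping summary")
    summary = {
        "library_id": result.library_id,
        "Clean tags": {
            "Total number": clean_total,
            "Distinct tag numbers": clean_distinct,
        },
        "All tag mapping to gene": {
            "Total number": result.mapped_all_total,
            "Total % of clean tags": percent(result.mapped_all_total, clean_total),
            "Distinct tag numbers": result.mapped_all_distinct,
            "Distinct tag % of clean tags": percent(result.mapped_all_distinct, clean_distinct),
        },
        "Unambiguous Tag mapping to gene": {
            "Total number": result.mapped_unambig_total,
            "Total % of clean tags": percent(result.mapped_unambig_total, clean_total),
            "Distinct tag numbers": result.mapped_unambig_distinct,
            "Distinct tag % of clean tags": percent(
                result.mapped_unambig_distinct, clean_distinct
            ),
        },
        "Unknown tags": {
            "Total number": result.unknown_total,
            "Total % of clean tags": percent(result.unknown_total, clean_total),
            "Distinct tag numbers": result.unknown_distinct,
            "Distinct tag % of clean tags": percent(result.unknown_distinct, clean_distinct),
        },
    }
    if n_reference_genes is not None:
        if n_reference_genes == 0:
            raise ValueError("n_reference_genes must be positive")
        n_all = len(result.all_mapped_genes)
        n_unambig = len(result.unambiguous_mapped_genes)
        summary["All tag-mapped genes"] = {
            "Number": n_all,
            "% of ref genes": percent(n_all, n_reference_genes),
        }
        summary["Unambiguous tag-mapped genes"] = {
            "Number": n_unambig,
            "% of ref genes": percent(n_unambig, n_reference_genes),
        }
    return summary


def strand_breakdown(result: MappingResult) -> dict[str, float]:
    """Fractions of distinct clean tags per strand class.

    Classes (sense-only / antisense-only / both-strand matches / unknown)
    partition the distinct clean tags, so the fractions sum to 1.
    """
    total = result.clean_distinct
    if total == 0:
        return {SENSE_ONLY: 0.0, ANTISENSE_ONLY: 0.0, BOTH: 0.0, UNKNOWN: 0.0}
    return {
        cls: result.strand_class_distinct.get(cls, 0) / total
        for cls in (SENSE_ONLY, ANTISENSE_ONLY, BOTH, UNKNOWN)
    }
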