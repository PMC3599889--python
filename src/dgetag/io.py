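"""Readers and writers for tag-library and truth-table files.

Three interchangeable on-disk forms for a tag library: plain text (one
tag per line, repeated by copy number), FASTQ with dummy qualities, and
a pre-counted TSV (``tag<TAB>count``).  All readers return a Counter of
tag sequence to copy number.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Mapping


def write_tags_text(counts: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tag in sorted(counts):
            line = tag + "\n"
            fh.write(line * counts[tag])


def write_tags_fastq(counts: Mapping[str, int], path: str | Path) -> None:
    """FASTQ with constant dummy qualities (no quality model is simulated)."""
    with open(path, "w") as fh:
        i = 0
        for tag in sorted(counts):
            qual = "I" * len(tag)
            for _ in range(counts[tag]):
                fh.write(f"@tag_{i}\n{tag}\n+\n{qual}\n")
                i += 1


def write_tags_tsv(counts: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tag\tcount\n")
        for tag in sorted(counts):
            fh.write(f"{tag}\t{counts[tag]}\n")


def read_tags(path: str | Path, fmt: str | None = None) -> Counter:
    """Read a tag library; format from ``fmt`` or the file extension.

    ``fmt`` is one of ``text``, ``fastq``, ``tsv``.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".fastq": "fastq", ".fq": "fastq", ".tsv": "tsv", ".txt": "text"}.get(
            suffix, "text"
        )
    counts: Counter = Counter()
    with open(path) as fh:
        if fmt == "tsv":
            header = fh.readline()
            if header and not header.startswith("tag"):
                tag, n = header.split("\t")
                counts[tag.strip().upper()] += int(n)
            for line in fh:
                if line.strip():
                    tag, n = line.rstrip("\n").split("\t")
                    counts[tag.upper()] += int(n)
        elif fmt == "fastq":
            for i, line in enumerate(fh):
                if i % 4 == 1:
                    counts[line.strip().upper()] += 1
        elif fmt == "text":
            for line in fh:
                tag = line.strip()
                if tag:
                    counts[tag.upper()] += 1
        else:
            raise ValueError(f"unknown tag-file format {fmt!r}")
    return counts


def write_truth_tsv(truth, path: str | Path) -> None:
    """Write the planted-effect table: gene_id, stage, genotype, log2fc, de_flag."""
    with open(path, "w") as fh:
        fh.write("gene_id\tstage\tgenotype\tlog2fc\tde_flag\n")
        for stage in truth.stage_names:
            fc = truth.log2fc[stage]
            for gene_id in truth.gene_ids:
                v = fc.loc[gene_id]
                fh.write(f"{gene_id}\t{stage}\tmutant\t{v:g}\t{int(v != 0)}\n")
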