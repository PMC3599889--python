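"""Expression quantification: TPM, detection, tag-abundance distributions,
sequencing saturation, and the qRT-PCR 2^-ddCt helper.

Counts are normalised to transcripts per million *clean tags*:
``TPM = count / clean_total * 1e6``.  The denominator is deliberately the
library's clean-tag total, not its mapped total, so per-gene TPM values
sum to 1e6 x (mapped fraction) rather than to 1e6.  A gene is *detected*
in a library when its TPM reaches a configurable threshold (default 1
TPM on unambiguous counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_BINS: tuple[tuple[int, float], ...] = (
    (1, 1),
    (2, 5),
    (6, 10),
    (11, 20),
    (21, 50),
    (51, 100),
    (101, math.inf),
)


def tpm_normalize(counts, clean_total: float):
    """Transcripts per million clean tags: count / clean_total x 1e6.

    Accepts scalars, arrays, Series or DataFrames; ``clean_total`` may be
    per-library (aligned on columns for a DataFrame).
    """
    if np.any(np.asarray(clean_total) <= 0):
        raise ValueError("clean_total must be positive")
    if isinstance(counts, pd.DataFrame):
        return counts.div(clean_total, axis="columns") * 1e6
    return counts / clean_total * 1e6


@dataclass
class ExpressionMatrix:
    """Gene x library unambiguous counts with TPM and detection flags."""

    counts: pd.DataFrame  # genes x libraries, integer counts
    clean_totals: pd.Series  # per-library clean-tag totals (TPM denominator)

    def __post_init__(self) -> None:
        self.clean_totals = self.clean_totals.reindex(self.counts.columns)
        if self.clean_totals.isna().any():
            missing = self.clean_totals[self.clean_totals.isna()].index.tolist()
            raise ValueError(f"clean totals missing for libraries: {missing}")
        if (self.clean_totals <= 0).any():
            raise ValueError("clean totals must be positive")

    @classmethod
    def from_mapping_results(
        cls, results: Sequence, clean_totals: Mapping[str, int] | None = None
    ) -> "ExpressionMatrix":
        """Assemble the matrix from per-library MappingResult objects,
        using unambiguous per-gene counts."""
        cols = {}
        totals = {}
        for res in results:
            cols[res.library_id] = pd.Series(res.gene_unambig, dtype="int64")
            totals[res.library_id] = res.clean_total
        counts = pd.DataFrame(cols).fillna(0).astype("int64").sort_index()
        if clean_totals is not None:
            totals = dict(clean_totals)
        return cls(counts=counts, clean_totals=pd.Series(totals, dtype="float64"))

    @property
    def tpm(self) -> pd.DataFrame:
        return tpm_normalize(self.counts, self.clean_totals)

    def detection(self, threshold: float = 1.0) -> pd.DataFrame:
        if threshold < 0:
            raise ValueError("detection threshold must be non-negative")
        if threshold == 0:
            return self.counts >= 1
        return self.tpm >= threshold

    def to_tsv(self, path: str | Path, float_format: str = "%.2f") -> None:
        """Write counts and TPM side by side (TPM printed to 2 decimals)."""
        tpm = self.tpm.add_suffix(":TPM")
        counts = self.counts.add_suffix(":count")
        out = pd.concat([counts, tpm], axis=1).sort_index()
        out.to_csv(path, sep="\t", float_format=float_format, index_label="gene_id")

    @classmethod
    def from_tsv(
        cls, path: str | Path, clean_totals: Mapping[str, float]
    ) -> "ExpressionMatrix":
        """Read a matrix written by :meth:`to_tsv` (count columns only)."""
        frame = pd.read_csv(path, sep="\t", index_col="gene_id")
        counts = frame[[c for c in frame.columns if c.endswith(":count")]].copy()
        counts.columns = [c[: -len(":count")] for c in counts.columns]
        return cls(
            counts=counts.astype("int64"),
            clean_totals=pd.Series(dict(clean_totals), dtype="float64"),
        )


def detect_genes(
    matrix: ExpressionMatrix, detection_threshold: float = 1.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Detection flags (gene x library) and per-library detected-gene counts."""
    flags = matrix.detection(detection_threshold)
    return flags, flags.sum(axis=0)


def copy_number_distribution(
    clean_counts: Mapping[str, int],
    bins: Sequence[tuple[int, float]] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Distribution of distinct clean tags over copy-number bins.

    Each distinct tag falls in exactly one ``[lo, hi]`` bin by its copy
    number; the bins must be disjoint and ordered.  Returns a frame with
    per-bin distinct-tag counts and percentages (summing to 100).
    """
    if not clean_counts:
        raise ValueError("empty clean-tag counts")
    for (lo1, hi1), (lo2, hi2) in zip(bins, bins[1:]):
        if lo2 <= hi1:
            raise ValueError(f"overlapping or unordered bins: [{lo1},{hi1}] and [{lo2},{hi2}]")
    labels = [f"{lo}" if lo == hi else (f">{lo - 1}" if math.isinf(hi) else f"{lo}-{hi}") for lo, hi in bins]
    counts = np.zeros(len(bins), dtype=int)
    unbinned = 0
    for copy in clean_counts.values():
        for i, (lo, hi) in enumerate(bins):
            if lo <= copy <= hi:
                counts[i] += 1
                break
        else:
            unbinned += 1
    if unbinned:
        raise ValueError(f"{unbinned} tags fall outside every bin")
    total = counts.sum()
    return pd.DataFrame(
        {
            "bin": labels,
            "distinct_tags": counts,
            "percent": counts / total * 100.0,
        }
    )


def saturation_curve(
    clean_counts: Mapping[str, int],
    mapping_result,
    n_steps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Genes detected vs sequencing depth, by subsampling without replacement.

    The library's clean tags are shuffled once (deterministic in ``seed``)
    and gene detection (>= 1 mapped tag) is evaluated at ``n_steps``
    evenly spaced depths up to the full clean total, separately for
    all-mapped and unambiguous assignment.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    tags = list(clean_counts)
    copies = np.fromiter((clean_counts[t] for t in tags), dtype=np.int64, count=len(tags))
    total = int(copies.sum())
    rng = np.random.default_rng(seed)
    stream = rng.permutation(np.repeat(np.arange(len(tags)), copies))

    # first depth at which each distinct tag has appeared at least once
    first_pos = np.full(len(tags), total, dtype=np.int64)
    np.minimum.at(first_pos, stream, np.arange(total))

    # earliest first-appearance over the tags that detect each gene
    gene_first_all: dict[str, int] = {}
    gene_first_unambig: dict[str, int] = {}
    for idx, tag in enumerate(tags):
        assigned = mapping_result.assignments.get(tag)
        if assigned is None:
            continue
        _, genes, unambiguous = assigned
        pos = int(first_pos[idx])
        for g in genes:
            if pos < gene_first_all.get(g, total + 1):
                gene_first_all[g] = pos
        if unambiguous:
            (g,) = genes
            if pos < gene_first_unambig.get(g, total + 1):
                gene_first_unambig[g] = pos

    all_first = np.sort(np.fromiter(gene_first_all.values(), dtype=np.int64))
    unambig_first = np.sort(np.fromiter(gene_first_unambig.values(), dtype=np.int64))
    depths = np.linspace(0, total, n_steps + 1, dtype=np.int64)[1:]
    rows = [
        (
            int(d),
            int(np.searchsorted(all_first, d, side="left")),
            int(np.searchsorted(unambig_first, d, side="left")),
        )
        for d in depths
    ]
    return pd.DataFrame(
        rows, columns=["tags_sampled", "genes_detected_all", "genes_detected_unambiguous"]
    )


def relative_expression_ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_cal: float,
    ct_ref_cal: float,
) -> float:
    """Relative qRT-PCR expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) in the sample minus the same
    difference in the calibrator; the result is 2 ** -ddCt.
    """
    for v in (ct_target_sample, ct_ref_sample, ct_target_cal, ct_ref_cal):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_cal - ct_ref_cal)
    return 2.0 ** (-ddct)
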