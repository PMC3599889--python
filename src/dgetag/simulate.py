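"""Synthetic unigene references and tag libraries with known ground truth.

The generator emulates a six-library NlaIII DGE experiment — two
genotypes (fertile wild type ``F``, male-sterile mutant ``S``) at three
anther stages (meiosis, tetrad, uninucleate microspore) — at a
configurable scale:

* unigenes are random ACGT sequences with a controlled fraction
  containing at least one CATG site;
* per-gene baseline abundances are log-normal, sampled per library with
  negative-binomial (gamma-Poisson) noise;
* a configurable fraction of CATG-containing genes carries planted
  genotype effects of fixed |log2 fold change| per stage (and stage
  effects within a genotype, so stage-pattern analyses have signal);
* each emitted tag is drawn uniformly from its gene's sense reference
  tags (antisense with a configurable probability), then passed through
  an independent per-base substitution error process;
* spurious copy-1 tags are appended to mimic the raw-tag singleton
  cloud removed by filtering.

Identical configuration (including seed) reproduces byte-identical
FASTA and tag files.
"""

from __future__ import annotations

import logging
import zlib
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import io as tagio
from .reference import SENSE, ReferenceTagLibrary, UnigeneRecord, extract_reference_tags

logger = logging.getLogger(__name__)

STAGES = ("meiosis", "tetrad", "uninucleate")
LIBRARY_GRID: tuple[tuple[str, str, str], ...] = (
    ("F-1", "WT", "meiosis"),
    ("F-2", "WT", "tetrad"),
    ("F-3", "WT", "uninucleate"),
    ("S-1", "mutant", "meiosis"),
    ("S-2", "mutant", "tetrad"),
    ("S-3", "mutant", "uninucleate"),
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of the emulated six-library experiment.

    Defaults follow the emulated study design: six libraries (2
    genotypes x 3 stages) of 5.8 million clean-scale tags against a
    116,520-gene unigene reference of which 87.52% contain a CATG site.
    Tests and examples pass explicitly scaled-down copies via
    ``dataclasses.replace``.
    """

    n_genes: int = 116_520
    gene_length_mean: float = 700.0
    gene_length_sd: float = 150.0
    catg_target_fraction: float = 0.8752
    n_libraries: int = 6
    library_size: int = 5_800_000
    nb_mean_log_mu: float = 1.0
    nb_mean_log_sd: float = 1.3
    nb_dispersion: float = 0.2
    de_fraction: float = 0.1
    log2fc_magnitude: float = 2.0
    error_rate: float = 0.005
    antisense_fraction: float = 0.05
    singleton_noise: int = 250_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("catg_target_fraction", "de_fraction", "error_rate", "antisense_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.singleton_noise < 0:
            raise ValueError("singleton_noise must be non-negative")

    def scaled(self, **overrides) -> "SimulationConfig":
        return replace(self, **overrides)


@dataclass
class SimulationTruth:
    """Planted ground truth: baselines, stage effects, genotype effects."""

    gene_ids: list[str]
    baseline_mean: np.ndarray
    stage_names: tuple[str, ...]
    log2fc: pd.DataFrame  # genes x stages, mutant-vs-WT planted effect
    de_flag: pd.DataFrame  # genes x stages, bool
    stage_effect: pd.DataFrame  # genes x stages, shared by both genotypes

    def __post_init__(self) -> None:
        if not ((self.log2fc != 0) == self.de_flag).all().all():
            raise ValueError("de_flag inconsistent with log2fc")


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Independent deterministic stream for one simulation stage."""
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _strip_catg(seq: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample bases until the sequence contains no CATG occurrence."""
    s = seq.tobytes()
    for _ in range(100):
        i = s.find(b"CATG")
        if i < 0:
            return np.frombuffer(s, dtype=np.uint8).copy()
        arr = bytearray(s)
        # replace the A so this site dies; random draw may create a new
        # site nearby, hence the loop
        arr[i + 1] = int(_BASES[rng.integers(0, 4)])
        s = bytes(arr)
    raise RuntimeError("could not remove CATG sites (pathological sequence)")


def generate_unigenes(config: SimulationConfig) -> list[UnigeneRecord]:
    """Random unigene set with a controlled CATG-containing fraction.

    Each gene is marked a priori as CATG-containing (probability
    ``catg_target_fraction``) or CATG-free, and its sequence is edited to
    guarantee the mark, so the realized fraction is binomial around the
    target (well within +/-0.05 for n_genes >= 2,000).
    """
    tag_len = 21
    if config.catg_target_fraction > 0 and config.gene_length_mean < tag_len:
        raise ValueError(
            "gene_length_mean too short to host a CATG+17 tag; "
            "catg_target_fraction is unreachable"
        )
    rng = _rng(config.seed, 0)
    lengths = np.maximum(
        np.rint(rng.normal(config.gene_length_mean, config.gene_length_sd, config.n_genes)),
        tag_len,
    ).astype(int)
    want_catg = rng.random(config.n_genes) < config.catg_target_fraction
    records = []
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        seq = _random_bases(rng, lengths[i])
        if want_catg[i]:
            if b"CATG" not in seq.tobytes():
                # plant one site with a full 17-nt tail available
                pos = int(rng.integers(0, lengths[i] - tag_len + 1))
                seq[pos : pos + 4] = np.frombuffer(b"CATG", dtype=np.uint8)
        else:
            seq = _strip_catg(seq, rng)
        records.append(
            UnigeneRecord(gene_id=f"G{i:0{width}d}", sequence=seq.tobytes().decode())
        )
    return records


def simulate_truth(
    config: SimulationConfig,
    gene_ids: Sequence[str] | None = None,
    eligible_gene_ids: Sequence[str] | None = None,
) -> SimulationTruth:
    """Draw baselines and planted effects.

    ``eligible_gene_ids`` restricts planted effects to the genes that can
    actually emit tags (those containing a CATG site); by default every
    gene is eligible.  Genotype effects (mutant vs WT) are planted per
    stage in a ``de_fraction`` of eligible genes with magnitude
    ``log2fc_magnitude`` and random sign; stage effects within a genotype
    are drawn the same way (first stage is the reference).
    """
    rng = _rng(config.seed, 1)
    n = config.n_genes
    if gene_ids is None:
        width = len(str(n))
        gene_ids = [f"G{i:0{width}d}" for i in range(n)]
    gene_ids = list(gene_ids)
    if len(gene_ids) != n:
        raise ValueError("gene_ids length must equal n_genes")
    baseline = rng.lognormal(config.nb_mean_log_mu, config.nb_mean_log_sd, n)
    eligible = np.ones(n, dtype=bool)
    if eligible_gene_ids is not None:
        elig_set = set(eligible_gene_ids)
        eligible = np.array([g in elig_set for g in gene_ids])

    def planted(stage_rng: np.random.Generator) -> np.ndarray:
        hit = (stage_rng.random(n) < config.de_fraction) & eligible
        sign = np.where(stage_rng.random(n) < 0.5, -1.0, 1.0)
        return np.where(hit, sign * config.log2fc_magnitude, 0.0)

    log2fc = np.column_stack([planted(rng) for _ in STAGES])
    stage_effect = np.column_stack(
        [np.zeros(n)] + [planted(rng) for _ in STAGES[1:]]
    )
    fc = pd.DataFrame(log2fc, index=gene_ids, columns=list(STAGES))
    return SimulationTruth(
        gene_ids=gene_ids,
        baseline_mean=baseline,
        stage_names=STAGES,
        log2fc=fc,
        de_flag=fc != 0,
        stage_effect=pd.DataFrame(stage_effect, index=gene_ids, columns=list(STAGES)),
    )


def _tags_to_matrix(tags: Sequence[str]) -> np.ndarray:
    flat = np.frombuffer("".join(tags).encode(), dtype=np.uint8)
    return flat.reshape(len(tags), -1)


def _apply_errors(
    counts: Counter, error_rate: float, rng: np.random.Generator
) -> Counter:
    """Independent per-base substitution on a tag multiset.

    The number of mutated copies of each tag is Binomial(count, q) with
    q = 1 - (1-e)^L; mutated copies receive >= 1 substitution at
    positions drawn from the conditional error pattern.
    """
    if error_rate == 0 or not counts:
        return Counter(counts)
    tags = sorted(counts)
    n_copies = np.fromiter((counts[t] for t in tags), dtype=np.int64, count=len(tags))
    tag_len = len(tags[0])
    q = 1.0 - (1.0 - error_rate) ** tag_len
    n_mut = rng.binomial(n_copies, q)
    out = Counter()
    for t, c, m in zip(tags, n_copies, n_mut):
        if c - m > 0:
            out[t] = int(c - m)
    total_mut = int(n_mut.sum())
    if total_mut == 0:
        return out
    src = np.repeat(np.arange(len(tags)), n_mut)
    mat = _tags_to_matrix(tags)[src].copy()
    # error masks conditioned on at least one substitution
    mask = rng.random((total_mut, tag_len)) < error_rate
    bad = ~mask.any(axis=1)
    while bad.any():
        mask[bad] = rng.random((int(bad.sum()), tag_len)) < error_rate
        bad = ~mask.any(axis=1)
    idx = _BASE_INDEX[mat]
    shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
    mutated_idx = (idx + shift) % 4
    mat = np.where(mask, _BASES[mutated_idx], mat)
    for row in mat:
        out[row.tobytes().decode()] += 1
    return out


def generate_tag_library(
    truth: SimulationTruth,
    reference: ReferenceTagLibrary,
    library_id: str,
    config: SimulationConfig,
    genotype: str | None = None,
    stage: str | None = None,
) -> Counter:
    """Emit one library's raw tag multiset (a Counter).

    Gene counts are gamma-Poisson (negative binomial at dispersion
    ``nb_dispersion``) around abundances set by the planted truth for
    this genotype x stage; tags are drawn uniformly from each gene's
    sense reference tags, switched to an antisense reference tag with
    probability ``antisense_fraction``, mutated at ``error_rate`` per
    base, and topped up with ``singleton_noise`` spurious copy-1 tags.
    """
    if len(reference) == 0:
        raise ValueError("empty reference-tag library")
    grid = {lid: (g, s) for lid, g, s in LIBRARY_GRID}
    if genotype is None or stage is None:
        if library_id not in grid:
            raise ValueError(
                f"library {library_id!r} is not in the default grid; pass genotype and stage"
            )
        genotype, stage = grid[library_id]
    if stage not in truth.stage_names:
        raise ValueError(f"unknown stage {stage!r}")
    rng = _rng(config.seed, 2, zlib.crc32(library_id.encode()))

    # per-gene sense/antisense reference-tag lists, one pass over the library
    sense_tags: dict[str, list[str]] = {}
    anti_tags: dict[str, list[str]] = {}
    for seq, hit_list in reference.hits.items():
        for g, off, strand in hit_list:
            (sense_tags if strand == SENSE else anti_tags).setdefault(g, []).append(seq)
    for d in (sense_tags, anti_tags):
        for g in d:
            d[g].sort()

    weights = truth.baseline_mean * np.exp2(truth.stage_effect[stage].to_numpy())
    if genotype != "WT":
        weights = weights * np.exp2(truth.log2fc[stage].to_numpy())
    has_tags = np.array([g in sense_tags for g in truth.gene_ids])
    n_skipped = int((~has_tags & (weights > 0)).sum())
    if n_skipped:
        logger.info(
            "library %s: %d genes have no sense reference tags and emit nothing",
            library_id,
            n_skipped,
        )
    weights = np.where(has_tags, weights, 0.0)
    if weights.sum() == 0:
        raise ValueError("no gene with reference tags has positive abundance")
    mean = config.library_size * weights / weights.sum()

    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mean / shape)
    else:
        lam = mean
    gene_counts = rng.poisson(lam)
    # the gamma-Poisson sum can undershoot the target depth; top up with a
    # multinomial draw on the expected abundances so raw >= library_size
    shortfall = config.library_size - int(gene_counts.sum())
    if shortfall > 0:
        gene_counts = gene_counts + rng.multinomial(shortfall, mean / mean.sum())

    emitted: Counter = Counter()
    for gi, g in enumerate(truth.gene_ids):
        c = int(gene_counts[gi])
        if c == 0:
            continue
        n_anti = (
            rng.binomial(c, config.antisense_fraction)
            if config.antisense_fraction > 0 and g in anti_tags
            else 0
        )
        for pool, k in ((anti_tags.get(g, ()), n_anti), (sense_tags[g], c - n_anti)):
            if k <= 0 or not pool:
                continue
            split = rng.multinomial(k, np.full(len(pool), 1.0 / len(pool)))
            for t, n in zip(pool, split):
                if n:
                    emitted[t] += int(n)

    emitted = _apply_errors(emitted, config.error_rate, rng)

    if config.singleton_noise:
        noise = _random_bases(rng, config.singleton_noise * 17).reshape(-1, 17)
        for row in noise:
            emitted["CATG" + row.tobytes().decode()] += 1
    return emitted


@dataclass
class SimulatedDataset:
    """All artefacts of one simulation: unigenes, reference, truth, raw tags."""

    config: SimulationConfig
    unigenes: list[UnigeneRecord]
    reference: ReferenceTagLibrary
    truth: SimulationTruth
    raw_libraries: dict[str, Counter]
    library_grid: tuple[tuple[str, str, str], ...]


def simulate_dataset(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    tag_format: str = "tsv",
) -> SimulatedDataset:
    """Run the full generator: unigenes -> reference tags -> truth -> libraries.

    With ``outdir`` set, writes ``unigenes.fasta``, ``truth.tsv`` and one
    tag file per library (``text``/``fastq``/``tsv`` format).
    """
    unigenes = generate_unigenes(config)
    reference = extract_reference_tags(unigenes)
    catg_ids = [u.gene_id for u in unigenes if "CATG" in u.sequence]
    truth = simulate_truth(
        config, gene_ids=[u.gene_id for u in unigenes], eligible_gene_ids=catg_ids
    )
    grid = LIBRARY_GRID[: config.n_libraries]
    raw = {
        lid: generate_tag_library(truth, reference, lid, config, genotype=g, stage=s)
        for lid, g, s in grid
    }
    ds = SimulatedDataset(
        config=config,
        unigenes=unigenes,
        reference=reference,
        truth=truth,
        raw_libraries=raw,
        library_grid=grid,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(unigenes, outdir / "unigenes.fasta")
        tagio.write_truth_tsv(truth, outdir / "truth.tsv")
        writer = {
            "text": (tagio.write_tags_text, ".txt"),
            "fastq": (tagio.write_tags_fastq, ".fastq"),
            "tsv": (tagio.write_tags_tsv, ".tsv"),
        }[tag_format]
        for lid, counts in raw.items():
            writer[0](counts, outdir / f"{lid}{writer[1]}")
    return ds


def write_fasta(unigenes: Sequence[UnigeneRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in unigenes:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
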