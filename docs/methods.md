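# Methods

This note documents the models, conventions and numerical choices
behind `dgetag`, in the order the pipeline runs them.

## Virtual reference tags

NlaIII DGE tags are 21-mers: the `CATG` recognition site plus the 17
sequenced bases downstream. The reference library takes **every**
occurrence of `CATG` in a unigene with at least 17 following bases as a
reference tag (overlapping occurrences each count; windows containing
`N` are skipped). The same scan on the reverse complement of each
unigene yields antisense reference tags, so tags from antisense
transcription can be recognised; reversing-and-complementing the whole
input provably swaps the two tag sets, which the test suite checks.

Conventions that the literature leaves open, made explicit here:

* **Tag identity** includes the `CATG` prefix (21-mers). 17-mer input
  (the sequenced tail alone) is canonicalised by prepending `CATG`.
* **Counting.** "Total reference tags" counts distinct tag sequences by
  default; a gene-tag-pair convention is available
  (`counting="pair"`), since published totals cannot disambiguate the
  two without the underlying data.
* **Ambiguity** is defined over sense hits: a tag is unambiguous iff
  its sense hits fall in exactly one gene. During mapping, per-strand
  ambiguity is used for the strand actually assigned.
* **Antisense offsets** are recorded in reverse-complement coordinates
  so the invariant `offset + 21 ≤ gene length` holds on both strands.

## Raw → clean filtering

The raw→clean step in published DGE reports is rarely specified. The
default here applies three rules, each independently configurable:
drop tags containing non-ACGT bases, drop tags identical to an adapter
entry, and drop tags whose library-wide copy number is below 2. The
copy-number rule dominates in practice and reproduces the
characteristic large drop from raw distinct to clean distinct tags;
raising `min_copies` provably never increases clean totals
(property-tested).

## Mapping

Exact match first, sense hits before antisense. A tag matching both
strands is credited to the sense gene counts and reported in a separate
"both" strand class for transparency. Ambiguous tags (several genes on
the assigned strand) increment the all-mapped tally of every hit gene
but never the unambiguous tallies, which is why "all tag-mapped genes"
exceeds "unambiguous tag-mapped genes" in the per-library report.
With `max_mismatch=1`, an unmatched tag is rescued only when exactly
one reference tag sequence lies at Hamming distance 1 (ties stay
unknown); this mode never decreases the mapped total. The conservation
identity `mapped_all + unknown = clean` holds exactly, for totals and
distinct counts, on every input.

## Quantification

TPM = count / clean_total × 10⁶. The denominator is deliberately the
**clean-tag** total, not the mapped total, so per-gene TPMs sum to
10⁶ × (mapped fraction). Detection defaults to TPM ≥ 1 on unambiguous
counts; because published per-stage detected-gene counts are far below
published all-tag-mapped gene counts, some such threshold is always in
play in this assay, and it is surfaced as an explicit parameter rather
than reconciled silently. Copy-number distributions use the
conventional bins 1, 2–5, 6–10, 11–20, 21–50, 51–100, >100
(configurable). Saturation curves subsample the clean-tag multiset
without replacement at evenly spaced depths (deterministic in the
seed) and report genes detected by ≥ 1 mapped tag, separately for
all-mapped and unambiguous assignment; the curve is non-decreasing by
construction and plateaus once the depth passes the coupon-collector
regime of the library.

The qRT-PCR helper implements 2^−ΔΔCt with
ΔΔCt = (Ct_target − Ct_ref)_sample − (Ct_target − Ct_ref)_calibrator.

## Differential expression

The Audic–Claverie conditional law of the second count given the first,

p(y|x) = (N₂/N₁)^y (x+y)! / (x! y! (1+N₂/N₁)^{x+y+1}) = NB(x+1, N₁/(N₁+N₂)),

is evaluated in log space (log-gamma terms). Tail probabilities use the
regularized incomplete-beta closed form of the negative-binomial CDF
for large counts; entries with x + y ≤ 2048 are recomputed by explicit
pmf summation, because the incomplete-beta routine loses *relative*
accuracy on extremely small tails while the p-values there are exactly
the ones a user inspects. Against exact rational arithmetic the
implementation agrees to ~3×10⁻¹⁴ relative over the full x, y ≤ 30
grid at library-size ratios 0.5, 1, 2.

The two-sided p-value is min(1, 2·min(P(Y≤y|x), P(Y≥y|x))). Note that
with inclusive discrete tails this doubling is *not* exactly symmetric
under exchanging (x, N₁) with (y, N₂); the asymmetry is bounded by
twice the boundary pmf terms and vanishes as counts grow. At λ = 50
the test's empirical type-I error at α = 0.05 is ≈ 0.045 — slightly
conservative, as expected for a discrete exact test.

Calling: the tested set is the union of genes detected in either
library; log₂FC is computed on TPM with zeros replaced by a floor
(default 0.001 TPM) so it stays finite while the test itself uses raw
counts; defaults FDR ≤ 0.001 (Benjamini–Hochberg, via statsmodels) and
|log₂FC| ≥ 1 follow the standard convention for this assay and are
configurable. Summary percentages (DE as % of tested, down as % of DE)
are rounded to the nearest integer, matching the reporting convention
of per-stage DGE comparisons.

**Known limitation.** The AC test models Poisson sampling of a fixed
relative abundance. Under biological overdispersion (the generator's
default negative-binomial dispersion of 0.2) it is anti-conservative:
abundant genes fluctuate more than Poisson between libraries and extra
calls appear. The DE-recovery validation therefore runs under Poisson
sampling (dispersion 0), where it measures the statistic against its
own model: sensitivity ≥ 0.9 and empirical FDP ≤ 0.05 on planted
|log₂FC| = 2 effects with baseline mean ≥ 50 counts at million-tag
depth. Dispersion-aware models (negative-binomial GLMs) are out of
scope by design; the AC statistic *is* the method implemented.

## Stage dynamics

Per genotype, each gene's detection triple across the ordered stages
(meiosis, tetrad, uninucleate microspore) maps to exactly one
category: 111 → constitutive, one-stage patterns → stage-specific
(named), two-stage patterns → two-stage, 000 → absent (excluded from
the expressed total). The same detection threshold feeds the category
and transition analyses. For each consecutive transition
prior → current (third stage "remaining"), the five disjoint classes
are gained_specific (010-type), gained_shared (011), retained_partial
(110), lost_from_prior_only (100) and lost_shared (101); constitutive
genes contribute to none. The below-axis split of the classical
transition plot corresponds to lost_from_prior_only vs lost_shared.

## Synthetic-data generator

The generator emulates a six-library anther DGE experiment — wild-type
(F) and male-sterile mutant (S) at three stages — with defaults at the
emulated study's design: 6 libraries, 116,520 unigenes, 87.52% of
genes containing a CATG site, 5.8 M tags per library. Tests, examples
and the acceptance script run explicitly scaled-down copies (hundreds
to thousands of genes, 10⁴–10⁶ tags), which preserve every structural
property being tested; the problem sizes used are stated where they
are used.

Model components and parameter defaults:

* **Unigenes**: random ACGT sequences, lengths ~ Normal(700, 150 nt)
  clipped at 21 nt (typical EST-assembly unigene scale). Each gene is
  marked CATG-containing with probability `catg_target_fraction` and
  its sequence edited to guarantee the mark (a site with a full 17-nt
  tail is planted, or all sites are removed), so the realised fraction
  is binomial around the target.
* **Abundance**: per-gene baseline means are log-normal
  (`nb_mean_log_mu=1.0`, `nb_mean_log_sd=1.3`), giving the
  heavy-tailed rank-abundance profile typical of transcriptomes (most
  distinct tags at 2–5 copies, a few percent above 100). Per-library
  counts are gamma-Poisson with dispersion 0.2, a mid-range bulk-RNA
  value; a multinomial top-up enforces the configured depth as a lower
  bound on raw totals.
* **Planted effects**: per stage, a `de_fraction` (default 0.1) of
  CATG-containing genes receives a genotype effect of
  ±`log2fc_magnitude` (default 2, random sign); stage effects within a
  genotype are drawn the same way against the first stage so
  stage-pattern analyses have signal. Non-DE genes have log₂FC exactly
  0.
* **Tag emission**: uniform over the gene's sense reference tags (the
  3′-bias of single-site protocols is deliberately not defaulted,
  since the all-sites reference convention is used); with probability
  `antisense_fraction` (default 0.05) the tag is drawn from the gene's
  antisense reference tags instead.
* **Errors**: independent per-base substitutions at `error_rate`
  (default 0.005; no indels — tags are fixed-length). The number of
  mutated copies of a tag is exactly Binomial(count, 1−(1−e)²¹), with
  ≥ 1 substitution per mutated copy.
* **Singleton noise**: `singleton_noise` random copy-1 `CATG`-anchored
  tags emulate the raw singleton cloud that copy-number filtering
  removes (default 250,000 at full scale).

Error characteristics, antisense rates and noise levels of the
original instrument runs are not public; these defaults are realistic
placeholders, not calibrations. What passing tests show is that the
pipeline's accounting, statistics and classifications are correct
under a controlled model with known truth; they do not certify
performance on real libraries, whose error and bias structure
(quality-dependent errors, PCR duplication, 3′ bias) the generator
deliberately omits.

Determinism: every stage draws from an independent
`numpy.random.SeedSequence` child of the configured seed (libraries
keyed by a CRC of their identifier), so identical configurations yield
byte-identical FASTA and tag files across processes.

## Numerical and degenerate-input conventions

Percentages in reports are part/whole × 100 rounded to 2 decimals
(integers for DE summary percentages); zero denominators raise rather
than return 0. Empty FASTA, non-ACGTN characters, duplicate gene ids,
mixed tag lengths, empty references, negative counts and out-of-range
p-values all raise explicit errors. Filtering that removes every tag
logs a warning and returns an empty library. Ties in one-mismatch
rescue go to "unknown" rather than arbitrary assignment.
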