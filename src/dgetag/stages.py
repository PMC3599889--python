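"""Stage-presence pattern analysis across three developmental stages.

For one genotype, each gene's detection flags across the three ordered
anther stages (meiosis, tetrad, uninucleate microspore) form a presence
triple.  Triples classify into: constitutive (present in all three),
stage-specific (exactly one stage), two-stage (exactly two), or absent —
the Venn-diagram categories of a stage series — and into transition
classes for each consecutive stage pair describing what is gained and
lost between stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CONSTITUTIVE = "constitutive"
TWO_STAGE = "two-stage"
ABSENT = "absent"

GAINED_SPECIFIC = "gained_specific"
GAINED_SHARED = "gained_shared"
RETAINED_PARTIAL = "retained_partial"
LOST_FROM_PRIOR_ONLY = "lost_from_prior_only"
LOST_SHARED = "lost_shared"

TRANSITION_CLASSES = (
    GAINED_SPECIFIC,
    GAINED_SHARED,
    RETAINED_PARTIAL,
    LOST_FROM_PRIOR_ONLY,
    LOST_SHARED,
)

# (present in prior, present in current, present in remaining) -> class
_TRANSITION_TABLE = {
    (False, True, False): GAINED_SPECIFIC,
    (False, True, True): GAINED_SHARED,
    (True, True, False): RETAINED_PARTIAL,
    (True, False, False): LOST_FROM_PRIOR_ONLY,
    (True, False, True): LOST_SHARED,
}


def categorize(presence: tuple[bool, bool, bool], stage_names: tuple[str, str, str]) -> str:
    n = sum(presence)
    if n == 3:
        return CONSTITUTIVE
    if n == 2:
        return TWO_STAGE
    if n == 1:
        return f"stage-specific:{stage_names[presence.index(True)]}"
    return ABSENT


@dataclass
class StagePatternReport:
    """Per-gene stage patterns of one genotype plus category counts."""

    genotype: str
    stages: tuple[str, str, str]
    patterns: pd.DataFrame  # columns: the 3 stages (bool) + "category"
    category_counts: dict[str, int]
    total_expressed: int  # genes present in >= 1 stage

    @property
    def stage_specific_total(self) -> int:
        return sum(
            v for k, v in self.category_counts.items() if k.startswith("stage-specific")
        )


def categorize_stages(
    detection: pd.DataFrame, genotype: str = "", stages: tuple[str, ...] | None = None
) -> StagePatternReport:
    """Classify each gene's presence triple across exactly three stages.

    ``detection`` is a gene x stage boolean frame (one genotype).  The
    triple maps to constitutive (111), two-stage (110/101/011),
    stage-specific:<stage> (100/010/001), or absent (000); absent genes
    are excluded from the expressed total.
    """
    cols = list(detection.columns) if stages is None else list(stages)
    if len(cols) != 3:
        raise ValueError(f"exactly 3 stages required, got {len(cols)}")
    det = detection[cols].astype(bool)
    names = tuple(cols)

    categories = [
        categorize((row[0], row[1], row[2]), names)
        for row in det.itertuples(index=False)
    ]
    patterns = det.copy()
    patterns["category"] = categories
    counts: dict[str, int] = {CONSTITUTIVE: 0, TWO_STAGE: 0, ABSENT: 0}
    for s in names:
        counts[f"stage-specific:{s}"] = 0
    for c in categories:
        counts[c] += 1
    total_expressed = len(det) - counts[ABSENT]
    return StagePatternReport(
        genotype=genotype,
        stages=names,
        patterns=patterns,
        category_counts=counts,
        total_expressed=total_expressed,
    )


def transition_analysis(report: StagePatternReport) -> pd.DataFrame:
    """Per-consecutive-stage-pair gain/loss classes.

    For the transition prior -> current (the third stage being
    "remaining"), each non-constitutive gene present in prior or current
    falls in exactly one of: gained_specific (present only in current),
    gained_shared (absent prior, present current and remaining),
    retained_partial (present prior and current, absent remaining),
    lost_from_prior_only (present only in prior), lost_shared (present
    prior and remaining, absent current).
    """
    s1, s2, s3 = report.stages
    det = report.patterns[[s1, s2, s3]]
    rows = []
    for prior, current, remaining in ((s1, s2, s3), (s2, s3, s1)):
        counts = {cls: 0 for cls in TRANSITION_CLASSES}
        triples = zip(det[prior], det[current], det[remaining])
        for t in triples:
            cls = _TRANSITION_TABLE.get(t)
            if cls is not None:
                counts[cls] += 1
        rows.append({"transition": f"{prior}->{current}", **counts})
    return pd.DataFrame(rows).set_index("transition")


def compare_genotypes(
    wt: StagePatternReport, mutant: StagePatternReport
) -> pd.DataFrame:
    """Side-by-side category and per-stage detection counts with ratios.

    Requires the two reports to share the same gene universe and stage
    labels; ratios are WT / mutant (NaN when the mutant count is 0).
    """
    if list(wt.patterns.index) != list(mutant.patterns.index):
        raise ValueError("gene universes differ between genotypes")
    if wt.stages != mutant.stages:
        raise ValueError("stage labels differ between genotypes")
    rows = []
    for s in wt.stages:
        rows.append(
            (f"detected:{s}", int(wt.patterns[s].sum()), int(mutant.patterns[s].sum()))
        )
    keys = sorted(set(wt.category_counts) | set(mutant.category_counts))
    for k in keys:
        rows.append((k, wt.category_counts.get(k, 0), mutant.category_counts.get(k, 0)))
    rows.append(("total_expressed", wt.total_expressed, mutant.total_expressed))
    frame = pd.DataFrame(rows, columns=["quantity", "wt", "mutant"]).set_index("quantity")
    frame["ratio_wt_over_mutant"] = frame["wt"] / frame["mutant"].where(frame["mutant"] != 0)
    return frame
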