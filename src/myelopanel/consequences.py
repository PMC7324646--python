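"""Consequence profiling: region/impact tabulation, silence partition,
nonsynonymous/synonymous ratio and PhyloP conservation binning.

The silence partition deliberately mirrors tumor-panel reporting practice
for this pipeline: missense, nonsense, splice-site and frameshift changes
are *non-silent*; synonymous, UTR, intronic, up/downstream changes and
in-frame (non-frameshift) indels are *silent*.  In-frame indels do alter
the protein; a switch moves them to non-silent if desired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

from .errors import ValidationError
from .records import (
    CODING_REGIONS,
    FUNCTIONAL_IMPACTS,
    GENOMIC_REGIONS,
    AnnotationRecord,
    ClassifiedVariant,
)

#: Functional impacts that always count as non-silent.
NON_SILENT_IMPACTS = frozenset({
    "nonsynonymous_snv",
    "stopgain",
    "stoploss",
    "splicing",
    "frameshift_insertion",
    "frameshift_deletion",
})

CONSERVATION_BINS = ("high", "moderate", "non_conserved", "missing")


def classify_silence(
    functional_impact: str,
    genomic_region: str,
    *,
    nonframeshift_silent: bool = True,
) -> str:
    """Partition a variant into ``non_silent`` or ``silent``.

    Non-silent: missense, stop-gain/loss, frameshift indels, and anything in
    a splicing region.  ``nonframeshift_silent=False`` moves in-frame indels
    to the non-silent side.
    """
    if genomic_region not in GENOMIC_REGIONS:
        raise ValidationError(f"unknown genomic_region {genomic_region!r}")
    if functional_impact not in FUNCTIONAL_IMPACTS:
        raise ValidationError(f"unknown functional_impact {functional_impact!r}")
    if genomic_region == "splicing" or functional_impact in NON_SILENT_IMPACTS:
        return "non_silent"
    if not nonframeshift_silent and functional_impact in (
        "nonframeshift_insertion", "nonframeshift_deletion"
    ):
        return "non_silent"
    return "silent"


def bin_conservation(phylop: Optional[float]) -> str:
    """Bin a PhyloP score: >4 high, [1, 4] moderate, <1 non-conserved."""
    if phylop is None:
        return "missing"
    if phylop > 4:
        return "high"
    if phylop >= 1:
        return "moderate"
    return "non_conserved"


@dataclass
class RegionImpactCounts:
    """Counts of variants per genomic region and, for coding (exonic or
    splice-region) variants, per functional impact."""

    region_counts: Dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in GENOMIC_REGIONS}
    )
    impact_counts: Dict[str, int] = field(
        default_factory=lambda: {
            i: 0 for i in FUNCTIONAL_IMPACTS if i != "not_applicable"
        }
    )
    total: int = 0

    @property
    def coding_total(self) -> int:
        return sum(self.impact_counts.values())

    def to_dict(self) -> dict:
        return {
            "region_counts": dict(self.region_counts),
            "impact_counts": dict(self.impact_counts),
            "total": self.total,
        }


def summarize_regions(
    annotations: Iterable[AnnotationRecord],
) -> RegionImpactCounts:
    """Tabulate annotations by genomic region and functional impact.

    Every variant increments exactly one region counter; coding variants
    additionally increment exactly one impact counter, so the impact counts
    sum to the exonic + splicing subtotal.
    """
    counts = RegionImpactCounts()
    for ann in annotations:
        if ann.genomic_region not in counts.region_counts:
            raise ValidationError(
                f"unknown genomic_region token {ann.genomic_region!r}"
            )
        counts.region_counts[ann.genomic_region] += 1
        counts.total += 1
        if ann.genomic_region in CODING_REGIONS:
            counts.impact_counts[ann.functional_impact] += 1
    return counts


def nonsyn_syn_ratio(counts: RegionImpactCounts) -> Optional[float]:
    """Nonsynonymous over synonymous SNV count; ``None`` when undefined."""
    syn = counts.impact_counts["synonymous_snv"]
    if syn == 0:
        return None
    return counts.impact_counts["nonsynonymous_snv"] / syn


@dataclass(frozen=True)
class RatioComparison:
    """Cohort nonsyn/syn ratio next to a reference cohort's ratio."""

    cohort_nonsyn: int
    cohort_syn: int
    reference_nonsyn: Optional[int] = None
    reference_syn: Optional[int] = None

    @property
    def cohort_ratio(self) -> Optional[float]:
        return self.cohort_nonsyn / self.cohort_syn if self.cohort_syn else None

    @property
    def reference_ratio(self) -> Optional[float]:
        if not self.reference_syn or self.reference_nonsyn is None:
            return None
        return self.reference_nonsyn / self.reference_syn

    def to_dict(self) -> dict:
        rnd = lambda r: None if r is None else round(r, 2)
        return {
            "cohort_nonsyn": self.cohort_nonsyn,
            "cohort_syn": self.cohort_syn,
            "cohort_ratio": rnd(self.cohort_ratio),
            "reference_nonsyn": self.reference_nonsyn,
            "reference_syn": self.reference_syn,
            "reference_ratio": rnd(self.reference_ratio),
        }


def compare_reference(
    counts: RegionImpactCounts, reference: Optional[Tuple[int, int]]
) -> RatioComparison:
    ref_nonsyn, ref_syn = reference if reference is not None else (None, None)
    return RatioComparison(
        cohort_nonsyn=counts.impact_counts["nonsynonymous_snv"],
        cohort_syn=counts.impact_counts["synonymous_snv"],
        reference_nonsyn=ref_nonsyn,
        reference_syn=ref_syn,
    )


def annotate_consequences(
    classified: Sequence[ClassifiedVariant],
    *,
    nonframeshift_silent: bool = True,
) -> None:
    """Fill ``silence`` and ``conservation_bin`` on classified variants in
    place."""
    for cv in classified:
        cv.silence = classify_silence(
            cv.ann.functional_impact,
            cv.ann.genomic_region,
            nonframeshift_silent=nonframeshift_silent,
        )
        cv.conservation_bin = bin_conservation(cv.ann.phylop)
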