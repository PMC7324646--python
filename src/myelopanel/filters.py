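"""Staged variant filtering: quality control, then population-AF rarity.

Removal conditions follow the tumor-only panel convention exactly: a record
is removed by QC when QUAL < 50 or DP < 20 or GQ < 20 (strict ``<``, so
equality at a threshold is retained), and routed to the *common* set when
its population allele frequency is >= 1% in either gnomAD or 1000 Genomes
(``>=``, so exactly 1% is common).  Missing allele frequencies count as
rare.  The common set is not discarded: it bypasses somatic/germline
interpretation but stays visible to the pharmacogenomic lookup, which must
see common polymorphisms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

from .errors import ValidationError
from .records import AnnotationRecord, VariantCall

Pair = Tuple[VariantCall, AnnotationRecord]


@dataclass(frozen=True)
class FilterThresholds:
    """QC and rarity thresholds; defaults are the panel-study values."""

    min_qual: float = 50.0
    min_depth: int = 20
    min_gq: float = 20.0
    max_pop_af: float = 0.01

    def __post_init__(self):
        if self.min_qual < 0 or self.min_depth < 0 or self.min_gq < 0:
            raise ValidationError("filter thresholds must be non-negative")
        if not (0.0 <= self.max_pop_af <= 1.0):
            raise ValidationError(
                f"max_pop_af must lie in [0, 1], got {self.max_pop_af}"
            )


def passes_qc(call: VariantCall, thresholds: FilterThresholds) -> bool:
    return (
        call.qual >= thresholds.min_qual
        and call.depth >= thresholds.min_depth
        and call.genotype_quality >= thresholds.min_gq
    )


def is_common(ann: AnnotationRecord, thresholds: FilterThresholds) -> bool:
    """True when either population AF reaches the cutoff ("either source
    suffices"); missing frequencies never make a variant common."""
    for af in (ann.af_gnomad, ann.af_1000g):
        if af is not None and af >= thresholds.max_pop_af:
            return True
    return False


def apply_qc_filter(
    variants: Sequence[Pair], thresholds: FilterThresholds
) -> Tuple[List[Pair], List[Pair]]:
    """Partition ``variants`` into (retained, removed) by site/genotype QC."""
    retained, removed = [], []
    for pair in variants:
        (retained if passes_qc(pair[0], thresholds) else removed).append(pair)
    return retained, removed


def apply_popaf_filter(
    variants: Sequence[Pair], thresholds: FilterThresholds
) -> Tuple[List[Pair], List[Pair]]:
    """Partition QC-passing ``variants`` into (rare, common) by population AF."""
    rare, common = [], []
    for pair in variants:
        (common if is_common(pair[1], thresholds) else rare).append(pair)
    return rare, common
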