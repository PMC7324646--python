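"""Multi-evidence prioritization of germline variants.

A germline variant is prioritized when it passes the global minor allele
frequency (GMAF) gate and carries at least one of these evidence classes:
ClinVar pathogenic/likely-pathogenic, protein-truncating (stop-gain or
stop-loss), splice-disrupting, frameshift indel, or missense predicted
deleterious by SIFT *and* damaging by PolyPhen2.  A high CADD score is
reported as supporting evidence but never gates the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .errors import ValidationError
from .records import ClassifiedVariant

DEFAULT_GMAF_CUTOFF = 0.01
DEFAULT_CADD_CUTOFF = 20.0


@dataclass
class PrioritizationResult:
    variant: ClassifiedVariant
    gmaf_pass: bool
    clinvar_pathogenic: bool
    protein_truncating: bool
    splice_disrupting: bool
    frameshift: bool
    missense_deleterious: bool
    cadd_high: bool
    verdict: str  # prioritized | not_prioritized
    notes: List[str] = field(default_factory=list)

    @property
    def prioritized(self) -> bool:
        return self.verdict == "prioritized"


def prioritize_germline(
    cv: ClassifiedVariant,
    gmaf_cutoff: float = DEFAULT_GMAF_CUTOFF,
    cadd_cutoff: float = DEFAULT_CADD_CUTOFF,
    *,
    possibly_damaging_counts: bool = True,
) -> PrioritizationResult:
    """Evaluate the evidence cascade on one germline-classified variant.

    ``possibly_damaging_counts`` controls whether PolyPhen2
    ``possibly_damaging`` counts as damaging (default) or only
    ``probably_damaging`` does.  Missing SIFT or PolyPhen2 on a missense
    variant yields ``missense_deleterious=False`` with a missing-evidence
    note, never an error.
    """
    if cv.origin != "germline":
        raise ValidationError(
            f"prioritize_germline expects a germline variant, got {cv.origin!r}"
        )
    ann = cv.ann
    gmaf_pass = all(
        af is None or af < gmaf_cutoff for af in (ann.af_gnomad, ann.af_1000g)
    )
    clinvar_pathogenic = ann.clinvar_class in ("pathogenic", "likely_pathogenic")
    protein_truncating = ann.functional_impact in ("stopgain", "stoploss")
    splice_disrupting = (
        ann.functional_impact == "splicing" or ann.genomic_region == "splicing"
    )
    frameshift = ann.functional_impact in (
        "frameshift_insertion", "frameshift_deletion"
    )
    damaging = {"probably_damaging"}
    if possibly_damaging_counts:
        damaging.add("possibly_damaging")
    notes: List[str] = []
    missense_deleterious = False
    if ann.functional_impact == "nonsynonymous_snv":
        if ann.sift_class is None or ann.polyphen2_class is None:
            notes.append("missing-evidence: SIFT or PolyPhen2 unavailable")
        else:
            missense_deleterious = (
                ann.sift_class == "deleterious"
                and ann.polyphen2_class in damaging
            )
    cadd_high = ann.cadd_phred is not None and ann.cadd_phred >= cadd_cutoff
    any_evidence = (
        clinvar_pathogenic
        or protein_truncating
        or splice_disrupting
        or frameshift
        or missense_deleterious
    )
    verdict = "prioritized" if (gmaf_pass and any_evidence) else "not_prioritized"
    return PrioritizationResult(
        variant=cv,
        gmaf_pass=gmaf_pass,
        clinvar_pathogenic=clinvar_pathogenic,
        protein_truncating=protein_truncating,
        splice_disrupting=splice_disrupting,
        frameshift=frameshift,
        missense_deleterious=missense_deleterious,
        cadd_high=cadd_high,
        verdict=verdict,
        notes=notes,
    )


def prioritize_cohort(
    classified: Sequence[ClassifiedVariant],
    gmaf_cutoff: float = DEFAULT_GMAF_CUTOFF,
    cadd_cutoff: float = DEFAULT_CADD_CUTOFF,
    **kwargs,
) -> List[PrioritizationResult]:
    return [
        prioritize_germline(cv, gmaf_cutoff, cadd_cutoff, **kwargs)
        for cv in classified
        if cv.origin == "germline"
    ]


def detect_recurrent_germline(
    prioritized: Sequence[PrioritizationResult], min_cases: int = 2
) -> Tuple[List[dict], List[dict]]:
    """Find recurrent prioritized germline mutations and multi-hit genes.

    Returns ``(recurrent, independent_events)``: *recurrent* groups the same
    (gene, protein change) seen in at least ``min_cases`` distinct cases;
    *independent_events* lists genes hit by at least ``min_cases`` distinct
    prioritized variants (e.g. three different mutations of one gene in
    three unrelated cases).
    """
    hits = [r.variant for r in prioritized if r.prioritized]
    by_change: Dict[Tuple[str, str], set] = {}
    by_gene: Dict[str, set] = {}
    for cv in hits:
        key = (cv.ann.gene, cv.ann.hgvs_p or f"{cv.call.chrom}:{cv.call.pos}"
               f":{cv.call.ref}>{cv.call.alt}")
        by_change.setdefault(key, set()).add(cv.case_id)
        by_gene.setdefault(cv.ann.gene, set()).add(key[1])
    recurrent = [
        {"gene": gene, "hgvs_p": change, "cases": sorted(cases)}
        for (gene, change), cases in sorted(by_change.items())
        if len(cases) >= min_cases
    ]
    independent = [
        {"gene": gene, "variants": sorted(changes)}
        for gene, changes in sorted(by_gene.items())
        if len(changes) >= min_cases
    ]
    return recurrent, independent
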