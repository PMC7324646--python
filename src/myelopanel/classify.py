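"""Tumor-only somatic/germline classification and clonal ordering.

Without a matched normal, somatic status is inferred from the variant
allele fraction alone: in a blood specimen whose tumor content is the
circulating-blast fraction *b*, a heterozygous somatic variant carried by
all blasts has expected VAF ``b/2``, while germline heterozygotes sit near
0.5 regardless of *b*.  A variant is therefore called somatic when
``vaf < b/2`` (strict), germline otherwise.  Clonal structure within a case
is read ordinally off the VAFs of its co-existing non-silent somatic
mutations: the highest-VAF mutation anchors the founding clone, and a
mutation joins it when its VAF is within ``delta_threshold`` of the
maximum, otherwise it is assigned to a subclone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import ClassificationError
from .panel import X_LINKED_GENES
from .records import AnnotationRecord, CaseMeta, ClassifiedVariant, VariantCall

logger = logging.getLogger(__name__)

#: Minimum number of alt reads the somatic threshold must be able to explain;
#: below this resolution the blast-based rule is untestable.
MIN_RESOLVABLE_ALT_READS = 3

DEFAULT_DELTA_THRESHOLD = 0.1


def somatic_vaf_threshold(case: CaseMeta) -> float:
    """Per-case somatic VAF cutoff: half the circulating-blast fraction."""
    return 0.5 * case.blast_fraction


def classify_origin(
    call: VariantCall, ann: AnnotationRecord, case: CaseMeta
) -> ClassifiedVariant:
    """Label one rare, QC-passing variant as somatic or germline.

    Somatic iff ``vaf < 0.5 * blast_fraction`` (strict inequality; the
    boundary is germline).  Caveats flag hemizygous X-linked sites in males
    (where a somatic VAF is doubled and may be misrouted) and cases whose
    threshold falls below read-count resolution.
    """
    if case.case_id != call.case_id:
        raise ClassificationError(
            f"variant case {call.case_id!r} does not match case meta "
            f"{case.case_id!r}"
        )
    if case.blast_percent is None:
        raise ClassificationError(
            f"case {case.case_id}: blast percentage unavailable"
        )
    threshold = somatic_vaf_threshold(case)
    vaf = call.vaf  # raises at zero depth
    origin = "somatic" if vaf < threshold else "germline"
    caveats = []
    if case.sex == "male" and ann.gene in X_LINKED_GENES:
        caveats.append("hemizygous_x_male")
    if threshold < MIN_RESOLVABLE_ALT_READS / call.depth:
        caveats.append("untestable_low_blast")
    return ClassifiedVariant(
        call=call,
        ann=ann,
        origin=origin,
        somatic_threshold=threshold,
        caveats=caveats,
    )


def classify_cohort(
    pairs: Sequence[Tuple[VariantCall, AnnotationRecord]],
    cases: Sequence[CaseMeta],
) -> List[ClassifiedVariant]:
    """Classify all rare QC-passing variants against their case metadata.

    Variants of cases absent from the manifest are reported unclassified
    (origin ``None``) with a caveat, not dropped.
    """
    by_id: Dict[str, CaseMeta] = {c.case_id: c for c in cases}
    out = []
    for call, ann in pairs:
        case = by_id.get(call.case_id)
        if case is None:
            logger.warning(
                "case %s not in manifest; variant %s:%s left unclassified",
                call.case_id, call.chrom, call.pos,
            )
            out.append(ClassifiedVariant(
                call=call, ann=ann, origin=None,
                caveats=["unclassified_no_case_meta"],
            ))
            continue
        out.append(classify_origin(call, ann, case))
    return out


@dataclass
class ClonalAssignment:
    """Founding-clone/subclone labels for one case's co-existing non-silent
    somatic mutations, ordered by descending VAF."""

    case_id: str
    variants: List[ClassifiedVariant] = field(default_factory=list)
    labels: List[str] = field(default_factory=list)  # founding | subclone
    delta_vafs: List[float] = field(default_factory=list)  # between ranks

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "mutations": [
                {
                    "gene": cv.ann.gene,
                    "hgvs_p": cv.ann.hgvs_p,
                    "vaf": round(cv.vaf, 4),
                    "clone": label,
                }
                for cv, label in zip(self.variants, self.labels)
            ],
        }


def assign_clones(
    variants: Sequence[ClassifiedVariant],
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
) -> Optional[ClonalAssignment]:
    """Order one case's non-silent somatic mutations into clones by VAF.

    Mutations are sorted by descending VAF; the top mutation is founding,
    and any other joins the founding clone when the gap to the maximum VAF
    is at most ``delta_threshold``, else it is labelled subclone.  Returns
    ``None`` for fewer than two mutations (no co-existence to order).
    """
    if len(variants) < 2:
        return None
    case_ids = {cv.case_id for cv in variants}
    if len(case_ids) != 1:
        raise ClassificationError(
            f"assign_clones expects one case, got {sorted(case_ids)}"
        )
    ranked = sorted(variants, key=lambda cv: cv.vaf, reverse=True)
    max_vaf = ranked[0].vaf
    labels = [
        "founding" if (max_vaf - cv.vaf) <= delta_threshold else "subclone"
        for cv in ranked
    ]
    deltas = [
        ranked[i].vaf - ranked[i + 1].vaf for i in range(len(ranked) - 1)
    ]
    assignment = ClonalAssignment(
        case_id=case_ids.pop(), variants=ranked, labels=labels,
        delta_vafs=deltas,
    )
    for cv, label in zip(ranked, labels):
        cv.clone_label = label
    return assignment


def assign_clones_by_case(
    classified: Sequence[ClassifiedVariant],
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
) -> List[ClonalAssignment]:
    """Run :func:`assign_clones` per case over the non-silent somatic set."""
    per_case: Dict[str, List[ClassifiedVariant]] = {}
    for cv in classified:
        if cv.origin == "somatic" and cv.silence == "non_silent":
            per_case.setdefault(cv.case_id, []).append(cv)
    out = []
    for case_id in sorted(per_case):
        assignment = assign_clones(per_case[case_id], delta_threshold)
        if assignment is not None:
            out.append(assignment)
    return out
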