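"""Worked-example tables for a 26-case ultra-deep myeloid-panel cohort.

These small fixtures carry the canonical numbers the package's reports are
designed around: a cohort-level region/impact table (293 QC-passing variants
with a nonsyn/syn ratio of 1.16), the somatic silence partition (23
non-silent vs 17 silent events), the VAFs of the seven cases with
co-existing non-silent somatic mutations (for clonal ordering), and the
headline cohort rates.  They double as regression oracles for the
tabulation, silence and clonal-ordering operations.

Note the region table and the functional-impact list are mutually
inconsistent by one variant (146 exonic vs 147 coding impacts, the
splice-site pair straddling the two views); the fixtures keep both views
verbatim rather than reconciling them.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .records import AnnotationRecord, ClassifiedVariant, VariantCall

N_CASES = 26

#: Cohort variants per genomic region (the region view; sums to 293).
TABLE1_REGION_COUNTS = {
    "exonic": 146,
    "intronic": 133,
    "upstream": 0,
    "downstream": 3,
    "UTR5": 2,
    "UTR3": 9,
}

#: Cohort coding variants per functional impact (the impact view; sums to 147).
TABLE1_IMPACT_COUNTS = {
    "nonsynonymous_snv": 71,
    "synonymous_snv": 61,
    "stopgain": 3,
    "splicing": 2,
    "frameshift_insertion": 3,
    "frameshift_deletion": 2,
    "nonframeshift_insertion": 2,
    "nonframeshift_deletion": 3,
}

TOTAL_QC_VARIANTS = 293
NONSYN_SYN_RATIO = 1.16

# Headline somatic/germline rates of the worked example.
SOMATIC_TOTAL = 38
SOMATIC_SNV = 31
SOMATIC_INDEL = 7
SOMATIC_PER_CASE = 1.46
CASES_WITH_ANY_PRIORITIZED = 23
PERCENT_CASES_WITH_ANY = 88.46
GERMLINE_PRIORITIZED = 18
PGX_CARRIER_CASES = 19
PGX_CARRIER_PERCENT = 73
STAG2_CASE_COUNT = 3
BCOR_COMBINED_CASE_COUNT = 4  # three somatic cases plus one germline case
CDKN2A_CASE_COUNT = 4

SOMATIC_NON_SILENT = 23
#: The silent category enumeration sums to 15 (and 23 + 15 = 38 matches the
#: somatic total of 31 SNVs + 7 indels); the headline silent count of the
#: worked example is quoted elsewhere as 17, which is inconsistent with both
#: its own enumeration and the total.  The enumeration is kept authoritative.
SOMATIC_SILENT = 15

#: Somatic events by (functional_impact, genomic_region): the non-silent and
#: silent category lists of the worked example (23 + 15 events).
SOMATIC_NON_SILENT_CATEGORIES: List[Tuple[str, str, int]] = [
    ("nonsynonymous_snv", "exonic", 18),
    ("stopgain", "exonic", 2),
    ("splicing", "splicing", 1),
    ("frameshift_deletion", "exonic", 2),
]
SOMATIC_SILENT_CATEGORIES: List[Tuple[str, str, int]] = [
    ("synonymous_snv", "exonic", 2),
    ("not_applicable", "downstream", 2),
    ("not_applicable", "UTR3", 1),
    ("not_applicable", "intronic", 7),
    ("nonframeshift_insertion", "exonic", 2),
    ("nonframeshift_deletion", "exonic", 1),
]

#: Co-existing non-silent somatic mutations of the seven co-mutated cases:
#: case -> [(gene, protein/cDNA change, impact, VAF)], plus the expected
#: founding/subclone label per mutation.
CO_MUTATED_CASES: Dict[str, List[Tuple[str, str, str, float]]] = {
    "AM01": [
        ("RUNX1", "p.R80H", "nonsynonymous_snv", 0.25),
        ("CBL", "c.1096-2", "splicing", 0.203),
    ],
    "AM03": [
        ("KIT", "p.D419fs", "frameshift_deletion", 0.418),
        ("KIT", "p.R420fs", "frameshift_deletion", 0.42),
        ("BCOR", "p.V1649I", "nonsynonymous_snv", 0.135),
    ],
    "AM16": [
        ("DNMT3A", "p.R730C", "nonsynonymous_snv", 0.112),
        ("STAG2", "p.L526F", "nonsynonymous_snv", 0.102),
    ],
    "AM19": [
        ("CUX1", "p.L509V", "nonsynonymous_snv", 0.366),
        ("STAG2", "p.L526F", "nonsynonymous_snv", 0.126),
    ],
    "AM23": [
        ("CDKN2A", "p.R90C", "nonsynonymous_snv", 0.214),
        ("RUNX1", "p.N434K", "nonsynonymous_snv", 0.159),
    ],
    "AM25": [
        ("CSF3R", "p.T618I", "nonsynonymous_snv", 0.108),
        ("BCORL1", "p.A400V", "nonsynonymous_snv", 0.097),
    ],
    "AM26": [
        ("SRSF2", "p.Q88X", "stopgain", 0.214),
        ("BCORL1", "p.A400V", "nonsynonymous_snv", 0.08),
    ],
}

#: Expected clone labels, aligned with CO_MUTATED_CASES entries.
EXPECTED_CLONE_LABELS: Dict[str, List[str]] = {
    "AM01": ["founding", "founding"],
    "AM03": ["founding", "founding", "subclone"],
    "AM16": ["founding", "founding"],
    "AM19": ["founding", "subclone"],
    "AM23": ["founding", "founding"],
    "AM25": ["founding", "founding"],
    "AM26": ["founding", "subclone"],
}

#: Synthetic stand-in for a healthy-reference nonsyn/syn count table whose
#: ratio is 0.88 (the real table would be recounted from population data).
REFERENCE_COUNTS_SYNTHETIC = (88, 100)


def _coding_region(impact: str) -> str:
    return "splicing" if impact == "splicing" else "exonic"


def region_fixture() -> List[AnnotationRecord]:
    """Annotations realizing the region view of the cohort table.

    Exonic records cycle through the coding impact categories; non-coding
    records carry ``not_applicable``.
    """
    coding_cycle = [
        impact
        for impact, n in TABLE1_IMPACT_COUNTS.items()
        if impact != "splicing"
        for _ in range(n)
    ]
    out = []
    for region, n in TABLE1_REGION_COUNTS.items():
        for i in range(n):
            if region == "exonic":
                out.append(AnnotationRecord(
                    gene="TET2", genomic_region="exonic",
                    functional_impact=coding_cycle[i % len(coding_cycle)],
                ))
            else:
                out.append(AnnotationRecord(
                    gene="TET2", genomic_region=region,
                    functional_impact="not_applicable",
                ))
    return out


def impact_fixture() -> List[AnnotationRecord]:
    """Annotations realizing the functional-impact view (147 coding)."""
    return [
        AnnotationRecord(
            gene="TET2",
            genomic_region=_coding_region(impact),
            functional_impact=impact,
        )
        for impact, n in TABLE1_IMPACT_COUNTS.items()
        for _ in range(n)
    ]


def somatic_category_fixture() -> List[Tuple[str, str]]:
    """(impact, region) pairs of the 40 worked-example somatic events."""
    pairs = []
    for impact, region, n in (
        SOMATIC_NON_SILENT_CATEGORIES + SOMATIC_SILENT_CATEGORIES
    ):
        pairs.extend([(impact, region)] * n)
    return pairs


def co_mutated_fixture(depth: int = 5000) -> Dict[str, List[ClassifiedVariant]]:
    """The seven co-mutated cases as somatic-classified variants.

    Read support is exact at the given depth (all worked-example VAFs are
    integer multiples of 1/5000), so the ordinal VAF structure is preserved.
    """
    out: Dict[str, List[ClassifiedVariant]] = {}
    for case_id, muts in CO_MUTATED_CASES.items():
        cvs = []
        for i, (gene, change, impact, vaf) in enumerate(muts):
            alt_depth = round(vaf * depth)
            assert abs(alt_depth / depth - vaf) < 1e-12
            call = VariantCall(
                case_id=case_id, chrom="chr1", pos=1000 + i, ref="A", alt="G",
                qual=3000.0, depth=depth, alt_depth=alt_depth,
                genotype_quality=99.0, genotype="het",
            )
            region = _coding_region(impact)
            ann = AnnotationRecord(
                gene=gene, genomic_region=region, functional_impact=impact,
                hgvs_p=change if change.startswith("p.") else None,
            )
            cvs.append(ClassifiedVariant(
                call=call, ann=ann, origin="somatic", silence="non_silent",
            ))
        out[case_id] = cvs
    return out
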