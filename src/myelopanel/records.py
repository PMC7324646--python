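"""Core record types of the pipeline.

A cohort is a list of :class:`CaseMeta`; each case contributes called
variants, carried as ``(VariantCall, AnnotationRecord)`` pairs.  The variant
allele fraction (VAF) is always re-derived from read support
(``alt_depth / depth``); any allele-frequency value produced by the caller is
ignored, so there is a single source of truth for VAF throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

from .errors import ValidationError

SEXES = frozenset({"male", "female", "unknown"})

GENOMIC_REGIONS = (
    "exonic",
    "splicing",
    "intronic",
    "upstream",
    "downstream",
    "UTR5",
    "UTR3",
)

FUNCTIONAL_IMPACTS = (
    "nonsynonymous_snv",
    "synonymous_snv",
    "stopgain",
    "stoploss",
    "splicing",
    "frameshift_insertion",
    "frameshift_deletion",
    "nonframeshift_insertion",
    "nonframeshift_deletion",
    "not_applicable",
)

GENOTYPES = frozenset({"het", "hom_alt", "hemi", "other"})
SIFT_CLASSES = frozenset({"deleterious", "tolerated"})
POLYPHEN2_CLASSES = frozenset({"probably_damaging", "possibly_damaging", "benign"})
CLINVAR_CLASSES = frozenset({"pathogenic", "likely_pathogenic", "vus", "benign_like"})

#: Regions where a coding functional-impact annotation is meaningful.
CODING_REGIONS = frozenset({"exonic", "splicing"})


def _check_choice(value, allowed, name, *, optional=False):
    if value is None:
        if optional:
            return
        raise ValidationError(f"{name} is required")
    if value not in allowed:
        raise ValidationError(
            f"invalid {name} {value!r}; allowed: {sorted(allowed)}"
        )


@dataclass(frozen=True)
class CaseMeta:
    """One cohort member.

    ``blast_percent`` is the percentage of circulating blast cells in
    peripheral blood (0-100); it proxies the tumor fraction of the specimen
    and drives the somatic/germline VAF threshold.
    """

    case_id: str
    sex: str
    blast_percent: float
    karyotype_note: Optional[str] = None

    def __post_init__(self):
        if not self.case_id:
            raise ValidationError("case_id must be non-empty")
        _check_choice(self.sex, SEXES, "sex")
        bp = self.blast_percent
        if bp is None or not (0.0 <= float(bp) <= 100.0):
            raise ValidationError(
                f"blast_percent must lie in [0, 100], got {bp!r} for {self.case_id}"
            )

    @property
    def blast_fraction(self) -> float:
        """Blast percentage rescaled to [0, 1]."""
        return self.blast_percent / 100.0


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one case, with quality and read support.

    Coordinates are 1-based and fully closed (VCF convention).
    """

    case_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    depth: int
    alt_depth: int
    genotype_quality: float
    genotype: str
    variant_id: Optional[str] = None

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt alleles must be non-empty")
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.depth < 0 or self.alt_depth < 0:
            raise ValidationError("depth and alt_depth must be non-negative")
        if self.alt_depth > self.depth:
            raise ValidationError(
                f"alt_depth {self.alt_depth} exceeds depth {self.depth} "
                f"at {self.chrom}:{self.pos}"
            )
        _check_choice(self.genotype, GENOTYPES, "genotype")

    @property
    def vaf(self) -> float:
        """Variant allele fraction, ``alt_depth / depth``.

        Undefined (raises) at zero depth; readers skip such records.
        """
        if self.depth == 0:
            raise ValidationError(
                f"VAF undefined at zero depth ({self.chrom}:{self.pos})"
            )
        return self.alt_depth / self.depth

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-variant functional annotation and external-database evidence.

    All fields are consumed as inputs (ANNOVAR-style categories, population
    allele frequencies, in-silico predictions, database identifiers); the
    pipeline never computes them.  ``None`` means missing (TSV token ``.``).
    """

    gene: str
    genomic_region: str
    functional_impact: str
    hgvs_p: Optional[str] = None
    af_gnomad: Optional[float] = None
    af_1000g: Optional[float] = None
    sift_class: Optional[str] = None
    polyphen2_class: Optional[str] = None
    cadd_phred: Optional[float] = None
    phylop: Optional[float] = None
    clinvar_class: Optional[str] = None
    cosmic_id: Optional[str] = None
    rsid: Optional[str] = None
    transcripts_affected: int = 1
    transcripts_total: int = 1

    def __post_init__(self):
        _check_choice(self.genomic_region, set(GENOMIC_REGIONS), "genomic_region")
        _check_choice(
            self.functional_impact, set(FUNCTIONAL_IMPACTS), "functional_impact"
        )
        coding = self.genomic_region in CODING_REGIONS
        if (self.functional_impact == "not_applicable") == coding:
            raise ValidationError(
                "functional_impact must be 'not_applicable' exactly when the "
                f"region is non-coding; got {self.functional_impact!r} in "
                f"{self.genomic_region!r}"
            )
        _check_choice(self.sift_class, SIFT_CLASSES, "sift_class", optional=True)
        _check_choice(
            self.polyphen2_class, POLYPHEN2_CLASSES, "polyphen2_class", optional=True
        )
        _check_choice(
            self.clinvar_class, CLINVAR_CLASSES, "clinvar_class", optional=True
        )
        for name in ("af_gnomad", "af_1000g"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.transcripts_affected > self.transcripts_total:
            raise ValidationError(
                "transcripts_affected exceeds transcripts_total"
            )


@dataclass(frozen=True)
class PgxRule:
    """A pharmacogenomic lookup rule: rsID, risk genotypes, drug annotation.

    ``risk_genotypes`` are unordered allele pairs written ``"G/C"`` (a single
    allele for hemizygous genotypes).  ``ref``/``alt`` let the lookup assign
    a homozygous-reference genotype to cases without a call at the site.
    """

    rsid: str
    gene: str
    ref: str
    alt: str
    risk_genotypes: frozenset
    annotation: str

    def __post_init__(self):
        if not self.risk_genotypes:
            raise ValidationError(f"rule {self.rsid}: risk_genotypes must be non-empty")

    @staticmethod
    def normalize_genotype(alleles) -> str:
        """Canonical unordered genotype string, e.g. ('C','G') -> 'C/G'."""
        return "/".join(sorted(alleles))


@dataclass
class ClassifiedVariant:
    """A variant after staged filtering, with origin and profile labels.

    ``origin`` is ``somatic`` iff ``vaf < somatic_threshold`` where the
    threshold is half the case's circulating-blast fraction; ``silence`` and
    ``conservation_bin`` are filled by the consequence-profiling stage and
    ``clone_label`` by clonal ordering.
    """

    call: VariantCall
    ann: AnnotationRecord
    origin: Optional[str] = None  # somatic | germline | None (unclassified)
    somatic_threshold: Optional[float] = None
    silence: Optional[str] = None  # silent | non_silent
    conservation_bin: Optional[str] = None  # high | moderate | non_conserved | missing
    clone_label: Optional[str] = None  # founding | subclone
    caveats: list = field(default_factory=list)

    @property
    def vaf(self) -> float:
        return self.call.vaf

    @property
    def case_id(self) -> str:
        return self.call.case_id


# Column order used by the classified-variant TSV (cohort_io round-trip).
CALL_FIELDS = [f.name for f in fields(VariantCall) if f.name != "variant_id"]
ANNOTATION_FIELDS = [f.name for f in fields(AnnotationRecord)]
CLASSIFIED_EXTRA_FIELDS = [
    "vaf",
    "origin",
    "somatic_threshold",
    "silence",
    "conservation_bin",
    "clone_label",
    "caveats",
]
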