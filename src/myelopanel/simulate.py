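"""Synthetic cohorts of ultra-deep targeted myeloid-panel variant calls.

The generator emulates a tumor-only amplicon-panel experiment on blood from
acute-leukemia cases: per-case circulating-blast percentages, germline
heterozygous/homozygous variants (expected VAF 0.5 / 1.0), somatic variants
whose expected VAF is ``0.5 x blast_fraction x CCF`` (cancer-cell fraction;
1 for the founding clone, below 1 for a subclone), hemizygous X-linked sites
in males, binomial read-support noise at ~5000x depth, and ANNOVAR-style
annotation fields spanning both branches of every downstream filter.  A
truth table aligned one-to-one with the emitted variants makes recovery of
the classifier's labels measurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as mio
from .errors import ValidationError
from .panel import GENE_NAMES, PANEL_GENES, X_LINKED_GENES
from .records import AnnotationRecord, CaseMeta, VariantCall

_AMINO = "ARNDCQEGHILKMFPSTWYV"
_BASES = "ACGT"

# Impact mix of an ultra-deep myeloid panel cohort: roughly half the calls
# fall outside coding sequence, and missense slightly outnumbers synonymous.
_DEFAULT_IMPACT_COUNTS = {
    "not_applicable": 147,
    "nonsynonymous_snv": 71,
    "synonymous_snv": 61,
    "stopgain": 3,
    "stoploss": 1,
    "splicing": 2,
    "frameshift_insertion": 3,
    "frameshift_deletion": 2,
    "nonframeshift_insertion": 2,
    "nonframeshift_deletion": 3,
}
_total = sum(_DEFAULT_IMPACT_COUNTS.values())
DEFAULT_IMPACT_WEIGHTS = {k: v / _total for k, v in _DEFAULT_IMPACT_COUNTS.items()}

# Non-coding region mix (intronic dominates on an exon-flanking panel).
_NONCODING_REGIONS = ("intronic", "upstream", "downstream", "UTR5", "UTR3")
_NONCODING_WEIGHTS = np.array([133.0, 1.0, 3.0, 2.0, 9.0])
_NONCODING_WEIGHTS = _NONCODING_WEIGHTS / _NONCODING_WEIGHTS.sum()


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_cases: int = 26
    seed: int = 0
    depth_mean: float = 5000.0
    depth_dispersion: float = 0.25  # lognormal sigma of depth
    blast_percent_range: Tuple[float, float] = (20.0, 90.0)
    germline_per_case_mean: float = 80.0
    somatic_per_case_mean: float = 1.5
    subclone_probability: float = 0.3
    subclone_ccf_range: Tuple[float, float] = (0.1, 0.6)
    #: Tumor-DNA fraction of the specimen as a fraction of the blast-count
    #: estimate: the morphological blast percentage overestimates the tumor
    #: content of extracted DNA (normal leukocytes dilute it), which is also
    #: why the somatic VAF cutoff at half the blast fraction is deliberately
    #: stringent rather than exactly calibrated.
    specimen_purity: float = 0.85
    impact_category_weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IMPACT_WEIGHTS)
    )
    fraction_male: float = 15 / 26
    common_af_fraction: float = 0.6  # germline calls with population AF >= 1%
    low_qual_rate: float = 0.02
    low_gq_rate: float = 0.02
    low_depth_rate: float = 0.01
    include_pgx_site: bool = True
    pgx_alt_freq: float = 0.52  # alt (C) allele frequency at rs1042522

    def __post_init__(self):
        if self.n_cases < 0:
            raise ValidationError("n_cases must be non-negative")
        for name in ("blast_percent_range", "subclone_ccf_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} must be ordered, got ({lo}, {hi})")
        lo, hi = self.blast_percent_range
        if not (0 <= lo <= hi <= 100):
            raise ValidationError("blast_percent_range must lie within [0, 100]")
        lo, hi = self.subclone_ccf_range
        if not (0 < lo <= hi < 1):
            raise ValidationError("subclone_ccf_range must lie within (0, 1)")
        if not (0 < self.specimen_purity <= 1):
            raise ValidationError("specimen_purity must lie in (0, 1]")
        if not (0 <= self.subclone_probability <= 1):
            raise ValidationError("subclone_probability must lie in [0, 1]")
        if not (0 <= self.fraction_male <= 1):
            raise ValidationError("fraction_male must lie in [0, 1]")
        total = sum(self.impact_category_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"impact_category_weights must sum to 1, got {total}"
            )


def expected_vaf(
    origin: str,
    genotype: str,
    blast_fraction: Optional[float] = None,
    ccf: Optional[float] = None,
    hemizygous: bool = False,
) -> float:
    """Expected VAF under the generative model.

    Germline: 0.5 for an autosomal heterozygote, 1.0 when homozygous or
    hemizygous.  Somatic: ``0.5 * blast_fraction * ccf`` for a heterozygous
    event, doubled when hemizygous.  Supplying a CCF for a germline variant
    is an error (germline variants are carried by every cell).
    """
    hemizygous = hemizygous or genotype == "hemi"
    if origin == "germline":
        if ccf is not None:
            raise ValidationError("ccf is meaningless for a germline variant")
        if hemizygous or genotype == "hom_alt":
            return 1.0
        if genotype == "het":
            return 0.5
        raise ValidationError(f"unsupported germline genotype {genotype!r}")
    if origin == "somatic":
        if blast_fraction is None or not (0.0 <= blast_fraction <= 1.0):
            raise ValidationError(
                f"blast_fraction must lie in [0, 1], got {blast_fraction!r}"
            )
        if ccf is None or not (0.0 < ccf <= 1.0):
            raise ValidationError(f"ccf must lie in (0, 1], got {ccf!r}")
        vaf = blast_fraction * ccf * (1.0 if hemizygous else 0.5)
        return min(vaf, 1.0)
    raise ValidationError(f"unknown origin {origin!r}")


def sample_read_support(
    expected: float, depth: int, rng: np.random.Generator
) -> Tuple[int, int]:
    """Binomial read support: ``alt_depth ~ Binomial(depth, expected)``."""
    if not (0.0 <= expected <= 1.0):
        raise ValidationError(f"expected_vaf must lie in [0, 1], got {expected}")
    if depth < 1:
        raise ValidationError(f"depth must be >= 1, got {depth}")
    return int(rng.binomial(depth, expected)), depth


@dataclass
class SimulatedCohort:
    config: SimConfig
    cases: List[CaseMeta]
    variants: List[Tuple[VariantCall, AnnotationRecord]]
    truth: pd.DataFrame

    def write(self, out_dir) -> dict:
        """Emit manifest TSV, annotated TSV, per-case VCFs and the truth TSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "manifest": out_dir / "manifest.tsv",
            "annotated_tsv": out_dir / "cohort.annotated.tsv",
            "truth": out_dir / "truth.tsv",
            "vcf_dir": out_dir / "vcf",
        }
        mio.write_manifest(self.cases, paths["manifest"])
        mio.write_variants_tsv(self.variants, paths["annotated_tsv"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        paths["vcf_dir"].mkdir(exist_ok=True)
        by_case: Dict[str, list] = {c.case_id: [] for c in self.cases}
        for pair in self.variants:
            by_case[pair[0].case_id].append(pair)
        for case in self.cases:
            mio.write_vcf(
                by_case[case.case_id],
                paths["vcf_dir"] / f"{case.case_id}.vcf",
                case.case_id,
            )
        return paths


def _draw_depth(cfg: SimConfig, rng) -> int:
    if rng.random() < cfg.low_depth_rate:
        return int(rng.integers(1, 20))
    sigma = cfg.depth_dispersion
    # mean-preserving lognormal around depth_mean
    d = cfg.depth_mean * math.exp(rng.normal(0.0, sigma) - sigma * sigma / 2)
    return max(1, int(round(d)))


def _draw_qual(cfg: SimConfig, rng) -> float:
    if rng.random() < cfg.low_qual_rate:
        return float(rng.uniform(5.0, 49.9))
    return float(rng.lognormal(math.log(3000.0), 0.5))


def _draw_gq(cfg: SimConfig, rng) -> float:
    if rng.random() < cfg.low_gq_rate:
        return float(np.floor(rng.uniform(0.0, 20.0)))
    return float(np.floor(rng.uniform(60.0, 100.0)))


def _draw_alleles(impact: str, rng) -> Tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    if impact in ("frameshift_insertion", "nonframeshift_insertion"):
        n = 3 if impact.startswith("nonframeshift") else int(rng.integers(1, 3))
        ins = "".join(_BASES[rng.integers(4)] for _ in range(n))
        return ref, ref + ins
    if impact in ("frameshift_deletion", "nonframeshift_deletion"):
        n = 3 if impact.startswith("nonframeshift") else int(rng.integers(1, 3))
        tail = "".join(_BASES[rng.integers(4)] for _ in range(n))
        return ref + tail, ref
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _draw_hgvs_p(impact: str, rng) -> Optional[str]:
    pos = int(rng.integers(1, 900))
    a = _AMINO[rng.integers(len(_AMINO))]
    b = _AMINO[rng.integers(len(_AMINO))]
    if impact == "nonsynonymous_snv":
        while b == a:
            b = _AMINO[rng.integers(len(_AMINO))]
        return f"p.{a}{pos}{b}"
    if impact == "synonymous_snv":
        return f"p.{a}{pos}{a}"
    if impact in ("stopgain", "stoploss"):
        return f"p.{a}{pos}X" if impact == "stopgain" else f"p.X{pos}{a}"
    if impact.startswith("frameshift"):
        return f"p.{a}{pos}fs"
    if impact.startswith("nonframeshift"):
        return f"p.{a}{pos}del" if impact.endswith("deletion") else f"p.{a}{pos}ins"
    return None


def _draw_annotation_scores(impact: str, non_silent: bool, rng) -> dict:
    out = {}
    if impact == "nonsynonymous_snv":
        out["sift_class"] = (
            None if rng.random() < 0.1
            else ("deleterious" if rng.random() < 0.25 else "tolerated")
        )
        u = rng.random()
        out["polyphen2_class"] = (
            None if rng.random() < 0.1
            else "probably_damaging" if u < 0.15
            else "possibly_damaging" if u < 0.30
            else "benign"
        )
    else:
        out["sift_class"] = None
        out["polyphen2_class"] = None
    out["cadd_phred"] = (
        None if rng.random() < 0.15
        else float(rng.uniform(10, 35) if non_silent else rng.uniform(0, 15))
    )
    if rng.random() < 0.1:
        out["phylop"] = None
    else:
        u = rng.random()
        if u < 0.4:
            out["phylop"] = float(rng.normal(5.5, 1.0))
        elif u < 0.65:
            out["phylop"] = float(np.clip(rng.normal(2.5, 0.8), 1.0, 4.0))
        else:
            out["phylop"] = float(rng.normal(-0.5, 1.2))
    u = rng.random()
    out["clinvar_class"] = (
        "pathogenic" if u < 0.02
        else "likely_pathogenic" if u < 0.04
        else "vus" if u < 0.14
        else "benign_like" if u < 0.24
        else None
    )
    return out


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate one cohort; deterministic given ``config`` (incl. its seed)."""
    rng = np.random.default_rng(config.seed)
    impacts = list(config.impact_category_weights)
    impact_p = np.array([config.impact_category_weights[i] for i in impacts])
    cases: List[CaseMeta] = []
    for i in range(config.n_cases):
        sex = "male" if rng.random() < config.fraction_male else "female"
        blast = float(rng.uniform(*config.blast_percent_range))
        cases.append(CaseMeta(
            case_id=f"SIM{i + 1:02d}", sex=sex, blast_percent=round(blast, 1),
        ))
    variants: List[Tuple[VariantCall, AnnotationRecord]] = []
    truth_rows: List[dict] = []
    counter = 0

    def emit(case: CaseMeta, origin: str, genotype: str, evaf: float,
             gene: str, impact: str, region: str, clone_id: Optional[int],
             ccf: Optional[float], hemizygous: bool, ann_kwargs: dict):
        nonlocal counter
        counter += 1
        vid = f"v{counter:06d}"
        depth = _draw_depth(config, rng)
        alt_depth, depth = sample_read_support(evaf, depth, rng)
        panel_gene = PANEL_GENES[gene]
        pos = int(rng.integers(panel_gene.start, panel_gene.end + 1))
        ref, alt = _draw_alleles(impact if region != "splicing" else "snv", rng)
        call = VariantCall(
            case_id=case.case_id, chrom=panel_gene.chrom, pos=pos,
            ref=ref, alt=alt, qual=round(_draw_qual(config, rng), 2),
            depth=depth, alt_depth=alt_depth,
            genotype_quality=_draw_gq(config, rng), genotype=genotype,
            variant_id=vid,
        )
        ann = AnnotationRecord(
            gene=gene, genomic_region=region, functional_impact=impact,
            **ann_kwargs,
        )
        variants.append((call, ann))
        truth_rows.append({
            "variant_id": vid,
            "case_id": case.case_id,
            "true_origin": origin,
            "clone_id": clone_id if clone_id is not None else -1,
            "true_ccf": ccf if ccf is not None else float("nan"),
            "expected_vaf": evaf,
            "hemizygous": hemizygous,
            "genotype": genotype,
        })

    for case in cases:
        blast_fraction = case.blast_percent / 100.0
        # one candidate subclone per case, shared by its subclonal mutations
        subclone_ccf = float(rng.uniform(*config.subclone_ccf_range))

        n_germline = int(rng.poisson(config.germline_per_case_mean))
        for _ in range(n_germline):
            gene = GENE_NAMES[rng.integers(len(GENE_NAMES))]
            impact = impacts[rng.choice(len(impacts), p=impact_p)]
            if impact == "splicing":
                region = "splicing"
            elif impact == "not_applicable":
                region = _NONCODING_REGIONS[
                    rng.choice(len(_NONCODING_REGIONS), p=_NONCODING_WEIGHTS)
                ]
            else:
                region = "exonic"
            hemizygous = case.sex == "male" and gene in X_LINKED_GENES
            if hemizygous:
                genotype = "hemi"
            else:
                genotype = "hom_alt" if rng.random() < 0.15 else "het"
            evaf = expected_vaf("germline", genotype, hemizygous=hemizygous)
            non_silent = impact in (
                "nonsynonymous_snv", "stopgain", "stoploss", "splicing",
                "frameshift_insertion", "frameshift_deletion",
            )
            ann_kwargs = _draw_annotation_scores(impact, non_silent, rng)
            if rng.random() < config.common_af_fraction:
                af = float(rng.uniform(0.01, 0.5))
                ann_kwargs["af_gnomad"] = af
                ann_kwargs["af_1000g"] = (
                    None if rng.random() < 0.2
                    else float(np.clip(af * rng.uniform(0.7, 1.3), 0.0, 1.0))
                )
                ann_kwargs["rsid"] = (
                    f"rs{rng.integers(10_000, 10_000_000)}"
                    if rng.random() < 0.95 else None
                )
            else:
                ann_kwargs["af_gnomad"] = (
                    None if rng.random() < 0.3
                    else float(10 ** rng.uniform(-6.5, -2.05))
                )
                ann_kwargs["af_1000g"] = (
                    None if rng.random() < 0.7
                    else float(10 ** rng.uniform(-4.0, -2.05))
                )
                ann_kwargs["rsid"] = (
                    f"rs{rng.integers(10_000_000, 999_999_999)}"
                    if rng.random() < 0.3 else None
                )
            ann_kwargs["hgvs_p"] = _draw_hgvs_p(impact, rng)
            ann_kwargs["transcripts_total"] = int(rng.integers(1, 8))
            ann_kwargs["transcripts_affected"] = int(
                rng.integers(1, ann_kwargs["transcripts_total"] + 1)
            )
            emit(case, "germline", genotype, evaf, gene, impact, region,
                 None, None, hemizygous, ann_kwargs)

        n_somatic = int(rng.poisson(config.somatic_per_case_mean))
        for _ in range(n_somatic):
            gene = GENE_NAMES[rng.integers(len(GENE_NAMES))]
            impact = impacts[rng.choice(len(impacts), p=impact_p)]
            if impact == "splicing":
                region = "splicing"
            elif impact == "not_applicable":
                region = _NONCODING_REGIONS[
                    rng.choice(len(_NONCODING_REGIONS), p=_NONCODING_WEIGHTS)
                ]
            else:
                region = "exonic"
            hemizygous = case.sex == "male" and gene in X_LINKED_GENES
            genotype = "hemi" if hemizygous else "het"
            in_subclone = rng.random() < config.subclone_probability
            ccf = subclone_ccf if in_subclone else 1.0
            clone_id = 1 if in_subclone else 0
            tumor_fraction = blast_fraction * config.specimen_purity
            evaf = expected_vaf(
                "somatic", genotype, tumor_fraction, ccf, hemizygous
            )
            non_silent = impact in (
                "nonsynonymous_snv", "stopgain", "stoploss", "splicing",
                "frameshift_insertion", "frameshift_deletion",
            )
            ann_kwargs = _draw_annotation_scores(impact, non_silent, rng)
            ann_kwargs["af_gnomad"] = (
                None if rng.random() < 0.8
                else float(10 ** rng.uniform(-6.5, -3.0))
            )
            ann_kwargs["af_1000g"] = None
            ann_kwargs["rsid"] = None
            ann_kwargs["cosmic_id"] = (
                f"COSM{rng.integers(100_000, 9_999_999)}"
                if rng.random() < 0.3 else None
            )
            ann_kwargs["hgvs_p"] = _draw_hgvs_p(impact, rng)
            ann_kwargs["transcripts_total"] = int(rng.integers(1, 8))
            ann_kwargs["transcripts_affected"] = int(
                rng.integers(1, ann_kwargs["transcripts_total"] + 1)
            )
            emit(case, "somatic", genotype, evaf, gene, impact, region,
                 clone_id, ccf, hemizygous, ann_kwargs)

        if config.include_pgx_site:
            q = config.pgx_alt_freq
            u = rng.random()
            if u < q * q:
                genotype = "hom_alt"
            elif u < q * q + 2 * q * (1 - q):
                genotype = "het"
            else:
                genotype = None  # homozygous reference: no call emitted
            if genotype is not None:
                counter += 1
                vid = f"v{counter:06d}"
                evaf = expected_vaf("germline", genotype)
                depth = _draw_depth(config, rng)
                alt_depth, depth = sample_read_support(evaf, depth, rng)
                tp53 = PANEL_GENES["TP53"]
                call = VariantCall(
                    case_id=case.case_id, chrom=tp53.chrom,
                    pos=tp53.start + 215, ref="G", alt="C",
                    qual=round(_draw_qual(config, rng), 2),
                    depth=depth, alt_depth=alt_depth,
                    genotype_quality=_draw_gq(config, rng),
                    genotype=genotype, variant_id=vid,
                )
                ann = AnnotationRecord(
                    gene="TP53", genomic_region="exonic",
                    functional_impact="nonsynonymous_snv", hgvs_p="p.P72R",
                    af_gnomad=0.54, af_1000g=0.52, sift_class="tolerated",
                    polyphen2_class="benign", rsid="rs1042522",
                    transcripts_affected=1, transcripts_total=1,
                )
                variants.append((call, ann))
                truth_rows.append({
                    "variant_id": vid, "case_id": case.case_id,
                    "true_origin": "germline", "clone_id": -1,
                    "true_ccf": float("nan"), "expected_vaf": evaf,
                    "hemizygous": False, "genotype": genotype,
                })

    truth = pd.DataFrame(
        truth_rows,
        columns=["variant_id", "case_id", "true_origin", "clone_id",
                 "true_ccf", "expected_vaf", "hemizygous", "genotype"],
    )
    return SimulatedCohort(
        config=config, cases=cases, variants=variants, truth=truth
    )


def simulate_and_write(config: SimConfig, out_dir) -> SimulatedCohort:
    sim = simulate_cohort(config)
    sim.write(out_dir)
    return sim


def config_with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
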