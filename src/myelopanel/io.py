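"""Readers and writers for cohort manifests, variant tables and reports.

Two variant dialects are supported: single-sample VCF 4.2 (annotations in
INFO, read support in per-sample ``DP``/``AD``/``GQ``) and a flat annotated
TSV with one row per (case, variant).  The TSV missing-value token is ``.``.
VAF is always recomputed from ``AD``; caller-provided AF fields are ignored.
Multi-allelic VCF records are split into one record per alt allele.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from cyvcf2 import VCF

from .errors import ConfigurationError, ValidationError
from .records import (
    ANNOTATION_FIELDS,
    CALL_FIELDS,
    FUNCTIONAL_IMPACTS,
    AnnotationRecord,
    CaseMeta,
    ClassifiedVariant,
    PgxRule,
    VariantCall,
)

logger = logging.getLogger(__name__)

MISSING = "."

#: INFO keys used by the VCF dialect, in emission order.
_INFO_KEYS = [
    ("GENE", "gene", "String"),
    ("REGION", "genomic_region", "String"),
    ("IMPACT", "functional_impact", "String"),
    ("HGVSP", "hgvs_p", "String"),
    ("AF_GNOMAD", "af_gnomad", "Float"),
    ("AF_1KG", "af_1000g", "Float"),
    ("SIFT", "sift_class", "String"),
    ("PP2", "polyphen2_class", "String"),
    ("CADD", "cadd_phred", "Float"),
    ("PHYLOP", "phylop", "Float"),
    ("CLINVAR", "clinvar_class", "String"),
    ("COSMIC", "cosmic_id", "String"),
    ("TA", "transcripts_affected", "Integer"),
    ("TT", "transcripts_total", "Integer"),
]

VARIANT_TSV_COLUMNS = ["variant_id"] + CALL_FIELDS + ANNOTATION_FIELDS


# ---------------------------------------------------------------------------
# manifest

def read_manifest(path) -> List[CaseMeta]:
    """Read a cohort manifest (TSV or CSV) into a list of :class:`CaseMeta`.

    Required columns: ``case_id``, ``sex``, ``blast_percent``; optional
    ``karyotype_note``.  Duplicate case ids and blank or out-of-range blast
    percentages are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
    sep = "\t" if "\t" in header_line else ","
    df = pd.read_csv(
        path, sep=sep, dtype=str, keep_default_na=False, skipinitialspace=True
    )
    df.columns = [c.strip() for c in df.columns]
    for col in ("case_id", "sex", "blast_percent"):
        if col not in df.columns:
            raise ConfigurationError(f"manifest {path} is missing column {col!r}")
    cases = []
    for _, row in df.iterrows():
        raw_bp = row["blast_percent"].strip()
        if raw_bp in ("", MISSING):
            raise ValidationError(
                f"manifest row {row['case_id']!r} has blank blast_percent"
            )
        note = row.get("karyotype_note", "")
        note = note.strip() or None if isinstance(note, str) else None
        cases.append(
            CaseMeta(
                case_id=row["case_id"].strip(),
                sex=row["sex"].strip(),
                blast_percent=float(raw_bp),
                karyotype_note=note,
            )
        )
    ids = [c.case_id for c in cases]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValidationError(f"duplicate case_id in manifest: {sorted(dupes)}")
    return cases


def write_manifest(cases: Sequence[CaseMeta], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["case_id", "sex", "blast_percent", "karyotype_note"])
        for c in cases:
            w.writerow(
                [c.case_id, c.sex, repr(float(c.blast_percent)),
                 c.karyotype_note or MISSING]
            )


# ---------------------------------------------------------------------------
# variants

class ReadVariantsResult(list):
    """List of ``(VariantCall, AnnotationRecord)`` with read accounting.

    ``n_input`` counts input records (after multi-allelic splitting) and
    ``n_skipped`` the records dropped with a warning, so that
    ``len(result) + n_skipped == n_input`` always holds.
    """

    def __init__(self, items=(), n_skipped: int = 0):
        super().__init__(items)
        self.n_skipped = n_skipped

    @property
    def n_input(self) -> int:
        return len(self) + self.n_skipped


def read_variants(path, dialect: str) -> ReadVariantsResult:
    """Read variant calls plus annotations from ``path``.

    ``dialect`` is ``"vcf"`` (single-sample VCF 4.2) or ``"annotated_tsv"``.
    Records with zero depth are skipped with a logged warning.
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "annotated_tsv":
        return _read_annotated_tsv(path)
    raise ConfigurationError(
        f"unknown dialect {dialect!r}; expected 'vcf' or 'annotated_tsv'"
    )


def _opt_str(value) -> Optional[str]:
    if value is None:
        return None
    value = str(value)
    return value if value and value != MISSING else None


def _genotype_from_vcf(genotype_row, alt_index: int) -> str:
    alleles = [a for a in genotype_row[:-1]]
    if len(alleles) == 1:
        return "hemi" if alleles[0] == alt_index else "other"
    if sorted(alleles) == [0, alt_index]:
        return "het"
    if alleles == [alt_index, alt_index]:
        return "hom_alt"
    return "other"


def _read_vcf(path) -> ReadVariantsResult:
    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise ConfigurationError(
            f"{path}: expected a single-sample VCF, found {len(vcf.samples)} samples"
        )
    case_id = vcf.samples[0]
    out, skipped = [], 0
    for v in vcf:
        ad = v.format("AD")
        dp = v.format("DP")
        gq = v.format("GQ")
        if ad is None or dp is None or gq is None:
            raise ConfigurationError(
                f"{path}: FORMAT must carry DP, AD and GQ at {v.CHROM}:{v.POS}"
            )
        ad_row = [int(x) for x in ad[0]]
        depth = int(dp[0][0])
        for k, alt in enumerate(v.ALT, start=1):
            alt_depth = ad_row[k] if k < len(ad_row) else 0
            rec_depth = max(depth, alt_depth)  # tolerate DP < sum(AD)
            if rec_depth <= 0:
                skipped += 1
                logger.warning(
                    "skipping zero-depth record %s:%s %s>%s in %s",
                    v.CHROM, v.POS, v.REF, alt, case_id,
                )
                continue
            call = VariantCall(
                case_id=case_id,
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt,
                qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                depth=rec_depth,
                alt_depth=alt_depth,
                genotype_quality=float(gq[0][0]),
                genotype=_genotype_from_vcf(v.genotypes[0], k),
                variant_id=_opt_str(v.INFO.get("VID")),
            )
            impact = _opt_str(v.INFO.get("IMPACT"))
            if impact is not None and impact not in FUNCTIONAL_IMPACTS:
                raise ValidationError(
                    f"unknown functional_impact token {impact!r}; "
                    f"allowed: {list(FUNCTIONAL_IMPACTS)}"
                )
            kwargs = {}
            for key, attr, typ in _INFO_KEYS:
                raw = v.INFO.get(key)
                if raw is None:
                    kwargs[attr] = None
                elif typ == "Float":
                    kwargs[attr] = float(raw)
                elif typ == "Integer":
                    kwargs[attr] = int(raw)
                else:
                    kwargs[attr] = _opt_str(raw)
            kwargs["rsid"] = _opt_str(v.ID)
            if kwargs["transcripts_affected"] is None:
                kwargs["transcripts_affected"] = 1
            if kwargs["transcripts_total"] is None:
                kwargs["transcripts_total"] = 1
            ann = AnnotationRecord(**kwargs)
            out.append((call, ann))
    return ReadVariantsResult(out, n_skipped=skipped)


def _read_annotated_tsv(path) -> ReadVariantsResult:
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    missing_cols = [
        c for c in VARIANT_TSV_COLUMNS if c not in df.columns and c != "variant_id"
    ]
    if missing_cols:
        raise ConfigurationError(
            f"annotated TSV {path} is missing columns: {missing_cols}"
        )
    out, skipped = [], 0
    for _, row in df.iterrows():
        depth = int(row["depth"])
        if depth <= 0:
            skipped += 1
            logger.warning(
                "skipping zero-depth record %s:%s in %s",
                row["chrom"], row["pos"], row["case_id"],
            )
            continue
        impact = row["functional_impact"]
        if impact not in FUNCTIONAL_IMPACTS:
            raise ValidationError(
                f"unknown functional_impact token {impact!r}; "
                f"allowed: {list(FUNCTIONAL_IMPACTS)}"
            )
        call = VariantCall(
            case_id=row["case_id"],
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            qual=float(row["qual"]),
            depth=depth,
            alt_depth=int(row["alt_depth"]),
            genotype_quality=float(row["genotype_quality"]),
            genotype=row["genotype"],
            variant_id=_opt_str(row.get("variant_id")),
        )
        ann = AnnotationRecord(
            gene=row["gene"],
            genomic_region=row["genomic_region"],
            functional_impact=impact,
            hgvs_p=_opt_str(row["hgvs_p"]),
            af_gnomad=_opt_float(row["af_gnomad"]),
            af_1000g=_opt_float(row["af_1000g"]),
            sift_class=_opt_str(row["sift_class"]),
            polyphen2_class=_opt_str(row["polyphen2_class"]),
            cadd_phred=_opt_float(row["cadd_phred"]),
            phylop=_opt_float(row["phylop"]),
            clinvar_class=_opt_str(row["clinvar_class"]),
            cosmic_id=_opt_str(row["cosmic_id"]),
            rsid=_opt_str(row["rsid"]),
            transcripts_affected=int(row["transcripts_affected"]),
            transcripts_total=int(row["transcripts_total"]),
        )
        out.append((call, ann))
    return ReadVariantsResult(out, n_skipped=skipped)


def _opt_float(value) -> Optional[float]:
    s = _opt_str(value)
    if s is None:
        return None
    f = float(s)
    return None if math.isnan(f) else f


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_variants_tsv(pairs: Iterable[Tuple[VariantCall, AnnotationRecord]],
                       path) -> None:
    """Write (call, annotation) pairs in the annotated-TSV dialect."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(VARIANT_TSV_COLUMNS)
        for call, ann in pairs:
            row = [_fmt(call.variant_id)]
            row += [_fmt(getattr(call, f)) for f in CALL_FIELDS]
            row += [_fmt(getattr(ann, f)) for f in ANNOTATION_FIELDS]
            w.writerow(row)


def write_vcf(pairs: Sequence[Tuple[VariantCall, AnnotationRecord]],
              path, case_id: str) -> None:
    """Write one case's variants as a single-sample VCF 4.2 file.

    Annotations ride in INFO; rsIDs in the ID column; read support in
    per-sample DP/AD/GQ.  Records must be sorted by (chrom, pos) for
    downstream readers; this writer sorts them.
    """
    pairs = sorted(pairs, key=lambda p: (p[0].chrom, p[0].pos, p[0].alt))
    chroms = sorted({c.chrom for c, _ in pairs})
    gt_codes = {"het": "0/1", "hom_alt": "1/1", "hemi": "1", "other": "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=myelopanel\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=VID,Number=1,Type=String,Description="Variant id">\n')
        for key, attr, typ in _INFO_KEYS:
            fh.write(
                f'##INFO=<ID={key},Number=1,Type={typ},Description="{attr}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                 'Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{case_id}\n")
        for call, ann in pairs:
            info = []
            if call.variant_id:
                info.append(f"VID={call.variant_id}")
            for key, attr, typ in _INFO_KEYS:
                v = getattr(ann, attr)
                if v is None:
                    continue
                if typ == "Float":
                    info.append(f"{key}={float(v):.6g}")
                else:
                    info.append(f"{key}={v}")
            ref_depth = max(call.depth - call.alt_depth, 0)
            fh.write(
                "\t".join([
                    call.chrom,
                    str(call.pos),
                    ann.rsid or MISSING,
                    call.ref,
                    call.alt,
                    f"{call.qual:.6g}",
                    "PASS",
                    ";".join(info) or MISSING,
                    "GT:AD:DP:GQ",
                    f"{gt_codes[call.genotype]}:{ref_depth},{call.alt_depth}:"
                    f"{call.depth}:{call.genotype_quality:.6g}",
                ]) + "\n"
            )


# ---------------------------------------------------------------------------
# classified variants

def write_classified_tsv(classified: Sequence[ClassifiedVariant], path) -> None:
    cols = VARIANT_TSV_COLUMNS + [
        "vaf", "origin", "somatic_threshold", "silence",
        "conservation_bin", "clone_label", "caveats",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for cv in classified:
            row = [_fmt(cv.call.variant_id)]
            row += [_fmt(getattr(cv.call, f)) for f in CALL_FIELDS]
            row += [_fmt(getattr(cv.ann, f)) for f in ANNOTATION_FIELDS]
            row += [
                _fmt(cv.vaf),
                _fmt(cv.origin),
                _fmt(cv.somatic_threshold),
                _fmt(cv.silence),
                _fmt(cv.conservation_bin),
                _fmt(cv.clone_label),
                ";".join(cv.caveats) if cv.caveats else MISSING,
            ]
            w.writerow(row)


def read_classified_tsv(path) -> List[ClassifiedVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        call = VariantCall(
            case_id=row["case_id"], chrom=row["chrom"], pos=int(row["pos"]),
            ref=row["ref"], alt=row["alt"], qual=float(row["qual"]),
            depth=int(row["depth"]), alt_depth=int(row["alt_depth"]),
            genotype_quality=float(row["genotype_quality"]),
            genotype=row["genotype"], variant_id=_opt_str(row["variant_id"]),
        )
        ann = AnnotationRecord(
            gene=row["gene"], genomic_region=row["genomic_region"],
            functional_impact=row["functional_impact"],
            hgvs_p=_opt_str(row["hgvs_p"]),
            af_gnomad=_opt_float(row["af_gnomad"]),
            af_1000g=_opt_float(row["af_1000g"]),
            sift_class=_opt_str(row["sift_class"]),
            polyphen2_class=_opt_str(row["polyphen2_class"]),
            cadd_phred=_opt_float(row["cadd_phred"]),
            phylop=_opt_float(row["phylop"]),
            clinvar_class=_opt_str(row["clinvar_class"]),
            cosmic_id=_opt_str(row["cosmic_id"]),
            rsid=_opt_str(row["rsid"]),
            transcripts_affected=int(row["transcripts_affected"]),
            transcripts_total=int(row["transcripts_total"]),
        )
        caveats = row["caveats"]
        out.append(ClassifiedVariant(
            call=call, ann=ann,
            origin=_opt_str(row["origin"]),
            somatic_threshold=_opt_float(row["somatic_threshold"]),
            silence=_opt_str(row["silence"]),
            conservation_bin=_opt_str(row["conservation_bin"]),
            clone_label=_opt_str(row["clone_label"]),
            caveats=caveats.split(";") if caveats not in ("", MISSING) else [],
        ))
    return out


# ---------------------------------------------------------------------------
# configuration tables

DEFAULT_PGX_RULES = (
    PgxRule(
        rsid="rs1042522",
        gene="TP53",
        ref="G",
        alt="C",
        risk_genotypes=frozenset({"G/G", "C/G"}),
        annotation=(
            "decreased response to cisplatin, paclitaxel, capecitabine, "
            "and oxaliplatin"
        ),
    ),
)


def read_pgx_rules(path) -> List[PgxRule]:
    """Read pharmacogenomic rules from a TSV.

    Columns: rsid, gene, ref, alt, risk_genotypes (comma-separated unordered
    genotype strings, e.g. ``G/G,G/C``), annotation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("rsid", "gene", "ref", "alt", "risk_genotypes", "annotation"):
        if col not in df.columns:
            raise ConfigurationError(f"PGx rules {path} is missing column {col!r}")
    rules = []
    for _, row in df.iterrows():
        genos = frozenset(
            PgxRule.normalize_genotype(g.strip().split("/"))
            for g in row["risk_genotypes"].split(",") if g.strip()
        )
        rules.append(PgxRule(
            rsid=row["rsid"], gene=row["gene"], ref=row["ref"], alt=row["alt"],
            risk_genotypes=genos, annotation=row["annotation"],
        ))
    return rules


def read_reference_counts(path) -> Tuple[int, int]:
    """Read a reference cohort's (nonsynonymous, synonymous) counts."""
    df = pd.read_csv(path, sep="\t")
    for col in ("nonsyn", "syn"):
        if col not in df.columns:
            raise ConfigurationError(
                f"reference counts {path} is missing column {col!r}"
            )
    return int(df["nonsyn"].iloc[0]), int(df["syn"].iloc[0])


# ---------------------------------------------------------------------------
# reports

def write_report(summary, classified: Sequence[ClassifiedVariant], out_dir):
    """Write the classified TSV, the summary JSON and the text report.

    Returns the three paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / "classified_variants.tsv"
    js = out_dir / "cohort_summary.json"
    txt = out_dir / "report.txt"
    write_classified_tsv(classified, tsv)
    with open(js, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(txt, "w") as fh:
        fh.write(summary.render_text())
    return tsv, js, txt
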