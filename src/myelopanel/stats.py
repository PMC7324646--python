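"""Cohort-level statistics and the machine-readable cohort summary.

Includes somatic/germline recurrence detection, a per-case mutation-burden
test (Kruskal-Wallis omnibus over cases followed by Dunn's post hoc with
multiple-testing correction, the replicate unit being per-gene somatic
counts within each case), pharmacogenomic genotype reporting, and the
summary object that is serialized to JSON and rendered as a text report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .classify import ClonalAssignment
from .consequences import (
    RatioComparison,
    RegionImpactCounts,
    compare_reference,
    summarize_regions,
)
from .errors import ValidationError
from .germline import PrioritizationResult, detect_recurrent_germline
from .panel import GENE_NAMES
from .records import (
    CODING_REGIONS,
    AnnotationRecord,
    CaseMeta,
    ClassifiedVariant,
    PgxRule,
    VariantCall,
)

Pair = Tuple[VariantCall, AnnotationRecord]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# recurrence

def _somatic_key(cv: ClassifiedVariant) -> Tuple:
    ann, call = cv.ann, cv.call
    if ann.genomic_region in CODING_REGIONS and ann.hgvs_p:
        return (ann.gene, ann.hgvs_p)
    return (ann.gene, call.chrom, call.pos, call.ref, call.alt)


def detect_recurrent_somatic(
    classified: Sequence[ClassifiedVariant], min_cases: int = 2
) -> Tuple[List[dict], List[dict]]:
    """Somatic mutations seen in at least ``min_cases`` distinct cases.

    Returns ``(non_silent, silent)`` recurrence lists.  Coding mutations are
    grouped by (gene, protein change); non-coding by genomic identity.  The
    output is sorted by key and invariant to the input's case order.
    """
    groups: Dict[Tuple, Dict[str, float]] = {}
    silence: Dict[Tuple, str] = {}
    for cv in classified:
        if cv.origin != "somatic":
            continue
        key = _somatic_key(cv)
        groups.setdefault(key, {})[cv.case_id] = cv.vaf
        silence[key] = cv.silence or "silent"
    non_silent, silent = [], []
    for key in sorted(groups, key=str):
        cases = groups[key]
        if len(cases) < min_cases:
            continue
        entry = {
            "gene": key[0],
            "mutation": key[1] if len(key) == 2 else
            f"{key[1]}:{key[2]}:{key[3]}>{key[4]}",
            "cases": sorted(cases),
            "vafs": {c: round(v, 4) for c, v in sorted(cases.items())},
        }
        (non_silent if silence[key] == "non_silent" else silent).append(entry)
    return non_silent, silent


# ---------------------------------------------------------------------------
# burden test

def per_case_gene_counts(
    classified: Sequence[ClassifiedVariant],
    cases: Sequence[CaseMeta],
    genes: Sequence[str] = GENE_NAMES,
) -> pd.DataFrame:
    """Per-gene somatic mutation counts within each case (cases x genes)."""
    counts = pd.DataFrame(
        0, index=[c.case_id for c in cases], columns=list(genes), dtype=int
    )
    for cv in classified:
        if cv.origin == "somatic" and cv.case_id in counts.index:
            counts.loc[cv.case_id, cv.ann.gene] += 1
    return counts


def dunn_posthoc(groups: Sequence[np.ndarray], labels: Sequence[str]):
    """Dunn's post hoc z statistics and two-sided p-values for all pairs.

    Uses pooled mid-ranks with the tie correction
    ``N(N+1)/12 - sum(t^3 - t) / (12 (N - 1))`` in the standard error.
    Returns ``(z, p, mean_ranks)`` with z and p as labelled DataFrames.
    """
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for label, size in zip(labels, sizes):
        mean_ranks[label] = ranks[start:start + size].mean()
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    k = len(groups)
    z = pd.DataFrame(0.0, index=labels, columns=labels)
    p = pd.DataFrame(1.0, index=labels, columns=labels)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            zij = (mean_ranks[labels[i]] - mean_ranks[labels[j]]) / se
            pij = 2.0 * sps.norm.sf(abs(zij))
            z.iat[i, j], z.iat[j, i] = zij, -zij
            p.iat[i, j] = p.iat[j, i] = pij
    return z, p, mean_ranks


@dataclass
class BurdenResult:
    omnibus_p: float
    alpha: float
    correction: str
    flagged: List[dict] = field(default_factory=list)
    mean_ranks: Dict[str, float] = field(default_factory=dict)
    adjusted_p: Optional[pd.DataFrame] = None

    @property
    def flagged_cases(self) -> List[str]:
        return [f["case_id"] for f in self.flagged]

    def to_dict(self) -> dict:
        return {
            "omnibus_p": self.omnibus_p,
            "alpha": self.alpha,
            "correction": self.correction,
            "flagged": self.flagged,
        }


def burden_test(
    counts: pd.DataFrame,
    alpha: float = 0.01,
    correction: str = "bonferroni",
) -> BurdenResult:
    """Flag cases with significantly elevated somatic mutation burden.

    ``counts`` holds per-gene somatic counts, one row per case (the
    replicate unit).  A Kruskal-Wallis omnibus test runs across cases; if it
    rejects at ``alpha``, all pairwise Dunn tests are corrected
    (``bonferroni`` or ``fdr_bh``) and a case is flagged when it beats a
    majority of the other cases at adjusted p < ``alpha`` with the higher
    mean rank.
    """
    if counts.shape[0] < 3:
        raise ValidationError("burden_test needs at least 3 cases")
    if correction not in ("bonferroni", "fdr_bh"):
        raise ValidationError(f"unknown correction {correction!r}")
    labels = list(counts.index)
    groups = [counts.loc[c].to_numpy(dtype=float) for c in labels]
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return BurdenResult(omnibus_p=1.0, alpha=alpha, correction=correction)
    _, omnibus_p = sps.kruskal(*groups)
    result = BurdenResult(
        omnibus_p=float(omnibus_p), alpha=alpha, correction=correction
    )
    if omnibus_p >= alpha:
        return result
    _, p, mean_ranks = dunn_posthoc(groups, labels)
    result.mean_ranks = {k: float(v) for k, v in mean_ranks.items()}
    k = len(labels)
    iu = np.triu_indices(k, 1)
    raw = p.to_numpy()[iu]
    adj = multipletests(raw, method=correction)[1]
    adj_mat = np.ones((k, k))
    adj_mat[iu] = adj
    adj_mat[(iu[1], iu[0])] = adj
    adj_df = pd.DataFrame(adj_mat, index=labels, columns=labels)
    result.adjusted_p = adj_df
    majority = (k - 1) / 2.0
    for i, case in enumerate(labels):
        wins = sum(
            1
            for j, other in enumerate(labels)
            if j != i
            and adj_df.iat[i, j] < alpha
            and mean_ranks[case] > mean_ranks[other]
        )
        if wins > majority:
            result.flagged.append({
                "case_id": case,
                "n_significant_pairs": wins,
                "min_adjusted_p": float(
                    min(adj_df.iat[i, j] for j in range(k) if j != i)
                ),
            })
    return result


# ---------------------------------------------------------------------------
# pharmacogenomics

@dataclass
class PgxReport:
    rule: PgxRule
    genotypes: Dict[str, str]  # case_id -> normalized genotype string
    carrier_count: int
    n_cases: int

    @property
    def carrier_fraction(self) -> float:
        return self.carrier_count / self.n_cases if self.n_cases else 0.0

    def to_dict(self) -> dict:
        return {
            "rsid": self.rule.rsid,
            "gene": self.rule.gene,
            "risk_genotypes": sorted(self.rule.risk_genotypes),
            "annotation": self.rule.annotation,
            "genotypes": dict(sorted(self.genotypes.items())),
            "carrier_count": self.carrier_count,
            "n_cases": self.n_cases,
            "carrier_fraction": self.carrier_fraction,
            "carrier_percent": round_half_up(100.0 * self.carrier_fraction, 0),
        }


def pharmaco_lookup(
    qc_variants: Sequence[Pair],
    rules: Sequence[PgxRule],
    cases: Sequence[CaseMeta],
) -> List[PgxReport]:
    """Per-rule genotype table over the QC-passing (pre-rarity) call set.

    A case without a call at the rule's rsID is genotyped homozygous
    reference.  A rule whose rsID is absent from the whole cohort is still
    reported, with the corresponding carrier count.
    """
    reports = []
    for rule in rules:
        genotypes: Dict[str, str] = {}
        for call, ann in qc_variants:
            if ann.rsid != rule.rsid:
                continue
            if call.genotype == "het":
                g = PgxRule.normalize_genotype((call.ref, call.alt))
            elif call.genotype == "hom_alt":
                g = PgxRule.normalize_genotype((call.alt, call.alt))
            elif call.genotype == "hemi":
                g = call.alt
            else:
                g = "unknown"
            genotypes[call.case_id] = g
        for case in cases:
            genotypes.setdefault(
                case.case_id, PgxRule.normalize_genotype((rule.ref, rule.ref))
            )
        carriers = sum(
            1 for g in genotypes.values() if g in rule.risk_genotypes
        )
        reports.append(PgxReport(
            rule=rule, genotypes=genotypes, carrier_count=carriers,
            n_cases=len(cases),
        ))
    return reports


# ---------------------------------------------------------------------------
# cohort summary

@dataclass
class CohortSummary:
    """Machine-readable cohort report (serialized to JSON and text)."""

    n_cases: int
    total_qc_variants: int
    region_impact: RegionImpactCounts
    ratio: RatioComparison
    somatic_counts: Dict[str, int]
    germline_prioritized_count: int
    per_case_somatic: Dict[str, int]
    recurrent_somatic_non_silent: List[dict]
    recurrent_somatic_silent: List[dict]
    recurrent_germline: List[dict]
    germline_independent_events: List[dict]
    burden: Optional[BurdenResult]
    clonal_assignments: List[ClonalAssignment]
    pgx_reports: List[PgxReport]
    co_occurrence: Dict[str, int]
    conservation_non_silent_somatic: Dict[str, int]

    @property
    def somatic_per_case(self) -> float:
        return self.somatic_counts["total"] / self.n_cases if self.n_cases else 0.0

    @property
    def nonsilent_any_per_case(self) -> float:
        """Non-silent somatic plus prioritized germline events per case."""
        if not self.n_cases:
            return 0.0
        events = self.somatic_counts["non_silent"] + self.germline_prioritized_count
        return events / self.n_cases

    @property
    def fraction_cases_with_any_prioritized(self) -> float:
        if not self.n_cases:
            return 0.0
        with_any = (
            self.co_occurrence["both"]
            + self.co_occurrence["somatic_only"]
            + self.co_occurrence["germline_only"]
        )
        return with_any / self.n_cases

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "total_qc_variants": self.total_qc_variants,
            "region_impact": self.region_impact.to_dict(),
            "nonsyn_syn": self.ratio.to_dict(),
            "somatic": {
                **self.somatic_counts,
                "per_case": round(self.somatic_per_case, 4),
                "per_case_rendered": round_half_up(self.somatic_per_case, 2),
                "recurrent_non_silent": self.recurrent_somatic_non_silent,
                "recurrent_silent": self.recurrent_somatic_silent,
                "conservation_non_silent":
                    dict(self.conservation_non_silent_somatic),
            },
            "germline": {
                "prioritized": self.germline_prioritized_count,
                "recurrent": self.recurrent_germline,
                "independent_events": self.germline_independent_events,
            },
            "per_case_somatic": dict(sorted(self.per_case_somatic.items())),
            "burden": self.burden.to_dict() if self.burden else None,
            "clonal_assignments": [a.to_dict() for a in self.clonal_assignments],
            "pharmacogenomics": [r.to_dict() for r in self.pgx_reports],
            "co_occurrence": dict(self.co_occurrence),
            "rates": {
                "somatic_per_case": self.somatic_per_case,
                "nonsilent_any_per_case": self.nonsilent_any_per_case,
                "fraction_cases_with_any_prioritized":
                    self.fraction_cases_with_any_prioritized,
                "percent_cases_with_any_prioritized": round_half_up(
                    100.0 * self.fraction_cases_with_any_prioritized, 2
                ),
            },
        }

    def render_text(self) -> str:
        ri = self.region_impact
        lines = []
        add = lines.append
        add("Cohort variant interpretation report")
        add("=" * 38)
        add(f"Cases: {self.n_cases}")
        add(f"QC-passing variants: {self.total_qc_variants}")
        add("")
        add("Variants by genomic region and functional impact")
        add(f"{'Genomic region':<28}{'No. of variants':>16}")
        exonic_plus_splice = (
            ri.region_counts["exonic"] + ri.region_counts["splicing"]
        )
        add(f"{'Exonic':<28}{exonic_plus_splice:>16}")
        for region, label in (
            ("intronic", "Intronic"), ("upstream", "Upstream"),
            ("downstream", "Downstream"), ("UTR5", "UTR5"), ("UTR3", "UTR3"),
        ):
            add(f"{label:<28}{ri.region_counts[region]:>16}")
        add(f"{'Total':<28}{ri.total:>16}")
        add("Functional impact")
        for impact, label in (
            ("nonsynonymous_snv", "Non-synonymous"),
            ("synonymous_snv", "Synonymous"),
            ("stopgain", "Stop-gain"),
            ("stoploss", "Stop-loss"),
            ("splicing", "Splicing"),
            ("frameshift_insertion", "Frameshift insertion"),
            ("frameshift_deletion", "Frameshift deletion"),
            ("nonframeshift_insertion", "Non-frameshift insertion"),
            ("nonframeshift_deletion", "Non-frameshift deletion"),
        ):
            add(f"{label:<28}{ri.impact_counts[impact]:>16}")
        add("")
        ratio = self.ratio.cohort_ratio
        ratio_s = "undefined" if ratio is None else f"{round_half_up(ratio, 2):.2f}"
        add(f"nonsyn/syn ratio: {ratio_s} "
            f"({self.ratio.cohort_nonsyn}/{self.ratio.cohort_syn})")
        ref = self.ratio.reference_ratio
        if ref is not None:
            add(f"reference cohort nonsyn/syn ratio: "
                f"{round_half_up(ref, 2):.2f} "
                f"({self.ratio.reference_nonsyn}/{self.ratio.reference_syn})")
        add("")
        sc = self.somatic_counts
        add(f"Somatic mutations: {sc['total']} "
            f"({sc['snv']} SNVs, {sc['indel']} indels; "
            f"{round_half_up(self.somatic_per_case, 2):.2f} mutation/case)")
        add(f"  non-silent: {sc['non_silent']}   silent: {sc['silent']}")
        add(f"  recurrent non-silent: {len(self.recurrent_somatic_non_silent)}"
            f"   recurrent silent: {len(self.recurrent_somatic_silent)}")
        if self.burden is not None:
            flagged = ", ".join(self.burden.flagged_cases) or "none"
            add(f"  burden-flagged cases (alpha={self.burden.alpha}, "
                f"{self.burden.correction}): {flagged}")
        add("")
        add(f"Prioritized germline variants: {self.germline_prioritized_count}")
        for entry in self.recurrent_germline:
            add(f"  recurrent: {entry['gene']} {entry['hgvs_p']} "
                f"in {len(entry['cases'])} cases")
        for entry in self.germline_independent_events:
            add(f"  multi-hit gene: {entry['gene']} "
                f"({len(entry['variants'])} independent variants)")
        add("")
        co = self.co_occurrence
        pct = round_half_up(
            100.0 * self.fraction_cases_with_any_prioritized, 2
        )
        add(f"Cases with any non-silent somatic or prioritized germline "
            f"mutation: {co['both'] + co['somatic_only'] + co['germline_only']}"
            f" ({pct:.2f}%)")
        add(f"  both: {co['both']}  somatic only: {co['somatic_only']}  "
            f"germline only: {co['germline_only']}  neither: {co['neither']}")
        add("")
        for report in self.pgx_reports:
            d = report.to_dict()
            add(f"Pharmacogenomics {d['rsid']} ({d['gene']}): "
                f"{d['carrier_count']} of {d['n_cases']} cases "
                f"({d['carrier_percent']:.0f}%) carry a risk genotype "
                f"[{', '.join(d['risk_genotypes'])}]")
            add(f"  {d['annotation']}")
        add("")
        add("Note: splice-region variants are folded into the Exonic row of "
            "the region table; the functional-impact rows therefore sum to "
            "the exonic + splicing subtotal.")
        return "\n".join(lines) + "\n"


def summarize_cohort(
    cases: Sequence[CaseMeta],
    qc_variants: Sequence[Pair],
    classified: Sequence[ClassifiedVariant],
    prioritized: Sequence[PrioritizationResult],
    assignments: Sequence[ClonalAssignment] = (),
    burden: Optional[BurdenResult] = None,
    pgx_reports: Sequence[PgxReport] = (),
    reference_counts: Optional[Tuple[int, int]] = None,
    min_recurrent_cases: int = 2,
) -> CohortSummary:
    """Assemble the cohort summary from the staged outputs.

    Every count is re-derived here from the tables passed in, so the summary
    can always be reproduced from the classified table alone.
    """
    region_impact = summarize_regions(ann for _, ann in qc_variants)
    ratio = compare_reference(region_impact, reference_counts)
    somatic = [cv for cv in classified if cv.origin == "somatic"]
    somatic_counts = {
        "total": len(somatic),
        "snv": sum(1 for cv in somatic if cv.call.is_snv),
        "indel": sum(1 for cv in somatic if not cv.call.is_snv),
        "non_silent": sum(1 for cv in somatic if cv.silence == "non_silent"),
        "silent": sum(1 for cv in somatic if cv.silence != "non_silent"),
    }
    per_case_somatic = {c.case_id: 0 for c in cases}
    for cv in somatic:
        per_case_somatic[cv.case_id] = per_case_somatic.get(cv.case_id, 0) + 1
    rec_ns, rec_s = detect_recurrent_somatic(classified, min_recurrent_cases)
    rec_germ, indep_germ = detect_recurrent_germline(
        prioritized, min_recurrent_cases
    )
    hits = [r.variant for r in prioritized if r.prioritized]
    cases_with_ns_somatic = {
        cv.case_id for cv in somatic if cv.silence == "non_silent"
    }
    cases_with_germ = {cv.case_id for cv in hits}
    co = {"both": 0, "somatic_only": 0, "germline_only": 0, "neither": 0}
    for c in cases:
        s = c.case_id in cases_with_ns_somatic
        g = c.case_id in cases_with_germ
        key = ("both" if s and g else "somatic_only" if s
               else "germline_only" if g else "neither")
        co[key] += 1
    conservation = {"high": 0, "moderate": 0, "non_conserved": 0, "missing": 0}
    for cv in somatic:
        if cv.silence == "non_silent":
            conservation[cv.conservation_bin or "missing"] += 1
    return CohortSummary(
        n_cases=len(cases),
        total_qc_variants=len(qc_variants),
        region_impact=region_impact,
        ratio=ratio,
        somatic_counts=somatic_counts,
        germline_prioritized_count=len(hits),
        per_case_somatic=per_case_somatic,
        recurrent_somatic_non_silent=rec_ns,
        recurrent_somatic_silent=rec_s,
        recurrent_germline=rec_germ,
        germline_independent_events=indep_germ,
        burden=burden,
        clonal_assignments=list(assignments),
        pgx_reports=list(pgx_reports),
        co_occurrence=co,
        conservation_non_silent_somatic=conservation,
    )
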