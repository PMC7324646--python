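"""End-to-end orchestration: QC -> rarity -> origin -> consequences ->
clones -> germline prioritization -> cohort statistics -> report files."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import yaml

from . import io as mio
from .classify import (
    DEFAULT_DELTA_THRESHOLD,
    assign_clones_by_case,
    classify_cohort,
)
from .consequences import annotate_consequences
from .errors import ConfigurationError, MyelopanelError
from .filters import FilterThresholds, apply_popaf_filter, apply_qc_filter
from .germline import DEFAULT_CADD_CUTOFF, DEFAULT_GMAF_CUTOFF, prioritize_cohort
from .records import ClassifiedVariant
from .stats import (
    CohortSummary,
    burden_test,
    per_case_gene_counts,
    pharmaco_lookup,
    summarize_cohort,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and options of one pipeline run; mirrors the YAML schema."""

    manifest: Path
    variants: Path  # annotated TSV file, or a directory of per-case VCFs
    out_dir: Path
    dialect: str = "annotated_tsv"  # annotated_tsv | vcf
    pgx_rules: Optional[Path] = None  # None -> bundled default rules
    reference_counts: Optional[Path] = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD
    gmaf_cutoff: float = DEFAULT_GMAF_CUTOFF
    cadd_cutoff: float = DEFAULT_CADD_CUTOFF
    possibly_damaging_counts: bool = True
    nonframeshift_silent: bool = True
    dunn_correction: str = "bonferroni"
    alpha: float = 0.01
    min_recurrent_cases: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = FilterThresholds(**raw.pop("thresholds", {}))
        for key in ("manifest", "variants", "out_dir", "pgx_rules",
                    "reference_counts"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        try:
            cfg = cls(thresholds=thresholds, **raw)
        except TypeError as exc:
            raise ConfigurationError(f"bad run config {path}: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("manifest", "variants", "pgx_rules", "reference_counts"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")
        if self.dialect not in ("annotated_tsv", "vcf"):
            raise ConfigurationError(f"unknown dialect {self.dialect!r}")

    def to_dict(self) -> dict:
        d = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in self.__dict__.items()
            if k != "thresholds"
        }
        d["thresholds"] = self.thresholds.__dict__
        return d


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, MyelopanelError):
                raise MyelopanelError(f"stage {name!r} failed: {exc}") from exc
            if isinstance(exc, MyelopanelError) and name not in str(exc):
                raise MyelopanelError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_variant_inputs(config: RunConfig):
    if config.dialect == "annotated_tsv":
        return mio.read_variants(config.variants, "annotated_tsv")
    vcf_dir = Path(config.variants)
    files = sorted(vcf_dir.glob("*.vcf"))
    if not files:
        raise ConfigurationError(f"no .vcf files found in {vcf_dir}")
    out = mio.ReadVariantsResult()
    for f in files:
        part = mio.read_variants(f, "vcf")
        out.extend(part)
        out.n_skipped += part.n_skipped
    return out


def run_pipeline(
    config: RunConfig,
) -> Tuple[CohortSummary, List[ClassifiedVariant]]:
    """Run every stage in order and write the report files.

    Each stage logs a row-conservation line (rows in = retained + removed).
    On failure the stage name is carried in the raised error and any
    partially written report files are removed.
    """
    config.validate()
    with _stage("read_inputs"):
        cases = mio.read_manifest(config.manifest)
        pairs = _read_variant_inputs(config)
        logger.info(
            "read_inputs: rows_in=%d rows_out_retained=%d rows_out_removed=%d",
            pairs.n_input, len(pairs), pairs.n_skipped,
        )
        rules = (
            mio.read_pgx_rules(config.pgx_rules)
            if config.pgx_rules is not None
            else list(mio.DEFAULT_PGX_RULES)
        )
        reference = (
            mio.read_reference_counts(config.reference_counts)
            if config.reference_counts is not None
            else None
        )
    with _stage("qc_filter"):
        retained, removed = apply_qc_filter(pairs, config.thresholds)
        logger.info(
            "qc_filter: rows_in=%d rows_out_retained=%d rows_out_removed=%d",
            len(pairs), len(retained), len(removed),
        )
    with _stage("pharmacogenomics"):
        pgx_reports = pharmaco_lookup(retained, rules, cases)
    with _stage("rarity_filter"):
        rare, common = apply_popaf_filter(retained, config.thresholds)
        logger.info(
            "rarity_filter: rows_in=%d rows_out_retained=%d "
            "rows_out_removed=%d", len(retained), len(rare), len(common),
        )
    with _stage("origin_classification"):
        classified = classify_cohort(rare, cases)
        annotate_consequences(
            classified, nonframeshift_silent=config.nonframeshift_silent
        )
        logger.info(
            "origin_classification: rows_in=%d rows_out_retained=%d "
            "rows_out_removed=%d", len(rare), len(classified), 0,
        )
    with _stage("clonal_ordering"):
        assignments = assign_clones_by_case(classified, config.delta_threshold)
    with _stage("germline_prioritization"):
        prioritized = prioritize_cohort(
            classified,
            config.gmaf_cutoff,
            config.cadd_cutoff,
            possibly_damaging_counts=config.possibly_damaging_counts,
        )
    with _stage("burden_test"):
        burden = None
        if len(cases) >= 3:
            counts = per_case_gene_counts(classified, cases)
            burden = burden_test(
                counts, alpha=config.alpha, correction=config.dunn_correction
            )
    with _stage("summary"):
        summary = summarize_cohort(
            cases, retained, classified, prioritized, assignments,
            burden=burden, pgx_reports=pgx_reports,
            reference_counts=reference,
            min_recurrent_cases=config.min_recurrent_cases,
        )
    out_dir = Path(config.out_dir)
    written: List[Path] = []
    try:
        with _stage("write_report"):
            written = list(mio.write_report(summary, classified, out_dir))
            run_manifest = {
                "config": config.to_dict(),
                "config_sha256": hashlib.sha256(
                    json.dumps(config.to_dict(), sort_keys=True).encode()
                ).hexdigest(),
                "inputs": {
                    "manifest": _sha256(Path(config.manifest)),
                },
                "counts": {
                    "input_records": pairs.n_input,
                    "qc_retained": len(retained),
                    "qc_removed": len(removed),
                    "rare": len(rare),
                    "common": len(common),
                },
            }
            if Path(config.variants).is_file():
                run_manifest["inputs"]["variants"] = _sha256(
                    Path(config.variants)
                )
            rm_path = out_dir / "run_manifest.json"
            with open(rm_path, "w") as fh:
                json.dump(run_manifest, fh, indent=2, sort_keys=True)
                fh.write("\n")
            written.append(rm_path)
    except MyelopanelError:
        for p in written:
            Path(p).unlink(missing_ok=True)
        raise
    return summary, classified
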