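import pytest

from myelopanel.records import AnnotationRecord, VariantCall
from myelopanel.simulate import SimConfig, simulate_cohort


def make_call(case_id="AM01", chrom="chr1", pos=100, ref="A", alt="G",
              qual=3000.0, depth=5000, alt_depth=2500,
              genotype_quality=99.0, genotype="het", variant_id=None):
    return VariantCall(
        case_id=case_id, chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual,
        depth=depth, alt_depth=alt_depth, genotype_quality=genotype_quality,
        genotype=genotype, variant_id=variant_id,
    )


def make_ann(gene="TET2", genomic_region="exonic",
             functional_impact="nonsynonymous_snv", **kwargs):
    return AnnotationRecord(
        gene=gene, genomic_region=genomic_region,
        functional_impact=functional_impact, **kwargs,
    )


def pairs_from_annotations(annotations, case_id="AM01"):
    """Wrap bare annotations in benign QC-passing calls."""
    return [
        (make_call(case_id=case_id, pos=i + 1, alt_depth=2500), ann)
        for i, ann in enumerate(annotations)
    ]


@pytest.fixture(scope="session")
def default_sim():
    """One seeded default cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    return simulate_cohort(SimConfig(
        seed=5, n_cases=6, germline_per_case_mean=10, somatic_per_case_mean=2,
    ))
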