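"""Generative model checks: VAF expectations, read-support noise, and
cohort-level determinism and calibration."""

import filecmp
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myelopanel.errors import ValidationError
from myelopanel.simulate import (
    SimConfig,
    expected_vaf,
    sample_read_support,
    simulate_cohort,
)


class TestExpectedVaf:
    @pytest.mark.parametrize(
        "origin,genotype,blast,ccf,hemi,expected",
        [
            ("somatic", "het", 0.80, 1.0, False, 0.40),
            ("germline", "het", None, None, False, 0.50),
            ("somatic", "het", 0.80, 0.25, False, 0.10),
            ("germline", "hom_alt", None, None, False, 1.0),
            ("germline", "het", None, None, True, 1.0),
            ("somatic", "het", 0.80, 0.5, True, 0.40),
            ("somatic", "hemi", 0.60, 1.0, False, 0.60),
        ],
    )
    def test_rule(self, origin, genotype, blast, ccf, hemi, expected):
        assert expected_vaf(origin, genotype, blast, ccf, hemi) == \
            pytest.approx(expected)

    def test_ccf_for_germline_is_error(self):
        with pytest.raises(ValidationError):
            expected_vaf("germline", "het", ccf=0.5)

    def test_bad_ccf_rejected(self):
        with pytest.raises(ValidationError):
            expected_vaf("somatic", "het", 0.5, ccf=0.0)

    @given(
        blast=st.floats(0.0, 1.0),
        ccf=st.floats(0.001, 1.0),
        hemi=st.booleans(),
    )
    @settings(deadline=None, max_examples=100)
    def test_somatic_vaf_in_unit_interval_and_monotone(self, blast, ccf, hemi):
        v = expected_vaf("somatic", "het", blast, ccf, hemi)
        assert 0.0 <= v <= 1.0
        # doubling rule: hemizygous VAF is twice the heterozygous one (capped)
        het = expected_vaf("somatic", "het", blast, ccf, False)
        hem = expected_vaf("somatic", "het", blast, ccf, True)
        assert hem == pytest.approx(min(2 * het, 1.0))


class TestReadSupport:
    def test_degenerate_binomials(self):
        rng = np.random.default_rng(0)
        assert sample_read_support(0.0, 5000, rng)[0] == 0
        assert sample_read_support(1.0, 5000, rng)[0] == 5000

    def test_out_of_range_expectation_rejected(self):
        with pytest.raises(ValidationError):
            sample_read_support(1.2, 100, np.random.default_rng(0))

    def test_unbiased_against_exact_binomial_moments(self):
        rng = np.random.default_rng(42)
        p, depth, n = 0.4, 5000, 10_000
        vafs = np.array(
            [sample_read_support(p, depth, rng)[0] / depth for _ in range(n)]
        )
        se_mean = math.sqrt(p * (1 - p) / depth / n)
        assert abs(vafs.mean() - p) < max(3 * se_mean, 0.005)
        exact_var = p * (1 - p) / depth
        assert vafs.var() == pytest.approx(exact_var, rel=0.1)


class TestSimulateCohort:
    def test_seeded_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=9, n_cases=4, germline_per_case_mean=12,
                        somatic_per_case_mean=2)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(cfg).write(d1)
        simulate_cohort(cfg).write(d2)
        for rel in ("manifest.tsv", "cohort.annotated.tsv", "truth.tsv"):
            assert filecmp.cmp(d1 / rel, d2 / rel, shallow=False), rel
        vcfs1 = sorted((d1 / "vcf").glob("*.vcf"))
        vcfs2 = sorted((d2 / "vcf").glob("*.vcf"))
        assert [f.name for f in vcfs1] == [f.name for f in vcfs2]
        for f1, f2 in zip(vcfs1, vcfs2):
            assert filecmp.cmp(f1, f2, shallow=False)

    def test_zero_somatic_mean_yields_no_somatic_truth(self):
        sim = simulate_cohort(SimConfig(seed=2, n_cases=5,
                                        somatic_per_case_mean=0.0))
        assert (sim.truth["true_origin"] == "somatic").sum() == 0

    def test_per_case_counts_poisson_mean(self, default_sim):
        truth = default_sim.truth
        germ = truth[(truth["true_origin"] == "germline")]
        # exclude the fixed pharmacogenomic site from the Poisson check
        germ = germ.merge(
            _rsids(default_sim), on="variant_id", how="left"
        )
        germ = germ[germ["rsid"] != "rs1042522"]
        counts = germ.groupby("case_id").size()
        mean = default_sim.config.germline_per_case_mean
        se = math.sqrt(mean / len(counts))
        assert abs(counts.mean() - mean) < 3 * se

    def test_truth_ccf_invariants(self, default_sim):
        truth = default_sim.truth
        somatic = truth[truth["true_origin"] == "somatic"]
        founding = somatic[somatic["clone_id"] == 0]
        subclone = somatic[somatic["clone_id"] > 0]
        assert (founding["true_ccf"] == 1.0).all()
        assert (subclone["true_ccf"] < 1.0).all()

    def test_germline_het_autosomal_vaf_median(self, default_sim):
        vafs = _germline_het_autosomal_vafs(default_sim, min_depth=1000)
        assert len(vafs) >= 500
        assert abs(float(np.median(vafs)) - 0.5) < 0.01

    def test_somatic_expected_vaf_below_classifier_threshold(self, default_sim):
        blast = {c.case_id: c.blast_percent / 100 for c in default_sim.cases}
        truth = default_sim.truth
        somatic = truth[truth["true_origin"] == "somatic"]
        for _, row in somatic.iterrows():
            thr = 0.5 * blast[row["case_id"]]
            if not row["hemizygous"]:
                assert row["expected_vaf"] < thr

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            SimConfig(blast_percent_range=(90, 20))
        with pytest.raises(ValidationError):
            SimConfig(subclone_ccf_range=(0.0, 0.5))
        with pytest.raises(ValidationError):
            SimConfig(impact_category_weights={"nonsynonymous_snv": 0.5})


def _rsids(sim):
    import pandas as pd
    return pd.DataFrame(
        [(c.variant_id, a.rsid) for c, a in sim.variants],
        columns=["variant_id", "rsid"],
    )


def _germline_het_autosomal_vafs(sim, min_depth=1000):
    truth = sim.truth.set_index("variant_id")
    vafs = []
    for call, ann in sim.variants:
        row = truth.loc[call.variant_id]
        if (
            row["true_origin"] == "germline"
            and row["genotype"] == "het"
            and not row["hemizygous"]
            and call.chrom != "chrX"
            and call.depth >= min_depth
        ):
            vafs.append(call.vaf)
    return np.array(vafs)
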