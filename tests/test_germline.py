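"""Germline evidence cascade and recurrence detection."""

import numpy as np
import pytest

from myelopanel.errors import ValidationError
from myelopanel.germline import (
    detect_recurrent_germline,
    prioritize_cohort,
    prioritize_germline,
)
from myelopanel.records import ClassifiedVariant

from conftest import make_ann, make_call


def germline_cv(case_id="AM01", **ann_kwargs):
    return ClassifiedVariant(
        call=make_call(case_id=case_id),
        ann=make_ann(**ann_kwargs),
        origin="germline",
    )


class TestCascade:
    def test_stop_gain_is_prioritized(self):
        cv = germline_cv(
            gene="WT1", functional_impact="stopgain", hgvs_p="p.R441X",
            rsid="rs121907909",
        )
        r = prioritize_germline(cv)
        assert r.protein_truncating
        assert r.prioritized

    def test_sift_and_polyphen_must_agree(self):
        cv = germline_cv(sift_class="deleterious", polyphen2_class="benign")
        assert not prioritize_germline(cv).prioritized

    def test_possibly_damaging_counts_by_default(self):
        cv = germline_cv(sift_class="deleterious",
                         polyphen2_class="possibly_damaging")
        assert prioritize_germline(cv).prioritized
        strict = prioritize_germline(cv, possibly_damaging_counts=False)
        assert not strict.prioritized

    def test_missing_predictions_noted_not_fatal(self):
        cv = germline_cv(sift_class=None, polyphen2_class=None)
        r = prioritize_germline(cv)
        assert not r.missense_deleterious
        assert any("missing-evidence" in n for n in r.notes)

    def test_gmaf_gate_blocks_common_variant(self):
        cv = germline_cv(functional_impact="stopgain", af_gnomad=0.02)
        r = prioritize_germline(cv)
        assert r.protein_truncating and not r.gmaf_pass
        assert not r.prioritized

    def test_cadd_is_advisory_only(self):
        cv = germline_cv(cadd_phred=35.0, sift_class="tolerated",
                         polyphen2_class="benign")
        r = prioritize_germline(cv)
        assert r.cadd_high and not r.prioritized

    def test_somatic_input_rejected(self):
        cv = germline_cv()
        cv.origin = "somatic"
        with pytest.raises(ValidationError):
            prioritize_germline(cv)

    def test_tightening_gmaf_never_adds_variants(self, default_sim):
        from myelopanel.classify import classify_cohort
        classified = classify_cohort(default_sim.variants, default_sim.cases)
        loose = {
            id(r.variant) for r in prioritize_cohort(classified, 0.01)
            if r.prioritized
        }
        tight = {
            id(r.variant) for r in prioritize_cohort(classified, 0.001)
            if r.prioritized
        }
        assert tight <= loose

    def test_brute_force_equivalence_on_simulated_flags(self):
        rng = np.random.default_rng(7)
        sift_opts = ["deleterious", "tolerated", None]
        pp2_opts = ["probably_damaging", "possibly_damaging", "benign", None]
        clinvar_opts = ["pathogenic", "likely_pathogenic", "vus",
                        "benign_like", None]
        impact_opts = ["nonsynonymous_snv", "synonymous_snv", "stopgain",
                       "stoploss", "splicing", "frameshift_insertion",
                       "frameshift_deletion", "nonframeshift_insertion"]
        cvs = []
        for i in range(200):
            impact = impact_opts[rng.integers(len(impact_opts))]
            region = "splicing" if impact == "splicing" else "exonic"
            cvs.append(germline_cv(
                case_id=f"C{i}",
                genomic_region=region,
                functional_impact=impact,
                sift_class=sift_opts[rng.integers(3)],
                polyphen2_class=pp2_opts[rng.integers(4)],
                clinvar_class=clinvar_opts[rng.integers(5)],
                af_gnomad=None if rng.random() < 0.4
                else float(rng.uniform(0, 0.03)),
                cadd_phred=float(rng.uniform(0, 40)),
            ))
        for cv in cvs:
            r = prioritize_germline(cv)
            a = cv.ann
            gmaf = a.af_gnomad is None or a.af_gnomad < 0.01
            missense_del = (
                a.functional_impact == "nonsynonymous_snv"
                and a.sift_class == "deleterious"
                and a.polyphen2_class in ("probably_damaging",
                                          "possibly_damaging")
            )
            brute = gmaf and (
                a.clinvar_class in ("pathogenic", "likely_pathogenic")
                or a.functional_impact in ("stopgain", "stoploss")
                or a.functional_impact == "splicing"
                or a.genomic_region == "splicing"
                or a.functional_impact in ("frameshift_insertion",
                                           "frameshift_deletion")
                or missense_del
            )
            assert r.prioritized == brute


class TestRecurrence:
    def _result(self, cv):
        return prioritize_germline(cv)

    def test_same_change_two_cases_is_recurrent(self):
        results = [
            self._result(germline_cv(
                case_id=c, gene="GATA2", hgvs_p="p.T358P",
                sift_class="deleterious",
                polyphen2_class="probably_damaging",
            ))
            for c in ("AM01", "AM03")
        ]
        recurrent, independent = detect_recurrent_germline(results)
        assert recurrent == [{
            "gene": "GATA2", "hgvs_p": "p.T358P", "cases": ["AM01", "AM03"]
        }]

    def test_three_distinct_variants_listed_as_independent(self):
        results = [
            self._result(germline_cv(
                case_id=c, gene="WT1", functional_impact="stopgain",
                hgvs_p=p,
            ))
            for c, p in (("AM02", "p.R441X"), ("AM05", "p.Q100X"),
                         ("AM09", "p.S50X"))
        ]
        recurrent, independent = detect_recurrent_germline(results)
        assert recurrent == []
        assert independent == [{
            "gene": "WT1",
            "variants": ["p.Q100X", "p.R441X", "p.S50X"],
        }]

    def test_empty_input(self):
        assert detect_recurrent_germline([]) == ([], [])
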