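"""Cohort statistics: recurrence, burden testing, pharmacogenomics, and
summary self-consistency."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from myelopanel.classify import classify_cohort
from myelopanel.consequences import annotate_consequences
from myelopanel.errors import ValidationError
from myelopanel.germline import prioritize_cohort
from myelopanel.io import DEFAULT_PGX_RULES
from myelopanel.records import CaseMeta, ClassifiedVariant
from myelopanel.stats import (
    burden_test,
    detect_recurrent_somatic,
    dunn_posthoc,
    per_case_gene_counts,
    pharmaco_lookup,
    round_half_up,
    summarize_cohort,
)

from conftest import make_ann, make_call


def somatic_cv(case_id, gene="STAG2", hgvs_p="p.L526F", vaf=0.1,
               silence="non_silent", pos=100):
    depth = 5000
    return ClassifiedVariant(
        call=make_call(case_id=case_id, pos=pos, depth=depth,
                       alt_depth=int(round(vaf * depth))),
        ann=make_ann(gene=gene, hgvs_p=hgvs_p),
        origin="somatic",
        silence=silence,
    )


class TestRecurrentSomatic:
    def test_three_case_recurrence_detected(self):
        cvs = [somatic_cv(c) for c in ("AM16", "AM19", "AM22")]
        non_silent, silent = detect_recurrent_somatic(cvs)
        assert len(non_silent) == 1 and silent == []
        entry = non_silent[0]
        assert entry["gene"] == "STAG2"
        assert entry["mutation"] == "p.L526F"
        assert entry["cases"] == ["AM16", "AM19", "AM22"]

    def test_singletons_yield_empty_lists(self):
        cvs = [somatic_cv("AM01", hgvs_p="p.A1B"),
               somatic_cv("AM02", hgvs_p="p.C2D")]
        assert detect_recurrent_somatic(cvs) == ([], [])

    def test_case_order_invariance(self):
        cvs = [somatic_cv(c) for c in ("AM01", "AM02", "AM03")]
        fwd = detect_recurrent_somatic(cvs)
        rev = detect_recurrent_somatic(list(reversed(cvs)))
        assert fwd == rev

    def test_planted_recurrences_recovered(self, default_sim):
        classified = classify_cohort(default_sim.variants, default_sim.cases)
        annotate_consequences(classified)
        case_ids = [c.case_id for c in default_sim.cases]
        planted = [
            somatic_cv(c, gene="CDKN2A", hgvs_p="p.R90C", pos=777)
            for c in case_ids[:4]
        ]
        non_silent, _ = detect_recurrent_somatic(classified + planted)
        hit = [e for e in non_silent if e["gene"] == "CDKN2A"
               and e["mutation"] == "p.R90C"]
        assert len(hit) == 1
        assert hit[0]["cases"] == sorted(case_ids[:4])


class TestBurden:
    def _counts(self, rows, genes=8):
        return pd.DataFrame(
            rows, index=[f"C{i}" for i in range(len(rows))],
            columns=[f"g{j}" for j in range(genes)],
        )

    def test_identical_counts_no_flags(self):
        counts = self._counts([[1] * 8] * 5)
        res = burden_test(counts)
        assert res.omnibus_p == 1.0
        assert res.flagged == []

    def test_needs_three_cases(self):
        with pytest.raises(ValidationError):
            burden_test(self._counts([[0] * 8] * 2))

    def test_planted_excess_cases_flagged(self):
        rng = np.random.default_rng(12)
        rows = [rng.poisson(0.3, 54) for _ in range(24)]
        rows += [rng.poisson(3.0, 54) for _ in range(2)]
        counts = pd.DataFrame(
            rows, index=[f"C{i:02d}" for i in range(26)],
            columns=[f"g{j}" for j in range(54)],
        )
        res = burden_test(counts, alpha=0.01)
        assert set(res.flagged_cases) == {"C24", "C25"}

    def test_null_single_replicate_unflagged(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.poisson(0.5, size=(26, 54)),
            index=[f"C{i:02d}" for i in range(26)],
            columns=[f"g{j}" for j in range(54)],
        )
        assert burden_test(counts, alpha=0.01).flagged == []

    def test_tiny_instance_agrees_with_exact_permutation(self):
        """3 cases, one visibly higher, but n too small for significance:
        the exact permutation distribution of the rank-sum confirms the
        Dunn p cannot clear alpha=0.01, so no flags is correct."""
        rows = [[0, 0, 1, 0], [0, 1, 0, 0], [3, 4, 3, 5]]
        counts = self._counts(rows, genes=4)
        res = burden_test(counts, alpha=0.01)
        assert res.flagged == []
        # exact permutation oracle for the extreme pair (C0 vs C2)
        pooled = rows[0] + rows[2]
        ranks = sps.rankdata(pooled)
        observed = abs(ranks[:4].mean() - ranks[4:].mean())
        diffs = []
        for idx in itertools.combinations(range(8), 4):
            a = [ranks[i] for i in idx]
            b = [ranks[i] for i in range(8) if i not in idx]
            diffs.append(abs(np.mean(a) - np.mean(b)))
        p_exact = np.mean([d >= observed - 1e-12 for d in diffs])
        assert p_exact > 0.01  # power limit, not a bug

    def test_dunn_z_matches_permutation_null_on_separated_groups(self):
        """Dunn's normal-approximation p agrees with a Monte-Carlo
        permutation p of the mean-rank gap on a small instance."""
        rng = np.random.default_rng(8)
        g1 = rng.poisson(1.0, 12).astype(float)
        g2 = rng.poisson(1.2, 12).astype(float)
        groups = [g1, g2]
        _, p, _ = dunn_posthoc(groups, ["a", "b"])
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        obs = abs(ranks[:12].mean() - ranks[12:].mean())
        n_perm, hits = 4000, 0
        for _ in range(n_perm):
            perm = rng.permutation(ranks)
            hits += abs(perm[:12].mean() - perm[12:].mean()) >= obs - 1e-12
        p_perm = hits / n_perm
        assert p.loc["a", "b"] == pytest.approx(p_perm, abs=0.05)


class TestPharmaco:
    def _cases(self, n=26):
        return [CaseMeta(case_id=f"AM{i:02d}", sex="female",
                         blast_percent=50) for i in range(1, n + 1)]

    def _pgx_pair(self, case_id, genotype):
        call = make_call(case_id=case_id, chrom="chr17", pos=7_579_472,
                         ref="G", alt="C", genotype=genotype,
                         alt_depth=2500 if genotype == "het" else 5000)
        ann = make_ann(gene="TP53", rsid="rs1042522")
        return call, ann

    def test_nineteen_of_26_carriers_is_73_percent(self):
        cases = self._cases()
        # 7 cases homozygous alt (C/C, non-risk), 12 het (C/G), 7 no call (G/G)
        pairs = [self._pgx_pair(c.case_id, "hom_alt") for c in cases[:7]]
        pairs += [self._pgx_pair(c.case_id, "het") for c in cases[7:19]]
        report, = pharmaco_lookup(pairs, DEFAULT_PGX_RULES, cases)
        assert report.carrier_count == 19
        assert report.to_dict()["carrier_percent"] == 73

    def test_absent_rsid_reports_zero_carriers_for_alt_risk(self):
        rule = DEFAULT_PGX_RULES[0]
        alt_risk = type(rule)(
            rsid="rs9999", gene="NRAS", ref="G", alt="A",
            risk_genotypes=frozenset({"A/A"}), annotation="synthetic rule",
        )
        report, = pharmaco_lookup([], [alt_risk], self._cases())
        assert report.carrier_count == 0
        assert report.to_dict()["carrier_percent"] == 0

    def test_brute_force_genotype_scan(self, default_sim):
        from myelopanel.filters import FilterThresholds, apply_qc_filter
        retained, _ = apply_qc_filter(default_sim.variants,
                                      FilterThresholds())
        report, = pharmaco_lookup(retained, DEFAULT_PGX_RULES,
                                  default_sim.cases)
        brute = 0
        genotyped = {
            c.case_id: c.genotype for c, a in retained
            if a.rsid == "rs1042522"
        }
        for case in default_sim.cases:
            g = genotyped.get(case.case_id)
            if g is None or g == "het":  # G/G and C/G are risk genotypes
                brute += 1
        assert report.carrier_count == brute


@pytest.fixture(scope="module")
def summary_inputs(default_sim):
    from myelopanel.filters import FilterThresholds, apply_popaf_filter, \
        apply_qc_filter
    retained, _ = apply_qc_filter(default_sim.variants, FilterThresholds())
    rare, _ = apply_popaf_filter(retained, FilterThresholds())
    classified = classify_cohort(rare, default_sim.cases)
    annotate_consequences(classified)
    prioritized = prioritize_cohort(classified)
    summary = summarize_cohort(
        default_sim.cases, retained, classified, prioritized,
    )
    return summary, classified, prioritized


class TestSummarize:
    def test_somatic_subtotals_consistent(self, summary_inputs):
        summary, classified, _ = summary_inputs
        sc = summary.somatic_counts
        assert sc["total"] == sc["snv"] + sc["indel"]
        assert sc["total"] == sc["non_silent"] + sc["silent"]
        assert sc["total"] == sum(
            1 for cv in classified if cv.origin == "somatic"
        )
        assert sc["total"] == sum(summary.per_case_somatic.values())

    def test_co_occurrence_cells_sum_to_cohort(self, summary_inputs):
        summary, _, _ = summary_inputs
        assert sum(summary.co_occurrence.values()) == summary.n_cases

    def test_fields_match_independent_recount(self, summary_inputs):
        summary, classified, prioritized = summary_inputs
        df = pd.DataFrame({
            "case_id": [cv.case_id for cv in classified],
            "origin": [cv.origin for cv in classified],
            "silence": [cv.silence for cv in classified],
            "is_snv": [cv.call.is_snv for cv in classified],
        })
        somatic = df[df["origin"] == "somatic"]
        assert summary.somatic_counts["snv"] == int(somatic["is_snv"].sum())
        assert summary.germline_prioritized_count == sum(
            r.prioritized for r in prioritized
        )
        ns_cases = set(
            somatic[somatic["silence"] == "non_silent"]["case_id"]
        )
        pg_cases = {
            r.variant.case_id for r in prioritized if r.prioritized
        }
        frac = len(ns_cases | pg_cases) / summary.n_cases
        assert summary.fraction_cases_with_any_prioritized == \
            pytest.approx(frac)

    def test_rates_scale(self, summary_inputs):
        summary, _, _ = summary_inputs
        assert 0 <= summary.fraction_cases_with_any_prioritized <= 1
        assert summary.somatic_per_case == pytest.approx(
            summary.somatic_counts["total"] / summary.n_cases
        )

    def test_per_case_gene_counts_totals(self, summary_inputs, default_sim):
        _, classified, _ = summary_inputs
        counts = per_case_gene_counts(classified, default_sim.cases)
        assert counts.shape == (26, 54)
        assert counts.to_numpy().sum() == sum(
            1 for cv in classified if cv.origin == "somatic"
        )


class TestRounding:
    @pytest.mark.parametrize("value,nd,expected", [
        (88.455, 2, 88.46),  # half-up at the printed precision
        (72.5, 0, 73.0),
        (1.455, 2, 1.46),
        (0.125, 2, 0.13),
    ])
    def test_round_half_up(self, value, nd, expected):
        assert round_half_up(value, nd) == expected
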