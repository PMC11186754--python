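"""Reportable-variant filtering and the two probabilistic evidence scores."""

import math

import numpy as np
import pytest

from clonedyn.prioritize import (
    FilterPolicy,
    filter_reportable,
    prob_absent_in_normal,
    prob_vaf_changed,
)
from .conftest import make_variant


def annotated(pos, **ann):
    defaults = dict(
        consequence="missense_variant",
        pathogenicity_score=0.9,
        population_af=0.001,
        gene="TP53",
    )
    defaults.update(ann)
    return make_variant(10, 100, 20, 100, pos=pos, annotations=defaults)


class TestFilterReportable:
    def test_all_clauses_pass(self):
        kept, reasons = filter_reportable([annotated(1)], FilterPolicy())
        assert len(kept) == 1 and not reasons

    def test_low_pathogenicity_rejected_with_reason(self):
        kept, reasons = filter_reportable(
            [annotated(1, pathogenicity_score=0.4)], FilterPolicy(revel_min=0.5)
        )
        assert not kept and reasons == {"pathogenicity": 1}

    def test_missing_score_passes_the_pathogenicity_clause(self):
        v = annotated(1)
        del v.annotations["pathogenicity_score"]
        kept, _ = filter_reportable([v], FilterPolicy(revel_min=0.5))
        assert len(kept) == 1

    def test_clause_by_clause_audit(self):
        # 10 variants, 4 designed to fail one distinct clause each
        policy = FilterPolicy(gene_list=frozenset({"TP53", "KRAS"}))
        variants = [annotated(i) for i in range(1, 7)]
        variants.append(annotated(7, consequence="synonymous_variant"))
        variants.append(annotated(8, pathogenicity_score=0.2))
        variants.append(annotated(9, population_af=0.5))
        variants.append(annotated(10, clinical_significance="likely_benign"))
        kept, reasons = filter_reportable(variants, policy)
        assert len(kept) == 6
        assert reasons == {
            "consequence": 1,
            "pathogenicity": 1,
            "population_af": 1,
            "clinical_significance": 1,
        }

    def test_gene_list_clause(self):
        policy = FilterPolicy(gene_list=frozenset({"KRAS"}))
        kept, reasons = filter_reportable([annotated(1, gene="TP53")], policy)
        assert not kept and reasons == {"gene_list": 1}

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(11)
        variants = [
            annotated(
                i,
                pathogenicity_score=float(rng.uniform(0, 1)),
                population_af=float(rng.uniform(0, 0.5)),
            )
            for i in range(1, 31)
        ]
        loose, _ = filter_reportable(variants, FilterPolicy(revel_min=0.3, gnomad_max=0.4))
        tight, _ = filter_reportable(variants, FilterPolicy(revel_min=0.7, gnomad_max=0.1))
        assert set(id(v) for v in tight) <= set(id(v) for v in loose)


class TestProbAbsentInNormal:
    def test_clean_normal_supports_absence(self):
        # independent closed form: Bayes factor of Binomial(100, 0.001) vs
        # Binomial(100, 0.5) at zero alt reads, equal priors
        expected = 0.999**100 / (0.999**100 + 0.5**100)
        assert prob_absent_in_normal(0, 100) == pytest.approx(expected, rel=1e-9)
        assert prob_absent_in_normal(0, 100) > 0.99

    def test_het_signal_supports_presence(self):
        l_noise = math.comb(100, 50) * 0.001**50 * 0.999**50
        l_het = math.comb(100, 50) * 0.5**100
        expected = l_noise / (l_noise + l_het)
        assert prob_absent_in_normal(50, 100) == pytest.approx(expected, rel=1e-6)
        assert prob_absent_in_normal(50, 100) < 0.01

    def test_zero_depth_is_uninformative(self):
        assert prob_absent_in_normal(0, 0) == 0.5

    def test_alt_above_depth_fatal(self):
        with pytest.raises(ValueError):
            prob_absent_in_normal(5, 3)


class TestProbVafChanged:
    def test_symmetric_null_matches_oracle_and_shrinks_with_depth(self):
        # identical counts/purities: the probability reflects only posterior
        # spread relative to delta, so it must match the analytic/high-rep
        # value and shrink toward 0 as depth grows
        rng = np.random.default_rng(5)
        n = 10**6
        oracle = np.mean(
            np.abs(rng.beta(20.5, 80.5, n) - rng.beta(20.5, 80.5, n)) / 0.5 > 0.05
        )
        p_shallow = prob_vaf_changed(20, 100, 0.5, 20, 100, 0.5)
        assert p_shallow == pytest.approx(oracle, abs=0.02)
        p_deep = prob_vaf_changed(200, 1000, 0.5, 200, 1000, 0.5)
        assert p_deep < p_shallow
        assert prob_vaf_changed(2000, 10000, 0.5, 2000, 10000, 0.5) < 0.1

    def test_extreme_separation_is_near_certain(self):
        assert prob_vaf_changed(0, 200, 0.5, 50, 100, 0.5) > 0.99

    def test_symmetry_under_sample_swap(self):
        a = prob_vaf_changed(10, 100, 0.4, 30, 100, 0.6, rng=1)
        b = prob_vaf_changed(30, 100, 0.6, 10, 100, 0.4, rng=1)
        assert a == pytest.approx(b, abs=0.02)

    def test_invariance_under_joint_purity_rescale(self):
        # multiplying both purities by c rescales both adjusted frequencies by
        # 1/c, so the probability is unchanged when delta rescales too
        a = prob_vaf_changed(10, 100, 0.4, 30, 100, 0.5, delta=0.05, rng=2)
        b = prob_vaf_changed(10, 100, 0.8, 30, 100, 1.0, delta=0.025, rng=2)
        assert a == pytest.approx(b, abs=1e-12)

    def test_moderate_case_matches_high_rep_oracle(self):
        # brute-force oracle: 10^6 Beta draws per sample, same Jeffreys model
        rng = np.random.default_rng(123)
        n = 10**6
        fb = rng.beta(10.5, 90.5, n)
        fr = rng.beta(30.5, 70.5, n)
        oracle = np.mean(np.abs(fb / 0.5 - fr / 0.5) > 0.05)
        est = prob_vaf_changed(10, 100, 0.5, 30, 100, 0.5, rng=0)
        se = math.sqrt(oracle * (1 - oracle) / 20_000)
        assert est == pytest.approx(oracle, abs=3 * se)

    def test_unknown_purity_refused(self):
        with pytest.raises(ValueError):
            prob_vaf_changed(10, 100, 0.0, 30, 100, 0.5)
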