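"""Purity estimation: robust max VAF, prior reconciliation, biopsy scaling."""

import numpy as np
import pytest

from clonedyn.data import BIOPSY, RESECTION, PurityEstimate
from clonedyn.purity import (
    estimate_biopsy_purity,
    estimate_case_purities,
    resolve_resection_purity,
    robust_max_vaf,
)
from .conftest import make_case, make_variant


def variants_with_vafs(vafs, depth=100, sample=RESECTION):
    out = []
    for i, f in enumerate(vafs):
        alt = int(round(f * depth))
        if sample == RESECTION:
            out.append(make_variant(0, depth, alt, depth, pos=100 + i))
        else:
            out.append(make_variant(alt, depth, 0, depth, pos=100 + i))
    return out


class TestRobustMaxVaf:
    def test_constant_distribution_returns_the_constant(self):
        vs = variants_with_vafs([0.40] * 50)
        assert robust_max_vaf(vs, RESECTION) == pytest.approx(0.40)

    def test_quantile_shields_against_cnv_outlier(self):
        # 0.95 is a copy-number-inflated outlier; the 0.75 quantile of the
        # sorted VAFs {0.1,0.2,0.3,0.4,0.95} sits at 0.40 (linear convention,
        # cross-checked by hand: index 0.75*(5-1)=3 in the sorted array).
        vs = variants_with_vafs([0.1, 0.2, 0.3, 0.4, 0.95])
        assert robust_max_vaf(vs, RESECTION, quantile=0.75) == pytest.approx(0.40)

    def test_no_qualifying_variants_gives_none(self):
        assert robust_max_vaf([], RESECTION) is None
        shallow = variants_with_vafs([0.3, 0.4], depth=10)
        assert robust_max_vaf(shallow, RESECTION, min_depth=30) is None

    def test_depth_floor_and_posterior_filter_apply(self):
        vs = variants_with_vafs([0.2] * 10, depth=100)
        vs += variants_with_vafs([0.9] * 5, depth=10)  # below the depth floor
        low_post = make_variant(0, 100, 95, 100, pos=999, posterior=0.5)
        assert robust_max_vaf(vs + [low_post], RESECTION) == pytest.approx(0.2)


class TestResolveResectionPurity:
    @pytest.mark.parametrize(
        "v,p1,p2,status,value",
        [
            (0.35, 0.30, 0.45, "known", 0.35),
            (0.35, 0.10, 0.60, "unknown", None),  # pathologists disagree
            (0.50, 0.30, 0.45, "unknown", None),  # v outside the prior interval
            (0.30, 0.30, 0.50, "known", 0.30),    # boundaries are inclusive
        ],
    )
    def test_reconciliation_rule(self, v, p1, p2, status, value):
        est = resolve_resection_purity(v, p1, p2)
        assert est.status == status
        if value is not None:
            assert est.value == pytest.approx(value)

    def test_p1_above_p2_is_fatal(self):
        with pytest.raises(ValueError):
            resolve_resection_purity(0.4, 0.6, 0.3)


class TestBiopsyScaling:
    def test_median_ratio_on_shared_variants(self):
        # every biopsy VAF exactly half its resection VAF -> s = 2
        vs = [make_variant(10, 100, 20, 100, pos=100 + i) for i in range(12)]
        case = make_case(vs)
        est = estimate_biopsy_purity(case, PurityEstimate.known(0.40, "simulated_truth"))
        assert est.status == "known"
        assert est.s == pytest.approx(2.0)
        assert est.value == pytest.approx(0.20)

    def test_identical_distributions_give_unit_scale(self):
        vs = [make_variant(20, 100, 20, 100, pos=100 + i) for i in range(12)]
        est = estimate_biopsy_purity(
            make_case(vs), PurityEstimate.known(0.40, "simulated_truth")
        )
        assert est.s == pytest.approx(1.0)
        assert est.value == pytest.approx(0.40)

    def test_wasserstein_grid_on_disjoint_sets(self):
        # biopsy-only variants carry the resection VAFs uniformly shrunk by
        # 0.5; the grid search should land on s = 2 (exact superposition).
        res_vafs = [0.10, 0.16, 0.22, 0.30, 0.38, 0.44]
        vs = []
        for i, f in enumerate(res_vafs):
            vs.append(make_variant(0, 100, int(f * 100), 100, pos=100 + i))
            vs.append(make_variant(int(f * 50), 100, 0, 100, pos=500 + i))
        est = estimate_biopsy_purity(
            make_case(vs), PurityEstimate.known(0.40, "simulated_truth"), min_shared=10
        )
        assert est.s == pytest.approx(2.0, abs=0.051)
        assert est.value == pytest.approx(0.20, abs=0.02)

    def test_scale_equivariance_of_median_ratio(self):
        # shrinking all biopsy VAFs by c multiplies s by 1/c
        base = [make_variant(20, 100, 30, 100, pos=100 + i) for i in range(12)]
        halved = [make_variant(10, 100, 30, 100, pos=100 + i) for i in range(12)]
        p = PurityEstimate.known(0.40, "simulated_truth")
        s1 = estimate_biopsy_purity(make_case(base), p).s
        s2 = estimate_biopsy_purity(make_case(halved), p).s
        assert s2 == pytest.approx(2.0 * s1)

    def test_too_few_nonzero_biopsy_vafs_is_unknown(self):
        vs = [make_variant(0, 100, 30, 100, pos=100 + i) for i in range(10)]
        vs.append(make_variant(10, 100, 20, 100, pos=999))
        est = estimate_biopsy_purity(
            make_case(vs), PurityEstimate.known(0.40, "simulated_truth")
        )
        assert est.status == "unknown"


def test_zero_purity_resolution_downgraded_to_unknown():
    # all-reference resection with p1 = 0 resolves to v = 0 under the literal
    # rule; the pipeline treats that as no analyzable tumor signal.
    vs = [make_variant(10, 100, 0, 100, pos=100 + i) for i in range(5)]
    case = make_case(vs, p1=0.0, p2=0.1)
    estimate_case_purities(case)
    assert case.purity_resection.status == "unknown"
    assert case.purity_biopsy.status == "unknown"
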