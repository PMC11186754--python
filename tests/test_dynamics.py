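"""Subclone qualification, lost/gained classification, cohort bookkeeping."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from clonedyn.data import PurityEstimate
from clonedyn.dynamics import (
    adjust_vaf,
    classify_subclones,
    detectable_in_other,
    summarize_cohort,
)
from .conftest import make_case, make_variant


@pytest.mark.parametrize(
    "f,purity,expected",
    [(0.05, 0.50, 0.10), (0.30, 1.00, 0.30), (0.60, 0.50, 1.00)],
)
def test_adjust_vaf(f, purity, expected):
    assert adjust_vaf(f, purity) == pytest.approx(expected)


def test_adjust_vaf_rejects_nonpositive_purity_and_propagates_nan():
    with pytest.raises(ValueError):
        adjust_vaf(0.2, 0.0)
    assert math.isnan(adjust_vaf(math.nan, 0.5))


@pytest.mark.parametrize(
    "f_adj,purity,depth,expected",
    [
        (0.20, 0.50, 100, True),   # 10 expected reads
        (0.10, 0.30, 30, False),   # 0.9 expected reads
        (0.10, 0.20, 100, True),   # exactly 2.0: the bound is inclusive
    ],
)
def test_detectable_in_other(f_adj, purity, depth, expected):
    assert detectable_in_other(f_adj, purity, depth) is expected


def six_variant_case():
    """Hand-built fixture: 2 biopsy-only, 1 resection-only, 3 shared variants,
    purities 0.5/0.5, depth 100 everywhere — classified by hand below."""
    vs = [
        make_variant(20, 100, 0, 100, pos=1),   # lost (adj biopsy VAF 0.4)
        make_variant(15, 100, 0, 100, pos=2),   # lost (adj 0.3)
        make_variant(0, 100, 30, 100, pos=3),   # gained (adj resection 0.6)
        make_variant(25, 100, 25, 100, pos=4),  # retained
        make_variant(25, 100, 25, 100, pos=5),  # retained
        make_variant(25, 100, 25, 100, pos=6),  # retained
    ]
    return make_case(vs, purity_b=0.5, purity_r=0.5)


def test_classification_of_hand_built_fixture():
    dyn = classify_subclones(six_variant_case())
    assert (dyn.n_total, dyn.n_lost, dyn.n_gained, dyn.n_retained) == (6, 2, 1, 3)
    assert dyn.fraction_lost == pytest.approx(1 / 3)
    assert dyn.fraction_gained == pytest.approx(1 / 6)
    assert dyn.n_resection == 4  # gained + the three retained
    assert dyn.analyzable


def test_posterior_filter_removes_low_confidence_variants():
    case = six_variant_case()
    for v in case.variants:
        v.somatic_posterior = 0.90
    dyn = classify_subclones(case)
    assert not dyn.analyzable and dyn.n_total == 0


def test_undetectable_in_shallow_other_sample_is_not_counted_lost():
    # biopsy-only subclone, but resection depth so shallow that even at the
    # same frequency it would get < 2 expected reads: excluded, not "lost".
    vs = [make_variant(20, 100, 0, 3, pos=1)]
    dyn = classify_subclones(make_case(vs, purity_b=0.5, purity_r=0.5))
    assert dyn.n_total == 0 and dyn.n_lost == 0 and not dyn.analyzable


def test_subthreshold_nonzero_other_sample_counts_retained():
    # adjusted VAF 0.04 in resection (0 < adj < 0.1) with 0.4 in biopsy:
    # not "lost" (alt reads nonzero), so retained.
    vs = [make_variant(20, 100, 2, 100, pos=1)]
    dyn = classify_subclones(make_case(vs, purity_b=0.5, purity_r=0.5))
    assert (dyn.n_total, dyn.n_lost, dyn.n_retained) == (1, 0, 1)


def test_unknown_purity_refused():
    with pytest.raises(ValueError):
        classify_subclones(make_case([make_variant(20, 100, 0, 100)]))


def test_cohort_summary_bookkeeping():
    analyzable = six_variant_case()
    unknown = make_case([make_variant(20, 100, 0, 100)], patient_id="P2")
    empty = make_case([], patient_id="P3", purity_b=0.5, purity_r=0.5)
    table, exclusions = summarize_cohort([analyzable, unknown, empty])
    assert len(table) == 1
    assert set(exclusions) == {("P2", "unknown_purity"), ("P3", "empty_qualifying_set")}
    assert table.iloc[0]["patient_id"] == "P1"


@st.composite
def random_case(draw):
    n = draw(st.integers(1, 25))
    vs = []
    for i in range(n):
        db = draw(st.integers(0, 300))
        dr = draw(st.integers(0, 300))
        vs.append(
            make_variant(
                draw(st.integers(0, db)), db, draw(st.integers(0, dr)), dr,
                pos=i + 1,
                posterior=draw(st.floats(0, 1, allow_nan=False)),
            )
        )
    pb = draw(st.floats(0.05, 1.0, allow_nan=False))
    pr = draw(st.floats(0.05, 1.0, allow_nan=False))
    return make_case(vs, purity_b=pb, purity_r=pr)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(random_case())
def test_counts_partition_and_fraction_bounds(case):
    dyn = classify_subclones(case)
    assert dyn.n_lost + dyn.n_gained + dyn.n_retained == dyn.n_total
    assert 0 <= dyn.fraction_lost <= 1 and 0 <= dyn.fraction_gained <= 1
    assert dyn.fraction_lost + dyn.fraction_gained <= 1
    assert dyn.analyzable == (dyn.n_total > 0)
    assert dyn.n_resection <= dyn.n_total


@settings(max_examples=60, derandomize=True, deadline=None)
@given(random_case(), st.floats(0.1, 0.5), st.floats(2.0, 10.0))
def test_tightening_thresholds_never_adds_subclones(case, vaf_min, min_reads):
    base = classify_subclones(case)
    stricter_vaf = classify_subclones(case, vaf_min=max(vaf_min, 0.1))
    stricter_reads = classify_subclones(case, min_reads=min_reads)
    assert stricter_vaf.n_total <= base.n_total
    assert stricter_reads.n_total <= base.n_total
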