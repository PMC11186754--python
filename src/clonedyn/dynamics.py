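"""Purity-adjusted subclone counting and lost/gained classification.

Each somatic variant is treated as the representative of the subclone it
founded.  A variant qualifies as a detectable subclone when it is confidently
somatic, its purity-adjusted VAF reaches the prevalence floor in at least one
sample, and — had it occurred at the same cellular frequency in the other
sample — it would be expected to be covered by at least ``min_reads`` reads
there.  Qualifying variants with zero alt reads in the resection but adjusted
VAF at or above the floor in the biopsy are "lost" subclones; the symmetric
case defines "gained" subclones; the rest are retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .data import BIOPSY, RESECTION, PatientCase, SubcloneDynamics, VariantCall

logger = logging.getLogger(__name__)

POSTERIOR_MIN = 0.95
VAF_MIN = 0.1
MIN_READS = 2.0


def adjust_vaf(f: float, purity: float) -> float:
    """Purity-adjusted VAF: ``min(1, f / purity)``.

    Divides the observed allele frequency by the sample's allele-scale purity,
    turning it into an estimate of the variant's cellular prevalence among
    tumor cells.  NaN input (undefined VAF at zero depth) propagates.
    """
    if purity <= 0:
        raise ValueError(f"purity must be > 0, got {purity}")
    if math.isnan(f):
        return math.nan
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"VAF out of [0,1]: {f}")
    return min(1.0, f / purity)


def detectable_in_other(
    f_adj: float, purity_other: float, depth_other: int, min_reads: float = MIN_READS
) -> bool:
    """Would a subclone at adjusted frequency ``f_adj`` be seen in the other sample?

    The cellular frequency is mapped back to the other sample's allele scale
    via its purity and multiplied by its depth; the expected number of
    alt-supporting reads must reach ``min_reads`` (inclusive).
    """
    if math.isnan(f_adj):
        return False
    return f_adj * purity_other * depth_other >= min_reads


@dataclass
class _Classified:
    variant: VariantCall
    adj_biopsy: float
    adj_resection: float
    fate: str  # lost | gained | retained


def _classify_variants(
    case: PatientCase,
    posterior_min: float,
    vaf_min: float,
    min_reads: float,
) -> list[_Classified]:
    pb = case.purity_biopsy.value
    pr = case.purity_resection.value
    out: list[_Classified] = []
    for var in case.variants:
        if var.somatic_posterior < posterior_min:
            continue
        ab = adjust_vaf(var.vaf_biopsy, pb)
        ar = adjust_vaf(var.vaf_resection, pr)
        in_b = not math.isnan(ab) and ab >= vaf_min
        in_r = not math.isnan(ar) and ar >= vaf_min
        if not (in_b or in_r):
            continue
        # Detectability is checked from every sample in which the subclone is
        # observed toward the respective other sample.  Alt reads in the other
        # sample are actual detection; the expected-reads test matters only
        # when the other sample shows none.
        if in_b and var.alt_resection == 0 and not detectable_in_other(
            ab, pr, var.depth_resection, min_reads
        ):
            continue
        if in_r and var.alt_biopsy == 0 and not detectable_in_other(
            ar, pb, var.depth_biopsy, min_reads
        ):
            continue
        if var.alt_resection == 0 and in_b:
            fate = "lost"
        elif var.alt_biopsy == 0 and in_r:
            fate = "gained"
        else:
            fate = "retained"
        out.append(_Classified(var, ab, ar, fate))
    return out


def classify_subclones(
    case: PatientCase,
    posterior_min: float = POSTERIOR_MIN,
    vaf_min: float = VAF_MIN,
    min_reads: float = MIN_READS,
) -> SubcloneDynamics:
    """Count qualifying subclones and split them into lost/gained/retained.

    Requires known purity estimates on both samples.  ``n_total`` is the size
    of the qualifying union over both samples and is the denominator of both
    fractions, so lost + gained + retained partitions it.  A patient with an
    empty qualifying set is flagged ``analyzable=False``.
    """
    if not case.purities_known:
        raise ValueError(
            f"{case.patient_id}: both purities must be known before subclone counting"
        )
    classified = _classify_variants(case, posterior_min, vaf_min, min_reads)
    fates = [c.fate for c in classified]
    n_resection = sum(
        1 for c in classified
        if not math.isnan(c.adj_resection) and c.adj_resection >= vaf_min
    )
    dyn = SubcloneDynamics.from_counts(
        n_lost=fates.count("lost"),
        n_gained=fates.count("gained"),
        n_retained=fates.count("retained"),
        n_resection=n_resection,
    )
    case.dynamics = dyn
    return dyn


COHORT_COLUMNS = [
    "patient_id",
    "regression_percent",
    "n_total",
    "n_resection",
    "n_lost",
    "n_gained",
    "n_retained",
    "fraction_lost",
    "fraction_gained",
    "purity_biopsy",
    "purity_biopsy_status",
    "purity_resection",
    "purity_resection_status",
]


def summarize_cohort(
    cases: Iterable[PatientCase],
    posterior_min: float = POSTERIOR_MIN,
    vaf_min: float = VAF_MIN,
    min_reads: float = MIN_READS,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Cohort dynamics table plus an exclusion log.

    Rows appear only for analyzable patients with known purities on both
    samples; every omitted patient is logged with its reason
    (``unknown_purity`` or ``empty_qualifying_set``).
    """
    rows = []
    exclusions: list[tuple[str, str]] = []
    for case in cases:
        if not case.purities_known:
            exclusions.append((case.patient_id, "unknown_purity"))
            logger.info("%s excluded: unknown purity", case.patient_id)
            continue
        dyn = case.dynamics
        if dyn is None:
            dyn = classify_subclones(
                case, posterior_min=posterior_min, vaf_min=vaf_min, min_reads=min_reads
            )
        if not dyn.analyzable:
            exclusions.append((case.patient_id, "empty_qualifying_set"))
            logger.info("%s excluded: empty qualifying set", case.patient_id)
            continue
        rows.append(
            {
                "patient_id": case.patient_id,
                "regression_percent": case.regression_percent,
                "n_total": dyn.n_total,
                "n_resection": dyn.n_resection,
                "n_lost": dyn.n_lost,
                "n_gained": dyn.n_gained,
                "n_retained": dyn.n_retained,
                "fraction_lost": dyn.fraction_lost,
                "fraction_gained": dyn.fraction_gained,
                "purity_biopsy": case.purity_biopsy.value,
                "purity_biopsy_status": case.purity_biopsy.status,
                "purity_resection": case.purity_resection.value,
                "purity_resection_status": case.purity_resection.status,
            }
        )
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return table, exclusions
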