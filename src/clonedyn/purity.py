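"""Tumor purity estimation from somatic VAF spectra.

Without copy-number variation, no somatic variant can exceed a VAF equal to
the tumor purity (on the allele scale), so the top of the somatic VAF
distribution estimates purity.  The resection estimate is reconciled with
two pathologist priors; the biopsy estimate is transferred from the
resection by scaling the biopsy VAF distribution onto the resection one.

All purities in this package live on the allele scale: purity is the
maximal attainable somatic VAF.  Under copy-neutral heterozygosity this is
half the cell-fraction purity; simulator, estimators and VAF adjustment all
share this single convention.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy.stats import wasserstein_distance

from .data import BIOPSY, RESECTION, PatientCase, PurityEstimate, VariantCall

logger = logging.getLogger(__name__)

DEFAULT_QUANTILE = 0.98
DEFAULT_MIN_DEPTH = 30
DEFAULT_POSTERIOR_MIN = 0.95
MAX_DISAGREEMENT = 0.2
WASSERSTEIN_GRID = np.round(np.arange(0.1, 10.0 + 1e-9, 0.05), 10)


def robust_max_vaf(
    variants: Sequence[VariantCall],
    sample: str,
    quantile: float = DEFAULT_QUANTILE,
    min_depth: int = DEFAULT_MIN_DEPTH,
    posterior_min: float = DEFAULT_POSTERIOR_MIN,
) -> float | None:
    """Robust maximum of the somatic VAF distribution in one sample.

    Operationalizes "the highest VAF of the distribution or a threshold for
    which higher VAFs could as well be explained by sampling or copy number
    variation" as a high quantile (default 0.98) of the VAFs of confidently
    somatic variants with depth >= ``min_depth``, capped at 1.0.

    Returns ``None`` when no variant qualifies (purity then unknown).
    """
    vafs = [
        v.vaf(sample)
        for v in variants
        if v.depth(sample) >= min_depth and v.somatic_posterior >= posterior_min
    ]
    vafs = [f for f in vafs if np.isfinite(f)]
    if not vafs:
        return None
    return float(min(1.0, np.quantile(vafs, quantile)))


def resolve_resection_purity(
    v: float,
    p1: float,
    p2: float,
    max_disagreement: float = MAX_DISAGREEMENT,
) -> PurityEstimate:
    """Reconcile the VAF-based purity ``v`` with the pathologist priors.

    ``v`` is reported as the posterior purity iff it lies within [p1, p2]
    and the pathologists agree sufficiently (p2 - p1 <= ``max_disagreement``,
    default 0.2); otherwise the purity is unknown.
    """
    if p1 > p2:
        raise ValueError(f"p1 > p2 ({p1} > {p2})")
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0 and 0.0 <= v <= 1.0):
        raise ValueError(f"v, p1, p2 must lie in [0,1]; got {v}, {p1}, {p2}")
    if p1 <= v <= p2 and (p2 - p1) <= max_disagreement:
        return PurityEstimate.known(v, method="vaf_max_consistent", v=v)
    return PurityEstimate.unknown(method="vaf_max_consistent", v=v)


def _scaling_factor(
    biopsy_vafs: np.ndarray,
    resection_vafs: np.ndarray,
    shared_ratios: np.ndarray,
    min_shared: int,
) -> tuple[float, str]:
    if shared_ratios.size >= min_shared:
        return float(np.median(shared_ratios)), "median_ratio"
    # Disjoint (or nearly) variant sets: grid-search the factor that best
    # superimposes the scaled biopsy distribution on the resection one.
    dists = [
        wasserstein_distance(s * biopsy_vafs, resection_vafs) for s in WASSERSTEIN_GRID
    ]
    return float(WASSERSTEIN_GRID[int(np.argmin(dists))]), "wasserstein_grid"


def estimate_biopsy_purity(
    case: PatientCase,
    resection_purity: PurityEstimate,
    min_shared: int = 10,
    posterior_min: float = DEFAULT_POSTERIOR_MIN,
) -> PurityEstimate:
    """Transfer the resection purity to the biopsy by distribution scaling.

    The factor ``s`` maps biopsy VAFs onto resection VAFs (resection ~= s *
    biopsy); since the same tumor cell fractions generate both spectra, the
    biopsy purity is ``resection_purity / s``.  ``s`` is the median per-variant
    VAF ratio when at least ``min_shared`` variants are observed (VAF > 0) in
    both samples, and otherwise the minimizer of the 1-Wasserstein distance
    between the scaled biopsy and the resection VAF distributions over the
    grid s in [0.1, 10] (step 0.05).
    """
    if resection_purity.status != "known":
        raise ValueError("resection purity must be known to scale the biopsy")
    somatic = [v for v in case.variants if v.somatic_posterior >= posterior_min]
    fb = np.array([v.vaf_biopsy for v in somatic], dtype=float)
    fr = np.array([v.vaf_resection for v in somatic], dtype=float)
    fb = np.nan_to_num(fb, nan=0.0)
    fr = np.nan_to_num(fr, nan=0.0)
    nonzero_b = fb[fb > 0]
    if nonzero_b.size < 3:
        logger.warning(
            "%s: only %d nonzero biopsy VAFs, biopsy purity unknown",
            case.patient_id, nonzero_b.size,
        )
        return PurityEstimate.unknown(method="scaled_from_resection")
    shared = (fb > 0) & (fr > 0)
    ratios = fr[shared] / fb[shared]
    s, how = _scaling_factor(nonzero_b, fr[fr > 0], ratios, min_shared)
    logger.debug("%s: biopsy scaling s=%.3f via %s", case.patient_id, s, how)
    value = min(1.0, resection_purity.value / s)
    if value <= 0:
        return PurityEstimate.unknown(method="scaled_from_resection")
    return PurityEstimate.known(value, method="scaled_from_resection", s=s)


def estimate_case_purities(
    case: PatientCase,
    quantile: float = DEFAULT_QUANTILE,
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_disagreement: float = MAX_DISAGREEMENT,
    min_shared: int = 10,
    posterior_min: float = DEFAULT_POSTERIOR_MIN,
) -> PatientCase:
    """Fill ``purity_resection`` and ``purity_biopsy`` on ``case`` in place."""
    v = robust_max_vaf(
        case.variants, RESECTION, quantile=quantile, min_depth=min_depth,
        posterior_min=posterior_min,
    )
    if v is None:
        case.purity_resection = PurityEstimate.unknown(method="vaf_max_consistent")
    else:
        case.purity_resection = resolve_resection_purity(
            v, case.p1, case.p2, max_disagreement=max_disagreement
        )
        if case.purity_resection.value == 0.0:
            # a purity of zero carries no analyzable tumor signal
            logger.warning("%s: resection purity resolved to 0; treating as unknown",
                           case.patient_id)
            case.purity_resection = PurityEstimate.unknown(
                method="vaf_max_consistent", v=v
            )
    if case.purity_resection.status == "known":
        case.purity_biopsy = estimate_biopsy_purity(
            case, case.purity_resection, min_shared=min_shared,
            posterior_min=posterior_min,
        )
    else:
        case.purity_biopsy = PurityEstimate.unknown(method="scaled_from_resection")
    return case
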