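"""Candidate resistance-variant filtering and VAF-change evidence.

Reportable candidates are nonsynonymous variants predicted pathogenic (when a
pathogenicity score is available), rare in the population, not labelled
(likely) benign, and hitting a supplied cancer-gene list.  Two probabilistic
scores accompany them: the probability that a variant is absent from the
matched normal (sequencing noise vs germline het, two-hypothesis binomial
model) and the probability that its purity-adjusted cellular frequency
changed between biopsy and resection (difference of Jeffreys-prior Beta
posteriors, Monte-Carlo).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .data import VariantCall

logger = logging.getLogger(__name__)

NONSYNONYMOUS = frozenset(
    {
        "missense", "missense_variant", "stop_gained", "stop_lost",
        "start_lost", "frameshift", "frameshift_variant",
        "inframe_insertion", "inframe_deletion", "nonsynonymous",
        "splice_acceptor_variant", "splice_donor_variant",
    }
)


@dataclass
class FilterPolicy:
    """Thresholds for the reportable-variant filter.

    Defaults follow the primary reporting policy (pathogenicity score > 0.5,
    population AF < 0.2, benign/likely-benign excluded); a stricter
    supplementary policy raises ``revel_min`` to 0.7.
    """

    require_nonsynonymous: bool = True
    revel_min: float = 0.5
    gnomad_max: float = 0.2
    excluded_clinical_labels: frozenset[str] = frozenset({"benign", "likely_benign"})
    gene_list: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        for t in (self.revel_min, self.gnomad_max):
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"threshold out of [0,1]: {t}")

STRICT_POLICY = FilterPolicy(revel_min=0.7)


def _rejection_reason(var: VariantCall, policy: FilterPolicy) -> str | None:
    ann = var.annotations
    if policy.require_nonsynonymous:
        cons = str(ann.get("consequence", "")).lower()
        if cons not in NONSYNONYMOUS:
            return "consequence"
    score = ann.get("pathogenicity_score")
    # "if available": variants without a score pass this clause.
    if score is not None and score <= policy.revel_min:
        return "pathogenicity"
    af = ann.get("population_af", 0.0) or 0.0
    if af >= policy.gnomad_max:
        return "population_af"
    label = str(ann.get("clinical_significance", "")).lower().replace(" ", "_")
    if label in policy.excluded_clinical_labels:
        return "clinical_significance"
    if policy.gene_list is not None and ann.get("gene") not in policy.gene_list:
        return "gene_list"
    return None


def filter_reportable(
    variants: Iterable[VariantCall], policy: FilterPolicy = FilterPolicy()
) -> tuple[list[VariantCall], Counter]:
    """Apply the reportability policy; returns (survivors, rejection tallies)."""
    kept: list[VariantCall] = []
    reasons: Counter = Counter()
    for var in variants:
        reason = _rejection_reason(var, policy)
        if reason is None:
            kept.append(var)
        else:
            reasons[reason] += 1
    if reasons:
        logger.info("filter_reportable rejections: %s", dict(reasons))
    return kept, reasons


def prob_absent_in_normal(
    alt_normal: int, depth_normal: int, error_rate: float = 0.001
) -> float:
    """Posterior probability the normal-sample alt reads are sequencing noise.

    Two-hypothesis model under equal priors: alt ~ Binomial(depth, error_rate)
    (variant absent) versus alt ~ Binomial(depth, 0.5) (germline het).  Zero
    depth is uninformative and returns 0.5.
    """
    if alt_normal > depth_normal:
        raise ValueError("alt_normal > depth_normal")
    if depth_normal == 0:
        return 0.5
    l_noise = stats.binom.logpmf(alt_normal, depth_normal, error_rate)
    l_het = stats.binom.logpmf(alt_normal, depth_normal, 0.5)
    # log-sum-exp for numerical stability at large depth
    m = max(l_noise, l_het)
    return float(np.exp(l_noise - m) / (np.exp(l_noise - m) + np.exp(l_het - m)))


def prob_vaf_changed(
    alt_b: int,
    depth_b: int,
    purity_b: float,
    alt_r: int,
    depth_r: int,
    purity_r: float,
    delta: float = 0.05,
    n_draws: int = 20_000,
    rng: np.random.Generator | int | None = 0,
) -> float:
    """Probability that the purity-adjusted cellular frequency changed.

    Each sample's VAF gets an independent Jeffreys-prior Beta posterior,
    Beta(alt + 1/2, depth - alt + 1/2); Monte-Carlo draws estimate
    P(|f_b / purity_b - f_r / purity_r| > delta).  Seeded and deterministic
    by default.
    """
    if purity_b is None or purity_r is None or purity_b <= 0 or purity_r <= 0:
        raise ValueError("both purities must be known and positive")
    if alt_b > depth_b or alt_r > depth_r:
        raise ValueError("alt reads exceed depth")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    fb = rng.beta(alt_b + 0.5, depth_b - alt_b + 0.5, size=n_draws)
    fr = rng.beta(alt_r + 0.5, depth_r - alt_r + 0.5, size=n_draws)
    return float(np.mean(np.abs(fb / purity_b - fr / purity_r) > delta))
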