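"""Core domain types for paired biopsy/resection somatic variant analysis.

A single somatic variant acts as the proxy for the subclone it founded, so
the per-variant read counts in the two samples carry all the information the
downstream purity and subclone-dynamics estimators use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

BIOPSY = "biopsy"
RESECTION = "resection"
SAMPLES = (BIOPSY, RESECTION)


@dataclass
class VariantCall:
    """One somatic variant with per-sample depth and alt-read counts.

    Coordinates follow the VCF convention (1-based, inclusive).  Multi-allelic
    records are split upstream, so ``alt`` is always a single allele.

    Parameters
    ----------
    somatic_posterior : float
        Probability in [0, 1] that the variant is somatic in the biopsy or
        the resection (taken from the caller's posterior tag).
    annotations : dict
        Optional keys: ``pathogenicity_score`` (REVEL-style, in [0, 1]),
        ``population_af`` (gnomAD-style), ``clinical_significance``,
        ``gene``, ``consequence``.
    alt_normal, depth_normal : int, optional
        Matched-normal counts, when a normal sample column is present.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth_biopsy: int
    alt_biopsy: int
    depth_resection: int
    alt_resection: int
    somatic_posterior: float = 1.0
    annotations: dict = field(default_factory=dict)
    alt_normal: Optional[int] = None
    depth_normal: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for s in SAMPLES:
            a, d = self.alt_reads(s), self.depth(s)
            if a < 0 or d < 0 or a > d:
                raise ValueError(
                    f"invalid counts in {s} at {self.chrom}:{self.pos}: alt={a} depth={d}"
                )
        if not 0.0 <= self.somatic_posterior <= 1.0:
            raise ValueError(f"somatic_posterior out of [0,1]: {self.somatic_posterior}")

    def depth(self, sample: str) -> int:
        return self.depth_biopsy if sample == BIOPSY else self.depth_resection

    def alt_reads(self, sample: str) -> int:
        return self.alt_biopsy if sample == BIOPSY else self.alt_resection

    def vaf(self, sample: str) -> float:
        """Variant allele frequency in ``sample``; NaN when depth is zero."""
        d = self.depth(sample)
        if d == 0:
            return math.nan
        return self.alt_reads(sample) / d

    @property
    def vaf_biopsy(self) -> float:
        return self.vaf(BIOPSY)

    @property
    def vaf_resection(self) -> float:
        return self.vaf(RESECTION)


@dataclass
class PurityEstimate:
    """Per-sample tumor purity on the allele scale (maximal attainable VAF).

    ``status`` is ``"known"`` iff ``value`` is present.  ``method`` records the
    provenance: ``vaf_max_consistent`` (resection rule), ``scaled_from_resection``
    (biopsy transfer), or ``simulated_truth``.  ``v`` is the robust maximal VAF
    used and ``s`` the biopsy-to-resection scaling factor, when applicable.
    """

    value: Optional[float] = None
    status: str = "unknown"
    method: Optional[str] = None
    v: Optional[float] = None
    s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status not in ("known", "unknown"):
            raise ValueError(f"bad status {self.status!r}")
        if (self.status == "known") != (self.value is not None):
            raise ValueError("status='known' iff value present")
        # value 0 is representable (degenerate no-tumor-signal decision) but is
        # downgraded to unknown before any use of purity as a divisor.
        if self.value is not None and not 0.0 <= self.value <= 1.0:
            raise ValueError(f"purity out of [0,1]: {self.value}")
        if self.s is not None and self.s <= 0:
            raise ValueError(f"scaling factor must be > 0: {self.s}")

    @classmethod
    def known(cls, value: float, method: str, v: float | None = None,
              s: float | None = None) -> "PurityEstimate":
        return cls(value=value, status="known", method=method, v=v, s=s)

    @classmethod
    def unknown(cls, method: str | None = None, v: float | None = None) -> "PurityEstimate":
        return cls(value=None, status="unknown", method=method, v=v)


@dataclass
class SubcloneDynamics:
    """Lost / gained / retained subclone counts for one patient.

    ``n_total`` counts qualifying subclones in the union of both samples;
    ``n_resection`` restricts to subclones qualifying in the resection.
    Fractions use ``n_total`` as the denominator, so
    ``n_lost + n_gained + n_retained == n_total`` is a partition.
    """

    n_total: int = 0
    n_lost: int = 0
    n_gained: int = 0
    n_retained: int = 0
    n_resection: int = 0
    fraction_lost: float = 0.0
    fraction_gained: float = 0.0
    analyzable: bool = False

    def __post_init__(self) -> None:
        if self.n_lost + self.n_gained + self.n_retained != self.n_total:
            raise ValueError("lost + gained + retained must equal total")
        if self.analyzable != (self.n_total > 0):
            raise ValueError("analyzable iff n_total > 0")
        for f in (self.fraction_lost, self.fraction_gained):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction out of [0,1]: {f}")

    @classmethod
    def from_counts(cls, n_lost: int, n_gained: int, n_retained: int,
                    n_resection: int = 0) -> "SubcloneDynamics":
        n_total = n_lost + n_gained + n_retained
        return cls(
            n_total=n_total,
            n_lost=n_lost,
            n_gained=n_gained,
            n_retained=n_retained,
            n_resection=n_resection,
            fraction_lost=n_lost / n_total if n_total else 0.0,
            fraction_gained=n_gained / n_total if n_total else 0.0,
            analyzable=n_total > 0,
        )


@dataclass
class PatientCase:
    """Paired biopsy + resection observations for one patient.

    ``p1`` and ``p2`` are the two pathologists' purity estimates of the
    resection sample (``p1 <= p2``); ``regression_percent`` is the pathological
    regression (percentage reduction of viable tumor cells) in [0, 100].
    Purity estimates and dynamics are filled in by the respective modules.
    """

    patient_id: str
    variants: list[VariantCall] = field(default_factory=list)
    p1: float = 0.0
    p2: float = 1.0
    regression_percent: Optional[float] = None
    purity_biopsy: Optional[PurityEstimate] = None
    purity_resection: Optional[PurityEstimate] = None
    dynamics: Optional[SubcloneDynamics] = None

    def __post_init__(self) -> None:
        if self.p1 > self.p2:
            raise ValueError(f"p1 > p2 ({self.p1} > {self.p2}) for {self.patient_id}")
        for p in (self.p1, self.p2):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"pathologist purity out of [0,1]: {p}")

    @property
    def purities_known(self) -> bool:
        return (
            self.purity_biopsy is not None
            and self.purity_biopsy.status == "known"
            and self.purity_resection is not None
            and self.purity_resection.status == "known"
        )
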