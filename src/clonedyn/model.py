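"""Model/Results interface over the paired-sample subclonal analysis.

:class:`PairedTumorModel` wraps one patient's paired observations together
with the analysis thresholds; :meth:`PairedTumorModel.fit` runs purity
estimation followed by subclone classification and returns a
:class:`PairedTumorResults` carrying the estimates, the per-variant
classification, and derived products (spectrum curves, VAF-change
probabilities, a summary table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import dynamics as _dyn
from . import purity as _purity
from . import prioritize as _prio
from . import spectrum as _spec
from .data import BIOPSY, RESECTION, PatientCase, PurityEstimate, SubcloneDynamics


@dataclass
class PairedTumorModel:
    """Subclonal-dynamics model for one patient's biopsy/resection pair.

    Parameters mirror the pipeline defaults: variants qualify at somatic
    posterior >= ``posterior_min`` and purity-adjusted VAF >= ``vaf_min``,
    with an expectation of at least ``min_reads`` reads in the other sample;
    resection purity is the ``quantile`` of the somatic VAF distribution
    (depth >= ``min_depth``) reconciled with the pathologist priors
    (agreement window ``max_disagreement``).
    """

    case: PatientCase
    posterior_min: float = 0.95
    vaf_min: float = 0.1
    min_reads: float = 2.0
    quantile: float = 0.98
    min_depth: int = 30
    max_disagreement: float = 0.2
    min_shared: int = 10

    @classmethod
    def from_vcf(
        cls,
        vcf_path,
        sample_names,
        priors=(0.0, 1.0),
        regression=None,
        patient_id=None,
        **kwargs,
    ) -> "PairedTumorModel":
        from .io import read_paired_case

        case = read_paired_case(
            vcf_path, sample_names, priors=priors, regression=regression,
            patient_id=patient_id,
        )
        return cls(case, **kwargs)

    def fit(self, purities: Optional[tuple[PurityEstimate, PurityEstimate]] = None
            ) -> "PairedTumorResults":
        """Estimate purities (unless supplied) and classify subclones."""
        case = self.case
        if purities is not None:
            case.purity_biopsy, case.purity_resection = purities
        else:
            _purity.estimate_case_purities(
                case,
                quantile=self.quantile,
                min_depth=self.min_depth,
                max_disagreement=self.max_disagreement,
                min_shared=self.min_shared,
                posterior_min=self.posterior_min,
            )
        dyn = None
        if case.purities_known:
            dyn = _dyn.classify_subclones(
                case,
                posterior_min=self.posterior_min,
                vaf_min=self.vaf_min,
                min_reads=self.min_reads,
            )
        return PairedTumorResults(model=self, case=case, dynamics=dyn)


@dataclass
class PairedTumorResults:
    """Fitted estimates for one patient."""

    model: PairedTumorModel
    case: PatientCase
    dynamics: Optional[SubcloneDynamics]

    @property
    def purity_biopsy(self) -> PurityEstimate:
        return self.case.purity_biopsy

    @property
    def purity_resection(self) -> PurityEstimate:
        return self.case.purity_resection

    @property
    def analyzable(self) -> bool:
        return self.dynamics is not None and self.dynamics.analyzable

    def spectrum(self, sample: str = RESECTION, vaf_grid=None,
                 region_mb: float = _spec.DEFAULT_REGION_MB) -> _spec.SpectrumCurve:
        grid = vaf_grid if vaf_grid is not None else _spec.DEFAULT_VAF_GRID
        return _spec.spectrum_curve(
            self.case.variants, sample, vaf_grid=grid, region_mb=region_mb,
            posterior_min=self.model.posterior_min,
        )

    def vaf_change_probabilities(self, delta: float = 0.05,
                                 n_draws: int = 20_000, seed: int = 0) -> pd.DataFrame:
        """Per-variant probability of a changed purity-adjusted frequency."""
        if not self.case.purities_known:
            raise ValueError("purities unknown; cannot adjust VAFs")
        import numpy as np

        rng = np.random.default_rng(seed)
        rows = []
        for v in self.case.variants:
            p = _prio.prob_vaf_changed(
                v.alt_biopsy, v.depth_biopsy, self.purity_biopsy.value,
                v.alt_resection, v.depth_resection, self.purity_resection.value,
                delta=delta, n_draws=n_draws, rng=rng,
            )
            row = {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "gene": v.annotations.get("gene"),
                "vaf_biopsy": v.vaf_biopsy, "vaf_resection": v.vaf_resection,
                "prob_vaf_changed": p,
            }
            if v.depth_normal is not None:
                row["prob_absent_in_normal"] = _prio.prob_absent_in_normal(
                    v.alt_normal, v.depth_normal
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary."""
        c = self.case
        lines = [
            "Paired tumor subclonal dynamics",
            "=" * 47,
            f"patient:              {c.patient_id}",
            f"variants:             {len(c.variants)}",
            f"pathologist priors:   [{c.p1:.2f}, {c.p2:.2f}]",
        ]
        for label, est in (
            ("purity (resection):", c.purity_resection),
            ("purity (biopsy):   ", c.purity_biopsy),
        ):
            if est is None:
                lines.append(f"{label}   (not estimated)")
            elif est.status == "known":
                extra = []
                if est.v is not None:
                    extra.append(f"v={est.v:.3f}")
                if est.s is not None:
                    extra.append(f"s={est.s:.3f}")
                suffix = f" ({', '.join(extra)})" if extra else ""
                lines.append(f"{label}   {est.value:.3f} [{est.method}]{suffix}")
            else:
                lines.append(f"{label}   unknown [{est.method}]")
        d = self.dynamics
        if d is None:
            lines.append("subclone dynamics:    not computed (unknown purity)")
        elif not d.analyzable:
            lines.append("subclone dynamics:    not analyzable (no qualifying subclones)")
        else:
            lines += [
                f"subclones (total):    {d.n_total}",
                f"subclones (resection):{d.n_resection:>5}",
                f"lost / gained / kept: {d.n_lost} / {d.n_gained} / {d.n_retained}",
                f"fraction lost:        {d.fraction_lost:.3f}",
                f"fraction gained:      {d.fraction_gained:.3f}",
            ]
        return "\n".join(lines)


def fit_cohort(
    cases: Sequence[PatientCase], **model_kwargs
) -> list[PairedTumorResults]:
    """Fit every case; returns one results object per patient (all of them,
    including those with unknown purity — cohort tables filter downstream)."""
    return [PairedTumorModel(case, **model_kwargs).fit() for case in cases]
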