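"""Mutational-spectrum curves: mutations per megabase vs minimal VAF.

Single-base substitutions are collapsed to the pyrimidine-reference
convention (six classes C>A, C>G, C>T, T>A, T>C, T>G); equal-length
multi-base substitutions are "MNV"; everything else (indels, mixed shapes)
is "complex".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import VariantCall

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G", "complex", "MNV")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

DEFAULT_REGION_MB = 1.94  # typical coding footprint of a ~500-gene panel
DEFAULT_VAF_GRID = tuple(np.round(np.arange(0.0, 1.0 + 1e-9, 0.05), 10))


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def classify_substitution(ref: str, alt: str) -> str:
    """Substitution class of a (ref, alt) allele pair.

    Purine-reference single-base pairs are reverse-complemented onto the
    pyrimidine strand, so e.g. G>T reports as C>A.
    """
    if not ref or not alt:
        raise ValueError("empty allele string")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r})")
    ref, alt = ref.upper(), alt.upper()
    if len(ref) == 1 and len(alt) == 1:
        if ref in ("A", "G"):
            ref, alt = revcomp(ref), revcomp(alt)
        label = f"{ref}>{alt}"
        return label if label in SUBSTITUTION_CLASSES else "complex"
    if len(ref) == len(alt) and set(ref + alt) <= set("ACGT"):
        return "MNV"
    return "complex"


@dataclass
class SpectrumCurve:
    """Cumulative per-class mutation counts/densities along a minimal-VAF grid."""

    sample: str
    vaf_grid: tuple[float, ...]
    region_mb: float
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def density(self, cls: str) -> np.ndarray:
        return self.counts[cls] / self.region_mb

    def total_counts(self) -> np.ndarray:
        return np.sum([self.counts[c] for c in SUBSTITUTION_CLASSES], axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in SUBSTITUTION_CLASSES:
            for t, n in zip(self.vaf_grid, self.counts[cls]):
                rows.append(
                    {
                        "sample": self.sample,
                        "class": cls,
                        "vaf_threshold": t,
                        "count": int(n),
                        "per_mb": n / self.region_mb,
                    }
                )
        return pd.DataFrame(rows)


def spectrum_curve(
    variants: Iterable[VariantCall],
    sample: str,
    vaf_grid: Sequence[float] = DEFAULT_VAF_GRID,
    region_mb: float = DEFAULT_REGION_MB,
    posterior_min: float = 0.95,
) -> SpectrumCurve:
    """Count somatic variants with VAF >= t per class at each grid threshold t."""
    grid = np.asarray(vaf_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty VAF grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("VAF grid must be strictly ascending")
    if region_mb <= 0:
        raise ValueError("region_mb must be > 0")
    counts = {cls: np.zeros(grid.size, dtype=int) for cls in SUBSTITUTION_CLASSES}
    for var in variants:
        if var.somatic_posterior < posterior_min:
            continue
        f = var.vaf(sample)
        if not np.isfinite(f):
            continue
        cls = classify_substitution(var.ref, var.alt)
        counts[cls] += f >= grid
    return SpectrumCurve(sample=sample, vaf_grid=tuple(grid), region_mb=region_mb,
                         counts=counts)
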