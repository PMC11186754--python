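"""Synthetic paired biopsy/resection cohorts with known clonal structure.

The generative model mirrors the assumptions the inference makes: each
nonlethal somatic mutation founds one subclone, so a clone tree with
per-clone mutation lists fully determines which mutations each tumor cell
carries.  Pre-therapy subclone population fractions are Dirichlet; therapy
multiplies them by per-clone survival factors (a killed clone's own cells
vanish, its descendants persist unless also killed) and renormalizes.  The
biopsy may spatially miss a clone, which removes that clone's whole subtree
from the biopsy sample.  Observed reads are Binomial draws at Poisson depths
from expected VAF = cellular prevalence x allele-scale purity, so the purity
bound (no somatic VAF above the purity) holds by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .data import PatientCase, PurityEstimate, VariantCall

_BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    """Study conditions for one simulated patient.

    ``selection`` is either a fraction in [0, 1] of non-root clones killed at
    random, or an explicit sequence of per-clone survival multipliers (length
    ``n_clones``; the root is clone 0).  ``mutations_per_clone`` is a Poisson
    mean; ``truncal_mutations`` overrides it for the root clone when set.
    Purities are on the allele scale (the maximal attainable somatic VAF).
    ``p_error`` is the half-width of the pathologist-prior noise around the
    true resection purity.  ``germline_contaminants`` adds that many
    germline-like variants (VAF ~ 0.5 in every sample) with somatic posterior
    below the 0.95 filter.
    """

    n_clones: int = 8
    mutations_per_clone: float = 10.0
    truncal_mutations: Optional[float] = None
    pre_prevalence: float = 5.0  # Dirichlet concentration per clone
    selection: Union[float, Sequence[float]] = 0.0
    spatial_miss_prob: float = 0.05
    purity_biopsy: float = 0.4
    purity_resection: float = 0.4
    mean_depth_biopsy: float = 150.0
    mean_depth_resection: float = 150.0
    p_error: float = 0.1
    germline_contaminants: int = 5
    topology: str = "random"  # "random" parent attachment or "star"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        for p in (self.spatial_miss_prob, self.purity_biopsy, self.purity_resection):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if min(self.mean_depth_biopsy, self.mean_depth_resection) <= 0:
            raise ValueError("depths must be > 0")
        if self.topology not in ("random", "star"):
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass
class SimTruth:
    """Ground truth for one simulated patient.

    Prevalences are cellular (subtree-summed subclone fractions); the
    ideal-observation lost/gained sets apply the classification thresholds at
    infinite depth, i.e. lost = mutation with resection prevalence exactly 0
    and biopsy prevalence >= 0.1, and symmetrically for gained.
    """

    parents: list[int]
    clone_mutations: list[list[int]]
    phi_pre: list[float]          # subclone fractions, resection-side pre-therapy
    phi_post: list[float]         # after selection + renormalization
    phi_biopsy: list[float]       # pre-therapy fractions after spatial miss
    biopsy_present: list[bool]
    purity_biopsy: float
    purity_resection: float
    lost_mutations: list[int]
    gained_mutations: list[int]
    n_qualifying_ideal: int
    fraction_lost_ideal: float
    fraction_gained_ideal: float
    mutation_prevalence_biopsy: list[float]
    mutation_prevalence_resection: list[float]

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _subtree_members(parents: Sequence[int]) -> list[list[int]]:
    """For each clone, the indices of its subtree (itself + all descendants)."""
    n = len(parents)
    children: list[list[int]] = [[] for _ in range(n)]
    for c in range(1, n):
        children[parents[c]].append(c)
    subtree: list[list[int]] = [[] for _ in range(n)]

    def collect(node: int) -> list[int]:
        members = [node]
        for ch in children[node]:
            members.extend(collect(ch))
        subtree[node] = members
        return members

    collect(0)
    return subtree


def _cellular_prevalence(phi: np.ndarray, subtree: list[list[int]]) -> np.ndarray:
    return np.array([phi[m].sum() for m in subtree])


def _survival(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    n = params.n_clones
    if np.isscalar(params.selection):
        frac = float(params.selection)
        if not 0.0 <= frac <= 1.0:
            raise ValueError("kill fraction must lie in [0,1]")
        surv = np.ones(n)
        n_kill = int(round(frac * (n - 1)))
        if n_kill:
            killed = rng.choice(np.arange(1, n), size=n_kill, replace=False)
            surv[killed] = 0.0
        return surv
    surv = np.asarray(params.selection, dtype=float)
    if surv.shape != (n,):
        raise ValueError("per-clone survival needs one multiplier per clone")
    if np.any(surv < 0):
        raise ValueError("survival multipliers must be >= 0")
    return surv


_MAX_RETRIES = 20


def simulate_case(
    params: SimParams, patient_id: str = "SIM-001"
) -> tuple[PatientCase, SimTruth]:
    """Generate one paired case plus its ground truth; deterministic in the seed."""
    rng = np.random.default_rng(params.seed)
    for attempt in range(_MAX_RETRIES):
        result = _try_simulate(params, patient_id, rng)
        if result is not None:
            return result
    raise RuntimeError(
        f"{patient_id}: degenerate prevalences in {_MAX_RETRIES} attempts"
    )


def _try_simulate(
    params: SimParams, patient_id: str, rng: np.random.Generator
) -> tuple[PatientCase, SimTruth] | None:
    n = params.n_clones
    # Clone tree: clone 0 is the truncal root; others attach to a random
    # earlier clone (or all to the root for the star topology).
    if params.topology == "star" or n == 1:
        parents = [0] * n
        parents[0] = -1
    else:
        parents = [-1] + [int(rng.integers(0, c)) for c in range(1, n)]
    subtree = _subtree_members(parents)

    mut_means = np.full(n, params.mutations_per_clone, dtype=float)
    if params.truncal_mutations is not None:
        mut_means[0] = params.truncal_mutations
    n_mut = rng.poisson(mut_means)
    clone_mutations: list[list[int]] = []
    idx = 0
    for c in range(n):
        clone_mutations.append(list(range(idx, idx + int(n_mut[c]))))
        idx += int(n_mut[c])
    n_variants = idx
    if n_variants == 0:
        return None

    phi_pre = rng.dirichlet(np.full(n, params.pre_prevalence))
    surv = _survival(params, rng)
    phi_post = phi_pre * surv
    if phi_post.sum() <= 0:
        return None
    phi_post = phi_post / phi_post.sum()

    # Spatial miss: each non-root clone absent from the biopsy with the given
    # probability; a missed clone takes its whole subtree with it.
    present = np.ones(n, dtype=bool)
    for c in range(1, n):
        if rng.random() < params.spatial_miss_prob:
            present[subtree[c]] = False
    phi_biopsy = phi_pre * present
    if phi_biopsy.sum() <= 0:
        return None
    phi_biopsy = phi_biopsy / phi_biopsy.sum()

    prev_biopsy_clone = _cellular_prevalence(phi_biopsy, subtree)
    prev_resection_clone = _cellular_prevalence(phi_post, subtree)

    mut_clone = np.empty(n_variants, dtype=int)
    for c, muts in enumerate(clone_mutations):
        mut_clone[muts] = c
    prev_b = prev_biopsy_clone[mut_clone]
    prev_r = prev_resection_clone[mut_clone]

    variants = _draw_reads(params, rng, prev_b, prev_r)
    variants.extend(_germline_contaminants(params, rng, start_pos=len(variants)))

    lost = [m for m in range(n_variants) if prev_r[m] == 0.0 and prev_b[m] >= 0.1]
    gained = [m for m in range(n_variants) if prev_b[m] == 0.0 and prev_r[m] >= 0.1]
    qualifying = [m for m in range(n_variants) if prev_b[m] >= 0.1 or prev_r[m] >= 0.1]
    nq = len(qualifying)

    u1, u2 = rng.uniform(0.0, params.p_error, size=2)
    p1 = float(np.clip(params.purity_resection - u1, 0.0, 1.0))
    p2 = float(np.clip(params.purity_resection + u2, 0.0, 1.0))

    case = PatientCase(
        patient_id=patient_id,
        variants=variants,
        p1=p1,
        p2=p2,
        regression_percent=float(np.round(rng.uniform(0, 100), 1)),
    )
    truth = SimTruth(
        parents=parents,
        clone_mutations=clone_mutations,
        phi_pre=phi_pre.tolist(),
        phi_post=phi_post.tolist(),
        phi_biopsy=phi_biopsy.tolist(),
        biopsy_present=present.tolist(),
        purity_biopsy=params.purity_biopsy,
        purity_resection=params.purity_resection,
        lost_mutations=lost,
        gained_mutations=gained,
        n_qualifying_ideal=nq,
        fraction_lost_ideal=len(lost) / nq if nq else 0.0,
        fraction_gained_ideal=len(gained) / nq if nq else 0.0,
        mutation_prevalence_biopsy=prev_b.tolist(),
        mutation_prevalence_resection=prev_r.tolist(),
    )
    return case, truth


def _draw_alleles(rng: np.random.Generator) -> tuple[str, str]:
    shape = rng.random()
    if shape < 0.94:  # SNV
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice([b for b in _BASES if b != ref]))
    elif shape < 0.97:  # dinucleotide MNV
        ref = "".join(rng.choice(_BASES, size=2))
        alt = "".join(rng.choice(_BASES, size=2))
        while alt == ref:
            alt = "".join(rng.choice(_BASES, size=2))
    else:  # small insertion (classed "complex" downstream)
        ref = str(rng.choice(_BASES))
        alt = ref + str(rng.choice(_BASES))
    return ref, alt


def _draw_reads(
    params: SimParams,
    rng: np.random.Generator,
    prev_b: np.ndarray,
    prev_r: np.ndarray,
) -> list[VariantCall]:
    n_variants = prev_b.size
    exp_vaf_b = prev_b * params.purity_biopsy
    exp_vaf_r = prev_r * params.purity_resection
    depth_b = rng.poisson(params.mean_depth_biopsy, size=n_variants)
    depth_r = rng.poisson(params.mean_depth_resection, size=n_variants)
    alt_b = rng.binomial(depth_b, exp_vaf_b)
    alt_r = rng.binomial(depth_r, exp_vaf_r)
    variants = []
    for m in range(n_variants):
        ref, alt = _draw_alleles(rng)
        depth_n = int(rng.poisson(params.mean_depth_biopsy))
        variants.append(
            VariantCall(
                chrom="chr1",
                pos=1000 * (m + 1),
                ref=ref,
                alt=alt,
                depth_biopsy=int(depth_b[m]),
                alt_biopsy=int(alt_b[m]),
                depth_resection=int(depth_r[m]),
                alt_resection=int(alt_r[m]),
                somatic_posterior=1.0,
                alt_normal=int(rng.binomial(depth_n, 0.001)),
                depth_normal=depth_n,
            )
        )
    return variants


def _germline_contaminants(
    params: SimParams, rng: np.random.Generator, start_pos: int
) -> list[VariantCall]:
    out = []
    for g in range(params.germline_contaminants):
        db = int(rng.poisson(params.mean_depth_biopsy))
        dr = int(rng.poisson(params.mean_depth_resection))
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        out.append(
            VariantCall(
                chrom="chr1",
                pos=1000 * (start_pos + g + 1),
                ref=ref,
                alt=alt,
                depth_biopsy=db,
                alt_biopsy=int(rng.binomial(db, 0.5)),
                depth_resection=dr,
                alt_resection=int(rng.binomial(dr, 0.5)),
                somatic_posterior=float(rng.uniform(0.0, 0.5)),
            )
        )
    return out


def truth_purities(case: PatientCase, truth: SimTruth) -> PatientCase:
    """Attach ground-truth purities to a simulated case (method='simulated_truth')."""
    case.purity_biopsy = PurityEstimate.known(truth.purity_biopsy, "simulated_truth")
    case.purity_resection = PurityEstimate.known(
        truth.purity_resection, "simulated_truth"
    )
    return case


def simulate_cohort(
    n_patients: int,
    params: Union[SimParams, Sequence[SimParams]],
    seed: int = 0,
    out_dir: Union[str, Path, None] = None,
) -> list[tuple[PatientCase, SimTruth]]:
    """Simulate ``n_patients`` independent cases from per-patient substreams.

    When ``out_dir`` is given, each case is written as a multi-sample VCF in
    the dialect :mod:`clonedyn.io` reads, with a priors CSV and a truth JSON
    alongside.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    from dataclasses import replace

    if isinstance(params, SimParams):
        param_list = [params] * n_patients
    else:
        param_list = list(params)
        if len(param_list) != n_patients:
            raise ValueError("need one SimParams per patient")
    substreams = np.random.SeedSequence(seed).spawn(n_patients)
    cohort = []
    for i, (p, ss) in enumerate(zip(param_list, substreams)):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        case, truth = simulate_case(
            replace(p, seed=sub_seed), patient_id=f"SIM-{i + 1:03d}"
        )
        cohort.append((case, truth))
    if out_dir is not None:
        from .io import write_cohort_inputs

        write_cohort_inputs(cohort, out_dir)
    return cohort
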