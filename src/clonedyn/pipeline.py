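"""End-to-end orchestration: read -> purity -> dynamics -> spectrum ->
prioritization -> report, from one YAML config, with a fixed output layout.

Output directory layout::

    purity.tsv            per-sample purity estimates and provenance
    cohort_dynamics.tsv   one row per analyzable patient (bubble-plot data)
    exclusions.tsv        omitted patients with reasons
    spectrum_biopsy.tsv / spectrum_resection.tsv
    prioritization.tsv    reportable candidates with change probabilities
    manifest.json         config echo, package version, seed
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .data import BIOPSY, RESECTION, PatientCase
from .dynamics import summarize_cohort
from .io import (
    SIM_SAMPLE_NAMES,
    read_paired_case,
    read_priors,
    write_exclusion_log,
)
from .model import PairedTumorModel
from .prioritize import FilterPolicy, filter_reportable
from .spectrum import DEFAULT_REGION_MB, DEFAULT_VAF_GRID, spectrum_curve

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run.  Threshold defaults are the analysis constants:
    somatic posterior >= 0.95, purity-adjusted VAF >= 0.1, expected reads
    >= 2, pathologist agreement p2 - p1 <= 0.2, pathogenicity score > 0.5,
    population AF < 0.2."""

    vcf_dir: str = "."
    priors_csv: str = "priors.csv"
    out_dir: str = "results"
    sample_names: dict = field(default_factory=lambda: dict(SIM_SAMPLE_NAMES))
    gene_list_file: Optional[str] = None
    posterior_min: float = 0.95
    vaf_min: float = 0.1
    min_reads: float = 2.0
    max_disagreement: float = 0.2
    quantile: float = 0.98
    min_depth: int = 30
    region_mb: float = DEFAULT_REGION_MB
    revel_min: float = 0.5
    gnomad_max: float = 0.2
    delta: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("posterior_min", "vaf_min", "max_disagreement", "quantile",
                     "revel_min", "gnomad_max", "delta"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {val}")
        if self.min_reads < 0 or self.min_depth < 0 or self.region_mb <= 0:
            raise ValueError("min_reads/min_depth must be >= 0, region_mb > 0")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_cases(config: RunConfig) -> tuple[list[PatientCase], list[tuple[str, str]]]:
    priors = read_priors(config.priors_csv)
    cases, failures = [], []
    for pid, info in sorted(priors.items()):
        vcf = Path(config.vcf_dir) / f"{pid}.vcf"
        try:
            cases.append(
                read_paired_case(
                    vcf,
                    config.sample_names,
                    priors=(info["p1"], info["p2"]),
                    regression=info["regression_percent"],
                    patient_id=pid,
                )
            )
        except Exception as exc:
            logger.error("%s: failed to read %s (%s)", pid, vcf, exc)
            failures.append((pid, f"unreadable_input:{exc.__class__.__name__}"))
    return cases, failures


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cases, failures = _load_cases(config)

    results = [
        PairedTumorModel(
            case,
            posterior_min=config.posterior_min,
            vaf_min=config.vaf_min,
            min_reads=config.min_reads,
            quantile=config.quantile,
            min_depth=config.min_depth,
            max_disagreement=config.max_disagreement,
        ).fit()
        for case in cases
    ]

    purity_rows = []
    for case in cases:
        for sample, est in ((BIOPSY, case.purity_biopsy),
                            (RESECTION, case.purity_resection)):
            purity_rows.append(
                {
                    "patient_id": case.patient_id,
                    "sample": sample,
                    "value": est.value if est else None,
                    "status": est.status if est else "unknown",
                    "method": est.method if est else None,
                    "v": est.v if est else None,
                    "s": est.s if est else None,
                }
            )
    pd.DataFrame(purity_rows).to_csv(out / "purity.tsv", sep="\t", index=False,
                                     float_format="%.6g")

    table, exclusions = summarize_cohort(
        cases, posterior_min=config.posterior_min, vaf_min=config.vaf_min,
        min_reads=config.min_reads,
    )
    table.to_csv(out / "cohort_dynamics.tsv", sep="\t", index=False,
                 float_format="%.6g")
    write_exclusion_log(failures + exclusions, out / "exclusions.tsv")

    for sample in (BIOPSY, RESECTION):
        frames = []
        for case in cases:
            curve = spectrum_curve(
                case.variants, sample, vaf_grid=DEFAULT_VAF_GRID,
                region_mb=config.region_mb, posterior_min=config.posterior_min,
            )
            df = curve.to_frame()
            df.insert(0, "patient_id", case.patient_id)
            frames.append(df)
        spec_table = (
            pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["patient_id", "sample", "class",
                                       "vaf_threshold", "count", "per_mb"])
        )
        spec_table.to_csv(out / f"spectrum_{sample}.tsv", sep="\t", index=False,
                          float_format="%.6g")

    _write_prioritization(config, results, out / "prioritization.tsv")

    manifest = {
        "package": "clonedyn",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "n_patients": len(cases),
        "n_analyzable": int(len(table)),
        "n_excluded": len(failures) + len(exclusions),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline done: %d patients, %d analyzable", len(cases), len(table))
    return out


def _write_prioritization(config: RunConfig, results, path: Path) -> None:
    gene_list = None
    if config.gene_list_file:
        gene_list = frozenset(
            line.strip()
            for line in Path(config.gene_list_file).read_text().splitlines()
            if line.strip()
        )
    policy = FilterPolicy(
        revel_min=config.revel_min, gnomad_max=config.gnomad_max, gene_list=gene_list
    )
    frames = []
    for res in results:
        if not res.case.purities_known:
            continue
        kept, _ = filter_reportable(res.case.variants, policy)
        if not kept:
            continue
        probs = res.vaf_change_probabilities(
            delta=config.delta, seed=config.seed
        )
        kept_keys = {(v.chrom, v.pos, v.ref, v.alt) for v in kept}
        mask = probs.apply(
            lambda r: (r["chrom"], r["pos"], r["ref"], r["alt"]) in kept_keys, axis=1
        )
        df = probs[mask].copy()
        df.insert(0, "patient_id", res.case.patient_id)
        frames.append(df)
    cols = ["patient_id", "chrom", "pos", "ref", "alt", "gene", "vaf_biopsy",
            "vaf_resection", "prob_vaf_changed", "prob_absent_in_normal"]
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=cols))
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def make_demo(seed: int = 0, workspace: Union[str, Path] = "demo") -> Path:
    """Simulate a small cohort, write its inputs, and run the pipeline on them."""
    from .simulate import SimParams, simulate_cohort

    workspace = Path(workspace)
    inputs = workspace / "inputs"
    params = SimParams(
        n_clones=6,
        mutations_per_clone=12.0,
        truncal_mutations=25.0,
        selection=0.3,
        spatial_miss_prob=0.05,
        purity_biopsy=0.35,
        purity_resection=0.4,
        mean_depth_biopsy=150.0,
        mean_depth_resection=200.0,
        p_error=0.08,
    )
    simulate_cohort(8, params, seed=seed, out_dir=inputs)
    config = RunConfig(
        vcf_dir=str(inputs),
        priors_csv=str(inputs / "priors.csv"),
        out_dir=str(workspace / "results"),
        seed=seed,
    )
    (workspace / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))
    return run_pipeline(config)
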