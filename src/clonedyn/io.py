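"""VCF / TSV input and output.

Canonical input is one multi-sample VCF 4.x per patient with biopsy,
resection and optionally normal sample columns, FORMAT fields ``DP`` and
``AD`` (Number=R), and a somatic-posterior INFO tag (default
``PROB_SOMATIC``, phred-scaled: posterior = 10^(-tag/10), the convention of
Bayesian somatic callers).  Multi-allelic records are split into one
:class:`~clonedyn.data.VariantCall` per alternate allele.
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import pysam

from .data import PatientCase, VariantCall
from .dynamics import COHORT_COLUMNS, summarize_cohort

logger = logging.getLogger(__name__)

DEFAULT_POSTERIOR_TAG = "PROB_SOMATIC"
ANNOTATION_TAGS = {
    "pathogenicity_score": "REVEL",
    "population_af": "GNOMAD_AF",
    "clinical_significance": "CLIN_SIG",
    "gene": "GENE",
    "consequence": "CONSEQUENCE",
}


def _phred_to_linear(x: float) -> float:
    return min(1.0, 10.0 ** (-x / 10.0))


def _scalar(value, index: int = 0):
    if isinstance(value, (tuple, list)):
        return value[index] if index < len(value) else None
    return value


def _info_get(rec, tag):
    # pysam raises on tags absent from the header; treat those as missing
    try:
        return rec.info.get(tag)
    except (KeyError, ValueError):
        return None


def read_paired_case(
    vcf_path: Union[str, Path],
    sample_names: Mapping[str, str],
    priors: tuple[float, float] = (0.0, 1.0),
    regression: Optional[float] = None,
    patient_id: Optional[str] = None,
    posterior_tag: str = DEFAULT_POSTERIOR_TAG,
    posterior_scale: str = "phred",
    annotation_tags: Mapping[str, str] = ANNOTATION_TAGS,
) -> PatientCase:
    """Read a multi-sample VCF into a :class:`PatientCase`.

    ``sample_names`` maps the roles ``biopsy``, ``resection`` and optionally
    ``normal`` to VCF sample column names.  Records whose genotype fields
    cannot be parsed are skipped with a logged count; records with zero depth
    in both tumor samples are retained (their VAFs are NaN).  A missing
    posterior tag yields ``somatic_posterior = 1.0`` with a warning.
    """
    vcf_path = Path(vcf_path)
    vf = pysam.VariantFile(str(vcf_path))
    for role in ("biopsy", "resection"):
        if role not in sample_names:
            raise ValueError(f"sample_names must name a {role!r} sample")
        if sample_names[role] not in vf.header.samples:
            raise ValueError(
                f"sample {sample_names[role]!r} ({role}) not in {vcf_path.name}"
            )
    normal = sample_names.get("normal")
    if normal is not None and normal not in vf.header.samples:
        raise ValueError(f"normal sample {normal!r} not in {vcf_path.name}")

    variants: list[VariantCall] = []
    n_skipped = 0
    n_missing_posterior = 0
    for rec in vf:
        alts = rec.alts or ()
        for ai, alt in enumerate(alts):
            try:
                variants.append(
                    _record_to_call(
                        rec, ai, alt, sample_names, normal,
                        posterior_tag, posterior_scale, annotation_tags,
                    )
                )
            except _MissingPosterior:
                n_missing_posterior += 1
                variants.append(
                    _record_to_call(
                        rec, ai, alt, sample_names, normal,
                        None, posterior_scale, annotation_tags,
                    )
                )
            except Exception as exc:  # unparseable record: skip, keep counting
                n_skipped += 1
                logger.debug("skipping %s:%s (%s)", rec.chrom, rec.pos, exc)
    vf.close()
    if n_skipped:
        logger.warning("%s: skipped %d unparseable records", vcf_path.name, n_skipped)
    if n_missing_posterior:
        logger.warning(
            "%s: %d records missing %s; somatic_posterior defaulted to 1.0",
            vcf_path.name, n_missing_posterior, posterior_tag,
        )
    p1, p2 = priors
    return PatientCase(
        patient_id=patient_id or vcf_path.stem,
        variants=variants,
        p1=p1,
        p2=p2,
        regression_percent=regression,
    )


class _MissingPosterior(Exception):
    pass


def _counts(sample_rec, allele_index: int) -> tuple[int, int]:
    ad = sample_rec.get("AD")
    alt = _scalar(ad, allele_index + 1)
    alt = int(alt) if alt is not None else 0
    dp = sample_rec.get("DP")
    if dp is None:
        dp = sum(int(a) for a in (ad or ()) if a is not None)
    return int(dp), alt


def _record_to_call(
    rec, allele_index, alt, sample_names, normal,
    posterior_tag, posterior_scale, annotation_tags,
) -> VariantCall:
    db, ab = _counts(rec.samples[sample_names["biopsy"]], allele_index)
    dr, ar = _counts(rec.samples[sample_names["resection"]], allele_index)
    if posterior_tag is None:
        posterior = 1.0
    else:
        raw = _info_get(rec, posterior_tag)
        if raw is None:
            raise _MissingPosterior()
        raw = float(_scalar(raw, allele_index) or _scalar(raw))
        posterior = _phred_to_linear(raw) if posterior_scale == "phred" else raw
    annotations = {}
    for key, tag in annotation_tags.items():
        val = _info_get(rec, tag)
        if val is not None:
            val = _scalar(val, allele_index) if isinstance(val, (tuple, list)) else val
            if key in ("pathogenicity_score", "population_af"):
                val = float(val)
            annotations[key] = val
    alt_n = depth_n = None
    if normal is not None:
        depth_n, alt_n = _counts(rec.samples[normal], allele_index)
    return VariantCall(
        chrom=rec.chrom,
        pos=rec.pos,
        ref=rec.ref,
        alt=alt,
        depth_biopsy=db,
        alt_biopsy=ab,
        depth_resection=dr,
        alt_resection=ar,
        somatic_posterior=posterior,
        annotations=annotations,
        alt_normal=alt_n,
        depth_normal=depth_n,
    )


def write_case_vcf(
    case: PatientCase,
    path: Union[str, Path],
    posterior_tag: str = DEFAULT_POSTERIOR_TAG,
    annotation_tags: Mapping[str, str] = ANNOTATION_TAGS,
) -> Path:
    """Write a case back to a multi-sample VCF (BIOPSY/RESECTION[/NORMAL] columns)."""
    path = Path(path)
    header = pysam.VariantHeader()
    header.add_line("##contig=<ID=chr1,length=248956422>")
    header.add_meta(
        "INFO",
        items=[("ID", posterior_tag), ("Number", "1"), ("Type", "Float"),
               ("Description", "Phred-scaled posterior probability of being somatic")],
    )
    info_types = {
        "pathogenicity_score": "Float",
        "population_af": "Float",
        "clinical_significance": "String",
        "gene": "String",
        "consequence": "String",
    }
    for key, tag in annotation_tags.items():
        header.add_meta(
            "INFO",
            items=[("ID", tag), ("Number", "1"), ("Type", info_types[key]),
                   ("Description", key.replace("_", " "))],
        )
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "DP"), ("Number", "1"),
                                     ("Type", "Integer"), ("Description", "Read depth")])
    header.add_meta("FORMAT", items=[("ID", "AD"), ("Number", "R"),
                                     ("Type", "Integer"),
                                     ("Description", "Allelic depths (ref,alt)")])
    has_normal = any(v.depth_normal is not None for v in case.variants)
    samples = ["BIOPSY", "RESECTION"] + (["NORMAL"] if has_normal else [])
    for s in samples:
        header.add_sample(s)
    vf = pysam.VariantFile(str(path), "w", header=header)
    for var in sorted(case.variants, key=lambda v: (v.chrom, v.pos, v.alt)):
        rec = vf.new_record(
            contig=var.chrom, start=var.pos - 1, alleles=(var.ref, var.alt)
        )
        phred = 0.0 if var.somatic_posterior >= 1.0 else (
            -10.0 * math.log10(max(var.somatic_posterior, 1e-30))
        )
        rec.info[posterior_tag] = round(phred, 4)
        for key, tag in annotation_tags.items():
            if key in var.annotations:
                rec.info[tag] = var.annotations[key]
        for sample, depth, alt in (
            ("BIOPSY", var.depth_biopsy, var.alt_biopsy),
            ("RESECTION", var.depth_resection, var.alt_resection),
        ):
            rec.samples[sample]["GT"] = (0, 1)
            rec.samples[sample]["DP"] = depth
            rec.samples[sample]["AD"] = (depth - alt, alt)
        if has_normal:
            dn = var.depth_normal or 0
            an = var.alt_normal or 0
            rec.samples["NORMAL"]["GT"] = (0, 0)
            rec.samples["NORMAL"]["DP"] = dn
            rec.samples["NORMAL"]["AD"] = (dn - an, an)
        vf.write(rec)
    vf.close()
    return path


SIM_SAMPLE_NAMES = {"biopsy": "BIOPSY", "resection": "RESECTION", "normal": "NORMAL"}


def write_cohort_inputs(cohort, out_dir: Union[str, Path]) -> Path:
    """Write a simulated cohort as per-patient VCFs + priors CSV + truth JSONs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case, truth in cohort:
        write_case_vcf(case, out_dir / f"{case.patient_id}.vcf")
        truth.to_json(out_dir / f"{case.patient_id}.truth.json")
        rows.append(
            {
                "patient_id": case.patient_id,
                "p1": case.p1,
                "p2": case.p2,
                "regression_percent": case.regression_percent,
            }
        )
    priors = out_dir / "priors.csv"
    with priors.open("w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["patient_id", "p1", "p2", "regression_percent"])
        w.writeheader()
        w.writerows(rows)
    return out_dir


def read_priors(path: Union[str, Path]) -> dict[str, dict]:
    """Priors CSV (patient_id, p1, p2[, regression_percent]) -> per-patient dict."""
    out = {}
    with Path(path).open() as fh:
        for row in csv.DictReader(fh):
            out[row["patient_id"]] = {
                "p1": float(row["p1"]),
                "p2": float(row["p2"]),
                "regression_percent": (
                    float(row["regression_percent"])
                    if row.get("regression_percent") not in (None, "")
                    else None
                ),
            }
    return out


def write_cohort_table(
    cases: Iterable[PatientCase], path: Union[str, Path]
) -> pd.DataFrame:
    """Write the per-patient dynamics table (the data behind the cohort bubble
    plot): one row per analyzable patient, fixed column order."""
    table, exclusions = summarize_cohort(cases)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return table


def write_exclusion_log(
    exclusions: Sequence[tuple[str, str]], path: Union[str, Path]
) -> None:
    with Path(path).open("w") as fh:
        fh.write("patient_id\treason\n")
        for pid, reason in exclusions:
            fh.write(f"{pid}\t{reason}\n")
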