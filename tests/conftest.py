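import pytest

from clonedyn.data import PatientCase, PurityEstimate, VariantCall


def make_variant(
    alt_b, depth_b, alt_r, depth_r,
    chrom="chr1", pos=100, ref="C", alt="T",
    posterior=1.0, annotations=None, alt_n=None, depth_n=None,
):
    return VariantCall(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        depth_biopsy=depth_b, alt_biopsy=alt_b,
        depth_resection=depth_r, alt_resection=alt_r,
        somatic_posterior=posterior,
        annotations=annotations or {},
        alt_normal=alt_n, depth_normal=depth_n,
    )


def make_case(variants, patient_id="P1", p1=0.3, p2=0.45,
              purity_b=None, purity_r=None):
    case = PatientCase(patient_id=patient_id, variants=variants, p1=p1, p2=p2)
    if purity_b is not None:
        case.purity_biopsy = PurityEstimate.known(purity_b, "simulated_truth")
    if purity_r is not None:
        case.purity_resection = PurityEstimate.known(purity_r, "simulated_truth")
    return case


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def case_factory():
    return make_case
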