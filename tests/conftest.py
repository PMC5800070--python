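import pytest
from hypothesis import settings

from cnvcohort import resources

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from cnvcohort.core import CNVCall, CnvType, GenomicInterval


@pytest.fixture(scope="session")
def fixture_calls():
    return resources.load_pcnv_calls()


@pytest.fixture(scope="session")
def fixture_patients():
    return resources.load_pcnv_patients()


@pytest.fixture(scope="session")
def catalog():
    return resources.load_locus_catalog()


@pytest.fixture(scope="session")
def lms_refs():
    return resources.load_lms_references()


@pytest.fixture(scope="session")
def calls_by_patient(fixture_calls):
    by: dict[str, list] = {}
    for c in fixture_calls:
        by.setdefault(c.patient_id, []).append(c)
    return by


def make_call(
    patient_id: str,
    chrom: str,
    start: int,
    end: int,
    cnv_type: str = "del",
    **kw,
) -> CNVCall:
    return CNVCall(
        patient_id=patient_id,
        interval=GenomicInterval(chrom, start, end),
        cnv_type=CnvType(cnv_type),
        **kw,
    )
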