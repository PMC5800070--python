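"""Loaders for the data files shipped inside the package.

* ``load_pcnv_calls`` / ``load_pcnv_patients`` — a fully transcribed
  61-patient clinical CMA case series (74 reportable imbalances, hg19)
  from a syndromic-obesity referral cohort of 279 screened patients; the
  cohort table carries the per-patient demographics and anthropometrics
  that accompany the calls.
* ``load_locus_catalog`` — genomic-disorder regions with
  syndromic-obesity causality flags.
* ``load_lms_references`` — synthetic LMS growth references (clearly
  labelled as such) for BMI-for-age and weight-for-height.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .anthro import LMSReference, read_lms_csv
from .core import CNVCall, LocusCatalogEntry, PatientRecord
from .io import read_cnv_table, read_cohort_table, read_locus_catalog

__all__ = [
    "data_path",
    "load_pcnv_calls",
    "load_pcnv_patients",
    "load_locus_catalog",
    "load_lms_references",
    "SCREENED_COHORT_SIZE",
]

# Size of the full referral screen behind the packaged positive-call series.
SCREENED_COHORT_SIZE = 279


def data_path(name: str) -> Path:
    with resources.as_file(resources.files("cnvcohort") / "data" / name) as p:
        return Path(p)


def load_pcnv_calls() -> list[CNVCall]:
    return read_cnv_table(data_path("pcnv_calls.tsv"))


def load_pcnv_patients() -> list[PatientRecord]:
    return read_cohort_table(data_path("pcnv_patients.tsv"))


def load_locus_catalog() -> list[LocusCatalogEntry]:
    return read_locus_catalog(data_path("locus_catalog.tsv"))


def load_lms_references() -> dict[str, LMSReference]:
    return {
        "bmi_for_age": read_lms_csv(
            data_path("lms_bmi_for_age_synthetic.csv"), metric="bmi_for_age"
        ),
        "weight_for_height": read_lms_csv(
            data_path("lms_weight_for_height_synthetic.csv"),
            metric="weight_for_height",
        ),
    }
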