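"""Validated readers and writers for the cohort's tabular formats.

All tables are plain TSV/CSV with a header row. CNV tables can also be
exchanged as 6-column BED (half-open coordinates, name = ``patient|type``).
Phenotype columns in cohort tables are prefixed ``ph_`` and coded
``1``/``0``/``NA``; ``NA`` (unknown) is distinct from ``0`` everywhere
downstream.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core import (
    CNVCall,
    ClinicalClass,
    CnvType,
    GeneRecord,
    GenomicInterval,
    LocusCatalogEntry,
    PatientRecord,
    RearrangementKind,
    Sex,
    WeightStatusNote,
    normalize_origin,
)

logger = logging.getLogger("cnvcohort")

__all__ = [
    "SchemaError",
    "RowValidationError",
    "read_cnv_table",
    "write_cnv_table",
    "write_cnv_bed",
    "read_cohort_table",
    "write_cohort_table",
    "read_locus_catalog",
    "read_gene_table",
    "read_gene_set",
    "PHENOTYPE_PREFIX",
]

PHENOTYPE_PREFIX = "ph_"

_CNV_COLUMNS = (
    "patient_id",
    "cnv_type",
    "cytoband",
    "chrom",
    "start",
    "end",
    "size",
    "origin",
    "clinical_class",
    "disorder_label",
    "rearrangement_kind",
)

_REQUIRED_CNV_COLUMNS = ("patient_id", "cnv_type", "chrom", "start", "end")


class SchemaError(ValueError):
    """A table is missing a required column or uses an unusable layout."""


class RowValidationError(ValueError):
    """A data row violates an invariant; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


def _read_tsv(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _opt(value: str) -> Optional[str]:
    value = value.strip()
    return value or None


def read_cnv_table(path: str | Path, dialect: str = "tsv") -> list[CNVCall]:
    """Read a CNV call table (``tsv`` or 6-column ``bed`` dialect)."""
    path = Path(path)
    if dialect == "bed":
        return _read_cnv_bed(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_tsv(path)
    _require_columns(df, _REQUIRED_CNV_COLUMNS, path)
    calls: list[CNVCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise RowValidationError(i, f"non-integer coordinates: {exc}") from None
        try:
            interval = GenomicInterval(row.chrom, start, end)
        except ValueError as exc:
            raise RowValidationError(i, str(exc)) from None
        size = getattr(row, "size", "")
        if str(size).strip():
            if int(size) != interval.length:
                raise RowValidationError(
                    i,
                    f"recorded size {size} != end - start = {interval.length} "
                    f"for {interval}",
                )
        origin, recognized = normalize_origin(getattr(row, "origin", ""))
        if not recognized:
            logger.warning(
                "%s row %d: unrecognized origin %r mapped to unknown",
                path.name, i, getattr(row, "origin", ""),
            )
        try:
            cnv_type = CnvType(str(row.cnv_type).strip().lower())
        except ValueError:
            raise RowValidationError(i, f"unknown CNV type {row.cnv_type!r}") from None
        clin = str(getattr(row, "clinical_class", "uncertain")).strip().lower()
        try:
            clinical_class = ClinicalClass(clin) if clin else ClinicalClass.UNCERTAIN
        except ValueError:
            raise RowValidationError(i, f"unknown clinical class {clin!r}") from None
        kind = str(getattr(row, "rearrangement_kind", "simple")).strip().lower()
        calls.append(
            CNVCall(
                patient_id=str(row.patient_id).strip(),
                interval=interval,
                cnv_type=cnv_type,
                cytoband=str(getattr(row, "cytoband", "")).strip(),
                origin=origin,
                clinical_class=clinical_class,
                disorder_label=_opt(str(getattr(row, "disorder_label", ""))),
                rearrangement_kind=(
                    RearrangementKind(kind) if kind else RearrangementKind.SIMPLE
                ),
            )
        )
    return calls


def _read_cnv_bed(path: Path) -> list[CNVCall]:
    calls = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise RowValidationError(i, "BED line needs >= 4 fields")
            chrom, start, end, name = fields[:4]
            patient_id, _, cnv_type = name.partition("|")
            try:
                interval = GenomicInterval(chrom, int(start), int(end))
            except ValueError as exc:
                raise RowValidationError(i, str(exc)) from None
            calls.append(
                CNVCall(
                    patient_id=patient_id,
                    interval=interval,
                    cnv_type=CnvType(cnv_type or "del"),
                )
            )
    return calls


def cnv_table_frame(calls: Sequence[CNVCall]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": c.patient_id,
            "cnv_type": c.cnv_type.value,
            "cytoband": c.cytoband,
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "size": c.interval.length,
            "origin": c.origin.value,
            "clinical_class": c.clinical_class.value,
            "disorder_label": c.disorder_label or "",
            "rearrangement_kind": c.rearrangement_kind.value,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=list(_CNV_COLUMNS))


def write_cnv_table(calls: Sequence[CNVCall], path: str | Path) -> None:
    cnv_table_frame(calls).to_csv(path, sep="\t", index=False)


def write_cnv_bed(calls: Sequence[CNVCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.interval.chrom, c.interval.start)):
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                f"\t{c.patient_id}|{c.cnv_type.value}\t0\t.\n"
            )


# -- cohort tables -----------------------------------------------------------

_COHORT_BASE = (
    "patient_id", "sex", "age_months", "weight_kg", "height_cm", "bmi",
    "bmi_percentile", "wfh_zscore", "weight_status_note",
)


def _parse_bool_token(token: str, row: int, column: str) -> Optional[bool]:
    token = token.strip()
    if token in ("", "NA", "na", "NaN", "nan", "."):
        return None
    if token in ("1", "true", "True"):
        return True
    if token in ("0", "false", "False"):
        return False
    raise RowValidationError(row, f"column {column}: unparseable boolean {token!r}")


def read_cohort_table(path: str | Path) -> list[PatientRecord]:
    """Read a one-row-per-patient cohort table with ``ph_`` phenotype columns."""
    path = Path(path)
    df = _read_tsv(path)
    _require_columns(df, ("patient_id", "sex", "age_months"), path)
    ph_cols = [c for c in df.columns if c.startswith(PHENOTYPE_PREFIX)]
    patients: list[PatientRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.to_dict("records"), start=1):
        pid = str(row["patient_id"]).strip()
        if pid in seen:
            raise RowValidationError(i, f"duplicate patient_id {pid!r}")
        seen.add(pid)
        try:
            age = int(float(row["age_months"]))
        except ValueError:
            raise RowValidationError(
                i, f"non-numeric age {row['age_months']!r}"
            ) from None
        try:
            sex = Sex(str(row["sex"]).strip().upper())
        except ValueError:
            raise RowValidationError(i, f"unknown sex {row['sex']!r}") from None

        def fnum(col: str) -> Optional[float]:
            raw = str(row.get(col, "")).strip()
            if raw in ("", "NA", "na", "NaN", "nan", "."):
                return None
            return float(raw)

        weight, height, bmi = fnum("weight_kg"), fnum("height_cm"), fnum("bmi")
        if weight is not None and height is not None and bmi is not None:
            implied = weight / (height / 100.0) ** 2
            if not math.isclose(bmi, implied, abs_tol=0.1):
                logger.warning(
                    "%s row %d (%s): recorded BMI %.2f inconsistent with "
                    "weight/height (implies %.2f); measured values kept",
                    path.name, i, pid, bmi, implied,
                )
        note_raw = str(row.get("weight_status_note", "")).strip()
        note = (
            WeightStatusNote(note_raw)
            if note_raw and note_raw not in ("NA", ".")
            else WeightStatusNote.MEASURED
        )
        phenotypes = {
            c[len(PHENOTYPE_PREFIX):]: _parse_bool_token(str(row[c]), i, c)
            for c in ph_cols
        }
        patients.append(
            PatientRecord(
                patient_id=pid,
                sex=sex,
                age_months=age,
                weight_kg=weight,
                height_cm=height,
                bmi=bmi,
                bmi_percentile=fnum("bmi_percentile"),
                wfh_zscore=fnum("wfh_zscore"),
                weight_status_note=note,
                phenotypes=phenotypes,
            )
        )
    return patients


def cohort_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame; phenotype columns are floats with NaN unknowns."""
    features: list[str] = []
    for p in patients:
        for name in p.phenotypes:
            if name not in features:
                features.append(name)
    rows = []
    for p in patients:
        row: dict = {
            "patient_id": p.patient_id,
            "sex": p.sex.value,
            "age_months": p.age_months,
            "weight_kg": p.weight_kg,
            "height_cm": p.height_cm,
            "bmi": p.bmi,
            "bmi_percentile": p.bmi_percentile,
            "wfh_zscore": p.wfh_zscore,
            "weight_status_note": p.weight_status_note.value,
            "pcnv": p.is_pcnv_carrier,
        }
        for name in features:
            val = p.phenotypes.get(name)
            row[PHENOTYPE_PREFIX + name] = float("nan") if val is None else float(val)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_table(patients: Sequence[PatientRecord], path: str | Path) -> None:
    df = cohort_frame(patients).drop(columns=["pcnv"])
    ph_cols = [c for c in df.columns if c.startswith(PHENOTYPE_PREFIX)]
    for c in ph_cols:
        df[c] = df[c].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    for c in ("weight_kg", "height_cm", "bmi", "bmi_percentile", "wfh_zscore"):
        df[c] = df[c].map(lambda v: "NA" if pd.isna(v) else repr(float(v)))
    df.to_csv(path, sep="\t", index=False)


# -- locus catalog and gene tables -------------------------------------------

def read_locus_catalog(path: str | Path) -> list[LocusCatalogEntry]:
    path = Path(path)
    df = _read_tsv(path)
    _require_columns(df, ("locus_id", "chrom", "start", "end"), path)
    entries = []
    seen: set[str] = set()
    for i, row in enumerate(df.to_dict("records"), start=1):
        locus_id = str(row["locus_id"]).strip()
        if locus_id in seen:
            raise RowValidationError(i, f"duplicate locus_id {locus_id!r}")
        seen.add(locus_id)
        entries.append(
            LocusCatalogEntry(
                locus_id=locus_id,
                region=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                known_genomic_disorder=str(row.get("known_genomic_disorder", "1")).strip()
                in ("1", "true", "True"),
                causal_for_syndromic_obesity=str(
                    row.get("causal_for_syndromic_obesity", "0")
                ).strip() in ("1", "true", "True"),
                causal_cnv_type=str(row.get("causal_cnv_type", "any")).strip() or "any",
                description=str(row.get("description", "")).strip(),
            )
        )
    return entries


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """BED-like gene table: chrom, start, end, symbol (header optional)."""
    path = Path(path)
    genes = []
    seen: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if i == 1 and fields[0] in ("chrom", "#chrom"):
                continue
            if len(fields) < 4:
                raise RowValidationError(i, "gene table line needs >= 4 fields")
            chrom, start, end, symbol = fields[:4]
            symbol = symbol.strip()
            if symbol in seen:
                raise RowValidationError(i, f"duplicate gene symbol {symbol!r}")
            seen.add(symbol)
            genes.append(
                GeneRecord(symbol=symbol, location=GenomicInterval(chrom, int(start), int(end)))
            )
    return genes


def read_gene_set(path: str | Path) -> set[str]:
    """One gene symbol per line; ``#`` comments and blanks ignored."""
    symbols = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                symbols.add(token)
    return symbols
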