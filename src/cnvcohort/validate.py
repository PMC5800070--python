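"""Cross-table consistency checks run before any analysis stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (
    CNVCall,
    CohortConfig,
    HG19_CHROM_LENGTHS,
    PatientRecord,
)

__all__ = ["ValidationReport", "validate_cohort"]


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def summary(self) -> str:
        lines = [f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"]
        lines += [f"ERROR: {e}" for e in self.errors]
        lines += [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines)


def validate_cohort(
    patients: Optional[Sequence[PatientRecord]],
    cnvs: Sequence[CNVCall],
    config: CohortConfig = CohortConfig(),
    chrom_lengths: dict[str, int] = HG19_CHROM_LENGTHS,
) -> ValidationReport:
    """Report-only validation of a cohort + CNV call pair.

    Errors (orphan CNVs, duplicate patients) should stop a pipeline run;
    warnings (coordinates past the chromosome end, unusual chromosome
    names) should not.
    """
    report = ValidationReport()
    if patients is not None:
        ids = [p.patient_id for p in patients]
        known = set(ids)
        if len(known) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            report.errors.append(f"duplicate patient ids: {', '.join(dupes)}")
        for call in cnvs:
            if call.patient_id not in known:
                report.errors.append(
                    f"orphan CNV: patient {call.patient_id} "
                    f"({call.interval}) absent from cohort table"
                )
    for call in cnvs:
        chrom = call.interval.chrom
        if chrom not in chrom_lengths:
            report.warnings.append(f"{call.patient_id}: unusual chromosome {chrom}")
        elif call.interval.end > chrom_lengths[chrom]:
            report.warnings.append(
                f"{call.patient_id}: {call.interval} extends past "
                f"{chrom} length {chrom_lengths[chrom]}"
            )
    return report
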