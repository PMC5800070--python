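"""Cohort-level summary tallies for a CMA CNV screen.

Reproduces the standard diagnostic-yield report of a microarray cohort:
patient- and imbalance-level counts by clinical class, CNV type, size,
inheritance, known-genomic-disorder overlap and syndromic-obesity
causality. Denominators are recorded per entry because yield tables mix
patient-level rates (over the cohort) with imbalance-level fractions
(over the pathogenic events):

* deletions / duplications / size classes are counted per imbalance;
* inheritance is counted per patient, each patient classified once by the
  strongest evidence across their pathogenic calls
  (de novo > inherited > not-maternal > unknown);
* known-disorder and causal-obesity counts are distinct patients whose
  pathogenic calls match the locus catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Optional, Sequence

from .core import CNVCall, ClinicalClass, CohortConfig, LocusCatalogEntry, Origin, PatientRecord
from .intervals import assign_to_catalog
from .phenstats import ContingencyTable2x2, ZeroMarginError, fisher_exact_2x2

__all__ = [
    "percent",
    "TallyEntry",
    "TallyReport",
    "tally",
    "causal_obesity_yield",
    "stratified_pcnv_rates",
]


def percent(count: int, denominator: int, decimals: int = 0) -> float:
    """100*count/denominator rounded half-up to ``decimals`` places."""
    if denominator == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    val = Decimal(100) * Decimal(count) / Decimal(denominator)
    return float(val.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TallyEntry:
    name: str
    count: int
    denominator: int
    level: str  # "patient" | "imbalance"
    available: bool = True

    @property
    def pct(self) -> float:
        return percent(self.count, self.denominator)


_ORIGIN_PRIORITY = (
    ("de_novo", lambda o: o is Origin.DE_NOVO),
    ("inherited", lambda o: o.is_inherited),
    ("not_maternal", lambda o: o is Origin.NOT_MATERNAL),
    ("unknown", lambda o: o is Origin.UNKNOWN),
)


def patient_origin_class(calls: Sequence[CNVCall]) -> str:
    """One inheritance label per patient over their pathogenic calls."""
    origins = [c.origin for c in calls if c.is_pathogenic]
    if not origins:
        return "unknown"
    for label, pred in _ORIGIN_PRIORITY:
        if any(pred(o) for o in origins):
            return label
    return "unknown"


@dataclass
class TallyReport:
    n_cohort: int
    entries: dict[str, TallyEntry] = field(default_factory=dict)

    def add(self, name: str, count: int, denominator: int, level: str,
            available: bool = True) -> None:
        self.entries[name] = TallyEntry(name, count, denominator, level, available)

    def __getitem__(self, name: str) -> TallyEntry:
        return self.entries[name]

    def count(self, name: str) -> int:
        return self.entries[name].count

    def to_rows(self) -> list[dict]:
        return [
            {
                "entry": e.name,
                "count": e.count,
                "denominator": e.denominator,
                "percent": e.pct,
                "level": e.level,
                "available": e.available,
            }
            for e in self.entries.values()
        ]


def _group_calls(cnvs: Sequence[CNVCall]) -> dict[str, list[CNVCall]]:
    by_patient: dict[str, list[CNVCall]] = {}
    for c in cnvs:
        by_patient.setdefault(c.patient_id, []).append(c)
    return by_patient


def tally(
    patients: Optional[Sequence[PatientRecord]],
    cnvs: Sequence[CNVCall],
    catalog: Sequence[LocusCatalogEntry],
    config: CohortConfig = CohortConfig(),
    n_cohort: Optional[int] = None,
) -> TallyReport:
    """Full diagnostic-yield tally.

    ``n_cohort`` defaults to ``len(patients)``; pass it explicitly when the
    call table covers only the CNV-positive subset of a larger screen.
    The "patients with any imbalance" entry is only meaningful when the
    call table includes non-pathogenic variants for all patients; it is
    marked unavailable when the table is restricted to clinically
    reportable calls.
    """
    if n_cohort is None:
        if patients is None:
            raise ValueError("need patients or an explicit n_cohort")
        n_cohort = len(patients)
    by_patient = _group_calls(cnvs)
    pathogenic = [c for c in cnvs if c.is_pathogenic]
    path_patients = {c.patient_id for c in pathogenic}
    report = TallyReport(n_cohort=n_cohort)
    report.add("cohort", n_cohort, n_cohort, "patient")

    any_class_patients = set(by_patient)
    # reportable-call tables under-count "any imbalance": benign calls of
    # CNV-negative patients are absent
    covers_whole_cohort = patients is not None and len(any_class_patients) >= n_cohort
    report.add("with_imbalances", len(any_class_patients), n_cohort, "patient",
               available=covers_whole_cohort)

    report.add("pcnv_patients", len(path_patients), n_cohort, "patient")
    report.add("pathogenic_imbalances", len(pathogenic), len(pathogenic), "imbalance")
    n_del = sum(1 for c in pathogenic if c.cnv_type.value == "del")
    n_dup = sum(1 for c in pathogenic if c.cnv_type.value == "dup")
    report.add("del", n_del, len(pathogenic), "imbalance")
    report.add("dup", n_dup, len(pathogenic), "imbalance")
    report.add(
        "large",
        sum(1 for c in pathogenic if c.length > config.large_cnv_bp),
        len(pathogenic),
        "imbalance",
    )

    origin_counts = {label: 0 for label, _ in _ORIGIN_PRIORITY}
    for pid in path_patients:
        origin_counts[patient_origin_class(by_patient[pid])] += 1
    for label in ("de_novo", "inherited", "not_maternal", "unknown"):
        report.add(f"origin_{label}", origin_counts[label], len(path_patients), "patient")

    for clazz, name in (
        (ClinicalClass.LIKELY_PATHOGENIC, "likely_pathogenic_patients"),
        (ClinicalClass.UNCERTAIN, "vus_patients"),
        (ClinicalClass.LIKELY_BENIGN, "likely_benign_patients"),
    ):
        n = len({c.patient_id for c in cnvs if c.clinical_class is clazz})
        report.add(name, n, n_cohort, "patient")

    known = [e for e in catalog if e.known_genomic_disorder]
    assignments, _ = assign_to_catalog(pathogenic, known, config.min_overlap_bp)
    report.add(
        "known_disorder_patients",
        len({a.call.patient_id for a in assignments}),
        n_cohort,
        "patient",
    )
    n_causal, _ = causal_obesity_yield(patients, cnvs, catalog, n_cohort, config)
    report.add("causal_obesity_patients", n_causal, n_cohort, "patient")
    return report


def causal_obesity_yield(
    patients: Optional[Sequence[PatientRecord]],
    cnvs: Sequence[CNVCall],
    catalog: Sequence[LocusCatalogEntry],
    n_cohort: int,
    config: CohortConfig = CohortConfig(),
    loci: Optional[Sequence[str]] = None,
) -> tuple[int, float]:
    """Distinct patients whose pathogenic CNVs hit a causal obesity locus.

    Causality is CNV-type aware (``causal_cnv_type`` in the catalog).
    ``loci`` optionally restricts the count to a subset of catalog ids,
    e.g. the three historically most frequent deletion syndromes.
    Returns ``(count, percent-of-cohort to one decimal)``.
    """
    causal_entries = [
        e
        for e in catalog
        if e.causal_for_syndromic_obesity and (loci is None or e.locus_id in loci)
    ]
    pathogenic = [c for c in cnvs if c.is_pathogenic]
    hit_patients: set[str] = set()
    for entry in causal_entries:
        assignments, _ = assign_to_catalog(pathogenic, [entry], config.min_overlap_bp)
        for a in assignments:
            if entry.causal_match(a.call):
                hit_patients.add(a.call.patient_id)
    return len(hit_patients), percent(len(hit_patients), n_cohort, decimals=1)


def stratified_pcnv_rates(
    patients: Sequence[PatientRecord],
    strata: Sequence[tuple[str, Callable[[PatientRecord], bool]]],
) -> list[dict]:
    """Carrier rates per stratum with pairwise Fisher comparisons.

    ``strata`` is a list of (name, predicate); the predicates must
    partition the patients they cover (overlap is an error). Rows carry
    n, carriers, the rate in percent, and the two-sided Fisher p against
    every other stratum.
    """
    membership: dict[str, str] = {}
    counts: dict[str, tuple[int, int]] = {}
    for name, pred in strata:
        members = [p for p in patients if pred(p)]
        for p in members:
            if p.patient_id in membership:
                raise ValueError(
                    f"strata overlap: {p.patient_id} in "
                    f"{membership[p.patient_id]!r} and {name!r}"
                )
            membership[p.patient_id] = name
        counts[name] = (len(members), sum(1 for p in members if p.is_pcnv_carrier))
    rows = []
    names = [name for name, _ in strata]
    for name in names:
        n, k = counts[name]
        row: dict = {
            "stratum": name,
            "n": n,
            "n_pcnv": k,
            "rate_pct": percent(k, n, decimals=1),
        }
        for other in names:
            if other == name:
                continue
            n2, k2 = counts[other]
            try:
                table = ContingencyTable2x2(a=k, b=n - k, c=k2, d=n2 - k2)
                _, p = fisher_exact_2x2(table)
            except ZeroMarginError:
                p = float("nan")
            row[f"p_vs_{other}"] = p
        rows.append(row)
    return rows
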