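"""Domain types for CNV cohort interpretation.

The objects here mirror what a clinical CMA (chromosomal microarray)
cohort study works with: genomic imbalances with hg19 coordinates, patient
records carrying anthropometrics and a boolean-with-unknown phenotype
profile, and a catalog of named genomic-disorder regions.

Coordinate convention: intervals are stored verbatim as printed in
clinical reports and treated as half-open ``[start, end)``, so
``length == end - start`` and touching intervals do not overlap.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

__all__ = [
    "GenomicInterval",
    "CnvType",
    "Origin",
    "ClinicalClass",
    "RearrangementKind",
    "CNVCall",
    "Sex",
    "AgeGroup",
    "PatientRecord",
    "LocusCatalogEntry",
    "GeneRecord",
    "CohortConfig",
    "HG19_CHROM_LENGTHS",
    "age_group",
]


# hg19 / GRCh37 chromosome lengths, used for coordinate sanity checks.
HG19_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430,
    "chr4": 191154276, "chr5": 180915260, "chr6": 171115067,
    "chr7": 159138663, "chr8": 146364022, "chr9": 141213431,
    "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392,
    "chr16": 90354753, "chr17": 81195210, "chr18": 78077248,
    "chr19": 59128983, "chr20": 63025520, "chr21": 48129895,
    "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
}


def canonical_chrom(chrom: str) -> str:
    """Return the ``chr``-prefixed form of a chromosome name."""
    chrom = str(chrom).strip()
    if not chrom:
        raise ValueError("empty chromosome name")
    if not chrom.startswith("chr"):
        chrom = "chr" + chrom
    return chrom


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", canonical_chrom(self.chrom))
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


class CnvType(str, enum.Enum):
    DEL = "del"
    DUP = "dup"


class Origin(str, enum.Enum):
    DE_NOVO = "de_novo"
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    NOT_MATERNAL = "not_maternal"
    INHERITED_UNSPECIFIED = "inherited_unspecified"
    UNKNOWN = "unknown"

    @property
    def is_inherited(self) -> bool:
        return self in (Origin.MATERNAL, Origin.PATERNAL, Origin.INHERITED_UNSPECIFIED)


class ClinicalClass(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain"
    LIKELY_BENIGN = "likely_benign"


class RearrangementKind(str, enum.Enum):
    SIMPLE = "simple"
    UNBALANCED_TRANSLOCATION = "unbalanced_translocation"
    INSERTIONAL_TRANSLOCATION = "insertional_translocation"
    COMPLEX_COMPONENT = "complex_component"


@dataclass(frozen=True)
class CNVCall:
    """One copy-number imbalance in one patient."""

    patient_id: str
    interval: GenomicInterval
    cnv_type: CnvType
    cytoband: str = ""
    origin: Origin = Origin.UNKNOWN
    clinical_class: ClinicalClass = ClinicalClass.UNCERTAIN
    disorder_label: Optional[str] = None
    rearrangement_kind: RearrangementKind = RearrangementKind.SIMPLE

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def is_pathogenic(self) -> bool:
        return self.clinical_class is ClinicalClass.PATHOGENIC


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class AgeGroup(str, enum.Enum):
    """Cohort age strata: infants, children, adolescents, adults.

    Boundaries in months: [0, 24), [24, 120), [120, 240), [240, inf).
    """

    INFANT = "infant"
    CHILD = "child"
    ADOLESCENT = "adolescent"
    ADULT = "adult"


def age_group(age_months: int) -> AgeGroup:
    if age_months < 0:
        raise ValueError(f"negative age {age_months}")
    if age_months < 24:
        return AgeGroup.INFANT
    if age_months < 120:
        return AgeGroup.CHILD
    if age_months < 240:
        return AgeGroup.ADOLESCENT
    return AgeGroup.ADULT


class WeightStatusNote(str, enum.Enum):
    MEASURED = "measured"
    REFERRED_OBESE = "referred_obese"
    HYPERPHAGIA_ONLY = "hyperphagia_only"


@dataclass
class PatientRecord:
    """One cohort member: demographics, anthropometrics, phenotype profile.

    ``phenotypes`` maps a feature name to True/False/None, where None means
    "not assessed"; unknowns are excluded from both numerator and
    denominator of every downstream rate.
    """

    patient_id: str
    sex: Sex
    age_months: int
    weight_kg: Optional[float] = None
    height_cm: Optional[float] = None
    bmi: Optional[float] = None
    bmi_percentile: Optional[float] = None
    wfh_zscore: Optional[float] = None
    weight_status_note: WeightStatusNote = WeightStatusNote.MEASURED
    phenotypes: dict[str, Optional[bool]] = field(default_factory=dict)
    cnvs: list[CNVCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_months < 0:
            raise ValueError(f"{self.patient_id}: negative age")
        if (
            self.bmi is not None
            and self.weight_kg is not None
            and self.height_cm is not None
        ):
            implied = self.weight_kg / (self.height_cm / 100.0) ** 2
            if not math.isclose(self.bmi, implied, abs_tol=0.1):
                # tolerated: a warning is raised by the reader, measured
                # values are kept
                pass

    @property
    def age_group(self) -> AgeGroup:
        return age_group(self.age_months)

    @property
    def is_pcnv_carrier(self) -> bool:
        return any(c.is_pathogenic for c in self.cnvs)

    def phenotype(self, name: str) -> Optional[bool]:
        return self.phenotypes.get(name)


@dataclass(frozen=True)
class LocusCatalogEntry:
    """A named genomic-disorder region.

    ``causal_cnv_type`` restricts the causal-for-syndromic-obesity flag to
    a CNV type ("del", "dup" or "any"): e.g. the proximal 16p11.2 deletion
    is an established obesity locus while the reciprocal duplication is
    not.
    """

    locus_id: str
    region: GenomicInterval
    known_genomic_disorder: bool = True
    causal_for_syndromic_obesity: bool = False
    causal_cnv_type: str = "any"
    description: str = ""

    def causal_match(self, call: CNVCall) -> bool:
        if not self.causal_for_syndromic_obesity:
            return False
        return self.causal_cnv_type in ("any", call.cnv_type.value)


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    location: GenomicInterval


@dataclass
class CohortConfig:
    """Analysis thresholds with the study's defaults.

    overweight/obesity cuts are BMI-for-age percentiles; severe obesity is
    BMI at or above ``severe_obesity_multiplier`` times the 95th-percentile
    BMI; ``large_cnv_bp`` splits the imbalance size tally; ``pair_alpha``
    is the phenotype-pair significance level; ``zscore_cut`` defines
    macro/microcephaly and tall/short stature; ``infant_wfh_z`` is the
    weight-for-height z threshold flagging excessive infant weight gain.
    """

    overweight_percentile_cut: float = 85.0
    obesity_percentile_cut: float = 95.0
    severe_obesity_multiplier: float = 1.20
    adult_obesity_bmi: float = 30.0
    large_cnv_bp: int = 5_000_000
    pair_alpha: float = 0.05
    zscore_cut: float = 2.0
    infant_wfh_z: float = 1.0
    min_overlap_bp: int = 1

    def __post_init__(self) -> None:
        for cut in (self.overweight_percentile_cut, self.obesity_percentile_cut):
            if not 0 < cut < 100:
                raise ValueError(f"percentile cut {cut} outside (0, 100)")
        if self.severe_obesity_multiplier <= 1:
            raise ValueError("severe_obesity_multiplier must exceed 1")
        if self.min_overlap_bp < 1:
            raise ValueError("min_overlap_bp must be >= 1")


# Normalization of origin strings as they appear in clinical tables.
ORIGIN_ALIASES: Mapping[str, Origin] = {
    "de novo": Origin.DE_NOVO,
    "denovo": Origin.DE_NOVO,
    "dn": Origin.DE_NOVO,
    "mat": Origin.MATERNAL,
    "maternal": Origin.MATERNAL,
    "pat": Origin.PATERNAL,
    "paternal": Origin.PATERNAL,
    "not mat": Origin.NOT_MATERNAL,
    "not maternal": Origin.NOT_MATERNAL,
    "inherited": Origin.INHERITED_UNSPECIFIED,
    "unk": Origin.UNKNOWN,
    "unknown": Origin.UNKNOWN,
    "--": Origin.UNKNOWN,
    "-": Origin.UNKNOWN,
    "": Origin.UNKNOWN,
}


def normalize_origin(text: str) -> tuple[Origin, bool]:
    """Map a free-text origin to the enum.

    Returns ``(origin, recognized)``; unrecognized strings map to unknown
    and the caller is expected to log a warning.
    """
    key = str(text).strip().lower()
    for enum_value in Origin:
        if key == enum_value.value:
            return enum_value, True
    if key in ORIGIN_ALIASES:
        return ORIGIN_ALIASES[key], True
    return Origin.UNKNOWN, False
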