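"""Seeded synthetic-cohort generator.

Emulates the statistical structure of a syndromic-obesity CMA referral
cohort so that every pipeline stage is testable without any external
data: 279 patients by default, 55% male, the referral screen's four-way
age structure, ~22% pathogenic-CNV carriers placed at genomic-disorder
catalog loci, a boolean phenotype spectrum whose base rates and
carrier enrichments default to the referral cohort's aggregate feature
counts, and anthropometrics drawn by inverting the same LMS reference the
classifier uses (so severity classification recovers the planted category
exactly).

Phenotype model: for a free feature, non-carriers show it with the base
rate p0 and carriers with logit(p) = logit(p0) + log_or. A pair effect
(A, B, log_psi) replaces independence between A and B *within carriers*
by the bivariate Bernoulli with the same margins and odds ratio
exp(log_psi), solved in closed form (Plackett construction), so planted
pair odds ratios are exact and analytic expectations exist for every
planted quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    CNVCall,
    ClinicalClass,
    CnvType,
    CohortConfig,
    GenomicInterval,
    LocusCatalogEntry,
    Origin,
    PatientRecord,
    Sex,
    WeightStatusNote,
)
from .anthro import LMSReference, lms_inverse

__all__ = [
    "DEFAULT_FEATURE_COUNTS",
    "default_phenotype_rates",
    "GeneratorParams",
    "SyntheticTruth",
    "SyntheticCohort",
    "bivariate_bernoulli_cells",
    "generate",
    "expected_summaries",
]


# Aggregate phenotype spectrum of the emulated referral cohort:
# feature -> (patients with the feature, of whom pathogenic-CNV carriers),
# over 279 screened patients of whom 61 carried pathogenic CNVs.
DEFAULT_FEATURE_COUNTS: dict[str, tuple[int, int]] = {
    "idd": (219, 55),
    "dysmorphism": (149, 49),
    "behavioral": (132, 29),
    "hyperphagia": (112, 27),
    "hypotonia": (88, 32),
    "language": (80, 28),
    "hands_feet": (65, 21),
    "genitalia": (56, 20),
    "eye_vision": (51, 16),
    "seizures": (31, 13),
    "motor": (29, 9),
    "skeletal": (23, 9),
    "brain": (19, 7),
    "hearing": (13, 6),
    "cardiac": (10, 4),
}
_EMULATED_N, _EMULATED_CARRIERS = 279, 61


def default_phenotype_rates() -> tuple[dict[str, float], dict[str, float]]:
    """(base rates in non-carriers, carrier log odds-ratio shifts)."""
    base, log_or = {}, {}
    n_nc = _EMULATED_N - _EMULATED_CARRIERS
    for feature, (total, carriers) in DEFAULT_FEATURE_COUNTS.items():
        p0 = (total - carriers) / n_nc
        p1 = carriers / _EMULATED_CARRIERS
        base[feature] = p0
        log_or[feature] = math.log(p1 / (1 - p1)) - math.log(p0 / (1 - p0))
    return base, log_or


def bivariate_bernoulli_cells(
    pa: float, pb: float, psi: float
) -> tuple[float, float, float, float]:
    """Cell probabilities (p11, p10, p01, p00) of the bivariate Bernoulli
    with margins pa, pb and odds ratio psi (Plackett closed form)."""
    if not (0 < pa < 1 and 0 < pb < 1):
        raise ValueError("margins must lie strictly inside (0, 1)")
    if psi <= 0:
        raise ValueError("odds ratio must be positive")
    if psi == 1.0:
        p11 = pa * pb
    else:
        s = 1.0 + (pa + pb) * (psi - 1.0)
        disc = s * s - 4.0 * psi * (psi - 1.0) * pa * pb
        if disc < 0:
            raise ValueError(f"odds ratio {psi} infeasible for margins {pa}, {pb}")
        p11 = (s - math.sqrt(disc)) / (2.0 * (psi - 1.0))
    cells = (p11, pa - p11, pb - p11, 1.0 - pa - pb + p11)
    if any(c < -1e-12 for c in cells):
        raise ValueError(f"odds ratio {psi} infeasible for margins {pa}, {pb}")
    return tuple(max(c, 0.0) for c in cells)  # type: ignore[return-value]


@dataclass
class GeneratorParams:
    """Study-condition parameters of the synthetic cohort."""

    n_patients: int = 279
    pcnv_prevalence: float = 61 / 279
    sex_ratio_male: float = 0.55
    # infants / children / adolescents / adults, the referral screen's mix
    age_group_weights: tuple[float, float, float, float] = (19, 153, 98, 10)
    phenotype_base_rates: dict[str, float] = field(
        default_factory=lambda: default_phenotype_rates()[0]
    )
    phenotype_carrier_log_or: dict[str, float] = field(
        default_factory=lambda: default_phenotype_rates()[1]
    )
    pair_effects: list[tuple[str, str, float]] = field(default_factory=list)
    # moderate vs severe among obese children/adolescents
    severity_mix: tuple[float, float] = (0.23, 0.77)
    missing_anthro_rate: float = 42 / 279
    adult_bmi_mean: float = 46.7
    adult_bmi_sd: float = 8.0
    infant_wfh_mean: float = 3.23
    infant_wfh_sd: float = 1.0
    locus_weights: Optional[dict[str, float]] = None
    size_jitter_bp: int = 200_000
    dup_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (
            ("pcnv_prevalence", self.pcnv_prevalence),
            ("sex_ratio_male", self.sex_ratio_male),
            ("missing_anthro_rate", self.missing_anthro_rate),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} outside [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        w = np.asarray(self.age_group_weights, dtype=float)
        if (w < 0).any() or w.sum() == 0:
            raise ValueError("age_group_weights must be non-negative, not all zero")
        if abs(sum(self.severity_mix) - 1.0) > 1e-9:
            raise ValueError("severity_mix must sum to 1")
        seen: set[str] = set()
        for a, b, _ in self.pair_effects:
            if a in seen or b in seen or a == b:
                raise ValueError(
                    "pair_effects must name disjoint feature pairs"
                )
            seen.update((a, b))
            for f in (a, b):
                if f not in self.phenotype_base_rates:
                    raise ValueError(f"pair effect names unknown feature {f!r}")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("params YAML must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        if "pair_effects" in raw:
            raw["pair_effects"] = [tuple(e) for e in raw["pair_effects"]]
        for key in ("age_group_weights", "severity_mix"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Everything planted: sufficient for analytic expectations."""

    carrier: np.ndarray
    assigned_locus: list[Optional[str]]
    feature_rate_noncarrier: dict[str, float]
    feature_rate_carrier: dict[str, float]
    pair_odds_ratios: dict[tuple[str, str], float]
    severity_mix: tuple[float, float]
    planted_category: list[Optional[str]]


@dataclass
class SyntheticCohort:
    patients: list[PatientRecord]
    cnvs: list[CNVCall]
    truth: SyntheticTruth
    frame: pd.DataFrame


_AGE_BOUNDS = ((0, 24), (24, 120), (120, 240), (240, 480))
_ORIGIN_MIX = (
    (Origin.DE_NOVO, 0.49),
    (Origin.UNKNOWN, 0.31),
    (Origin.MATERNAL, 0.05),
    (Origin.PATERNAL, 0.05),
    (Origin.NOT_MATERNAL, 0.10),
)


def _carrier_rate(p0: float, log_or: float) -> float:
    return 1.0 / (1.0 + math.exp(-(math.log(p0 / (1 - p0)) + log_or)))


def generate(
    params: GeneratorParams,
    catalog: Optional[Sequence[LocusCatalogEntry]] = None,
    lms_refs: Optional[dict[str, LMSReference]] = None,
    config: CohortConfig = CohortConfig(),
) -> SyntheticCohort:
    """Draw one synthetic cohort; byte-reproducible given ``params.seed``.

    All randomness flows from a single numpy Generator in a fixed
    column-wise draw order indexed by patient position, so results do not
    depend on any container insertion order.
    """
    if catalog is None:
        from .resources import load_locus_catalog

        catalog = load_locus_catalog()
    if lms_refs is None:
        from .resources import load_lms_references

        lms_refs = load_lms_references()
    catalog = [e for e in catalog if e.known_genomic_disorder]
    if not catalog:
        raise ValueError("need a non-empty locus catalog")
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    carrier = rng.random(n) < params.pcnv_prevalence
    male = rng.random(n) < params.sex_ratio_male
    weights = np.asarray(params.age_group_weights, dtype=float)
    group = rng.choice(4, size=n, p=weights / weights.sum())
    age_u = rng.random(n)
    lo = np.array([_AGE_BOUNDS[g][0] for g in group])
    hi = np.array([_AGE_BOUNDS[g][1] for g in group])
    age_months = (lo + age_u * (hi - lo)).astype(int)

    # phenotypes: paired features first (joint draw in carriers), then free
    features = list(params.phenotype_base_rates)
    paired = {f for a, b, _ in params.pair_effects for f in (a, b)}
    rate_c = {
        f: _carrier_rate(params.phenotype_base_rates[f],
                         params.phenotype_carrier_log_or.get(f, 0.0))
        for f in features
    }
    pheno = np.zeros((n, len(features)), dtype=bool)
    col = {f: k for k, f in enumerate(features)}
    pair_ors: dict[tuple[str, str], float] = {}
    for a, b, log_psi in params.pair_effects:
        psi = math.exp(log_psi)
        pair_ors[(a, b)] = psi
        cells = bivariate_bernoulli_cells(rate_c[a], rate_c[b], psi)
        u = rng.random(n)
        cum = np.cumsum(cells)
        joint = np.searchsorted(cum, u, side="right")  # 0:11, 1:10, 2:01, 3:00
        ua, ub = rng.random(n), rng.random(n)
        ind_a = ua < params.phenotype_base_rates[a]
        ind_b = ub < params.phenotype_base_rates[b]
        pheno[:, col[a]] = np.where(carrier, np.isin(joint, (0, 1)), ind_a)
        pheno[:, col[b]] = np.where(carrier, np.isin(joint, (0, 2)), ind_b)
    for f in features:
        if f in paired:
            continue
        u = rng.random(n)
        p = np.where(carrier, rate_c[f], params.phenotype_base_rates[f])
        pheno[:, col[f]] = u < p

    # anthropometrics
    missing = rng.random(n) < params.missing_anthro_rate
    sev_u = rng.random(n)
    ratio_mod = 1.0 + 0.199 * rng.random(n)
    ratio_sev = np.minimum(1.2 + rng.exponential(0.12, size=n), 1.9)
    severe = sev_u < params.severity_mix[1]
    ratio = np.where(severe, ratio_sev, ratio_mod)
    wfh_draw = np.clip(
        rng.normal(params.infant_wfh_mean, params.infant_wfh_sd, size=n),
        config.infant_wfh_z + 0.05, None,
    )
    adult_bmi = np.clip(
        rng.normal(params.adult_bmi_mean, params.adult_bmi_sd, size=n),
        config.adult_obesity_bmi + 0.1, None,
    )
    bmi_ref = lms_refs["bmi_for_age"]
    bmi = np.full(n, np.nan)
    wfh_z = np.full(n, np.nan)
    planted_category: list[Optional[str]] = [None] * n
    for i in range(n):
        if missing[i]:
            continue
        if group[i] == 0:
            wfh_z[i] = wfh_draw[i]
            planted_category[i] = "infant_high_wfh"
        elif group[i] == 3:
            bmi[i] = adult_bmi[i]
            planted_category[i] = "adult_obesity"
        else:
            sex = "M" if male[i] else "F"
            p95 = bmi_ref.percentile_value(
                sex, float(age_months[i]), config.obesity_percentile_cut
            )
            bmi[i] = ratio[i] * p95
            planted_category[i] = (
                "severe_obesity" if ratio[i] >= config.severe_obesity_multiplier
                else "moderate_obesity"
            )

    # carrier CNVs at catalog loci
    if params.locus_weights is None:
        locus_w = np.ones(len(catalog))
    else:
        locus_w = np.array(
            [params.locus_weights.get(e.locus_id, 0.0) for e in catalog]
        )
        if (locus_w < 0).any() or locus_w.sum() == 0:
            raise ValueError("locus weights must be non-negative, not all zero")
    locus_idx = rng.choice(len(catalog), size=n, p=locus_w / locus_w.sum())
    size_u = rng.random(n)
    start_u = rng.random(n)
    type_u = rng.random(n)
    origin_u = rng.random(n)
    origin_cum = np.cumsum([w for _, w in _ORIGIN_MIX])
    cnvs: list[CNVCall] = []
    assigned_locus: list[Optional[str]] = [None] * n
    for i in range(n):
        if not carrier[i]:
            continue
        entry = catalog[locus_idx[i]]
        region = entry.region
        max_jitter = min(params.size_jitter_bp, region.length // 4)
        size = region.length - int(size_u[i] * max_jitter)
        start = region.start + int(start_u[i] * (region.length - size))
        if entry.causal_cnv_type == "dup":
            cnv_type = CnvType.DUP
        elif entry.causal_cnv_type == "del":
            cnv_type = CnvType.DEL
        else:
            cnv_type = CnvType.DUP if type_u[i] < params.dup_fraction else CnvType.DEL
        origin = _ORIGIN_MIX[int(np.searchsorted(origin_cum, origin_u[i]))][0]
        cnvs.append(
            CNVCall(
                patient_id=f"S{i + 1:04d}",
                interval=GenomicInterval(region.chrom, start, start + size),
                cnv_type=cnv_type,
                cytoband=entry.locus_id,
                origin=origin,
                clinical_class=ClinicalClass.PATHOGENIC,
                disorder_label=entry.description or entry.locus_id,
            )
        )
        assigned_locus[i] = entry.locus_id

    cnv_by_patient: dict[str, list[CNVCall]] = {}
    for c in cnvs:
        cnv_by_patient.setdefault(c.patient_id, []).append(c)
    patients = []
    for i in range(n):
        pid = f"S{i + 1:04d}"
        patients.append(
            PatientRecord(
                patient_id=pid,
                sex=Sex.M if male[i] else Sex.F,
                age_months=int(age_months[i]),
                bmi=None if np.isnan(bmi[i]) else float(bmi[i]),
                wfh_zscore=None if np.isnan(wfh_z[i]) else float(wfh_z[i]),
                weight_status_note=(
                    WeightStatusNote.REFERRED_OBESE
                    if missing[i]
                    else WeightStatusNote.MEASURED
                ),
                phenotypes={f: bool(pheno[i, col[f]]) for f in features},
                cnvs=cnv_by_patient.get(pid, []),
            )
        )
    frame = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "sex": np.where(male, "M", "F"),
            "age_months": age_months,
            "bmi": bmi,
            "wfh_zscore": wfh_z,
            "pcnv": carrier,
        }
        | {f"ph_{f}": pheno[:, col[f]].astype(float) for f in features}
    )
    truth = SyntheticTruth(
        carrier=carrier,
        assigned_locus=assigned_locus,
        feature_rate_noncarrier=dict(params.phenotype_base_rates),
        feature_rate_carrier=rate_c,
        pair_odds_ratios=pair_ors,
        severity_mix=params.severity_mix,
        planted_category=planted_category,
    )
    return SyntheticCohort(patients=patients, cnvs=cnvs, truth=truth, frame=frame)


def expected_summaries(truth: SyntheticTruth) -> dict:
    """Closed-form expectations for every planted quantity."""
    feature_or = {}
    for f, p0 in truth.feature_rate_noncarrier.items():
        p1 = truth.feature_rate_carrier[f]
        feature_or[f] = (p1 / (1 - p1)) / (p0 / (1 - p0))
    return {
        "feature_odds_ratios": feature_or,
        "pair_odds_ratios": dict(truth.pair_odds_ratios),
        "expected_severe_share": truth.severity_mix[1],
        "expected_carrier_rate": float(np.mean(truth.carrier)),
    }
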