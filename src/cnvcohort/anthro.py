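"""LMS growth-reference computations and obesity-severity grading.

A growth reference in LMS form gives, per sex and tabulation index (age
in months for BMI-for-age, height in cm for weight-for-height), a
Box-Cox power L, a median M and a coefficient of variation S. A
measurement x converts to a z-score by

    Z = ((x/M)**L - 1) / (L*S)      for L != 0
    Z = ln(x/M) / S                 for L == 0

and the inverse (the measurement at a given percentile) is

    x = M * (1 + L*S*z)**(1/L)      for L != 0
    x = M * exp(S*z)                for L == 0.

Pediatric obesity severity follows the percent-of-95th-percentile scale:
a BMI of 100-119% of the sex/age 95th-percentile BMI is moderate obesity
and >= 120% severe obesity; the extreme-BMI curves are the 95th-percentile
curve scaled by fixed multipliers (1.1x ... 1.9x).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AgeGroup, CohortConfig, PatientRecord, Sex

__all__ = [
    "LMSReference",
    "read_lms_csv",
    "lms_zscore",
    "lms_inverse",
    "zscore_to_percentile",
    "percentile_to_zscore",
    "SeverityCategory",
    "SeverityResult",
    "classify_weight_status",
    "extreme_bmi_curves",
]


class CoverageError(ValueError):
    """The reference table does not cover the requested sex/index."""


def lms_zscore(x: float, L: float, M: float, S: float):
    """Z-score of measurement ``x`` under an LMS triple; vectorized in x."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or M <= 0 or S <= 0:
        raise ValueError("x, M and S must be positive")
    if L == 0:
        z = np.log(x / M) / S
    else:
        z = ((x / M) ** L - 1.0) / (L * S)
    return z if z.ndim else float(z)


def lms_inverse(p: float, L: float, M: float, S: float):
    """Measurement at percentile ``p`` (0 < p < 100); vectorized in p."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 100):
        raise ValueError("percentile must lie strictly between 0 and 100")
    z = stats.norm.ppf(p / 100.0)
    x = _lms_from_z(z, L, M, S)
    return x if np.ndim(x) else float(x)


def _lms_from_z(z, L: float, M: float, S: float):
    if M <= 0 or S <= 0:
        raise ValueError("M and S must be positive")
    if L == 0:
        return M * np.exp(S * np.asarray(z, dtype=float))
    base = 1.0 + L * S * np.asarray(z, dtype=float)
    if np.any(base <= 0):
        raise ValueError("z outside the support of the Box-Cox transform")
    return M * base ** (1.0 / L)


def zscore_to_percentile(z) -> float:
    out = stats.norm.cdf(z) * 100.0
    return out if np.ndim(out) else float(out)


def percentile_to_zscore(p) -> float:
    out = stats.norm.ppf(np.asarray(p, dtype=float) / 100.0)
    return out if np.ndim(out) else float(out)


@dataclass
class LMSReference:
    """Sex- and index-tabulated L/M/S rows for one growth metric.

    ``metric`` names the measurement system (``bmi_for_age``,
    ``weight_for_height``, ...); the index is age in months or height in
    cm depending on the metric. Rows must be strictly increasing in index
    within each sex.
    """

    metric: str
    table: pd.DataFrame  # columns: sex, index, L, M, S

    def __post_init__(self) -> None:
        required = {"sex", "index", "L", "M", "S"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"LMS table needs columns {sorted(required)}")
        if (self.table["S"] <= 0).any() or (self.table["M"] <= 0).any():
            raise ValueError("M and S must be positive throughout")
        for sex, sub in self.table.groupby("sex"):
            idx = sub["index"].to_numpy()
            if not np.all(np.diff(idx) > 0):
                raise ValueError(f"index not strictly increasing for sex {sex}")

    def _sex_table(self, sex: Sex | str) -> pd.DataFrame:
        sex = Sex(sex).value
        sub = self.table[self.table["sex"] == sex]
        if sub.empty:
            raise CoverageError(f"{self.metric}: no rows for sex {sex}")
        return sub

    def index_range(self, sex: Sex | str) -> tuple[float, float]:
        sub = self._sex_table(sex)
        return float(sub["index"].iloc[0]), float(sub["index"].iloc[-1])

    def lookup(
        self, sex: Sex | str, index_value: float, interpolation: str = "linear"
    ) -> tuple[float, float, float]:
        """Interpolated (L, M, S) at ``index_value``.

        ``linear`` interpolates componentwise between the bracketing rows;
        ``nearest_half_month`` snaps to the closest tabulated row, choosing
        the lower row on exact midpoints.
        """
        sub = self._sex_table(sex)
        idx = sub["index"].to_numpy()
        lo, hi = idx[0], idx[-1]
        if not lo <= index_value <= hi:
            raise CoverageError(
                f"{self.metric}: index {index_value} outside [{lo}, {hi}] "
                f"for sex {Sex(sex).value}"
            )
        triples = sub[["L", "M", "S"]].to_numpy()
        if interpolation == "linear":
            L, M, S = (
                np.interp(index_value, idx, triples[:, k]) for k in range(3)
            )
            return float(L), float(M), float(S)
        if interpolation == "nearest_half_month":
            pos = int(np.searchsorted(idx, index_value))
            if pos == 0:
                choice = 0
            elif pos == len(idx):
                choice = len(idx) - 1
            elif idx[pos] == index_value:
                choice = pos
            else:
                below, above = idx[pos - 1], idx[pos]
                # exact midpoint ties resolve to the lower row
                choice = pos - 1 if index_value - below <= above - index_value else pos
            L, M, S = triples[choice]
            return float(L), float(M), float(S)
        raise ValueError(f"unknown interpolation mode {interpolation!r}")

    def zscore(self, sex, index_value: float, x: float, **kw) -> float:
        L, M, S = self.lookup(sex, index_value, **kw)
        return float(lms_zscore(x, L, M, S))

    def percentile_value(self, sex, index_value: float, p: float, **kw) -> float:
        L, M, S = self.lookup(sex, index_value, **kw)
        return float(lms_inverse(p, L, M, S))


_SEX_CODES = {"1": "M", "2": "F", "m": "M", "f": "F", "male": "M", "female": "F"}
_INDEX_COLUMNS = ("agemos", "age", "height", "length", "index")


def read_lms_csv(path: str | Path, metric: str = "bmi_for_age") -> LMSReference:
    """Read an LMS reference CSV in the CDC column dialect.

    Columns are matched case-insensitively: Sex (1=male, 2=female, or
    M/F), one index column (Agemos / Height / ...), and L, M, S. Extra
    columns (tabulated percentiles) are ignored; ``#`` comment lines are
    skipped.
    """
    df = pd.read_csv(path, comment="#")
    lower = {c.lower().strip(): c for c in df.columns}
    missing = [c for c in ("sex", "l", "m", "s") if c not in lower]
    if missing:
        raise ValueError(f"{path}: missing LMS column(s) {missing}")
    index_col = next((lower[c] for c in _INDEX_COLUMNS if c in lower), None)
    if index_col is None:
        raise ValueError(f"{path}: no recognizable index column {_INDEX_COLUMNS}")
    out = pd.DataFrame(
        {
            "sex": df[lower["sex"]]
            .astype(str)
            .str.strip()
            .str.lower()
            .map(_SEX_CODES),
            "index": df[index_col].astype(float),
            "L": df[lower["l"]].astype(float),
            "M": df[lower["m"]].astype(float),
            "S": df[lower["s"]].astype(float),
        }
    )
    if out["sex"].isna().any():
        raise ValueError(f"{path}: unrecognized sex codes")
    out = out.sort_values(["sex", "index"], kind="mergesort").reset_index(drop=True)
    return LMSReference(metric=metric, table=out)


class SeverityCategory(str, enum.Enum):
    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    MODERATE_OBESITY = "moderate_obesity"
    SEVERE_OBESITY = "severe_obesity"
    ADULT_OBESITY = "adult_obesity"
    INFANT_HIGH_WFH = "infant_high_wfh"
    UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class SeverityResult:
    patient_id: str
    category: SeverityCategory
    zscore: Optional[float] = None
    percentile: Optional[float] = None
    pct_of_95th: Optional[float] = None

    @property
    def is_obese(self) -> bool:
        return self.category in (
            SeverityCategory.MODERATE_OBESITY,
            SeverityCategory.SEVERE_OBESITY,
            SeverityCategory.ADULT_OBESITY,
        )


def classify_weight_status(
    patient: PatientRecord,
    refs: dict[str, LMSReference],
    config: CohortConfig = CohortConfig(),
    interpolation: str = "linear",
) -> SeverityResult:
    """Age-group-appropriate weight-status classification.

    * infants (< 24 mo): weight-for-height z-score; above
      ``config.infant_wfh_z`` flags excessive weight gain;
    * children/adolescents (24-239 mo): BMI-for-age percentile, with the
      moderate/severe obesity split on percent of the 95th-percentile BMI;
    * adults (>= 240 mo): absolute BMI against ``config.adult_obesity_bmi``.

    Patients referred as obese (or with hyperphagia only) but lacking the
    required measurement are unclassifiable: they stay in the cohort but
    drop out of severity strata.
    """
    group = patient.age_group
    if group is AgeGroup.INFANT:
        z = patient.wfh_zscore
        if z is None:
            if (
                patient.weight_kg is not None
                and patient.height_cm is not None
                and "weight_for_height" in refs
            ):
                z = refs["weight_for_height"].zscore(
                    patient.sex, patient.height_cm, patient.weight_kg,
                    interpolation=interpolation,
                )
            else:
                return SeverityResult(patient.patient_id, SeverityCategory.UNCLASSIFIABLE)
        pct = zscore_to_percentile(z)
        category = (
            SeverityCategory.INFANT_HIGH_WFH
            if z > config.infant_wfh_z
            else SeverityCategory.NORMAL
        )
        return SeverityResult(patient.patient_id, category, zscore=z, percentile=pct)

    if group is AgeGroup.ADULT:
        bmi = patient.bmi
        if bmi is None and patient.weight_kg and patient.height_cm:
            bmi = patient.weight_kg / (patient.height_cm / 100.0) ** 2
        if bmi is None:
            return SeverityResult(patient.patient_id, SeverityCategory.UNCLASSIFIABLE)
        if bmi >= config.adult_obesity_bmi:
            category = SeverityCategory.ADULT_OBESITY
        elif bmi >= 25:
            category = SeverityCategory.OVERWEIGHT
        elif bmi >= 18.5:
            category = SeverityCategory.NORMAL
        else:
            category = SeverityCategory.UNDERWEIGHT
        return SeverityResult(patient.patient_id, category)

    # children and adolescents
    bmi = patient.bmi
    if bmi is None and patient.weight_kg and patient.height_cm:
        bmi = patient.weight_kg / (patient.height_cm / 100.0) ** 2
    if bmi is None:
        return SeverityResult(patient.patient_id, SeverityCategory.UNCLASSIFIABLE)
    if "bmi_for_age" not in refs:
        raise CoverageError("bmi_for_age reference required for children/adolescents")
    ref = refs["bmi_for_age"]
    L, M, S = ref.lookup(patient.sex, patient.age_months, interpolation=interpolation)
    z = float(lms_zscore(bmi, L, M, S))
    pct = zscore_to_percentile(z)
    p95 = float(lms_inverse(config.obesity_percentile_cut, L, M, S))
    ratio = 100.0 * bmi / p95
    if pct >= config.obesity_percentile_cut:
        # tolerance so a BMI constructed as exactly multiplier * P95
        # lands on the severe side despite rounding in the ratio
        category = (
            SeverityCategory.SEVERE_OBESITY
            if ratio >= 100.0 * config.severe_obesity_multiplier - 1e-9
            else SeverityCategory.MODERATE_OBESITY
        )
    elif pct >= config.overweight_percentile_cut:
        category = SeverityCategory.OVERWEIGHT
    elif pct >= 5:
        category = SeverityCategory.NORMAL
    else:
        category = SeverityCategory.UNDERWEIGHT
    return SeverityResult(
        patient.patient_id, category, zscore=z, percentile=pct, pct_of_95th=ratio
    )


def extreme_bmi_curves(
    ref: LMSReference,
    multipliers: Iterable[float],
    sex: Sex | str,
    ages_months: Sequence[float],
    base_percentile: float = 95.0,
) -> pd.DataFrame:
    """Extreme-BMI curves: the ``base_percentile`` BMI curve scaled by
    each multiplier, per age. Returns long-form (age_months, multiplier,
    bmi)."""
    multipliers = list(multipliers)
    if any(not 1.0 <= m <= 3.0 for m in multipliers):
        raise ValueError("multipliers must lie in [1, 3]")
    rows = []
    for age in ages_months:
        p95 = ref.percentile_value(sex, age, base_percentile)
        for m in multipliers:
            rows.append(
                {"age_months": float(age), "multiplier": float(m), "bmi": m * p95}
            )
    return pd.DataFrame(rows)
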