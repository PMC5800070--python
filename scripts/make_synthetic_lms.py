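"""Regenerate the packaged synthetic LMS growth-reference fixtures.

The packaged tables are *synthetic*: smooth, monotone-median curves with
realistic magnitudes for pediatric BMI-for-age (24-240 months) and infant
weight-for-height (65-120 cm), in the CDC CSV column dialect
(Sex, Agemos/Height, L, M, S; sex coded 1=male, 2=female). They exercise
every LMS code path without bundling any third-party reference data; real
CDC files load through the same reader.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

DATA = Path(__file__).resolve().parents[1] / "src" / "cnvcohort" / "data"


def bmi_lms(age_months: np.ndarray, sex: str):
    """Smooth BMI-for-age curves: median dips in early childhood then
    rises through adolescence; skewness deepens and spread widens with
    age, a little more in males."""
    t = (age_months - 24.0) / 216.0  # 0..1 over 24-240 months
    if sex == "M":
        M = 16.6 - 4.6 * t + 14.0 * t**2 - 4.6 * t**3
        S = 0.082 + 0.055 * t
    else:
        M = 16.4 - 4.2 * t + 14.2 * t**2 - 4.9 * t**3
        S = 0.086 + 0.060 * t
    L = -1.3 - 1.4 * t * (2.0 - t) / 1.0 * 0.5 - 0.3 * t
    return L, M, S


def wfh_lms(height_cm: np.ndarray, sex: str):
    """Weight-for-height: near-power-law median, mild positive skew."""
    a = 7.3 if sex == "M" else 7.1
    M = a * (height_cm / 65.0) ** 1.85
    L = np.full_like(height_cm, -0.4, dtype=float)
    S = 0.080 + 0.0002 * (height_cm - 65.0)
    return L, M, S


def write(path: Path, index_name: str, index: np.ndarray, fn) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        fh.write("# synthetic LMS reference fixture; regenerate with "
                 "scripts/make_synthetic_lms.py\n")
        writer.writerow(["Sex", index_name, "L", "M", "S"])
        for code, sex in ((1, "M"), (2, "F")):
            L, M, S = fn(index, sex)
            L = np.broadcast_to(L, index.shape)
            for i, x in enumerate(index):
                writer.writerow(
                    [code, f"{x:g}", f"{float(L[i]):.4f}",
                     f"{float(M[i]):.4f}", f"{float(S[i]):.5f}"]
                )


def main() -> None:
    ages = np.arange(24.0, 240.5 + 0.001, 0.5)
    heights = np.arange(65.0, 120.0 + 0.001, 0.5)
    write(DATA / "lms_bmi_for_age_synthetic.csv", "Agemos", ages, bmi_lms)
    write(DATA / "lms_weight_for_height_synthetic.csv", "Height", heights, wfh_lms)
    print("wrote", DATA / "lms_bmi_for_age_synthetic.csv")
    print("wrote", DATA / "lms_weight_for_height_synthetic.csv")


if __name__ == "__main__":
    main()
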