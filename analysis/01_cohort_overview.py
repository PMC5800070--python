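"""Diagnostic-yield overview of the packaged CMA cohort.

Validates the packaged 61-patient pathogenic-CNV case series against its
cohort table, then tallies the yield of the 279-patient screen it came
from: carriers, imbalances by type/size, inheritance, known-disorder and
causal-obesity overlap. Writes results/tally.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from cnvcohort import resources, tally, causal_obesity_yield
from cnvcohort.validate import validate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    patients = resources.load_pcnv_patients()
    calls = resources.load_pcnv_calls()
    catalog = resources.load_locus_catalog()

    report = validate_cohort(patients, calls)
    print(f"validation: {report.summary().splitlines()[0]}")
    if not report.ok:
        sys.exit(1)

    t = tally(patients, calls, catalog, n_cohort=resources.SCREENED_COHORT_SIZE)
    df = pd.DataFrame(t.to_rows())
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "tally.tsv", sep="\t", index=False)

    print(f"\n{t.count('pcnv_patients')} of {t.n_cohort} screened patients "
          f"({t['pcnv_patients'].pct:.0f}%) carry pathogenic CNVs, "
          f"{t.count('pathogenic_imbalances')} imbalances in total "
          f"({t.count('del')} deletions, {t.count('dup')} duplications; "
          f"{t.count('large')} exceed 5 Mb).")
    print(f"Inheritance (per carrier): {t.count('origin_de_novo')} de novo, "
          f"{t.count('origin_inherited')} inherited, "
          f"{t.count('origin_not_maternal')} not-maternal, "
          f"{t.count('origin_unknown')} undetermined.")
    n_causal, pct = causal_obesity_yield(patients, calls, catalog, t.n_cohort)
    n_top3, pct3 = causal_obesity_yield(
        patients, calls, catalog, t.n_cohort, loci=("1p36", "2q37", "17p11.2")
    )
    print(f"{t.count('known_disorder_patients')} carriers match known "
          f"genomic-disorder regions; {n_causal} ({pct}%) hit loci causal for "
          f"syndromic obesity, {n_top3} ({pct3}%) the three most frequent "
          f"deletion syndromes (1p36, 2q37, 17p11.2).")
    print(f"\nwrote {RESULTS / 'tally.tsv'}")


if __name__ == "__main__":
    main()
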