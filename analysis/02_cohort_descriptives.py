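#!/usr/bin/env python
"""Apply the eligibility filters and produce the descriptive tables.

Reads the patient-level table, runs the five-step filter contract (2016
diagnosis window, complete demographics, no treatment switching, the four
study strategies, minimum 0.5% strategy share), and writes the filter
report, the treatment frequency table and crude mortality rates per 1000
patient-years.
"""

import argparse
from pathlib import Path

import drcausal as dc


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--min-share", type=float, default=0.005)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    records = dc.read_cohort_csv(args.cohort)
    filtered, report = dc.apply_study_filters(
        records, min_treatment_share=args.min_share
    )
    report.to_json(args.outdir / "filter_report.json")
    dc.write_cohort_csv(filtered, args.outdir / "cohort_filtered.csv")

    freq = dc.treatment_frequency_table(filtered)
    freq.to_csv(args.outdir / "treatment_frequencies.csv", index=False)

    mort = dc.mortality_rate(filtered)
    mort.to_csv(args.outdir / "mortality_rates.csv", index=False)

    print("filter chain:")
    for name, n_in, n_out in report.steps:
        print(f"  {name}: {n_in} -> {n_out}")
    print("\ntreatment frequencies:\n", freq.to_string(index=False))
    print("\nmortality per 1000 patient-years:\n",
          mort.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
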