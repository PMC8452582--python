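"""Simulate the study cohort and export its raw measurement data.

Generates the default 82 healthy volunteers + 19 HFrEF patients with paired
conventional/CS measurements and two repeat-reader variants, writes all
sampled time-volume curves as long-format CSV, one example contour file, and
prints the group-level phenotype summary.
"""

from pathlib import Path

import numpy as np

from atriakit.core import TimeVolumeCurve
from atriakit.io import cohort_curves_frame, write_contours_json, write_curves_csv
from atriakit.pipeline import summarize_distribution
from atriakit.synthetic_data import CohortConfig, contours_from_curve, generate_cohort

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260928 % (2**31 - 1)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cohort = generate_cohort(CohortConfig(n_hv=82, n_hfref=19, seed=SEED))
    df = cohort_curves_frame(cohort)
    write_curves_csv(df, OUT / "cohort_curves.csv")
    print(f"wrote {len(df)} curve samples for {cohort.n_subjects} subjects "
          f"({(cohort.group == 'HV').sum()} HV / "
          f"{(cohort.group == 'HFrEF').sum()} HFrEF)")

    example = TimeVolumeCurve(cohort.curves("LA", "conv")[0])
    write_contours_json(
        contours_from_curve(example, vertices=200), OUT / "example_contours.json"
    )

    print("\nconventional-technique phenotype summary (median [IQR]):")
    for group in ("HV", "HFrEF"):
        mask = cohort.group == group
        params = {
            **cohort.parameters("LA", "conv"),
            **cohort.parameters("RA", "conv"),
        }
        parts = []
        for name in ("LAVmin", "LAVmax", "TEF", "PEF", "AEF"):
            s = summarize_distribution(params[name][mask], form="median_iqr")
            parts.append(f"{name} {s.text()}")
        print(f"  {group:6s} " + "; ".join(parts))


if __name__ == "__main__":
    main()
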