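"""Quantify landmark-detection accuracy on noise-free and noisy curves.

Every synthetic curve carries its generating control landmarks as ground
truth, so the emptying-fraction error of the detection chain (circular
smoothing, cyclic extremum search, half-window refinement on the raw curve)
can be measured directly. Writes per-parameter error summaries for the
noise-free case and for the default 1 ml per-phase noise.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from atriakit.atrial_function import compute_function_batch, locate_landmarks_batch
from atriakit.synthetic_data import CohortConfig, generate_cohort, sample_curves

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260928 % (2**31 - 1)


def recovery(noise_sd: float) -> list[dict]:
    cfg = CohortConfig(n_hv=100, n_hfref=100, seed=SEED, curve_noise_sd=noise_sd)
    cohort = generate_cohort(cfg, readers=False)
    curves = cohort.curves("LA", "conv")
    fn = compute_function_batch(locate_landmarks_batch(curves, smooth_window=3))
    truth = cohort.parameters("LA", "conv")
    rows = []
    for name, est in (("TEF", fn["tef"]), ("PEF", fn["pef"]), ("AEF", fn["aef"])):
        err = np.abs(est - truth[name])
        rows.append({
            "parameter": name,
            "noise_sd_ml": noise_sd,
            "mean_abs_error_pct_points": round(float(np.nanmean(err)), 3),
            "p95_abs_error_pct_points": round(float(np.nanpercentile(err, 95)), 3),
            "max_abs_error_pct_points": round(float(np.nanmax(err)), 3),
            "n_invalid": int(np.isnan(est).sum()),
            "n": est.size,
        })
    return rows


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = pd.DataFrame(recovery(0.0) + recovery(1.0))
    table.to_csv(OUT / "landmark_recovery.csv", index=False)
    print(table.to_string(index=False))
    nf = table[table["noise_sd_ml"] == 0.0]
    print(f"\nnoise-free worst error {nf['max_abs_error_pct_points'].max():.2f} "
          "percentage points across 200 curves - pure 25-phase sampling error")


if __name__ == "__main__":
    main()
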