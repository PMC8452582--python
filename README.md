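# atriakit

Atrial cine-CMR volumetry, time-volume-curve function, edge sharpness, and
method-agreement statistics — a tested re-implementation of the analysis
side of an atrial compressed-sensing (CS) cine comparison study, driven
entirely by synthetic cohorts and phantom images with known ground truth.

## The problem

Accelerated (compressed-sensing) cine sequences cut atrial acquisition time
by ~70 %, but before they can replace conventional cine clinically, their
atrial measurements must agree with the conventional ones and discriminate
disease equally well. The measurements at stake are, per subject:

* **volumes** by the area-length technique — biplane for the left atrium,
  `V = (8/3π)·A₂·A₄/L` from the 2- and 4-chamber views, monoplane
  `V = (8/3π)·A²/L` for the right atrium (no dedicated right-heart
  2-chamber view);
* **function** from the 25-phase time-volume curve via its four landmarks
  (Vmax, mid-diastolic Vmin and Vmax, Vmin):

      TEF = 100·(Vmax − Vmin)/Vmax                 (reservoir)
      PEF = 100·(Vmax − mid-diastolic Vmin)/Vmax   (conduit)
      AEF = 100·(mid-diastolic Vmax − Vmin)/mid-diastolic Vmax  (booster)

* **image sharpness** as the mean inverse 20–80 % rise distance (1/d,
  mm⁻¹) across 8 intensity profiles drawn orthogonally to the
  myocardium/blood-pool edge found by a Deriche gradient + Hough line;
* **agreement and diagnostics**: Mann-Whitney U, R², two-way
  absolute-agreement ICC, Bland-Altman bias and limits of agreement,
  Fleiss κ, ROC/AUC with Youden operating points, and the DeLong test for
  paired AUCs.

The study's raw scans are not public, so this package ships a first-class
synthetic-data module: cohorts of healthy-volunteer and HFrEF curve
phenotypes with configurable conventional-vs-CS disagreement and reader
jitter, elliptical contours that invert the area-length formula, and
phantom frames with a linear-ramp edge of known width (true sharpness
`1/(0.6·width)`). Every downstream stage is tested against this ground
truth; see `docs/methods.md` for models, parameters, and limitations.

## Worked example

```python
from atriakit import (
    CurvePhenotype, generate_volume_curve, contours_from_curve,
    curve_from_contours, find_landmarks, compute_function,
)

# a healthy-volunteer-like curve: Vmin 24, diastasis 35, pre-A 40, Vmax 70 ml
pheno = CurvePhenotype(v_min=24, v_dia=35, v_preA=40, v_max=70)
curve = generate_volume_curve(pheno, phases=25, seed=0)

# invert to contours, measure back through biplane area-length volumetry
measured = curve_from_contours(contours_from_curve(curve, vertices=200), "LA")
fn = compute_function(find_landmarks(measured, smooth_window=3))
print(f"TEF {fn.tef:.1f}%  PEF {fn.pef:.1f}%  AEF {fn.aef:.1f}%")
```

prints

```
TEF 65.7%  PEF 49.8%  AEF 40.0%
```

— the emptying fractions implied by the control landmarks
(TEF = 100·(70−24)/70 = 65.7 %, PEF = 50 %, AEF = 40 %), recovered through
the full contour → volume → landmark chain. The area-length round trip at
200 vertices is accurate to < 0.01 %; the 0.2-point PEF deficit is the
25-phase sampling error at the diastasis landmark, which falls between two
reconstructed phases.

The numbered scripts under `analysis/` run the study end to end and write
tables under `results/`:

```
01_simulate_cohort.py       # 82 HV + 19 HFrEF, curves CSV + contours JSON
02_volumetry_validation.py  # spheroid exactness + round-trip convergence
03_function_recovery.py     # landmark recovery vs generator ground truth
04_sharpness_phantoms.py    # ramp-oracle sweep + conv-vs-CS comparison
05_agreement_report.py      # technique / observer / diagnostic tables
```

For example, `05_agreement_report.py` reports for the default seed a
technique comparison whose LAVmin row reads bias −1.7 ml, LoA −9.4 to
6.0 ml, ICC 0.93, and a diagnostic table where PEF (AUC 0.99) and LAVmin
(AUC 0.96) lead the seven parameters — the structure the pipeline is
calibrated to reproduce. A CLI mirrors the scripts for shell use:
`atriakit simulate|volumes|function|sharpness|run` (see `--help`).

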