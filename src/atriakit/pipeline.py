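"""End-to-end study runs: simulate, measure, compare, report.

``run_study`` chains the synthetic cohort generator, area-length volumetry
(through the contour round trip), landmark extraction, and the statistics
battery into the three report tables of a technique-comparison study:

* technique comparison per parameter (median/IQR per technique, Mann-Whitney
  p, R^2, Bland-Altman bias and limits of agreement, ICC);
* inter- and intra-observer ICCs for the four volume parameters;
* diagnostic performance (AUC, sensitivity, specificity at the Youden
  cutoff) per parameter and technique, with the paired DeLong p;

plus a conventional-vs-CS phantom sharpness comparison. All numbers are kept
at full precision in memory and rounded only at serialization (1 decimal for
ml and percent, 2 for ICC/R^2/AUC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement_stats as ag
from .atrial_function import compute_function_batch, locate_landmarks_batch
from .core import AtriakitError
from .sharpness import SharpnessConfig, compute_sharpness
from .synthetic_data import (
    Cohort,
    CohortConfig,
    PhantomImageConfig,
    REPORT_PARAMETERS,
    TechniqueDisagreementModel,
    ellipse_polygons,
    generate_cohort,
)
from .volumetry import atrial_length, biplane_volume, monoplane_volume, polygon_area

__all__ = [
    "RunConfig",
    "StudyReport",
    "DistributionSummary",
    "run_study",
    "summarize_distribution",
    "measure_parameters",
    "PARAMETER_CHAMBER",
    "PARAMETER_DIRECTION",
]

#: Which chamber each report parameter is measured from.
PARAMETER_CHAMBER = {
    "LAVmin": "LA", "LAVmax": "LA", "TEF": "LA", "PEF": "LA", "AEF": "LA",
    "RAVmin": "RA", "RAVmax": "RA",
}

#: Expected direction of separation: +1 = higher in HFrEF (volumes),
#: -1 = lower in HFrEF (emptying fractions).
PARAMETER_DIRECTION = {
    "LAVmin": +1, "LAVmax": +1, "RAVmin": +1, "RAVmax": +1,
    "TEF": -1, "PEF": -1, "AEF": -1,
}

VOLUME_PARAMETERS = ("LAVmin", "LAVmax", "RAVmin", "RAVmax")


@dataclass
class RunConfig:
    """Configuration of one end-to-end study run (simulate mode)."""

    seed: int = 0
    cohort: CohortConfig | None = None
    disagreement: TechniqueDisagreementModel | None = None
    smooth_window: int = 3
    via_contours: bool = True   # measure volumes through the contour round trip
    vertices: int = 200
    aspect_ratio: float = 0.7
    length_rule: str = "min"
    include_readers: bool = True
    include_sharpness: bool = True
    n_phantoms: int = 8
    conv_edge_width_mm: float = 2.5
    cs_edge_width_mm: float = 4.0
    phantom_noise_sd: float = 5.0

    def resolved_cohort(self) -> CohortConfig:
        cfg = self.cohort or CohortConfig()
        cfg.seed = self.seed if self.cohort is None else cfg.seed
        return cfg


@dataclass
class DistributionSummary:
    form: str          # "median_iqr" or "mean_sd"
    location: float    # median or mean
    low: float         # q1 or mean - sd
    high: float        # q3 or mean + sd
    n: int

    def text(self, decimals: int = 1) -> str:
        if self.form == "median_iqr":
            return (
                f"{self.location:.{decimals}f} "
                f"[{self.low:.{decimals}f}-{self.high:.{decimals}f}]"
            )
        sd = (self.high - self.low) / 2.0
        return f"{self.location:.{decimals}f} +- {sd:.{decimals}f}"


def summarize_distribution(values, form: str | None = None) -> DistributionSummary:
    """Median/IQR or mean +- SD, gated by the KS normality test.

    Quartiles use linear interpolation (type 7), the SPSS-compatible
    convention. Pass ``form`` ("median_iqr" / "mean_sd") to bypass the
    gate and force one reporting style.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 5:
        raise AtriakitError("need at least 5 values to summarise")
    if np.ptp(v) == 0:
        raise AtriakitError("degenerate (constant) distribution")
    if form is None:
        _, p = ag.ks_normality(v)
        form = "median_iqr" if p < 0.05 else "mean_sd"
    if form == "median_iqr":
        q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
        return DistributionSummary("median_iqr", float(med), float(q1), float(q3), v.size)
    mean, sd = float(v.mean()), float(v.std(ddof=1))
    return DistributionSummary("mean_sd", mean, mean - sd, mean + sd, v.size)


# ---------------------------------------------------------------------------
# measurement: cohort landmarks -> (optionally) contours -> parameters
# ---------------------------------------------------------------------------

def _volumes_through_contours(
    curves: np.ndarray, chamber: str, vertices: int, aspect_ratio: float,
    length_rule: str,
) -> np.ndarray:
    """Round-trip each curve through elliptical contours and area-length."""
    polys, annuli = ellipse_polygons(curves, aspect_ratio, vertices)
    areas = polygon_area(polys)
    lengths = atrial_length(polys, annuli)
    if chamber == "LA":  # identical synthetic 2CH/4CH views
        return biplane_volume(areas, areas, lengths, lengths, length_rule=length_rule)
    return monoplane_volume(areas, lengths)


def measure_parameters(
    cohort: Cohort,
    chamber: str,
    technique: str,
    reader: str,
    config: RunConfig,
) -> dict[str, np.ndarray]:
    """Per-subject report parameters measured from sampled curves.

    Runs the full measurement chain (curve sampling with noise, optional
    contour round trip, landmark detection, emptying fractions). Subjects
    whose noisy landmarks violate an ordering prerequisite get NaN for the
    affected parameters only.
    """
    curves = cohort.curves(chamber, technique, reader)
    if curves.shape[0] == 0:
        names = ("LAVmin", "LAVmax", "TEF", "PEF", "AEF") if chamber == "LA" \
            else ("RAVmin", "RAVmax")
        return {p: np.empty(0) for p in names}
    if config.via_contours:
        curves = _volumes_through_contours(
            curves, chamber, config.vertices, config.aspect_ratio,
            config.length_rule,
        )
    lm = locate_landmarks_batch(curves, config.smooth_window)
    if chamber == "RA":
        return {"RAVmin": lm["v_min"], "RAVmax": lm["v_max"]}
    fn = compute_function_batch(lm)
    return {
        "LAVmin": lm["v_min"],
        "LAVmax": lm["v_max"],
        "TEF": fn["tef"],
        "PEF": fn["pef"],
        "AEF": fn["aef"],
    }


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    table3: pd.DataFrame        # technique comparison, 7 parameter rows
    table4: pd.DataFrame        # inter/intra-observer ICCs
    table5: pd.DataFrame        # diagnostic performance
    sharpness: dict
    seed: int
    failures: list = field(default_factory=list)

    @property
    def any_failed(self) -> bool:
        return bool(self.failures) or (self.table3["status"] != "ok").any()

    def _rounded_table3(self) -> pd.DataFrame:
        t = self.table3.copy()
        for c in ("bias", "loa_lower", "loa_upper"):
            t[c] = t[c].round(1)
        for c in ("r_squared", "icc"):
            t[c] = t[c].round(2)
        t["p_mwu"] = t["p_mwu"].map(
            lambda p: "<0.0001" if (np.isfinite(p) and p < 1e-4) else round(p, 4)
        )
        return t

    def _rounded_table5(self) -> pd.DataFrame:
        t = self.table5.copy()
        for c in ("auc_conv", "auc_cs"):
            t[c] = t[c].round(2)
        for c in ("sens_conv", "spec_conv", "sens_cs", "spec_cs"):
            t[c] = t[c].round(1)
        t["p_delong"] = t["p_delong"].round(3)
        return t

    def to_csv(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self._rounded_table3().to_csv(out / "technique_comparison.csv", index=False)
        self.table4.round(2).to_csv(out / "observer_agreement.csv", index=False)
        self._rounded_table5().to_csv(out / "diagnostic_performance.csv", index=False)
        with open(out / "sharpness.json", "w") as fh:
            json.dump(self.sharpness, fh, indent=2, sort_keys=True)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "technique_comparison": self._rounded_table3().to_dict("records"),
            "observer_agreement": self.table4.round(2).to_dict("records"),
            "diagnostic_performance": self._rounded_table5().to_dict("records"),
            "sharpness": self.sharpness,
            "failures": self.failures,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _joint_finite(*arrays):
    mask = np.ones(arrays[0].shape, dtype=bool)
    for a in arrays:
        mask &= np.isfinite(a)
    return mask


def _technique_comparison(params_conv, params_cs) -> pd.DataFrame:
    rows = []
    for name in REPORT_PARAMETERS:
        row = {"parameter": name, "status": "ok", "reason": ""}
        try:
            a, b = params_conv[name], params_cs[name]
            mask = _joint_finite(a, b)
            a, b = a[mask], b[mask]
            sa, sb = summarize_distribution(a), summarize_distribution(b)
            _, p = ag.mann_whitney_u(a, b)
            ba = ag.bland_altman(a, b)
            row.update(
                conv=sa.text(), cs=sb.text(), n=int(mask.sum()),
                n_excluded=int((~mask).sum()),
                p_mwu=p,
                r_squared=ag.r_squared(a, b),
                bias=ba.bias, loa_lower=ba.loa_lower, loa_upper=ba.loa_upper,
                icc=ag.icc_absolute(np.column_stack([a, b])),
            )
        except AtriakitError as err:
            row.update(
                status="failed", reason=str(err), conv="", cs="", n=0,
                n_excluded=0, p_mwu=np.nan, r_squared=np.nan, bias=np.nan,
                loa_lower=np.nan, loa_upper=np.nan, icc=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _observer_agreement(measurements, cohort: Cohort, rng) -> pd.DataFrame:
    """Inter-observer (R1 vs R2) and intra-observer (R1 vs repeat) ICCs.

    Mirrors the emulated study's subsets: up to 20 HV + 19 HFrEF for the
    inter-observer analysis, up to 20 HV for the intra-observer one.
    """
    hv_idx = np.flatnonzero(cohort.group == "HV")
    hf_idx = np.flatnonzero(cohort.group == "HFrEF")
    inter_idx = np.concatenate([
        rng.choice(hv_idx, size=min(20, hv_idx.size), replace=False),
        rng.choice(hf_idx, size=min(19, hf_idx.size), replace=False),
    ]).astype(int)
    intra_idx = rng.choice(hv_idx, size=min(20, hv_idx.size), replace=False)
    rows = []
    for name in VOLUME_PARAMETERS:
        chamber = PARAMETER_CHAMBER[name]
        row = {"parameter": name}
        for tech in ("conv", "cs"):
            r1 = measurements[(chamber, tech, "R1")][name]
            r2 = measurements[(chamber, tech, "R2")][name]
            r1b = measurements[(chamber, tech, "R1b")][name]
            m_inter = np.column_stack([r1[inter_idx], r2[inter_idx]])
            m_intra = np.column_stack([r1[intra_idx], r1b[intra_idx]])
            m_inter = m_inter[_joint_finite(m_inter[:, 0], m_inter[:, 1])]
            m_intra = m_intra[_joint_finite(m_intra[:, 0], m_intra[:, 1])]
            row[f"icc_inter_{tech}"] = ag.icc_absolute(m_inter)
            row[f"icc_intra_{tech}"] = ag.icc_absolute(m_intra)
        rows.append(row)
    return pd.DataFrame(rows)


def _diagnostic_performance(params_conv, params_cs, labels) -> pd.DataFrame:
    rows = []
    for name in REPORT_PARAMETERS:
        direction = PARAMETER_DIRECTION[name]
        row = {"parameter": name, "status": "ok"}
        try:
            a, b = params_conv[name], params_cs[name]
            mask = _joint_finite(a, b)
            a, b, y = a[mask], b[mask], labels[mask]
            roc_a = ag.roc_auc(a, y, direction)
            roc_b = ag.roc_auc(b, y, direction)
            _, p, _, _ = ag.delong_test(a * direction, b * direction, y)
            row.update(
                auc_conv=roc_a.auc, sens_conv=roc_a.sensitivity,
                spec_conv=roc_a.specificity,
                auc_cs=roc_b.auc, sens_cs=roc_b.sensitivity,
                spec_cs=roc_b.specificity,
                p_delong=p,
            )
        except AtriakitError as err:
            row.update(
                status="failed", reason=str(err),
                auc_conv=np.nan, sens_conv=np.nan, spec_conv=np.nan,
                auc_cs=np.nan, sens_cs=np.nan, spec_cs=np.nan, p_delong=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _sharpness_comparison(config: RunConfig) -> dict:
    """Phantom-based sharpness of a sharp (conventional) vs blurred (CS) edge."""
    values = {"conv": [], "cs": []}
    for i in range(config.n_phantoms):
        for tech, width in (
            ("conv", config.conv_edge_width_mm),
            ("cs", config.cs_edge_width_mm),
        ):
            phantom = PhantomImageConfig(
                edge_width_mm=width,
                tilt_deg=10.0 + 9.0 * i,
                noise_sd=config.phantom_noise_sd,
                seed=int(config.seed % (2**31 - 1) + 97 * i + (0 if tech == "conv" else 1)),
            )
            from .synthetic_data import render_phantom_frame

            frame = render_phantom_frame(phantom)
            res = compute_sharpness(
                frame.image, frame.sidecar["pixel_spacing_mm"], SharpnessConfig()
            )
            values[tech].append(res.sharpness)
    conv = np.array(values["conv"])
    cs = np.array(values["cs"])
    _, p = ag.mann_whitney_u(conv, cs)
    return {
        "conv_mean_mm_inv": float(conv.mean()),
        "conv_sd_mm_inv": float(conv.std(ddof=1)) if conv.size > 1 else 0.0,
        "cs_mean_mm_inv": float(cs.mean()),
        "cs_sd_mm_inv": float(cs.std(ddof=1)) if cs.size > 1 else 0.0,
        "p_mwu": float(p),
        "conv_edge_width_mm": config.conv_edge_width_mm,
        "cs_edge_width_mm": config.cs_edge_width_mm,
        "n_phantoms": config.n_phantoms,
    }


def run_study(config: RunConfig | None = None) -> StudyReport:
    """Simulate a cohort and produce the full study report.

    Deterministic for a fixed seed: the same configuration serialises to
    byte-identical CSV/JSON. A failed parameter row does not abort the run;
    it is marked in the row's status with the failing stage's message.
    """
    config = config or RunConfig()
    cohort_cfg = config.resolved_cohort()
    cohort = generate_cohort(
        cohort_cfg, config.disagreement, readers=config.include_readers
    )

    combos = [("LA", t, r) for t in ("conv", "cs")
              for r in (("R1", "R2", "R1b") if config.include_readers else ("R1",))]
    combos += [("RA", t, r) for t in ("conv", "cs")
               for r in (("R1", "R2", "R1b") if config.include_readers else ("R1",))]
    measurements = {
        key: measure_parameters(cohort, *key, config=config) for key in combos
    }
    params_conv = {**measurements[("LA", "conv", "R1")],
                   **measurements[("RA", "conv", "R1")]}
    params_cs = {**measurements[("LA", "cs", "R1")],
                 **measurements[("RA", "cs", "R1")]}

    failures: list[str] = []
    table3 = _technique_comparison(params_conv, params_cs)

    if config.include_readers and cohort.n_subjects >= 2:
        obs_rng = np.random.default_rng(
            np.random.SeedSequence([cohort_cfg.seed, 0x0B5]))
        try:
            table4 = _observer_agreement(measurements, cohort, obs_rng)
        except AtriakitError as err:
            failures.append(f"observer agreement: {err}")
            table4 = pd.DataFrame()
    else:
        table4 = pd.DataFrame()

    labels = cohort.group == "HFrEF"
    if labels.any() and (~labels).any():
        table5 = _diagnostic_performance(params_conv, params_cs, labels)
    else:
        table5 = pd.DataFrame()
        failures.append("diagnostic performance: needs both groups")

    sharp = {}
    if config.include_sharpness:
        try:
            sharp = _sharpness_comparison(config)
        except AtriakitError as err:
            failures.append(f"sharpness: {err}")

    return StudyReport(
        table3=table3, table4=table4, table5=table5,
        sharpness=sharp, seed=cohort_cfg.seed, failures=failures,
    )
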