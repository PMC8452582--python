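"""Synthetic atrial cohorts, contours, and cine-like phantom frames.

Nothing downstream of segmentation requires real scans: this module builds

* 25-phase atrial **time-volume curves** with the reservoir / conduit /
  booster morphology of healthy volunteers (HV) and heart-failure patients
  with reduced ejection fraction (HFrEF), from four control landmarks
  (Vmin at the trigger, Vmax at end ventricular systole, a diastasis
  minimum, a pre-atrial-contraction maximum) joined by cosine-smoothed
  monotone segments;
* paired **conventional-vs-CS** (compressed-sensing) measurements, where the
  CS reading of each derived parameter equals the conventional one minus a
  configured bias plus Gaussian disagreement noise — the structure reported
  by Bland-Altman method comparisons of the two sequences;
* **repeat-reader** variants with independent multiplicative jitter on each
  landmark volume;
* elliptical **contour polygons** whose biplane/monoplane area-length volume
  reproduces a prescribed curve (the inverse of the volumetry formula,
  enabling round-trip tests);
* grayscale **phantom frames** with a tilted ellipse of blood-pool intensity
  on a myocardium background, separated by a linear-ramp edge of known
  width measured normal to the boundary (ground-truth sharpness
  ``1/(0.6 * width)``).

Healthy-volunteer defaults centre the landmark distribution on the
conventional-technique cohort medians of the emulated study (LAVmin 24.0 ml,
LAVmax 70.3 ml, PEF 53.9 %, AEF 40.3 %); the HFrEF defaults are calibration
choices that produce a dilated, hypocontractile atrium whose diagnostic
ranking puts PEF and LAVmin on top (see docs/methods.md).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .core import AtriakitError, ContourSet, InvalidConfigError, TimeVolumeCurve

__all__ = [
    "CurvePhenotype",
    "TechniqueDisagreementModel",
    "ChamberDistribution",
    "GroupDistribution",
    "CohortConfig",
    "Cohort",
    "PhantomImageConfig",
    "PhantomFrame",
    "generate_volume_curve",
    "sample_curves",
    "generate_cohort",
    "ellipse_polygons",
    "contours_from_curve",
    "ellipse_signed_distance",
    "render_phantom_frame",
    "REPORT_PARAMETERS",
]

#: The seven parameters of the technique-comparison report, in display order.
REPORT_PARAMETERS = ("LAVmin", "LAVmax", "RAVmin", "RAVmax", "TEF", "PEF", "AEF")


class GenerationError(AtriakitError):
    """Rejection sampling exhausted its retry budget."""


#: Smallest admissible landmark volume (ml): keeps even heavily truncated
#: phenotype tails physiologic and noisy curve samples strictly positive.
V_FLOOR_ML = 8.0


# ---------------------------------------------------------------------------
# curve phenotype and sampling
# ---------------------------------------------------------------------------

@dataclass
class CurvePhenotype:
    """Control landmarks of one atrial time-volume curve.

    Volumes in ml, times as fractions of the cardiac cycle. Ordering
    ``0 < v_min <= v_dia <= v_preA <= v_max`` and
    ``0 < t_max < t_dia < t_preA < 1`` is required.
    """

    v_min: float
    v_dia: float
    v_preA: float
    v_max: float
    t_max: float = 0.40
    t_dia: float = 0.70
    t_preA: float = 0.88
    noise_sd: float = 0.0

    def validate(self) -> None:
        if not (0 < self.v_min <= self.v_dia <= self.v_preA <= self.v_max):
            raise InvalidConfigError(
                "phenotype volumes must satisfy 0 < v_min <= v_dia <= "
                f"v_preA <= v_max, got {self.v_min}, {self.v_dia}, "
                f"{self.v_preA}, {self.v_max}"
            )
        if not (0 < self.t_max < self.t_dia < self.t_preA < 1):
            raise InvalidConfigError(
                "phenotype times must satisfy 0 < t_max < t_dia < t_preA < 1"
            )
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")

    # Ground-truth emptying fractions implied by the control landmarks.
    @property
    def tef(self) -> float:
        return 100.0 * (self.v_max - self.v_min) / self.v_max

    @property
    def pef(self) -> float:
        return 100.0 * (self.v_max - self.v_dia) / self.v_max

    @property
    def aef(self) -> float:
        return 100.0 * (self.v_preA - self.v_min) / self.v_preA


def sample_curves(
    control_volumes: np.ndarray,
    times: np.ndarray,
    phases: int,
) -> np.ndarray:
    """Sample cosine-interpolated curves at equispaced cycle fractions.

    ``control_volumes`` has columns (v_min, v_dia, v_preA, v_max) and
    ``times`` columns (t_max, t_dia, t_preA); both are (n, .) stacks.
    The interpolant passes through (0, v_min), (t_max, v_max),
    (t_dia, v_dia), (t_preA, v_preA), (1, v_min); each segment is a cosine
    half-wave, hence monotone with zero slope at every control point (so a
    25-phase sampling grid loses almost nothing at the extrema).
    Returns (n, phases), noise-free.
    """
    cv = np.atleast_2d(np.asarray(control_volumes, float))
    tt = np.atleast_2d(np.asarray(times, float))
    n = cv.shape[0]
    knot_t = np.column_stack(
        [np.zeros(n), tt[:, 0], tt[:, 1], tt[:, 2], np.ones(n)]
    )
    knot_v = np.column_stack([cv[:, 0], cv[:, 3], cv[:, 1], cv[:, 2], cv[:, 0]])
    t = np.arange(phases) / phases  # (p,)
    # segment index 0..3 for every (curve, sample)
    seg = (t[None, :, None] >= knot_t[:, None, 1:4]).sum(axis=-1)
    t0 = np.take_along_axis(knot_t, seg, axis=1)
    t1 = np.take_along_axis(knot_t, seg + 1, axis=1)
    v0 = np.take_along_axis(knot_v, seg, axis=1)
    v1 = np.take_along_axis(knot_v, seg + 1, axis=1)
    s = (t[None, :] - t0) / (t1 - t0)
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * s))


def generate_volume_curve(
    phenotype: CurvePhenotype,
    phases: int = 25,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> TimeVolumeCurve:
    """One seeded time-volume curve for a phenotype.

    Ground-truth TEF/PEF/AEF computed from the control landmarks are
    attached as metadata, alongside the phenotype itself.
    """
    phenotype.validate()
    if phases < 8:
        raise InvalidConfigError("phases must be >= 8")
    cv = np.array(
        [[phenotype.v_min, phenotype.v_dia, phenotype.v_preA, phenotype.v_max]]
    )
    tt = np.array([[phenotype.t_max, phenotype.t_dia, phenotype.t_preA]])
    v = sample_curves(cv, tt, phases)[0]
    if phenotype.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, phenotype.noise_sd, size=phases)
    return TimeVolumeCurve(
        volumes=v,
        metadata={
            "phenotype": phenotype,
            "tef": phenotype.tef,
            "pef": phenotype.pef,
            "aef": phenotype.aef,
        },
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class TechniqueDisagreementModel:
    """Additive conventional-vs-CS disagreement at the parameter level.

    ``bias[p]`` is the mean of (conventional - CS) for parameter ``p`` and
    ``sd[p]`` the SD of that difference, in the parameter's own units. The
    defaults are the Bland-Altman rows of the emulated study's technique
    comparison, with ``sd = (upper LoA - bias) / 1.96``.
    """

    bias: dict[str, float] = field(default_factory=lambda: {
        "LAVmin": -2.0, "LAVmax": 3.0, "RAVmin": -3.0, "RAVmax": -0.8,
        "TEF": 4.2, "PEF": 3.3, "AEF": 6.99,
    })
    sd: dict[str, float] = field(default_factory=lambda: {
        "LAVmin": (5.6 - (-2.0)) / 1.96,
        "LAVmax": (13.8 - 3.0) / 1.96,
        "RAVmin": (10.4 - (-3.0)) / 1.96,
        "RAVmax": (17.9 - (-0.8)) / 1.96,
        "TEF": (13.4 - 4.2) / 1.96,
        "PEF": (13.4 - 3.3) / 1.96,
        "AEF": (22.2 - 6.99) / 1.96,
    })

    def validate(self) -> None:
        if any(v < 0 for v in self.sd.values()):
            raise InvalidConfigError("disagreement sd must be >= 0")

    @classmethod
    def exact(cls) -> "TechniqueDisagreementModel":
        """Zero bias, zero noise: CS readings identical to conventional."""
        zeros = dict.fromkeys(REPORT_PARAMETERS, 0.0)
        return cls(bias=dict(zeros), sd=dict(zeros))


@dataclass
class ChamberDistribution:
    """Gaussian (mean, sd) marginals for one chamber's phenotype draw.

    The draw is parameterised by (Vmax, TEF, PEF, AEF) rather than the raw
    four volumes: the calibration targets of the emulated study are stated
    in fraction space, and the landmark volumes follow as
    ``v_min = v_max (1 - TEF/100)``, ``v_dia = v_max (1 - PEF/100)``,
    ``v_preA = v_min / (1 - AEF/100)``.
    """

    v_max: tuple[float, float]
    tef: tuple[float, float]
    pef: tuple[float, float]
    aef: tuple[float, float]


@dataclass
class GroupDistribution:
    la: ChamberDistribution
    ra: ChamberDistribution
    t_max: tuple[float, float] = (0.40, 0.02)
    t_dia: tuple[float, float] = (0.70, 0.03)
    t_preA: tuple[float, float] = (0.88, 0.015)


def _default_hv() -> GroupDistribution:
    return GroupDistribution(
        la=ChamberDistribution(
            v_max=(70.3, 11.0), tef=(65.9, 7.5), pef=(53.9, 6.0), aef=(40.3, 6.5)
        ),
        ra=ChamberDistribution(
            v_max=(72.0, 12.0), tef=(52.0, 6.0), pef=(40.0, 6.0), aef=(30.0, 6.0)
        ),
    )


def _default_hfref() -> GroupDistribution:
    # Dilated atria with depressed conduit (PEF) and booster (AEF) function;
    # see docs/methods.md for the calibration targets behind these numbers.
    return GroupDistribution(
        la=ChamberDistribution(
            v_max=(100.0, 16.0), tef=(53.0, 7.0), pef=(30.0, 8.0), aef=(36.0, 9.0)
        ),
        ra=ChamberDistribution(
            v_max=(78.0, 20.0), tef=(45.0, 8.0), pef=(30.0, 7.0), aef=(26.0, 8.0)
        ),
    )


@dataclass
class CohortConfig:
    """Cohort sizes, sampling grid, and phenotype distributions."""

    n_hv: int = 82
    n_hfref: int = 19
    phases: int = 25
    seed: int = 0
    hv: GroupDistribution = field(default_factory=_default_hv)
    hfref: GroupDistribution = field(default_factory=_default_hfref)
    reader_jitter_sd: float = 0.03  # relative, per landmark volume
    curve_noise_sd: float = 1.0     # ml, per sampled phase
    min_gap_ml: float = 2.0         # smallest admissible landmark separation
    max_redraws: int = 100

    def validate(self) -> None:
        if self.n_hv < 0 or self.n_hfref < 0 or self.n_hv + self.n_hfref < 0:
            raise InvalidConfigError("cohort sizes must be non-negative")
        if self.phases < 8:
            raise InvalidConfigError("phases must be >= 8")
        if self.reader_jitter_sd < 0 or self.curve_noise_sd < 0:
            raise InvalidConfigError("jitter and noise sds must be >= 0")


@dataclass
class Cohort:
    """Arrays over subjects; the in-memory product of :func:`generate_cohort`.

    ``landmarks[(chamber, technique, reader)]`` is an ``(n, 4)`` array with
    columns (v_min, v_dia, v_preA, v_max); ``times[chamber]`` is ``(n, 3)``
    with columns (t_max, t_dia, t_preA), shared across techniques and
    readers (the timing comes from the same heart).
    """

    group: np.ndarray  # (n,) of "HV" / "HFrEF"
    landmarks: dict[tuple[str, str, str], np.ndarray]
    times: dict[str, np.ndarray]
    phases: int
    curve_noise_sd: float
    config: CohortConfig

    @property
    def n_subjects(self) -> int:
        return self.group.shape[0]

    def parameters(self, chamber: str, technique: str, reader: str = "R1"):
        """Derived parameters from the stored landmark volumes.

        Returns a dict of (n,) arrays keyed by the chamber's parameter names
        (``LAVmin``/``LAVmax``/``TEF``/``PEF``/``AEF`` for LA, ``RAVmin``/
        ``RAVmax`` for RA).
        """
        lv = self.landmarks[(chamber, technique, reader)]
        v_min, v_dia, v_preA, v_max = lv.T
        if chamber == "LA":
            return {
                "LAVmin": v_min,
                "LAVmax": v_max,
                "TEF": 100.0 * (v_max - v_min) / v_max,
                "PEF": 100.0 * (v_max - v_dia) / v_max,
                "AEF": 100.0 * (v_preA - v_min) / v_preA,
            }
        return {"RAVmin": v_min, "RAVmax": v_max}

    def curves(
        self,
        chamber: str,
        technique: str,
        reader: str = "R1",
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Sampled (n, phases) curves, with seeded per-phase Gaussian noise.

        Pass an explicit ``rng`` for reproducible noise across calls; without
        one, a generator derived from the cohort seed and the measurement key
        is used, so repeated calls are deterministic.
        """
        lv = self.landmarks[(chamber, technique, reader)]
        v = sample_curves(lv, self.times[chamber], self.phases)
        if self.curve_noise_sd > 0:
            if rng is None:
                # process-independent measurement key (hash() is salted)
                key = zlib.crc32(f"{chamber}/{technique}/{reader}".encode())
                rng = np.random.default_rng(
                    np.random.SeedSequence([self.config.seed, key])
                )
            v = v + rng.normal(0.0, self.curve_noise_sd, size=v.shape)
        return v


def _landmarks_from_fractions(v_max, tef, pef, aef):
    """(v_min, v_dia, v_preA, v_max) columns from fraction parameters."""
    v_min = v_max * (1.0 - tef / 100.0)
    v_dia = v_max * (1.0 - pef / 100.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_preA = v_min / (1.0 - aef / 100.0)
    return np.column_stack([v_min, v_dia, v_preA, v_max])


def _valid_landmarks(lv: np.ndarray, gap: float) -> np.ndarray:
    v_min, v_dia, v_preA, v_max = lv.T
    return (
        np.isfinite(lv).all(axis=1)
        & (v_min > 0)
        & (v_dia >= v_min + gap)
        & (v_preA >= v_dia + gap)
        & (v_max >= v_preA)
    )


def _retry_fill(draw, valid, n, max_redraws, what):
    """Vectorised truncated redraw: re-draw only the still-invalid rows."""
    out = draw(np.arange(n))
    bad = ~valid(out)
    tries = 0
    while np.any(bad):
        tries += 1
        if tries > max_redraws:
            raise GenerationError(
                f"{what}: retry budget exhausted for subject index(es) "
                f"{np.flatnonzero(bad).tolist()}"
            )
        idx = np.flatnonzero(bad)
        out[idx] = draw(idx)
        bad = ~valid(out)
    return out


def _truncated_normal(rng, mu, sd, lo, hi):
    """Exact truncated-normal draw per row via the inverse CDF.

    The limit of redraw-until-valid sampling; rows where the window has
    essentially no probability mass collapse towards the nearer bound.
    """
    from scipy.special import ndtr, ndtri

    mu = np.asarray(mu, float)
    sd = np.broadcast_to(np.asarray(sd, float), mu.shape)
    a = ndtr((lo - mu) / np.where(sd > 0, sd, 1.0))
    b = ndtr((hi - mu) / np.where(sd > 0, sd, 1.0))
    u = rng.uniform(0.0, 1.0, size=mu.shape)
    with np.errstate(divide="ignore"):
        q = ndtri(np.clip(a + u * (b - a), 1e-12, 1 - 1e-12))
    x = mu + sd * q
    x = np.clip(x, lo, hi)
    return np.where(sd > 0, x, np.clip(mu, lo, hi))


def _assemble_landmarks(
    rng, draw_pair, dia_frac, prea_frac, n, gap, max_redraws, what
) -> np.ndarray:
    """Build (v_min, v_dia, v_preA, v_max) columns by staged sampling.

    The (Vmin, Vmax) pair is drawn with truncated redraws; the diastasis
    and pre-A volumes are then drawn from normals truncated to their
    ordering-feasible windows. Staging keeps one landmark's constraint from
    distorting another's marginal (in particular, the CS disagreement on
    Vmin/Vmax survives intact).
    """
    pair = _retry_fill(
        draw_pair,
        lambda p: (p[:, 0] >= V_FLOOR_ML) & (p[:, 1] >= p[:, 0] + 2.0 * gap),
        n, max_redraws, f"{what} (Vmin/Vmax)",
    )
    v_min, v_max = pair[:, 0], pair[:, 1]
    # diastasis: PEF truncated so v_min + gap <= v_dia <= v_max - gap
    pef_mu, pef_sd = dia_frac(v_min, v_max)
    pef_lo = 100.0 * gap / v_max
    pef_hi = 100.0 * (1.0 - (v_min + gap) / v_max)
    pef = _truncated_normal(rng, pef_mu, pef_sd, pef_lo, pef_hi)
    v_dia = v_max * (1.0 - pef / 100.0)
    # pre-A: AEF truncated so v_dia + gap <= v_preA <= v_max
    aef_mu, aef_sd = prea_frac(v_min, v_max)
    aef_lo = 100.0 * (1.0 - v_min / (v_dia + gap))
    aef_hi = 100.0 * (1.0 - v_min / v_max)
    aef = _truncated_normal(rng, aef_mu, aef_sd, aef_lo, aef_hi)
    v_prea = v_min / (1.0 - aef / 100.0)
    return np.column_stack([v_min, v_dia, v_prea, v_max])


def _draw_chamber(rng, cd: ChamberDistribution, n, gap, max_redraws, what):
    def draw_pair(idx):
        v_max = rng.normal(*cd.v_max, size=idx.size)
        tef = rng.normal(*cd.tef, size=idx.size)
        v_min = v_max * (1.0 - tef / 100.0)
        return np.column_stack([v_min, v_max])

    return _assemble_landmarks(
        rng, draw_pair,
        lambda v_min, v_max: (np.full(n, cd.pef[0]), cd.pef[1]),
        lambda v_min, v_max: (np.full(n, cd.aef[0]), cd.aef[1]),
        n, gap, max_redraws, what,
    )


def _draw_group(
    rng: np.random.Generator,
    dist: GroupDistribution,
    n: int,
    gap: float,
    max_redraws: int,
    label: str,
):
    """Per-group phenotype draw: landmark volumes per chamber plus timings."""
    la = _draw_chamber(rng, dist.la, n, gap, max_redraws, f"{label} LA")
    ra = _draw_chamber(rng, dist.ra, n, gap, max_redraws, f"{label} RA")

    def times_draw(idx):
        return np.column_stack([
            rng.normal(*dist.t_max, size=idx.size),
            rng.normal(*dist.t_dia, size=idx.size),
            rng.normal(*dist.t_preA, size=idx.size),
        ])

    def times_valid(tt):
        return (
            (tt[:, 0] > 0.05)
            & (tt[:, 1] > tt[:, 0] + 0.04)
            & (tt[:, 2] > tt[:, 1] + 0.04)
            & (tt[:, 2] < 0.97)
        )

    tt = _retry_fill(times_draw, times_valid, n, max_redraws, f"{label} timing")
    return la, ra, tt


def _apply_disagreement(
    rng: np.random.Generator,
    lv: np.ndarray,
    chamber: str,
    model: TechniqueDisagreementModel,
    gap: float,
    max_redraws: int,
):
    """CS landmark volumes: conventional parameters minus bias plus noise.

    The disagreement acts on the functionally independent parameter subset
    (Vmin, Vmax, PEF, AEF); the TEF difference is then implied (the five LA
    rows of the technique comparison overdetermine a four-landmark curve).
    Parameters absent from the model (the RA fractions) pass through
    unchanged. Staged redraws keep each parameter's disagreement marginal
    intact when another landmark's ordering constraint fires.
    """
    v_min, v_dia, v_preA, v_max = lv.T
    if chamber == "LA":
        keys = {"vmin": "LAVmin", "vmax": "LAVmax", "pef": "PEF", "aef": "AEF"}
    else:
        keys = {"vmin": "RAVmin", "vmax": "RAVmax", "pef": None, "aef": None}
    relevant = [k for k in keys.values() if k is not None]
    if all(
        model.bias.get(k, 0.0) == 0.0 and model.sd.get(k, 0.0) == 0.0
        for k in relevant
    ):
        return lv.copy()  # exact-agreement shortcut: bit-identical readings
    pef_conv = 100.0 * (v_max - v_dia) / v_max
    aef_conv = 100.0 * (v_preA - v_min) / v_preA

    def cs_draw(slot, conv_values, idx):
        key = keys[slot]
        if key is None:
            return conv_values[idx]
        b = model.bias.get(key, 0.0)
        s = model.sd.get(key, 0.0)
        noise = rng.normal(0.0, s, size=idx.size) if s > 0 else 0.0
        return conv_values[idx] - b - noise

    def draw_pair(idx):
        return np.column_stack([
            cs_draw("vmin", v_min, idx), cs_draw("vmax", v_max, idx)
        ])

    def frac_params(slot, conv_values):
        key = keys[slot]
        mu = conv_values - model.bias.get(key, 0.0) if key else conv_values
        sd = model.sd.get(key, 0.0) if key else 0.0
        return lambda v_min_cs, v_max_cs: (mu, sd)

    return _assemble_landmarks(
        rng, draw_pair,
        frac_params("pef", pef_conv),
        frac_params("aef", aef_conv),
        lv.shape[0], gap, max_redraws, f"CS disagreement ({chamber})",
    )


def _apply_reader_jitter(
    rng: np.random.Generator,
    lv: np.ndarray,
    jitter_sd: float,
    gap: float,
    max_redraws: int,
):
    """Independent multiplicative jitter on each landmark volume.

    Per-landmark (not one global scale) so that reader variability also
    shows up in the emptying fractions, as it does between human readers.
    Each jittered landmark is drawn from a normal truncated to the window
    its ordering constraints leave open (the redraw-until-valid limit);
    base phenotypes sitting exactly on a constraint boundary therefore
    cannot strand the sampler.
    """
    if jitter_sd == 0:
        return lv.copy()
    v_min, v_dia, v_prea, v_max = lv.T
    big = np.inf
    v_min_j = _truncated_normal(rng, v_min, jitter_sd * v_min, V_FLOOR_ML, big)
    v_max_j = _truncated_normal(
        rng, v_max, jitter_sd * v_max, v_min_j + 2.0 * gap, big
    )
    v_dia_j = _truncated_normal(
        rng, v_dia, jitter_sd * v_dia, v_min_j + gap, v_max_j - gap
    )
    v_prea_j = _truncated_normal(
        rng, v_prea, jitter_sd * v_prea, v_dia_j + gap, v_max_j
    )
    return np.column_stack([v_min_j, v_dia_j, v_prea_j, v_max_j])


def generate_cohort(
    config: CohortConfig | None = None,
    disagreement: TechniqueDisagreementModel | None = None,
    readers: bool = True,
) -> Cohort:
    """Simulate a two-group cohort of paired-technique atrial measurements.

    For every subject: a conventional-technique landmark set per chamber
    drawn from the group's phenotype distribution (truncated redraw enforces
    the ordering invariants), a CS landmark set via the disagreement model,
    and — when ``readers`` is on — a second reader ("R2") and a repeat read
    by the first reader ("R1b"), both for either technique.
    """
    config = config or CohortConfig()
    config.validate()
    disagreement = disagreement or TechniqueDisagreementModel()
    disagreement.validate()
    rng = np.random.default_rng(config.seed)

    groups, las, ras, tts = [], [], [], []
    for label, n, dist in (
        ("HV", config.n_hv, config.hv),
        ("HFrEF", config.n_hfref, config.hfref),
    ):
        if n == 0:
            continue
        la, ra, tt = _draw_group(
            rng, dist, n, config.min_gap_ml, config.max_redraws, label
        )
        groups.append(np.full(n, label))
        las.append(la)
        ras.append(ra)
        tts.append(tt)

    if groups:
        group = np.concatenate(groups)
        la = np.concatenate(las)
        ra = np.concatenate(ras)
        tt = np.concatenate(tts)
    else:
        group = np.empty(0, dtype="<U5")
        la = ra = np.empty((0, 4))
        tt = np.empty((0, 3))

    landmarks: dict[tuple[str, str, str], np.ndarray] = {}
    for chamber, conv in (("LA", la), ("RA", ra)):
        cs = (
            _apply_disagreement(
                rng, conv, chamber, disagreement,
                config.min_gap_ml, config.max_redraws,
            )
            if conv.size
            else conv.copy()
        )
        landmarks[(chamber, "conv", "R1")] = conv
        landmarks[(chamber, "cs", "R1")] = cs
        if readers:
            for technique, base in (("conv", conv), ("cs", cs)):
                for reader in ("R2", "R1b"):
                    landmarks[(chamber, technique, reader)] = (
                        _apply_reader_jitter(
                            rng, base, config.reader_jitter_sd,
                            config.min_gap_ml, config.max_redraws,
                        )
                        if base.size
                        else base.copy()
                    )

    return Cohort(
        group=group,
        landmarks=landmarks,
        times={"LA": tt, "RA": tt.copy()},
        phases=config.phases,
        curve_noise_sd=config.curve_noise_sd,
        config=config,
    )


# ---------------------------------------------------------------------------
# inverse volumetry: contours from a prescribed curve
# ---------------------------------------------------------------------------

def ellipse_polygons(
    volumes_ml: np.ndarray, aspect_ratio: float, vertices: int
) -> tuple[np.ndarray, np.ndarray]:
    """Elliptical polygons whose area-length volume reproduces ``volumes_ml``.

    Long semi-axis ``a = (3 V / (4 pi r^2))^(1/3)`` (V in mm^3), short
    semi-axis ``b = r a``. The polygon starts at the basal apex (origin),
    long axis along +y; the annulus landmarks are the two vertices adjacent
    to the base, so their midpoint sits at the apex and the measured length
    approaches ``2a``. Returns ``(polys, annuli)`` of shapes
    ``(..., vertices, 2)`` and ``(..., 2, 2)``.
    """
    v = np.asarray(volumes_ml, dtype=float)
    if np.any(v <= 0):
        bad = np.argwhere(v <= 0)
        raise AtriakitError(f"non-positive volume at phase index {bad[0].tolist()}")
    if not (0 < aspect_ratio <= 1):
        raise InvalidConfigError("aspect_ratio must be in (0, 1]")
    if vertices < 16:
        raise InvalidConfigError("vertices must be >= 16")
    a = (3.0 * v * 1000.0 / (4.0 * np.pi * aspect_ratio**2)) ** (1.0 / 3.0)
    b = aspect_ratio * a
    theta = 2.0 * np.pi * np.arange(vertices) / vertices
    x = b[..., None] * np.sin(theta)
    y = a[..., None] * (1.0 - np.cos(theta))
    polys = np.stack([x, y], axis=-1)
    annuli = np.stack([polys[..., 1, :], polys[..., -1, :]], axis=-2)
    return polys, annuli


def contours_from_curve(
    curve: TimeVolumeCurve,
    aspect_ratio: float = 0.7,
    vertices: int = 200,
    chamber: str = "LA",
) -> ContourSet:
    """Per-phase contours reproducing a time-volume curve under volumetry.

    LA emits identical ellipses in the 2CH and 4CH views; RA only the 4CH
    view. Round-tripping through the area-length formulas recovers the
    curve within the polygon-inscription tolerance (~``2/vertices``
    relative).
    """
    polys, annuli = ellipse_polygons(curve.volumes, aspect_ratio, vertices)
    views = {"LA": ("LA2CH", "LA4CH"), "RA": ("RA4CH",)}[chamber]
    return ContourSet(
        views={v: polys.copy() for v in views},
        annulus={v: annuli.copy() for v in views},
    )


# ---------------------------------------------------------------------------
# phantom frames
# ---------------------------------------------------------------------------

@dataclass
class PhantomImageConfig:
    """A tilted-ellipse blood pool on myocardium with a linear-ramp edge."""

    shape: tuple[int, int] = (96, 96)          # rows, cols (pixels)
    pixel_spacing_mm: float = 1.5
    blood_intensity: float = 1000.0
    myocardium_intensity: float = 300.0
    edge_width_mm: float = 3.0
    center_mm: tuple[float, float] | None = None  # (x, y); None -> centre
    semi_axes_mm: tuple[float, float] = (30.0, 20.0)
    tilt_deg: float = 25.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.edge_width_mm <= 0:
            raise InvalidConfigError("edge width must be > 0")
        if self.pixel_spacing_mm <= 0:
            raise InvalidConfigError("pixel spacing must be > 0")
        if self.blood_intensity == self.myocardium_intensity:
            raise InvalidConfigError("blood and myocardium intensities must differ")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")


@dataclass
class PhantomFrame:
    image: np.ndarray       # float intensities, (rows, cols)
    sidecar: dict


def ellipse_signed_distance(
    x: np.ndarray, y: np.ndarray, a: float, b: float
) -> np.ndarray:
    """Signed Euclidean distance to the ellipse x^2/a^2 + y^2/b^2 = 1.

    Positive outside, negative inside. Solved per point by bisection on the
    nearest-point condition ``(a px/(t+a^2))^2 + (b py/(t+b^2))^2 = 1``,
    which has a unique root for ``t > -min(a, b)^2``; accuracy is far below
    any pixel scale.
    """
    px = np.maximum(np.abs(np.asarray(x, float)), 1e-9)
    py = np.maximum(np.abs(np.asarray(y, float)), 1e-9)
    m = max(a, b)
    r = np.hypot(px, py)
    t_lo = np.full_like(px, -min(a, b) ** 2 + 1e-12)
    t_hi = 2.0 * (r * m + m * m)
    for _ in range(90):
        t = 0.5 * (t_lo + t_hi)
        f = (a * px / (t + a * a)) ** 2 + (b * py / (t + b * b)) ** 2 - 1.0
        pos = f > 0
        t_lo = np.where(pos, t, t_lo)
        t_hi = np.where(pos, t_hi, t)
    t = 0.5 * (t_lo + t_hi)
    qx = a * a * px / (t + a * a)
    qy = b * b * py / (t + b * b)
    d = np.hypot(px - qx, py - qy)
    inside = (px / a) ** 2 + (py / b) ** 2 < 1.0
    return np.where(inside, -d, d)


def render_phantom_frame(config: PhantomImageConfig) -> PhantomFrame:
    """Render one phantom frame plus its ground-truth sidecar.

    The intensity crosses linearly from blood pool to myocardium over
    ``edge_width_mm`` measured normal to the (tilted) ellipse boundary, so
    the true 20-80 % rise distance is ``0.6 * edge_width_mm`` and the true
    sharpness ``1 / (0.6 * edge_width_mm)`` per mm. An ``under_resolved``
    flag is set in the sidecar when the ramp spans fewer than two pixels.
    """
    config.validate()
    rows, cols = config.shape
    sp = config.pixel_spacing_mm
    yy, xx = np.mgrid[0:rows, 0:cols]
    x = xx * sp
    y = yy * sp
    cx, cy = (
        config.center_mm
        if config.center_mm is not None
        else ((cols - 1) * sp / 2.0, (rows - 1) * sp / 2.0)
    )
    phi = np.deg2rad(config.tilt_deg)
    xr = (x - cx) * np.cos(phi) + (y - cy) * np.sin(phi)
    yr = -(x - cx) * np.sin(phi) + (y - cy) * np.cos(phi)
    a, b = config.semi_axes_mm
    d = ellipse_signed_distance(xr, yr, a, b)
    ramp = np.clip(0.5 - d / config.edge_width_mm, 0.0, 1.0)
    img = config.myocardium_intensity + (
        config.blood_intensity - config.myocardium_intensity
    ) * ramp
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    sidecar = {
        "pixel_spacing_mm": sp,
        "edge_width_mm": config.edge_width_mm,
        "seed": config.seed,
        "ground_truth_sharpness_mm_inv": 1.0 / (0.6 * config.edge_width_mm),
        "under_resolved": bool(config.edge_width_mm < 2.0 * sp),
    }
    return PhantomFrame(image=img, sidecar=sidecar)
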