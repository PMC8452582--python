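"""Atrial time-volume-curve landmarks and emptying fractions.

Four landmarks are read off each curve (see the physiology of one cycle):
Vmax (end of ventricular systole, reservoir full), a mid-diastolic minimum
(diastasis, end of passive emptying), a mid-diastolic maximum (pre-A volume,
just before atrial contraction), and Vmin (after atrial contraction). From
these the emptying fractions are

    TEF = 100 * (Vmax - Vmin) / Vmax            (total / reservoir)
    PEF = 100 * (Vmax - mid-diastolic Vmin) / Vmax    (passive / conduit)
    AEF = 100 * (mid-diastolic Vmax - Vmin) / mid-diastolic Vmax
                                                (active / booster)

together with the corresponding emptying volumes TEV, PEV, AEV in ml.

Landmark detection is anchored at the global maximum of a circularly
smoothed copy of the curve and then walks forward in cyclic phase order:
first local minimum -> diastasis; first subsequent local maximum -> pre-A;
global minimum of the remaining segment -> Vmin. Landmark *volumes* are
always read from the unsmoothed curve at the located phases, so smoothing
never biases amplitudes. Curves without an atrial kick (no interior local
extrema, as in severe heart failure or atrial fibrillation) fall back to a
single mid-diastolic phase midway between Vmax and Vmin, with ``no_kick``
set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AtriakitError, TimeVolumeCurve

__all__ = [
    "CurveLandmarks",
    "AtrialFunction",
    "find_landmarks",
    "compute_function",
    "locate_landmarks_batch",
    "compute_function_batch",
]


class DegenerateCurveError(AtriakitError):
    """The curve carries no usable shape (constant, or too few phases)."""


@dataclass
class CurveLandmarks:
    """The four curve landmarks: volume (ml) and phase index for each."""

    v_max: float
    v_min: float
    v_mid_min: float
    v_mid_max: float
    phase_max: int
    phase_min: int
    phase_mid_min: int
    phase_mid_max: int
    no_kick: bool = False

    def validate(self) -> None:
        if not (self.v_min <= self.v_mid_min <= self.v_mid_max <= self.v_max):
            raise AtriakitError(
                "landmark ordering violated: need "
                f"Vmin <= midVmin <= midVmax <= Vmax, got "
                f"{self.v_min:.3f}, {self.v_mid_min:.3f}, "
                f"{self.v_mid_max:.3f}, {self.v_max:.3f}"
            )


@dataclass
class AtrialFunction:
    """Emptying fractions (percent) and volumes (ml)."""

    tef: float
    pef: float
    aef: float
    tev: float
    pev: float
    aev: float
    no_kick: bool = False


def _circular_smooth(volumes: np.ndarray, window: int) -> np.ndarray:
    """Circular moving average along the last axis, odd window >= 1."""
    if window < 1 or window % 2 == 0:
        raise AtriakitError("smooth_window must be odd and >= 1")
    if window == 1:
        return volumes
    half = window // 2
    idx = (np.arange(volumes.shape[-1])[:, None]
           + np.arange(-half, half + 1)[None, :]) % volumes.shape[-1]
    return volumes[..., idx].mean(axis=-1)


def _refine(V: np.ndarray, phases: np.ndarray, half: int, pick) -> np.ndarray:
    """Snap located phases to the unsmoothed extremum within +- half."""
    p = V.shape[1]
    offs = np.arange(-half, half + 1)
    cand = (phases[:, None] + offs[None, :]) % p
    vals = np.take_along_axis(V, cand, axis=1)
    best = pick(vals, axis=1)
    return cand[np.arange(V.shape[0]), best]


def locate_landmarks_batch(
    volumes: np.ndarray, smooth_window: int = 3
) -> dict[str, np.ndarray]:
    """Vectorised landmark location for a stack of curves.

    Parameters
    ----------
    volumes : array (n_curves, phases)
    smooth_window : odd int
        Circular moving-average window used only to *locate* phases.

    Returns
    -------
    dict with integer phase arrays ``phase_max/phase_min/phase_mid_min/
    phase_mid_max``, float volume arrays ``v_*`` read from the unsmoothed
    input, and a boolean ``no_kick`` array.
    """
    V = np.asarray(volumes, dtype=float)
    if V.ndim != 2:
        raise AtriakitError("expected a (n_curves, phases) array")
    n, p = V.shape
    if p < 8:
        raise DegenerateCurveError("need at least 8 phases")
    if np.any(~np.isfinite(V)):
        raise AtriakitError("non-finite volumes")
    flat = np.ptp(V, axis=1) <= 1e-12 * np.maximum(1.0, np.abs(V).max(initial=0.0))
    if np.any(flat):
        raise DegenerateCurveError(
            f"constant curve(s) at row(s) {np.flatnonzero(flat).tolist()}"
        )

    S = _circular_smooth(V, smooth_window)
    i_max = S.argmax(axis=1)  # earliest phase on ties

    # Roll every row so the located maximum sits at offset 0.
    offs = (i_max[:, None] + np.arange(p)[None, :]) % p
    R = np.take_along_axis(S, offs, axis=1)

    j = np.arange(1, p - 1)
    # First point of a plateau counts; earliest phase wins ties.
    is_min = (R[:, j] < R[:, j - 1]) & (R[:, j] <= R[:, j + 1])
    is_max = (R[:, j] > R[:, j - 1]) & (R[:, j] >= R[:, j + 1])

    has_min = is_min.any(axis=1)
    j1 = np.where(has_min, is_min.argmax(axis=1) + 1, 0)  # rolled offset
    after = np.arange(1, p - 1)[None, :] > j1[:, None]
    is_max_after = is_max & after
    has_kick = has_min & is_max_after.any(axis=1)
    j2 = np.where(has_kick, is_max_after.argmax(axis=1) + 1, 0)
    # Vmin: global minimum of the remaining cyclic segment (after the pre-A
    # bump, before the curve returns to Vmax).  Empty segment -> no kick.
    has_kick &= j2 < p - 1
    col = np.arange(p)[None, :]
    masked = np.where(col > j2[:, None], R, np.inf)
    masked[:, 0] = np.inf
    jmin_kick = masked.argmin(axis=1)

    # Fallback (no atrial kick): Vmin is the global minimum excluding the
    # anchor phase; both mid landmarks collapse onto the phase midway
    # (cyclically) between Vmax and Vmin, earlier phase on odd spans.
    jmin_global = np.where(
        np.arange(p)[None, :] == 0, np.inf, R
    ).argmin(axis=1)
    jmid = jmin_global // 2

    jmin = np.where(has_kick, jmin_kick, jmin_global)
    j1 = np.where(has_kick, j1, jmid)
    j2 = np.where(has_kick, j2, jmid)

    phase = lambda off: (i_max + off) % p
    ph_max, ph_min = phase(0), phase(jmin)
    ph_mid_min, ph_mid_max = phase(j1), phase(j2)

    # Smoothing can drag a located extremum one phase towards the gentler
    # neighbouring segment; snap each phase to the unsmoothed extremum
    # inside the smoothing half-window (ties -> earliest phase).
    half = smooth_window // 2
    if half:
        ph_max = _refine(V, ph_max, half, np.argmax)
        ph_min = _refine(V, ph_min, half, np.argmin)
        kick = has_kick
        ph_mid_min = np.where(
            kick, _refine(V, ph_mid_min, half, np.argmin), ph_mid_min
        )
        ph_mid_max = np.where(
            kick, _refine(V, ph_mid_max, half, np.argmax), ph_mid_max
        )
    rows = np.arange(n)
    return {
        "phase_max": ph_max,
        "phase_min": ph_min,
        "phase_mid_min": ph_mid_min,
        "phase_mid_max": ph_mid_max,
        "v_max": V[rows, ph_max],
        "v_min": V[rows, ph_min],
        "v_mid_min": V[rows, ph_mid_min],
        "v_mid_max": V[rows, ph_mid_max],
        "no_kick": ~has_kick,
    }


def find_landmarks(
    curve: TimeVolumeCurve, smooth_window: int = 3
) -> CurveLandmarks:
    """Locate the four landmarks of a single time-volume curve.

    The default 3-phase smoothing suppresses single-phase noise spikes when
    locating extrema; volumes are read from the raw curve.
    """
    out = locate_landmarks_batch(curve.volumes[None, :], smooth_window)
    return CurveLandmarks(
        v_max=float(out["v_max"][0]),
        v_min=float(out["v_min"][0]),
        v_mid_min=float(out["v_mid_min"][0]),
        v_mid_max=float(out["v_mid_max"][0]),
        phase_max=int(out["phase_max"][0]),
        phase_min=int(out["phase_min"][0]),
        phase_mid_min=int(out["phase_mid_min"][0]),
        phase_mid_max=int(out["phase_mid_max"][0]),
        no_kick=bool(out["no_kick"][0]),
    )


def compute_function(landmarks: CurveLandmarks) -> AtrialFunction:
    """Emptying fractions/volumes from a validated landmark quadruple."""
    landmarks.validate()
    if landmarks.v_max <= 0 or landmarks.v_mid_max <= 0:
        raise AtriakitError("Vmax and mid-diastolic Vmax must be positive")
    tef = 100.0 * (landmarks.v_max - landmarks.v_min) / landmarks.v_max
    pef = 100.0 * (landmarks.v_max - landmarks.v_mid_min) / landmarks.v_max
    aef = 100.0 * (landmarks.v_mid_max - landmarks.v_min) / landmarks.v_mid_max
    return AtrialFunction(
        tef=tef,
        pef=pef,
        aef=aef,
        tev=landmarks.v_max - landmarks.v_min,
        pev=landmarks.v_max - landmarks.v_mid_min,
        aev=landmarks.v_mid_max - landmarks.v_min,
        no_kick=landmarks.no_kick,
    )


def compute_function_batch(lm: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Vectorised emptying fractions for ``locate_landmarks_batch`` output.

    Rows whose landmark read-offs violate the ordering invariant (possible
    on noisy curves with a near-absent atrial kick) get NaN fractions and a
    True entry in ``invalid`` instead of raising, so cohort pipelines can
    drop them per-parameter.
    """
    v_max, v_min = lm["v_max"], lm["v_min"]
    v_mid_min, v_mid_max = lm["v_mid_min"], lm["v_mid_max"]
    ok_total = (v_min <= v_max) & (v_max > 0)
    ok_passive = ok_total & (v_min <= v_mid_min) & (v_mid_min <= v_max)
    ok_active = (
        ok_passive & (v_mid_min <= v_mid_max) & (v_mid_max <= v_max)
        & (v_mid_max > 0)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        tef = 100.0 * (v_max - v_min) / v_max
        pef = 100.0 * (v_max - v_mid_min) / v_max
        aef = 100.0 * (v_mid_max - v_min) / v_mid_max
    out = {
        "tef": np.where(ok_total, tef, np.nan),
        "pef": np.where(ok_passive, pef, np.nan),
        "aef": np.where(ok_active, aef, np.nan),
        "tev": np.where(ok_total, v_max - v_min, np.nan),
        "pev": np.where(ok_passive, v_max - v_mid_min, np.nan),
        "aev": np.where(ok_active, v_mid_max - v_min, np.nan),
        "invalid": ~ok_active,
    }
    return out
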