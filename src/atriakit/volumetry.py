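"""Area-length atrial volumetry.

The left atrium is measured with the biplane area-length technique from the
2-chamber and 4-chamber cine views,

    V = (8 / 3pi) * A_2ch * A_4ch / L,

and the right atrium with the monoplane variant from the 4-chamber view only
(no dedicated right-heart 2-chamber view is acquired in routine protocols),

    V = (8 / 3pi) * A^2 / L.

Areas are planimetric contour areas in mm^2, L is the atrial long-axis length
in mm, and volumes are returned in ml. The formula is exact for a prolate
spheroid imaged through its long axis in both views.

The long-axis length is not standardised across vendors; here it is the
distance from the midpoint of the two annulus landmarks to the farthest
contour vertex, and the biplane denominator uses the minimum across the two
views (the conservative convention in echo/CMR practice). Both choices are
configurable at the call sites that need them.

All geometric functions broadcast over leading axes, so a whole cohort of
``(n_subjects, phases, vertices, 2)`` contour stacks can be processed in one
call.
"""

from __future__ import annotations

import numpy as np

from .core import AtriakitError, ContourSet, TimeVolumeCurve

__all__ = [
    "AREA_LENGTH_COEFF",
    "polygon_area",
    "atrial_length",
    "biplane_volume",
    "monoplane_volume",
    "curve_from_contours",
]

#: 8/(3*pi), kept at full floating precision (not the rounded 0.85).
AREA_LENGTH_COEFF = 8.0 / (3.0 * np.pi)

#: Views required per chamber.
CHAMBER_VIEWS = {"LA": ("LA2CH", "LA4CH"), "RA": ("RA4CH",)}


def _as_closed_free(polygon: np.ndarray) -> np.ndarray:
    """Drop an explicitly repeated closing vertex; accept both dialects."""
    polygon = np.asarray(polygon, dtype=float)
    if polygon.ndim < 2 or polygon.shape[-1] != 2:
        raise AtriakitError("polygon must have shape (..., n_vertices, 2)")
    if polygon.shape[-2] >= 2 and np.allclose(
        polygon[..., 0, :], polygon[..., -1, :]
    ):
        polygon = polygon[..., :-1, :]
    if polygon.shape[-2] < 3:
        raise AtriakitError("polygon needs at least 3 distinct vertices")
    return polygon


def polygon_area(polygon: np.ndarray) -> np.ndarray | float:
    """Absolute shoelace area of a simple closed polygon, in mm^2.

    Orientation-independent. Broadcasts over leading axes.
    """
    p = _as_closed_free(polygon)
    x, y = p[..., 0], p[..., 1]
    xn, yn = np.roll(x, -1, axis=-1), np.roll(y, -1, axis=-1)
    area = 0.5 * np.abs(np.sum(x * yn - xn * y, axis=-1))
    return float(area) if area.ndim == 0 else area


def atrial_length(polygon: np.ndarray, annulus: np.ndarray) -> np.ndarray | float:
    """Atrial long-axis length: annulus midpoint to the farthest vertex (mm).

    ``annulus`` holds the two annulus landmark points, shape ``(..., 2, 2)``.
    """
    p = _as_closed_free(polygon)
    annulus = np.asarray(annulus, dtype=float)
    if annulus.shape[-2:] != (2, 2):
        raise AtriakitError("annulus must hold exactly two landmark points")
    mid = annulus.mean(axis=-2)  # (..., 2)
    d = np.linalg.norm(p - mid[..., None, :], axis=-1)
    length = d.max(axis=-1)
    return float(length) if length.ndim == 0 else length


def _check_positive(**values: np.ndarray | float) -> None:
    for name, v in values.items():
        if np.any(np.asarray(v) <= 0):
            raise AtriakitError(f"{name} must be strictly positive")


def biplane_volume(
    area_2ch,
    area_4ch,
    length_2ch,
    length_4ch,
    length_rule: str = "min",
):
    """Biplane area-length volume in ml.

    ``length_rule`` selects the long-axis length used in the denominator:
    ``"min"`` (default), ``"mean"``, ``"2ch"`` or ``"4ch"``.
    """
    _check_positive(
        area_2ch=area_2ch, area_4ch=area_4ch,
        length_2ch=length_2ch, length_4ch=length_4ch,
    )
    a2, a4 = np.asarray(area_2ch, float), np.asarray(area_4ch, float)
    l2, l4 = np.asarray(length_2ch, float), np.asarray(length_4ch, float)
    if length_rule == "min":
        length = np.minimum(l2, l4)
    elif length_rule == "mean":
        length = 0.5 * (l2 + l4)
    elif length_rule == "2ch":
        length = l2
    elif length_rule == "4ch":
        length = l4
    else:
        raise AtriakitError(f"unknown length_rule {length_rule!r}")
    vol = AREA_LENGTH_COEFF * a2 * a4 / length / 1000.0
    return float(vol) if vol.ndim == 0 else vol


def monoplane_volume(area_4ch, length_4ch):
    """Monoplane (single-view) area-length volume in ml."""
    _check_positive(area_4ch=area_4ch, length_4ch=length_4ch)
    a, length = np.asarray(area_4ch, float), np.asarray(length_4ch, float)
    vol = AREA_LENGTH_COEFF * a * a / length / 1000.0
    return float(vol) if vol.ndim == 0 else vol


def curve_from_contours(
    contours: ContourSet,
    chamber: str,
    length_rule: str = "min",
) -> TimeVolumeCurve:
    """Per-phase area-length volumes for one chamber: the time-volume curve.

    LA uses the biplane formula on the 2CH + 4CH views, RA the monoplane
    formula on the 4CH view. Phase order is preserved.
    """
    if chamber not in CHAMBER_VIEWS:
        raise AtriakitError(f"chamber must be 'LA' or 'RA', got {chamber!r}")
    needed = CHAMBER_VIEWS[chamber]
    missing = [v for v in needed if v not in contours.views or v not in contours.annulus]
    if missing:
        raise AtriakitError(
            f"chamber {chamber}: missing views/annulus for {', '.join(missing)}"
        )
    areas = {v: polygon_area(contours.views[v]) for v in needed}
    lengths = {
        v: atrial_length(contours.views[v], contours.annulus[v]) for v in needed
    }
    if chamber == "LA":
        vols = biplane_volume(
            areas["LA2CH"], areas["LA4CH"],
            lengths["LA2CH"], lengths["LA4CH"],
            length_rule=length_rule,
        )
    else:
        vols = monoplane_volume(areas["RA4CH"], lengths["RA4CH"])
    return TimeVolumeCurve(
        volumes=np.atleast_1d(vols),
        metadata={"chamber": chamber, "source": "area-length"},
    )
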