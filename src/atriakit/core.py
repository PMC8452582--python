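"""Shared containers for atrial cine analysis.

Volumes are millilitres, coordinates are physical millimetres (y-down image
convention), and a cardiac cycle is sampled at a fixed number of reconstructed
phases (25 in the default acquisition emulated here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["TimeVolumeCurve", "ContourSet", "AtriakitError", "InvalidConfigError"]


class AtriakitError(ValueError):
    """Base class for domain errors raised by this package."""


class InvalidConfigError(AtriakitError):
    """A configuration object violates its invariants."""


@dataclass
class TimeVolumeCurve:
    """Per-phase atrial volume over one cardiac cycle.

    Parameters
    ----------
    volumes : array of shape (phases,)
        Atrial volume in ml at each reconstructed phase. Phase 0 is the
        ECG trigger (R wave), where the atrium is near its minimum.
    periodic : bool
        Whether the curve wraps around (phase after the last is phase 0).
    metadata : dict
        Free-form provenance; synthetic curves carry their generating
        control points and ground-truth emptying fractions here.
    """

    volumes: np.ndarray
    periodic: bool = True
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.ndim != 1:
            raise InvalidConfigError("volumes must be a 1-D array")

    @property
    def phases(self) -> int:
        return self.volumes.shape[0]


@dataclass
class ContourSet:
    """Closed atrial contour polygons per view and phase, in mm.

    ``views`` maps a view name (``"LA2CH"``, ``"LA4CH"``, ``"RA4CH"``) to an
    array of shape ``(phases, n_vertices, 2)``; ``annulus`` maps the same
    view names to the two mitral/tricuspid annulus landmark points per phase,
    shape ``(phases, 2, 2)``.
    """

    views: dict[str, np.ndarray]
    annulus: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, poly in self.views.items():
            poly = np.asarray(poly, dtype=float)
            if poly.ndim != 3 or poly.shape[-1] != 2 or poly.shape[1] < 3:
                raise InvalidConfigError(
                    f"view {name!r}: expected (phases, >=3 vertices, 2) array"
                )
            self.views[name] = poly
        for name, ann in self.annulus.items():
            ann = np.asarray(ann, dtype=float)
            if ann.ndim != 3 or ann.shape[1:] != (2, 2):
                raise InvalidConfigError(
                    f"annulus {name!r}: expected (phases, 2, 2) array"
                )
            self.annulus[name] = ann

    @property
    def phases(self) -> int:
        return next(iter(self.views.values())).shape[0]
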