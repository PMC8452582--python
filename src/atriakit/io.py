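"""File formats: curve CSV, contour JSON, 16-bit PNG frames with sidecars.

Curve CSV schema: ``subject,group,technique,reader,phase,volume_ml``.
Contour JSON (per subject): ``{"views": {view: [[[x_mm, y_mm], ...] per
phase]}, "annulus": {view: [[[x, y], [x, y]] per phase]}}``.
Phantom frames: 16-bit grayscale PNG plus a JSON sidecar holding at least
``pixel_spacing_mm``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .core import AtriakitError, ContourSet, TimeVolumeCurve
from .synthetic_data import Cohort

__all__ = [
    "cohort_curves_frame",
    "write_curves_csv",
    "read_curves_csv",
    "write_contours_json",
    "read_contours_json",
    "write_phantom_png",
    "read_phantom_png",
]

CURVE_COLUMNS = ["subject", "group", "technique", "reader", "phase", "volume_ml"]


def cohort_curves_frame(cohort: Cohort) -> pd.DataFrame:
    """All sampled curves of a cohort as a long-format table."""
    frames = []
    for (chamber, technique, reader) in sorted(cohort.landmarks):
        v = cohort.curves(chamber, technique, reader)
        n, p = v.shape
        frames.append(pd.DataFrame({
            "subject": np.repeat(np.arange(n), p),
            "group": np.repeat(cohort.group, p),
            "chamber": chamber,
            "technique": technique,
            "reader": reader,
            "phase": np.tile(np.arange(p), n),
            "volume_ml": v.ravel(),
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["subject", "group", "chamber"] + CURVE_COLUMNS[2:]
    )


def write_curves_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_curves_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("subject", "phase", "volume_ml") if c not in df.columns]
    if missing:
        raise AtriakitError(f"curve CSV missing column(s): {', '.join(missing)}")
    return df


def curves_from_frame(df: pd.DataFrame, **selectors) -> dict[int, TimeVolumeCurve]:
    """Per-subject curves from a long-format table, after filtering.

    ``selectors`` filter on equality, e.g. ``technique="conv"``.
    """
    sub = df
    for col, val in selectors.items():
        if col in sub.columns:
            sub = sub[sub[col] == val]
    out = {}
    for subject, grp in sub.groupby("subject"):
        grp = grp.sort_values("phase")
        out[int(subject)] = TimeVolumeCurve(volumes=grp["volume_ml"].to_numpy())
    return out


def write_contours_json(contours: ContourSet, path) -> None:
    payload = {
        "views": {k: v.tolist() for k, v in contours.views.items()},
        "annulus": {k: v.tolist() for k, v in contours.annulus.items()},
    }
    Path(path).write_text(json.dumps(payload))


def read_contours_json(path) -> ContourSet:
    payload = json.loads(Path(path).read_text())
    if "views" not in payload or "annulus" not in payload:
        raise AtriakitError("contour JSON must hold 'views' and 'annulus'")
    return ContourSet(
        views={k: np.asarray(v, float) for k, v in payload["views"].items()},
        annulus={k: np.asarray(v, float) for k, v in payload["annulus"].items()},
    )


def write_phantom_png(image: np.ndarray, sidecar: dict, path) -> None:
    """16-bit grayscale PNG plus ``<path>.json`` sidecar."""
    path = Path(path)
    arr = np.clip(np.round(np.asarray(image, float)), 0, 65535).astype(np.uint16)
    Image.fromarray(arr, mode="I;16").save(path)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def read_phantom_png(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    img = np.asarray(Image.open(path), dtype=float)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise AtriakitError(f"missing sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    if "pixel_spacing_mm" not in sidecar:
        raise AtriakitError("sidecar must record pixel_spacing_mm")
    return img, sidecar
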