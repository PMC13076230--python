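"""Pillar detection, diameter measurement and swelling calibration.

Pillars are located on the FITC (pillar-channel) projection by global
thresholding, connected components and centroiding, then snapped to a
least-squares rectangular lattice; empty lattice sites are flagged
absent.  Diameters are equivalent-disc diameters of the thresholded
footprints, and the swelling factor compares them with the mold-side
design diameter.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import GridNotFoundError, ValidationError
from .stack import Projection2D


@dataclass
class PillarGrid:
    """Detected pillar lattice.

    ``pillars`` columns: pillar_id, row, col, x_um, y_um, diameter_um,
    present (bool), border_flag (bool; footprint clipped by the image
    edge, excluded from swelling statistics).
    """

    pillars: pd.DataFrame
    pitch_um: float
    mold_diameter_um: float | None = None

    @property
    def present(self) -> pd.DataFrame:
        return self.pillars[self.pillars["present"]]

    def to_csv(self, path) -> None:
        self.pillars.to_csv(path, index=False)


def _binarize(img: np.ndarray, threshold) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if threshold is None or threshold == "otsu":
        if img.max() <= img.min():
            raise GridNotFoundError("image has no dynamic range")
        threshold = threshold_otsu(img)
    return img > float(threshold)


DiameterMeasurement = namedtuple("DiameterMeasurement", "diameter_um border_clipped")


def measure_diameter(projection: Projection2D, center_um, threshold=None) -> DiameterMeasurement:
    """Equivalent-disc diameter of the footprint containing ``center_um``.

    The component of the thresholded pillar channel nearest the given
    center is measured as sqrt(4*area/pi).  Footprints touching the
    image border are flagged (their area is truncated).
    """
    px = projection.pixel_size_um
    mask = _binarize(projection.data, threshold)
    labels = label(mask)
    iy = int(round(center_um[1] / px))
    ix = int(round(center_um[0] / px))
    if not (0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1]):
        raise ValidationError(f"center {center_um} µm outside the image")
    lab = labels[iy, ix]
    if lab == 0:
        # fall back to nearest labelled pixel within one expected radius
        ys, xs = np.nonzero(labels)
        if ys.size == 0:
            raise GridNotFoundError("no foreground at or near the requested center")
        d2 = (ys - iy) ** 2 + (xs - ix) ** 2
        lab = labels[ys[np.argmin(d2)], xs[np.argmin(d2)]]
    comp = labels == lab
    area_px = int(comp.sum())
    ys, xs = np.nonzero(comp)
    border = bool(ys.min() == 0 or xs.min() == 0
                  or ys.max() == mask.shape[0] - 1 or xs.max() == mask.shape[1] - 1)
    diameter = np.sqrt(4.0 * area_px / np.pi) * px
    return DiameterMeasurement(float(diameter), border)


def _fit_axis(values: np.ndarray, pitch0: float):
    """LSQ fit positions ~ origin + index*pitch, index by rounding."""
    origin = values.min()
    idx = np.round((values - origin) / pitch0).astype(int)
    for _ in range(3):
        A = np.vstack([np.ones_like(values), idx.astype(float)]).T
        (origin, pitch), *_ = np.linalg.lstsq(A, values, rcond=None)
        if pitch <= 0:
            pitch = pitch0
        new_idx = np.round((values - origin) / pitch).astype(int)
        if np.array_equal(new_idx, idx):
            break
        idx = new_idx
    idx -= idx.min()
    return idx, float(origin + (np.round((values.min() - origin) / pitch)) * pitch), float(pitch)


def detect_pillars(projection: Projection2D, expected_pitch: float,
                   expected_diameter: float, threshold=None,
                   mold_diameter_um: float | None = None) -> PillarGrid:
    """Detect pillar centers on the pillar-channel projection.

    Components smaller than ~10% of the expected footprint are treated
    as debris.  Centroids are fit to an axis-aligned rectangular lattice
    by least squares; lattice sites without a detected disc are returned
    as absent records.  Raises :class:`GridNotFoundError` when fewer
    than 4 pillars are found.
    """
    if expected_pitch <= 0 or expected_diameter <= 0:
        raise ValidationError("expected pitch and diameter must be positive")
    px = projection.pixel_size_um
    mask = _binarize(projection.data, threshold)
    labels = label(mask)
    min_area = 0.1 * np.pi * (expected_diameter / 2 / px) ** 2
    rows = []
    for rp in regionprops(labels):
        if rp.area < min_area:
            continue
        cy, cx = rp.centroid
        border = bool(rp.bbox[0] == 0 or rp.bbox[1] == 0
                      or rp.bbox[2] == mask.shape[0] or rp.bbox[3] == mask.shape[1])
        rows.append({"x_um": cx * px, "y_um": cy * px,
                     "diameter_um": np.sqrt(4.0 * rp.area / np.pi) * px,
                     "border_flag": border})
    if len(rows) < 4:
        raise GridNotFoundError(f"only {len(rows)} pillar candidates found (need >= 4)")
    df = pd.DataFrame(rows)

    col_idx, _, pitch_x = _fit_axis(df["x_um"].to_numpy(), expected_pitch)
    row_idx, _, pitch_y = _fit_axis(df["y_um"].to_numpy(), expected_pitch)
    df["row"], df["col"] = row_idx, col_idx
    pitch = float((pitch_x + pitch_y) / 2.0)

    # resolve collisions: keep the candidate nearest its lattice node
    ox = np.polyfit(col_idx, df["x_um"], 1)
    oy = np.polyfit(row_idx, df["y_um"], 1)
    node_x = np.polyval(ox, col_idx)
    node_y = np.polyval(oy, row_idx)
    df["residual_um"] = np.hypot(df["x_um"] - node_x, df["y_um"] - node_y)
    df = df.sort_values("residual_um").drop_duplicates(["row", "col"], keep="first")

    records = []
    seen = {(int(r), int(c)) for r, c in zip(df["row"], df["col"])}
    for r in range(int(df["row"].max()) + 1):
        for c in range(int(df["col"].max()) + 1):
            if (r, c) in seen:
                hit = df[(df["row"] == r) & (df["col"] == c)].iloc[0]
                records.append({"row": r, "col": c, "x_um": hit["x_um"],
                                "y_um": hit["y_um"], "diameter_um": hit["diameter_um"],
                                "present": True, "border_flag": bool(hit["border_flag"])})
            else:
                records.append({"row": r, "col": c,
                                "x_um": float(np.polyval(ox, c)),
                                "y_um": float(np.polyval(oy, r)),
                                "diameter_um": np.nan, "present": False,
                                "border_flag": False})
    out = pd.DataFrame(records).sort_values(["row", "col"]).reset_index(drop=True)
    out.insert(0, "pillar_id", np.arange(len(out)))
    return PillarGrid(out, pitch_um=pitch, mold_diameter_um=mold_diameter_um)


def swelling_factor(measured_um, mold_D: float) -> tuple:
    """Mean and s.d. of the fractional swelling ``(measured - D) / D``."""
    if mold_D <= 0:
        raise ValidationError("mold diameter must be positive")
    m = np.asarray(list(measured_um), dtype=float)
    m = m[np.isfinite(m)]
    if m.size == 0:
        raise ValidationError("swelling_factor needs at least one unflagged measurement")
    s = (m - mold_D) / mold_D
    sd = float(s.std(ddof=1)) if s.size > 1 else 0.0
    return float(s.mean()), sd


def grid_swelling(grid: PillarGrid, mold_D: float | None = None) -> tuple:
    """Swelling statistics over unflagged present pillars of a grid."""
    if mold_D is None:
        mold_D = grid.mold_diameter_um
    if mold_D is None:
        raise ValidationError("mold diameter unknown")
    good = grid.present[~grid.present["border_flag"]]
    return swelling_factor(good["diameter_um"], mold_D)
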