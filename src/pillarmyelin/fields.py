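"""Field-level statistics: nuclei counts, score distributions, per-cell
wrapping metrics and group comparisons.

The quantification unit is a field (a fixed imaging region, e.g.
250 x 250 µm or a 15 x 15 pillar block).  Cells are counted as
Hoechst-positive nuclei on the full-height projection; the wrapping
efficiency of a condition is summarised as the score distribution, the
number of fully wrapped (score 3) pillars per cell, and fold changes
against a reference condition, with one-way ANOVA plus Tukey HSD for
between-condition reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.stats import f_oneway
from skimage.filters import threshold_otsu
from skimage.morphology import h_maxima
from skimage.segmentation import watershed
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DegenerateDataError, ValidationError
from .stack import Projection2D

SCORES = (0, 1, 2, 3)


@dataclass
class NucleiCount:
    count: int
    flags: tuple = ()


def count_nuclei(projection: Projection2D, min_area_um2: float = 12.0,
                 threshold: float | None = None, *, h_suppress_px: int = 1) -> NucleiCount:
    """Count nuclei on a full-height projection.

    Threshold (Otsu by default), split touching blobs by a watershed on
    the distance transform seeded at h-maxima (suppression ``h_suppress_px``
    pixels), then count components above ``min_area_um2``.  Blank or
    near-saturated images return a flagged count rather than an error.
    """
    img = np.asarray(projection.data, dtype=float)
    px = projection.pixel_size_um
    flags = []
    if img.max() - img.min() <= 1e-9 * max(abs(img.max()), 1.0):
        return NucleiCount(0, ("blank",))
    if np.mean(img >= 0.999 * img.max()) > 0.5:
        flags.append("saturated")
    if threshold is None:
        threshold = threshold_otsu(img)
    mask = img > threshold
    min_area_px = min_area_um2 / px ** 2
    dist = ndi.distance_transform_edt(mask)
    seeds, n_seeds = ndi.label(h_maxima(dist, h_suppress_px))
    if n_seeds == 0:
        return NucleiCount(0, tuple(flags) + ("blank",))
    labels = watershed(-dist, seeds, mask=mask)
    count = sum(1 for i in range(1, labels.max() + 1)
                if np.sum(labels == i) >= min_area_px)
    return NucleiCount(int(count), tuple(flags))


@dataclass
class FieldSummary:
    """Per-field aggregate of wrap measurements and cell counts."""

    field_id: str
    extent_um: tuple
    n_cells: int
    n_pillars: int
    n_excluded: int
    score_counts: dict        # score -> count over unflagged pillars
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")

    @property
    def score_percent(self) -> dict:
        if self.n_pillars == 0:
            return {s: float("nan") for s in SCORES}
        return {s: 100.0 * self.score_counts.get(s, 0) / self.n_pillars for s in SCORES}

    @property
    def score3_per_cell(self) -> float:
        """Fully wrapped pillars divided by the number of cells in the field."""
        if self.n_cells == 0:
            return float("nan")
        return self.score_counts.get(3, 0) / self.n_cells

    @property
    def pillar_to_cell_ratio(self) -> float:
        if self.n_cells == 0:
            return float("nan")
        return self.n_pillars / self.n_cells

    @property
    def flags(self) -> tuple:
        return ("no_cells",) if self.n_cells == 0 else ()

    def to_dict(self) -> dict:
        d = {"field_id": self.field_id, "condition": self.condition,
             "extent_x_um": self.extent_um[0], "extent_y_um": self.extent_um[1],
             "n_cells": self.n_cells, "n_pillars": self.n_pillars,
             "n_excluded": self.n_excluded,
             "score3_per_cell": self.score3_per_cell,
             "pillar_to_cell_ratio": self.pillar_to_cell_ratio,
             "flags": ";".join(self.flags)}
        for s in SCORES:
            d[f"count_score{s}"] = self.score_counts.get(s, 0)
            d[f"pct_score{s}"] = self.score_percent[s]
        return d


def summarize_field(measurements: pd.DataFrame, n_cells: int, extent_um,
                    field_id: str = "field", condition: str | None = None) -> FieldSummary:
    """Aggregate per-pillar wrap measurements into a :class:`FieldSummary`.

    Flagged (out-of-bounds) pillars are excluded from all counts and
    denominators; their number is reported as ``n_excluded`` so no
    exclusion is silent.  ``n_cells = 0`` leaves the per-cell metrics
    undefined (NaN) while counts are still reported.
    """
    if len(measurements) == 0:
        raise ValidationError("measurements must be non-empty")
    flagged = measurements["flags"].fillna("").str.contains("out_of_bounds")
    good = measurements[~flagged]
    counts = {int(s): int((good["score"] == s).sum()) for s in SCORES}
    return FieldSummary(field_id=field_id, extent_um=tuple(extent_um),
                        n_cells=int(n_cells), n_pillars=int(len(good)),
                        n_excluded=int(flagged.sum()), score_counts=counts,
                        condition=condition)


def fold_change(value, reference_value):
    """Elementwise ratio of values to a (positive scalar) reference.

    For condition-level fold changes the convention is mean of per-field
    values divided by the mean of the reference fields' values.
    """
    ref = float(reference_value)
    if not ref > 0:
        raise ValidationError("reference value must be positive")
    arr = np.asarray(value, dtype=float) / ref
    return float(arr) if arr.ndim == 0 else arr


def condition_fold_changes(per_field: pd.DataFrame, reference: str,
                           value_col: str = "value",
                           condition_col: str = "condition") -> pd.DataFrame:
    """Mean-of-fields fold change of each condition against a reference."""
    if reference not in set(per_field[condition_col]):
        raise ValidationError(f"reference condition {reference!r} not present")
    ref_mean = per_field.loc[per_field[condition_col] == reference, value_col].mean()
    means = per_field.groupby(condition_col)[value_col].mean()
    out = (means / ref_mean).reset_index()
    out.columns = [condition_col, "fold_change"]
    return out


@dataclass
class GroupComparison:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame


def compare_groups(groups: dict) -> GroupComparison:
    """One-way ANOVA with Tukey HSD post hoc over per-field values.

    ``groups`` maps condition label to a sequence of per-field values.
    Requires at least two groups of at least two fields each with
    nonzero overall variance.
    """
    if len(groups) < 2:
        raise DegenerateDataError("ANOVA requires at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise DegenerateDataError(f"group {k!r} has fewer than 2 fields")
    pooled = np.concatenate(list(arrays.values()))
    if pooled.std() == 0:
        raise DegenerateDataError("all values identical; variance is zero")
    f, p = f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    res = pairwise_tukeyhsd(values, labels)
    tukey = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return GroupComparison(float(f), float(p), tukey)


def summaries_table(summaries) -> pd.DataFrame:
    """Wide per-field table for CSV export."""
    return pd.DataFrame([s.to_dict() for s in summaries])


def tidy_table(summaries) -> pd.DataFrame:
    """Long-format (condition, field, metric, value) table for plotting."""
    rows = []
    for s in summaries:
        base = {"condition": s.condition, "field": s.field_id}
        metrics = {"n_cells": s.n_cells, "n_pillars": s.n_pillars,
                   "score3_per_cell": s.score3_per_cell,
                   "pillar_to_cell_ratio": s.pillar_to_cell_ratio}
        metrics.update({f"pct_score{k}": v for k, v in s.score_percent.items()})
        for m, v in metrics.items():
            rows.append({**base, "metric": m, "value": v})
    return pd.DataFrame(rows)
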