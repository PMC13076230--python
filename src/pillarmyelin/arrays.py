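"""Micropillar array geometry.

An array is molded as a rectangular grid of circles of diameter ``D``
(mold side) separated edge-to-edge by ``d``.  On immersion the hydrogel
swells, increasing pillar diameter by a fraction ``s`` (measured at
~26% for polyacrylamide in PBS), so the realized diameter is
``D * (1 + s)`` and the center-to-center pitch is realized diameter
plus ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: Fractional diameter increase of polyacrylamide features between the
#: mold and the PBS-immersed state (mean of the calibration measurement).
DEFAULT_SWELLING = 0.26


@dataclass(frozen=True)
class ArraySpec:
    """Design-side description of a micropillar array.

    Parameters
    ----------
    mold_diameter_um : float
        Circle diameter ``D`` on the mold, µm.
    interpillar_um : float
        Edge-to-edge spacing ``d`` between neighbouring pillars, µm.
    height_um : float
        Pillar height ``h``, µm.
    swelling_fraction : float
        Relative diameter increase ``s`` on immersion, in ``[0, 1)``.
    rows, cols : int
        Grid dimensions (pillar counts per axis).
    pixel_size_um : float
        Lateral voxel calibration used when rendering/imaging.
    z_step_um : float
        Axial slice spacing.
    """

    mold_diameter_um: float
    interpillar_um: float
    height_um: float
    swelling_fraction: float = DEFAULT_SWELLING
    rows: int = 5
    cols: int = 5
    pixel_size_um: float = 0.25
    z_step_um: float = 2.0

    def __post_init__(self) -> None:
        for name in ("mold_diameter_um", "interpillar_um", "height_um",
                     "pixel_size_um", "z_step_um"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if not (0 <= self.swelling_fraction < 1):
            raise ValidationError(
                f"swelling_fraction must be in [0, 1), got {self.swelling_fraction!r}")
        if self.rows < 1 or self.cols < 1:
            raise ValidationError("rows and cols must be >= 1")

    @property
    def realized_diameter_um(self) -> float:
        """Swollen (in-liquid) pillar diameter, ``D * (1 + s)``."""
        return self.mold_diameter_um * (1.0 + self.swelling_fraction)

    @property
    def pitch_um(self) -> float:
        """Center-to-center pillar spacing, realized diameter plus ``d``."""
        return self.realized_diameter_um + self.interpillar_um

    @property
    def n_sites(self) -> int:
        return self.rows * self.cols


def make_array_spec(mold_D: float, d: float, h: float, s: float = DEFAULT_SWELLING,
                    rows: int = 5, cols: int = 5, *,
                    pixel_size_um: float = 0.25, z_step_um: float = 2.0) -> ArraySpec:
    """Build a validated :class:`ArraySpec` from mold-side parameters."""
    return ArraySpec(mold_diameter_um=mold_D, interpillar_um=d, height_um=h,
                     swelling_fraction=s, rows=rows, cols=cols,
                     pixel_size_um=pixel_size_um, z_step_um=z_step_um)
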