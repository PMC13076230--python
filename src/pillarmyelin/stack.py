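"""Calibrated multi-channel z-stacks and maximum-intensity projections.

The quantification workflow uses two projections of each confocal stack:
a full-height projection of the nuclear channel (to count cell bodies)
and a base-excluded projection of the MBP channel (to isolate myelin
wrapped around the pillars from signal on the gel base).

Conventions: voxel index ``(z, y, x)``; coordinates sit at pixel
centers with physical position ``index * calibration``; z index 0 is
the gel base.  Slice inclusion in a projection is decided by the slice
center against the half-open interval ``[z_lo, z_hi)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import ValidationError

#: Canonical channel roles, in storage order used by the generator.
CHANNEL_ROLES = ("PILLAR", "MBP", "NUCLEI")


@dataclass
class ImageStack:
    """A µm-calibrated 3D multi-channel intensity raster.

    Attributes
    ----------
    data : ndarray, shape (C, Z, Y, X)
        Non-negative intensities.
    channels : tuple of str
        Role name per channel axis entry (e.g. ``("PILLAR", "MBP", "NUCLEI")``).
    pixel_size_um, z_step_um : float
        Lateral and axial calibration.
    """

    data: np.ndarray
    channels: tuple
    pixel_size_um: float
    z_step_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channels = tuple(self.channels)
        if self.data.ndim != 4:
            raise ValidationError(f"expected (C, Z, Y, X) data, got shape {self.data.shape}")
        if self.data.shape[0] != len(self.channels):
            raise ValidationError("number of channel roles must match data axis 0")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("each channel role may map to exactly one channel")
        if self.data.shape[1] < 1:
            raise ValidationError("stack needs at least one z-slice")
        if not (self.pixel_size_um > 0 and self.z_step_um > 0):
            raise ValidationError("calibration must be positive")
        if self.data.size and float(self.data.min()) < 0:
            raise ValidationError("intensities must be non-negative")

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def z_centers_um(self) -> np.ndarray:
        """Physical z position of each slice center (index * z_step)."""
        return np.arange(self.n_z) * self.z_step_um

    @property
    def extent_um(self) -> tuple:
        """(height_y, width_x) of the field in µm."""
        return (self.data.shape[2] * self.pixel_size_um,
                self.data.shape[3] * self.pixel_size_um)

    def channel(self, role: str) -> np.ndarray:
        """Return the (Z, Y, X) volume for a channel role."""
        try:
            return self.data[self.channels.index(role)]
        except ValueError:
            raise ValidationError(
                f"unknown channel role {role!r}; stack has {self.channels}") from None


@dataclass
class Projection2D:
    """A per-pixel maximum over a z-range of one channel."""

    data: np.ndarray
    channel_role: str
    z_lo_um: float
    z_hi_um: float
    pixel_size_um: float

    def as_stack(self) -> ImageStack:
        """Wrap as a one-slice stack (projection of it is idempotent)."""
        return ImageStack(self.data[None, None], (self.channel_role,),
                          self.pixel_size_um, max(self.z_hi_um - self.z_lo_um, 1e-9))


def max_project(stack: ImageStack, channel_role: str,
                z_lo: float = 0.0, z_hi: float | None = None) -> Projection2D:
    """Maximum-intensity projection of one channel over ``[z_lo, z_hi)``.

    ``z_hi=None`` means "to the top" (all slices at or above ``z_lo``).
    Raises :class:`ValidationError` when no slice center falls in range.
    """
    hi = np.inf if z_hi is None else float(z_hi)
    if not z_lo < hi:
        raise ValidationError(f"need z_lo < z_hi, got [{z_lo}, {hi})")
    centers = stack.z_centers_um
    sel = (centers >= z_lo) & (centers < hi)
    if not sel.any():
        raise ValidationError(
            f"no slice center in [{z_lo}, {hi}) µm; slices at {centers.tolist()}")
    vol = stack.channel(channel_role)
    proj = vol[sel].max(axis=0)
    hi_eff = hi if np.isfinite(hi) else float(centers[-1] + stack.z_step_um)
    return Projection2D(proj, channel_role, float(z_lo), hi_eff, stack.pixel_size_um)


# ---------------------------------------------------------------------------
# OME-TIFF round trip


def write_stack(path, stack: ImageStack) -> None:
    """Write an OME-TIFF with channel names and physical-size metadata."""
    tifffile.imwrite(
        str(path),
        np.asarray(stack.data, dtype=np.float32),
        ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": list(stack.channels)},
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_step_um,
            "PhysicalSizeZUnit": "µm",
        },
    )


def read_stack(path, *, pixel_size_um: float | None = None,
               z_step_um: float | None = None,
               channels: tuple | None = None) -> ImageStack:
    """Load an OME-TIFF stack, resolving calibration and channel roles.

    Metadata in the file wins unless an explicit override is given; a file
    with neither calibration metadata nor an override is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta = {}
        names: list = []
        if tf.ome_metadata:
            ome = tifffile.xml2dict(tf.ome_metadata)
            image = ome.get("OME", {}).get("Image", {})
            if isinstance(image, list):
                image = image[0]
            pixels = image.get("Pixels", {})
            meta = pixels
            ch = pixels.get("Channel", [])
            if isinstance(ch, dict):
                ch = [ch]
            names = [c.get("Name") for c in ch if isinstance(c, dict)]

    # Normalise axes to (C, Z, Y, X), inserting missing singleton axes.
    if set(axes) <= {"C", "Z", "Y", "X"}:
        for ax in ("C", "Z"):
            if ax not in axes:
                data = data[None]
                axes = ax + axes
        order = [axes.index(ax) for ax in "CZYX"]
        data = np.transpose(data, order)
    else:
        # unlabelled layout (plain TIFF): assume trailing (Y, X), leading
        # axes (C, Z) in that order, padding singleton axes as needed
        while data.ndim < 4:
            data = data[None]
        if data.ndim != 4:
            raise ValidationError(f"cannot interpret {data.ndim}D data in {path}")

    px = pixel_size_um if pixel_size_um is not None else meta.get("PhysicalSizeX")
    dz = z_step_um if z_step_um is not None else meta.get("PhysicalSizeZ")
    if px is None:
        raise ValidationError(f"{path} carries no pixel-size metadata and no override given")
    if dz is None:
        dz = px  # single-slice files routinely omit PhysicalSizeZ

    if channels is not None:
        roles = tuple(channels)
    elif names and all(names):
        roles = tuple(names)
    elif data.shape[0] == len(CHANNEL_ROLES):
        roles = CHANNEL_ROLES
    elif data.shape[0] == 1:
        roles = ("UNKNOWN",)
    else:
        raise ValidationError(f"cannot resolve channel roles for {path}")
    if len(roles) != data.shape[0]:
        raise ValidationError(
            f"{len(roles)} channel roles given for {data.shape[0]} channels")
    known = set(CHANNEL_ROLES) | {"UNKNOWN"}
    for r in roles:
        if r not in known:
            raise ValidationError(f"unknown channel role {r!r}; expected one of {sorted(known)}")
    return ImageStack(data, roles, float(px), float(dz))


def write_projection(path, projection: Projection2D) -> None:
    """Export a projection as a single-plane calibrated TIFF."""
    tifffile.imwrite(
        str(path), np.asarray(projection.data, dtype=np.float32), ome=True,
        metadata={"axes": "YX",
                  "PhysicalSizeX": projection.pixel_size_um,
                  "PhysicalSizeY": projection.pixel_size_um},
    )
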