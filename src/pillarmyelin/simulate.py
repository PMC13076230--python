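"""Seeded synthetic inputs with ground truth.

This module renders the three kinds of raw data the pipeline consumes —
multi-channel pillar-field z-stacks, colloidal-probe AFM force curves
and TEM-style lamellar intensity transects — with known ground truth
attached, so every downstream measurement can be validated by recovery
against the configured truth.

The image model is deliberately simple: anti-aliased cylinders (FITC
pillar channel), annular myelin arcs of configured angular coverage and
radial thickness placed only above a base-exclusion height (MBP
channel), ellipsoidal nuclei near the gel base (Hoechst channel), then
Gaussian blur, a constant background, optional Poisson counting noise
and Gaussian read noise.  No confocal PSF or TEM imaging physics is
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import erf

from .arrays import ArraySpec, make_array_spec
from .afm import ForceCurve, hertz_force
from .errors import GeometryError, ValidationError
from .lamellae import LamellaProfile
from .stack import CHANNEL_ROLES, ImageStack

DEFAULT_BASE_EXCLUSION_UM = 4.0


@dataclass
class NoiseModel:
    """Additive/counting noise applied after rendering the clean field.

    All intensities are relative to a clean in-structure peak of 1.0.
    ``poisson_scale`` is the expected photon count at peak (0 disables
    Poisson noise); ``blur_sd_um`` is the lateral Gaussian blur applied
    per slice.
    """

    background: float = 0.05
    gaussian_sd: float = 0.02
    poisson_scale: float = 0.0
    blur_sd_um: float = 0.4

    def __post_init__(self) -> None:
        for name in ("background", "gaussian_sd", "poisson_scale", "blur_sd_um"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @classmethod
    def none(cls) -> "NoiseModel":
        """Noiseless (and blur-free) rendering, for oracle tests."""
        return cls(background=0.0, gaussian_sd=0.0, poisson_scale=0.0, blur_sd_um=0.0)


@dataclass
class FieldTruth:
    """Ground truth for one rendered field.

    ``centers_um`` holds (x, y) of each present pillar; ``arcs`` one
    list of ``(start_rad, span_rad)`` tuples per pillar (the rendered
    myelin arcs); ``coverage`` their summed angular fraction.
    """

    centers_um: np.ndarray          # (N, 2) x, y of present pillars
    coverage: np.ndarray            # (N,) fraction of circumference in [0, 1]
    thickness_um: np.ndarray        # (N,) radial ring thickness
    rows: np.ndarray                # (N,) lattice row index
    cols: np.ndarray                # (N,) lattice col index
    arcs: list                      # per pillar: [(start_rad, span_rad), ...]
    nuclei_um: np.ndarray           # (M, 2) x, y of nuclei centers
    seed: int
    absent_sites: tuple = ()        # (row, col) sites left empty

    def __post_init__(self) -> None:
        self.centers_um = np.atleast_2d(np.asarray(self.centers_um, dtype=float))
        self.coverage = np.asarray(self.coverage, dtype=float)
        self.thickness_um = np.asarray(self.thickness_um, dtype=float)
        self.nuclei_um = np.asarray(self.nuclei_um, dtype=float).reshape(-1, 2)
        if np.any((self.coverage < 0) | (self.coverage > 1)):
            raise ValidationError("coverage must lie in [0, 1]")
        n = self.centers_um.shape[0]
        if not (len(self.coverage) == len(self.thickness_um) == len(self.arcs) == n):
            raise ValidationError("one truth record per rendered pillar required")

    @property
    def n_pillars(self) -> int:
        return self.centers_um.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pillar_id": np.arange(self.n_pillars),
            "row": self.rows, "col": self.cols,
            "x_um": self.centers_um[:, 0], "y_um": self.centers_um[:, 1],
            "coverage": self.coverage, "thickness_um": self.thickness_um,
        })


def field_margin_um(spec: ArraySpec) -> float:
    """Empty border around the outermost pillar centers."""
    return 0.5 * spec.pitch_um + 4.0


def make_field_truth(spec: ArraySpec, coverage=0.0, thickness_um=0.66,
                     n_nuclei: int = 0, seed: int = 0, absent=(),
                     n_arcs: int = 1, min_nucleus_sep_um: float = 12.0) -> FieldTruth:
    """Lay out grid centers, myelin arcs and nuclei for one field.

    ``coverage`` is a scalar or a per-present-pillar sequence; each
    pillar's covered fraction is rendered as ``n_arcs`` contiguous arcs
    (default one) with a uniformly random start angle.  ``absent`` lists
    (row, col) sites to leave empty.  Nuclei are rejection-sampled with
    a minimum pairwise separation near the gel base.
    """
    rng = np.random.default_rng(seed)
    absent = {tuple(a) for a in absent}
    margin = field_margin_um(spec)
    centers, rows, cols = [], [], []
    for r in range(spec.rows):
        for c in range(spec.cols):
            if (r, c) in absent:
                continue
            centers.append((margin + c * spec.pitch_um, margin + r * spec.pitch_um))
            rows.append(r)
            cols.append(c)
    centers = np.asarray(centers, dtype=float)
    n = len(centers)
    cov = np.broadcast_to(np.asarray(coverage, dtype=float), (n,)).copy()
    thick = np.broadcast_to(np.asarray(thickness_um, dtype=float), (n,)).copy()
    if n_arcs < 1:
        raise ValidationError("n_arcs must be >= 1")
    arcs = []
    for ci in cov:
        start = rng.uniform(0.0, 2 * np.pi)
        if ci <= 0:
            arcs.append([])
        elif n_arcs == 1 or ci >= 1.0:
            arcs.append([(start, 2 * np.pi * min(ci, 1.0))])
        else:
            span = 2 * np.pi * ci / n_arcs
            gap = 2 * np.pi / n_arcs
            arcs.append([(start + j * gap, span) for j in range(n_arcs)])

    extent_x = (spec.cols - 1) * spec.pitch_um + 2 * margin
    extent_y = (spec.rows - 1) * spec.pitch_um + 2 * margin
    nuclei = []
    attempts = 0
    while len(nuclei) < n_nuclei and attempts < 200 * max(n_nuclei, 1):
        attempts += 1
        p = rng.uniform([6.0, 6.0], [extent_x - 6.0, extent_y - 6.0])
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_nucleus_sep_um for q in nuclei):
            nuclei.append(p)
    if len(nuclei) < n_nuclei:
        raise GeometryError(
            f"could not place {n_nuclei} nuclei with {min_nucleus_sep_um} µm separation "
            f"in a {extent_x:.0f}x{extent_y:.0f} µm field")
    return FieldTruth(centers, cov, thick, np.asarray(rows), np.asarray(cols),
                      arcs, np.asarray(nuclei, dtype=float).reshape(-1, 2), seed,
                      tuple(sorted(absent)))


def _soft_disc(r_um: np.ndarray, radius_um: float, px: float) -> np.ndarray:
    """Anti-aliased disc indicator: 1 inside, 0 outside, linear over ~1 px."""
    return np.clip((radius_um - r_um) / px + 0.5, 0.0, 1.0)


def render_field(spec: ArraySpec, truth: FieldTruth, noise: NoiseModel | None = None,
                 seed: int = 0, *, base_exclusion_um: float = DEFAULT_BASE_EXCLUSION_UM,
                 field_size_um: tuple | None = None) -> tuple:
    """Render a 3-channel stack (PILLAR, MBP, NUCLEI) for one field.

    Pillars are cylinders spanning the full height; myelin arcs sit at
    the pillar surface with the configured coverage and radial thickness,
    only above ``base_exclusion_um``; nuclei are ellipsoids near the
    base.  Identical ``(spec, truth, noise, seed)`` give bit-identical
    output.  Returns ``(stack, truth)``.
    """
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    px = spec.pixel_size_um
    margin = field_margin_um(spec)
    ext_x = (spec.cols - 1) * spec.pitch_um + 2 * margin
    ext_y = (spec.rows - 1) * spec.pitch_um + 2 * margin
    if field_size_um is not None:
        if field_size_um[0] < ext_x or field_size_um[1] < ext_y:
            raise GeometryError(
                f"field {field_size_um} µm smaller than grid footprint "
                f"({ext_x:.1f}, {ext_y:.1f}) µm")
        ext_x, ext_y = field_size_um
    nx, ny = int(round(ext_x / px)), int(round(ext_y / px))
    n_z = int(np.floor(spec.height_um / spec.z_step_um)) + 1
    clean = np.zeros((3, n_z, ny, nx), dtype=np.float64)
    z_centers = np.arange(n_z) * spec.z_step_um

    radius = spec.realized_diameter_um / 2.0
    pillar_z = z_centers <= spec.height_um
    myelin_z = (z_centers >= base_exclusion_um) & (z_centers <= spec.height_um)

    for i in range(truth.n_pillars):
        xc, yc = truth.centers_um[i]
        t = truth.thickness_um[i]
        r_max = radius + t + 2.0
        x0 = max(int((xc - r_max) / px) - 1, 0)
        x1 = min(int((xc + r_max) / px) + 2, nx)
        y0 = max(int((yc - r_max) / px) - 1, 0)
        y1 = min(int((yc + r_max) / px) + 2, ny)
        xs = np.arange(x0, x1) * px - xc
        ys = np.arange(y0, y1) * px - yc
        X, Y = np.meshgrid(xs, ys)
        R = np.hypot(X, Y)
        disc = _soft_disc(R, radius, px)
        clean[0, pillar_z, y0:y1, x0:x1] = np.maximum(
            clean[0, pillar_z, y0:y1, x0:x1], disc)
        if truth.arcs[i]:
            ring = _soft_disc(R, radius + t, px) - _soft_disc(R, radius, px)
            theta = np.mod(np.arctan2(Y, X), 2 * np.pi)
            ang = np.zeros_like(R)
            for start, span in truth.arcs[i]:
                if span >= 2 * np.pi - 1e-12:
                    ang[:] = 1.0
                    break
                rel = np.mod(theta - start, 2 * np.pi)
                ang = np.maximum(ang, (rel <= span).astype(float))
            arc = np.clip(ring, 0, 1) * ang
            clean[1, myelin_z, y0:y1, x0:x1] = np.maximum(
                clean[1, myelin_z, y0:y1, x0:x1], arc)

    # nuclei: ellipsoids centered ~2.5 µm above the base
    ax_l, ax_z, zc_n = 4.0, 2.5, 2.5
    for (xn, yn) in truth.nuclei_um:
        x0 = max(int((xn - ax_l - 1) / px) - 1, 0)
        x1 = min(int((xn + ax_l + 1) / px) + 2, nx)
        y0 = max(int((yn - ax_l - 1) / px) - 1, 0)
        y1 = min(int((yn + ax_l + 1) / px) + 2, ny)
        xs = np.arange(x0, x1) * px - xn
        ys = np.arange(y0, y1) * px - yn
        X, Y = np.meshgrid(xs, ys)
        for iz, z in enumerate(z_centers):
            f = 1.0 - ((z - zc_n) / ax_z) ** 2
            if f <= 0:
                continue
            r_eff = ax_l * np.sqrt(f)
            blob = _soft_disc(np.hypot(X, Y), r_eff, px)
            clean[2, iz, y0:y1, x0:x1] = np.maximum(clean[2, iz, y0:y1, x0:x1], blob)

    if noise.blur_sd_um > 0:
        sd_px = noise.blur_sd_um / px
        for c in range(3):
            for iz in range(n_z):
                clean[c, iz] = gaussian_filter(clean[c, iz], sd_px)
    out = clean + noise.background
    if noise.poisson_scale > 0:
        out = rng.poisson(out * noise.poisson_scale) / noise.poisson_scale
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    out = np.clip(out, 0.0, None).astype(np.float32)
    stack = ImageStack(out, CHANNEL_ROLES, px, spec.z_step_um)
    return stack, truth


# ---------------------------------------------------------------------------
# AFM force curves


def generate_force_curve(E: float, R: float, k: float, nu: float = 0.5,
                         contact_z: float = 0.0, noise_sd: float = 0.0,
                         seed: int = 0, *, n_samples: int = 1024,
                         baseline_span_m: float = 2e-6,
                         indent_span_m: float = 2.5e-6) -> ForceCurve:
    """Simulate an approach force curve over a Hertzian sample.

    Beyond the contact point the measured force satisfies the implicit
    system ``F = (4/3)(E/(1-nu^2)) sqrt(R) delta^(3/2)`` with the true
    indentation ``delta = (z - contact_z) - F/k`` (the cantilever bends
    by ``F/k``); solved per sample by Newton iteration.  The pre-contact
    region is a zero baseline.  Gaussian force noise of ``noise_sd`` N
    is added throughout.
    """
    if not (E > 0 and R > 0 and k > 0):
        raise ValidationError("E, R and k must all be positive")
    if not (0 <= nu <= 0.5):
        raise ValidationError("Poisson ratio must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    z = np.linspace(contact_z - baseline_span_m, contact_z + indent_span_m, n_samples)
    amp = (4.0 / 3.0) * (E / (1.0 - nu ** 2)) * np.sqrt(R)
    F = np.zeros_like(z)
    s = z - contact_z
    post = s > 0
    u = s[post].copy()  # initial guess: rigid cantilever
    a = amp / k
    for _ in range(60):
        fval = u + a * u ** 1.5 - s[post]
        dval = 1.0 + 1.5 * a * np.sqrt(u)
        step = fval / dval
        u = np.clip(u - step, 0.0, None)
        if np.max(np.abs(step)) < 1e-18:
            break
    F[post] = amp * u ** 1.5
    if noise_sd > 0:
        F = F + rng.normal(0.0, noise_sd, size=F.shape)
    return ForceCurve(z, F, k=k, R=R, nu=nu,
                      meta={"true_E_pa": E, "true_contact_z_m": contact_z,
                            "noise_sd_n": noise_sd, "seed": seed})


# ---------------------------------------------------------------------------
# lamellar profiles


def generate_lamella_profile(n_layers: int, period_nm: float = 13.0,
                             noise_sd: float = 0.0, seed: int = 0, *,
                             dr_nm: float = 0.5, modulation: float = 0.8,
                             edge_sd_nm: float = 1.0,
                             margin_periods: float = 2.0) -> LamellaProfile:
    """Simulate a radial transect across an ``n_layers`` myelin wrap.

    The trace is a cosine lamellar modulation (one intensity peak per
    layer) under a smoothed top-hat band envelope of width
    ``n_layers * period_nm``, so the true total thickness is
    ``n_layers * period_nm`` by construction.  Gaussian noise of
    ``noise_sd`` (relative to a peak of ~1) is added.
    """
    if n_layers < 1:
        raise ValidationError("n_layers must be >= 1")
    if period_nm <= 0:
        raise ValidationError("period_nm must be positive")
    rng = np.random.default_rng(seed)
    margin = margin_periods * period_nm
    width = n_layers * period_nm
    span = width + 2 * margin
    r = np.arange(0.0, span + dr_nm / 2, dr_nm)
    left, right = margin, margin + width
    env = 0.5 * (erf((r - left) / (np.sqrt(2) * edge_sd_nm))
                 - erf((r - right) / (np.sqrt(2) * edge_sd_nm)))
    if n_layers == 1:
        y = env  # a lone lamella is a single band, no internal periodicity
    else:
        y = env * 0.5 * (1.0 - modulation * np.cos(2 * np.pi * (r - left) / period_nm))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return LamellaProfile(r, y, meta={
        "true_n_layers": n_layers, "true_period_nm": period_nm,
        "true_thickness_nm": n_layers * period_nm, "seed": seed,
        "noise_sd": noise_sd,
    })


__all__ = [
    "ArraySpec", "make_array_spec", "NoiseModel", "FieldTruth",
    "make_field_truth", "render_field", "generate_force_curve",
    "generate_lamella_profile", "DEFAULT_BASE_EXCLUSION_UM",
]
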