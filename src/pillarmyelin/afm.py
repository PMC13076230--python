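"""AFM force-curve processing and spherical Hertz fits.

A colloidal-probe force–distance curve is reduced to a Young's modulus
in four steps mirroring standard instrument-software processing:
moving-average smoothing, baseline subtraction on the pre-contact
segment, contact-point estimation, and cantilever-bending correction
``delta = (z - z0) - F/k`` before fitting the spherical Hertz relation

    F = (4/3) * (E / (1 - nu^2)) * sqrt(R) * delta^(3/2)

which is linear in ``E`` once the contact point is fixed.  Hydrogel
stiffness is reported as the average of a 3x3 grid of indentations per
gel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.optimize import minimize_scalar

from .errors import (InsufficientDataError, NoContactError, ValidationError)


def hertz_force(delta: np.ndarray, E: float, R: float, nu: float = 0.5) -> np.ndarray:
    """Spherical-indenter Hertz force at indentation depth ``delta`` (m)."""
    delta = np.asarray(delta, dtype=float)
    return (4.0 / 3.0) * (E / (1.0 - nu ** 2)) * np.sqrt(R) * np.clip(delta, 0, None) ** 1.5


@dataclass
class ForceCurve:
    """Raw approach segment of a force–distance measurement.

    ``z`` is the piezo position in metres, increasing toward the sample;
    ``force`` is the cantilever deflection force in newtons.  Probe
    constants: spring constant ``k`` (N/m), bead radius ``R`` (m) and
    sample Poisson ratio ``nu`` (0.5 for incompressible hydrogels).
    ``meta`` carries generator annotations (true modulus, contact point).
    """

    z: np.ndarray
    force: np.ndarray
    k: float
    R: float
    nu: float = 0.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.z.shape != self.force.shape or self.z.ndim != 1:
            raise ValidationError("z and force must be 1D arrays of equal length")
        if self.z.size < 100:
            raise ValidationError(f"curve needs >=100 samples, got {self.z.size}")
        dz = np.diff(self.z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValidationError("z must be strictly monotone")
        if not (self.k > 0 and self.R > 0):
            raise ValidationError("spring constant and bead radius must be positive")
        if not (0 <= self.nu <= 0.5):
            raise ValidationError("Poisson ratio must lie in [0, 0.5]")
        if dz[0] < 0:  # store in approach order
            self.z = self.z[::-1].copy()
            self.force = self.force[::-1].copy()


@dataclass
class HertzFit:
    """Result of fitting one processed curve."""

    E_pa: float
    contact_z_m: float
    rms_residual_n: float
    delta_range_m: tuple
    n_points: int


@dataclass
class PreprocessedCurve:
    """Baseline-corrected post-contact samples with the contact point."""

    delta: np.ndarray  # indentation depth, m
    force: np.ndarray  # baseline-subtracted force, N
    contact_z_m: float
    baseline_noise_sd: float


def _segment_cost(z, f, k, z0):
    """Total squared residual of a flat-baseline + Hertz two-segment model."""
    pre = z <= z0
    n_pre = int(pre.sum())
    if n_pre < 2 or (~pre).sum() < 3:
        return np.inf, 0.0
    A = np.vstack([np.ones(n_pre), z[pre]]).T
    coef, *_ = np.linalg.lstsq(A, f[pre], rcond=None)
    base = coef[0] + coef[1] * z
    fc = f - base
    ss_pre = float(np.sum(fc[pre] ** 2))
    zq, fq = z[~pre], fc[~pre]
    delta = (zq - z0) - fq / k
    ok = delta > 0
    if ok.sum() < 3:
        return np.inf, 0.0
    x = delta[ok] ** 1.5
    amp = max(float(np.dot(fq[ok], x) / np.dot(x, x)), 0.0)
    ss_post = float(np.sum((fq[ok] - amp * x) ** 2)) + float(np.sum(fq[~ok] ** 2))
    return ss_pre + ss_post, amp


def preprocess(curve: ForceCurve, smooth_window: int = 11,
               min_baseline_fraction: float = 0.1) -> PreprocessedCurve:
    """Smooth, baseline-subtract, locate the contact point and bend-correct.

    The contact point is found by a two-segment fit (straight baseline
    plus Hertz-shaped indentation) over a grid of candidate positions,
    refined by a bounded scalar minimisation; curves whose
    baseline-subtracted force never rises above the baseline noise are
    rejected as contact-free.
    """
    if smooth_window < 1:
        raise ValidationError("smooth_window must be >= 1")
    z = curve.z
    f = uniform_filter1d(curve.force, size=max(int(smooth_window), 1), mode="nearest")
    n = z.size
    lo = max(int(np.ceil(min_baseline_fraction * n)), 2)
    hi = n - 10
    if hi <= lo:
        raise ValidationError("curve too short for the requested baseline fraction")

    step = max((hi - lo) // 128, 1)
    cand = z[lo:hi:step]
    costs = [_segment_cost(z, f, curve.k, z0)[0] for z0 in cand]
    best = int(np.argmin(costs))
    if not np.isfinite(costs[best]):
        raise NoContactError("no viable two-segment split found")
    z_lo = cand[max(best - 1, 0)]
    z_hi = cand[min(best + 1, len(cand) - 1)]
    if z_hi > z_lo:
        res = minimize_scalar(lambda v: _segment_cost(z, f, curve.k, v)[0],
                              bounds=(z_lo, z_hi), method="bounded",
                              options={"xatol": (z[1] - z[0]) / 10})
        z0 = float(res.x)
    else:
        z0 = float(cand[best])

    pre = z <= z0
    A = np.vstack([np.ones(int(pre.sum())), z[pre]]).T
    coef, *_ = np.linalg.lstsq(A, f[pre], rcond=None)
    fc = f - (coef[0] + coef[1] * z)
    noise_sd = float(np.std(fc[pre]))

    post = z > z0
    peak = float(fc[post].max(initial=0.0))
    floor = max(5.0 * noise_sd, 1e-13 + 1e-6 * float(np.abs(f).max()))
    if peak < floor:
        raise NoContactError(
            f"max baseline-subtracted force {peak:.3g} N below detection floor {floor:.3g} N")

    delta = (z[post] - z0) - fc[post] / curve.k
    keep = delta > 0
    return PreprocessedCurve(delta[keep], fc[post][keep], z0, noise_sd)


def fit_hertz(delta: np.ndarray, force: np.ndarray, R: float, nu: float = 0.5,
              delta_max_fit: float | None = None, *, min_points: int = 20,
              contact_z: float = float("nan")) -> HertzFit:
    """Least-squares Hertz fit for ``E`` on (indentation, force) samples.

    ``delta_max_fit`` caps the indentation depth used (default 10% of the
    bead radius, the shallow-indentation validity range of the model).
    """
    delta = np.asarray(delta, dtype=float)
    force = np.asarray(force, dtype=float)
    if not (R > 0):
        raise ValidationError("bead radius must be positive")
    if delta_max_fit is None:
        delta_max_fit = 0.1 * R
    sel = (delta > 0) & (delta <= delta_max_fit)
    if int(sel.sum()) < min_points:
        raise InsufficientDataError(
            f"only {int(sel.sum())} post-contact samples with delta <= "
            f"{delta_max_fit:.3g} m (need >= {min_points})")
    d, fq = delta[sel], force[sel]
    x = d ** 1.5
    amp = float(np.dot(fq, x) / np.dot(x, x))
    E = amp * 0.75 * (1.0 - nu ** 2) / np.sqrt(R)
    if not E > 0:
        raise InsufficientDataError("fitted modulus is non-positive; curve unusable")
    rms = float(np.sqrt(np.mean((fq - amp * x) ** 2)))
    return HertzFit(E_pa=E, contact_z_m=contact_z, rms_residual_n=rms,
                    delta_range_m=(float(d.min()), float(d.max())), n_points=int(d.size))


def process_curve(curve: ForceCurve, smooth_window: int = 11,
                  delta_max_fit: float | None = None) -> HertzFit:
    """Full chain: preprocess a raw curve and fit the Hertz model."""
    prep = preprocess(curve, smooth_window=smooth_window)
    return fit_hertz(prep.delta, prep.force, curve.R, curve.nu,
                     delta_max_fit, contact_z=prep.contact_z_m)


def aggregate_gel(E_values) -> tuple:
    """Mean and s.d. of per-curve moduli for one gel (e.g. a 3x3 grid)."""
    E = np.asarray(list(E_values), dtype=float)
    if E.size == 0:
        raise ValidationError("aggregate_gel requires at least one modulus")
    sd = float(E.std(ddof=1)) if E.size > 1 else 0.0
    return float(E.mean()), sd


# ---------------------------------------------------------------------------
# text IO


def read_force_curve(path, k: float | None = None, R: float | None = None,
                     nu: float | None = None) -> ForceCurve:
    """Read a two-column (z_m, F_N) delimited text curve.

    Probe constants may live in ``# key = value`` header lines or be
    supplied as arguments (arguments win).
    """
    path = Path(path)
    header: dict = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if line.startswith("#") and "=" in line:
            key, _, val = line.lstrip("#").partition("=")
            try:
                header[key.strip()] = float(val)
            except ValueError:
                pass
    data = np.loadtxt(path, comments="#", delimiter=",", ndmin=2)
    kk = k if k is not None else header.get("k")
    RR = R if R is not None else header.get("R")
    nn = nu if nu is not None else header.get("nu", 0.5)
    if kk is None or RR is None:
        raise ValidationError(f"{path}: spring constant and bead radius must be provided")
    return ForceCurve(data[:, 0], data[:, 1], k=float(kk), R=float(RR), nu=float(nn))


def write_force_curve(path, curve: ForceCurve) -> None:
    lines = [f"# k = {curve.k}", f"# R = {curve.R}", f"# nu = {curve.nu}"]
    for key, val in curve.meta.items():
        lines.append(f"# {key} = {val}")
    lines.append("# z_m,force_n")
    lines += [f"{z:.9e},{f:.9e}" for z, f in zip(curve.z, curve.force)]
    Path(path).write_text("\n".join(lines) + "\n")


def fits_table(fits, labels=None) -> pd.DataFrame:
    """Tabulate per-curve fits for CSV export."""
    rows = []
    for i, fit in enumerate(fits):
        rows.append({
            "curve": labels[i] if labels is not None else i,
            "E_pa": fit.E_pa,
            "contact_z_m": fit.contact_z_m,
            "rms_residual_n": fit.rms_residual_n,
            "delta_min_m": fit.delta_range_m[0],
            "delta_max_m": fit.delta_range_m[1],
            "n_points": fit.n_points,
        })
    return pd.DataFrame(rows)
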