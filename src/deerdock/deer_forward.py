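"""Forward simulation of PELDOR/DEER time-domain signals.

Links distance distributions P(r) to dipolar time traces through the
angle-averaged dipolar kernel, handles modulation depth and the
exponential intermolecular background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import fresnel

from .structures import C2Pose, rotation_z

__all__ = [
    "DIPOLAR_CONSTANT_MHZ_NM3",
    "DistanceDistribution",
    "DeerTrace",
    "BackgroundModel",
    "dipolar_kernel",
    "kernel_matrix",
    "form_factor",
    "apply_background",
    "remove_background",
    "fit_background",
    "dimer_modulation_depth",
    "trace_from_pose",
    "PoseTrace",
    "default_r_grid",
    "write_trace",
    "read_trace",
]

log = logging.getLogger(__name__)

# Standard nitroxide dipolar coupling constant: nu_dd = 52.04 MHz at r = 1 nm.
DIPOLAR_CONSTANT_MHZ_NM3 = 52.04


def default_r_grid(r_min: float = 1.0, r_max: float = 8.0, dr: float = 0.02) -> np.ndarray:
    """Default distance grid, nm (covers 1.8-4.4 nm signals and longer predictions)."""
    n = int(round((r_max - r_min) / dr))
    return r_min + dr * np.arange(n + 1)


def _check_uniform(x: np.ndarray, name: str, rtol: float = 1e-6) -> float:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError(f"{name} must be a 1-D grid with >= 2 points")
    d = np.diff(x)
    if d.min() <= 0:
        raise ValueError(f"{name} must be strictly increasing")
    if (d.max() - d.min()) > rtol * d.mean():
        raise ValueError(f"{name} must be uniformly spaced")
    return float(d.mean())


@dataclass
class DistanceDistribution:
    """P(r) on a uniform grid: r in nm, densities p in 1/nm, unit trapezoid integral."""

    r: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        _check_uniform(self.r, "r grid")
        if self.p.shape != self.r.shape:
            raise ValueError("r and p must have the same shape")
        if (self.p < -1e-12).any():
            raise ValueError("densities must be non-negative")
        integral = np.trapezoid(self.p, self.r)
        if abs(integral - 1.0) > 1e-9:
            raise ValueError(f"p must integrate to 1 (trapezoid), got {integral}")

    @classmethod
    def from_unnormalized(cls, r: np.ndarray, p: np.ndarray) -> "DistanceDistribution":
        p = np.clip(np.asarray(p, dtype=float), 0.0, None)
        integral = np.trapezoid(p, r)
        if integral <= 0:
            raise ValueError("cannot normalize an all-zero distribution")
        return cls(r, p / integral)

    @classmethod
    def gaussian(cls, r: np.ndarray, mean: float, sd: float) -> "DistanceDistribution":
        p = np.exp(-0.5 * ((np.asarray(r) - mean) / sd) ** 2)
        return cls.from_unnormalized(r, p)


@dataclass
class DeerTrace:
    """Normalized dipolar time trace: t in microseconds from 0, v with v[0] = 1."""

    t: np.ndarray
    v: np.ndarray
    kind: str = "primary"  # "primary" | "form_factor"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        _check_uniform(self.t, "t grid")
        if abs(self.t[0]) > 1e-12:
            raise ValueError("time grid must start at 0")
        if self.v.shape != self.t.shape:
            raise ValueError("t and v must have the same shape")
        if abs(self.v[0] - 1.0) > 1e-9:
            raise ValueError("trace must be normalized to v[0] = 1")
        if self.kind not in ("primary", "form_factor"):
            raise ValueError(f"unknown trace kind {self.kind!r}")


@dataclass(frozen=True)
class BackgroundModel:
    """Intermolecular background B(t) = exp(-k * t^(d/3)); homogeneous 3-D default."""

    k: float
    dimensionality: float = 3.0

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("background rate k must be >= 0")
        if self.dimensionality <= 0:
            raise ValueError("dimensionality must be positive")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return np.exp(-self.k * np.asarray(t, dtype=float) ** (self.dimensionality / 3.0))


def dipolar_kernel(t, r, method: str = "fresnel"):
    """Angle-averaged dipolar kernel K(t, r).

    K(t, r) = int_0^1 cos[(3u^2 - 1) w t] du with w = 2 pi * 52.04 / r^3
    (t in us, r in nm). Closed form via Fresnel integrals; midpoint
    quadrature available as an independent cross-check.
    """
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    if (r <= 0).any():
        raise ValueError("r must be positive")
    if (t < 0).any():
        raise ValueError("t must be non-negative")
    omega = 2.0 * np.pi * DIPOLAR_CONSTANT_MHZ_NM3 / r**3  # rad/us
    x = omega * t
    if method == "fresnel":
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.sqrt(6.0 * x / np.pi)
            s, c = fresnel(z)
            k = np.sqrt(np.pi / (6.0 * x)) * (np.cos(x) * c + np.sin(x) * s)
        return np.where(x < 1e-9, 1.0, k)
    if method == "quadrature":
        # 2001-node Gauss-Legendre on u in [0, 1]
        nodes, gl_w = np.polynomial.legendre.leggauss(2001)
        u = 0.5 * (nodes + 1.0)
        gl_w = 0.5 * gl_w
        shape = x.shape
        xf = np.atleast_1d(x).ravel()
        k = np.cos((3.0 * u[None, :] ** 2 - 1.0) * xf[:, None]) @ gl_w
        return k.reshape(shape) if shape else float(k[0])
    raise ValueError(f"unknown kernel method {method!r}")


def kernel_matrix(t: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Kernel matrix K[t_i, r_j], shape (len(t), len(r))."""
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    return dipolar_kernel(t[:, None], r[None, :])


def form_factor(p: DistanceDistribution, t: np.ndarray, depth: float) -> DeerTrace:
    """F(t) = 1 - depth + depth * int P(r) K(t, r) dr, with F(0) = 1."""
    if not 0.0 <= depth <= 1.0:
        raise ValueError("modulation depth must be in [0, 1]")
    t = np.asarray(t, dtype=float)
    km = kernel_matrix(t, p.r)
    dr = p.r[1] - p.r[0]
    w = np.full_like(p.r, dr)
    w[0] = w[-1] = dr / 2.0  # trapezoid weights
    v = 1.0 - depth + depth * (km @ (p.p * w))
    return DeerTrace(t, v / v[0], kind="form_factor")


def apply_background(trace: DeerTrace, bg: BackgroundModel) -> DeerTrace:
    """V(t) = F(t) * B(t), renormalized to V(0) = 1; output kind 'primary'."""
    b = bg.evaluate(trace.t)
    if (b <= 0).any():
        raise ValueError("background reaches zero or below")
    v = trace.v * b
    return DeerTrace(trace.t, v / v[0], kind="primary")


def remove_background(trace: DeerTrace, bg: BackgroundModel) -> DeerTrace:
    """Divide out B(t); inverse of apply_background. Output kind 'form_factor'."""
    b = bg.evaluate(trace.t)
    if (b <= 0).any():
        raise ValueError("background reaches zero or below")
    v = trace.v / b
    return DeerTrace(trace.t, v / v[0], kind="form_factor")


def fit_background(
    trace: DeerTrace, fit_start_frac: float = 0.25, dimensionality: float = 3.0
) -> BackgroundModel:
    """Log-linear least-squares background fit on the trace tail.

    Fits ln V = a - k * t^(d/3) over t >= fit_start_frac * t_max (default:
    final 75% of the trace), where the intramolecular oscillations have
    decayed to the 1 - depth plateau.
    """
    if not 0.0 <= fit_start_frac < 1.0:
        raise ValueError("fit_start_frac must be in [0, 1)")
    mask = trace.t >= fit_start_frac * trace.t[-1]
    if mask.sum() < 2:
        raise ValueError("background fit window contains fewer than 2 points")
    if (trace.v[mask] <= 0).any():
        raise ValueError("trace must be positive in the background fit window")
    x = trace.t[mask] ** (dimensionality / 3.0)
    y = np.log(trace.v[mask])
    slope, _ = np.polyfit(x, y, 1)
    return BackgroundModel(max(-slope, 0.0), dimensionality)


def dimer_modulation_depth(label_fraction: float, inversion_efficiency: float) -> float:
    """Expected dimer modulation depth: probability the partner protomer is
    labeled times the pump-pulse inversion efficiency."""
    if not 0.0 <= label_fraction <= 1.0:
        raise ValueError("label_fraction must be in [0, 1]")
    if not 0.0 <= inversion_efficiency <= 1.0:
        raise ValueError("inversion_efficiency must be in [0, 1]")
    return label_fraction * inversion_efficiency


@dataclass
class PoseTrace:
    """Forward-calculated trace for a C2 pose plus the per-rotamer-pair signals.

    kernel holds one row per surviving rotamer pair: 1 - depth + depth * K(t, d_pair),
    so the weighted row sum reproduces the trace (columns at t = 0 are all 1).
    """

    trace: DeerTrace
    pair_distances: np.ndarray
    pair_weights: np.ndarray
    kernel: np.ndarray


def trace_from_pose(
    ensemble,
    pose: C2Pose,
    t: np.ndarray,
    depth: float,
    center: np.ndarray | None = None,
    zero_tol: float = 1e-9,
) -> PoseTrace:
    """Forward-calculate the C2 inter-protomer PELDOR trace for a spin ensemble.

    The ensemble (positions/weights) is placed by the pose (after subtracting
    `center`, the protomer geometric centre used for dimer assembly) and paired
    with its 180 deg z-rotated image. Zero-distance degenerate pairs are
    dropped with a warning.
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError("modulation depth must be in [0, 1]")
    pos = np.asarray(ensemble.positions, dtype=float)
    w = np.asarray(ensemble.weights, dtype=float)
    if center is not None:
        pos = pos - np.asarray(center, dtype=float)
    a = pose.transform.apply(pos)
    b = a @ rotation_z(180.0).T
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1).ravel()
    wpair = np.outer(w, w).ravel()
    nonzero = d > zero_tol
    if not nonzero.all():
        log.warning(
            "dropping %d zero-distance spin pair(s) (on-axis degenerate case)",
            int((~nonzero).sum()),
        )
    d, wpair = d[nonzero], wpair[nonzero]
    if len(d) == 0:
        raise ValueError("all spin pairs are at zero distance; pose is degenerate")
    wpair = wpair / wpair.sum()
    t = np.asarray(t, dtype=float)
    rows = 1.0 - depth + depth * dipolar_kernel(t[None, :], d[:, None])
    v = wpair @ rows
    return PoseTrace(
        trace=DeerTrace(t, v / v[0], kind="form_factor"),
        pair_distances=d,
        pair_weights=wpair,
        kernel=rows,
    )


def write_trace(trace: DeerTrace, path, header: str = "") -> None:
    """Two-column ASCII trace file: t [us], signal; '#' comments."""
    lines = [f"# {line}" for line in header.splitlines() if line]
    lines.append(f"# kind: {trace.kind}")
    lines.append("# columns: t_us  signal")
    lines += [f"{ti:.6e} {vi:.10e}" for ti, vi in zip(trace.t, trace.v)]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_trace(path, kind: str | None = None) -> DeerTrace:
    """Read a two-column ASCII trace; kind taken from header unless overridden."""
    file_kind = "primary"
    t, v = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# kind:"):
                    file_kind = line.split(":", 1)[1].strip()
                continue
            cols = line.split()
            t.append(float(cols[0]))
            v.append(float(cols[1]))
    return DeerTrace(np.array(t), np.array(v), kind=kind or file_kind)
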