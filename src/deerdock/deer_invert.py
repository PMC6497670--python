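"""Non-negative Tikhonov inversion of DEER form factors.

Recovers P(r) by minimizing ||K p - f||^2 + reg^2 ||L2 p||^2 subject to
p >= 0, with L-curve corner selection of the regularization parameter and
an optional 1-D scan for the modulation depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .deer_forward import DeerTrace, DistanceDistribution, kernel_matrix

__all__ = [
    "TikhonovResult",
    "tikhonov_invert",
    "select_reg_param",
    "distribution_moments",
    "second_difference_operator",
]

_DEFAULT_REG_CANDIDATES = np.logspace(-3, 3, 13)
_DEPTH_SCAN = np.arange(0.05, 0.951, 0.01)


@dataclass
class TikhonovResult:
    distribution: DistanceDistribution
    reg_param: float
    residual_norm: float
    seminorm: float
    fit: DeerTrace
    depth: float


def second_difference_operator(n: int) -> np.ndarray:
    """Second-difference seminorm operator with zero-second-derivative
    boundary rows (forces the solution smooth at the grid edges)."""
    if n < 3:
        raise ValueError("need at least 3 grid points")
    l2 = np.zeros((n, n))
    for i in range(1, n - 1):
        l2[i, i - 1 : i + 2] = (1.0, -2.0, 1.0)
    l2[0, 0:3] = (1.0, -2.0, 1.0)
    l2[-1, -3:] = (1.0, -2.0, 1.0)
    return l2


def _design(trace: DeerTrace, r_grid: np.ndarray) -> np.ndarray:
    km = kernel_matrix(trace.t, r_grid)
    dr = r_grid[1] - r_grid[0]
    w = np.full(len(r_grid), dr)
    w[0] = w[-1] = dr / 2.0
    return km * w  # A @ p approximates int P(r) K(t,r) dr


def _solve_one(a: np.ndarray, l2: np.ndarray, f_mod: np.ndarray, reg: float):
    stacked = np.vstack([a, reg * l2])
    rhs = np.concatenate([f_mod, np.zeros(l2.shape[0])])
    p, _ = nnls(stacked, rhs)
    residual = float(np.linalg.norm(a @ p - f_mod))
    seminorm = float(np.linalg.norm(l2 @ p))
    return p, residual, seminorm


def _corner_index(x: np.ndarray, y: np.ndarray) -> int:
    """Corner of a discrete L-curve: the point farthest from the chord
    joining the curve endpoints (triangle method, a robust stand-in for the
    maximum-curvature point on coarse log-spaced grids)."""
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm < 1e-12:
        raise ValueError("degenerate flat L-curve; choose reg_param manually")
    chord = chord / norm
    rel = np.column_stack([x, y]) - p0
    perp = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    if perp.max() < 1e-9:
        raise ValueError("degenerate flat L-curve; choose reg_param manually")
    return int(np.argmax(perp))


def _depth_scan(a, l2, v, reg: float) -> float:
    best_depth, best_res = None, np.inf
    for lam in _DEPTH_SCAN:
        f_mod = (v - (1.0 - lam)) / lam
        p, _, _ = _solve_one(a, l2, f_mod, reg)
        res = float(np.linalg.norm(lam * (a @ p) + (1.0 - lam) - v))
        if res < best_res - 1e-15:
            best_res, best_depth = res, float(lam)
    return best_depth


def select_reg_param(
    trace: DeerTrace,
    r_grid: np.ndarray,
    candidates: np.ndarray | None = None,
    depth: float = 1.0,
) -> float:
    """L-curve corner selection of the Tikhonov regularization parameter.

    Returns the candidate maximizing the curvature of the (log residual
    norm, log seminorm) curve. Deterministic; duplicate candidates are
    deduplicated. Raises on a degenerate flat L-curve.
    """
    if candidates is None:
        candidates = _DEFAULT_REG_CANDIDATES
    regs = np.unique(np.asarray(candidates, dtype=float))
    if len(regs) < 8:
        raise ValueError("need at least 8 distinct log-spaced reg_param candidates")
    if (regs <= 0).any():
        raise ValueError("reg_param candidates must be positive")
    a = _design(trace, np.asarray(r_grid, dtype=float))
    l2 = second_difference_operator(len(r_grid))
    f_mod = (trace.v - (1.0 - depth)) / depth
    rho = np.empty(len(regs))
    eta = np.empty(len(regs))
    for i, reg in enumerate(regs):
        _, rho[i], eta[i] = _solve_one(a, l2, f_mod, reg)
    log_rho = np.log10(np.clip(rho, 1e-14, None))
    log_eta = np.log10(np.clip(eta, 1e-14, None))
    if np.ptp(log_rho) < 1e-6 and np.ptp(log_eta) < 1e-6:
        raise ValueError("degenerate flat L-curve; choose reg_param manually")
    return float(regs[_corner_index(log_rho, log_eta)])


def tikhonov_invert(
    trace: DeerTrace,
    r_grid: np.ndarray,
    reg_param: float | None = None,
    depth: float | None = None,
    reg_candidates: np.ndarray | None = None,
) -> TikhonovResult:
    """Invert a form factor to a distance distribution.

    reg_param=None triggers L-curve selection; depth=None triggers a 1-D
    modulation-depth scan (0.05-0.95, step 0.01) minimizing the residual.
    The returned distribution is renormalized to unit integral.
    """
    if trace.kind != "form_factor":
        raise ValueError("tikhonov_invert expects a background-corrected form factor")
    r_grid = np.asarray(r_grid, dtype=float)
    a = _design(trace, r_grid)
    l2 = second_difference_operator(len(r_grid))
    if depth is None:
        scan_reg = reg_param if reg_param is not None else 1.0
        depth = _depth_scan(a, l2, trace.v, scan_reg)
    if not 0.0 < depth <= 1.0:
        raise ValueError("modulation depth must be in (0, 1]")
    if reg_param is None:
        reg_param = select_reg_param(trace, r_grid, reg_candidates, depth=depth)
    if reg_param <= 0:
        raise ValueError("reg_param must be positive")
    f_mod = (trace.v - (1.0 - depth)) / depth
    p, residual, seminorm = _solve_one(a, l2, f_mod, reg_param)
    if p.sum() <= 0:
        raise ValueError(
            "all-zero Tikhonov solution; check the modulation depth and r grid range"
        )
    fit_v = depth * (a @ p) + (1.0 - depth)
    fit = DeerTrace(trace.t, fit_v / fit_v[0], kind="form_factor")
    return TikhonovResult(
        distribution=DistanceDistribution.from_unnormalized(r_grid, p),
        reg_param=float(reg_param),
        residual_norm=residual,
        seminorm=seminorm,
        fit=fit,
        depth=float(depth),
    )


def distribution_moments(p: DistanceDistribution) -> tuple[float, float]:
    """Trapezoidal mean and standard deviation of a distance distribution (nm)."""
    mean = float(np.trapezoid(p.r * p.p, p.r))
    var = float(np.trapezoid((p.r - mean) ** 2 * p.p, p.r))
    return mean, float(np.sqrt(max(var, 0.0)))
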