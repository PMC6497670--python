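"""Maximum-entropy (BioEn-style) reweighting of spin-label rotamer pairs.

Minimizes theta * S_KL(w || w0) + chi^2(w) / 2 over the probability
simplex in log-weight coordinates, with L-curve selection of the
confidence parameter theta and minimum-total-chi^2 conformer selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "ReweightProblem",
    "BioEnSolution",
    "reweight",
    "theta_lcurve",
    "select_conformer",
    "marginal_weights",
]

_DEFAULT_THETAS = np.logspace(-2, 4, 13)


@dataclass
class ReweightProblem:
    """One site's reweighting problem.

    kernel: (n_pairs, n_times) forward-calculated form-factor signals per
    rotamer pair; f_exp: experimental form factor; sigma: noise sd;
    w0: reference weights (uniform default).
    """

    kernel: np.ndarray
    f_exp: np.ndarray
    sigma: float
    w0: np.ndarray | None = None

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=float)
        self.f_exp = np.asarray(self.f_exp, dtype=float).ravel()
        if self.kernel.ndim != 2:
            raise ValueError("kernel must be 2-D (pairs x timepoints)")
        if self.kernel.shape[1] != len(self.f_exp):
            raise ValueError("kernel column count must match the experimental trace")
        if self.sigma <= 0:
            raise ValueError("noise sd must be positive")
        n = self.kernel.shape[0]
        if self.w0 is None:
            self.w0 = np.full(n, 1.0 / n)
        else:
            self.w0 = np.asarray(self.w0, dtype=float).ravel()
            if len(self.w0) != n:
                raise ValueError("w0 length must match kernel row count")
            if (self.w0 <= 0).any():
                raise ValueError("reference weights must be positive")
            if abs(self.w0.sum() - 1.0) > 1e-9:
                raise ValueError("reference weights must sum to 1")

    @classmethod
    def from_trace_tail(cls, kernel, f_exp, w0=None, tail_frac: float = 0.2):
        """Estimate the noise sd from the final `tail_frac` of the trace."""
        f = np.asarray(f_exp, dtype=float)
        tail = f[int(np.floor(len(f) * (1.0 - tail_frac))):]
        sigma = float(np.std(tail, ddof=1)) if len(tail) > 2 else 1.0
        return cls(kernel, f, max(sigma, 1e-6), w0)


@dataclass
class BioEnSolution:
    theta: float
    weights: np.ndarray
    chi2: float
    skl: float

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if (w < -1e-12).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if self.skl < -1e-9 or self.chi2 < -1e-12:
            raise ValueError("skl and chi2 must be non-negative")
        self.weights = w


def _chi2(w: np.ndarray, problem: ReweightProblem) -> float:
    resid = w @ problem.kernel - problem.f_exp
    return float((resid**2).sum() / problem.sigma**2)


def _skl(w: np.ndarray, w0: np.ndarray) -> float:
    mask = w > 0
    return float(np.sum(w[mask] * np.log(w[mask] / w0[mask])))


def reweight(
    problem: ReweightProblem,
    theta: float,
    grad_tol: float = 1e-6,
    max_iter: int = 5000,
) -> BioEnSolution:
    """Minimize theta * S_KL + chi^2 / 2 over the simplex (log-weight coords).

    Weights are parameterized as w_i proportional to w0_i * exp(g_i) with the
    last g fixed to 0 (softmax contract). Deterministic; raises if the
    gradient norm stays above `grad_tol` after the iteration cap.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    w0 = problem.w0
    n = len(w0)
    k = problem.kernel
    f = problem.f_exp
    inv_s2 = 1.0 / problem.sigma**2
    log_w0 = np.log(w0)

    def weights_of(g_free: np.ndarray) -> np.ndarray:
        g = np.concatenate([g_free, [0.0]])
        logits = log_w0 + g
        logits -= logits.max()
        w = np.exp(logits)
        return w / w.sum()

    def objective(g_free: np.ndarray):
        w = weights_of(g_free)
        resid = w @ k - f
        chi2 = float((resid**2).sum()) * inv_s2
        skl = float(np.sum(w * (np.log(np.clip(w, 1e-300, None)) - log_w0)))
        val = theta * skl + 0.5 * chi2
        # gradient wrt w, projected through the softmax Jacobian
        dw = theta * (np.log(np.clip(w, 1e-300, None)) - log_w0 + 1.0) + (
            k @ resid
        ) * inv_s2
        grad_full = w * (dw - float(w @ dw))
        return val, grad_full[:-1]

    if n == 1:
        w = np.array([1.0])
        return BioEnSolution(theta, w, _chi2(w, problem), 0.0)

    # gradient magnitudes scale with theta and with the data misfit, so the
    # convergence check is relative to both
    _, grad0 = objective(np.zeros(n - 1))
    scale = max(1.0, theta, float(np.linalg.norm(grad0)))
    x = np.zeros(n - 1)
    gnorm = np.inf
    for _ in range(4):  # restarts help L-BFGS past ftol stalls
        res = minimize(
            objective,
            x,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-18, "gtol": grad_tol * 1e-2},
        )
        x = res.x
        _, grad = objective(x)
        gnorm = float(np.linalg.norm(grad))
        if gnorm <= grad_tol * scale:
            break
    if gnorm > grad_tol * scale:
        raise RuntimeError(f"BioEn optimizer did not converge: final gradient norm {gnorm:.2e}")
    res_x = x
    w = weights_of(res_x)
    chi2 = _chi2(w, problem)
    skl = _skl(w, w0)
    obj_w0 = 0.5 * _chi2(w0, problem)  # S_KL(w0||w0) = 0
    if theta * skl + 0.5 * chi2 > obj_w0 + 1e-9:
        # never return something worse than the reference
        w, chi2, skl = w0.copy(), _chi2(w0, problem), 0.0
    return BioEnSolution(float(theta), w, chi2, skl)


def theta_lcurve(
    problem: ReweightProblem,
    thetas: np.ndarray | None = None,
    monotonicity_tol: float = 1e-6,
) -> tuple[float, np.ndarray]:
    """L-curve selection of theta.

    Returns (chosen theta, table) where table rows are (theta, chi2, skl)
    sorted by descending theta. chi2 must be non-increasing and skl
    non-decreasing as theta decreases (a violation beyond tolerance signals
    optimizer failure). The corner is the point of maximum curvature of the
    (log chi2, skl) curve; a zero-misfit degenerate curve falls back to the
    largest theta.
    """
    if thetas is None:
        thetas = _DEFAULT_THETAS
    thetas = np.sort(np.unique(np.asarray(thetas, dtype=float)))[::-1]
    if len(thetas) < 8:
        raise ValueError("need at least 8 distinct log-spaced theta values")
    rows = []
    for th in thetas:
        sol = reweight(problem, th)
        rows.append((th, sol.chi2, sol.skl))
    table = np.array(rows)
    chi2s, skls = table[:, 1], table[:, 2]
    scale = max(chi2s.max(), 1.0)
    if (np.diff(chi2s) > monotonicity_tol * scale).any():
        raise RuntimeError("chi2 not monotone along the theta grid; optimizer failure")
    if (np.diff(skls) < -monotonicity_tol * max(skls.max(), 1.0)).any():
        raise RuntimeError("S_KL not monotone along the theta grid; optimizer failure")
    if skls.max() < 1e-10 or np.ptp(chi2s) < 1e-12 * scale:
        return float(thetas[0]), table  # zero-misfit degenerate case
    log_chi2 = np.log10(np.clip(chi2s, 1e-14, None))
    curv = np.zeros(len(thetas))
    for i in range(1, len(thetas) - 1):
        p0 = np.array([log_chi2[i - 1], skls[i - 1]])
        p1 = np.array([log_chi2[i], skls[i]])
        p2 = np.array([log_chi2[i + 1], skls[i + 1]])
        a = np.linalg.norm(p1 - p0)
        b = np.linalg.norm(p2 - p1)
        c = np.linalg.norm(p2 - p0)
        if a * b * c > 0:
            cross = (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p1[1] - p0[1]) * (p2[0] - p0[0])
            curv[i] = 2.0 * abs(cross) / (a * b * c)
    return float(thetas[int(np.argmax(curv))]), table


def select_conformer(
    conformer_problems: list[dict],
    theta_policy: float | str = 10.0,
) -> tuple[int, np.ndarray]:
    """Pick the conformer with minimal total (summed over sites) chi^2.

    theta_policy: a fixed theta shared by all sites, or "lcurve" for
    per-site L-curve selection. Ties break toward the lower index.
    """
    if len(conformer_problems) == 0:
        raise ValueError("need at least one conformer")
    sites = sorted(conformer_problems[0])
    for i, probs in enumerate(conformer_problems):
        if sorted(probs) != sites:
            raise ValueError(f"conformer {i} does not cover the same sites")
    totals = np.empty(len(conformer_problems))
    for i, probs in enumerate(conformer_problems):
        total = 0.0
        for site in sites:
            problem = probs[site]
            if theta_policy == "lcurve":
                theta, _ = theta_lcurve(problem)
            else:
                theta = float(theta_policy)
            total += reweight(problem, theta).chi2
        totals[i] = total
    return int(np.argmin(totals)), totals


def marginal_weights(pair_weights: np.ndarray, n_rotamers: int, axis: int = 0) -> np.ndarray:
    """Marginalize joint rotamer-pair weights over the partner index."""
    w = np.asarray(pair_weights, dtype=float).reshape(n_rotamers, -1)
    m = w.sum(axis=1 - axis)
    return m / m.sum()
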