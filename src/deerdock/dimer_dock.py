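"""C2-symmetric rigid-body dimer docking against PELDOR data.

Two search modes, matching the two experimental strategies:

* grid mode: exhaustive search over (alpha, beta, x, y) scored by the RMSD
  between simulated and target mean inter-protomer spin distances, with a
  radial contact cull before ensemble scoring, followed by local
  simplex refinement;
* contact-sweep (time-domain) mode: spin/revolve the second protomer in
  fixed angular steps, slide it radially to the first clash-free touching
  position, and score summed per-site chi-squared between forward-calculated
  and experimental form factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .deer_forward import DeerTrace, kernel_matrix, default_r_grid
from .spin_labeling import SpinSiteEnsemble, _bin_pairs
from .structures import C2Pose, Structure, rotation_y, rotation_z

__all__ = [
    "C2Pose",
    "RestraintSet",
    "DockResult",
    "GridSpec",
    "score_distance",
    "grid_search",
    "refine",
    "contact_sweep",
    "DistanceObjective",
]

log = logging.getLogger(__name__)

_PENALTY = 1e6


@dataclass(frozen=True)
class RestraintSet:
    """Per-site target mean +/- sd inter-protomer distances (nm)."""

    entries: dict

    def __post_init__(self):
        for site, (mean, sd) in self.entries.items():
            if mean <= 0:
                raise ValueError(f"restraint mean for {site} must be positive")
            if sd < 0:
                raise ValueError(f"restraint sd for {site} must be non-negative")

    @property
    def sites(self) -> list:
        return sorted(self.entries)

    def targets(self) -> np.ndarray:
        return np.array([self.entries[s][0] for s in self.sites])


@dataclass
class DockResult:
    pose: C2Pose
    score: float
    mode: str  # "distance" | "timedomain"
    clash_free: bool
    per_site_means: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("score must be non-negative")


@dataclass(frozen=True)
class GridSpec:
    """Docking grid; defaults span the full production search space
    (alpha 0-360/10 deg, beta 0-180/5 deg, x and y +/-7.5/0.25 nm)."""

    alpha: np.ndarray = field(default_factory=lambda: np.arange(0.0, 360.1, 10.0))
    beta: np.ndarray = field(default_factory=lambda: np.arange(0.0, 180.1, 5.0))
    x: np.ndarray = field(default_factory=lambda: np.arange(-7.5, 7.51, 0.25))
    y: np.ndarray = field(default_factory=lambda: np.arange(-7.5, 7.51, 0.25))

    @property
    def n_nodes(self) -> int:
        return len(self.alpha) * len(self.beta) * len(self.x) * len(self.y)


def pose_equivalents(pose: C2Pose) -> tuple[C2Pose, C2Pose]:
    """The two C2 poses with identical inter-protomer distance data.

    (alpha, beta, x, y) and (alpha + 180, 180 - beta, x, -y) place the spin
    pairs at the same mutual distances (z-mirror related dimers), so no
    distance- or time-domain score can separate them.
    """
    return (
        pose,
        C2Pose((pose.alpha + 180.0) % 360.0, 180.0 - pose.beta, pose.x, -pose.y),
    )


def pose_parameter_error(found: C2Pose, truth: C2Pose) -> tuple[float, float, float, float]:
    """Per-parameter |found - truth| minimized over the exact pose equivalence
    class, with alpha compared on the circle."""
    best = None
    for eq in pose_equivalents(truth):
        da = abs(found.alpha - eq.alpha) % 360.0
        da = min(da, 360.0 - da)
        err = (da, abs(found.beta - eq.beta), abs(found.x - eq.x), abs(found.y - eq.y))
        if best is None or sum(err) < sum(best):
            best = err
    return best


def _pair_sums(p: np.ndarray):
    """Flattened pairwise sums/differences used by the C2 distance formula.

    For A' = p + t and B' = Rz(180) A', the inter-protomer distances are
    d_ij^2 = (p_ix + p_jx + 2tx)^2 + (p_iy + p_jy + 2ty)^2 + (p_iz - p_jz)^2.
    """
    sx = (p[:, 0][:, None] + p[:, 0][None, :]).ravel()
    sy = (p[:, 1][:, None] + p[:, 1][None, :]).ravel()
    dz2 = ((p[:, 2][:, None] - p[:, 2][None, :]) ** 2).ravel()
    return sx, sy, dz2


def _rotation(alpha: float, beta: float) -> np.ndarray:
    return rotation_y(beta) @ rotation_z(alpha)


def _site_mean(positions: np.ndarray, weights: np.ndarray, rot: np.ndarray, tx, ty):
    """Weighted mean inter-protomer pair distance; tx/ty may be arrays of nodes."""
    e = positions @ rot.T
    sx, sy, dz2 = _pair_sums(e)
    wpair = np.outer(weights, weights).ravel()
    tx = np.atleast_1d(tx)
    ty = np.atleast_1d(ty)
    d = np.sqrt(
        (sx[None, :] + 2.0 * tx[:, None]) ** 2
        + (sy[None, :] + 2.0 * ty[:, None]) ** 2
        + dz2[None, :]
    )
    return d @ wpair


def _prepare(protomer: Structure, ensembles: dict, max_rotamers: int | None):
    center = protomer.geometric_center
    ca = protomer.ca_coords() - center
    prepped = {}
    for site, ens in ensembles.items():
        e = ens.shifted(-center)
        if max_rotamers is not None:
            e = e.thinned(max_rotamers)
        prepped[site] = e
    return center, ca, prepped


def score_distance(
    pose: C2Pose,
    ensembles: dict,
    restraints: RestraintSet,
    center: np.ndarray | None = None,
) -> tuple[float, dict]:
    """RMSD between simulated and target per-site mean distances (nm).

    Ensembles are given in the protomer frame; `center` is the protomer
    geometric centre used for dimer assembly (None if pre-centred).
    """
    missing = [s for s in restraints.sites if s not in ensembles]
    if missing:
        raise ValueError(f"no spin ensemble for restraint site(s): {missing}")
    rot = _rotation(pose.alpha, pose.beta)
    t = np.array([pose.x, pose.y])
    means = {}
    for site in restraints.sites:
        ens = ensembles[site]
        pos = ens.positions if center is None else ens.positions - np.asarray(center)
        means[site] = float(_site_mean(pos, ens.weights, rot, t[0], t[1])[0])
    dev = np.array([means[s] - restraints.entries[s][0] for s in restraints.sites])
    return float(np.sqrt(np.mean(dev**2))), means


def grid_search(
    protomer: Structure,
    ensembles: dict,
    restraints: RestraintSet,
    grid: GridSpec | None = None,
    clash_cut: float = 0.4,
    contact_cut: float = 1.0,
    max_rotamers: int | None = 24,
    top_k: int = 10,
) -> list[DockResult]:
    """Exhaustive distance-restraint grid search over C2 poses.

    Every grid node is considered; nodes failing the clash/contact criterion
    (CA-CA) are excluded. A radial cull (protomer bounding sphere vs the
    contact cutoff) removes unreachable translations before the exact pair
    check. Results are sorted by ascending RMSD with lexicographic
    (alpha, beta, x, y) tie-breaks. Deterministic.

    max_rotamers thins each ensemble (uniform stride) for grid scoring;
    pass None to score with full ensembles.
    """
    grid = grid or GridSpec()
    center, ca, prepped = _prepare(protomer, ensembles, max_rotamers)
    sites = restraints.sites
    missing = [s for s in sites if s not in prepped]
    if missing:
        raise ValueError(f"no spin ensemble for restraint site(s): {missing}")
    targets = restraints.targets()

    nodes = np.array([(xi, yi) for xi in grid.x for yi in grid.y])
    r_max = float(np.linalg.norm(ca, axis=1).max())
    # contact is impossible when the bounding spheres are farther apart than the cutoff
    reachable = 2.0 * np.linalg.norm(nodes, axis=1) - 2.0 * r_max <= contact_cut
    nodes = nodes[reachable]
    if len(nodes) == 0:
        raise ValueError("no grid translation can bring the protomers into contact")

    clash2, contact2 = clash_cut**2, contact_cut**2
    rec_score, rec_pose, rec_means = [], [], []
    for alpha in grid.alpha:
        for beta in grid.beta:
            rot = _rotation(alpha, beta)
            p = ca @ rot.T
            sx, sy, dz2 = _pair_sums(p)
            dx = sx[None, :] + 2.0 * nodes[:, 0:1]
            dy = sy[None, :] + 2.0 * nodes[:, 1:2]
            dmin2 = (dx * dx + dy * dy + dz2[None, :]).min(axis=1)
            ok = (dmin2 >= clash2) & (dmin2 <= contact2)
            if not ok.any():
                continue
            sel = nodes[ok]
            means = np.stack(
                [
                    _site_mean(
                        prepped[s].positions, prepped[s].weights, rot, sel[:, 0], sel[:, 1]
                    )
                    for s in sites
                ]
            )  # (n_sites, n_sel)
            rmsd = np.sqrt(((means - targets[:, None]) ** 2).mean(axis=0))
            rec_score.append(rmsd)
            rec_means.append(means)
            rec_pose.append(
                np.column_stack(
                    [np.full(len(sel), alpha), np.full(len(sel), beta), sel]
                )
            )
    if not rec_score:
        raise ValueError("no clash-free in-contact pose on the grid")
    scores = np.concatenate(rec_score)
    poses = np.vstack(rec_pose)
    means_all = np.hstack(rec_means)
    order = np.lexsort((poses[:, 3], poses[:, 2], poses[:, 1], poses[:, 0], scores))
    results = []
    for idx in order[: max(top_k, 1)]:
        a, b, xi, yi = poses[idx]
        results.append(
            DockResult(
                pose=C2Pose(float(a), float(b), float(xi), float(yi)),
                score=float(scores[idx]),
                mode="distance",
                clash_free=True,
                per_site_means={s: float(means_all[j, idx]) for j, s in enumerate(sites)},
            )
        )
    return results


class DistanceObjective:
    """Clash-penalized distance-RMSD objective over C2 poses (for refinement)."""

    def __init__(
        self,
        protomer: Structure,
        ensembles: dict,
        restraints: RestraintSet,
        clash_cut: float = 0.4,
        contact_cut: float = 1.0,
        require_contact: bool = True,
        max_rotamers: int | None = None,
    ):
        self.center, self._ca, self._ens = _prepare(protomer, ensembles, max_rotamers)
        self.restraints = restraints
        self.clash_cut = clash_cut
        self.contact_cut = contact_cut
        self.require_contact = require_contact
        self.mode = "distance"

    def evaluate(self, pose: C2Pose):
        rot = _rotation(pose.alpha, pose.beta)
        p = self._ca @ rot.T
        sx, sy, dz2 = _pair_sums(p)
        dmin2 = (
            (sx + 2.0 * pose.x) ** 2 + (sy + 2.0 * pose.y) ** 2 + dz2
        ).min()
        clash_free = dmin2 >= self.clash_cut**2
        in_contact = dmin2 <= self.contact_cut**2
        rmsd, means = score_distance(pose, self._ens, self.restraints)
        return rmsd, means, clash_free, in_contact

    def __call__(self, pose: C2Pose) -> float:
        rmsd, _, clash_free, in_contact = self.evaluate(pose)
        if not clash_free or (self.require_contact and not in_contact):
            return _PENALTY + rmsd
        return rmsd


def _pose_from_vector(vec: np.ndarray) -> C2Pose:
    alpha = float(vec[0]) % 360.0
    beta = float(vec[1])
    if not 0.0 <= beta <= 180.0:
        raise ValueError(f"beta left its domain during refinement: {beta}")
    return C2Pose(alpha, beta, float(vec[2]), float(vec[3]))


def refine(
    start: C2Pose,
    score_fn,
    bounds: tuple | None = None,
    steps: tuple = (10.0, 5.0, 0.25, 0.25),
    tol: float = 1e-4,
    max_iter: int = 2000,
) -> DockResult:
    """Derivative-free simplex refinement of a pose.

    The initial simplex spans one grid cell per parameter; iteration stops
    when the score change falls below `tol`. Deterministic given the start;
    the returned score never exceeds the start score.
    """
    x0 = np.array(start.as_tuple(), dtype=float)
    if bounds is None:
        bounds = [(None, None), (0.0, 180.0), (None, None), (None, None)]

    def objective(vec):
        beta = min(max(vec[1], 0.0), 180.0)
        penalty = abs(vec[1] - beta) * _PENALTY
        pose = _pose_from_vector([vec[0], beta, vec[2], vec[3]])
        val = float(score_fn(pose)) + penalty
        if not np.isfinite(val):
            raise ValueError(f"non-finite score at pose {pose}")
        return val

    simplex = np.vstack([x0] + [x0 + np.eye(4)[i] * steps[i] for i in range(4)])
    # keep the simplex inside the beta domain
    simplex[:, 1] = np.clip(simplex[:, 1], 0.0, 180.0)
    for i in range(1, 5):
        if np.allclose(simplex[i], x0):
            simplex[i] = x0 - np.eye(4)[i - 1] * steps[i - 1]
            simplex[i, 1] = np.clip(simplex[i, 1], 0.0, 180.0)
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "fatol": tol,
            "xatol": tol,
            "maxiter": max_iter,
        },
    )
    start_score = objective(x0)
    best_vec, best_score = (res.x, res.fun) if res.fun <= start_score else (x0, start_score)
    pose = _pose_from_vector([best_vec[0], min(max(best_vec[1], 0.0), 180.0), best_vec[2], best_vec[3]])
    if hasattr(score_fn, "evaluate"):
        score, means, clash_free, _ = score_fn.evaluate(pose)
        mode = getattr(score_fn, "mode", "distance")
        return DockResult(pose, float(score_fn(pose)), mode, clash_free, means)
    return DockResult(pose, float(best_score), "distance", best_score < _PENALTY, {})


def contact_sweep(
    protomer: Structure,
    ensembles: dict,
    traces: dict,
    depth: float,
    phi1_step: float = 5.0,
    phi2_step: float = 10.0,
    touch_dist: float = 0.5,
    clash_cut: float = 0.4,
    contact_cut: float = 1.0,
    sigma: dict | float = 1.0,
    r_grid: np.ndarray | None = None,
    max_rotamers: int | None = 24,
    top_k: int = 10,
) -> list[DockResult]:
    """Time-domain contact-sweep docking.

    For each (phi1, phi2) pair the second protomer is spun about its own z
    axis (phi2 steps), revolved about the first protomer's z axis (phi1
    steps) and slid radially inward to the first clash-free touching
    position (closest CA-CA pair at `touch_dist`, solved in closed form).
    Each touching pose is scored by the summed per-site chi-squared between
    forward-calculated (uniform-rotamer) and experimental form factors.
    Unreachable nodes are skipped with a log entry.
    """
    if not clash_cut <= touch_dist <= contact_cut:
        raise ValueError("touch_dist must lie in [clash_cut, contact_cut]")
    sites = sorted(traces)
    center, ca, prepped = _prepare(protomer, ensembles, max_rotamers)
    missing = [s for s in sites if s not in prepped]
    if missing:
        raise ValueError(f"no spin ensemble for trace site(s): {missing}")
    if r_grid is None:
        r_grid = default_r_grid(0.05, 15.0, 0.05)
    kms = {s: kernel_matrix(traces[s].t, r_grid) for s in sites}
    dr = r_grid[1] - r_grid[0]
    trap = np.full(len(r_grid), dr)
    trap[0] = trap[-1] = dr / 2.0

    results = []
    touch2 = touch_dist**2
    for phi2 in np.arange(0.0, 360.0, phi2_step):
        rot = rotation_z(phi2)
        p = ca @ rot.T
        sx, sy, dz2 = _pair_sums(p)
        c_rest = sx**2 + sy**2 + dz2
        for phi1 in np.arange(0.0, 360.0, phi1_step):
            c, s = np.cos(np.deg2rad(phi1)), np.sin(np.deg2rad(phi1))
            b_lin = c * sx + s * sy
            disc = b_lin**2 - c_rest + touch2
            valid = disc >= 0
            if not valid.any():
                log.info("contact sweep: no contact reachable at phi1=%g phi2=%g", phi1, phi2)
                continue
            rho = float(((-b_lin[valid] + np.sqrt(disc[valid])) / 2.0).max())
            if rho <= 0:
                log.info("contact sweep: touching radius non-positive at phi1=%g phi2=%g", phi1, phi2)
                continue
            pose = C2Pose(phi2 % 360.0, 0.0, rho * c, rho * s)
            chi2 = 0.0
            for site in sites:
                ens = prepped[site]
                d = _c2_pair_distances(ens.positions, rot, rho * c, rho * s)
                wpair = np.outer(ens.weights, ens.weights).ravel()
                dist = _bin_pairs(d, wpair, r_grid, clip=True)
                f_sim = 1.0 - depth + depth * (kms[site] @ (dist.p * trap))
                sig = sigma[site] if isinstance(sigma, dict) else sigma
                chi2 += float((((f_sim - traces[site].v) / sig) ** 2).sum())
            results.append(DockResult(pose, chi2, "timedomain", True, {}))
    if not results:
        raise ValueError("contact sweep found no reachable contact pose")
    results.sort(key=lambda r: (r.score, r.pose.alpha, r.pose.x, r.pose.y))
    return results[: max(top_k, 1)]


def _c2_pair_distances(positions: np.ndarray, rot: np.ndarray, tx: float, ty: float):
    e = positions @ rot.T
    sx, sy, dz2 = _pair_sums(e)
    return np.sqrt((sx + 2.0 * tx) ** 2 + (sy + 2.0 * ty) ** 2 + dz2)
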