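"""Spin-label position ensembles and inter-site distance distributions.

The default label model is a uniform spherical-shell stand-in for a
rotamer library: candidate nitroxide positions are sampled uniformly in a
shell around the site's (pseudo-)C-beta and filtered against protein
heavy-atom clashes. A file-based hook accepts real rotamer tables defined
in the local backbone frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .deer_forward import DistanceDistribution
from .structures import C2Pose, Structure, rotation_z

__all__ = [
    "SpinSiteEnsemble",
    "attach_label",
    "pair_distance_distribution",
    "c2_pair_distribution",
    "load_rotamer_table",
]

log = logging.getLogger(__name__)


@dataclass
class SpinSiteEnsemble:
    """Weighted cloud of spin-centre positions for one labeled site (nm)."""

    site: tuple[str, int]
    positions: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if len(self.positions) < 1:
            raise ValueError("ensemble must contain at least one position")
        if len(self.weights) != len(self.positions):
            raise ValueError("weights and positions must have equal length")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def centroid(self) -> np.ndarray:
        return self.weights @ self.positions

    def shifted(self, offset: np.ndarray) -> "SpinSiteEnsemble":
        return SpinSiteEnsemble(self.site, self.positions + np.asarray(offset), self.weights)

    def thinned(self, max_positions: int) -> "SpinSiteEnsemble":
        """Deterministic subsample (uniform stride) for fast grid scoring."""
        n = len(self)
        if max_positions >= n:
            return self
        idx = np.unique(np.linspace(0, n - 1, max_positions).round().astype(int))
        w = self.weights[idx]
        return SpinSiteEnsemble(self.site, self.positions[idx], w / w.sum())


def _pseudo_cbeta(atoms: dict[str, np.ndarray]) -> np.ndarray:
    """Ideal C-beta from backbone N/CA/C (tetrahedral construction, nm)."""
    n, ca, c = atoms["N"], atoms["CA"], atoms["C"]
    b = ca - n
    cvec = c - ca
    a = np.cross(b, cvec)
    # standard ideal-geometry coefficients (derived for Angstrom); the cross
    # term scales quadratically with length, hence the factor 10
    return -0.58273431 * a * 10.0 + 0.56802827 * b - 0.54067466 * cvec + ca


def _label_center(atoms: dict[str, np.ndarray], site) -> np.ndarray:
    if "CB" in atoms:
        return atoms["CB"]
    if all(k in atoms for k in ("N", "CA", "C")):
        return _pseudo_cbeta(atoms)
    if "CA" in atoms:
        # C-alpha-trace fallback (toy models carry no sidechain/backbone detail)
        return atoms["CA"]
    raise ValueError(f"site {site} lacks backbone atoms needed to place a label")


def _backbone_frame(atoms: dict[str, np.ndarray], site):
    for key in ("N", "CA", "C"):
        if key not in atoms:
            raise ValueError(f"site {site} lacks backbone atom {key} for the rotamer frame")
    n, ca, c = atoms["N"], atoms["CA"], atoms["C"]
    e1 = (n - ca) / np.linalg.norm(n - ca)
    e3 = np.cross(e1, c - ca)
    e3 = e3 / np.linalg.norm(e3)
    e2 = np.cross(e3, e1)
    return ca, np.stack([e1, e2, e3])


def load_rotamer_table(path) -> np.ndarray:
    """Read a whitespace-separated rotamer table: dx dy dz weight (nm, local frame)."""
    table = np.loadtxt(path, comments="#", ndmin=2)
    if table.shape[1] != 4:
        raise ValueError("rotamer table must have 4 columns: dx dy dz weight")
    if (table[:, 3] < 0).any() or table[:, 3].sum() <= 0:
        raise ValueError("rotamer weights must be non-negative with positive sum")
    return table


def attach_label(
    structure: Structure,
    site: tuple[str, int],
    model: str = "uniform-shell",
    seed: int = 0,
    n_candidates: int = 200,
    shell: tuple[float, float] = (0.4, 0.9),
    clash_radius: float = 0.25,
    rotamer_table: np.ndarray | None = None,
) -> SpinSiteEnsemble:
    """Attach a spin-label position ensemble to a residue.

    "uniform-shell": n_candidates positions sampled uniformly in the shell
    (radii in nm) around the site's C-beta (pseudo-C-beta from backbone, or
    C-alpha for C-alpha-trace models); candidates within clash_radius of any
    protein heavy atom are rejected; survivors get uniform weights.
    Deterministic for fixed seed.

    "table": positions from a (dx, dy, dz, weight) rotamer table expressed in
    the local backbone frame (origin CA, e1 = unit(N - CA), e3 = unit(e1 x
    (C - CA)), e2 = e3 x e1); same clash filter, weights renormalized.
    """
    chain, resnum = site
    atoms = structure.residue(chain, int(resnum))
    if model == "uniform-shell":
        center = _label_center(atoms, site)
        rng = np.random.default_rng(seed)
        r_in, r_out = shell
        u = rng.random(n_candidates)
        radius = (u * (r_out**3 - r_in**3) + r_in**3) ** (1.0 / 3.0)
        direction = rng.normal(size=(n_candidates, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        candidates = center + radius[:, None] * direction
        weights = np.full(n_candidates, 1.0)
    elif model == "table":
        if rotamer_table is None:
            raise ValueError("model='table' requires a rotamer_table")
        origin, frame = _backbone_frame(atoms, site)
        candidates = origin + rotamer_table[:, :3] @ frame
        weights = rotamer_table[:, 3].astype(float)
    else:
        raise ValueError(f"unknown label model {model!r}")

    dmin = cdist(candidates, structure.coords).min(axis=1)
    keep = dmin >= clash_radius
    if not keep.any():
        raise ValueError(f"site {site} is buried: all label candidates clash with the protein")
    w = weights[keep]
    return SpinSiteEnsemble((chain, int(resnum)), candidates[keep], w / w.sum())


def _bin_pairs(
    d: np.ndarray, w: np.ndarray, r_grid: np.ndarray, clip: bool = False
) -> DistanceDistribution:
    """Linear-sharing (cloud-in-cell) histogram of weighted distances.

    Mass between two grid nodes is split linearly, which preserves the first
    moment of the pair-distance set for interior distances. With clip=True,
    out-of-range distances accumulate in the edge bins instead of raising.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    dr = r_grid[1] - r_grid[0]
    if d.min() < r_grid[0] or d.max() > r_grid[-1]:
        if not clip:
            raise ValueError(
                f"pair distances span [{d.min():.3f}, {d.max():.3f}] nm, outside the "
                f"r grid [{r_grid[0]:.3f}, {r_grid[-1]:.3f}] nm; extend the grid"
            )
        d = np.clip(d, r_grid[0], r_grid[-1])
    pos = (d - r_grid[0]) / dr
    lo = np.clip(np.floor(pos).astype(int), 0, len(r_grid) - 2)
    frac = pos - lo
    masses = np.zeros(len(r_grid))
    np.add.at(masses, lo, w * (1.0 - frac))
    np.add.at(masses, lo + 1, w * frac)
    return DistanceDistribution.from_unnormalized(r_grid, masses / dr)


def pair_distance_distribution(
    a: SpinSiteEnsemble,
    b: SpinSiteEnsemble,
    r_grid: np.ndarray,
    zero_tol: float = 1e-9,
) -> DistanceDistribution:
    """Distribution of all inter-ensemble distances |p_i - q_j| weighted w_i v_j.

    Zero-distance degenerate pairs are dropped with a warning rather than
    binned; remaining weights are renormalized to unit integral.
    """
    d = cdist(a.positions, b.positions).ravel()
    w = np.outer(a.weights, b.weights).ravel()
    nonzero = d > zero_tol
    if not nonzero.all():
        log.warning("dropping %d zero-distance pair(s)", int((~nonzero).sum()))
    d, w = d[nonzero], w[nonzero]
    if len(d) == 0:
        raise ValueError("all pair distances are zero; ensembles coincide")
    return _bin_pairs(d, w / w.sum(), r_grid)


def c2_pair_distribution(
    protomer_ensemble: SpinSiteEnsemble,
    pose: C2Pose,
    r_grid: np.ndarray,
    center: np.ndarray | None = None,
) -> DistanceDistribution:
    """Inter-protomer distance distribution between the two C2 copies of a site.

    The ensemble is placed with the same convention as dimer assembly
    (centre at origin unless `center`, the protomer geometric centre, is
    given, then pose transform), and paired with its 180 deg z-rotation.
    """
    pos = protomer_ensemble.positions
    if center is not None:
        pos = pos - np.asarray(center, dtype=float)
    a_pos = pose.transform.apply(pos)
    b_pos = a_pos @ rotation_z(180.0).T
    a = SpinSiteEnsemble(protomer_ensemble.site, a_pos, protomer_ensemble.weights)
    b = SpinSiteEnsemble(protomer_ensemble.site, b_pos, protomer_ensemble.weights)
    return pair_distance_distribution(a, b, r_grid)
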