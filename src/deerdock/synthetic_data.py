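"""Synthetic inputs for every pipeline stage.

Toy C-alpha-trace protomers built from ideal helices, ground-truth C2
dimer scenarios with labeled sites and noisy dipolar traces, and uptake
time courses following the quadratic mixing model. Every generator is a
pure function of its seed and spec.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import deer_forward as df
from . import spin_labeling as sl
from .dimer_dock import RestraintSet
from .deer_invert import distribution_moments
from .structures import C2Pose, Structure, clash_and_contact, make_c2_dimer, write_pdb
from .transport_mixing import MixingModel, UptakeTimeCourse, predicted_rate

__all__ = [
    "ToySpec",
    "GroundTruth",
    "make_toy_protomer",
    "make_truth_scenario",
    "make_uptake_dataset",
    "find_touching_pose",
]

_HELIX_RISE = 0.15  # nm per residue
_HELIX_TURN = 100.0  # deg per residue


@dataclass(frozen=True)
class ToySpec:
    """Toy protomer: ideal C-alpha helices on a circle, axes along z."""

    n_helices: int = 3
    helix_len: int = 20
    ring_radius: float = 2.0
    helix_radius: float = 0.23
    label_sites: tuple = ((("A", 5)), (("A", 25)), (("A", 45)))
    seed: int = 0
    jitter_sd: float = 0.02

    def __post_init__(self):
        if self.n_helices < 1:
            raise ValueError("need at least one helix")
        n_res = self.n_helices * self.helix_len
        for chain, resnum in self.label_sites:
            if not 1 <= resnum <= n_res:
                raise ValueError(f"label site {(chain, resnum)} outside residue range 1..{n_res}")


@dataclass
class GroundTruth:
    """Everything needed to check recovery of a synthetic scenario."""

    pose: C2Pose
    site_distributions: dict
    restraints: RestraintSet
    depth: float
    background_k: float
    noise_sd: float
    mixing: MixingModel | None = None


def make_toy_protomer(spec: ToySpec) -> Structure:
    """C-alpha-trace protomer: ideal helices (0.15 nm rise, 100 deg turn per
    residue) arranged on a circle with axes along z; small seeded jitter
    makes scenarios distinct across seeds. Deterministic per seed."""
    axis_angles = 2.0 * np.pi * np.arange(spec.n_helices) / max(spec.n_helices, 1)
    centers = spec.ring_radius * np.column_stack([np.cos(axis_angles), np.sin(axis_angles)])
    if spec.n_helices > 1:
        axis_sep = np.linalg.norm(centers[0] - centers[1])
        if axis_sep < 2.0 * spec.helix_radius:
            raise ValueError("helix placement overlaps: axes closer than two helix radii")
    rng = np.random.default_rng(spec.seed)
    coords = []
    half_height = (spec.helix_len - 1) * _HELIX_RISE / 2.0
    for h in range(spec.n_helices):
        for i in range(spec.helix_len):
            phase = np.deg2rad(_HELIX_TURN * i) + axis_angles[h]
            coords.append(
                [
                    centers[h, 0] + spec.helix_radius * np.cos(phase),
                    centers[h, 1] + spec.helix_radius * np.sin(phase),
                    i * _HELIX_RISE - half_height,
                ]
            )
    coords = np.asarray(coords) + rng.normal(scale=spec.jitter_sd, size=(len(coords), 3))
    n = len(coords)
    return Structure(
        chain_ids=np.full(n, "A"),
        res_ids=np.arange(1, n + 1),
        res_names=np.full(n, "ALA"),
        atom_names=np.full(n, "CA"),
        elements=np.full(n, "C"),
        coords=coords,
        label=f"toy-protomer-seed{spec.seed}",
    )


def find_touching_pose(
    protomer: Structure,
    alpha: float,
    beta: float,
    phi: float,
    min_distance: float = 0.7,
) -> C2Pose:
    """C2 pose with the given rotation whose translation lies along direction
    `phi` (deg, in-plane) at the radius where the closest inter-protomer
    CA-CA distance equals `min_distance` (bisection). Guarantees a clash-free,
    in-contact truth pose for synthetic recovery scenarios."""
    c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))

    def dmin(rho):
        a, b = make_c2_dimer(protomer, C2Pose(alpha, beta, rho * c, rho * s))
        return clash_and_contact(a, b)[2]

    # scan inward for the outermost radius where the protomers come closer
    # than the target, then bisect the touching point just outside it
    hi = 20.0
    lo = None
    for rho in np.linspace(hi, 0.0, 801):
        if dmin(rho) < min_distance:
            lo = rho
            break
        hi = rho
    if lo is None:
        raise ValueError(
            f"no touching position along phi={phi} deg for this rotation"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if dmin(mid) < min_distance:
            lo = mid
        else:
            hi = mid
    return C2Pose(alpha, beta, hi * c, hi * s)


def make_truth_scenario(
    spec: ToySpec,
    pose: C2Pose,
    depth: float = 0.35,
    background_k: float = 0.1,
    noise_sd: float = 0.01,
    t_max: float = 3.0,
    dt: float = 0.008,
    r_grid: np.ndarray | None = None,
    out_dir=None,
) -> tuple[GroundTruth, dict]:
    """Build a ground-truth C2 dimer scenario and (optionally) its file bundle.

    Returns (GroundTruth, objects) where objects holds the protomer,
    per-site ensembles, true distributions, noise-free form factors and
    noisy primary traces. With out_dir set, writes protomer PDB, per-site
    P(r) CSVs, two-column trace files, a restraint CSV and a manifest JSON;
    reruns with the same seed are byte-identical.
    """
    protomer = make_toy_protomer(spec)
    a, b = make_c2_dimer(protomer, pose)
    clashing, in_contact, dmin = clash_and_contact(a, b)
    if clashing or not in_contact:
        raise ValueError(
            f"truth pose must be clash-free and in contact (min CA-CA {dmin:.2f} nm)"
        )
    center = protomer.geometric_center
    t = dt * np.arange(int(round(t_max / dt)) + 1)
    rng = np.random.default_rng(spec.seed + 7919)

    ensembles = {
        tuple(site): sl.attach_label(protomer, tuple(site), seed=spec.seed + 31 * site[1])
        for site in spec.label_sites
    }
    if r_grid is None:
        # span the actual pair-distance range of this scenario
        from .structures import rotation_z

        lo, hi = np.inf, 0.0
        for ens in ensembles.values():
            a = pose.transform.apply(ens.positions - center)
            b = a @ rotation_z(180.0).T
            d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
            lo = min(lo, float(d.min()))
            hi = max(hi, float(d.max()))
        r_min = max(0.01, np.floor((lo - 0.2) * 10.0) / 10.0)
        r_max = np.ceil((hi + 0.5) * 10.0) / 10.0
        r_grid = df.default_r_grid(r_min, r_max, 0.02)

    distributions, form_factors, traces, restraints = {}, {}, {}, {}
    for site in spec.label_sites:
        site = tuple(site)
        ens = ensembles[site]
        dist = sl.c2_pair_distribution(ens, pose, r_grid, center=center)
        distributions[site] = dist
        ff = df.form_factor(dist, t, depth)
        form_factors[site] = ff
        primary = df.apply_background(ff, df.BackgroundModel(background_k))
        noisy = primary.v + rng.normal(scale=noise_sd, size=len(t)) if noise_sd > 0 else primary.v
        traces[site] = df.DeerTrace(t, noisy / noisy[0], kind="primary")
        mean, sd = distribution_moments(dist)
        restraints[site] = (mean, sd)

    truth = GroundTruth(
        pose=pose,
        site_distributions=distributions,
        restraints=RestraintSet(restraints),
        depth=depth,
        background_k=background_k,
        noise_sd=noise_sd,
    )
    objects = {
        "protomer": protomer,
        "ensembles": ensembles,
        "form_factors": form_factors,
        "traces": traces,
        "r_grid": r_grid,
    }
    if out_dir is not None:
        _write_bundle(Path(out_dir), spec, truth, objects)
    return truth, objects


def _site_tag(site) -> str:
    return f"{site[0]}{site[1]}"


def _write_bundle(out_dir: Path, spec: ToySpec, truth: GroundTruth, objects: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_pdb(objects["protomer"], out_dir / "protomer.pdb")
    manifest = {
        "seed": spec.seed,
        "pose": dict(zip(("alpha", "beta", "x", "y"), truth.pose.as_tuple())),
        "depth": truth.depth,
        "background_k": truth.background_k,
        "noise_sd": truth.noise_sd,
        "sites": {},
    }
    rows = []
    for site, dist in truth.site_distributions.items():
        tag = _site_tag(site)
        pr_file = f"pr_{tag}.csv"
        trace_file = f"trace_{tag}.dat"
        pd.DataFrame({"r_nm": dist.r, "p_per_nm": dist.p}).to_csv(
            out_dir / pr_file, index=False, float_format="%.8e"
        )
        df.write_trace(
            objects["traces"][site],
            out_dir / trace_file,
            header=f"synthetic primary trace, site {tag}, depth={truth.depth}, "
            f"k={truth.background_k}, noise_sd={truth.noise_sd}, seed={spec.seed}",
        )
        mean, sd = truth.restraints.entries[site]
        rows.append({"chain": site[0], "residue": site[1], "mean_nm": mean, "sd_nm": sd})
        manifest["sites"][tag] = {
            "chain": site[0],
            "residue": site[1],
            "pr_csv": pr_file,
            "trace": trace_file,
            "mean_nm": round(mean, 8),
            "sd_nm": round(sd, 8),
        }
    pd.DataFrame(rows).to_csv(out_dir / "restraints.csv", index=False, float_format="%.8e")
    manifest["protomer_pdb"] = "protomer.pdb"
    manifest["restraints_csv"] = "restraints.csv"
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def make_uptake_dataset(
    model: MixingModel,
    f_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    time_grid=(0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0),
    noise_sd: float = 0.5,
    replicates: int = 3,
    plateau: float | None = None,
    seed: int = 0,
) -> list[UptakeTimeCourse]:
    """Uptake time courses under the quadratic mixing model.

    uptake(t) = rate(f) * t, saturating exponentially toward `plateau` when
    given, plus seeded Gaussian noise; `replicates` technical replicates per
    mixing fraction.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(time_grid, dtype=float)
    out = []
    for f_wt in f_grid:
        rate = predicted_rate(f_wt, model)
        if plateau is None:
            clean = rate * t
        else:
            clean = plateau * (1.0 - np.exp(-rate * t / plateau))
        frames = []
        for rep in range(1, replicates + 1):
            noisy = clean + (rng.normal(scale=noise_sd, size=len(t)) if noise_sd > 0 else 0.0)
            frames.append(
                pd.DataFrame({"time_min": t, "uptake": noisy, "replicate": rep})
            )
        out.append(UptakeTimeCourse(pd.concat(frames, ignore_index=True), float(f_wt)))
    return out
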