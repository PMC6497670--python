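"""Protein coordinate handling: PDB I/O, rigid transforms, C2 dimer assembly,
clash/contact detection and buried surface area.

All coordinates are stored in nanometres; Angstrom appear only at the PDB
file boundary and in reported surface areas (A^2). The membrane normal is
the +z axis by convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Structure",
    "RigidTransform",
    "C2Pose",
    "rotation_z",
    "rotation_y",
    "read_pdb",
    "write_pdb",
    "make_c2_dimer",
    "clash_and_contact",
    "buried_surface",
    "VDW_RADII_NM",
]

# Bondi van der Waals radii, nm. Fixed table; unknown elements are an error.
VDW_RADII_NM = {
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "SE": 0.190,
    "F": 0.147,
    "CL": 0.175,
    "BR": 0.185,
    "I": 0.198,
    "FE": 0.156,
    "ZN": 0.139,
    "MG": 0.173,
}

_WATER_RES = {"HOH", "WAT", "H2O", "DOD", "SOL"}


def rotation_z(angle_deg: float) -> np.ndarray:
    """Active right-handed rotation about the z axis."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_y(angle_deg: float) -> np.ndarray:
    """Active right-handed rotation about the y axis."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform: x -> rotation @ x + translation (nm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float)
        trans = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if trans.shape != (3,):
            raise ValueError("translation must be a 3-vector")
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(rot) - 1.0) > 1e-9:
            raise ValueError("rotation determinant must be +1 (proper rotation)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", trans)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out if np.asarray(points).ndim == 2 else out[0]

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class C2Pose:
    """Four docking parameters of a C2-symmetric parallel dimer.

    alpha (deg, [0, 360]) rotates the centred protomer about z, beta
    (deg, [0, 180]) tilts about y, then (x, y) translates in-plane; the
    partner protomer is the 180 deg z-rotation of the placed copy
    (gamma = 0 and z = 0 by construction).
    """

    alpha: float
    beta: float
    x: float
    y: float

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 360.0):
            raise ValueError(f"alpha must be in [0, 360], got {self.alpha}")
        if not (0.0 <= self.beta <= 180.0):
            raise ValueError(f"beta must be in [0, 180], got {self.beta}")
        if not np.isfinite([self.alpha, self.beta, self.x, self.y]).all():
            raise ValueError("pose parameters must be finite")

    @property
    def transform(self) -> RigidTransform:
        """Placement of protomer A: translate(x,y,0) ∘ rot_y(beta) ∘ rot_z(alpha)."""
        rot = rotation_y(self.beta) @ rotation_z(self.alpha)
        return RigidTransform(rot, np.array([self.x, self.y, 0.0]))

    def as_tuple(self):
        return (self.alpha, self.beta, self.x, self.y)


@dataclass
class Structure:
    """Atom-level coordinate set. Coordinates in nm, (N, 3)."""

    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        for attr in ("chain_ids", "res_ids", "res_names", "atom_names", "elements"):
            arr = np.asarray(getattr(self, attr))
            if len(arr) != n:
                raise ValueError(f"{attr} length {len(arr)} != number of atoms {n}")
            setattr(self, attr, arr)
        if not np.isfinite(self.coords).all():
            raise ValueError("all atom positions must be finite")
        keys = list(zip(self.chain_ids, self.res_ids, self.atom_names))
        if len(set(keys)) != n:
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate (chain, residue, atom) key: {dup}")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def geometric_center(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def transformed(self, tf: RigidTransform, label: str | None = None) -> "Structure":
        return replace(
            self,
            coords=tf.apply(self.coords),
            label=self.label if label is None else label,
        )

    def select_atoms(self, atom_name: str) -> "Structure":
        mask = self.atom_names == atom_name
        return Structure(
            self.chain_ids[mask],
            self.res_ids[mask],
            self.res_names[mask],
            self.atom_names[mask],
            self.elements[mask],
            self.coords[mask],
            label=self.label,
        )

    def ca_coords(self) -> np.ndarray:
        mask = self.atom_names == "CA"
        if not mask.any():
            raise ValueError(f"structure '{self.label}' has no CA atoms")
        return self.coords[mask]

    def residue(self, chain_id: str, res_id: int) -> dict[str, np.ndarray]:
        """Atom-name -> position map for one residue."""
        mask = (self.chain_ids == chain_id) & (self.res_ids == int(res_id))
        if not mask.any():
            raise KeyError(f"residue ({chain_id}, {res_id}) not found")
        return dict(zip(self.atom_names[mask], self.coords[mask]))


def _validate_pdb_text(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise ValueError(f"unparseable {rec} record at line {lineno}: too short")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise ValueError(
                f"unparseable coordinate field in {rec} record at line {lineno}"
            ) from exc


def read_pdb(path) -> Structure:
    """Read protein heavy atoms from a PDB file (Angstrom converted to nm).

    Hydrogens, waters and altlocs other than blank/'A' are skipped.
    Raises on unparseable ATOM/HETATM records (with line number), duplicate
    atom keys, or an empty selection.
    """
    from biotite.structure.io.pdb import PDBFile

    with open(path) as fh:
        text = fh.read()
    _validate_pdb_text(text)
    pdb = PDBFile.read(io.StringIO(text))
    try:
        arr = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:
        raise ValueError(f"no protein heavy atoms found in {path}") from exc
    elements = np.char.upper(arr.element.astype(str))
    mask = (elements != "H") & (elements != "D")
    mask &= ~np.isin(np.char.upper(arr.res_name.astype(str)), list(_WATER_RES))
    if not mask.any():
        raise ValueError(f"no protein heavy atoms found in {path}")
    arr = arr[mask]
    return Structure(
        chain_ids=arr.chain_id.astype(str),
        res_ids=arr.res_id.astype(int),
        res_names=arr.res_name.astype(str),
        atom_names=arr.atom_name.astype(str),
        elements=np.char.upper(arr.element.astype(str)),
        coords=arr.coord / 10.0,  # A -> nm
        label=str(path),
    )


def write_pdb(structure: Structure, path) -> None:
    """Write a Structure to PDB (nm converted back to Angstrom)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(structure)
    arr = struc.AtomArray(n)
    arr.chain_id = structure.chain_ids.astype("U4")
    arr.res_id = structure.res_ids.astype(int)
    arr.res_name = structure.res_names.astype("U5")
    arr.atom_name = structure.atom_names.astype("U6")
    arr.element = structure.elements.astype("U2")
    arr.coord = np.asarray(structure.coords, dtype=np.float32) * 10.0
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def make_c2_dimer(protomer: Structure, pose: C2Pose) -> tuple[Structure, Structure]:
    """Assemble an exactly C2-symmetric dimer about the z axis.

    The protomer is centred at its geometric centre, placed by the pose
    transform (A'), and the partner B' is the 180 deg z-rotation of A'.
    """
    if len(protomer) == 0:
        raise ValueError("protomer must be non-empty")
    center = protomer.geometric_center
    centered = replace(protomer, coords=protomer.coords - center)
    a = centered.transformed(pose.transform, label=f"{protomer.label}|A")
    c2 = RigidTransform(rotation_z(180.0), np.zeros(3))
    b = a.transformed(c2, label=f"{protomer.label}|B")
    return a, b


def clash_and_contact(
    a: Structure,
    b: Structure,
    clash_cut: float = 0.4,
    contact_cut: float = 1.0,
    ca_only: bool = True,
) -> tuple[bool, bool, float]:
    """Clash/contact verdict from inter-structure CA-CA distances (nm).

    is_clashing: any distance < clash_cut; is_in_contact: min <= contact_cut.
    Set ca_only=False for the full heavy-atom check.
    """
    if not clash_cut < contact_cut:
        raise ValueError("clash_cut must be smaller than contact_cut")
    pa = a.ca_coords() if ca_only else a.coords
    pb = b.ca_coords() if ca_only else b.coords
    dmin = float(cdist(pa, pb).min())
    return dmin < clash_cut, dmin <= contact_cut, dmin


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _atom_radii(structure: Structure, radii: dict[str, float] | None) -> np.ndarray:
    table = dict(VDW_RADII_NM)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    unknown = sorted({e for e in structure.elements if e.upper() not in table})
    if unknown:
        raise ValueError(f"no van der Waals radius for element(s): {', '.join(unknown)}")
    return np.array([table[e.upper()] for e in structure.elements])


def _sasa(coords: np.ndarray, radii: np.ndarray, probe: float, n_points: int) -> float:
    """Shrake-Rupley solvent-accessible surface area, nm^2."""
    sphere = _sphere_points(n_points)
    ext = radii + probe
    total = 0.0
    d2 = cdist(coords, coords, "sqeuclidean")
    for i in range(len(coords)):
        # neighbours whose extended spheres can occlude atom i's surface
        reach = (ext[i] + ext) ** 2
        nb = np.where((d2[i] < reach) & (np.arange(len(coords)) != i))[0]
        pts = coords[i] + ext[i] * sphere
        if len(nb):
            occluded = (
                cdist(pts, coords[nb], "sqeuclidean") < (ext[nb] ** 2)[None, :]
            ).any(axis=1)
            frac = 1.0 - occluded.mean()
        else:
            frac = 1.0
        total += frac * 4.0 * np.pi * ext[i] ** 2
    return total


def buried_surface(
    a: Structure,
    b: Structure,
    probe: float = 0.14,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> float:
    """Buried surface area SASA(a) + SASA(b) - SASA(a u b), reported in A^2.

    Shrake-Rupley sphere sampling with `n_points` (>= 100) per atom and
    probe radius in nm (default 0.14).
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    ra = _atom_radii(a, radii)
    rb = _atom_radii(b, radii)
    sasa_a = _sasa(a.coords, ra, probe, n_points)
    sasa_b = _sasa(b.coords, rb, probe, n_points)
    both = np.vstack([a.coords, b.coords])
    sasa_ab = _sasa(both, np.concatenate([ra, rb]), probe, n_points)
    return (sasa_a + sasa_b - sasa_ab) * 100.0  # nm^2 -> A^2
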