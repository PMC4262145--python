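"""Torsion angles, per-atom local frames and pair interaction geometry.

Every heavy atom carries an orthonormal right-handed frame built from its
covalent context: with reference atoms (b, c) — b the atom's bonded
predecessor and c the predecessor of b — the axes are

    z = unit(a - b),  x = unit component of (c - b) orthogonal to z,
    y = z cross x.

The interaction between two framed atoms i, j is described by six scalars:
the distance d, the spherical direction (theta, phi) of each atom seen from
the other's frame (theta the azimuth in the frame's x-y plane measured from
x, phi the elevation toward z), and omega, the signed angle between the
projections of the two z-axes onto the plane perpendicular to the
inter-atomic axis.  All six are invariant under a global rigid motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import RESIDUE_HEAVY_ATOMS, Residue

__all__ = [
    "Frame",
    "PairGeometry",
    "GeometryError",
    "dihedral",
    "local_frame",
    "residue_frames",
    "pair_geometry",
    "FRAME_REFERENCES",
]


class GeometryError(ValueError):
    """Degenerate geometry: collinear points, coincident origins, etc."""


_EPS = 1e-10


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in (-pi, pi], IUPAC convention
    (positive clockwise looking from p2 towards p3)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise GeometryError("collinear points: dihedral undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    angle = float(np.arctan2(y, x))
    # map -pi to +pi so the range is (-pi, pi]
    return np.pi if angle <= -np.pi + 1e-15 else angle


@dataclass
class Frame:
    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    @property
    def axes(self) -> np.ndarray:
        return np.stack([self.x, self.y, self.z])


@dataclass
class PairGeometry:
    d: float
    theta_i: float
    phi_i: float
    theta_j: float
    phi_j: float
    omega: float  # nan when a z-axis is parallel to the inter-atomic axis

    @property
    def omega_defined(self) -> bool:
        return np.isfinite(self.omega)


def _frame_from_points(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> Frame:
    z = a - b
    nz = np.linalg.norm(z)
    if nz < _EPS:
        raise GeometryError("coincident frame atoms")
    z = z / nz
    v = c - b
    x = v - np.dot(v, z) * z
    nx = np.linalg.norm(x)
    if nx < _EPS:
        raise GeometryError("collinear frame atoms")
    x = x / nx
    y = np.cross(z, x)
    return Frame(origin=np.asarray(a, dtype=float), x=x, y=y, z=z)


def _build_frame_references() -> dict[tuple[str, str], tuple[str, str]]:
    """(residue, atom) -> (b, c) reference atoms, all within the residue.

    Side-chain atoms use their bonded parent and grandparent along the
    side-chain tree; backbone atoms use fixed in-residue triples.
    """
    backbone = {"N": ("CA", "C"), "CA": ("C", "O"), "C": ("CA", "N"),
                "O": ("C", "CA"), "CB": ("CA", "N")}
    side_parent = {
        # atom: (parent, grandparent); residue-specific entries override
        "SG": ("CB", "CA"), "OG": ("CB", "CA"), "OG1": ("CB", "CA"),
        "CG": ("CB", "CA"), "CG1": ("CB", "CA"), "CG2": ("CB", "CA"),
        "CD": ("CG", "CB"), "CD1": ("CG", "CB"), "CD2": ("CG", "CB"),
        "OD1": ("CG", "CB"), "OD2": ("CG", "CB"), "ND1": ("CG", "CB"),
        "ND2": ("CG", "CB"), "SD": ("CG", "CB"),
        "NE": ("CD", "CG"), "OE1": ("CD", "CG"), "OE2": ("CD", "CG"),
        "NE2": ("CD", "CG"), "NZ": ("CE", "CD"),
        "CE1": ("CD1", "CG"), "CE2": ("CD2", "CG"), "CE3": ("CD2", "CG"),
        "NE1": ("CD1", "CG"), "CZ2": ("CE2", "CD2"), "CZ3": ("CE3", "CD2"),
        "CH2": ("CZ2", "CE2"), "OH": ("CZ", "CE1"),
    }
    specific = {
        ("ILE", "CD1"): ("CG1", "CB"),
        ("MET", "CE"): ("SD", "CG"),
        ("LYS", "CE"): ("CD", "CG"),
        ("ARG", "CZ"): ("NE", "CD"),
        ("ARG", "NH1"): ("CZ", "NE"),
        ("ARG", "NH2"): ("CZ", "NE"),
        ("PHE", "CZ"): ("CE1", "CD1"),
        ("TYR", "CZ"): ("CE1", "CD1"),
        ("HIS", "CE1"): ("ND1", "CG"),
        ("HIS", "NE2"): ("CD2", "CG"),
    }
    refs: dict[tuple[str, str], tuple[str, str]] = {}
    for res, atoms in RESIDUE_HEAVY_ATOMS.items():
        for atom in atoms:
            if (res, atom) in specific:
                refs[(res, atom)] = specific[(res, atom)]
            elif atom in backbone:
                refs[(res, atom)] = backbone[atom]
            elif atom in side_parent:
                refs[(res, atom)] = side_parent[atom]
            else:  # pragma: no cover - table is complete by construction
                raise KeyError((res, atom))
    # Gly has no CB: its CA frame still uses (C, O)
    return refs


FRAME_REFERENCES = _build_frame_references()


def local_frame(residue: Residue, atom_name: str) -> Frame:
    """Local frame of one heavy atom, from its in-residue reference atoms.

    Raises GeometryError when a reference atom is missing or the three
    points are degenerate; callers skip the affected pairs.
    """
    b_name, c_name = FRAME_REFERENCES[(residue.residue_name, atom_name)]
    a = residue.coords(atom_name)
    b = residue.coords(b_name)
    c = residue.coords(c_name)
    if a is None or b is None or c is None:
        raise GeometryError(
            f"missing frame reference for {residue.residue_name} {atom_name}"
        )
    return _frame_from_points(a, b, c)


def residue_frames(residue: Residue) -> dict[str, Frame]:
    """Frames for every heavy atom of the residue that supports one."""
    frames: dict[str, Frame] = {}
    for name in residue.atoms:
        try:
            frames[name] = local_frame(residue, name)
        except GeometryError:
            continue
    return frames


def _spherical_in_frame(frame: Frame, point: np.ndarray, d: float):
    v = (point - frame.origin) / d
    theta = float(np.arctan2(np.dot(v, frame.y), np.dot(v, frame.x)))
    phi = float(np.arcsin(np.clip(np.dot(v, frame.z), -1.0, 1.0)))
    return theta, phi


def pair_geometry(frame_i: Frame, frame_j: Frame) -> PairGeometry:
    """Six-parameter relative geometry of two framed atoms."""
    v = frame_j.origin - frame_i.origin
    d = float(np.linalg.norm(v))
    if d < _EPS:
        raise GeometryError("coincident atom positions")
    theta_i, phi_i = _spherical_in_frame(frame_i, frame_j.origin, d)
    theta_j, phi_j = _spherical_in_frame(frame_j, frame_i.origin, d)
    u = v / d
    pi_ = frame_i.z - np.dot(frame_i.z, u) * u
    pj_ = frame_j.z - np.dot(frame_j.z, u) * u
    npi, npj = np.linalg.norm(pi_), np.linalg.norm(pj_)
    if npi < 1e-8 or npj < 1e-8:
        omega = float("nan")  # z-axis parallel to the inter-atomic axis
    else:
        omega = float(np.arctan2(np.dot(np.cross(pi_, pj_), u),
                                 np.dot(pi_, pj_)))
    return PairGeometry(d, theta_i, phi_i, theta_j, phi_j, omega)
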