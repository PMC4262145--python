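"""Synthetic idealized protein structures for training and evaluation tests.

Chains are built by sequential internal-to-Cartesian placement (NeRF) from a
fixed ideal-geometry table, with backbone (phi, psi, peptide omega) and
side-chain chi angles fully controllable; recomputing any chi from the built
coordinates recovers the requested value exactly (to numerical precision)
because chi-defining atoms are placed with that very dihedral.

Decoys are Gaussian coordinate perturbations of a native; their noise level
sigma serves as a quality surrogate mapped to (0, 1] by 1 / (1 + sigma).
Planted training sets position a second chain so that a designated atom
pair occurs at a controlled distance with the azimuth theta_i drawn tightly
around a rotamer-state-dependent mode, enabling parameter-recovery tests of
the rotamer-conditioned angular statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import local_frame
from .rotamers import CHI_ATOMS, RotamerScheme
from .structure import RESIDUE_HEAVY_ATOMS, Atom, Residue, StructureModel

__all__ = [
    "FixtureSpec",
    "build_chain",
    "helix",
    "make_decoys",
    "planted_training_set",
    "sigma_quality",
    "AA1TO3",
]

AA1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# Ideal covalent geometry (lengths in A, angles in degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
BOND_CA_CB = 1.53
ANGLE_C_CA_CB = 110.6
IMPROPER_N_C_CA_CB = -122.6  # fixes a consistent CA hand for all fixtures

# Side-chain z-matrix: atom, (a, b, c) placement references, bond length,
# bond angle at c, and the dihedral a-b-c-atom: ("chi", k, offset_deg) uses
# the residue's chi_k plus a branch offset, ("const", v) a fixed value.
_Z: dict[str, list[tuple]] = {
    "GLY": [], "ALA": [],
    "CYS": [("SG", ("N", "CA", "CB"), 1.81, 114.4, ("chi", 1, 0))],
    "SER": [("OG", ("N", "CA", "CB"), 1.42, 110.8, ("chi", 1, 0))],
    "THR": [("OG1", ("N", "CA", "CB"), 1.43, 109.6, ("chi", 1, 0)),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 120))],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 0)),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 120))],
    "PRO": [("CG", ("N", "CA", "CB"), 1.50, 104.5, ("chi", 1, 0)),
            ("CD", ("CA", "CB", "CG"), 1.51, 105.5, ("chi", 2, 0))],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.53, 110.4, ("chi", 1, 0)),
            ("CG2", ("N", "CA", "CB"), 1.53, 110.5, ("chi", 1, 120)),
            ("CD1", ("CA", "CB", "CG1"), 1.52, 113.8, ("chi", 2, 0))],
    "LEU": [("CG", ("N", "CA", "CB"), 1.53, 116.3, ("chi", 1, 0)),
            ("CD1", ("CA", "CB", "CG"), 1.52, 110.6, ("chi", 2, 0)),
            ("CD2", ("CA", "CB", "CG"), 1.52, 110.6, ("chi", 2, 120))],
    "ASP": [("CG", ("N", "CA", "CB"), 1.52, 112.6, ("chi", 1, 0)),
            ("OD1", ("CA", "CB", "CG"), 1.25, 118.4, ("chi", 2, 0)),
            ("OD2", ("CA", "CB", "CG"), 1.25, 118.4, ("chi", 2, 180))],
    "ASN": [("CG", ("N", "CA", "CB"), 1.52, 112.6, ("chi", 1, 0)),
            ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, ("chi", 2, 0)),
            ("ND2", ("CA", "CB", "CG"), 1.33, 116.4, ("chi", 2, 180))],
    "GLU": [("CG", ("N", "CA", "CB"), 1.53, 114.0, ("chi", 1, 0)),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0)),
            ("OE1", ("CB", "CG", "CD"), 1.25, 118.4, ("chi", 3, 0)),
            ("OE2", ("CB", "CG", "CD"), 1.25, 118.4, ("chi", 3, 180))],
    "GLN": [("CG", ("N", "CA", "CB"), 1.53, 114.0, ("chi", 1, 0)),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0)),
            ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, ("chi", 3, 0)),
            ("NE2", ("CB", "CG", "CD"), 1.33, 116.4, ("chi", 3, 180))],
    "MET": [("CG", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1, 0)),
            ("SD", ("CA", "CB", "CG"), 1.81, 112.7, ("chi", 2, 0)),
            ("CE", ("CB", "CG", "SD"), 1.79, 100.9, ("chi", 3, 0))],
    "LYS": [("CG", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1, 0)),
            ("CD", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0)),
            ("CE", ("CB", "CG", "CD"), 1.52, 111.3, ("chi", 3, 0)),
            ("NZ", ("CG", "CD", "CE"), 1.47, 111.9, ("chi", 4, 0))],
    "ARG": [("CG", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1, 0)),
            ("CD", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0)),
            ("NE", ("CB", "CG", "CD"), 1.46, 112.0, ("chi", 3, 0)),
            ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, ("chi", 4, 0)),
            ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, ("const", 0.0)),
            ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, ("const", 180.0))],
    "HIS": [("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0)),
            ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, ("chi", 2, 0)),
            ("CD2", ("CA", "CB", "CG"), 1.36, 129.7, ("chi", 2, 180)),
            ("CE1", ("CB", "CG", "ND1"), 1.32, 109.3, ("const", 180.0)),
            ("NE2", ("CB", "CG", "CD2"), 1.37, 107.2, ("const", 180.0))],
    "PHE": [("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0)),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.7, ("chi", 2, 0)),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.7, ("chi", 2, 180)),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 120.7, ("const", 180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 120.7, ("const", 180.0)),
            ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, ("const", 0.0))],
    "TYR": [("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0)),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.7, ("chi", 2, 0)),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.7, ("chi", 2, 180)),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 120.7, ("const", 180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 120.7, ("const", 180.0)),
            ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, ("const", 0.0)),
            ("OH", ("CD1", "CE1", "CZ"), 1.38, 120.0, ("const", 180.0))],
    "TRP": [("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0)),
            ("CD1", ("CA", "CB", "CG"), 1.37, 126.9, ("chi", 2, 0)),
            ("CD2", ("CA", "CB", "CG"), 1.43, 126.6, ("chi", 2, 180)),
            ("NE1", ("CB", "CG", "CD1"), 1.38, 110.2, ("const", 180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.41, 107.2, ("const", 180.0)),
            ("CE3", ("CB", "CG", "CD2"), 1.40, 133.9, ("const", 0.0)),
            ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.4, ("const", 180.0)),
            ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.6, ("const", 180.0)),
            ("CH2", ("CD2", "CE2", "CZ2"), 1.37, 117.5, ("const", 0.0))],
}

# Default chi values (degrees) when a fixture spec leaves them unset.
_DEFAULT_CHI = {"PRO": (25.0, -35.0)}


def _default_chis(resname: str) -> tuple[float, ...]:
    if resname in _DEFAULT_CHI:
        return _DEFAULT_CHI[resname]
    n = len(CHI_ATOMS[resname])
    return tuple(-60.0 if k == 0 else 180.0 for k in range(n))


def place(a, b, c, r: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: position d with |d-c| = r, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = dihedral (IUPAC sign)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = (-np.cos(theta) * bc
         + np.sin(theta) * (np.cos(chi) * m + np.sin(chi) * n))
    return c + r * d


@dataclass
class FixtureSpec:
    sequence: str
    phi: list[float] | float = -57.0
    psi: list[float] | float = -47.0
    omega_pep: list[float] | float = 180.0
    chi: dict[int, tuple[float, ...]] = field(default_factory=dict)
    chain_id: str = "A"
    identifier: str = "fixture"
    start_seq: int = 1

    def _per_residue(self, value) -> list[float]:
        n = len(self.sequence)
        return list(value) if isinstance(value, (list, tuple)) else [value] * n


def build_chain(spec: FixtureSpec) -> StructureModel:
    """Deterministic all-heavy-atom chain with the requested dihedrals."""
    n_res = len(spec.sequence)
    resnames = []
    for letter in spec.sequence:
        if letter not in AA1TO3:
            raise ValueError(f"invalid residue letter {letter!r}")
        resnames.append(AA1TO3[letter])
    phi = spec._per_residue(spec.phi)
    psi = spec._per_residue(spec.psi)
    omega = spec._per_residue(spec.omega_pep)

    backbone = []  # per residue dict N, CA, C
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    c0 = place((0.0, 1.0, 0.0), n0, ca0, BOND_CA_C, ANGLE_N_CA_C, 0.0)
    backbone.append({"N": n0, "CA": ca0, "C": c0})
    for k in range(1, n_res):
        prev = backbone[-1]
        n_next = place(prev["N"], prev["CA"], prev["C"],
                       BOND_C_N, ANGLE_CA_C_N, psi[k - 1])
        ca_next = place(prev["CA"], prev["C"], n_next,
                        BOND_N_CA, ANGLE_C_N_CA, omega[k - 1])
        c_next = place(prev["C"], n_next, ca_next,
                       BOND_CA_C, ANGLE_N_CA_C, phi[k])
        backbone.append({"N": n_next, "CA": ca_next, "C": c_next})

    model = StructureModel(spec.identifier)
    chain: list[Residue] = []
    for k, resname in enumerate(resnames):
        res = Residue(resname, spec.chain_id, spec.start_seq + k)
        coords = dict(backbone[k])
        coords["O"] = place(coords["N"], coords["CA"], coords["C"],
                            BOND_C_O, ANGLE_CA_C_O, psi[k] + 180.0)
        if resname != "GLY":
            coords["CB"] = place(coords["N"], coords["C"], coords["CA"],
                                 BOND_CA_CB, ANGLE_C_CA_CB, IMPROPER_N_C_CA_CB)
        chis = spec.chi.get(k, _default_chis(resname))
        for name, (ra, rb, rc), r, ang, dspec in _Z[resname]:
            if dspec[0] == "chi":
                _, idx, offset = dspec
                if idx - 1 >= len(chis):
                    raise ValueError(
                        f"residue {k} ({resname}) needs chi{idx}")
                dih = chis[idx - 1] + offset
            else:
                dih = dspec[1]
            coords[name] = place(coords[ra], coords[rb], coords[rc],
                                 r, ang, dih)
        for name in RESIDUE_HEAVY_ATOMS[resname]:
            res.atoms[name] = Atom(resname, name, coords[name])
        chain.append(res)
    model.chains[spec.chain_id] = chain
    return model


def helix(sequence: str, identifier: str = "helix",
          chi: dict[int, tuple[float, ...]] | None = None) -> StructureModel:
    """Canonical alpha-helix (phi = -57, psi = -47) fixture."""
    return build_chain(FixtureSpec(sequence, identifier=identifier,
                                   chi=chi or {}))


def sigma_quality(sigma: float) -> float:
    """Quality surrogate in (0, 1] for a decoy at noise level sigma (A)."""
    return 1.0 / (1.0 + sigma)


def make_decoys(model: StructureModel, n: int, sigma_levels, seed: int):
    """Gaussian coordinate-noise decoys: n per sigma level, seeded.

    Returns a list of (StructureModel, sigma) with identifiers
    '<native>_s<sigma>_<index>'.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    eye = np.eye(3)
    for sigma in sigma_levels:
        for i in range(n):
            decoy = model.transformed(eye, np.zeros(3))
            decoy.identifier = f"{model.identifier}_s{sigma:g}_{i}"
            for res in decoy.residues():
                for atom in res.atoms.values():
                    atom.position = atom.position + rng.normal(
                        0.0, sigma, size=3)
            out.append((decoy, float(sigma)))
    return out


def planted_training_set(
    residue_i: str = "SER",
    atom_i: str = "CB",
    residue_j: str = "GLY",
    atom_j: str = "N",
    modes: dict[str, float] | None = None,
    state_chis: dict[str, tuple[float, ...]] | None = None,
    n_structures: int = 200,
    seed: int = 0,
    distance: float = 5.25,  # a distance-bin center, so samples share a bin
    theta_noise: float = 0.05,
    scheme: RotamerScheme | None = None,
) -> list[StructureModel]:
    """Two-chain structures with a planted state-dependent angular mode.

    Chain A holds a single residue of type ``residue_i`` whose chi angles
    (``state_chis``, keyed by state symbol) set the rotameric state; chain B
    holds one ``residue_j``, rigidly positioned so that ``atom_j`` sits at
    distance ``distance`` from ``atom_i`` with azimuth theta_i distributed
    tightly (sd ``theta_noise`` rad) around ``modes[state]``; elevation and
    chain-B orientation are randomized.  Cross-chain pairs bypass the
    sequence-separation filter, so the accumulator accepts every structure.
    """
    if distance < 2.0:
        raise ValueError("pair distance must be >= 2 A (physically constructible)")
    modes = modes if modes is not None else {"g+": 1.0, "t": -1.0}
    state_chis = state_chis if state_chis is not None else {
        "g+": (60.0,), "g-": (-60.0,), "t": (180.0,)}
    missing = set(modes) - set(state_chis)
    if missing:
        raise ValueError(f"no chi angles given for states {sorted(missing)}")
    rng = np.random.default_rng(seed)
    symbols = sorted(modes)
    structures = []
    for s in range(n_structures):
        symbol = symbols[s % len(symbols)]
        spec_a = FixtureSpec(
            sequence=[k for k, v in AA1TO3.items() if v == residue_i][0],
            chi={0: state_chis[symbol]},
            chain_id="A", identifier=f"planted_{s}")
        model = build_chain(spec_a)
        res_a = model.chains["A"][0]
        frame = local_frame(res_a, atom_i)
        theta = modes[symbol] + rng.normal(0.0, theta_noise)
        elev = np.arcsin(rng.uniform(-0.95, 0.95))
        direction = (np.cos(elev) * np.cos(theta) * frame.x
                     + np.cos(elev) * np.sin(theta) * frame.y
                     + np.sin(elev) * frame.z)
        target = frame.origin + distance * direction

        spec_b = FixtureSpec(
            sequence=[k for k, v in AA1TO3.items() if v == residue_j][0],
            chain_id="B", identifier="partner")
        for _ in range(32):
            partner = build_chain(spec_b)
            rot = Rotation.random(rng=rng).as_matrix()
            res_b = partner.chains["B"][0]
            anchor = rot @ res_b.atoms[atom_j].position
            shift = target - anchor
            for atom in res_b.atoms.values():
                atom.position = rot @ atom.position + shift
            min_d = min(
                float(np.linalg.norm(pa.position - pb.position))
                for pa in res_a.atoms.values()
                for pb in res_b.atoms.values())
            if min_d >= 2.0:
                break
        else:
            raise ValueError("could not place partner without clashes")
        res_b.sequence_index = 1
        model.chains["B"] = [res_b]
        structures.append(model)
    return structures
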