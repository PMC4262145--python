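"""Side-chain dihedral angles and per-atom rotameric states.

Each residue's conformation is summarised by its chi angles; each heavy atom
is assigned a discrete rotameric state from the (at most two) chi angles
whose rotating bonds lie within three bond lengths of the atom.  sp3-sp3
dihedrals use the three staggered wells g+ [0, 120), g- [-120, 0) and
t (remaining third of the circle); non-rotameric terminal dihedrals (last
chi of Asn, Asp, Gln, Glu, His, Trp, Phe, Tyr) and proline's chi1 use two
sign regions.  The backbone oxygen is governed by {chi1, chi2} because its
contacts depend on the backbone psi / side-chain packing.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .geometry import GeometryError, dihedral
from .structure import RESIDUE_HEAVY_ATOMS, Residue, default_type_table

__all__ = [
    "SP3",
    "NONROT",
    "RotamerScheme",
    "RotamerState",
    "chi_angles",
    "classify_dihedral",
    "assign_state",
    "state_count",
    "default_scheme",
    "CHI_ATOMS",
]

SP3 = ("g+", "g-", "t")
NONROT = ("plus", "minus")

# Four-atom definitions of the side-chain dihedrals, per residue.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "CYS": [("N", "CA", "CB", "SG")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "GLY": [],
    "ALA": [],
}

# Chi numbers (1-based) whose alphabet is the two-region non-rotameric one.
_NONROT_CHIS: set[tuple[str, int]] = {
    ("ASP", 2), ("ASN", 2), ("GLU", 3), ("GLN", 3),
    ("HIS", 2), ("PHE", 2), ("TYR", 2), ("TRP", 2),
}

# Governing dihedrals per atom (chi numbers, ascending, at most two).
_SCHEME: dict[str, dict[str, tuple[int, ...]]] = {}


def _add(res: str, atoms: tuple[str, ...] | str, chis: tuple[int, ...]):
    group = _SCHEME.setdefault(res, {})
    for a in ([atoms] if isinstance(atoms, str) else atoms):
        group[a] = chis


_BB = ("C", "O", "N", "CA")
_add("GLY", _BB, ())
_add("ALA", _BB + ("CB",), ())
for _r in ("CYS", "SER", "THR", "VAL"):
    _add(_r, RESIDUE_HEAVY_ATOMS[_r], (1,))
_add("PRO", RESIDUE_HEAVY_ATOMS["PRO"], (1,))
for _r in ("ILE", "LEU", "ASP", "ASN"):
    _add(_r, RESIDUE_HEAVY_ATOMS[_r], (1, 2))
_add("GLU", _BB + ("CB", "CG"), (1, 2))
_add("GLU", ("CD", "OE1", "OE2"), (2, 3))
_add("GLN", _BB + ("CB",), (1, 2))
_add("GLN", ("CG", "CD", "OE1", "NE2"), (2, 3))
_add("MET", _BB + ("CB",), (1, 2))
_add("MET", ("CG", "SD", "CE"), (2, 3))
_add("ARG", _BB + ("CB",), (1, 2))
_add("ARG", "CG", (2, 3))
_add("ARG", ("CD", "NE", "CZ"), (3, 4))
_add("ARG", ("NH1", "NH2"), (4,))
_add("LYS", _BB + ("CB",), (1, 2))
_add("LYS", "CG", (2, 3))
_add("LYS", ("CD", "CE", "NZ"), (3, 4))
_add("HIS", _BB + ("CB", "CG", "ND1", "CD2"), (1, 2))
_add("HIS", ("CE1", "NE2"), (2,))
for _r in ("PHE", "TYR"):
    _add(_r, _BB + ("CB",), (1,))
    _add(_r, ("CG", "CD1", "CD2"), (1, 2))
_add("PHE", ("CE1", "CE2", "CZ"), (2,))
_add("TYR", ("CE1", "CE2", "CZ", "OH"), (2,))
_add("TRP", _BB + ("CB", "CG", "CD1", "CD2"), (1, 2))
_add("TRP", ("NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"), (2,))


@dataclass(frozen=True)
class RotamerState:
    residue_name: str
    state_index: int
    defined: bool


class RotamerScheme:
    """Per-atom governing dihedrals and state alphabets.

    Parameters
    ----------
    pro_three_state:
        Proline chi1 is split into two sign regions by default; setting this
        flag uses the three staggered sp3 wells instead (both conventions are
        supported because the two sources of the scheme disagree).
    """

    def __init__(self, pro_three_state: bool = False):
        self.pro_three_state = pro_three_state
        self.entries = {
            (res, atom): chis
            for res, atoms in _SCHEME.items()
            for atom, chis in atoms.items()
        }
        table = default_type_table()
        missing = set(table.entries) - set(self.entries)
        if missing:  # pragma: no cover - construction-time audit
            raise AssertionError(f"scheme does not cover {sorted(missing)[:5]}")

    def alphabet(self, residue_name: str, chi: int) -> tuple[str, ...]:
        if residue_name == "PRO" and chi == 1:
            return SP3 if self.pro_three_state else NONROT
        if (residue_name, chi) in _NONROT_CHIS:
            return NONROT
        return SP3

    def dihedrals_for(self, residue_name: str, atom_name: str) -> tuple[int, ...]:
        try:
            return self.entries[(residue_name, atom_name)]
        except KeyError:
            raise KeyError(
                f"no rotamer scheme entry for ({residue_name!r}, {atom_name!r})"
            ) from None

    def state_count(self, residue_name: str, atom_name: str) -> int:
        n = 1
        for chi in self.dihedrals_for(residue_name, atom_name):
            n *= len(self.alphabet(residue_name, chi))
        return n

    def max_states(self) -> int:
        return max(self.state_count(r, a) for r, a in self.entries)


_DEFAULT_SCHEME = RotamerScheme()


def default_scheme() -> RotamerScheme:
    return _DEFAULT_SCHEME


def load_scheme_file(pro_three_state: bool = False) -> RotamerScheme:
    """Load and validate the shipped human-readable scheme table.

    The TSV mirrors the built-in scheme (residue, atom, dihedrals, states);
    a mismatch between file and code raises, guarding against edits that
    would silently change the trained tables.  The printed state count for
    Pro follows the three-state variant, as in the published table.
    """
    scheme = RotamerScheme(pro_three_state=pro_three_state)
    printed = RotamerScheme(pro_three_state=True)
    text = resources.files("rotas.data").joinpath("rotamer_scheme.tsv").read_text()
    seen = set()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        res, atom, dihedrals, n_states = line.split("\t")
        chis = () if dihedrals == "-" else tuple(
            int(tok[3:]) for tok in dihedrals.split(",")
        )
        if scheme.dihedrals_for(res, atom) != chis:
            raise ValueError(f"scheme file mismatch for ({res}, {atom})")
        if printed.state_count(res, atom) != int(n_states):
            raise ValueError(f"state count mismatch for ({res}, {atom})")
        seen.add((res, atom))
    if seen != set(scheme.entries):
        raise ValueError("scheme file does not cover all 167 atom types")
    return scheme


def chi_angles(residue: Residue) -> list[float | None]:
    """Chi angles in degrees, one entry per defined chi of the residue type;
    None where a defining atom is missing or the geometry is degenerate."""
    angles: list[float | None] = []
    for quad in CHI_ATOMS[residue.residue_name]:
        coords = [residue.coords(name) for name in quad]
        if any(c is None for c in coords):
            angles.append(None)
            continue
        try:
            angles.append(float(np.degrees(dihedral(*coords))))
        except GeometryError:
            angles.append(None)
    return angles


def classify_dihedral(angle_deg: float | None, alphabet: tuple[str, ...]) -> str | None:
    """Map a dihedral in degrees, range (-180, 180], to its state symbol.

    sp3 wells are half-open on the right: g+ = [0, 120), g- = [-120, 0),
    t = [120, 180] plus (-180, -120); the two-region alphabets split on the
    angle's sign with 0 assigned to the positive region.
    """
    if angle_deg is None:
        return None
    a = float(angle_deg)
    if alphabet is SP3 or alphabet == SP3:
        if 0.0 <= a < 120.0:
            return "g+"
        if -120.0 <= a < 0.0:
            return "g-"
        return "t"
    return "plus" if a >= 0.0 else "minus"


def assign_state(
    residue: Residue,
    atom_name: str,
    scheme: RotamerScheme | None = None,
    chis: list[float | None] | None = None,
) -> RotamerState:
    """Rotameric state of one heavy atom, mixed-radix over its governing
    dihedrals in chi order.  Undefined chi angles yield defined=False."""
    scheme = scheme or _DEFAULT_SCHEME
    chi_numbers = scheme.dihedrals_for(residue.residue_name, atom_name)
    if not chi_numbers:
        return RotamerState(residue.residue_name, 0, True)
    if chis is None:
        chis = chi_angles(residue)
    index = 0
    for chi in chi_numbers:
        alphabet = scheme.alphabet(residue.residue_name, chi)
        angle = chis[chi - 1] if chi - 1 < len(chis) else None
        symbol = classify_dihedral(angle, alphabet)
        if symbol is None:
            return RotamerState(residue.residue_name, -1, False)
        index = index * len(alphabet) + alphabet.index(symbol)
    return RotamerState(residue.residue_name, index, True)


def state_count(residue_name: str, atom_name: str,
                scheme: RotamerScheme | None = None) -> int:
    return (scheme or _DEFAULT_SCHEME).state_count(residue_name, atom_name)
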