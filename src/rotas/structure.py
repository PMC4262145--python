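"""Heavy-atom protein structure model and residue-specific atom typing.

Reads PDB files into a lightweight validated model holding only the heavy
atoms of the 20 standard amino acids, and assigns each atom one of the 167
residue-specific heavy-atom types used by the potential.  Alternate
locations are resolved deterministically (highest occupancy, then lowest
B-factor, then altloc code), matching the convention used when the training
statistics are collected.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "AtomTypeTable",
    "AtomTypingError",
    "EmptyStructureError",
    "RESIDUE_HEAVY_ATOMS",
    "STANDARD_RESIDUES",
    "read_pdb",
    "write_pdb",
    "resolve_altlocs",
    "atom_type_of",
    "completeness_report",
    "default_type_table",
]

# Heavy atoms per standard residue, in a fixed canonical order (backbone
# first, then side chain outward).  The enumeration of the 167 atom types is
# derived from this table and is stable across releases.
RESIDUE_HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    "GLY": ("N", "CA", "C", "O"),
    "ALA": ("N", "CA", "C", "O", "CB"),
    "CYS": ("N", "CA", "C", "O", "CB", "SG"),
    "SER": ("N", "CA", "C", "O", "CB", "OG"),
    "THR": ("N", "CA", "C", "O", "CB", "OG1", "CG2"),
    "PRO": ("N", "CA", "C", "O", "CB", "CG", "CD"),
    "VAL": ("N", "CA", "C", "O", "CB", "CG1", "CG2"),
    "ILE": ("N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"),
    "LEU": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"),
    "ASP": ("N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"),
    "ASN": ("N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"),
    "GLU": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"),
    "GLN": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"),
    "MET": ("N", "CA", "C", "O", "CB", "CG", "SD", "CE"),
    "LYS": ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"),
    "ARG": ("N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "HIS": ("N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "PHE": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "TRP": (
        "N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3",
        "CZ2", "CZ3", "CH2",
    ),
}

STANDARD_RESIDUES = tuple(sorted(RESIDUE_HEAVY_ATOMS))

# Maximum peptide-bond C–N distance; larger gaps mark a chain break and the
# sequence separation across a break is treated as infinite downstream.
PEPTIDE_BOND_MAX = 2.5


class AtomTypingError(KeyError):
    """Raised for a (residue, atom) pair outside the 167-type table."""


class EmptyStructureError(ValueError):
    """Raised when a PDB file contains no standard protein residues."""


@dataclass
class Atom:
    residue_name: str
    atom_name: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = " "

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"invalid position for {self.atom_name}")


@dataclass
class Residue:
    residue_name: str
    chain_id: str
    sequence_index: int
    insertion_code: str = " "
    atoms: dict[str, Atom] = field(default_factory=dict)

    def get(self, atom_name: str) -> Atom | None:
        return self.atoms.get(atom_name)

    def coords(self, atom_name: str) -> np.ndarray | None:
        a = self.atoms.get(atom_name)
        return None if a is None else a.position


@dataclass
class StructureModel:
    identifier: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def residues(self):
        for chain in self.chains.values():
            yield from chain

    def atoms(self):
        for res in self.residues():
            for atom in res.atoms.values():
                yield res, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy under the rigid motion x -> R x + t."""
        out = StructureModel(self.identifier)
        for cid, chain in self.chains.items():
            new_chain = []
            for res in chain:
                nr = Residue(res.residue_name, res.chain_id, res.sequence_index,
                             res.insertion_code)
                for name, a in res.atoms.items():
                    nr.atoms[name] = Atom(a.residue_name, name,
                                          rotation @ a.position + translation,
                                          a.occupancy, a.b_factor, a.altloc)
                new_chain.append(nr)
            out.chains[cid] = new_chain
        return out


class AtomTypeTable:
    """Stable enumeration of the 167 residue-specific heavy-atom types.

    Types are numbered residue-by-residue in alphabetical residue order and,
    within a residue, in the canonical atom order of RESIDUE_HEAVY_ATOMS.
    """

    def __init__(self) -> None:
        self.entries: dict[tuple[str, str], int] = {}
        idx = 0
        for res in STANDARD_RESIDUES:
            for atom in RESIDUE_HEAVY_ATOMS[res]:
                self.entries[(res, atom)] = idx
                idx += 1
        self.n_types = idx

    def type_of(self, residue_name: str, atom_name: str) -> int:
        try:
            return self.entries[(residue_name, atom_name)]
        except KeyError:
            raise AtomTypingError(
                f"no atom type for ({residue_name!r}, {atom_name!r})"
            ) from None

    def checksum(self) -> str:
        payload = ";".join(
            f"{r},{a},{i}" for (r, a), i in sorted(self.entries.items())
        )
        return hashlib.sha256(payload.encode()).hexdigest()


_TYPE_TABLE = AtomTypeTable()


def default_type_table() -> AtomTypeTable:
    return _TYPE_TABLE


def atom_type_of(residue_name: str, atom_name: str) -> int:
    """Type index in [0, 166] for a standard residue's heavy atom."""
    return _TYPE_TABLE.type_of(residue_name, atom_name)


def _pick(candidates: list[Atom]) -> Atom:
    return min(candidates, key=lambda a: (-a.occupancy, a.b_factor, a.altloc))


def resolve_altlocs(residue):
    """Keep one atom per name: highest occupancy, then lowest B, then altloc.

    Accepts either a Residue (whose atoms are already unique by name, so the
    call is an identity — the operation is idempotent) or an iterable of raw
    Atom records possibly sharing atom names, in which case the resolved
    mapping name -> Atom is returned.
    """
    if isinstance(residue, Residue):
        resolved = resolve_altlocs(residue.atoms.values())
        out = Residue(residue.residue_name, residue.chain_id,
                      residue.sequence_index, residue.insertion_code)
        out.atoms = resolved
        return out
    by_name: dict[str, list[Atom]] = {}
    for atom in residue:
        by_name.setdefault(atom.atom_name, []).append(atom)
    return {name: _pick(cands) for name, cands in by_name.items()}


def _iter_atom_records(bio_residue):
    for atom in bio_residue.get_atoms():
        if isinstance(atom, DisorderedAtom):
            yield from atom.disordered_get_list()
        else:
            yield atom


def read_pdb(path: str | Path, identifier: str | None = None) -> StructureModel:
    """Parse a PDB file into a heavy-atom StructureModel.

    Only the first MODEL is read; hydrogens, waters, hetero groups and
    nonstandard residues are dropped (nonstandard residues with a warning).
    Alternate locations are resolved by occupancy / B-factor / altloc code.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(identifier or path.stem, str(path))
    try:
        bio_model = next(structure.get_models())
    except StopIteration:
        raise EmptyStructureError(f"{path}: no MODEL in file")

    model = StructureModel(identifier or path.stem)
    for bio_chain in bio_model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, seq, icode = bio_res.id
            if hetflag != " ":
                continue
            resname = bio_res.get_resname().strip()
            if resname not in RESIDUE_HEAVY_ATOMS:
                warnings.warn(
                    f"{model.identifier}: dropping nonstandard residue "
                    f"{resname} {bio_chain.id}{seq}"
                )
                continue
            res = Residue(resname, bio_chain.id, seq, icode or " ")
            by_name: dict[str, list[Atom]] = {}
            for rec in _iter_atom_records(bio_res):
                element = (rec.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                name = rec.get_name().strip()
                if name == "OXT" or (resname, name) not in _TYPE_TABLE.entries:
                    # terminal variants / unexpected names are not typed
                    continue
                by_name.setdefault(name, []).append(
                    Atom(resname, name, np.array(rec.get_coord(), dtype=float),
                         float(rec.get_occupancy() or 0.0),
                         float(rec.get_bfactor() or 0.0),
                         rec.get_altloc() or " ")
                )
            res.atoms = resolve_altlocs(
                a for cands in by_name.values() for a in cands
            )
            if res.atoms:
                residues.append(res)
        if residues:
            residues.sort(key=lambda r: (r.sequence_index, r.insertion_code))
            model.chains[bio_chain.id] = residues
    if not model.chains:
        raise EmptyStructureError(f"{path}: no standard protein residues")
    return model


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write standard-conforming ATOM records (fixture support)."""
    lines = []
    serial = 1
    for cid, chain in model.chains.items():
        for res in chain:
            for name in RESIDUE_HEAVY_ATOMS[res.residue_name]:
                atom = res.atoms.get(name)
                if atom is None:
                    continue
                x, y, z = atom.position
                el = name[0] if name[0] in "CNOS" else name[1]
                pdb_name = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d} {pdb_name}{atom.altloc}{res.residue_name:>3s} "
                    f"{cid}{res.sequence_index:4d}{res.insertion_code}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
                    f"{atom.b_factor:6.2f}          {el:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def completeness_report(model: StructureModel) -> list[tuple[str, int, str, str]]:
    """List heavy atoms expected by the type table but absent from the model.

    Returns tuples (chain_id, sequence_index, residue_name, atom_name).
    """
    missing = []
    for res in model.residues():
        for name in RESIDUE_HEAVY_ATOMS[res.residue_name]:
            if name not in res.atoms:
                missing.append((res.chain_id, res.sequence_index,
                                res.residue_name, name))
    return missing


def chain_segments(chain: list[Residue]) -> list[list[int]]:
    """Indices of contiguous segments; a numbering gap or a C–N distance
    above PEPTIDE_BOND_MAX starts a new segment."""
    segments: list[list[int]] = []
    current = [0] if chain else []
    for k in range(1, len(chain)):
        prev, cur = chain[k - 1], chain[k]
        gap = cur.sequence_index - prev.sequence_index
        broken = gap > 1 or gap < 0
        if not broken:
            c = prev.coords("C")
            n = cur.coords("N")
            if c is not None and n is not None:
                broken = float(np.linalg.norm(n - c)) > PEPTIDE_BOND_MAX
        if broken:
            segments.append(current)
            current = [k]
        else:
            current.append(k)
    if current:
        segments.append(current)
    return segments


def sequence_separation(model: StructureModel) -> dict[int, tuple[str, int, int]]:
    """Map residue ordinal (enumeration order of model.residues()) to
    (chain_id, segment_id, position) for separation tests.

    Two residues are separated by |pos_a - pos_b| when they share a chain and
    segment, and infinitely otherwise.
    """
    info: dict[int, tuple[str, int, int]] = {}
    ordinal = 0
    seg_counter = 0
    for cid, chain in model.chains.items():
        index_of = {}
        for k, res in enumerate(chain):
            index_of[k] = ordinal
            ordinal += 1
        for seg in chain_segments(chain):
            for pos, k in enumerate(seg):
                info[index_of[k]] = (cid, seg_counter, pos)
            seg_counter += 1
    return info
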