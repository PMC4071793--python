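"""Hierarchical protein-structure model and PDB-format I/O.

The model keeps author residue numbering (the numbering printed in PDB
columns 23-26) as the only public numbering, because functional-site
literature refers to residues by those numbers (e.g. Glu272).  Alternate
locations are collapsed on reading; hydrogens are kept in the model but
excluded from surface/cavity atom selections elsewhere.

Crystal-content arithmetic (Matthews coefficient and solvent fraction)
lives here because it only needs the unit cell parsed from CRYST1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "CrystalCell",
    "read_structure",
    "write_structure",
    "extract_sequence",
    "matthews_solvent",
    "solvent_fraction_from_vm",
    "PDBParseError",
]

#: Matthews' reciprocal partial-specific-volume constant (A^3/Da): the
#: protein volume per Dalton assumed when converting Vm to solvent fraction.
MATTHEWS_PROTEIN_CONSTANT = 1.23

# 3-letter -> 1-letter for the standard amino acids plus common modified
# residues that substitute for a standard one in the polymer.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine models as Met
    "SEC": "U", "PYL": "O",
}

STANDARD_AA = frozenset(k for k in THREE_TO_ONE if k not in ("SEC", "PYL"))


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be interpreted."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")


@dataclass
class Residue:
    name: str
    number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    kind: str = "polymer"  # polymer | hetero | water

    def __post_init__(self) -> None:
        if self.name == "HOH":
            self.kind = "water"
        elif self.kind == "water" and self.name != "HOH":
            raise ValueError("kind='water' requires residue name HOH")

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atoms(self, names: list[str]) -> bool:
        return all(self.atom(n) is not None for n in names)


@dataclass
class CrystalCell:
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    spacegroup: str = "P 1"
    z: int = 1  # polymer copies per unit cell (CRYST1 Z value)

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edges must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must lie in (0, 180) degrees")

    @property
    def volume(self) -> float:
        """Triclinic cell volume in A^3."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return (self.a * self.b * self.c
                * math.sqrt(max(0.0, 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg)))


class Structure:
    """Chains of residues in file order, with an optional crystal cell."""

    def __init__(self, id: str = "", cell: CrystalCell | None = None):
        self.id = id
        self.cell = cell
        self.chains: dict[str, list[Residue]] = {}

    def add_residue(self, chain_id: str, residue: Residue) -> None:
        residues = self.chains.setdefault(chain_id, [])
        if any(r.key == residue.key for r in residues):
            raise ValueError(
                f"duplicate residue {residue.number}{residue.icode} in chain {chain_id!r}")
        residues.append(residue)

    def residues(self, chain: str | None = None, kind: str | None = None) -> Iterator[Residue]:
        chains = [chain] if chain is not None else list(self.chains)
        for cid in chains:
            for res in self.chains[cid]:
                if kind is None or res.kind == kind:
                    yield res

    def get_residue(self, chain: str, number: int, icode: str = "") -> Residue:
        for res in self.chains[chain]:
            if res.number == number and res.icode == icode:
                return res
        raise KeyError(f"residue {number}{icode} not in chain {chain!r}")

    def atom_records(self, chain: str | None = None,
                     include_hydrogens: bool = True,
                     kinds: tuple[str, ...] = ("polymer", "hetero", "water"),
                     ) -> list[tuple[str, Residue, Atom]]:
        """Flat (chain_id, residue, atom) list in file order."""
        out = []
        chains = [chain] if chain is not None else list(self.chains)
        for cid in chains:
            for res in self.chains[cid]:
                if res.kind not in kinds:
                    continue
                for atom in res.atoms:
                    if not include_hydrogens and atom.element in ("H", "D"):
                        continue
                    out.append((cid, res, atom))
        return out

    def coords(self, **kwargs) -> np.ndarray:
        recs = self.atom_records(**kwargs)
        if not recs:
            return np.empty((0, 3))
        return np.array([a.coords for _, _, a in recs])

    def n_residues(self, kind: str | None = None) -> int:
        return sum(1 for _ in self.residues(kind=kind))


# ---------------------------------------------------------------------------
# Reading


def _classify(res_name: str, het_flag: bool) -> str:
    if res_name == "HOH":
        return "water"
    if het_flag and res_name not in STANDARD_AA:
        return "hetero"
    return "polymer"


def _collapse_altlocs(atoms: list[Atom], policy: str) -> list[Atom]:
    """Keep one atom per name.  'highest-occupancy' keeps the altloc with the
    greatest occupancy (ties -> first in file); 'first' keeps the first seen."""
    kept: dict[str, Atom] = {}
    for atom in atoms:
        prev = kept.get(atom.name)
        if prev is None:
            kept[atom.name] = atom
        elif policy == "highest-occupancy" and atom.occupancy > prev.occupancy:
            kept[atom.name] = atom
    return list(kept.values())


def read_structure(source: str | Path, altloc_policy: str = "highest-occupancy",
                   model_index: int = 0) -> Structure:
    """Parse PDB-format text (or a file path) into a :class:`Structure`.

    All ATOM/HETATM records of the selected model are represented; alternate
    locations are collapsed per *altloc_policy*; CRYST1 becomes the crystal
    cell when present.
    """
    if altloc_policy not in ("highest-occupancy", "first"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).is_file()):
        text = Path(source).read_text()
        struct_id = Path(source).stem
    else:
        text = str(source)
        struct_id = ""
    _validate_pdb_lines(text)
    try:
        gst = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(str(exc)) from exc
    if len(gst) == 0:
        raise PDBParseError("no coordinate records found")
    if model_index >= len(gst):
        raise PDBParseError(
            f"model index {model_index} out of range ({len(gst)} models present)")

    cell = None
    gc = gst.cell
    if gc.a > 1.0 and not (gc.a == gc.b == gc.c == 1.0):
        cell = CrystalCell(gc.a, gc.b, gc.c, gc.alpha, gc.beta, gc.gamma,
                           spacegroup=gst.spacegroup_hm or "P 1",
                           z=_cryst1_z(text, gst))
    struct = Structure(id=gst.name or struct_id, cell=cell)
    model = gst[model_index]
    for chain in model:
        for gres in chain:
            raw = [Atom(name=ga.name,
                        element=ga.element.name.upper() or _infer_element(ga.name),
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        altloc=(ga.altloc or "").strip("\x00"),
                        bfactor=ga.b_iso)
                   for ga in gres]
            res = Residue(name=gres.name.strip(),
                          number=gres.seqid.num,
                          icode=(gres.seqid.icode or "").strip(),
                          atoms=_collapse_altlocs(raw, altloc_policy),
                          kind=_classify(gres.name.strip(), gres.het_flag == "H"))
            struct.add_residue(chain.name, res)
    return struct


def _validate_pdb_lines(text: str) -> None:
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise PDBParseError(f"line {i}: coordinate record truncated")
            try:
                int(line[22:26])
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError as exc:
                raise PDBParseError(f"line {i}: malformed fixed-column field") from exc


def _cryst1_z(text: str, gst: "gemmi.Structure") -> int:
    for line in text.splitlines():
        if line.startswith("CRYST1") and len(line) >= 70:
            try:
                return int(line[66:70])
            except ValueError:
                break
    sg = gemmi.find_spacegroup_by_name(gst.spacegroup_hm or "P 1")
    return len(sg.operations()) if sg else 1


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if stripped[:2] in ("FE", "ZN", "MG", "MN", "CA", "NA", "CL", "SE"):
        return stripped[:2]
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


# ---------------------------------------------------------------------------
# Writing


def write_structure(structure: Structure,
                    bfactor_override: dict[tuple[str, int, str], float] | None = None,
                    ) -> str:
    """Serialise to PDB-format text.

    *bfactor_override* maps (chain, resnum, icode) to a value written into the
    B-factor column for every atom of that residue — used to colour structures
    by per-residue scores in molecular viewers.
    """
    lines: list[str] = []
    if structure.cell is not None:
        c = structure.cell
        lines.append(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} {c.spacegroup:<11s}{c.z:4d}")
    serial = 1
    for cid, residues in structure.chains.items():
        for res in residues:
            if not -999 <= res.number <= 9999:
                raise ValueError(
                    f"residue number {res.number} does not fit PDB columns")
            record = "ATOM  " if res.kind == "polymer" else "HETATM"
            for atom in res.atoms:
                b = atom.bfactor
                if bfactor_override is not None:
                    b = bfactor_override.get((cid, res.number, res.icode), b)
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                x, y, z = atom.coords
                lines.append(
                    f"{record}{serial % 100000:5d} {name}{atom.altloc or ' '}"
                    f"{res.name:>3s} {cid[:1] or 'A'}{res.number:4d}{res.icode or ' '}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{b:6.2f}"
                    f"          {atom.element:>2s}")
                serial += 1
        lines.append(f"TER   {serial % 100000:5d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Sequence extraction and crystal content


def extract_sequence(structure: Structure, chain: str) -> tuple[str, list[int]]:
    """One-letter sequence of a chain's polymer residues, with the parallel
    list of author residue numbers (gaps in numbering are preserved)."""
    if chain not in structure.chains:
        raise KeyError(f"chain {chain!r} not present")
    seq, numbers = [], []
    for res in structure.chains[chain]:
        if res.kind != "polymer":
            continue
        seq.append(THREE_TO_ONE.get(res.name, "X"))
        numbers.append(res.number)
    return "".join(seq), numbers


def solvent_fraction_from_vm(vm: float) -> float:
    """Solvent fraction 1 - 1.23/Vm of a crystal with Matthews coefficient
    *vm* (A^3/Da), clipped at 0."""
    if vm <= 0:
        raise ValueError("Vm must be positive")
    frac = 1.0 - MATTHEWS_PROTEIN_CONSTANT / vm
    if frac < 0:
        warnings.warn(f"Vm={vm:.2f} <= {MATTHEWS_PROTEIN_CONSTANT}: solvent fraction clipped to 0")
        return 0.0
    return frac


def matthews_solvent(cell: CrystalCell, molecular_weight: float,
                     n_mol_per_asu: int = 1) -> tuple[float, float]:
    """Matthews coefficient Vm = V_cell / (Z * n_mol * MW) and the derived
    solvent fraction, for *n_mol_per_asu* copies of a molecule of
    *molecular_weight* Daltons per asymmetric unit."""
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    if n_mol_per_asu < 1:
        raise ValueError("n_mol_per_asu must be >= 1")
    z_total = cell.z * n_mol_per_asu
    vm = cell.volume / (z_total * molecular_weight)
    return vm, solvent_fraction_from_vm(vm)
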