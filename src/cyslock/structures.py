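"""Protein structures, cysteine anchors and binding-pocket extraction.

The docking side of the package works on a *pocket*: the set of protein
atoms within a cutoff radius of the Sγ (thiol sulfur) of a designated
cysteine, each atom carrying a partial charge and Lennard-Jones
parameters.  Structures are read from PDB text; multi-model files double
as trajectory containers (see :mod:`cyslock.pocketmap`).

Parsing is deliberately strict and desk-scale: altloc ``A``/blank is
kept and other altlocs dropped, insertion codes are rejected, and every
coordinate parse failure reports its line number.  The packaged default
parameter table is a united-atom-style set (heavy atoms only), so
absolute energies are not comparable to programs that use an all-atom
charge model; rankings within one run are.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "ProteinStructure",
    "CysteineAnchor",
    "Pocket",
    "PDBParseError",
    "StructureError",
    "AnchorError",
    "ParameterizationError",
    "read_structure",
    "write_structure",
    "find_anchor",
    "extract_pocket",
    "parameterize",
    "load_parameter_table",
    "default_parameter_table",
]

DEFAULT_POCKET_RADIUS = 10.0  # Angstrom around the anchor S-gamma

_RECOGNIZED_ELEMENTS = frozenset(
    "H HE LI BE B C N O F NE NA MG AL SI P S CL AR K CA MN FE CO NI CU ZN SE BR I".split()
)


class PDBParseError(ValueError):
    """Malformed PDB record (message names the offending line)."""


class StructureError(ValueError):
    """Internally inconsistent structure (e.g. ragged models)."""


class AnchorError(ValueError):
    """The requested anchor residue is not a cysteine with an SG atom."""


class ParameterizationError(KeyError):
    """One or more (residue, atom) pairs missing from the parameter table."""

    def __init__(self, misses: Sequence[tuple[str, str]]):
        self.misses = list(misses)
        listing = ", ".join(f"{r}/{a}" for r, a in self.misses)
        super().__init__(f"no parameters for: {listing}")

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]


@dataclass
class AtomRecord:
    """One atom of a protein structure.

    ``partial_charge`` (e), ``lj_sigma`` (A) and ``lj_epsilon``
    (kcal/mol) stay ``None`` until :func:`parameterize` fills them.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    xyz: np.ndarray
    partial_charge: float | None = None
    lj_sigma: float | None = None
    lj_epsilon: float | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.serial}: xyz must be a finite 3-vector")
        if self.element.upper() not in _RECOGNIZED_ELEMENTS:
            raise ValueError(f"atom {self.serial}: unrecognized element {self.element!r}")
        if self.lj_sigma is not None and self.lj_sigma <= 0:
            raise ValueError("lj_sigma must be positive")
        if self.lj_epsilon is not None and self.lj_epsilon < 0:
            raise ValueError("lj_epsilon must be non-negative")

    @property
    def parameterized(self) -> bool:
        return self.partial_charge is not None and self.lj_sigma is not None


@dataclass
class ProteinStructure:
    """Parsed structure: one atom list per MODEL block (>= 1)."""

    models: list[list[AtomRecord]]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.models or not self.models[0]:
            raise StructureError("structure has no atoms")
        n0 = len(self.models[0])
        for i, m in enumerate(self.models):
            if len(m) != n0:
                raise StructureError(
                    f"model {i + 1} has {len(m)} atoms, model 1 has {n0}"
                )
        key0 = [(a.chain_id, a.residue_number, a.name) for a in self.models[0]]
        for i, m in enumerate(self.models[1:], start=2):
            if [(a.chain_id, a.residue_number, a.name) for a in m] != key0:
                raise StructureError(f"model {i} atom ordering differs from model 1")

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def atoms(self) -> list[AtomRecord]:
        """Atoms of the first model."""
        return self.models[0]

    def coords(self, model: int = 0) -> np.ndarray:
        return np.array([a.xyz for a in self.models[model]])


@dataclass(frozen=True)
class CysteineAnchor:
    """The covalent attachment site: a cysteine Sγ."""

    chain_id: str
    residue_number: int
    sg_index: int


@dataclass
class Pocket:
    """Parameterized atom subset within ``radius`` of the anchor Sγ."""

    atoms: list[AtomRecord]
    anchor: CysteineAnchor
    radius: float
    sg_index: int = 0  # index of S-gamma within `atoms`
    cb_index: int | None = None  # index of the anchor residue's CB, if present

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    @property
    def total_charge(self) -> float:
        return float(sum(a.partial_charge for a in self.atoms))

    @property
    def sg_xyz(self) -> np.ndarray:
        return self.atoms[self.sg_index].xyz

    @property
    def parameterized(self) -> bool:
        return all(a.parameterized for a in self.atoms)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: ATOM record shorter than 54 columns")
    altloc = line[16]
    if altloc not in (" ", "A"):
        return None  # type: ignore[return-value]  # caller drops
    icode = line[26]
    if icode != " ":
        raise PDBParseError(
            f"line {lineno}: insertion code {icode!r} not supported"
        )
    try:
        serial = int(line[6:11])
        resnum = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad serial/residue number: {exc}") from None
    coords = []
    for lo, hi, label in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
        token = line[lo:hi].strip()
        try:
            coords.append(float(token))
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: malformed {label} coordinate {token!r}"
            ) from None
    name = line[12:16].strip()
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back on the first alphabetic character of the atom name
        element = next((c for c in name if c.isalpha()), "")
    return AtomRecord(
        serial=serial,
        name=name,
        element=element.upper(),
        residue_name=line[17:20].strip(),
        chain_id=line[21],
        residue_number=resnum,
        xyz=np.array(coords),
    )


def read_structure(pdb_text: str, source_id: str = "") -> ProteinStructure:
    """Parse PDB text into a :class:`ProteinStructure`.

    One model per ``MODEL`` block; a file without MODEL records is a
    single model.  Atom order is preserved; coordinates are read at the
    PDB's native 0.001 A precision.
    """
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            current = []
        elif rec == "ENDMDL":
            models.append(current)
            current = []
        elif rec in ("ATOM", "HETATM"):
            atom = _parse_atom_line(line, lineno)
            if atom is not None:
                current.append(atom)
    if current:
        models.append(current)
    if not models or all(not m for m in models):
        raise PDBParseError("no ATOM/HETATM records found")
    models = [m for m in models if m]
    return ProteinStructure(models=models, source_id=source_id)


def write_structure(structure: ProteinStructure) -> str:
    """Render a structure back to PDB text (multi-model if needed)."""
    lines: list[str] = []
    multi = structure.n_models > 1
    for i, model in enumerate(structure.models, start=1):
        if multi:
            lines.append(f"MODEL     {i:>4d}")
        for a in model:
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {a.serial:>5d} {name}{'':1s}{a.residue_name:>3s} "
                f"{a.chain_id}{a.residue_number:>4d}    "
                f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Anchor and pocket
# ---------------------------------------------------------------------------

def find_anchor(
    structure: ProteinStructure, chain_id: str, residue_number: int
) -> CysteineAnchor:
    """Locate the Sγ of the cysteine at ``chain_id:residue_number``."""
    atoms = structure.atoms
    residue = [
        (i, a)
        for i, a in enumerate(atoms)
        if a.chain_id == chain_id and a.residue_number == residue_number
    ]
    if not residue:
        raise KeyError(f"residue {chain_id}:{residue_number} not found")
    resname = residue[0][1].residue_name
    if resname != "CYS":
        raise AnchorError(
            f"residue {chain_id}:{residue_number} is {resname}, not CYS"
        )
    for i, a in residue:
        if a.name == "SG":
            return CysteineAnchor(chain_id, residue_number, sg_index=i)
    raise AnchorError(f"CYS {chain_id}:{residue_number} has no SG atom")


def extract_pocket(
    structure: ProteinStructure,
    anchor: CysteineAnchor,
    radius: float = DEFAULT_POCKET_RADIUS,
    model: int = 0,
) -> Pocket:
    """Atom-wise cut: all atoms within ``radius`` of the anchor Sγ.

    Whole-residue inclusion is off; the Sγ itself is always a member.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    atoms = structure.models[model]
    sg = atoms[anchor.sg_index].xyz
    coords = np.array([a.xyz for a in atoms])
    dist = np.linalg.norm(coords - sg, axis=1)
    keep = [i for i in range(len(atoms)) if dist[i] <= radius or i == anchor.sg_index]
    picked = [replace(atoms[i]) for i in keep]
    sg_index = keep.index(anchor.sg_index)
    cb_index = None
    for j, a in enumerate(picked):
        if (
            a.chain_id == anchor.chain_id
            and a.residue_number == anchor.residue_number
            and a.name == "CB"
        ):
            cb_index = j
            break
    return Pocket(atoms=picked, anchor=anchor, radius=radius,
                  sg_index=sg_index, cb_index=cb_index)


# ---------------------------------------------------------------------------
# Parameterization
# ---------------------------------------------------------------------------

ParameterTable = Mapping[tuple[str, str], tuple[float, float, float]]


def load_parameter_table(tsv_text: str) -> dict[tuple[str, str], tuple[float, float, float]]:
    """Parse a TSV of ``residue_name  atom_name  charge_e  sigma_A  epsilon_kcal``."""
    table: dict[tuple[str, str], tuple[float, float, float]] = {}
    for line in tsv_text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, atom, q, sig, eps = line.split("\t")
        table[(res, atom)] = (float(q), float(sig), float(eps))
    return table


def default_parameter_table() -> dict[tuple[str, str], tuple[float, float, float]]:
    """The packaged united-atom parameter set for the 20 standard residues."""
    text = resources.files("cyslock.data").joinpath("protein_params.tsv").read_text()
    return load_parameter_table(text)


def parameterize(pocket: Pocket, table: ParameterTable | None = None) -> Pocket:
    """Attach charges and LJ parameters to every pocket atom (in place).

    Raises :class:`ParameterizationError` listing every unmapped
    (residue, atom) pair at once.
    """
    if table is None:
        table = default_parameter_table()
    misses = [
        (a.residue_name, a.name)
        for a in pocket.atoms
        if (a.residue_name, a.name) not in table
    ]
    if misses:
        raise ParameterizationError(misses)
    for a in pocket.atoms:
        q, sig, eps = table[(a.residue_name, a.name)]
        a.partial_charge = q
        a.lj_sigma = sig
        a.lj_epsilon = eps
    return pocket
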