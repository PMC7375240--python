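"""Ligand parsing, Michael-acceptor warhead detection and the covalent
addition transform.

Covalent screening at a cysteine requires an electrophilic *warhead*: a
C=C double bond conjugated to an electron-withdrawing group, which the
thiolate attacks at the β-carbon (Michael addition).  No leaving group
departs, so the protein mass increases by the monoisotopic mass of the
whole parent compound — the quantity the mass-spectrometry validation
in :mod:`cyslock.modcheck` checks against.

Molecules are handled as RDKit heavy-atom graphs (hydrogens implicit).
Partial charges come from the Gasteiger–Marsili iterative partial
equalization of orbital electronegativity; implicit-hydrogen charges
are folded into their heavy atom, matching the united-atom protein
parameter set.  Lennard-Jones parameters are assigned per element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

__all__ = [
    "Ligand",
    "WarheadMatch",
    "AnchoredLigand",
    "LigandParseError",
    "WARHEAD_PATTERNS",
    "parse_ligand",
    "parse_smiles_library",
    "detect_warheads",
    "apply_michael_addition",
    "find_rotatable_bonds",
    "load_warhead_patterns",
]


class LigandParseError(ValueError):
    """Unparseable SMILES or SDF input."""


# element -> (sigma A, epsilon kcal/mol); united heavy atoms
_ELEMENT_LJ = {
    "C": (3.55, 0.070),
    "N": (3.25, 0.170),
    "O": (2.96, 0.210),
    "S": (3.55, 0.250),
    "P": (3.74, 0.200),
    "F": (2.94, 0.061),
    "CL": (3.40, 0.300),
    "BR": (3.47, 0.470),
    "I": (3.67, 0.580),
    "H": (2.50, 0.030),
}

def load_warhead_patterns() -> list[tuple[str, "Chem.Mol"]]:
    """Compiled warhead SMARTS patterns, packaged order preserved."""
    text = resources.files("cyslock.data").joinpath("warheads.txt").read_text()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pattern_id, smarts = line.split("\t")
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"bad warhead SMARTS for {pattern_id}")
        out.append((pattern_id, patt))
    return out


@dataclass
class Ligand:
    """A parsed, parameterized small molecule (heavy-atom graph)."""

    mol: Chem.Mol
    id: str
    partial_charges: np.ndarray  # e, united (implicit-H charges folded in)
    lj_sigma: np.ndarray  # A
    lj_epsilon: np.ndarray  # kcal/mol
    _consumed: set = field(default_factory=set, repr=False)

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def elements(self) -> list[str]:
        return [a.GetSymbol() for a in self.mol.GetAtoms()]

    @property
    def formula(self) -> str:
        """Hill-notation elemental formula (e.g. ``C3H5NO``)."""
        return rdMolDescriptors.CalcMolFormula(self.mol)

    @property
    def bonds(self) -> list[tuple[int, int, float]]:
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in self.mol.GetBonds()
        ]


@dataclass(frozen=True)
class WarheadMatch:
    """One matched electrophilic site on a ligand."""

    pattern_id: str
    beta_c: int  # carbon attacked by the thiol
    alpha_c: int
    ewg_atom: int  # carbonyl C / sulfonyl S anchoring the conjugation


@dataclass
class AnchoredLigand:
    """Ligand after Michael addition, ready for covalent attachment.

    ``mol`` carries the post-addition connectivity: the former C=C is a
    single bond, the α-carbon has gained a hydrogen, and a thiol sulfur
    placeholder atom (index ``s_index``) is bonded to ``beta_c`` — at
    docking time this atom is superposed onto the pocket Sγ.
    """

    mol: Chem.Mol
    parent: Ligand
    match: WarheadMatch
    s_index: int
    anchor_bond_length: float = 1.81  # S-C single bond, A
    mass_delta: float = 0.0  # Da, monoisotopic mass of the intact parent
    partial_charges: np.ndarray | None = None  # adduct charges, incl. the S
    lj_sigma: np.ndarray | None = None
    lj_epsilon: np.ndarray | None = None

    @property
    def beta_c(self) -> int:
        return self.match.beta_c

    @property
    def ligand_atom_indices(self) -> list[int]:
        """Indices of the parent-ligand atoms (everything but the S)."""
        return [i for i in range(self.mol.GetNumAtoms()) if i != self.s_index]


def _united_charges(mol: Chem.Mol) -> np.ndarray:
    AllChem.ComputeGasteigerCharges(mol)
    q = np.empty(mol.GetNumAtoms())
    for i, atom in enumerate(mol.GetAtoms()):
        q[i] = float(atom.GetDoubleProp("_GasteigerCharge")) + float(
            atom.GetDoubleProp("_GasteigerHCharge")
        )
    return q


def _element_lj(mol: Chem.Mol, lig_id: str) -> tuple[np.ndarray, np.ndarray]:
    sig = np.empty(mol.GetNumAtoms())
    eps = np.empty(mol.GetNumAtoms())
    for i, atom in enumerate(mol.GetAtoms()):
        key = atom.GetSymbol().upper()
        if key not in _ELEMENT_LJ:
            raise LigandParseError(f"{lig_id}: no LJ parameters for element {key}")
        sig[i], eps[i] = _ELEMENT_LJ[key]
    return sig, eps


def _parameterize_mol(mol: Chem.Mol, lig_id: str) -> Ligand:
    charges = _united_charges(mol)
    sig, eps = _element_lj(mol, lig_id)
    return Ligand(mol=mol, id=lig_id, partial_charges=charges,
                  lj_sigma=sig, lj_epsilon=eps)


def parse_ligand(record: str, lig_id: str = "") -> Ligand:
    """Parse a SMILES string or an SDF (mol) block into a :class:`Ligand`.

    Records containing newlines are treated as SDF V2000 blocks,
    anything else as SMILES.  Partial charges are assigned immediately
    (Gasteiger, deterministic); parsing is therefore the only setup a
    ligand needs before screening.
    """
    if "\n" in record:
        mol = Chem.MolFromMolBlock(record, sanitize=True)
    else:
        mol = Chem.MolFromSmiles(record)
    if mol is None:
        raise LigandParseError(f"could not parse ligand record {lig_id or record!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise LigandParseError(f"{lig_id or record!r}: disconnected structure")
    return _parameterize_mol(mol, lig_id or Chem.MolToSmiles(mol))


def parse_smiles_library(text: str) -> list[Ligand]:
    """Parse a SMILES library: one molecule per line, optional tab-separated id."""
    ligands = []
    for i, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smiles = parts[0]
        lig_id = parts[1] if len(parts) > 1 else f"mol{i}"
        ligands.append(parse_ligand(smiles, lig_id))
    return ligands


def detect_warheads(ligand: Ligand) -> list[WarheadMatch]:
    """All non-overlapping warhead matches, ordered by β-carbon index.

    Each C=C electrophile is reported once, under the first (most
    specific) pattern that matches it; an empty list is a valid result.
    """
    matches: dict[int, WarheadMatch] = {}
    for pattern_id, patt in load_warhead_patterns():
        for hit in ligand.mol.GetSubstructMatches(patt):
            beta, alpha, ewg = hit[0], hit[1], hit[2]
            if beta not in matches:
                matches[beta] = WarheadMatch(pattern_id, beta, alpha, ewg)
    return [matches[b] for b in sorted(matches)]


def apply_michael_addition(ligand: Ligand, match: WarheadMatch) -> AnchoredLigand:
    """Reduce the warhead C=C and open the thiol attachment at β-C.

    The β–α double bond becomes single, the α-carbon gains one
    hydrogen, and a placeholder sulfur is bonded to the β-carbon to
    stand for the cysteine Sγ.  ``mass_delta`` is the monoisotopic mass
    of the intact neutral parent — Michael addition transfers the whole
    molecule with no leaving group.
    """
    mol = ligand.mol
    key = (match.beta_c, match.alpha_c)
    bond = None
    if max(key) < mol.GetNumAtoms():
        bond = mol.GetBondBetweenAtoms(*key)
    if (
        key in ligand._consumed
        or bond is None
        or bond.GetBondType() != Chem.BondType.DOUBLE
    ):
        raise ValueError(
            f"{ligand.id}: stale warhead match — "
            f"atoms {match.beta_c}-{match.alpha_c} are not an intact double bond"
        )
    ligand._consumed.add(key)
    rw = Chem.RWMol(mol)
    rw.GetBondBetweenAtoms(match.beta_c, match.alpha_c).SetBondType(
        Chem.BondType.SINGLE
    )
    alpha = rw.GetAtomWithIdx(match.alpha_c)
    alpha.SetNumExplicitHs(alpha.GetTotalNumHs() + 1)
    alpha.SetNoImplicit(True)
    s_index = rw.AddAtom(Chem.Atom(16))
    rw.AddBond(match.beta_c, s_index, Chem.BondType.SINGLE)
    adduct = rw.GetMol()
    Chem.SanitizeMol(adduct)
    mass_delta = rdMolDescriptors.CalcExactMolWt(ligand.mol)
    sig, eps = _element_lj(adduct, ligand.id)
    return AnchoredLigand(
        mol=adduct, parent=ligand, match=match, s_index=s_index,
        mass_delta=mass_delta,
        partial_charges=_united_charges(adduct), lj_sigma=sig, lj_epsilon=eps,
    )


_AMIDE = Chem.MolFromSmarts("[CX3](=O)[NX3]")


def find_rotatable_bonds(anchored: AnchoredLigand) -> list[tuple[int, int]]:
    """Rotatable bonds of the anchored ligand, breadth-first from the anchor.

    A bond rotates if it is single, acyclic and joins two non-terminal
    heavy atoms; amide C–N bonds are held planar.  The S–Cβ anchor bond
    is always first and always rotatable (in the complex the sulfur is
    bonded to the cysteine Cβ, so torsion about S–Cβ moves the whole
    ligand).  Each pair is oriented (nearer-anchor atom, distal atom).
    """
    mol = anchored.mol
    amide_pairs = set()
    for hit in mol.GetSubstructMatches(_AMIDE):
        amide_pairs.add(frozenset((hit[0], hit[2])))

    # BFS depth from the anchor sulfur
    depth = {anchored.s_index: 0}
    frontier = [anchored.s_index]
    while frontier:
        nxt = []
        for i in frontier:
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j not in depth:
                    depth[j] = depth[i] + 1
                    nxt.append(j)
        frontier = nxt

    rotatable: list[tuple[int, int]] = [(anchored.s_index, anchored.beta_c)]
    candidates = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if anchored.s_index in (i, j):
            continue  # the anchor bond is already in; S has no other bonds
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        if mol.GetAtomWithIdx(i).GetDegree() < 2 or mol.GetAtomWithIdx(j).GetDegree() < 2:
            continue  # terminal heavy atom on one side
        if frozenset((i, j)) in amide_pairs:
            continue
        near, far = (i, j) if depth[i] <= depth[j] else (j, i)
        candidates.append((depth[near], near, far))
    candidates.sort()
    rotatable.extend((near, far) for _, near, far in candidates)
    return rotatable
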