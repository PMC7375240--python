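"""Covalent attachment geometry and exhaustive torsion-scan enumeration.

The pose search is deliberately exhaustive rather than stochastic: with
the ligand tethered to the cysteine Sγ, the remaining degrees of
freedom are the torsions about its rotatable bonds, and every torsion
is stepped on a fixed grid (default 30°, i.e. 12 states per bond).  A
warhead-sized ligand with 2–3 rotatable bonds therefore yields a few
hundred to a few thousand conformers, all of which are scored.

Geometry model: internal geometry (bond lengths, angles) comes from a
seeded distance-geometry embedding of the adduct and is held fixed;
only torsions vary.  The placeholder sulfur is superposed exactly onto
the pocket Sγ, with the Sγ–Cβ bond pointing anti to the cysteine
Sγ–Cβ(protein) bond as a tetrahedral-like starting direction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .ligands import AnchoredLigand, find_rotatable_bonds
from .structures import Pocket

__all__ = [
    "Conformer",
    "ConformerSet",
    "GeometryError",
    "place_anchor",
    "enumerate_conformers",
    "prune_internal_clashes",
    "write_conformers_pdb",
]

_EMBED_SEED = 1234567  # fixed: embedding must be reproducible bit-for-bit


class GeometryError(RuntimeError):
    """Covalent attachment geometry cannot be built."""


@dataclass
class Conformer:
    """One realized pose: torsion assignment plus pocket-frame coordinates.

    ``coords`` covers every atom of the adduct molecule including the
    placeholder sulfur (which sits exactly on the pocket Sγ);
    ``torsion_assignment`` is parallel to the rotatable-bond list of
    the anchored ligand, in degrees.
    """

    anchored: AnchoredLigand
    torsion_assignment: tuple[float, ...]
    coords: np.ndarray

    @property
    def ligand_coords(self) -> np.ndarray:
        return self.coords[self.anchored.ligand_atom_indices]


@dataclass
class ConformerSet:
    anchored: AnchoredLigand
    conformers: list[Conformer]
    increment_deg: float
    cap: int

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)


# ---------------------------------------------------------------------------
# small vector-geometry helpers
# ---------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _rotation_matrix(axis_unit: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis_unit
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return c * np.eye(3) + s * K + (1.0 - c) * np.outer(axis_unit, axis_unit)


def _rotate_about_bond(
    coords: np.ndarray, pivot: np.ndarray, axis_unit: np.ndarray,
    moving: np.ndarray, angle_deg: float
) -> None:
    R = _rotation_matrix(axis_unit, angle_deg)
    coords[moving] = (coords[moving] - pivot) @ R.T + pivot


def _distal_atoms(mol: Chem.Mol, near: int, far: int) -> np.ndarray:
    """Atoms on the `far` side of bond (near, far), excluding axis atoms."""
    seen = {near, far}
    stack = [far]
    out = []
    while stack:
        i = stack.pop()
        for nb in mol.GetAtomWithIdx(i).GetNeighbors():
            j = nb.GetIdx()
            if j not in seen:
                seen.add(j)
                out.append(j)
                stack.append(j)
    return np.array(sorted(out), dtype=int)


def _torsion_reference(mol: Chem.Mol, near: int, far: int, exclude: int) -> int:
    """Lowest-index heavy neighbor of `near` other than `far`/`exclude`."""
    cands = [
        nb.GetIdx()
        for nb in mol.GetAtomWithIdx(near).GetNeighbors()
        if nb.GetIdx() not in (far, exclude)
    ]
    if not cands:
        raise GeometryError(f"atom {near} has no torsion reference neighbor")
    return min(cands)


@dataclass
class _TorsionTable:
    """Precomputed rotation machinery for one anchored ligand."""

    bonds: list[tuple[int, int]]  # oriented (near-anchor, distal)
    moving: list[np.ndarray]  # distal atom sets, parallel to bonds


def _build_torsion_table(anchored: AnchoredLigand) -> _TorsionTable:
    mol = anchored.mol
    bonds = find_rotatable_bonds(anchored)
    moving = []
    for near, far in bonds:
        if near == anchored.s_index:
            # anchor bond: everything but the axis atoms swings
            m = np.array(
                [i for i in range(mol.GetNumAtoms()) if i not in (near, far)],
                dtype=int,
            )
        else:
            m = _distal_atoms(mol, near, far)
        moving.append(m)
    return _TorsionTable(bonds=bonds, moving=moving)


# ---------------------------------------------------------------------------
# embedding and placement
# ---------------------------------------------------------------------------

def _embed_coords(anchored: AnchoredLigand) -> np.ndarray:
    """Deterministic 3-D coordinates for the adduct (heavy atoms)."""
    mol = Chem.AddHs(Chem.Mol(anchored.mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = _EMBED_SEED
    if AllChem.EmbedMolecule(mol, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise GeometryError(f"could not embed {anchored.parent.id}")
    try:
        AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    except Exception:
        pass  # embedding geometry is acceptable without refinement
    mol = Chem.RemoveHs(mol)
    return np.array(mol.GetConformer().GetPositions(), dtype=float)


def place_anchor(
    anchored: AnchoredLigand, pocket: Pocket, bond_length: float = 1.81
) -> Conformer:
    """Build the covalently attached start pose.

    The placeholder sulfur is mapped onto the pocket Sγ; the Sγ–Cβ
    (ligand) bond is scaled to ``bond_length`` and directed anti to the
    cysteine's own Sγ–CB bond; every rotatable torsion (including the
    anchor torsion CB–Sγ–Cβ–ref) starts at 0°.
    """
    if pocket.cb_index is None:
        raise GeometryError(
            "pocket lacks the CB atom of the anchor cysteine; "
            "cannot orient the covalent attachment"
        )
    coords = _embed_coords(anchored)
    table = _build_torsion_table(anchored)
    s, beta = anchored.s_index, anchored.beta_c
    mol = anchored.mol

    # zero all internal torsions (everything except the anchor bond)
    for (near, far), moving in zip(table.bonds[1:], table.moving[1:]):
        a = _torsion_reference(mol, near, far, exclude=-1)
        d = _torsion_reference(mol, far, near, exclude=-1)
        cur = _dihedral(coords[a], coords[near], coords[far], coords[d])
        axis = coords[far] - coords[near]
        axis /= np.linalg.norm(axis)
        _rotate_about_bond(coords, coords[near], axis, moving, -cur)

    sg = pocket.sg_xyz
    cb = pocket.atoms[pocket.cb_index].xyz
    direction = sg - cb
    direction /= np.linalg.norm(direction)

    # scale the S-Cbeta bond to the requested length, then superpose
    sb = coords[beta] - coords[s]
    sb_len = np.linalg.norm(sb)
    if sb_len < 1e-9:
        raise GeometryError("degenerate embedded S-C bond")
    non_s = np.array([i for i in range(len(coords)) if i != s], dtype=int)
    coords[non_s] += (bond_length / sb_len - 1.0) * sb  # shift not scale: keep
    # NOTE: uniform shift keeps all ligand-internal geometry; only the S-C
    # distance changes.
    sb = coords[beta] - coords[s]
    sbu = sb / np.linalg.norm(sb)

    # minimal rotation taking the embedded S->beta direction onto `direction`
    v = np.cross(sbu, direction)
    c = float(np.dot(sbu, direction))
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else _rotation_matrix(
            _any_perpendicular(sbu), 180.0
        )
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    coords = (coords - coords[s]) @ R.T + sg

    # anchor torsion CB-S-beta-ref to 0 degrees
    if mol.GetAtomWithIdx(beta).GetDegree() > 1:
        ref = _torsion_reference(mol, beta, s, exclude=-1)
        cur = _dihedral(cb, coords[s], coords[beta], coords[ref])
        axis = coords[beta] - coords[s]
        axis /= np.linalg.norm(axis)
        _rotate_about_bond(coords, coords[s], axis, table.moving[0], -cur)

    n_bonds = len(table.bonds)
    return Conformer(
        anchored=anchored,
        torsion_assignment=tuple([0.0] * n_bonds),
        coords=coords,
    )


def _any_perpendicular(u: np.ndarray) -> np.ndarray:
    v = np.cross(u, [1.0, 0.0, 0.0])
    if np.linalg.norm(v) < 1e-6:
        v = np.cross(u, [0.0, 1.0, 0.0])
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# enumeration and pruning
# ---------------------------------------------------------------------------

def enumerate_conformers(
    start: Conformer, increment_deg: float = 30.0, cap: int = 10_000
) -> ConformerSet:
    """Full torsion-grid Cartesian product, lexicographic, capped.

    Each rotatable bond takes values {0, inc, 2·inc, ...}; the product
    is enumerated in lexicographic order over the breadth-first bond
    ordering and truncated at ``cap``.  Rotations are applied from the
    anchor outward so each recorded angle is an offset from the start
    pose about the bond's current axis.
    """
    if increment_deg <= 0 or 360.0 % increment_deg != 0:
        raise ValueError(f"increment must divide 360, got {increment_deg}")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    anchored = start.anchored
    table = _build_torsion_table(anchored)
    values = np.arange(0.0, 360.0, increment_deg)
    conformers: list[Conformer] = []
    for assignment in itertools.islice(
        itertools.product(values, repeat=len(table.bonds)), cap
    ):
        coords = start.coords.copy()
        for (near, far), moving, angle in zip(
            table.bonds, table.moving, assignment
        ):
            if angle == 0.0:
                continue
            axis = coords[far] - coords[near]
            axis /= np.linalg.norm(axis)
            _rotate_about_bond(coords, coords[near], axis, moving, angle)
        conformers.append(
            Conformer(anchored=anchored, torsion_assignment=tuple(assignment),
                      coords=coords)
        )
    return ConformerSet(
        anchored=anchored, conformers=conformers,
        increment_deg=increment_deg, cap=cap,
    )


def prune_internal_clashes(
    conf_set: ConformerSet, min_dist: float = 1.2
) -> ConformerSet:
    """Drop conformers with a non-bonded intramolecular pair under ``min_dist``.

    Pairs separated by one or two bonds (1-2 and 1-3) are constrained by
    the fixed internal geometry and are not tested; 1-4 and beyond are.
    Survivor order is preserved.
    """
    if not conf_set.conformers or min_dist <= 0:
        return ConformerSet(
            anchored=conf_set.anchored, conformers=list(conf_set.conformers),
            increment_deg=conf_set.increment_deg, cap=conf_set.cap,
        )
    mol = conf_set.anchored.mol
    topo = Chem.GetDistanceMatrix(mol)
    iu = np.triu_indices(mol.GetNumAtoms(), k=1)
    nonbonded = topo[iu] >= 3
    ii, jj = iu[0][nonbonded], iu[1][nonbonded]
    survivors = []
    for conf in conf_set.conformers:
        d = np.linalg.norm(conf.coords[ii] - conf.coords[jj], axis=1)
        if not np.any(d < min_dist):
            survivors.append(conf)
    return ConformerSet(
        anchored=conf_set.anchored, conformers=survivors,
        increment_deg=conf_set.increment_deg, cap=conf_set.cap,
    )


def write_conformers_pdb(conf_set: ConformerSet, max_models: int = 100) -> str:
    """Render conformers as a multi-model PDB (ligand as HETATM LIG)."""
    mol = conf_set.anchored.mol
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    lines = []
    for m, conf in enumerate(conf_set.conformers[:max_models], start=1):
        lines.append(f"MODEL     {m:>4d}")
        for i, (sym, xyz) in enumerate(zip(symbols, conf.coords), start=1):
            name = f"{sym}{i}"[:4]
            lines.append(
                f"HETATM{i:>5d} {name:<4s} LIG L{1:>4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {sym.upper():>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
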