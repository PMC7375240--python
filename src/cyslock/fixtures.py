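"""Deterministic synthetic inputs for every pipeline in the package.

Each generator is a pure function of (seed, parameters): toy pockets
with a cysteine anchor, warhead-bearing SMILES libraries, multi-state
Cα trajectories and perturbed HSQC peak lists.  Defaults mirror the
shapes of the study the package emulates — a 120-compound electrophile
library, a two-state pocket trajectory, a ~180-residue ¹⁵N-labeled
GTPase — at a scale that runs in seconds.

The geometries are statistical stand-ins, not force-field-quality
structures: pocket residues are rigid heavy-atom stubs scattered on a
shell around the anchor, and trajectory states are smoothed random
walks.  They exercise every parser, invariant and algorithm in the
package; they do not predict chemistry.
"""

from __future__ import annotations

import numpy as np

from .pocketmap import ca_rmsd

__all__ = [
    "make_toy_pocket",
    "make_ligand_library",
    "make_trajectory",
    "make_peaklists",
]

_ANCHOR_RESNUM = 107  # homage to the anchor cysteine of the target GTPase


def _pdb_atom(serial, name, resname, chain, resnum, xyz, element) -> str:
    nm = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:>5d} {nm} {resname:>3s} {chain}{resnum:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def make_toy_pocket(seed: int, n_residues: int = 8) -> str:
    """PDB text for a toy pocket: an anchor CYS ringed by residue stubs.

    The cysteine (chain A, residue 107) carries N, CA, CB and SG with
    SG at the origin; the other ``n_residues - 1`` residues are
    backbone+CB stubs whose CA sits 4-7.4 Å from SG, biased away from
    the ligand attachment direction (anti to SG→CB) so the open face
    of the pocket stays dockable.  Fully parameterizable by the
    packaged table.
    """
    if n_residues < 2:
        raise ValueError("a pocket needs the anchor plus at least one residue")
    rng = np.random.default_rng(seed)
    lines = []
    serial = 1

    # anchor cysteine: SG at origin, CB along -z, CA/N continuing the chain
    sg = np.zeros(3)
    cb = np.array([0.0, 0.0, -1.81])
    ca = cb + np.array([0.0, 1.23, -0.89])
    n = ca + np.array([1.20, 0.60, -0.50])
    for name, xyz, elem in (("N", n, "N"), ("CA", ca, "C"),
                            ("CB", cb, "C"), ("SG", sg, "S")):
        lines.append(_pdb_atom(serial, name, "CYS", "A", _ANCHOR_RESNUM,
                               xyz, elem))
        serial += 1

    # the attachment direction is anti to SG->CB, i.e. +z
    attach = np.array([0.0, 0.0, 1.0])
    resnames = ["ALA", "SER", "LEU", "THR", "VAL", "PHE", "GLY", "ASN",
                "ILE", "MET"]
    placed = 0
    resnum = 1
    while placed < n_residues - 1:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if np.dot(v, attach) > 0.34:  # keep a ~70 degree cone open
            continue
        r = rng.uniform(4.0, 7.4)  # stub atoms stay within 10 A of SG
        center = sg + r * v
        resname = resnames[placed % len(resnames)]
        ca = center
        nn = ca + np.array([1.33, 0.48, 0.0])
        c = ca + np.array([-1.21, 0.70, 0.0])
        o = c + np.array([-0.65, 1.05, 0.0])
        atoms = [("N", nn, "N"), ("CA", ca, "C"), ("C", c, "C"), ("O", o, "O")]
        if resname != "GLY":
            atoms.append(("CB", ca + np.array([0.25, -1.33, 0.65]), "C"))
        for name, xyz, elem in atoms:
            lines.append(_pdb_atom(serial, name, resname, "A", resnum,
                                   xyz, elem))
            serial += 1
        placed += 1
        resnum += 1
        if resnum == _ANCHOR_RESNUM:
            resnum += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# small chemistry vocabulary for the synthetic library
_WARHEAD_CORES = [
    "C=CC(=O)N{tail}",      # acrylamide
    "C=CC(=O)O{tail}",      # acrylate ester
    "C=CC(=O){tail}",       # enone
    "C=CS(=O)(=O){tail}",   # vinyl sulfone
    "C=CS(=O)(=O)O{tail}",  # vinyl sulfonate
]
_TAILS = ["C", "CC", "CCC", "CCO", "CCN", "CCOC", "CC(C)C", "CCc1ccccc1",
          "Cc1ccccc1", "CCCO"]
_INERT = ["c1ccccc1", "CCCCCC", "CCOCC", "CC(C)CC(C)C", "c1ccccc1C",
          "CCCNCCC", "COc1ccccc1", "CCCCO"]


def make_ligand_library(
    seed: int, n: int = 120, warhead_fraction: float = 0.9
) -> str:
    """SMILES library text: round(n·fraction) single-warhead compounds.

    Warhead compounds are one Michael-acceptor core with an inert
    aliphatic/aromatic tail; the remainder carry no electrophile.
    Ids run L0001..  Same seed, same text, byte for byte.
    """
    if n < 1:
        raise ValueError("library size must be >= 1")
    if not 0 <= warhead_fraction <= 1:
        raise ValueError("warhead_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_warhead = int(round(n * warhead_fraction))
    smiles: list[str] = []
    for i in range(n):
        if i < n_warhead:
            core = _WARHEAD_CORES[int(rng.integers(len(_WARHEAD_CORES)))]
            tail = _TAILS[int(rng.integers(len(_TAILS)))]
            smiles.append(core.format(tail=tail))
        else:
            smiles.append(_INERT[int(rng.integers(len(_INERT)))])
    order = rng.permutation(n)
    lines = [
        f"{smiles[j]}\tL{i + 1:04d}" for i, j in enumerate(order)
    ]
    return "\n".join(lines) + "\n"


def make_trajectory(
    seed: int,
    n_frames: int = 100,
    state_fractions: tuple[float, ...] = (0.6, 0.4),
    noise: float = 0.3,
    separation: float = 5.0,
    n_residues: int = 40,
) -> tuple[str, list[int]]:
    """Multi-model Cα PDB emulating a multi-state pocket trajectory.

    Each state is an independent smoothed 3.8 Å-step random walk;
    frames add isotropic Gaussian noise (sd ``noise`` Å per
    coordinate) to their state's reference.  States are verified to be
    at least ``separation`` Å apart in superposed Cα RMSD — with the
    default 10:1 separation:noise ratio a correct clusterer must
    recover the generating labels exactly.  Returns (pdb_text,
    per-frame state labels).
    """
    fractions = np.asarray(state_fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9 or (fractions <= 0).any():
        raise ValueError("state_fractions must be positive and sum to 1")
    if n_frames < len(fractions):
        raise ValueError("need at least one frame per state")
    if noise < 0 or noise >= separation / 10.0:
        raise ValueError("noise must satisfy 0 <= noise < separation/10")
    rng = np.random.default_rng(seed)

    refs = []
    for _ in fractions:
        steps = rng.normal(size=(n_residues, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        walk = 3.8 * np.cumsum(steps, axis=0)
        refs.append(walk - walk.mean(axis=0))
    # amplify inter-state differences until every pair clears the
    # separation floor in superposed RMSD (short chains can start close)
    for j in range(1, len(refs)):
        for _ in range(60):
            if all(ca_rmsd(refs[i], refs[j]) >= separation for i in range(j)):
                break
            nearest = min(range(j), key=lambda i: ca_rmsd(refs[i], refs[j]))
            refs[j] = refs[nearest] + 1.5 * (refs[j] - refs[nearest])
            refs[j] -= refs[j].mean(axis=0)
        else:
            raise RuntimeError("could not separate synthetic states")

    counts = np.floor(fractions * n_frames).astype(int)
    for i in np.argsort(-(fractions * n_frames - counts))[: n_frames - counts.sum()]:
        counts[i] += 1
    labels = [s for s, c in enumerate(counts) for _ in range(c)]

    lines = []
    for m, state in enumerate(labels, start=1):
        coords = refs[state] + rng.normal(scale=noise, size=(n_residues, 3)) \
            if noise > 0 else refs[state]
        lines.append(f"MODEL     {m:>4d}")
        for i, xyz in enumerate(coords, start=1):
            lines.append(_pdb_atom(i, "CA", "ALA", "A", i, xyz, "C"))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n", labels


def make_peaklists(
    seed: int,
    n_residues: int = 180,
    perturbed_ranges: tuple[tuple[int, int], ...] = ((64, 78), (90, 113)),
    csp_magnitude: float = 0.1,
    attenuated_set: tuple[int, ...] = (107,),
) -> tuple[str, str]:
    """Apo/bound HSQC peak-list TSV pair with engineered perturbations.

    Residues inside ``perturbed_ranges`` get a combined CSP of exactly
    ``csp_magnitude`` (split 0.8/0.6 between the ¹H and weighted ¹⁵N
    components); everywhere else the jitter keeps CSP below 0.01.
    ``attenuated_set`` residues (which must lie inside the perturbed
    ranges, so segment summaries stay exact) drop to a 0.1 intensity
    ratio in the bound list.
    """
    spans = sorted(perturbed_ranges)
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 <= b1 + 1:  # touching ranges would merge into one segment
            raise ValueError("perturbed ranges overlap or touch")
    for a, b in spans:
        if not (1 <= a <= b <= n_residues):
            raise ValueError(f"range ({a},{b}) outside 1..{n_residues}")
    in_range = lambda r: any(a <= r <= b for a, b in spans)
    for r in attenuated_set:
        if not in_range(r):
            raise ValueError(f"attenuated residue {r} outside perturbed ranges")

    rng = np.random.default_rng(seed)
    apo = ["residue_number\th_ppm\tn_ppm\tintensity"]
    bound = ["residue_number\th_ppm\tn_ppm\tintensity"]
    for res in range(1, n_residues + 1):
        h = rng.uniform(7.0, 9.5)
        nppm = rng.uniform(105.0, 130.0)
        inten = rng.uniform(0.8e6, 1.2e6)
        apo.append(f"{res}\t{h:.4f}\t{nppm:.4f}\t{inten:.1f}")
        if in_range(res):
            dh = 0.8 * csp_magnitude
            dn = 0.6 * csp_magnitude / 0.2  # 0.2 = standard 15N weight
        else:
            dh = rng.uniform(-0.005, 0.005)
            dn = rng.uniform(-0.02, 0.02)
        ratio = 0.1 if res in attenuated_set else rng.uniform(0.8, 1.2)
        bound.append(
            f"{res}\t{h + dh:.4f}\t{nppm + dn:.4f}\t{inten * ratio:.1f}"
        )
    return "\n".join(apo) + "\n", "\n".join(bound) + "\n"
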