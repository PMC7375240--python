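"""Pocket-state discovery from trajectory frames, and the cysteine
conservation screen.

Molecular-dynamics post-processing only: frames arrive as a multi-model
PDB (the trajectory container used throughout the package), are reduced
to Cα coordinates, compared by least-squares-superposed RMSD, and
partitioned with k-medoids on the pairwise RMSD matrix.  Medoids serve
as the representative structures of the pocket states; cluster
occupancies (fractions of frames) quantify how often each state is
visited.  Running the MD itself is out of scope.

The conservation screen asks whether a reference residue — e.g. the
RhoA Cys107 attacked by the covalent ligand — is unique to one branch
of a family alignment, i.e. whether targeting it can buy selectivity.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from scipy.spatial.transform import Rotation

from .structures import ProteinStructure, read_structure

__all__ = [
    "FrameSet",
    "ClusterReport",
    "AlignmentColumnReport",
    "extract_even",
    "ca_rmsd",
    "pairwise_rmsd",
    "cluster_frames",
    "conservation_screen",
    "write_frame_pdb",
]


@dataclass
class FrameSet:
    """Trajectory Cα coordinates: (n_frames, n_residues, 3), Å."""

    frames: np.ndarray
    residue_numbers: list[int]
    source: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_res, 3)")
        if self.frames.shape[1] != len(self.residue_numbers):
            raise ValueError("residue_numbers length mismatch")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ClusterReport:
    """k-cluster partition of a FrameSet, ordered by descending occupancy."""

    k: int
    labels: np.ndarray  # per-frame cluster id, 0..k-1
    occupancies: np.ndarray  # per-cluster fraction, descending
    medoid_frame: np.ndarray  # per-cluster representative frame index

    def __post_init__(self) -> None:
        if abs(float(self.occupancies.sum()) - 1.0) > 1e-9:
            raise ValueError("occupancies must sum to 1")

    def to_tsv(self) -> str:
        lines = ["cluster\toccupancy\tmedoid_model"]
        for c in range(self.k):
            lines.append(
                f"{c}\t{self.occupancies[c]:.6f}\t{self.medoid_frame[c]}"
            )
        return "\n".join(lines) + "\n"


@dataclass
class AlignmentColumnReport:
    """One alignment column, mapped from a reference residue number."""

    column_index: int  # 0-based into the alignment
    reference_id: str
    reference_residue_number: int
    target_symbol: str
    symbols: list[tuple[str, str]]  # (sequence id, symbol at column)

    @property
    def matching_ids(self) -> list[str]:
        return [sid for sid, sym in self.symbols if sym == self.target_symbol]


# ---------------------------------------------------------------------------
# frame extraction
# ---------------------------------------------------------------------------

def extract_even(
    frames_source: str | ProteinStructure, n_keep: int
) -> FrameSet:
    """Evenly thin a multi-model trajectory to ``n_keep`` Cα frames.

    Kept model indices are round(i·(M−1)/(K−1)); the first and last
    models always survive.  ``n_keep == 1`` keeps the first model.
    """
    structure = (
        read_structure(frames_source)
        if isinstance(frames_source, str)
        else frames_source
    )
    n_models = structure.n_models
    if n_keep < 1 or n_keep > n_models:
        raise ValueError(f"n_keep must be in [1, {n_models}], got {n_keep}")
    if n_keep == 1:
        picked = [0]
    else:
        picked = sorted(
            {int(i * (n_models - 1) / (n_keep - 1) + 0.5) for i in range(n_keep)}
        )
    ca_idx = [i for i, a in enumerate(structure.models[0]) if a.name == "CA"]
    if not ca_idx:
        raise ValueError("trajectory has no CA atoms")
    residue_numbers = [structure.models[0][i].residue_number for i in ca_idx]
    frames = np.array(
        [[structure.models[m][i].xyz for i in ca_idx] for m in picked]
    )
    return FrameSet(frames=frames, residue_numbers=residue_numbers,
                    source=structure.source_id)


def write_frame_pdb(frames: FrameSet, index: int) -> str:
    """Render one frame (e.g. a cluster medoid) as a single-model Cα PDB."""
    if not 0 <= index < frames.n_frames:
        raise IndexError(f"frame {index} out of range [0, {frames.n_frames})")
    lines = []
    for i, (resnum, xyz) in enumerate(
        zip(frames.residue_numbers, frames.frames[index]), start=1
    ):
        lines.append(
            f"ATOM  {i:>5d}  CA  ALA A{resnum:>4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"           C"
        )
    return "\n".join(lines) + "\nEND\n"


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def _kabsch(ac: np.ndarray, bc: np.ndarray):
    """Least-squares fit of centered coordinate sets (proper rotation).

    Wraps :meth:`Rotation.align_vectors`, muting its warning for
    rank-deficient inputs (e.g. collinear points) — the returned fit is
    still a valid least-squares solution there.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(ac, bc)
    # recompute the residual directly: the solver's reported rssd loses
    # ~8 digits to cancellation when the fit is near-perfect
    return rot, float(
        np.sqrt(np.sum((ac - rot.apply(bc)) ** 2))
    )


def ca_rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = True) -> float:
    """Cα RMSD between two frames, optionally after optimal superposition.

    Superposition is the least-squares rigid fit (Kabsch): centroids
    removed, proper rotation enforced.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if superpose:
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        _, rssd = _kabsch(ac, bc)
        return float(rssd / np.sqrt(n))
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def pairwise_rmsd(frames: FrameSet, superpose: bool = True) -> np.ndarray:
    """Symmetric matrix of frame-vs-frame Cα RMSD."""
    x = frames.frames
    n = frames.n_frames
    centered = x - x.mean(axis=1, keepdims=True)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if superpose:
                _, rssd = _kabsch(centered[i], centered[j])
                d[i, j] = d[j, i] = rssd / np.sqrt(x.shape[1])
            else:
                d[i, j] = d[j, i] = np.sqrt(
                    np.mean(np.sum((x[i] - x[j]) ** 2, axis=1))
                )
    return d


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _init_medoids(dist: np.ndarray, k: int) -> list[int]:
    """Deterministic seeding: most central frame, then farthest-point."""
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        min_d = dist[:, medoids].min(axis=1)
        min_d[medoids] = -1.0
        medoids.append(int(np.argmax(min_d)))
    return medoids


def cluster_frames(frames: FrameSet, k: int = 10, seed: int = 0) -> ClusterReport:
    """k-medoids (PAM-style alternation) on the superposed-RMSD matrix.

    Initialization is deterministic (central frame + farthest-point),
    so results do not depend on ``seed``; the argument is kept so
    callers can treat this like any seeded clusterer.  Clusters are
    reported in descending occupancy, ties broken by the smaller medoid
    frame index.
    """
    n = frames.n_frames
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    dist = pairwise_rmsd(frames)
    medoids = _init_medoids(dist, k)
    labels = np.zeros(n, dtype=int)
    for _ in range(100):
        # assignment step; ties go to the lower medoid list position
        labels = np.argmin(dist[:, medoids], axis=1)
        new_medoids = []
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:  # cannot happen: medoid stays its own member
                new_medoids.append(medoids[c])
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids.append(int(members[np.argmin(within)]))
        if new_medoids == medoids:
            break
        medoids = new_medoids

    sizes = np.bincount(labels, minlength=k)
    order = sorted(range(k), key=lambda c: (-sizes[c], medoids[c]))
    relabel = {old: new for new, old in enumerate(order)}
    final_labels = np.array([relabel[c] for c in labels], dtype=int)
    occupancies = np.array([sizes[c] / n for c in order])
    medoid_frame = np.array([medoids[c] for c in order], dtype=int)
    return ClusterReport(k=k, labels=final_labels, occupancies=occupancies,
                         medoid_frame=medoid_frame)


# ---------------------------------------------------------------------------
# conservation screen
# ---------------------------------------------------------------------------

_GAPS = {"-", "."}


def conservation_screen(
    alignment_fasta: str,
    reference_id: str,
    reference_residue_number: int,
    target_symbol: str = "C",
) -> AlignmentColumnReport:
    """Locate a reference residue's alignment column and read it down.

    ``reference_residue_number`` is 1-based into the *ungapped*
    reference sequence.  The report lists every sequence's symbol at
    that column; :attr:`AlignmentColumnReport.matching_ids` gives the
    sequences sharing the target symbol (default cysteine).
    """
    records = list(SeqIO.parse(io.StringIO(alignment_fasta), "fasta"))
    if not records:
        raise ValueError("empty alignment")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    ref = next((r for r in records if r.id == reference_id), None)
    if ref is None:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    if reference_residue_number < 1:
        raise ValueError("reference residue number must be >= 1")
    count = 0
    column = -1
    for i, sym in enumerate(str(ref.seq)):
        if sym not in _GAPS:
            count += 1
            if count == reference_residue_number:
                column = i
                break
    if column < 0:
        raise ValueError(
            f"{reference_id} has only {count} residues; "
            f"residue {reference_residue_number} is out of range"
        )
    symbols = [(r.id, str(r.seq)[column].upper()) for r in records]
    return AlignmentColumnReport(
        column_index=column,
        reference_id=reference_id,
        reference_residue_number=reference_residue_number,
        target_symbol=target_symbol.upper(),
        symbols=symbols,
    )
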