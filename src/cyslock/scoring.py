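"""Pocket–ligand scoring: Coulomb electrostatics + Lennard-Jones 6-12.

The score of a pose is the weighted sum of two pairwise terms over all
ligand-atom / pocket-atom pairs within a distance cutoff:

    E_es  = Σ 332.0637 · qᵢqⱼ / (ε · rᵢⱼ)            [kcal/mol]
    E_vdw = Σ 4 ε̄ᵢⱼ [ (σ̄ᵢⱼ/rᵢⱼ)¹² − (σ̄ᵢⱼ/rᵢⱼ)⁶ ]   [kcal/mol]

with a distance-independent dielectric ε and Lorentz–Berthelot
combining (σ̄ arithmetic mean, ε̄ geometric mean).  Clashed poses are
dominated by the r⁻¹² repulsion and score strongly positive; favorable
electrostatic and dispersion contacts drive the score negative — the
sign convention the screen ranks on.  No intra-ligand energy enters
the score: it measures fit to the pocket only.

The anchor Sγ and the cysteine Cβ are excluded from the pairwise sums
by default, since the ligand is covalently bonded through them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .confsearch import Conformer, ConformerSet
from .structures import Pocket

__all__ = [
    "COULOMB_CONSTANT",
    "ScoreBreakdown",
    "ScoringConfig",
    "ScoringError",
    "coulomb_energy",
    "lj_energy",
    "score_conformer",
    "score_set",
    "best_score",
    "coulomb_energy_arrays",
    "lj_energy_arrays",
]

COULOMB_CONSTANT = 332.0637  # kcal * A / (mol * e^2)


class ScoringError(RuntimeError):
    """Scoring attempted on unparameterized or singular geometry."""


@dataclass(frozen=True)
class ScoreBreakdown:
    """Energy terms of one scored conformer (kcal/mol)."""

    electrostatic: float
    vdw: float
    total: float
    conformer_index: int = 0


@dataclass(frozen=True)
class ScoringConfig:
    dielectric: float = 4.0  # distance-independent
    w_es: float = 1.0
    w_vdw: float = 1.0
    cutoff: float = 12.0  # A
    exclude_pocket_atoms: tuple[int, ...] | None = None  # None -> Sγ + CB

    def __post_init__(self) -> None:
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def _pocket_arrays(pocket: Pocket, config: ScoringConfig):
    if not pocket.parameterized:
        raise ScoringError("pocket atoms are not parameterized")
    exclude = config.exclude_pocket_atoms
    if exclude is None:
        exclude = (pocket.sg_index,) + (
            (pocket.cb_index,) if pocket.cb_index is not None else ()
        )
    keep = [i for i in range(len(pocket.atoms)) if i not in set(exclude)]
    q = np.array([pocket.atoms[i].partial_charge for i in keep])
    sig = np.array([pocket.atoms[i].lj_sigma for i in keep])
    eps = np.array([pocket.atoms[i].lj_epsilon for i in keep])
    xyz = np.array([pocket.atoms[i].xyz for i in keep])
    return q, sig, eps, xyz


def _ligand_arrays(conformer: Conformer):
    anc = conformer.anchored
    if anc.partial_charges is None:
        raise ScoringError("anchored ligand is not parameterized")
    idx = anc.ligand_atom_indices
    return (
        anc.partial_charges[idx],
        anc.lj_sigma[idx],
        anc.lj_epsilon[idx],
        conformer.coords[idx],
    )


# ---------------------------------------------------------------------------
# array-level terms (also the public building blocks for custom systems)
# ---------------------------------------------------------------------------

def coulomb_energy_arrays(
    q_lig: np.ndarray, xyz_lig: np.ndarray,
    q_pkt: np.ndarray, xyz_pkt: np.ndarray,
    dielectric: float = 4.0, cutoff: float = np.inf,
) -> float:
    """Pairwise Coulomb sum over ligand x pocket within ``cutoff``."""
    d = np.linalg.norm(xyz_lig[:, None, :] - xyz_pkt[None, :, :], axis=-1)
    with np.errstate(divide="ignore"):
        e = COULOMB_CONSTANT * np.outer(q_lig, q_pkt) / (dielectric * d)
    e[d > cutoff] = 0.0
    return float(e.sum())


def lj_energy_arrays(
    sig_lig: np.ndarray, eps_lig: np.ndarray, xyz_lig: np.ndarray,
    sig_pkt: np.ndarray, eps_pkt: np.ndarray, xyz_pkt: np.ndarray,
    cutoff: float = np.inf,
) -> float:
    """Pairwise LJ 6-12 sum with Lorentz–Berthelot combining."""
    d = np.linalg.norm(xyz_lig[:, None, :] - xyz_pkt[None, :, :], axis=-1)
    if np.any(d == 0.0):
        raise ScoringError("coincident ligand and pocket atoms (r = 0)")
    sig = 0.5 * (sig_lig[:, None] + sig_pkt[None, :])
    eps = np.sqrt(np.outer(eps_lig, eps_pkt))
    sr6 = (sig / d) ** 6
    e = 4.0 * eps * (sr6 * sr6 - sr6)
    e[d > cutoff] = 0.0
    return float(e.sum())


# ---------------------------------------------------------------------------
# conformer-level API
# ---------------------------------------------------------------------------

def coulomb_energy(
    conformer: Conformer, pocket: Pocket, config: ScoringConfig = ScoringConfig()
) -> float:
    q_p, _, _, xyz_p = _pocket_arrays(pocket, config)
    q_l, _, _, xyz_l = _ligand_arrays(conformer)
    return coulomb_energy_arrays(
        q_l, xyz_l, q_p, xyz_p, config.dielectric, config.cutoff
    )


def lj_energy(
    conformer: Conformer, pocket: Pocket, config: ScoringConfig = ScoringConfig()
) -> float:
    _, sig_p, eps_p, xyz_p = _pocket_arrays(pocket, config)
    _, sig_l, eps_l, xyz_l = _ligand_arrays(conformer)
    return lj_energy_arrays(
        sig_l, eps_l, xyz_l, sig_p, eps_p, xyz_p, config.cutoff
    )


def score_conformer(
    conformer: Conformer, pocket: Pocket,
    config: ScoringConfig = ScoringConfig(), conformer_index: int = 0,
) -> ScoreBreakdown:
    es = coulomb_energy(conformer, pocket, config)
    vdw = lj_energy(conformer, pocket, config)
    return ScoreBreakdown(
        electrostatic=es, vdw=vdw,
        total=config.w_es * es + config.w_vdw * vdw,
        conformer_index=conformer_index,
    )


def score_set(
    conf_set: ConformerSet, pocket: Pocket,
    config: ScoringConfig = ScoringConfig(),
) -> list[ScoreBreakdown]:
    """Score every conformer (vectorized across the set)."""
    if not conf_set.conformers:
        return []
    q_p, sig_p, eps_p, xyz_p = _pocket_arrays(pocket, config)
    anc = conf_set.anchored
    idx = anc.ligand_atom_indices
    q_l, sig_l, eps_l = (
        anc.partial_charges[idx], anc.lj_sigma[idx], anc.lj_epsilon[idx]
    )
    xyz = np.stack([c.coords[idx] for c in conf_set.conformers])  # (n, m, 3)
    d = np.linalg.norm(xyz[:, :, None, :] - xyz_p[None, None, :, :], axis=-1)
    if np.any(d == 0.0):
        raise ScoringError("coincident ligand and pocket atoms (r = 0)")
    mask = d <= config.cutoff
    with np.errstate(divide="ignore"):
        es_pair = COULOMB_CONSTANT * np.outer(q_l, q_p)[None] / (
            config.dielectric * d
        )
    sig = 0.5 * (sig_l[:, None] + sig_p[None, :])[None]
    eps = np.sqrt(np.outer(eps_l, eps_p))[None]
    sr6 = (sig / d) ** 6
    vdw_pair = 4.0 * eps * (sr6 * sr6 - sr6)
    es = (es_pair * mask).sum(axis=(1, 2))
    vdw = (vdw_pair * mask).sum(axis=(1, 2))
    total = config.w_es * es + config.w_vdw * vdw
    return [
        ScoreBreakdown(electrostatic=float(e), vdw=float(v), total=float(t),
                       conformer_index=i)
        for i, (e, v, t) in enumerate(zip(es, vdw, total))
    ]


def best_score(
    conf_set: ConformerSet, pocket: Pocket,
    config: ScoringConfig = ScoringConfig(),
) -> ScoreBreakdown:
    """Minimum-total breakdown; ties resolved to the lowest conformer index."""
    scores = score_set(conf_set, pocket, config)
    if not scores:
        raise ValueError("cannot take the best score of an empty conformer set")
    return min(scores, key=lambda s: (s.total, s.conformer_index))
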