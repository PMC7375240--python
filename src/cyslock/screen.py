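"""Library screening: warhead detection → covalent attachment → torsion
scan → scoring → ranking → top-fraction selection.

Every compound is docked once through its first detected warhead (the
match with the lowest β-carbon index).  Compounds without a warhead
cannot bond to the cysteine and are excluded from the ranking;
per-compound failures are recorded but never abort the screen.  The
whole pipeline is deterministic: identical inputs and configuration
give byte-identical output tables.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field

import pandas as pd

from . import confsearch, ligands, scoring
from .structures import Pocket

__all__ = [
    "ScreenConfig",
    "CompoundRecord",
    "ScreenResult",
    "run_screen",
    "select_top_fraction",
    "result_table",
    "write_result_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Everything a screen needs beyond the pocket and the library."""

    scoring: scoring.ScoringConfig = field(default_factory=scoring.ScoringConfig)
    increment_deg: float = 30.0
    cap: int = 10_000
    fraction: float = 0.10
    bond_length: float = 1.81  # S-Cβ, A
    min_internal_dist: float = 1.2  # intramolecular clash floor, A
    all_warheads: bool = False  # dock every warhead, keep the best


@dataclass
class CompoundRecord:
    compound_id: str
    status: str  # scored | no_warhead | failed
    best: scoring.ScoreBreakdown | None = None
    n_conformers: int = 0
    warhead: str | None = None
    detail: str = ""


@dataclass
class ScreenResult:
    records: list[CompoundRecord]
    ranking: list[str]  # scored compound ids, ascending best total
    selected: list[str]
    fraction: float

    @property
    def n_scored(self) -> int:
        return len(self.ranking)

    def record(self, compound_id: str) -> CompoundRecord:
        return next(r for r in self.records if r.compound_id == compound_id)


def _dock_one(
    ligand: ligands.Ligand, match: ligands.WarheadMatch,
    pocket: Pocket, config: ScreenConfig,
) -> tuple[scoring.ScoreBreakdown, int]:
    anchored = ligands.apply_michael_addition(ligand, match)
    anchored.anchor_bond_length = config.bond_length
    start = confsearch.place_anchor(anchored, pocket, config.bond_length)
    conf_set = confsearch.enumerate_conformers(
        start, config.increment_deg, config.cap
    )
    conf_set = confsearch.prune_internal_clashes(
        conf_set, config.min_internal_dist
    )
    best = scoring.best_score(conf_set, pocket, config.scoring)
    return best, len(conf_set)


def run_screen(
    library: list[ligands.Ligand] | str,
    pocket: Pocket,
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Screen a ligand library against a parameterized pocket.

    ``library`` may be a list of parsed ligands or raw SMILES-library
    text (one molecule per line, optional tab-separated id).
    """
    if isinstance(library, str):
        library = ligands.parse_smiles_library(library)
    if not library:
        raise ValueError("empty ligand library")
    if not pocket.parameterized:
        raise ValueError("pocket must be parameterized before screening")

    records: list[CompoundRecord] = []
    for lig in library:
        t0 = time.perf_counter()
        matches = ligands.detect_warheads(lig)
        if not matches:
            records.append(CompoundRecord(lig.id, "no_warhead"))
            logger.info("%s: no warhead", lig.id)
            continue
        todo = matches if config.all_warheads else matches[:1]
        best: scoring.ScoreBreakdown | None = None
        n_conf = 0
        used = None
        try:
            for match in todo:
                b, n = _dock_one(lig, match, pocket, config)
                n_conf += n
                if best is None or b.total < best.total:
                    best, used = b, match.pattern_id
            records.append(
                CompoundRecord(lig.id, "scored", best=best,
                               n_conformers=n_conf, warhead=used)
            )
            logger.info(
                "%s: %d conformers, best %.3f kcal/mol (%.2f s)",
                lig.id, n_conf, best.total, time.perf_counter() - t0,
            )
        except Exception as exc:  # per-compound failure must not abort
            records.append(
                CompoundRecord(lig.id, "failed", detail=str(exc))
            )
            logger.warning("%s: failed (%s)", lig.id, exc)

    scored = [r for r in records if r.status == "scored"]
    ranking = [
        r.compound_id
        for r in sorted(scored, key=lambda r: (r.best.total, r.compound_id))
    ]
    result = ScreenResult(
        records=records, ranking=ranking, selected=[], fraction=config.fraction
    )
    result.selected = select_top_fraction(result, config.fraction)
    return result


def select_top_fraction(result: ScreenResult, fraction: float = 0.10) -> list[str]:
    """The first ceil(fraction x n_scored) ids of the ranking.

    The ranking itself already breaks score ties by ascending compound
    id, so boundary ties resolve by ranking order.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = math.ceil(fraction * len(result.ranking))
    return result.ranking[:n]


def result_table(result: ScreenResult) -> pd.DataFrame:
    nan = float("nan")
    rank_of = {cid: i + 1 for i, cid in enumerate(result.ranking)}
    rows = [
        {
            "compound_id": r.compound_id,
            "status": r.status,
            "rank": rank_of.get(r.compound_id, nan),
            "best_total": r.best.total if r.best else nan,
            "electrostatic": r.best.electrostatic if r.best else nan,
            "vdw": r.best.vdw if r.best else nan,
            "conformer_index": r.best.conformer_index if r.best else nan,
            "n_conformers": r.n_conformers,
            "warhead": r.warhead or "",
            "selected": r.compound_id in result.selected,
        }
        for r in result.records
    ]
    df = pd.DataFrame(rows)
    df["rank"] = df["rank"].astype("Int64")
    df["conformer_index"] = df["conformer_index"].astype("Int64")
    return df.sort_values(
        "rank", na_position="last", kind="stable"
    ).reset_index(drop=True)


def write_result_tsv(result: ScreenResult) -> str:
    df = result_table(result)
    return df.to_csv(sep="\t", index=False, float_format="%.6f")
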