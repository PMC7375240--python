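"""Covalent-modification evidence: adduct masses, tryptic digestion and
NMR chemical-shift-perturbation (CSP) classification.

A covalent inhibitor announces itself twice in the wet lab: mass
spectrometry sees the modified tryptic peptide shifted by exactly the
adduct's monoisotopic mass (for a Michael addition, the whole parent
compound — no leaving group), and HSQC/TROSY NMR sees amide resonances
near the modification site move or vanish.  This module implements the
desk side of both checks.

Masses come from pyteomics' IUPAC atomic-mass tables; digestion follows
the standard trypsin rule (cleave C-terminal to K/R, suppressed before
P); CSP combines ¹H and ¹⁵N shift changes as

    Δδ = sqrt(Δδ_H² + (w_N · Δδ_N)²),  w_N = 0.2 by default.
"""

from __future__ import annotations

import io
import itertools
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from pyteomics import mass as _pmass
from pyteomics.auxiliary import PyteomicsError

__all__ = [
    "ElementalFormula",
    "PeptideRecord",
    "PeakList",
    "CSPRecord",
    "PerturbationSummary",
    "formula_mass",
    "tryptic_digest",
    "match_adduct",
    "compute_csp",
    "classify_perturbations",
    "rhoa_sequence",
]

CSP_THRESHOLD = 0.05  # ppm, combined; strictly-greater counts as perturbed

_AA = set("ACDEFGHIKLMNPQRSTVWY")
_HILL_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalFormula:
    """Element→count map with Hill-notation parsing and display."""

    def __init__(self, counts: dict[str, int] | str):
        if isinstance(counts, str):
            counts = self._parse(counts)
        bad = [e for e, c in counts.items() if c < 1]
        if bad:
            raise ValueError(f"non-positive element counts: {bad}")
        for e in counts:
            if e not in _pmass.nist_mass:
                raise ValueError(f"unrecognized element {e!r}")
        self.counts = dict(counts)

    @staticmethod
    def _parse(text: str) -> dict[str, int]:
        if not re.fullmatch(r"(?:[A-Z][a-z]?\d*)*", text):
            raise ValueError(f"cannot parse formula {text!r}")
        counts: dict[str, int] = {}
        for sym, num in _HILL_TOKEN.findall(text):
            if not sym:
                continue
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        return counts

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical (alphabetical if no carbon)
        elems = sorted(self.counts)
        if "C" in self.counts:
            elems = ["C"] + (["H"] if "H" in self.counts else []) + [
                e for e in elems if e not in ("C", "H")
            ]
        return "".join(
            f"{e}{self.counts[e] if self.counts[e] > 1 else ''}" for e in elems
        )

    def __repr__(self) -> str:
        return f"ElementalFormula({str(self)!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, ElementalFormula) and self.counts == other.counts

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for e, c in other.counts.items():
            merged[e] = merged.get(e, 0) + c
        return ElementalFormula(merged)


def formula_mass(
    formula: ElementalFormula | str, kind: str = "monoisotopic"
) -> float:
    """Mass of an elemental formula in Da (``monoisotopic`` or ``average``)."""
    if kind not in ("monoisotopic", "average"):
        raise ValueError(f"kind must be monoisotopic or average, got {kind!r}")
    if isinstance(formula, str):
        formula = ElementalFormula(formula)
    if not formula.counts:
        return 0.0
    try:
        return float(
            _pmass.calculate_mass(formula=str(formula),
                                  average=(kind == "average"))
        )
    except PyteomicsError as exc:
        raise ValueError(str(exc)) from None


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeptideRecord:
    """One tryptic peptide with 1-based inclusive parent coordinates."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int

    def monoisotopic_mass(self) -> float:
        return float(_pmass.calculate_mass(sequence=self.sequence))

    def contains(self, residue_number: int) -> bool:
        return self.start <= residue_number <= self.end


def tryptic_digest(sequence: str, max_missed: int = 0) -> list[PeptideRecord]:
    """In-silico trypsin: cleave after K/R except before P.

    Emits every peptide with at most ``max_missed`` missed cleavages,
    ordered by start position (then length).
    """
    sequence = sequence.strip().upper()
    bad = sorted(set(sequence) - _AA)
    if bad:
        raise ValueError(f"invalid residue symbols: {''.join(bad)}")
    if not sequence:
        return []
    # cut points AFTER these 0-based positions
    cuts = [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    bounds = [0] + [c + 1 for c in cuts] + [len(sequence)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            start, end = bounds[i], bounds[j]
            peptides.append(
                PeptideRecord(
                    sequence=sequence[start:end],
                    start=start + 1,
                    end=end,
                    missed_cleavages=j - i - 1,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def rhoa_sequence() -> str:
    """The packaged human RhoA sequence (residues 1-193, UniProt P61586)."""
    text = resources.files("cyslock.data").joinpath("rhoa_p61586.fasta").read_text()
    return "".join(
        line.strip() for line in text.splitlines() if not line.startswith(">")
    )


# ---------------------------------------------------------------------------
# adduct matching
# ---------------------------------------------------------------------------

def match_adduct(
    observed_delta: float,
    candidate_formulas: list[ElementalFormula | str],
    tol_ppm: float = 10.0,
    base_mass: float = 1500.0,
) -> list[tuple[ElementalFormula, float, float]]:
    """Rank candidate adduct formulas against an observed mass shift.

    The ppm tolerance is converted to Da on ``base_mass`` (the
    unmodified peptide mass, since the instrument error scales with the
    measured m/z, not with the shift).  Returns (formula, monoisotopic
    mass, signed error) tuples sorted by |error|, stable for ties.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if base_mass <= 0:
        raise ValueError("base_mass must be positive")
    tol_da = tol_ppm * 1e-6 * base_mass
    out = []
    for f in candidate_formulas:
        formula = ElementalFormula(f) if isinstance(f, str) else f
        m = formula_mass(formula)
        err = m - observed_delta
        if abs(err) <= tol_da:
            out.append((formula, m, err))
    out.sort(key=lambda t: abs(t[2]))
    return out


# ---------------------------------------------------------------------------
# chemical shift perturbation
# ---------------------------------------------------------------------------

@dataclass
class PeakList:
    """HSQC peak list: one row per assigned backbone amide."""

    table: pd.DataFrame  # columns: residue_number, h_ppm, n_ppm, intensity

    COLUMNS = ("residue_number", "h_ppm", "n_ppm", "intensity")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"peak list missing columns: {sorted(missing)}")
        dup = self.table["residue_number"].duplicated()
        if dup.any():
            dupes = sorted(self.table.loc[dup, "residue_number"].unique())
            raise ValueError(f"duplicated residue rows: {dupes}")
        if (self.table["intensity"] < 0).any():
            raise ValueError("negative peak intensity")

    @classmethod
    def from_tsv(cls, text: str) -> "PeakList":
        df = pd.read_csv(io.StringIO(text), sep="\t")
        df.columns = [c.strip().lower() for c in df.columns]
        rename = {"residue": "residue_number"}
        df = df.rename(columns=rename)
        return cls(df[list(cls.COLUMNS)].astype(
            {"residue_number": int, "h_ppm": float, "n_ppm": float,
             "intensity": float}
        ))

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False, float_format="%.6f")

    @property
    def residues(self) -> set[int]:
        return set(self.table["residue_number"])


@dataclass
class CSPRecord:
    residue_number: int
    csp: float | None  # ppm; None when the bound peak vanished
    attenuated: bool
    perturbed: bool = False


@dataclass
class PerturbationSummary:
    records: list[CSPRecord]
    threshold: float
    perturbed_residues: list[int]
    segments: list[tuple[int, int]]  # maximal runs of consecutive residues


def compute_csp(
    apo: PeakList,
    bound: PeakList,
    n_weight: float = 0.2,
    attenuation_floor: float = 0.2,
) -> list[CSPRecord]:
    """Per-residue combined ¹H/¹⁵N shift change between apo and bound.

    Residues present in both lists get Δδ = sqrt(Δδ_H² + (w·Δδ_N)²)
    and an attenuation flag (bound/apo intensity ratio below
    ``attenuation_floor``).  Residues whose peak disappears from the
    bound list are flagged attenuated with undefined CSP — the NMR
    signature of strong local perturbation or exchange broadening.
    """
    a = apo.table.set_index("residue_number")
    b = bound.table.set_index("residue_number")
    shared = sorted(set(a.index) & set(b.index))
    if not shared:
        raise ValueError("peak lists share no residues")
    records = []
    for res in sorted(a.index):
        if res in b.index:
            dh = float(b.loc[res, "h_ppm"] - a.loc[res, "h_ppm"])
            dn = float(b.loc[res, "n_ppm"] - a.loc[res, "n_ppm"])
            csp = (dh * dh + (n_weight * dn) ** 2) ** 0.5
            apo_int = float(a.loc[res, "intensity"])
            ratio = (
                float(b.loc[res, "intensity"]) / apo_int
                if apo_int > 0
                else float("inf")
            )
            records.append(
                CSPRecord(res, csp, attenuated=ratio < attenuation_floor)
            )
        else:
            records.append(CSPRecord(res, None, attenuated=True))
    return records


def classify_perturbations(
    records: list[CSPRecord], threshold: float = CSP_THRESHOLD
) -> PerturbationSummary:
    """Flag perturbed residues and summarize them as contiguous segments.

    A residue is perturbed iff its CSP is strictly greater than
    ``threshold`` or its peak is attenuated/vanished.  Segments are
    maximal runs of consecutive residue numbers among the perturbed.
    """
    perturbed = []
    for r in records:
        r.perturbed = r.attenuated or (r.csp is not None and r.csp > threshold)
        if r.perturbed:
            perturbed.append(r.residue_number)
    perturbed.sort()
    segments = []
    for _, grp in itertools.groupby(
        enumerate(perturbed), key=lambda t: t[1] - t[0]
    ):
        run = [res for _, res in grp]
        segments.append((run[0], run[-1]))
    return PerturbationSummary(
        records=records, threshold=threshold,
        perturbed_residues=perturbed, segments=segments,
    )
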