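"""Peptide mass computation and cross-platform mass alignment.

Theoretical singly protonated masses ([M+H]+) are computed from residue
elemental compositions in two regimes: monoisotopic (reflector-mode and
ESI data, isotopically resolved) and average (linear-mode signals, whose
broad peaks integrate the whole isotope envelope).  Observed masses from
the three platforms are aligned by ppm tolerance: each linear-mode (LM)
profiling label is matched to the nearest reflector-mode (RM) peak, and
the RM mass is matched against the theoretical monoisotopic [M+H]+ of
every ESI-identified peptide; multiple candidates inside the tolerance
flag the signal as ambiguous.  Cysteine is treated as the free thiol and
the only supported modification is N-terminal acetylation, matching the
no-enzyme, no-fixed-modification search space of endogenous urinary
peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "PeptideRecord",
    "PeptideMatch",
    "RESIDUE_FORMULAS",
    "peptide_mh",
    "ppm_error",
    "align_platforms",
    "mme_summary",
    "load_reference_identifications",
]

# Monoisotopic masses: most abundant isotopes.  Average masses: CODATA-2005
# standard atomic weights (C 12.0107 etc.), the table in long-standing use
# by MS vendor software for average peptide masses.
ELEMENT_MONO = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052,
                "O": 15.9949146221, "S": 31.97207069}
ELEMENT_AVG = {"C": 12.0107, "H": 1.00794, "N": 14.0067,
               "O": 15.9994, "S": 32.065}

# residue (= amino acid minus water) compositions, (C, H, N, O, S)
RESIDUE_FORMULAS = {
    "G": (2, 3, 1, 1, 0), "A": (3, 5, 1, 1, 0), "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0), "V": (5, 9, 1, 1, 0), "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1), "L": (6, 11, 1, 1, 0), "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0), "D": (4, 5, 1, 3, 0), "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0), "E": (5, 7, 1, 3, 0), "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0), "F": (9, 9, 1, 1, 0), "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0), "W": (11, 10, 2, 1, 0),
}
_WATER = (0, 2, 0, 1, 0)
_ACETYL = (2, 2, 0, 1, 0)  # N-terminal acetylation, net +C2H2O
PROTON = 1.007276

_MODS = {None: None, "none": None, "": None, "acetyl": _ACETYL,
         "N-acetylation": _ACETYL}


def _mass(comp, kind: str) -> float:
    table = {"mono": ELEMENT_MONO, "average": ELEMENT_AVG}[kind]
    return sum(n * table[el] for n, el in zip(comp, "CHNOS"))


def peptide_mh(sequence: str, n_term_mod: str | None = None, kind: str = "mono") -> float:
    """Theoretical [M+H]+ of a peptide in Da.

    ``kind`` is ``"mono"`` (monoisotopic) or ``"average"``;
    ``n_term_mod`` is ``None`` or ``"acetyl"``.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    if kind not in ("mono", "average"):
        raise ValueError(f"kind must be 'mono' or 'average', got {kind!r}")
    if n_term_mod not in _MODS:
        raise ValueError(f"unknown N-terminal modification {n_term_mod!r}")
    comp = list(_WATER)
    for pos, aa in enumerate(sequence, start=1):
        try:
            res = RESIDUE_FORMULAS[aa]
        except KeyError:
            raise ValueError(
                f"unknown residue {aa!r} at position {pos} of {sequence!r}"
            ) from None
        comp = [c + r for c, r in zip(comp, res)]
    mod = _MODS[n_term_mod]
    if mod is not None:
        comp = [c + m for c, m in zip(comp, mod)]
    return _mass(comp, kind) + PROTON


def ppm_error(observed: float, reference: float) -> float:
    """Signed mass measurement error: (observed - reference) / reference * 1e6."""
    if reference <= 0:
        raise ValueError("reference mass must be positive")
    return (observed - reference) / reference * 1e6


@dataclass(frozen=True)
class PeptideRecord:
    """One ESI-identified endogenous peptide."""

    sequence: str
    n_term_mod: str | None = None
    charge_observed: int = 1
    experimental_mh: float = float("nan")  # singly protonated, from ESI
    protein_id: str = ""
    start: int = 0
    stop: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = [a for a in self.sequence if a not in RESIDUE_FORMULAS]
        if bad:
            raise ValueError(f"non-standard residues {bad} in {self.sequence!r}")
        if self.start and self.stop and self.stop - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"{self.protein_id}: residue span {self.start}-{self.stop} "
                f"does not match sequence length {len(self.sequence)}"
            )

    @property
    def theo_mono_mh(self) -> float:
        return peptide_mh(self.sequence, self.n_term_mod, "mono")

    @property
    def theo_avg_mh(self) -> float:
        return peptide_mh(self.sequence, self.n_term_mod, "average")


@dataclass
class PeptideMatch:
    """One LM profiling signal aligned through RM to ESI identifications."""

    lm_mz: float
    rm_mz: float
    candidates: list  # PeptideRecord, all within tolerance
    mme_lm_ppm: list = field(default_factory=list)  # LM vs theoretical average
    mme_rm_ppm: list = field(default_factory=list)  # RM vs theoretical mono
    esi_vs_rm_ppm: list = field(default_factory=list)  # ESI experimental vs RM

    def __post_init__(self) -> None:
        self.mme_lm_ppm = [ppm_error(self.lm_mz, c.theo_avg_mh) for c in self.candidates]
        self.mme_rm_ppm = [ppm_error(self.rm_mz, c.theo_mono_mh) for c in self.candidates]
        self.esi_vs_rm_ppm = [ppm_error(c.experimental_mh, self.rm_mz) for c in self.candidates]

    @property
    def ambiguous(self) -> bool:
        return len(self.candidates) > 1


def align_platforms(
    lm_peaks,
    rm_peaks,
    esi_records,
    tol_lm_ppm: float = 1000.0,
    tol_rm_ppm: float = 100.0,
) -> list[PeptideMatch]:
    """Three-platform alignment LM -> RM -> ESI theoretical masses.

    Each LM label gets the nearest RM peak within ``tol_lm_ppm`` (linear
    mode is recalibrated to 1000 ppm, hence the wide default); each
    matched RM peak collects every ESI record whose theoretical
    monoisotopic [M+H]+ lies within ``tol_rm_ppm``.  All candidates are
    retained, so near-isobaric identifications surface as ambiguous
    matches rather than silent choices.
    """
    if tol_lm_ppm <= 0 or tol_rm_ppm <= 0:
        raise ValueError("tolerances must be positive")
    matches = []
    rm_peaks = sorted(float(x) for x in rm_peaks)
    for lm in lm_peaks:
        lm = float(lm)
        in_tol = [rm for rm in rm_peaks if abs(ppm_error(rm, lm)) <= tol_lm_ppm]
        if not in_tol:
            continue
        rm = min(in_tol, key=lambda x: abs(x - lm))
        cands = [r for r in esi_records
                 if abs(ppm_error(rm, r.theo_mono_mh)) <= tol_rm_ppm]
        if cands:
            matches.append(PeptideMatch(lm, rm, cands))
    return matches


def mme_summary(matches: list[PeptideMatch]) -> dict:
    """Integer-rounded extremes of each signed ppm error across all matches."""
    if not matches:
        raise ValueError("no matches to summarize")
    out = {}
    for name in ("mme_lm_ppm", "mme_rm_ppm", "esi_vs_rm_ppm"):
        vals = [v for m in matches for v in getattr(m, name)]
        out[name] = (round(min(vals)), round(max(vals)))
    return out


def load_reference_identifications() -> pd.DataFrame:
    """The shipped identification list of the eight urinary peptide fragments.

    Columns mirror the cross-platform identification layout: LM/RM
    observed m/z, ESI experimental [M+H]+, charge, sequence, N-terminal
    modification and parent-protein coordinates.
    """
    with resources.files("peptidome.data").joinpath("identified_peptides.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["n_term_mod"] = df["n_term_mod"].where(df["n_term_mod"].notna(), None)
    return df


def records_from_frame(df: pd.DataFrame) -> list[PeptideRecord]:
    return [
        PeptideRecord(
            sequence=row.sequence,
            n_term_mod=(None if pd.isna(row.n_term_mod) or not row.n_term_mod
                        else row.n_term_mod),
            charge_observed=int(row.charge),
            experimental_mh=float(row.experimental_mh),
            protein_id=row.protein_id,
            start=int(row.start),
            stop=int(row.stop),
        )
        for row in df.itertuples()
    ]
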