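"""Alpha-diversity indices over genus abundance vectors.

Six closed-form indices, all using natural logarithms, for a stratum with
``S`` genera, counts ``Ni``, total ``Nt`` and frequencies ``Pi = Ni/Nt``:

=====================  =======================================================
Margalef richness      D' = (S - 1) / ln Nt
Shannon–Wiener         H' = -Σ Pi ln Pi                    (nats)
Simpson diversity      Ds = 1 - Σ Pi²
Simpson dominance      λ  = Σ Pi²            (so λ + Ds = 1)
PIE                    Σ (Ni/Nt) (Nt - Ni)/(Nt - 1)  = Nt/(Nt-1) · Ds
Pielou evenness        J  = H' / ln S
=====================  =======================================================

Degenerate strata yield NaN with a machine-readable flag instead of raising:
``J`` is undefined when S = 1 (ln 1 = 0) and ``D'``/``PIE`` when Nt = 1, so a
full per-tissue grid always renders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import PLANTS, TISSUES, AbundanceVector, IsolateCatalog, tabulate_abundance
from .errors import EmptyStratumError

#: flag names for index values that are undefined on a degenerate stratum
UNDEFINED_J = "undefined_J"
UNDEFINED_D = "undefined_D"
UNDEFINED_PIE = "undefined_PIE"

INDEX_ROWS = (
    "S",
    "margalef",
    "shannon",
    "simpson",
    "pie",
    "dominance",
    "pielou",
)

#: Cells of the original survey's published diversity grid that the stated
#: formulas do not reproduce.  The P. ternata root stratum has S=5 genera and
#: Nt=6 isolates, so (S-1)/ln Nt = 2.2324, but the survey prints 2.7906
#: (= 5/ln 6, i.e. a richness of 6 — species rather than genus rank).  The
#: package always reports the formula value and annotates the discrepancy.
KNOWN_PRINTED_DISCREPANCIES: dict[tuple[str, str, str], float] = {
    ("PT", "root", "margalef"): 2.7906,
}

#: presentation labels, Table-style
INDEX_LABELS = {
    "S": "Species richness (S)",
    "margalef": "Margalef index (D')",
    "shannon": "Shannon-Wiener index (H')",
    "simpson": "Simpson diversity index (Ds)",
    "pie": "PIE index (PIE)",
    "dominance": "Dominant index (lambda)",
    "pielou": "Pielou index (J)",
}


@dataclass(frozen=True)
class DiversityIndices:
    """The seven per-stratum statistics (S plus six indices)."""

    stratum: tuple[str | None, str | None]
    s: int
    margalef: float
    shannon: float
    simpson: float
    dominance: float
    pie: float
    pielou: float
    flags: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {
            "S": self.s,
            "margalef": self.margalef,
            "shannon": self.shannon,
            "simpson": self.simpson,
            "pie": self.pie,
            "dominance": self.dominance,
            "pielou": self.pielou,
        }


def compute_indices(abundance: AbundanceVector) -> DiversityIndices:
    """All indices for one abundance vector (natural logs throughout)."""
    counts = np.asarray(list(abundance.counts.values()), dtype=float)
    nt = counts.sum()
    s = len(counts)
    pi = counts / nt
    shannon = float(-(pi * np.log(pi)).sum())
    lam = float((pi**2).sum())
    simpson = 1.0 - lam
    flags = set()
    if nt > 1:
        margalef = (s - 1) / math.log(nt)
        pie = float((counts / nt * (nt - counts) / (nt - 1)).sum())
    else:
        margalef = math.nan
        pie = math.nan
        flags.update({UNDEFINED_D, UNDEFINED_PIE})
    if s > 1:
        pielou = shannon / math.log(s)
    else:
        pielou = math.nan
        flags.add(UNDEFINED_J)
    return DiversityIndices(
        stratum=abundance.stratum,
        s=s,
        margalef=margalef,
        shannon=shannon,
        simpson=simpson,
        dominance=lam,
        pie=pie,
        pielou=pielou,
        flags=frozenset(flags),
    )


def diversity_table(catalog: IsolateCatalog) -> dict[tuple[str, str], DiversityIndices]:
    """One :class:`DiversityIndices` per (plant, tissue) stratum present.

    Strata with zero isolates are omitted (the survey simply found nothing
    there), never errors.
    """
    out: dict[tuple[str, str], DiversityIndices] = {}
    for plant in PLANTS:
        for tissue in TISSUES:
            try:
                ab = tabulate_abundance(catalog, plant=plant, tissue=tissue)
            except EmptyStratumError:
                continue
            out[(plant, tissue)] = compute_indices(ab)
    return out


def diversity_frame(catalog: IsolateCatalog) -> pd.DataFrame:
    """Full-precision grid: index rows x (plant, tissue) stratum columns."""
    table = diversity_table(catalog)
    cols = {}
    for (plant, tissue), idx in table.items():
        cols[(plant, tissue)] = idx.as_dict()
    df = pd.DataFrame(cols, index=list(INDEX_ROWS))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["plant", "tissue"])
    return df


def format_table(df: pd.DataFrame, digits: int = 4) -> pd.DataFrame:
    """Presentation copy rounded half-even to ``digits`` decimals (S stays int)."""
    out = df.copy()
    for row in out.index:
        if row == "S":
            out.loc[row] = out.loc[row].astype(int)
        else:
            out.loc[row] = np.round(out.loc[row].astype(float), digits)
    return out
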