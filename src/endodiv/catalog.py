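"""Isolate catalog: the culturable-survey table and genus abundance tabulation.

The catalog is one row per purified isolate: strain code, host plant
(*Pinellia ternata* ``PT`` or *P. pedatisecta* ``PP``), the tissue it was
cultured from, and the closest ITS match it was identified as.  All community
statistics downstream work at genus rank, where the genus is the first token
of the closest-match binomial.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

from .errors import EmptyStratumError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

PLANTS = ("PT", "PP")
TISSUES = ("root", "stem", "leaf", "tuber")
PLANT_NAMES = {"PT": "Pinellia ternata", "PP": "Pinellia pedatisecta"}

#: required columns of a catalog file, in canonical order
SCHEMA = (
    "strain_code",
    "plant",
    "tissue",
    "closest_match",
    "match_accession",
    "coverage_pct",
    "identity_pct",
    "own_accession",
)


def genus_of(binomial: str) -> str:
    """Genus of a ``Genus epithet`` binomial: its first whitespace token.

    A bare ``Genus sp.`` identification yields the genus; surrounding
    whitespace is ignored.
    """
    if binomial is None or not str(binomial).strip():
        raise ValidationError("empty binomial: cannot derive a genus")
    return str(binomial).split()[0]


@dataclass(frozen=True)
class IsolateRecord:
    """One row of the survey table."""

    strain_code: str
    plant: str
    tissue: str
    closest_match: str
    match_accession: str
    coverage_pct: float
    identity_pct: float
    own_accession: str
    species_class: str | None = None

    def __post_init__(self) -> None:
        if self.plant not in PLANTS:
            raise ValidationError(
                f"{self.strain_code}: unknown plant code {self.plant!r} "
                f"(expected one of {PLANTS})"
            )
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"{self.strain_code}: unknown tissue {self.tissue!r} "
                f"(expected one of {TISSUES})"
            )
        if not (0 <= self.coverage_pct <= 100) or not (0 <= self.identity_pct <= 100):
            raise ValidationError(
                f"{self.strain_code}: coverage/identity must lie in [0, 100]"
            )
        genus_of(self.closest_match)  # raises on empty

    @property
    def genus(self) -> str:
        return genus_of(self.closest_match)


@dataclass(frozen=True)
class IsolateCatalog:
    """Ordered collection of isolate records with unique strain codes."""

    records: tuple[IsolateRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = Counter(r.strain_code for r in self.records)
        dupes = sorted(code for code, k in seen.items() if k > 1)
        if dupes:
            raise ValidationError(f"duplicate strain_code(s): {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[IsolateRecord]:
        return iter(self.records)

    def filter(self, plant: str | None = None, tissue: str | None = None) -> "IsolateCatalog":
        """Subset by plant and/or tissue; filters of ``None`` keep everything."""
        if plant is not None and plant not in PLANTS:
            raise ValidationError(f"unknown plant filter {plant!r}")
        if tissue is not None and tissue not in TISSUES:
            raise ValidationError(f"unknown tissue filter {tissue!r}")
        kept = tuple(
            r
            for r in self.records
            if (plant is None or r.plant == plant)
            and (tissue is None or r.tissue == tissue)
        )
        return replace(self, records=kept)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {c: getattr(r, c) for c in SCHEMA} | {"genus": r.genus}
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(SCHEMA) + ["genus"])


@dataclass(frozen=True)
class AbundanceVector:
    """Genus -> isolate count within one stratum.

    ``counts`` maps each genus to its Ni (positive); Nt is the stratum total
    and Pi the relative frequencies Ni/Nt.  Genus order is lexicographic.
    """

    stratum: tuple[str | None, str | None]
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            raise EmptyStratumError(
                f"stratum {self.stratum}: no isolates; diversity is undefined"
            )
        bad = {g: n for g, n in self.counts.items() if int(n) != n or n < 1}
        if bad:
            raise ValidationError(f"non-positive genus counts: {bad}")
        object.__setattr__(
            self, "counts", dict(sorted((g, int(n)) for g, n in self.counts.items()))
        )

    @property
    def nt(self) -> int:
        return sum(self.counts.values())

    @property
    def s(self) -> int:
        return len(self.counts)

    @property
    def pi(self) -> dict[str, float]:
        nt = self.nt
        return {g: n / nt for g, n in self.counts.items()}


def read_catalog(path: str | Path, dialect: str | None = None) -> IsolateCatalog:
    """Read a catalog TSV/CSV.

    The dialect is taken from the file suffix unless given explicitly.  A
    header naming every schema column is required; extra columns (such as an
    optional ``species_class``) are carried through.
    """
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if dialect not in ("tsv", "csv"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("%s: catalog has a header but no data rows", path)
        return IsolateCatalog(records=(), provenance=str(path))
    records = []
    for _, row in df.iterrows():
        records.append(
            IsolateRecord(
                strain_code=row["strain_code"],
                plant=row["plant"],
                tissue=row["tissue"],
                closest_match=row["closest_match"],
                match_accession=row["match_accession"],
                coverage_pct=float(row["coverage_pct"]),
                identity_pct=float(row["identity_pct"]),
                own_accession=row["own_accession"],
                species_class=row.get("species_class"),
            )
        )
    return IsolateCatalog(records=tuple(records), provenance=str(path))


def write_catalog(catalog: IsolateCatalog, path: str | Path, dialect: str | None = None) -> None:
    """Write a catalog back out; ``read_catalog`` round-trips it."""
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "\t" if dialect == "tsv" else ","
    df = catalog.to_frame().drop(columns=["genus"])
    # coverage/identity were read as text; render integers without a decimal
    for col in ("coverage_pct", "identity_pct"):
        df[col] = [f"{v:g}" for v in df[col].astype(float)]
    df.to_csv(path, sep=sep, index=False)


def tabulate_abundance(
    catalog: IsolateCatalog,
    plant: str | None = None,
    tissue: str | None = None,
) -> AbundanceVector:
    """Genus abundance vector over the (optionally filtered) catalog."""
    sub = catalog.filter(plant=plant, tissue=tissue)
    if len(sub) == 0:
        raise EmptyStratumError(
            f"no isolates for plant={plant!r}, tissue={tissue!r}"
        )
    return AbundanceVector(
        stratum=(plant, tissue), counts=Counter(r.genus for r in sub)
    )


@dataclass(frozen=True)
class CatalogSummary:
    """Headline counts over a catalog."""

    n_isolates: int
    n_genera: int
    isolates_per_plant: dict[str, int]
    isolates_per_tissue: dict[str, int]
    genera_per_tissue: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_isolates": self.n_isolates,
            "n_genera": self.n_genera,
            "isolates_per_plant": dict(self.isolates_per_plant),
            "isolates_per_tissue": dict(self.isolates_per_tissue),
            "genera_per_tissue": dict(self.genera_per_tissue),
        }


def summary_counts(catalog: IsolateCatalog) -> CatalogSummary:
    """Per-plant and per-tissue isolate totals and distinct-genus counts.

    Per-tissue figures pool both host plants.
    """
    per_plant = {p: 0 for p in PLANTS}
    per_tissue = {t: 0 for t in TISSUES}
    genera_per_tissue: dict[str, set] = {t: set() for t in TISSUES}
    genera: set[str] = set()
    for r in catalog:
        per_plant[r.plant] += 1
        per_tissue[r.tissue] += 1
        genera_per_tissue[r.tissue].add(r.genus)
        genera.add(r.genus)
    return CatalogSummary(
        n_isolates=len(catalog),
        n_genera=len(genera),
        isolates_per_plant=per_plant,
        isolates_per_tissue=per_tissue,
        genera_per_tissue={t: len(g) for t, g in genera_per_tissue.items()},
    )
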