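"""Packaged survey transcriptions.

Three small TSVs ship with the package: the 77-isolate survey catalog, the
radicle-inhibition screen of all 77 fermentation broths, and the
disc-diffusion/MIC panel of the seven purified compounds plus the gentamicin
positive control.  The real deposited ITS sequences (GenBank ON677855 to
ON677931) are referenced by accession in the catalog but are never fetched;
the phylogeny stage runs on synthetic alignments from :mod:`endodiv.simulate`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .bioactivity import InhibitionResult, ZoneRecord, read_phytotoxicity, read_zone_table
from .catalog import IsolateCatalog, read_catalog


def _data_path(name: str) -> Path:
    return Path(resources.files("endodiv").joinpath("data", name))


def isolate_catalog_path() -> Path:
    return _data_path("pinellia_isolates.tsv")


def phytotoxicity_path() -> Path:
    return _data_path("phytotoxicity_screen.tsv")


def zone_table_path() -> Path:
    return _data_path("compound_zones.tsv")


def load_isolate_catalog() -> IsolateCatalog:
    """The packaged 77-isolate *Pinellia* survey catalog."""
    return read_catalog(isolate_catalog_path())


def load_phytotoxicity() -> list[InhibitionResult]:
    """Radicle inhibition rates of the 77 fermentation broths."""
    return read_phytotoxicity(phytotoxicity_path())


def load_zone_table() -> list[ZoneRecord]:
    """IZD/MIC panel of compounds 1-7 and the positive control."""
    return read_zone_table(zone_table_path())
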