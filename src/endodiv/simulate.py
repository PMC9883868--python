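"""Synthetic-data generators mirroring the survey's input structure.

Three generators feed the pipeline without any external downloads: a
multinomial community sampler emitting isolate catalogs, a truncated-normal
radicle-length assay, and Jukes–Cantor sequence evolution along a tree for
the phylogeny stage.

All randomness derives from one seeded root generator with a named substream
per generator call, so adding a new generator never perturbs the streams of
existing ones and every output is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bioactivity import RadicleAssay
from .catalog import PLANTS, TISSUES, IsolateCatalog, IsolateRecord
from .errors import ValidationError
from .phylogeny import Alignment, Node, PhyloTree

_BASES = np.array(list("ACGT"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for the named stream of a root seed."""
    h = int.from_bytes(hashlib.blake2s(name.encode(), digest_size=4).digest(), "big")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(h,)))


# ---------------------------------------------------------------------------
# community


@dataclass(frozen=True)
class CommunitySpec:
    """Multinomial genus-abundance model for one or more strata.

    ``genus_probabilities`` is the community composition (must sum to 1);
    ``n_isolates`` applies to every emitted (plant, tissue) stratum.
    """

    genus_probabilities: Mapping[str, float]
    n_isolates: int
    plants: tuple[str, ...] = ("PT",)
    tissues: tuple[str, ...] = ("tuber",)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genus_probabilities:
            raise ValidationError("empty genus probability vector")
        total = float(sum(self.genus_probabilities.values()))
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"genus probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.genus_probabilities.values()):
            raise ValidationError("negative genus probability")
        if self.n_isolates < 0:
            raise ValidationError("n_isolates must be >= 0")
        for p in self.plants:
            if p not in PLANTS:
                raise ValidationError(f"unknown plant {p!r}")
        for t in self.tissues:
            if t not in TISSUES:
                raise ValidationError(f"unknown tissue {t!r}")


def _records_from_counts(
    counts: Mapping[str, int], plant: str, tissue: str, start: int
) -> list[IsolateRecord]:
    records = []
    serial = start
    for genus in sorted(counts):
        for _ in range(int(counts[genus])):
            records.append(
                IsolateRecord(
                    strain_code=f"{plant}S{serial:03d}",
                    plant=plant,
                    tissue=tissue,
                    closest_match=f"{genus} sp.",
                    match_accession="SIM000000.0",
                    coverage_pct=100.0,
                    identity_pct=100.0,
                    own_accession=f"SIM{serial:06d}",
                )
            )
            serial += 1
    return records


def catalog_from_counts(
    counts: Mapping[str, int], plant: str = "PT", tissue: str = "tuber"
) -> IsolateCatalog:
    """Deterministic catalog with exactly the given genus counts."""
    return IsolateCatalog(
        records=tuple(_records_from_counts(counts, plant, tissue, 1)),
        provenance="forced-counts",
    )


def simulate_catalog(spec: CommunitySpec) -> IsolateCatalog:
    """Multinomial draw of genus counts per stratum, expanded to records."""
    genera = sorted(spec.genus_probabilities)
    probs = np.array([spec.genus_probabilities[g] for g in genera])
    records: list[IsolateRecord] = []
    serial = 1
    for plant in spec.plants:
        for tissue in spec.tissues:
            rng = substream(spec.seed, f"community/{plant}/{tissue}")
            draw = rng.multinomial(spec.n_isolates, probs)
            counts = {g: int(n) for g, n in zip(genera, draw) if n > 0}
            new = _records_from_counts(counts, plant, tissue, serial)
            serial += len(new)
            records.extend(new)
    return IsolateCatalog(records=tuple(records), provenance=f"simulated(seed={spec.seed})")


# ---------------------------------------------------------------------------
# radicle assay


@dataclass(frozen=True)
class AssaySpec:
    """Normal-replicate radicle assay with a fractional inhibition effect.

    Control lengths ~ Normal(control_mean, control_sd) truncated at 0 (by
    clipping); treated lengths have mean control_mean * (1 - effect).  A full
    effect of 1 yields exactly-zero treated lengths (complete inhibition
    leaves no radicle), not a truncated normal around 0.
    """

    control_mean: float = 20.0
    control_sd: float = 1.0
    effect: float = 0.0
    replicates: int = 3
    seed: int = 0
    sample_id: str = "sim"

    def __post_init__(self) -> None:
        if self.control_mean <= 0:
            raise ValidationError("control_mean must be > 0")
        if not 0 <= self.effect <= 1:
            raise ValidationError("effect must lie in [0, 1]")
        if self.control_sd < 0:
            raise ValidationError("control_sd must be >= 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")


def simulate_radicle_assay(spec: AssaySpec) -> RadicleAssay:
    rng = substream(spec.seed, f"radicle/{spec.sample_id}")
    control = np.clip(
        rng.normal(spec.control_mean, spec.control_sd, spec.replicates), 0, None
    )
    if spec.effect >= 1.0:
        treated = np.zeros(spec.replicates)
    else:
        treated = np.clip(
            rng.normal(
                spec.control_mean * (1 - spec.effect),
                spec.control_sd,
                spec.replicates,
            ),
            0,
            None,
        )
    return RadicleAssay(
        sample_id=spec.sample_id,
        treated_lengths=tuple(float(x) for x in treated),
        control_lengths=tuple(float(x) for x in control),
    )


# ---------------------------------------------------------------------------
# sequence evolution


def evolve_sequences(
    tree: PhyloTree, length: int, seed: int = 0, model: str = "jc69"
) -> Alignment:
    """Jukes–Cantor site-independent evolution along a branch-length tree.

    Branch lengths are expected substitutions per site.  The root sequence is
    i.i.d. uniform over A/C/G/T; along a branch of length d each site changes
    to one of the three other bases with total probability
    (3/4)(1 - exp(-4d/3)).
    """
    if model != "jc69":
        raise ValidationError(f"unsupported evolution model {model!r}")
    if length < 1:
        raise ValidationError("alignment length must be >= 1")
    rng = substream(seed, "evolve")
    root_seq = rng.integers(0, 4, size=length)
    taxa: list[str] = []
    seqs: list[str] = []

    def walk(node: Node, seq: np.ndarray, at_root: bool) -> None:
        if not at_root:
            d = node.length
            if d < 0:
                raise ValidationError(f"negative branch length {d}")
            p_change = 0.75 * (1 - math.exp(-4 * d / 3))
            mutate = rng.random(length) < p_change
            if mutate.any():
                seq = seq.copy()
                # jump to one of the other three bases, uniformly
                seq[mutate] = (seq[mutate] + rng.integers(1, 4, mutate.sum())) % 4
        if node.is_leaf:
            taxa.append(node.label)
            seqs.append("".join(_BASES[seq]))
        else:
            for child in node.children:
                walk(child, seq, False)

    walk(tree.root, root_seq, True)
    return Alignment(taxa=tuple(taxa), sequences=tuple(seqs))
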