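"""Distance-based phylogeny: p/JC69/K2P distances, neighbor-joining, bootstrap.

The tree builder is a from-scratch Saitou–Nei neighbor-joining agglomeration
with deterministic tie-breaking, clamped non-negative branch lengths, and
bipartition-matched bootstrap supports.  It operates on pre-aligned ITS-like
DNA; alignment construction itself is out of scope.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from Bio import SeqIO

from .errors import (
    IncomparablePairError,
    InsufficientTaxaError,
    SaturationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

IUPAC_DNA = set("ACGTUNRYSWKMBDHV-")
_UNAMBIGUOUS = "ACGT"
DISTANCE_MODELS = ("p", "jc69", "k2p")

# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class Alignment:
    """Equal-length DNA sequences with unique taxon labels."""

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise ValidationError("taxa and sequences differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon labels in alignment")
        if self.sequences:
            ref = len(self.sequences[0])
            for t, s in zip(self.taxa, self.sequences):
                if len(s) != ref:
                    raise ValidationError(
                        f"record {t!r} has length {len(s)} != {ref}; "
                        "input must be pre-aligned"
                    )
        seqs = tuple(s.upper().replace("U", "T") for s in self.sequences)
        bad = {c for s in seqs for c in s} - IUPAC_DNA
        if bad:
            raise ValidationError(f"non-IUPAC characters in alignment: {sorted(bad)}")
        object.__setattr__(self, "sequences", seqs)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def sequence_of(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def resample_columns(self, columns: np.ndarray) -> "Alignment":
        """Alignment restricted to the given column indices (with repeats)."""
        seqs = tuple("".join(s[c] for c in columns) for s in self.sequences)
        return Alignment(taxa=self.taxa, sequences=seqs)


def read_fasta(path: str | Path) -> Alignment:
    """Read a pre-aligned FASTA; labels are truncated at the first whitespace."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 3:
        raise InsufficientTaxaError(
            f"{path}: {len(records)} records; at least 3 taxa are required"
        )
    taxa = tuple(r.id for r in records)
    seqs = tuple(str(r.seq) for r in records)
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        ref = len(seqs[0])
        offender = next(t for t, s in zip(taxa, seqs) if len(s) != ref)
        raise ValidationError(
            f"{path}: record {offender!r} has a different length; input must be aligned"
        )
    return Alignment(taxa=taxa, sequences=seqs)


# ---------------------------------------------------------------------------
# distances


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValidationError("distance matrix has negative entries")
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.labels.index(p) for p in pair)
        return float(self.values[i, j])


def _encode(aln: Alignment) -> np.ndarray:
    """Byte matrix; only A/C/G/T count as comparable (pairwise deletion)."""
    return np.frombuffer(
        "".join(aln.sequences).encode("ascii"), dtype="S1"
    ).reshape(len(aln.taxa), aln.length)


def compute_distances(
    aln: Alignment, model: str = "p", gap_mode: str = "pairwise_deletion"
) -> DistanceMatrix:
    """Pairwise distances under p, JC69 or K2P with pairwise deletion.

    Sites with a gap or any ambiguity code in either sequence of a pair are
    excluded for that pair only.  JC69 saturates at p >= 3/4; K2P whenever its
    logarithm arguments are non-positive.
    """
    if model not in DISTANCE_MODELS:
        raise ValidationError(f"unknown distance model {model!r}")
    if gap_mode != "pairwise_deletion":
        raise ValidationError(f"unsupported gap mode {gap_mode!r}")
    mat = _encode(aln)
    ok = np.isin(mat, [c.encode() for c in _UNAMBIGUOUS])
    n = len(aln.taxa)
    d = np.zeros((n, n))
    purine = np.isin(mat, [b"A", b"G"])
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ok[i] & ok[j]
            m = int(comparable.sum())
            if m == 0:
                raise IncomparablePairError(
                    f"pair ({aln.taxa[i]}, {aln.taxa[j]}): no comparable sites"
                )
            diff = (mat[i] != mat[j]) & comparable
            p = diff.sum() / m
            if model == "p":
                dist = p
            elif model == "jc69":
                if p >= 0.75:
                    raise SaturationError(
                        f"pair ({aln.taxa[i]}, {aln.taxa[j]}): p={p:.4f} >= 0.75, "
                        "JC69 correction undefined"
                    )
                dist = -0.75 * np.log(1 - 4 * p / 3)
            else:  # k2p
                transition = diff & (purine[i] == purine[j])
                pp = transition.sum() / m
                qq = p - pp
                a1 = 1 - 2 * pp - qq
                a2 = 1 - 2 * qq
                if a1 <= 0 or a2 <= 0:
                    raise SaturationError(
                        f"pair ({aln.taxa[i]}, {aln.taxa[j]}): K2P correction undefined"
                    )
                dist = -0.5 * np.log(a1) - 0.25 * np.log(a2)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=aln.taxa, values=d)


# ---------------------------------------------------------------------------
# trees


@dataclass
class Node:
    """Tree node; ``length`` is the branch to the parent (root: ignored)."""

    label: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree, represented with a (typically trifurcating) root node."""

    root: Node

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(leaf.label for leaf in self.root.leaves()))

    def total_length(self) -> float:
        def walk(n: Node, at_root: bool) -> float:
            t = 0.0 if at_root else n.length
            return t + sum(walk(c, False) for c in n.children)

        return walk(self.root, True)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized to the side NOT holding the
        lexicographically first taxon (so the set is rooting-invariant)."""
        all_taxa = set(self.taxa)
        ref = min(all_taxa)
        splits: set[frozenset[str]] = set()

        def walk(n: Node, at_root: bool) -> set[str]:
            if n.is_leaf:
                return {n.label}
            below = set()
            for c in n.children:
                below |= walk(c, False)
            if not at_root and 1 < len(below) < len(all_taxa) - 1:
                side = below if ref not in below else all_taxa - below
                splits.add(frozenset(side))
            return below

        walk(self.root, True)
        return splits

    def internal_edges(self) -> list[Node]:
        """Internal (non-root, non-leaf) nodes, i.e. the supported edges."""
        out = []

        def walk(n: Node, at_root: bool) -> None:
            if not n.is_leaf and not at_root:
                out.append(n)
            for c in n.children:
                walk(c, False)

        walk(self.root, True)
        return out

    def to_newick(self) -> str:
        root = self.root
        if root.is_leaf:
            return f"{_quote(root.label)};"
        inner = ",".join(_newick_string(c) for c in root.children)
        label = "" if root.support is None else _fmt_num(root.support)
        return f"({inner}){label};"


_NEEDS_QUOTES = re.compile(r"[\s()\[\]{}:;,']")


def _quote(label: str) -> str:
    if _NEEDS_QUOTES.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_num(x: float) -> str:
    return f"{x:.10g}"


def _newick_string(node: Node) -> str:
    if node.is_leaf:
        return f"{_quote(node.label)}:{_fmt_num(node.length)}"
    inner = ",".join(_newick_string(c) for c in node.children)
    label = "" if node.support is None else _fmt_num(node.support)
    return f"({inner}){label}:{_fmt_num(node.length)}"


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    """Serialize to Newick (supports as internal-node labels); optionally write."""
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_newick(source: str | Path) -> PhyloTree:
    """Parse Newick text or a file into a :class:`PhyloTree`.

    Internal-node labels that parse as numbers are taken as bootstrap supports.
    Parsing is delegated to dendropy; the in-memory form is converted.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(")
    ):
        text = Path(source).read_text()
    else:
        text = source
    dt = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )

    def convert(dn) -> Node:
        node = Node()
        node.length = float(dn.edge.length or 0.0)
        if dn.is_leaf():
            node.label = dn.taxon.label if dn.taxon else dn.label
        else:
            raw = dn.label
            if raw is not None:
                try:
                    node.support = float(raw)
                except ValueError:
                    node.label = raw
            node.children = [convert(c) for c in dn.child_nodes()]
        return node

    return PhyloTree(root=convert(dt.seed_node))


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Q-criterion minimization; ties go to the smallest (row, column) pair in
    the current matrix order.  Negative branch-length estimates are clamped
    to zero with the deficit moved onto the sister branch, so the path length
    between the two joined nodes is preserved.
    """
    n = len(dm.labels)
    if n < 3:
        raise InsufficientTaxaError(f"neighbor joining needs >= 3 taxa, got {n}")
    d = dm.values.astype(float).copy()
    nodes: list[Node] = [Node(label=lab) for lab in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major scan of the upper triangle => smallest (i, j) on ties
        iu, ju = np.triu_indices(m, k=1)
        k = int(np.lexsort((ju, iu, np.round(q[iu, ju], 12)))[0])
        i, j = int(iu[k]), int(ju[k])
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            li, lj = 0.0, d[i, j]
        if lj < 0:
            li, lj = d[i, j], 0.0
        nodes[i].length, nodes[j].length = float(li), float(lj)
        new = Node(children=[nodes[i], nodes[j]])
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d_new = np.zeros((len(keep) + 1, len(keep) + 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        d = d_new
        nodes = [nodes[x] for x in keep] + [new]

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    return PhyloTree(root=Node(children=[a, b, c]))


def bootstrap_support(
    aln: Alignment,
    replicates: int = 1000,
    seed: int = 0,
    model: str = "p",
    gap_mode: str = "pairwise_deletion",
) -> PhyloTree:
    """Reference NJ tree with bootstrap supports on its internal edges.

    Columns are resampled with replacement per replicate; each replicate r
    consumes its own substream of one seeded generator, so identical seeds
    give identical supports and adding replicates never perturbs earlier
    ones.  Support = percent of non-skipped replicate trees containing the
    same bipartition; replicates whose distances are undefined are skipped
    and counted (warning if more than 10% skip).
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    ref = nj_tree(compute_distances(aln, model=model, gap_mode=gap_mode))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in ref.bipartitions()}
    streams = np.random.SeedSequence(seed).spawn(replicates)
    skipped = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        cols = rng.integers(0, aln.length, size=aln.length)
        rep = aln.resample_columns(cols)
        try:
            rep_tree = nj_tree(compute_distances(rep, model=model, gap_mode=gap_mode))
        except (IncomparablePairError, SaturationError):
            skipped += 1
            continue
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    valid = replicates - skipped
    if skipped > 0.1 * replicates:
        logger.warning(
            "bootstrap: %d of %d replicates skipped (undefined distances)",
            skipped,
            replicates,
        )
    if valid == 0:
        raise SaturationError("all bootstrap replicates had undefined distances")

    all_taxa = set(ref.taxa)
    refmin = min(all_taxa)
    for node in ref.internal_edges():
        below = {leaf.label for leaf in node.leaves()}
        if not (1 < len(below) < len(all_taxa) - 1):
            continue
        side = frozenset(below if refmin not in below else all_taxa - below)
        node.support = 100.0 * counts[side] / valid
    return ref
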