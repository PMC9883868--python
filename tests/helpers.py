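"""Test-only oracles and generators, independent of the code paths they check."""

from __future__ import annotations

import math

import numpy as np

from endodiv.phylogeny import DistanceMatrix, Node, PhyloTree


# ---------------------------------------------------------------------------
# brute-force diversity formulas (plain Python, no shared code with the package)

def brute_force_indices(counts: list[int]) -> dict[str, float]:
    nt = sum(counts)
    s = len(counts)
    pi = [n / nt for n in counts]
    h = -sum(p * math.log(p) for p in pi)
    lam = sum(p * p for p in pi)
    return {
        "S": s,
        "margalef": (s - 1) / math.log(nt) if nt > 1 else math.nan,
        "shannon": h,
        "simpson": 1 - lam,
        "dominance": lam,
        "pie": sum((n / nt) * (nt - n) / (nt - 1) for n in counts) if nt > 1 else math.nan,
        "pielou": h / math.log(s) if s > 1 else math.nan,
    }


# ---------------------------------------------------------------------------
# textbook ANOVA / t statistics (explicit loops)

def brute_force_anova_f(groups: list[list[float]]) -> float:
    all_values = [x for g in groups for x in g]
    grand = sum(all_values) / len(all_values)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_values) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def brute_force_pooled_t(a: list[float], b: list[float]) -> float:
    ma, mb = sum(a) / len(a), sum(b) / len(b)
    sa = sum((x - ma) ** 2 for x in a)
    sb = sum((x - mb) ** 2 for x in b)
    sp2 = (sa + sb) / (len(a) + len(b) - 2)
    return (ma - mb) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))


# ---------------------------------------------------------------------------
# random trees and additive distance matrices

def random_binary_tree(n_taxa: int, rng: np.random.Generator) -> PhyloTree:
    """Random topology by sequential joining; branch lengths U(0.1, 1)."""
    nodes = [Node(label=f"T{i}") for i in range(n_taxa)]
    for node in nodes:
        node.length = float(rng.uniform(0.1, 1.0))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        new = Node(children=[nodes[i], nodes[j]], length=float(rng.uniform(0.1, 1.0)))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [new]
    return PhyloTree(root=Node(children=nodes))


def path_distance_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances by direct traversal."""
    pair_d: dict[tuple[str, str], float] = {}

    def walk(node: Node) -> dict[str, float]:
        if node.is_leaf:
            return {node.label: 0.0}
        child_maps = []
        for c in walk_children(node):
            child_maps.append(c)
        merged: dict[str, float] = {}
        for i in range(len(child_maps)):
            for j in range(i + 1, len(child_maps)):
                for a, da in child_maps[i].items():
                    for b, db in child_maps[j].items():
                        pair_d[tuple(sorted((a, b)))] = da + db
            merged |= child_maps[i]
        return merged

    def walk_children(node: Node) -> list[dict[str, float]]:
        out = []
        for c in node.children:
            sub = walk(c)
            out.append({leaf: d + c.length for leaf, d in sub.items()})
        return out

    walk(tree.root)
    labels = tuple(sorted({t for pair in pair_d for t in pair}))
    n = len(labels)
    m = np.zeros((n, n))
    for (a, b), d in pair_d.items():
        i, j = labels.index(a), labels.index(b)
        m[i, j] = m[j, i] = d
    return DistanceMatrix(labels=labels, values=m)
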