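"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap.

The tree stage mirrors the classic workflow for gene-family surveys: a
pairwise distance matrix from a supplied protein MSA, Saitou–Nei neighbor
joining, and column-resampling bootstrap supports on the point-estimate
tree's internal bipartitions.  The distance function is pluggable;
p-distance with pairwise deletion of gapped columns is the default.

Trees are :class:`skbio.TreeNode` objects; the returned "root" is the
trifurcating internal node conventionally used to print an unrooted tree.
Negative NJ branch lengths are clamped to zero and the tree is flagged
(``tree.negative_clamped``).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .io_formats import SequenceRecord


def p_distance_matrix(msa: Sequence[SequenceRecord]) -> DistanceMatrix:
    """Pairwise p-distance with pairwise deletion of gap-containing columns."""
    if len(msa) < 3:
        raise ValueError("need at least 3 taxa")
    length = len(msa[0].sequence)
    for rec in msa:
        if len(rec.sequence) != length:
            raise ValueError(f"row {rec.id!r} breaks the equal-length MSA invariant")
    chars = np.array([list(rec.sequence) for rec in msa])
    gaps = chars == "-"
    n = len(msa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gaps[i] | gaps[j])
            comparable = int(ok.sum())
            if comparable == 0:
                raise ValueError(
                    f"pair ({msa[i].id}, {msa[j].id}) has no comparable columns"
                )
            d[i, j] = d[j, i] = np.count_nonzero(chars[i, ok] != chars[j, ok]) / comparable
    return DistanceMatrix(d, ids=[rec.id for rec in msa])


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    On equal Q the pair with the smallest (i, j) position in the current
    node order is joined.  Returns the trifurcating "root" of the unrooted
    tree; ``tree.negative_clamped`` records whether any negative branch
    length was clamped to zero.
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm)  # validates symmetry / zero diagonal
    n0 = len(dm.ids)
    if n0 < 3:
        raise ValueError("need at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    d = dm.data.copy()
    active = list(range(n0))
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for a_pos in range(r):
            for b_pos in range(a_pos + 1, r):
                i, j = active[a_pos], active[b_pos]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0]:
                    best = (q, i, j)
        _, i, j = best
        li = clamp(0.5 * d[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2)))
        lj = clamp(d[i, j] - (0.5 * d[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))))
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])

        # grow the matrix with the new node's distances
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = clamp(0.5 * (d[a, b] + d[a, c] - d[b, c]))
    lb = clamp(0.5 * (d[a, b] + d[b, c] - d[a, c]))
    lc = clamp(0.5 * (d[a, c] + d[b, c] - d[a, b]))
    nodes[a].length, nodes[b].length, nodes[c].length = la, lb, lc
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    root.negative_clamped = clamped
    return root


def bipartitions(tree: TreeNode, taxa: Sequence[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, canonicalized so the
    reported side never contains the first taxon."""
    all_taxa = frozenset(taxa)
    ref = taxa[0]
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(tip.name for tip in node.tips())
        if ref in side:
            side = all_taxa - side
        if 2 <= len(side) <= len(all_taxa) - 2:
            out.add(side)
    return out


def bootstrap_support(
    msa: Sequence[SequenceRecord],
    n_reps: int,
    seed: int,
    distance_fn: Callable[[Sequence[SequenceRecord]], DistanceMatrix] = p_distance_matrix,
) -> TreeNode:
    """NJ point tree with bootstrap supports on its internal bipartitions.

    Columns are resampled with replacement ``n_reps`` times; each internal
    (non-trivial) bipartition's support is the percentage of replicate trees
    containing it.  Seeded and reproducible.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    taxa = [rec.id for rec in msa]
    point = neighbor_joining(distance_fn(msa))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(point, taxa)}

    chars = np.array([list(rec.sequence) for rec in msa])
    length = chars.shape[1]
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = [
            SequenceRecord(rec.id, "".join(chars[i, cols]))
            for i, rec in enumerate(msa)
        ]
        for bp in bipartitions(neighbor_joining(distance_fn(resampled)), taxa):
            if bp in counts:
                counts[bp] += 1

    all_taxa = frozenset(taxa)
    ref = taxa[0]
    for node in point.non_tips(include_self=False):
        side = frozenset(tip.name for tip in node.tips())
        if ref in side:
            side = all_taxa - side
        if side in counts:
            node.support = 100.0 * counts[side] / n_reps
    return point


def to_newick(tree: TreeNode, decimals: int = 6) -> str:
    """Newick text with bootstrap supports as internal labels and fixed
    branch-length precision."""

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            body = node.name or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            support = getattr(node, "support", None)
            label = f"{support:.0f}" if support is not None else ""
            body = f"({inner}){label}"
        if node.length is not None:
            body += f":{node.length:.{decimals}f}"
        return body

    return fmt(tree) + ";\n"
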