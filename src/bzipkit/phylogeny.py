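"""p-distance, neighbor-joining trees, and bootstrap support.

The tree-building recipe is the classic distance pipeline for protein
family surveys: pairwise p-distances (proportion of differing sites,
pairwise deletion of gaps and X), Saitou-Nei neighbor joining on the
distance matrix, and nonparametric bootstrap over alignment columns with
per-bipartition support percentages mapped back onto the original tree.

Neighbor joining is implemented here explicitly (Q-criterion, standard
split branch lengths, deterministic lowest-index tie-breaking, negative
lengths clamped to zero); trees are dendropy objects so Newick
serialization and bipartition bookkeeping use the standard library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

log = logging.getLogger(__name__)

DEFAULT_EXCLUDE = frozenset({"-", "X", "?", "."})


@dataclass
class Alignment:
    """Equal-length aligned sequences with '-' gap characters."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("aligned rows have unequal lengths")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, column_indices: np.ndarray) -> "Alignment":
        rows = ["".join(r[i] for i in column_indices) for r in self.rows]
        return Alignment(list(self.ids), rows)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0):
            raise ValueError("distance matrix diagonal is not zero")


class IncomparablePairError(ValueError):
    """A sequence pair shares no comparable (ungapped, known) sites."""


def p_distance(
    alignment: Alignment, exclude: frozenset = DEFAULT_EXCLUDE
) -> DistanceMatrix:
    """Proportion of differing sites per pair, with pairwise deletion.

    Sites where either row carries a gap or unknown character are excluded
    pair by pair; a pair left with zero comparable sites raises
    :class:`IncomparablePairError` naming the pair.
    """
    n = len(alignment.ids)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    chars = np.array([list(r) for r in alignment.rows])
    valid = ~np.isin(chars, sorted(exclude))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            n_sites = int(both.sum())
            if n_sites == 0:
                raise IncomparablePairError(
                    f"pair ({alignment.ids[i]!r}, {alignment.ids[j]!r}) has "
                    "no comparable sites"
                )
            mismatches = int((chars[i][both] != chars[j][both]).sum())
            d[i, j] = d[j, i] = mismatches / n_sites
    return DistanceMatrix(list(alignment.ids), d)


def nj_tree(
    dist: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; unrooted tree with clamped branch lengths.

    At each step the pair minimizing
    ``Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)``
    is joined, ties broken by lowest (row, column) index; branch lengths use
    the standard split formula, negatives clamped to 0 (logged).
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa for a tree")
    taxa = taxon_namespace or dendropy.TaxonNamespace(dist.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = [
        dendropy.Node(taxon=taxa.require_taxon(label=t)) for t in dist.ids
    ]
    D = dist.matrix.copy()

    def clamp(x: float) -> float:
        if x < 0:
            log.debug("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        iu = np.triu_indices(m, k=1)
        flat = Q[iu]
        best = int(np.argmin(flat))  # row-major upper triangle: lowest (i, j) tie
        i, j = int(iu[0][best]), int(iu[1][best])
        dij = D[i, j]
        bi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        bj = dij - bi
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = clamp(bi)
        nodes[j].edge.length = clamp(bj)
        dnew = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        M = np.zeros((len(keep) + 1, len(keep) + 1))
        M[: len(keep), : len(keep)] = D[np.ix_(keep, keep)]
        M[-1, : len(keep)] = dnew[keep]
        M[: len(keep), -1] = dnew[keep]
        D = M
        nodes = [nodes[k] for k in keep] + [parent]

    # join the last three around a central (unrooted) node
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    center = dendropy.Node()
    lengths = [
        (d01 + d02 - d12) / 2,
        (d01 + d12 - d02) / 2,
        (d02 + d12 - d01) / 2,
    ]
    for node, length in zip(nodes, lengths):
        center.add_child(node)
        node.edge.length = clamp(length)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def _internal_bipartitions(tree: dendropy.Tree) -> dict[int, dendropy.Edge]:
    """Split bitmask -> edge for internal (non-trivial) edges."""
    tree.encode_bipartitions()
    out = {}
    n_taxa = len(tree.taxon_namespace)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.head_node.is_leaf():
            continue
        bipartition = edge.bipartition
        # skip trivial splits (single taxon or all-but-root artifacts)
        mask = bipartition.split_bitmask
        size = bin(mask).count("1")
        if 2 <= size <= n_taxa - 2:
            out[bipartition.split_bitmask] = edge
    return out


def bootstrap(
    alignment: Alignment,
    replicates: int = 1000,
    seed: int = 0,
    exclude: frozenset = DEFAULT_EXCLUDE,
) -> tuple[dendropy.Tree, int]:
    """NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement ``replicates`` times; each
    replicate is rebuilt with p-distance + NJ, and each internal edge of
    the original tree receives the percentage of usable replicates
    containing the same bipartition. Replicates producing an incomparable
    pair are skipped (logged) and the denominator adjusted. Returns
    ``(tree, n_replicates_used)``; supports are stored as node labels and
    as ``edge.bootstrap_support``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    dist = p_distance(alignment, exclude)
    tree = nj_tree(dist)
    targets = _internal_bipartitions(tree)
    counts = dict.fromkeys(targets, 0)
    used = 0
    for _ in range(replicates):
        cols = rng.integers(0, alignment.n_sites, alignment.n_sites)
        try:
            rep_dist = p_distance(alignment.resample_columns(cols), exclude)
        except IncomparablePairError as exc:
            log.info("bootstrap replicate skipped: %s", exc)
            continue
        rep_tree = nj_tree(rep_dist, taxon_namespace=tree.taxon_namespace)
        rep_masks = set(_internal_bipartitions(rep_tree))
        used += 1
        for mask in counts:
            if mask in rep_masks:
                counts[mask] += 1
    for mask, edge in targets.items():
        support = 100.0 * counts[mask] / used if used else 0.0
        edge.bootstrap_support = support
        edge.head_node.label = f"{support:g}"
    return tree, used


def distance_report(dist: DistanceMatrix):
    import pandas as pd

    return pd.DataFrame(dist.matrix, index=dist.ids, columns=dist.ids)
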