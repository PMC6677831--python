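"""Distance-based protein phylogenetics: Poisson correction + Neighbor-Joining.

Pairwise distances are the Poisson multiple-hit correction
d = -ln(1 - p) of the proportion p of differing amino-acid sites, computed
after complete deletion of alignment columns containing gaps or missing
data. Trees are built by the Saitou-Nei Neighbor-Joining agglomeration
with deterministic tie-breaking and MEGA-style clamping of negative branch
estimates (the deficit is transferred to the sibling branch). Trees are
dendropy objects, serialized as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import dendropy

__all__ = [
    "AlignedSequences",
    "complete_deletion",
    "poisson_distance",
    "distance_matrix",
    "neighbor_joining",
    "total_branch_length",
    "read_fasta_alignment",
    "write_newick",
    "read_newick",
]


@dataclass
class AlignedSequences:
    """Named equal-length aligned amino-acid rows; gap character '-'."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in count")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("aligned rows must all have the same length")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def read_fasta_alignment(path) -> AlignedSequences:
    from Bio import SeqIO

    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(str(rec.seq).upper())
    return AlignedSequences(names, rows)


def complete_deletion(aln: AlignedSequences) -> AlignedSequences:
    """Drop every column containing a gap '-' or missing datum 'X'."""
    keep = [
        i
        for i in range(aln.n_columns)
        if all(row[i] not in "-X" for row in aln.rows)
    ]
    if not keep:
        raise ValueError("complete deletion removed every column")
    return AlignedSequences(
        list(aln.names), ["".join(row[i] for i in keep) for row in aln.rows]
    )


def poisson_distance(row_a: str, row_b: str) -> float:
    """d = -ln(1 - p), p the proportion of differing sites (gap-free rows)."""
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    if not row_a:
        raise ValueError("empty rows")
    p = sum(a != b for a, b in zip(row_a, row_b)) / len(row_a)
    if p >= 1.0:
        raise ValueError("p >= 1: Poisson-corrected distance undefined")
    return float(-np.log1p(-p))


def distance_matrix(aln: AlignedSequences) -> np.ndarray:
    """Symmetric Poisson-corrected distance matrix over all row pairs."""
    n = aln.n_sequences
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = poisson_distance(aln.rows[i], aln.rows[j])
    return d


def neighbor_joining(matrix: np.ndarray, names: list[str]) -> dendropy.Tree:
    """Saitou-Nei Neighbor-Joining on a symmetric distance matrix.

    Deterministic: Q-criterion ties are broken by the lexicographically
    smallest active index pair. Negative branch-length estimates are
    clamped to zero with the deficit moved onto the sibling branch.
    Returns an unrooted binary dendropy tree with 2N-3 edges.
    """
    d = np.asarray(matrix, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("matrix must be symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if len(names) != n:
        raise ValueError("need one name per row")

    taxa = dendropy.TaxonNamespace(names)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = {}
    for i, name in enumerate(names):
        nd = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes[i] = nd

    d = d.copy()
    active = list(range(n))
    next_id = n
    full = {(i, j): d[i, j] for i in range(n) for j in range(n)}

    def dist(i, j):
        return full[(i, j)] if i <= j else full[(j, i)]

    def set_dist(i, j, v):
        full[(min(i, j), max(i, j))] = v

    while len(active) > 2:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best, best_q = None, np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (i, j) < best
                ):
                    best_q, best = q, (i, j)
        i, j = best
        dij = dist(i, j)
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        # MEGA-style clamp: negatives zeroed, deficit moved to the sibling
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        parent = dendropy.Node()
        ni, nj = nodes.pop(i), nodes.pop(j)
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = vi
        nj.edge.length = vj
        u = next_id
        next_id += 1
        nodes[u] = parent
        for k in active:
            if k in (i, j):
                continue
            set_dist(u, k, 0.5 * (dist(i, k) + dist(j, k) - dij))
        active = [k for k in active if k not in (i, j)] + [u]

    i, j = active
    ni, nj = nodes[i], nodes[j]
    # attach the last pending node onto the other, producing an unrooted
    # tree with the remaining distance on the connecting edge
    root = ni if ni.child_nodes() else nj
    leaf = nj if root is ni else ni
    root.add_child(leaf)
    leaf.edge.length = max(0.0, dist(i, j))
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def total_branch_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths (substitutions/site)."""
    return float(sum(e.length or 0.0 for e in tree.edges() if e.head_node is not tree.seed_node))


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def tree_path_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf patristic distances keyed by sorted name pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for a in range(len(taxa)):
        for b in range(a + 1, len(taxa)):
            key = tuple(sorted((taxa[a].label, taxa[b].label)))
            out[key] = float(pdm.patristic_distance(taxa[a], taxa[b]))
    return out
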