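"""Distance phylogenetics: Poisson-corrected amino-acid distances,
neighbor-joining, and bootstrap supports.

The distance d = -ln(1 - p) converts the observed fraction p of differing
amino acids between two sequences into the expected number of substitutions
per site under a Poisson model with equal rates across sites and residues.
Ambiguous positions (gaps or X) are removed per sequence pair (pairwise
deletion) or across all rows (complete deletion).

Trees are dendropy objects; bootstrap supports are the fraction of
column-resampled replicates whose NJ tree contains each bipartition of the
full-data tree, reported on a 0-1 scale as internal-node labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .conservation import AMINO_ACIDS, Alignment

__all__ = [
    "DistanceMatrix",
    "pairwise_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "write_newick",
    "read_newick",
]

_AMBIGUOUS = frozenset("-X")


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, substitutions/site

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if np.any(self.d < -1e-12) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and non-negative")
        np.fill_diagonal(self.d, 0.0)


def _usable_mask(rows: list[str]) -> np.ndarray:
    arr = np.array([list(r) for r in rows])
    return ~np.isin(arr, list(_AMBIGUOUS))


def pairwise_distance_matrix(msa: Alignment, model: str = "poisson",
                             deletion: str = "pairwise") -> DistanceMatrix:
    """Pairwise evolutionary distances from an alignment.

    model 'p' gives the raw difference fraction; 'poisson' applies
    d = -ln(1 - p).  *deletion* removes ambiguous (gap/X) columns per pair
    ('pairwise') or wherever any row is ambiguous ('complete').
    """
    if msa.n_rows < 3:
        raise ValueError("need >= 3 sequences")
    if model not in ("poisson", "p"):
        raise ValueError(f"unknown model {model!r}")
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion {deletion!r}")
    ids = list(msa.ids)
    rows = [msa.rows[i] for i in ids]
    ok = _usable_mask(rows)  # (n_rows, length) True where unambiguous
    arr = np.array([list(r) for r in rows])
    if deletion == "complete":
        keep = ok.all(axis=0)
        ok = np.repeat(keep[None, :], len(ids), axis=0)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = ok[i] & ok[j]
            n_usable = int(usable.sum())
            if n_usable == 0:
                raise ValueError(f"no usable sites between {ids[i]!r} and {ids[j]!r}")
            p = float((arr[i][usable] != arr[j][usable]).sum()) / n_usable
            if model == "p":
                dist = p
            else:
                if p >= 1.0:
                    raise ValueError(
                        f"p=1 between {ids[i]!r} and {ids[j]!r}: Poisson "
                        "correction undefined")
                dist = -np.log(1.0 - p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids=ids, d=d)


def _new_tree(taxa: list[str]) -> tuple[dendropy.Tree, dict[str, dendropy.Node]]:
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False
    nodes = {}
    for t in ns:
        node = dendropy.Node(taxon=t)
        nodes[t.label] = node
    return tree, nodes


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor-joining on a symmetric distance matrix.

    Ties in the Q criterion are broken by the smallest (i, j) index pair;
    negative branch lengths are clamped to zero with the deficit moved to
    the sister branch, so total path lengths are preserved.
    Returns an unrooted dendropy tree.
    """
    n0 = len(dm.ids)
    if n0 < 3:
        raise ValueError("need >= 3 taxa")
    tree, leaf_nodes = _new_tree(dm.ids)
    d = dm.d.copy()
    nodes = [leaf_nodes[t] for t in dm.ids]
    active = list(range(n0))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> smallest (i, j) in active-index order
        flat = np.argmin(q)
        qmin = q.flat[flat]
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        ai, aj = min((int(i), int(j)) for i, j in ties if i < j)
        i, j = active[ai], active[aj]
        li = 0.5 * sub[ai, aj] + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = sub[ai, aj] - li
        li, lj = _clamp_pair(li, lj)
        parent = dendropy.Node()
        ci, cj = nodes[i], nodes[j]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = li
        cj.edge.length = lj
        # distances from the new node to the remaining taxa
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d = np.vstack([d, new_d])
        new_col = np.append(new_d, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # join the last three nodes at an unrooted trivalent root
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    la, lb = _clamp_pair(la, lb)
    lb, lc = _clamp_pair(lb, lc)
    la, lc = _clamp_pair(la, lc)
    root = dendropy.Node()
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        root.add_child(node)
        node.edge.length = max(0.0, length)
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


def _clamp_pair(x: float, y: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sister."""
    if x < 0:
        y += x
        x = 0.0
    if y < 0:
        x += y
        y = 0.0
    return x, max(0.0, y)


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial splits as frozensets of taxon labels (smaller side,
    ties broken lexicographically) — taxon-order independent."""
    all_taxa = frozenset(t.label for t in tree.taxon_namespace)
    splits = set()
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(leaves) <= len(all_taxa) - 2:
            other = all_taxa - leaves
            side = min(leaves, other, key=lambda s: (len(s), sorted(s)))
            splits.add(side)
    return splits


def bootstrap_support(msa: Alignment, n_reps: int = 500, seed: int = 0,
                      model: str = "poisson", deletion: str = "pairwise",
                      ) -> dendropy.Tree:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement *n_reps* times; each replicate's
    NJ tree votes for the full-data tree's bipartitions.  Supports (fraction
    of replicates, 0-1 scale) are stored as internal-node labels.
    Deterministic for a given *seed*.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full_dm = pairwise_distance_matrix(msa, model=model, deletion=deletion)
    tree = neighbor_joining(full_dm)
    counts: dict[frozenset, int] = {split: 0 for split in _bipartitions(tree)}
    rng = np.random.default_rng(seed)
    length = msa.length
    base_rows = {i: msa.rows[i] for i in msa.ids}
    n_used = 0
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        rep_rows = {i: "".join(base_rows[i][c] for c in cols) for i in msa.ids}
        rep = Alignment(ids=list(msa.ids), rows=rep_rows)
        try:
            rep_tree = neighbor_joining(pairwise_distance_matrix(
                rep, model=model, deletion=deletion))
        except ValueError:
            # degenerate replicate (saturated pair or no usable sites):
            # discarded, and supports normalised over retained replicates
            continue
        n_used += 1
        rep_splits = _bipartitions(rep_tree)
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    if n_used == 0:
        raise ValueError("every bootstrap replicate was degenerate")

    all_taxa = frozenset(t.label for t in tree.taxon_namespace)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(leaves) <= len(all_taxa) - 2:
            side = min(leaves, all_taxa - leaves, key=lambda s: (len(s), sorted(s)))
            node.label = f"{counts.get(side, 0) / n_used:.3f}"
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Newick text with 6-significant-digit branch lengths and bootstrap
    supports as internal-node labels; round-trips through `read_newick`."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6g",
        suppress_internal_node_labels=False,
    ).strip() + "\n"


def read_newick(text: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=text, schema="newick",
                             suppress_internal_node_taxa=True)
    tree.is_rooted = False
    return tree
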