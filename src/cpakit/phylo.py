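"""Desk-scale tree building and tree utilities.

Neighbor-joining over maximum-likelihood pairwise distances stands in for the
large-scale ML tree searches a cluster would run; bootstrap bipartition
supports and greedy phylogenetic-diversity (PD) subset selection follow the
canonical algorithms.  Trees are dendropy objects throughout; Newick I/O
stores edge supports as internal-node labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .substitution import SubstitutionModel, encode_sequence

log = logging.getLogger(__name__)

MAX_DISTANCE = 3.0  # saturation cap, substitutions per site


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with labelled rows/columns."""

    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(m < 0) or not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("distances must be >= 0 with zero diagonal")
        self.matrix = (m + m.T) / 2.0

    def __len__(self) -> int:
        return len(self.labels)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.matrix):
                fh.write(lab + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def _pair_ml_distance(counts: np.ndarray, model: SubstitutionModel) -> float:
    """1-D ML optimisation of the distance for one pair's 20x20 count matrix."""
    pi = model.frequencies
    nz = counts > 0
    if counts[nz].sum() == 0:
        raise ValueError("no comparable sites")
    log_pi = np.log(pi)

    def nll(t: float) -> float:
        P = model.transition_matrix(t)
        with np.errstate(divide="ignore"):
            ll = counts[nz] * (log_pi[np.where(nz)[0]] + np.log(np.maximum(P[nz], 1e-300)))
        return -ll.sum()

    if np.trace(counts) == counts.sum():
        return 0.0
    res = minimize_scalar(nll, bounds=(1e-8, MAX_DISTANCE), method="bounded",
                          options={"xatol": 1e-6})
    t = float(res.x)
    if nll(MAX_DISTANCE) <= res.fun:
        return MAX_DISTANCE
    return min(t, MAX_DISTANCE)


def pairwise_distances(
    ids: list[str], rows: list[str], model: SubstitutionModel | None = None
) -> DistanceMatrix:
    """ML pairwise distances under ``model`` from aligned rows.

    Gap/unknown sites are excluded pairwise; a pair with zero comparable
    sites raises an error naming the pair.
    """
    model = model or SubstitutionModel.lg()
    if len(ids) != len(rows):
        raise ValueError("ids and rows differ in length")
    enc = np.array([encode_sequence(r) for r in rows])
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = enc[i], enc[j]
            ok = (a >= 0) & (b >= 0)
            if not ok.any():
                raise ValueError(f"no comparable sites between {ids[i]!r} and {ids[j]!r}")
            counts = np.zeros((20, 20))
            np.add.at(counts, (a[ok], b[ok]), 1.0)
            counts = (counts + counts.T) / 2.0  # reversibility: symmetrise the pattern
            dm[i, j] = dm[j, i] = _pair_ml_distance(counts, model)
    return DistanceMatrix(list(ids), dm)


# -- neighbor joining ---------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical Saitou-Nei neighbor joining; deterministic tie-break.

    Ties in the Q criterion resolve to the lexicographically smallest (i, j)
    index pair.  Negative branch lengths are clamped to zero (logged).
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    taxon_namespace = dendropy.TaxonNamespace(dm.labels)
    nodes = []
    for lab in dm.labels:
        node = dendropy.Node(taxon=taxon_namespace.get_taxon(lab))
        nodes.append(node)
    D = dm.matrix.copy()
    active = list(range(n))
    clamped = 0

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lexicographically smallest argmin
        flat = np.argmin(Q)
        qmin = Q.flat[flat]
        ii, jj = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))[0]
        if ii > jj:
            ii, jj = jj, ii
        a, b = active[ii], active[jj]
        d_ab = D[a, b]
        la = 0.5 * d_ab + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lb = d_ab - la
        if la < 0 or lb < 0:
            clamped += 1
            la, lb = max(la, 0.0), max(lb, 0.0)
        parent = dendropy.Node()
        na, nb = nodes[a], nodes[b]
        parent.add_child(na)
        parent.add_child(nb)
        na.edge.length = la
        nb.edge.length = lb
        # distances to the new node
        new_row = 0.5 * (D[a, :] + D[b, :] - d_ab)
        D = np.vstack([D, new_row])
        D = np.hstack([D, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        active = [x for x in active if x not in (a, b)] + [len(nodes) - 1]

    a, b = active
    root = dendropy.Node()
    root.add_child(nodes[a])
    root.add_child(nodes[b])
    half = D[a, b] / 2.0
    nodes[a].edge.length = max(half, 0.0)
    nodes[b].edge.length = max(D[a, b] - half, 0.0)
    if clamped:
        log.info("NJ clamped %d negative branch lengths to zero", clamped)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# -- splits and bootstrap -----------------------------------------------------------


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial splits of the unrooted tree, one per internal edge.

    Each split is canonicalised as the smaller leaf set (ties: the side whose
    sorted label tuple is lexicographically smaller).
    """
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = leaves - below
        if len(below) < 2 or len(other) < 2:
            continue
        side = min(below, other, key=lambda s: (len(s), tuple(sorted(s))))
        splits.add(side)
    return splits


def bootstrap_supports(
    ids: list[str],
    rows: list[str],
    n_replicates: int = 100,
    seed: int = 0,
    model: SubstitutionModel | None = None,
) -> dendropy.Tree:
    """NJ tree from the base alignment with bootstrap split supports.

    Columns are resampled with replacement per replicate; each internal edge
    of the base tree is annotated (``edge.head_node.label`` and
    ``edge.bipartition support``) with the fraction of replicate trees
    containing its split.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    model = model or SubstitutionModel.lg()
    base = nj_tree(pairwise_distances(ids, rows, model))
    rng = np.random.default_rng(seed)
    L = len(rows[0])
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        idx = rng.integers(0, L, size=L)
        rep_rows = ["".join(row[i] for i in idx) for row in rows]
        try:
            rep_tree = nj_tree(pairwise_distances(ids, rep_rows, model))
        except ValueError:
            continue  # replicate with an incomparable pair: skipped
        for split in bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    leaves = frozenset(ids)
    for node in base.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = leaves - below
        if len(below) < 2 or len(other) < 2:
            continue
        side = min(below, other, key=lambda s: (len(s), tuple(sorted(s))))
        support = counts.get(side, 0) / n_replicates
        node.label = f"{support:.2f}"
        node.annotations["support"] = support
    return base


def leaf_instability(
    ids: list[str],
    rows: list[str],
    n_replicates: int = 20,
    seed: int = 0,
    model: SubstitutionModel | None = None,
) -> dict[str, float]:
    """Diagnostic only: per-leaf mean Jaccard disagreement of the splits a
    leaf participates in across bootstrap replicates (rogue-taxon indicator)."""
    model = model or SubstitutionModel.lg()
    rng = np.random.default_rng(seed)
    base_splits = bipartitions(nj_tree(pairwise_distances(ids, rows, model)))
    L = len(rows[0])
    disagreement = {i: 0.0 for i in ids}
    for _ in range(n_replicates):
        idx = rng.integers(0, L, size=L)
        rep_rows = ["".join(row[i] for i in idx) for row in rows]
        rep_splits = bipartitions(nj_tree(pairwise_distances(ids, rep_rows, model)))
        missing = base_splits - rep_splits
        for leaf in ids:
            in_missing = sum(1 for s in missing if leaf in s)
            in_base = sum(1 for s in base_splits if leaf in s)
            if in_base:
                disagreement[leaf] += in_missing / in_base
    return {leaf: v / n_replicates for leaf, v in disagreement.items()}


# -- phylogenetic diversity ---------------------------------------------------------


def _leaf_sets(tree: dendropy.Tree) -> list[tuple[frozenset, float]]:
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        out.append((below, node.edge.length or 0.0))
    return out


def phylogenetic_diversity(tree: dendropy.Tree, leaf_subset) -> float:
    """Total branch length of the minimal subtree connecting ``leaf_subset``."""
    subset = frozenset(leaf_subset)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = subset - leaves
    if unknown:
        raise ValueError(f"unknown leaves: {sorted(unknown)}")
    if len(subset) < 2:
        raise ValueError("phylogenetic diversity needs at least 2 leaves")
    total = 0.0
    for below, length in _leaf_sets(tree):
        k = len(below & subset)
        if 0 < k < len(subset):
            total += length
    return total


def select_diverse_subset(tree: dendropy.Tree, k: int) -> list[str]:
    """Greedy PD maximisation: the PDA-style most-divergent leaf subset.

    Starts from the pair of leaves with maximal path distance, then adds the
    leaf with maximal PD gain (ties: lexicographically smallest label).
    Greedy selection is provably optimal for PD maximisation on trees.
    Returns exactly ``k`` leaf labels, sorted.
    """
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    n = len(leaves)
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}]")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(leaves)}
    # diameter pair, lexicographic tie-break
    best = (-1.0, None, None)
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            d = pdm.patristic_distance(taxa[a], taxa[b])
            if d > best[0] + 1e-15:
                best = (d, a, b)
    chosen = {best[1], best[2]}
    # adjacency with parent pointers rooted at an arbitrary chosen leaf
    label_of = {}
    adj: dict = {}
    for node in tree.preorder_node_iter():
        adj.setdefault(node, [])
        if node.parent_node is not None:
            adj[node].append((node.parent_node, node.edge.length or 0.0))
            adj.setdefault(node.parent_node, []).append((node, node.edge.length or 0.0))
        if node.is_leaf():
            label_of[node.taxon.label] = node
    root = label_of[best[1]]
    parent = {root: (None, 0.0)}
    stack = [root]
    order = []
    while stack:
        u = stack.pop()
        order.append(u)
        for v, w in adj[u]:
            if v not in parent:
                parent[v] = (u, w)
                stack.append(v)
    covered = {root}

    def mark(leaf_label: str) -> float:
        gain = 0.0
        node = label_of[leaf_label]
        while node not in covered:
            covered.add(node)
            up, w = parent[node]
            gain += w
            node = up
        return gain

    mark(best[2])
    while len(chosen) < k:
        best_gain, best_leaf = -1.0, None
        for lab in leaves:
            if lab in chosen:
                continue
            gain = 0.0
            node = label_of[lab]
            while node not in covered:
                up, w = parent[node]
                gain += w
                node = up
            if gain > best_gain + 1e-15:
                best_gain, best_leaf = gain, lab
        chosen.add(best_leaf)
        mark(best_leaf)
    return sorted(chosen)


# -- Newick I/O ---------------------------------------------------------------------


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, real_value_format_specifier=".6g")


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
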