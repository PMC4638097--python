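"""Distance phylogenetics on binary marker matrices.

Samples (plus the all-zero reference pseudo-sample) are compared by the
Euclidean distance on their 0/1 marker rows — sqrt of the number of
differing markers.  Trees are built with BioNJ (Gascuel 1997, Mol Biol
Evol 14:685), a variance-weighted neighbour joining that behaves well when
branch lengths are heterogeneous, as they are here (long tumour branches,
short normal branch).  Classical neighbour joining is the constant-variance
special case and is exposed for cross-checking; UPGMA (average linkage) is
provided as a concordance check.  Clade confidence comes from bootstrap
resampling of marker columns: the support of an internal edge is the
percentage of replicate trees containing the same leaf bipartition.

Branch lengths may come out slightly negative, as is standard for
neighbour-joining methods; they are kept as estimated (clamping, if wanted,
is a display decision).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .sharing import PartitionSummary
from .trees import Node, bipartitions, clade_leafsets, root_on_leaf_edge
from .variant_matrix import REFERENCE_LABEL, BinaryMarkerMatrix


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix must have a zero diagonal")


def binary_distance(matrix: BinaryMarkerMatrix) -> DistanceMatrix:
    """Euclidean distance between binary rows: sqrt(# differing markers)."""
    if len(matrix.samples) < 2:
        raise ValueError("need at least two rows to compute distances")
    X = matrix.data.astype(np.int32)
    s = X.sum(axis=1)
    cross = X @ X.T
    hamming = s[:, None] + s[None, :] - 2 * cross
    return DistanceMatrix(list(matrix.samples), np.sqrt(hamming.astype(float)))


def _pair_distances(X: np.ndarray) -> np.ndarray:
    X = X.astype(np.int32)
    s = X.sum(axis=1)
    hamming = s[:, None] + s[None, :] - 2 * (X @ X.T)
    return np.sqrt(hamming.astype(float))


# ---------------------------------------------------------------------------
# BioNJ

def bionj(dist: DistanceMatrix, uniform_variance: bool = False) -> Node:
    """Build an unrooted BioNJ tree from a distance matrix.

    The agglomeration follows Gascuel (1997): pair (i, j) minimising
    Q(i,j) = (r-2) d(i,j) - S_i - S_j is joined (ties broken by lowest index
    pair for determinism); branch lengths are b_i = d(i,j)/2 +
    (S_i - S_j)/(2(r-2)); the reduced distances are the variance-weighted
    mean d(u,k) = lam*d(i,k) + (1-lam)*d(j,k) - lam*b_i - (1-lam)*b_j with
    lam = 1/2 + sum_k(v(j,k) - v(i,k)) / (2(r-2) v(i,j)) clamped to [0,1],
    and variances reduce as v(u,k) = lam*v(i,k) + (1-lam)*v(j,k) -
    lam*(1-lam)*v(i,j).  Variances are initialised to the distances
    themselves; with ``uniform_variance=True`` they are held constant, which
    makes lam = 1/2 throughout and reproduces classical neighbour joining
    exactly.  The last three nodes are joined onto a central (trifurcating)
    node with their exact three-point branch lengths.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("BioNJ needs at least three taxa")
    d = dist.values.copy()
    v = np.ones_like(d) if uniform_variance else d.copy()
    nodes: list[Node] = [Node(lbl) for lbl in dist.labels]
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = np.ix_(active, active)
        dd = d[sub]
        S = dd.sum(axis=1)
        Q = (r - 2) * dd - S[:, None] - S[None, :]
        Q[np.tril_indices(r)] = np.inf  # consider i<j only
        # np.argmin returns the first (row-major) minimum: ties break to the
        # lowest (i, j) index pair, keeping the agglomeration deterministic
        a, b = np.unravel_index(int(np.argmin(Q)), Q.shape)
        i, j = active[a], active[b]
        dij = d[i, j]
        bi = 0.5 * dij + (S[a] - S[b]) / (2.0 * (r - 2))
        bj = dij - bi
        vij = v[i, j]
        if uniform_variance or vij <= 0:
            lam = 0.5
        else:
            others = [k for k in active if k != i and k != j]
            lam = 0.5 + (v[j, others] - v[i, others]).sum() / (2.0 * (r - 2) * vij)
            lam = min(1.0, max(0.0, lam))

        parent = Node(None)
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = bi, bj
        parent.children = [ni, nj]

        # reuse slot i for the new node u
        for k in active:
            if k == i or k == j:
                continue
            duk = lam * d[i, k] + (1 - lam) * d[j, k] - lam * bi - (1 - lam) * bj
            vuk = lam * v[i, k] + (1 - lam) * v[j, k] - lam * (1 - lam) * vij
            d[i, k] = d[k, i] = duk
            v[i, k] = v[k, i] = vuk
        d[i, i] = v[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    root = Node(None)
    nodes[i].length = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    nodes[j].length = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    nodes[k].length = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root.children = [nodes[i], nodes[j], nodes[k]]
    return root


def neighbor_joining(dist: DistanceMatrix) -> Node:
    """Classical Saitou–Nei neighbour joining (BioNJ with constant variances)."""
    return bionj(dist, uniform_variance=True)


# ---------------------------------------------------------------------------
# UPGMA (concordance check; average linkage via scipy)

def upgma(dist: DistanceMatrix) -> Node:
    """Ultrametric average-linkage tree; used as a topology concordance check."""
    n = len(dist.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least two taxa")
    if n == 2:
        h = dist.values[0, 1] / 2.0
        return Node(None, children=[Node(dist.labels[0], h), Node(dist.labels[1], h)])
    Z = average(squareform(dist.values, checks=False))
    nodes = [Node(lbl) for lbl in dist.labels]
    heights = [0.0] * n
    for row in Z:
        a, b, h, _ = int(row[0]), int(row[1]), float(row[2]), row[3]
        height = h / 2.0  # linkage heights are cophenetic distances
        left, right = nodes[a], nodes[b]
        left.length = height - heights[a]
        right.length = height - heights[b]
        nodes.append(Node(None, children=[left, right]))
        heights.append(height)
    return nodes[-1]


# ---------------------------------------------------------------------------
# Rooting and bootstrap

def root_with_reference(tree: Node, reference: str = REFERENCE_LABEL) -> Node:
    """Root the tree on the edge leading to the reference pseudo-sample."""
    return root_on_leaf_edge(tree, reference)


def bootstrap_support(
    matrix: BinaryMarkerMatrix,
    reps: int = 10_000,
    seed: Optional[int] = None,
    builder: Callable[[DistanceMatrix], Node] = bionj,
    variable_only: bool = False,
) -> Node:
    """Point-estimate tree with bootstrap supports on its internal edges.

    Marker columns are resampled with replacement (same width); each
    replicate rebuilds the distance matrix and tree, and the support of each
    internal edge of the point-estimate tree is the percentage of replicates
    whose tree contains the same bipartition.  By default every matrix
    column is resampled, including the constant germline-shared ones;
    ``variable_only=True`` restricts to columns that vary across samples.
    Deterministic for a fixed seed.
    """
    if reps < 1:
        raise ValueError("need at least one bootstrap replicate")
    if matrix.n_markers < 1:
        raise ValueError("need at least one marker to bootstrap")
    X = matrix.data
    if variable_only:
        keep = (X != X[0]).any(axis=0)
        X = X[:, keep]
        if X.shape[1] == 0:
            raise ValueError("no variable columns to bootstrap")
    labels = list(matrix.samples)
    tree = builder(DistanceMatrix(labels, _pair_distances(X)))
    splits = bipartitions(tree)
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    ncols = X.shape[1]
    for _ in range(reps):
        idx = rng.integers(0, ncols, size=ncols)
        rep_tree = builder(DistanceMatrix(labels, _pair_distances(X[:, idx])))
        rep_splits = bipartitions(rep_tree)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    for s, node in splits.items():
        node.support = 100.0 * counts[s] / reps
    return tree


# ---------------------------------------------------------------------------
# Clonality calls

@dataclass
class MonophylyResult:
    monophyletic: bool
    support: Optional[float]  # % support of the tumour clade (or smallest containing clade)
    clade: frozenset = field(default_factory=frozenset)


def tumour_monophyly(tree: Node, roles: Mapping[str, str]) -> MonophylyResult:
    """Do the tumour samples form a clade excluding normal and reference?

    Works on rooted or unrooted trees via bipartitions.  If not
    monophyletic, reports the support of the smallest clade containing all
    tumours (on the reference-rooted tree).
    """
    tumours = frozenset(s for s, r in roles.items() if r == "tumour")
    leaves = frozenset(tree.leaf_names())
    anchor = min(leaves)
    target = leaves - tumours if anchor in tumours else tumours
    splits = bipartitions(tree)
    if target in splits:
        return MonophylyResult(True, splits[target].support, tumours)
    # smallest clade containing all tumours, on the rooted view
    rooted = tree if REFERENCE_LABEL not in leaves else root_with_reference(tree)
    best_node, best_set = None, leaves
    for node, leafset in clade_leafsets(rooted).items():
        if tumours <= leafset and len(leafset) <= len(best_set):
            best_node, best_set = node, leafset
    support = best_node.support if best_node is not None else None
    return MonophylyResult(False, support, best_set)


@dataclass
class ContaminationReport:
    flagged: bool
    normal_in_tumour_clade: bool
    normal_branch_not_shorter: bool
    low_tumour_fraction: bool
    normal_branch_length: float
    min_tumour_branch_length: float
    tumour_associated_fraction: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def flag_normal_contamination(
    rooted_tree: Node,
    roles: Mapping[str, str],
    partition: PartitionSummary,
    matrix: Optional[BinaryMarkerMatrix] = None,
    min_tumour_fraction: float = 0.20,
) -> ContaminationReport:
    """Heuristics for neoplastic contamination of the normal sample.

    Flags when (a) the normal leaf falls inside the smallest clade holding
    all tumours, or (b) the normal terminal branch is at least as long as
    the shortest tumour terminal branch (tumour branches should carry the
    excess somatic load), or (c) the tumour-associated marker fraction is
    below ``min_tumour_fraction`` (a contaminated normal absorbs trunk
    markers into the all-shared class).

    When ``matrix`` is given, the terminal branches for rule (b) are taken
    from a BioNJ tree on squared Euclidean (marker-count) distances, which
    are additive on tree-like binary data, so terminal branches estimate
    per-sample mutation loads.  On the sqrt (display) scale the long
    germline-shared path deflates sample-to-sample distances and inflates
    the fitted normal branch even for a clean patient, which would make the
    rule fire spuriously.
    """
    normal = next(s for s, r in roles.items() if r == "normal")
    tumours = [s for s, r in roles.items() if r == "tumour"]
    leafsets = clade_leafsets(rooted_tree)
    tum_set = frozenset(tumours)
    smallest = None
    for node, leafset in leafsets.items():
        if tum_set <= leafset and (smallest is None or len(leafset) < len(smallest)):
            smallest = leafset
    inside = normal in (smallest or frozenset())
    if matrix is not None:
        dist = binary_distance(matrix)
        count_tree = bionj(DistanceMatrix(dist.labels, dist.values**2))
        branch_tree = (
            root_with_reference(count_tree)
            if REFERENCE_LABEL in dist.labels else count_tree
        )
    else:
        branch_tree = rooted_tree
    nb = branch_tree.find_leaf(normal).length
    tb = min(branch_tree.find_leaf(t).length for t in tumours)
    not_shorter = nb >= tb
    low_frac = partition.tumour_associated_fraction < min_tumour_fraction
    return ContaminationReport(
        flagged=inside or not_shorter or low_frac,
        normal_in_tumour_clade=inside,
        normal_branch_not_shorter=not_shorter,
        low_tumour_fraction=low_frac,
        normal_branch_length=float(nb),
        min_tumour_branch_length=float(tb),
        tumour_associated_fraction=partition.tumour_associated_fraction,
    )
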