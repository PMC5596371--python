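"""Phenetic clustering of karyotypes against ideal reference karyotypes.

Pipeline, applied to one asymmetry index at a time: the per-taxon index
values (real taxa plus the six ideal karyotypes) are categorized into
ordinal bins, pairwise distances are taken as absolute differences of the
ordinal codes, replicate UPGMA trees are built (replicates differ only in
the random resolution of tied joins and in leaf input order), a
majority-rule consensus (clades in more than half of the replicates) is
taken, and the consensus is rooted on the fully symmetric ideal karyotype A
as outgroup.

Trees are ``dendropy.Tree`` objects throughout and serialize as Newick with
consensus support percentages as internal-node labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CategoryBinning",
    "categorize",
    "distance_matrix",
    "upgma",
    "UPGMAResult",
    "majority_consensus",
    "root_on_outgroup",
    "run_cluster_analysis",
    "ClusterResult",
]


@dataclass(frozen=True)
class CategoryBinning:
    """Ordinal binning of an index: ``n_bins`` half-open bins over
    ``edges`` (ascending cut points, ``len(edges) == n_bins + 1``); the last
    bin is closed at the top so the full range is covered."""

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.edges) < 2:
            raise ValueError("need at least 2 edges")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @classmethod
    def equal_width(cls, values, n_bins: int = 5) -> "CategoryBinning":
        """Equal-width bins spanning the pooled range of ``values``."""
        lo = float(np.min(values))
        hi = float(np.max(values))
        if lo == hi:  # degenerate: widen symmetrically so binning stays valid
            lo, hi = lo - 0.5, hi + 0.5
        return cls(edges=tuple(np.linspace(lo, hi, n_bins + 1)))

    def assign(self, value: float, *, strict: bool = False) -> int:
        """Ordinal code (1-based) of ``value``; out-of-range values clamp to
        the end bins unless ``strict``."""
        if not np.isfinite(value):
            raise ValueError(f"cannot categorize non-finite value {value!r}")
        if value < self.edges[0] or value > self.edges[-1]:
            if strict:
                raise ValueError(
                    f"value {value!r} outside binning range "
                    f"[{self.edges[0]}, {self.edges[-1]}]"
                )
            return 1 if value < self.edges[0] else self.n_bins
        # half-open [lo, hi) bins, last bin closed at the top
        code = int(np.searchsorted(self.edges, value, side="right"))
        return min(code, self.n_bins) if code > 0 else 1


def categorize(values: pd.Series, binning: CategoryBinning) -> pd.Series:
    """Map per-taxon index values to ordinal category codes (1..n_bins)."""
    return pd.Series(
        [binning.assign(v) for v in values], index=values.index, dtype=int
    )


def distance_matrix(values) -> np.ndarray:
    """Pairwise absolute differences of per-taxon values (or ordinal codes)."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need a 1-d array of at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in distance input")
    return np.abs(arr[:, None] - arr[None, :])


@dataclass
class UPGMAResult:
    """A UPGMA tree plus its cophenetic distances (label-indexed)."""

    tree: dendropy.Tree
    cophenetic: pd.DataFrame


def upgma(
    dist: np.ndarray,
    labels: list[str],
    *,
    rng: np.random.Generator | None = None,
) -> UPGMAResult:
    """Agglomerate a distance matrix by UPGMA (average linkage).

    Cluster distances are the unweighted arithmetic means over member
    pairs; a join at distance d places the new node at height d/2, so the
    output tree is ultrametric.  When several pairs tie for the minimum
    distance, one is chosen uniformly at random from ``rng`` (first pair in
    row-major order when ``rng`` is None).
    """
    d = np.asarray(dist, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix does not match labels")
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    tns = dendropy.TaxonNamespace(labels)
    nodes: dict[int, dendropy.Node] = {}
    for i, lab in enumerate(labels):
        nodes[i] = dendropy.Node(taxon=tns.get_taxon(lab))
    sizes = {i: 1 for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dd = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    next_id = n
    active = list(range(n))

    while len(active) > 1:
        dmin = min(dd[key] for key in dd)
        ties = [key for key, v in dd.items() if v <= dmin + 1e-12]
        i, j = ties[0] if rng is None else ties[rng.integers(len(ties))]
        h = dd[(i, j)] / 2.0
        parent = dendropy.Node()
        for child in (i, j):
            nodes[child].edge.length = h - heights[child]
            parent.add_child(nodes[child])
        for a in members[i]:
            for b in members[j]:
                coph[a, b] = coph[b, a] = 2.0 * h
        k = next_id
        next_id += 1
        nodes[k] = parent
        heights[k] = h
        sizes[k] = sizes[i] + sizes[j]
        members[k] = members[i] + members[j]
        active = [x for x in active if x not in (i, j)]
        for x in active:
            dij_x = (
                sizes[i] * dd[tuple(sorted((x, i)))]
                + sizes[j] * dd[tuple(sorted((x, j)))]
            ) / sizes[k]
            dd[(x, k) if x < k else (k, x)] = dij_x
        dd = {
            key: v
            for key, v in dd.items()
            if i not in key and j not in key
        }
        active.append(k)

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[active[0]]
    tree.is_rooted = True
    return UPGMAResult(
        tree=tree,
        cophenetic=pd.DataFrame(coph, index=labels, columns=labels),
    )


def _leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def _clades(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial rooted clades (leaf-label sets of internal nodes below
    the root)."""
    all_leaves = _leaf_labels(tree)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(clade) < len(all_leaves):
            out.add(clade)
    return out


def _tree_from_clades(
    leaves: list[str],
    clades: dict[frozenset[str], float | None],
) -> dendropy.Tree:
    """Assemble a rooted dendropy tree from nested clades; values are
    support percentages stored as internal-node labels."""
    tns = dendropy.TaxonNamespace(sorted(leaves))
    root = dendropy.Node()
    node_of: dict[frozenset[str], dendropy.Node] = {frozenset(leaves): root}
    for clade in sorted(clades, key=len, reverse=True):
        nd = dendropy.Node()
        sup = clades[clade]
        if sup is not None:
            nd.label = f"{sup:g}"
        node_of[clade] = nd
    # attach each clade to the smallest strictly-containing clade
    for clade in sorted(clades, key=len, reverse=True):
        parents = [
            c for c in node_of if len(c) > len(clade) and clade < c
        ]
        parent = min(parents, key=len)
        node_of[parent].add_child(node_of[clade])
    for leaf in leaves:
        singles = [c for c in node_of if leaf in c and len(c) > 1]
        parent = min(singles, key=len)
        node_of[parent].add_child(
            dendropy.Node(taxon=tns.get_taxon(leaf))
        )
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def majority_consensus(trees: list[dendropy.Tree]) -> dendropy.Tree:
    """Majority-rule consensus of rooted trees.

    Retains exactly the clades present in strictly more than half of the
    input trees; conflicting minority clades collapse into polytomies.
    Support percentages are recorded as internal-node labels.
    """
    if not trees:
        raise ValueError("no trees given")
    leaf_sets = {_leaf_labels(t) for t in trees}
    if len(leaf_sets) != 1:
        raise ValueError("trees do not share a common leaf set")
    leaves = sorted(next(iter(leaf_sets)))
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for clade in _clades(t):
            counts[clade] = counts.get(clade, 0) + 1
    half = len(trees) / 2.0
    retained = {
        clade: 100.0 * cnt / len(trees)
        for clade, cnt in counts.items()
        if cnt > half
    }
    return _tree_from_clades(leaves, retained)


def root_on_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Re-root so that ``outgroup`` is sister to all remaining leaves.

    Each internal clade is read as an unrooted bipartition and re-oriented
    away from the outgroup, preserving every bipartition of the input
    topology; support labels travel with their bipartition.
    """
    leaves = sorted(_leaf_labels(tree))
    if outgroup not in leaves:
        raise ValueError(f"outgroup {outgroup!r} not among the leaves")
    all_set = frozenset(leaves)
    ingroup = all_set - {outgroup}
    support: dict[frozenset[str], float | None] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if not 1 < len(clade) < len(leaves):
            continue
        oriented = all_set - clade if outgroup in clade else clade
        if 1 < len(oriented) < len(ingroup) or oriented == ingroup:
            sup = None
            if node.label is not None:
                try:
                    sup = float(node.label)
                except ValueError:
                    sup = None
            if oriented not in support or support[oriented] is None:
                support[oriented] = sup
    support.setdefault(ingroup, None)
    return _tree_from_clades(leaves, support)


@dataclass
class ClusterResult:
    """Output of one per-index cluster analysis."""

    index_name: str
    codes: pd.Series
    binning: CategoryBinning
    replicate_trees: list[UPGMAResult] = field(repr=False)
    consensus: dendropy.Tree = field(repr=False)
    nearest_ideal: pd.DataFrame

    @property
    def newick(self) -> str:
        return self.consensus.as_string(schema="newick").strip()


def run_cluster_analysis(
    values: pd.Series,
    *,
    index_name: str = "",
    ideal_labels: list[str] | None = None,
    n_replicates: int = 10,
    binning: CategoryBinning | None = None,
    n_bins: int = 5,
    seed: int = 1,
    use_raw_values: bool = False,
    outgroup: str = "ideal_A",
) -> ClusterResult:
    """Full per-index pipeline: categorize, cluster, consense, root.

    ``values`` maps taxon labels (real taxa plus pseudo-taxa named
    ``ideal_A`` .. ``ideal_F``) to one index's values.  Returns the rooted
    consensus plus, per real taxon, the ideal karyotype at the smallest mean
    cophenetic distance over the replicate trees (ties resolved toward the
    more symmetric ideal).
    """
    if ideal_labels is None:
        ideal_labels = [f"ideal_{c}" for c in "ABCDEF" if f"ideal_{c}" in values.index]
    missing = [lab for lab in ideal_labels + [outgroup] if lab not in values.index]
    if missing:
        raise ValueError(f"missing pseudo-taxa in values: {sorted(set(missing))}")
    if binning is None:
        binning = CategoryBinning.equal_width(values.to_numpy(), n_bins=n_bins)
    codes = categorize(values, binning)
    feature = values.astype(float) if use_raw_values else codes.astype(float)
    labels = list(values.index)

    results: list[UPGMAResult] = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep + 1])
        order = list(rng.permutation(len(labels)))
        lab_perm = [labels[i] for i in order]
        d = distance_matrix(feature.loc[lab_perm].to_numpy())
        results.append(upgma(d, lab_perm, rng=rng))

    consensus = majority_consensus([r.tree for r in results])
    consensus = root_on_outgroup(consensus, outgroup)

    real = [lab for lab in labels if lab not in ideal_labels]
    mean_coph = sum(
        r.cophenetic.loc[labels, labels] for r in results
    ) / len(results)
    rows = []
    for taxon in real:
        dists = mean_coph.loc[taxon, ideal_labels]
        best = dists.idxmin()  # idxmin takes the first minimum: A before B...
        rows.append(
            {
                "taxon": taxon,
                "nearest_ideal": best.replace("ideal_", ""),
                "mean_cophenetic": float(dists.min()),
            }
        )
    nearest = pd.DataFrame(rows)
    return ClusterResult(
        index_name=index_name,
        codes=codes,
        binning=binning,
        replicate_trees=results,
        consensus=consensus,
        nearest_ideal=nearest,
    )
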