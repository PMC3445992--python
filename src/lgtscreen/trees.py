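"""Gene-tree I/O, taxonomy annotation, neighbor joining, bootstrap, rooting.

Trees are held as :class:`dendropy.Tree` objects wrapped in
:class:`AnnotatedGeneTree`, which adds a gene identifier and a per-leaf
taxonomy map. Bootstrap support values travel as internal-node labels in
Newick (integer percentages 0-100) and are mirrored onto ``node.support``
attributes after parsing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DOMAINS = ("Bacteria", "Archaea", "Eukaryota")


class NewickParseError(ValueError):
    """Malformed Newick input; carries an approximate character offset."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


@dataclass(frozen=True)
class TaxonRecord:
    """Taxonomy labels for one tree leaf.

    ``phylum`` may be empty only for eukaryotes (many protist lineages in
    public trees carry no stable phylum name); ``domain`` is always one of
    Bacteria / Archaea / Eukaryota.
    """

    leaf_id: str
    species: str
    genus: str
    phylum: str
    domain: str

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise ValueError(
                f"domain must be one of {DOMAINS}, got {self.domain!r}"
            )
        if not self.phylum and self.domain != "Eukaryota":
            raise ValueError(
                f"empty phylum only allowed for Eukaryota ({self.leaf_id})"
            )


@dataclass
class AnnotatedGeneTree:
    """A per-gene phylogeny whose leaves may carry :class:`TaxonRecord`s."""

    gene_id: str
    tree: dendropy.Tree
    annotations: dict[str, TaxonRecord] = field(default_factory=dict)

    @property
    def leaf_ids(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def record(self, leaf_id: str) -> TaxonRecord:
        try:
            return self.annotations[leaf_id]
        except KeyError:
            raise KeyError(f"leaf {leaf_id!r} has no taxonomy annotation")

    def is_fully_annotated(self) -> bool:
        return all(lid in self.annotations for lid in self.leaf_ids)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal.

    Triangle-inequality violations are tolerated (NJ accepts them) but
    reported by :meth:`triangle_violations`.
    """

    taxon_ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxon_ids)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")

    def triangle_violations(self, tol: float = 1e-9) -> int:
        n = len(self.taxon_ids)
        count = 0
        for i in range(n):
            for j in range(i + 1, n):
                if np.any(self.d[i, j] > self.d[i] + self.d[j] + tol):
                    count += 1
        return count

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.d, index=self.taxon_ids, columns=self.taxon_ids).to_csv(
            path, sep="\t"
        )


# ---------------------------------------------------------------------------
# Newick I/O


def _attach_supports(tree: dendropy.Tree) -> None:
    """Move numeric internal-node labels into ``node.support`` (int or None)."""
    for node in tree.preorder_node_iter():
        node.support = None
        if node.is_leaf():
            continue
        label = node.label
        if label is None:
            continue
        try:
            value = float(label)
        except ValueError:
            continue
        if not (0 <= value <= 100):
            raise NewickParseError(
                f"internal node label {label!r} outside bootstrap range [0, 100]"
            )
        node.support = int(round(value))


def parse_newick(data: str, gene_id: str = "") -> AnnotatedGeneTree:
    """Parse a Newick string into an (unannotated) :class:`AnnotatedGeneTree`.

    Numeric internal-node labels in [0, 100] are interpreted as bootstrap
    support of the subtending edge. Fewer than three leaves or duplicate
    leaf names are rejected.
    """
    try:
        tree = dendropy.Tree.get(
            data=data,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        offset = getattr(exc, "col_num", None)
        raise NewickParseError(f"malformed Newick: {exc}", offset=offset) from exc
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise NewickParseError(f"tree has {len(leaves)} leaves; need at least 3")
    if len(set(leaves)) != len(leaves):
        dupes = sorted({x for x in leaves if leaves.count(x) > 1})
        raise NewickParseError(f"duplicate leaf names: {dupes}")
    _attach_supports(tree)
    return AnnotatedGeneTree(gene_id=gene_id, tree=tree)


def read_newick(path, gene_id: str = "") -> AnnotatedGeneTree:
    with open(path) as fh:
        return parse_newick(fh.read(), gene_id=gene_id)


def write_newick(gtree: AnnotatedGeneTree, path=None) -> str:
    """Serialize; bootstrap supports are written as internal-node labels."""
    for node in gtree.tree.preorder_node_iter():
        if not node.is_leaf():
            support = getattr(node, "support", None)
            node.label = None if support is None else str(int(support))
    text = gtree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    ).strip() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Taxonomy


def read_taxonomy(path) -> dict[str, TaxonRecord]:
    """Read a taxonomy TSV with header ``leaf_id species genus phylum domain``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    expected = ["leaf_id", "species", "genus", "phylum", "domain"]
    if list(df.columns) != expected:
        raise ValueError(f"taxonomy header must be {expected}, got {list(df.columns)}")
    if df["leaf_id"].duplicated().any():
        dupes = sorted(df.loc[df["leaf_id"].duplicated(), "leaf_id"])
        raise ValueError(f"duplicate leaf_id in taxonomy table: {dupes}")
    return {
        row.leaf_id: TaxonRecord(row.leaf_id, row.species, row.genus, row.phylum, row.domain)
        for row in df.itertuples()
    }


def write_taxonomy(records: Mapping[str, TaxonRecord] | Iterable[TaxonRecord], path) -> None:
    if isinstance(records, Mapping):
        records = records.values()
    rows = [
        (r.leaf_id, r.species, r.genus, r.phylum, r.domain) for r in records
    ]
    pd.DataFrame(
        rows, columns=["leaf_id", "species", "genus", "phylum", "domain"]
    ).to_csv(path, sep="\t", index=False)


def annotate(
    gtree: AnnotatedGeneTree,
    taxonomy: Mapping[str, TaxonRecord],
    strict: bool = True,
) -> tuple[AnnotatedGeneTree, int]:
    """Attach taxonomy records to every leaf.

    In strict mode any leaf missing from the table is an error. In lenient
    mode unknown leaves are pruned; the number dropped is returned and the
    result must still have >= 3 leaves.
    """
    missing = [lid for lid in gtree.leaf_ids if lid not in taxonomy]
    if missing and strict:
        raise KeyError(f"leaves missing from taxonomy table: {sorted(missing)}")
    dropped = 0
    if missing:
        keep = [lid for lid in gtree.leaf_ids if lid in taxonomy]
        if len(keep) < 3:
            raise ValueError(
                f"dropping {len(missing)} unannotated leaves leaves "
                f"{len(keep)} < 3 leaves"
            )
        taxa = [
            t for t in gtree.tree.taxon_namespace if t.label in set(keep)
        ]
        gtree.tree.retain_taxa(taxa)
        dropped = len(missing)
        logger.info("annotate: dropped %d unannotated leaves", dropped)
    gtree.annotations = {lid: taxonomy[lid] for lid in gtree.leaf_ids}
    return gtree, dropped


# ---------------------------------------------------------------------------
# Bipartitions


def split_set(gtree: AnnotatedGeneTree | dendropy.Tree) -> set[frozenset]:
    """Nontrivial bipartitions as canonical frozensets of leaf labels.

    The canonical side of each split is the one *not* containing the
    alphabetically first leaf, so split sets compare equal across rootings
    and leaf orderings.
    """
    tree = gtree.tree if isinstance(gtree, AnnotatedGeneTree) else gtree
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = labels[0]
    all_leaves = frozenset(labels)
    splits: set[frozenset] = set()
    for node in tree.preorder_internal_node_iter():
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in below:
            below = all_leaves - below
        if 1 < len(below) < len(all_leaves) - 1:
            splits.add(below)
    return splits


# ---------------------------------------------------------------------------
# Neighbor joining

# Hand-written (rather than delegated) so that pair tie-breaking and the
# negative-branch-length convention are deterministic and documented:
# ties on the Q criterion join the lexicographically smallest (i, j) pair,
# and negative branch estimates are clamped to zero with the deficit
# moved to the sibling edge.


def build_nj_tree(dm: DistanceMatrix) -> AnnotatedGeneTree:
    """Neighbor joining (Saitou & Nei) on a distance matrix.

    Returns an unrooted tree whose leaves are exactly ``dm.taxon_ids``. On
    an additive matrix the tree's path-length distances reproduce the input
    to numerical precision.
    """
    n = len(dm.taxon_ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    d = dm.d.astype(float).copy()
    # nodes[i]: (dendropy node, sort key for deterministic tie-break)
    taxon_ns = dendropy.TaxonNamespace()
    nodes: list[tuple[dendropy.Node, str]] = []
    for name in dm.taxon_ids:
        taxon = taxon_ns.new_taxon(label=name)
        node = dendropy.Node(taxon=taxon)
        nodes.append((node, name))

    active = list(range(n))
    clamped = 0

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # all minimizing pairs, then break ties lexicographically by label
        ii, jj = np.where(np.isclose(q, qmin, rtol=0, atol=1e-12))
        candidates = sorted(
            (tuple(sorted((nodes[active[a]][1], nodes[active[b]][1]))), a, b)
            for a, b in zip(ii, jj)
            if a < b
        )
        _, ai, bj = candidates[0]
        i, j = active[ai], active[bj]

        li = 0.5 * sub[ai, bj] + (r[ai] - r[bj]) / (2 * (m - 2))
        lj = sub[ai, bj] - li
        if li < 0:
            lj += li
            li = 0.0
            clamped += 1
        if lj < 0:
            li += lj
            lj = 0.0
            clamped += 1

        parent = dendropy.Node()
        ni, _ = nodes[i]
        nj_, _ = nodes[j]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = max(li, 0.0)
        nj_.edge.length = max(lj, 0.0)

        # distances from the new node u to every other active node
        new_row = 0.5 * (d[i, active] + d[j, active] - d[i, j])
        d[i, active] = new_row
        d[active, i] = new_row
        d[i, i] = 0.0
        nodes[i] = (parent, min(nodes[i][1], nodes[j][1]))
        active.remove(j)

    # join the last three nodes at an unresolved central node
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lengths = []
    for val in (la, lb, lc):
        if val < 0:
            clamped += 1
            val = 0.0
        lengths.append(val)
    center = dendropy.Node()
    for idx, length in zip((a, b, c), lengths):
        child, _ = nodes[idx]
        center.add_child(child)
        child.edge.length = length

    if clamped:
        logger.info("build_nj_tree: clamped %d negative branch lengths", clamped)

    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = center
    tree.is_rooted = False
    out = AnnotatedGeneTree(gene_id="", tree=tree)
    for node in tree.preorder_node_iter():
        node.support = None
    return out


def tree_distance_matrix(gtree: AnnotatedGeneTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances of a tree (the additive matrix)."""
    pdm = gtree.tree.phylogenetic_distance_matrix()
    labels = sorted(lf.taxon.label for lf in gtree.tree.leaf_node_iter())
    taxa = {t.label: t for t in gtree.tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(
    characters: np.ndarray,
    taxon_ids: Sequence[str],
    tree_builder: Callable[[np.ndarray, Sequence[str]], AnnotatedGeneTree],
    n_reps: int,
    seed: int,
) -> dict[frozenset, float]:
    """Bootstrap support for every split of the full-data tree.

    ``characters`` is a taxa-by-columns matrix of resampleable characters;
    ``tree_builder`` maps a resampled matrix (plus taxon ids) to a tree.
    Columns are resampled with replacement; support of a split is the
    percentage of replicate trees containing the same bipartition.
    Resampling draws column indices in a canonical (taxon-order-free) way,
    so the result is invariant to taxon input order at fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    characters = np.asarray(characters)
    if characters.shape[0] != len(taxon_ids):
        raise ValueError("characters must have one row per taxon")
    full_tree = tree_builder(characters, taxon_ids)
    target = split_set(full_tree)
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    ncols = characters.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rep_tree = tree_builder(characters[:, cols], taxon_ids)
        rep_splits = split_set(rep_tree)
        for split in target:
            if split in rep_splits:
                counts[split] += 1
    return {split: 100.0 * c / n_reps for split, c in counts.items()}


def apply_bootstrap(gtree: AnnotatedGeneTree, supports: Mapping[frozenset, float]) -> None:
    """Write split supports onto the tree's internal ``node.support`` fields."""
    labels = sorted(lf.taxon.label for lf in gtree.tree.leaf_node_iter())
    anchor = labels[0]
    all_leaves = frozenset(labels)
    for node in gtree.tree.preorder_internal_node_iter():
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in below:
            below = all_leaves - below
        if below in supports:
            node.support = int(round(supports[below]))


def hamming_distance_matrix(characters: np.ndarray, taxon_ids: Sequence[str]) -> DistanceMatrix:
    """Per-site mismatch fraction between rows; a simple bootstrap substrate."""
    characters = np.asarray(characters)
    n = characters.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.mean(characters[i] != characters[j])
    return DistanceMatrix(list(taxon_ids), d)


def nj_from_characters(characters: np.ndarray, taxon_ids: Sequence[str]) -> AnnotatedGeneTree:
    """Hamming distances -> NJ; the default ``tree_builder`` for bootstrap."""
    return build_nj_tree(hamming_distance_matrix(characters, taxon_ids))


# ---------------------------------------------------------------------------
# Rooting


def midpoint_root(gtree: AnnotatedGeneTree) -> AnnotatedGeneTree:
    """Root at the midpoint of the longest leaf-to-leaf path (in place).

    With all-zero branch lengths there is no length signal; the root is
    placed on a centroid edge instead and a warning is logged.
    """
    tree = gtree.tree
    lengths = [e.length or 0.0 for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
    if all(l == 0.0 for l in lengths):
        logger.warning("midpoint_root: all branch lengths zero; rooting at centroid edge")
        _root_at_centroid_edge(tree)
        tree.is_rooted = True
        return gtree

    # support labels belong to splits, which re-rooting preserves;
    # dendropy moves node labels around, so pin supports to splits first
    supports = _support_by_split(tree)

    u, v, diameter = _diameter_pair(tree)
    half = diameter / 2.0
    cum = 0.0
    for child, length, ascending in _path_edges(tree, u, v):
        if cum + length >= half - 1e-12:
            offset_from_u_end = half - cum  # along this edge, from the u side
            from_parent = (
                length - offset_from_u_end if ascending else offset_from_u_end
            )
            _reroot_within_edge(tree, child, from_parent)
            break
        cum += length
    _restore_supports(tree, supports)
    tree.is_rooted = True
    return gtree


def _diameter_pair(tree):
    pdm = tree.phylogenetic_distance_matrix()
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    best = (None, None, -1.0)
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            d = pdm.patristic_distance(a.taxon, b.taxon)
            if d > best[2]:
                best = (a, b, d)
    return best


def _path_edges(tree, u, v):
    """Edges on the u->v path as (child_node, length, ascending) triples."""
    anc_u = [u] + list(u.ancestor_iter())
    anc_v = set([v] + list(v.ancestor_iter()))
    lca = next(nd for nd in anc_u if nd in anc_v)
    edges = []
    node = u
    while node is not lca:
        edges.append((node, node.edge.length or 0.0, True))
        node = node.parent_node
    down = []
    node = v
    while node is not lca:
        down.append((node, node.edge.length or 0.0, False))
        node = node.parent_node
    return edges + list(reversed(down))


def _reroot_within_edge(tree, child, from_parent):
    """Place the root on the edge above ``child``, ``from_parent`` below its
    parent; a zero/full offset roots at the adjacent node instead."""
    length = child.edge.length or 0.0
    eps = 1e-12
    if from_parent <= eps:
        target = child.parent_node
    elif from_parent >= length - eps:
        target = child
        if target.is_leaf():  # cannot root at a leaf; nudge inside the edge
            target = None
    else:
        target = None
    if target is None:
        parent = child.parent_node
        mid = dendropy.Node()
        parent.remove_child(child)
        parent.add_child(mid)
        mid.edge.length = min(max(from_parent, eps), length - eps)
        mid.add_child(child)
        child.edge.length = length - mid.edge.length
        target = mid
    if target is not tree.seed_node:
        tree.reroot_at_node(target, update_bipartitions=False,
                            suppress_unifurcations=True)


def _support_by_split(tree: dendropy.Tree) -> dict[frozenset, int]:
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor, all_leaves = labels[0], frozenset(labels)
    out = {}
    for node in tree.preorder_internal_node_iter():
        support = getattr(node, "support", None)
        if support is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in below:
            below = all_leaves - below
        out[below] = support
    return out


def _restore_supports(tree: dendropy.Tree, supports: dict[frozenset, int]) -> None:
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor, all_leaves = labels[0], frozenset(labels)
    for node in tree.preorder_node_iter():
        node.support = None
        node.label = None
    for node in tree.preorder_internal_node_iter():
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in below:
            below = all_leaves - below
        if below in supports:
            node.support = supports[below]


def _root_at_centroid_edge(tree: dendropy.Tree) -> None:
    """Root on the edge minimizing the larger leaf count of its two sides."""
    n_total = sum(1 for _ in tree.leaf_node_iter())
    best, best_node = None, None
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = sum(1 for _ in node.leaf_iter())
        worst_side = max(below, n_total - below)
        if best is None or worst_side < best:
            best, best_node = worst_side, node
    supports = _support_by_split(tree)
    tree.reroot_at_edge(best_node.edge, update_bipartitions=False)
    _restore_supports(tree, supports)


def max_root_to_leaf_depth(gtree: AnnotatedGeneTree) -> float:
    tree = gtree.tree
    return max(
        lf.distance_from_root() for lf in tree.leaf_node_iter()
    )
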