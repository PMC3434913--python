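"""Tree-guided partitioning and the net p-distance gap search.

Given a rooted tree with posterior-probability support on internal nodes,
specimens are grouped by moving outward from the root until supported nodes
(PP >= ``pp_min``, default 0.95) are encountered; each supported node's tip
set becomes one block and tips that never pass a supported node become
singletons.  Repeating the traversal inside each block yields a refinement
chain of candidate partitions ("rings").  For each ring the gap search
compares the maximum within-block mean p-distance against the minimum
between-block *net* p-distance; rings with a positive gap are admissible and
the admissible ring with the largest gap is preferred.

A UPGMA stand-in builds an ultrametric tree from a distance matrix when no
externally estimated chronogram is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import InputError, ModelError, ParseError
from .partition import Partition
from .seqdata import DistanceMatrix, _within_mean, net_between_distance


# ---------------------------------------------------------------------------
# tree plumbing


def _leaf_labels(node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def node_support(node) -> float | None:
    """Support value attached to a node, or None when absent."""
    return getattr(node, "support", None)


def _attach_supports(tree: dendropy.Tree) -> None:
    for nd in tree.preorder_node_iter():
        sup = None
        if not nd.is_leaf():
            if nd.label is not None:
                try:
                    sup = float(nd.label)
                except ValueError:
                    sup = None
            if sup is None:
                v = nd.annotations.get_value("posterior")
                if v is not None:
                    try:
                        sup = float(v)
                    except (TypeError, ValueError):
                        sup = None
        nd.support = sup


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick tree, reading internal-node labels (or BEAST-style
    ``posterior`` comment fields) as support values.  Missing supports are
    stored as ``None``, never as 0."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise ParseError(f"invalid Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = sorted({x for x in labels if labels.count(x) > 1})
    if dupes:
        raise ParseError(f"duplicate tip labels: {dupes}")
    _attach_supports(tree)
    return tree


def read_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree with supports encoded as internal-node labels."""
    t = tree.clone(depth=1)
    for nd in t.preorder_node_iter():
        if not nd.is_leaf():
            sup = getattr(nd, "support", None)
            nd.label = None if sup is None else f"{sup:.4f}"
    return t.as_string(schema="newick", suppress_rooting=True).strip()


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")


def set_node_ages(tree: dendropy.Tree, ultrametric_tol: float | None = None) -> float:
    """Attach ``node.age`` (time before present) to every node; returns depth.

    When ``ultrametric_tol`` is given, raise :class:`ModelError` if root-to-tip
    path lengths differ by more than the tolerance.
    """
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaf_depths = [lf.root_distance for lf in tree.leaf_node_iter()]
    depth = max(leaf_depths)
    if ultrametric_tol is not None and depth - min(leaf_depths) > ultrametric_tol:
        raise ModelError(
            "tree is not ultrametric (root-to-tip spread "
            f"{depth - min(leaf_depths):.3g} > {ultrametric_tol:.3g}); supply a "
            "chronogram or build one with upgma_tree"
        )
    for nd in tree.preorder_node_iter():
        nd.age = 0.0 if nd.is_leaf() else depth - nd.root_distance
    return depth


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> bool:
    try:
        set_node_ages(tree, ultrametric_tol=tol)
    except ModelError:
        return False
    return True


def upgma_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """UPGMA (average-linkage) ultrametric tree from a distance matrix.

    Node height is half the merge distance; supports are absent.
    """
    if len(dm.ids) < 2:
        raise InputError("need >= 2 taxa for UPGMA")
    if not np.all(np.isfinite(dm.d)):
        raise InputError("non-finite distances in matrix")
    Z = linkage(squareform(dm.d, checks=False), method="average")
    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[int, tuple[dendropy.Node, float]] = {}
    for i, sid in enumerate(dm.ids):
        nd = dendropy.Node()
        nd.taxon = taxa.get_taxon(sid)
        nodes[i] = (nd, 0.0)
    n = len(dm.ids)
    for k, (a, b, h, _) in enumerate(Z):
        parent = dendropy.Node()
        height = h / 2.0
        for child_key in (int(a), int(b)):
            child, child_h = nodes.pop(child_key)
            child.edge.length = height - child_h
            parent.add_child(child)
        nodes[n + k] = (parent, height)
    (root, _), = nodes.values()
    tree.seed_node = root
    _attach_supports(tree)
    return tree


# ---------------------------------------------------------------------------
# ring partitions


def _cut_below(children, pp_min: float):
    """Blocks obtained by descending from ``children`` to the first supported
    node on each path; returns (blocks, block -> cut node or None)."""
    blocks: list[frozenset[str]] = []
    cut_nodes: dict[frozenset[str], object] = {}
    stack = list(children)
    while stack:
        nd = stack.pop()
        if nd.is_leaf():
            b = frozenset([nd.taxon.label])
            blocks.append(b)
            cut_nodes[b] = None
        else:
            sup = node_support(nd)
            if sup is not None and sup >= pp_min:
                b = _leaf_labels(nd)
                blocks.append(b)
                cut_nodes[b] = nd
            else:
                stack.extend(nd.child_nodes())
    return blocks, cut_nodes


def _has_supported_below(node, pp_min: float) -> bool:
    for nd in node.preorder_iter():
        if nd is node or nd.is_leaf():
            continue
        sup = node_support(nd)
        if sup is not None and sup >= pp_min:
            return True
    return False


def ring_partitions(tree: dendropy.Tree, pp_min: float = 0.95, n_levels: int = 3) -> list[Partition]:
    """Partitions at successive supported-node rings, root outward.

    Level 1 cuts each root-to-tip path at the first supported node below the
    root (the root itself never defines a block); level k+1 recurses inside
    each level-k block to its next supported nodes.  Blocks whose subtree
    contains no further supported node persist unchanged, so the levels form a
    refinement chain.
    """
    root = tree.seed_node
    all_tips = _leaf_labels(root)
    if not _has_supported_below(root, pp_min):
        warnings.warn("no supported nodes at all; returning single-block partitions")
        return [Partition([all_tips], method="treepart", parameter=("level", k + 1))
                for k in range(n_levels)]
    blocks, cut_nodes = _cut_below(root.child_nodes(), pp_min)
    levels = [Partition(blocks, method="treepart", parameter=("level", 1))]
    for k in range(1, n_levels):
        new_blocks: list[frozenset[str]] = []
        new_cuts: dict[frozenset[str], object] = {}
        for b in blocks:
            c = cut_nodes.get(b)
            if c is None or not _has_supported_below(c, pp_min):
                new_blocks.append(b)
                new_cuts[b] = c
            else:
                sub, subcuts = _cut_below(c.child_nodes(), pp_min)
                new_blocks.extend(sub)
                new_cuts.update(subcuts)
        blocks, cut_nodes = new_blocks, new_cuts
        levels.append(Partition(blocks, method="treepart", parameter=("level", k + 1)))
    return levels


# ---------------------------------------------------------------------------
# gap search


@dataclass
class GapReport:
    """Within/between p-distance summary for one ring partition."""

    level: int
    partition: Partition
    max_within: float
    min_between_net: float | None
    gap: float | None
    admissible: bool
    preferred: bool = False

    def row(self) -> str:
        mb = "NA" if self.min_between_net is None else f"{self.min_between_net:.6f}"
        gp = "NA" if self.gap is None else f"{self.gap:.6f}"
        return (f"{self.level}\t{self.partition.n_blocks}\t{self.max_within:.6f}\t"
                f"{mb}\t{gp}\t{int(self.admissible)}\t{int(self.preferred)}")


def gap_search(partitions: list[Partition], dm: DistanceMatrix) -> list[GapReport]:
    """Evaluate each ring partition's barcode gap.

    ``max_within`` is the maximum block-mean within distance, ``min_between_net``
    the minimum pairwise net p-distance between blocks; a level is admissible
    when the gap is positive, and the admissible level with the largest gap is
    flagged preferred (ties toward the earlier level).
    """
    if not partitions:
        raise InputError("no partitions to evaluate")
    reports: list[GapReport] = []
    for lvl, part in enumerate(partitions, start=1):
        max_within = max(_within_mean(dm, sorted(b)) for b in part.blocks)
        if part.n_blocks < 2:
            reports.append(GapReport(lvl, part, max_within, None, None, False))
            continue
        min_net = min(
            net_between_distance(dm, sorted(a), sorted(b))
            for a, b in combinations(part.blocks, 2)
        )
        gap = min_net - max_within
        reports.append(GapReport(lvl, part, max_within, min_net, gap, gap > 0))
    best = None
    for r in reports:
        if r.admissible and (best is None or r.gap > best.gap):
            best = r
    if best is not None:
        best.preferred = True
    return reports


def write_gap_reports(reports: list[GapReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("level\tn_blocks\tmax_within\tmin_between_net\tgap\tadmissible\tpreferred\n")
        for r in reports:
            fh.write(r.row() + "\n")
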