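"""Newick I/O and rooted-topology utilities built on dendropy.

Trees are ``dendropy.Tree`` objects, always treated as rooted; congruence
comparisons (Robinson-Foulds) are made in the unrooted sense on shared leaf
sets.  Multifurcations are allowed and treated as soft polytomies.
"""

from __future__ import annotations

from typing import Iterable

import dendropy
from dendropy.calculate import treecompare

from magtrace.errors import InputError, NewickParseError


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single rooted tree from a newick string.

    Underscores in unquoted labels are preserved verbatim.  Duplicate leaf
    labels are rejected.
    """
    if not text or not text.strip():
        raise NewickParseError("empty newick string")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        pos = getattr(exc, "column", None)
        raise NewickParseError(str(exc), position=pos) from exc
    labels = leaf_labels(tree)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickParseError(f"duplicate leaf labels: {', '.join(dupes)}")
    if any(l is None for l in labels):
        raise NewickParseError("unlabeled leaf in newick input")
    return tree


def read_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def _needs_quoting(label: str) -> bool:
    return any(ch in label for ch in " ()[]{}:;,'\"")


def _node_newick(node: dendropy.Node) -> str:
    children = node.child_nodes()
    if children:
        body = "(" + ",".join(_node_newick(c) for c in children) + ")"
        label = node.label or ""
    else:
        label = node.taxon.label if node.taxon else (node.label or "")
    if label and _needs_quoting(label):
        label = "'" + label.replace("'", "''") + "'"
    s = (body if children else "") + label
    if node.edge.length is not None:
        s += f":{node.edge.length:g}"
    return s


def serialize(tree: dendropy.Tree) -> str:
    """Compact newick string (no rooting token, trailing ';')."""
    return _node_newick(tree.seed_node) + ";"


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(serialize(tree) + "\n")


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label if lf.taxon else lf.label for lf in tree.leaf_node_iter()]


def restrict_to_leaves(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Induced topology on ``keep``; suppressed degree-2 nodes sum lengths."""
    keep = set(keep)
    labels = set(leaf_labels(tree))
    unknown = keep - labels
    if unknown:
        raise InputError(f"unknown leaves: {', '.join(sorted(unknown))}")
    if len(keep) < 2:
        raise InputError("restriction needs at least 2 leaves")
    sub = tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True
    )
    sub.is_rooted = True
    # drop a possible leftover unifurcate root (outgroup removed)
    seed = sub.seed_node
    while len(seed.child_nodes()) == 1:
        child = seed.child_nodes()[0]
        if child.edge.length is not None and seed.edge.length is not None:
            child.edge.length += seed.edge.length
        sub.seed_node = child
        child.parent_node = None
        seed = child
    return sub


def _to_common_namespace(t1: dendropy.Tree, t2: dendropy.Tree):
    tns = dendropy.TaxonNamespace()
    c1 = dendropy.Tree.get(
        data=serialize(t1),
        schema="newick",
        taxon_namespace=tns,
        preserve_underscores=True,
        rooting="force-rooted",
    )
    c2 = dendropy.Tree.get(
        data=serialize(t2),
        schema="newick",
        taxon_namespace=tns,
        preserve_underscores=True,
        rooting="force-rooted",
    )
    return c1, c2


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance (symmetric bipartition difference).

    Zero iff the two trees are topologically identical in the unrooted sense.
    """
    l1, l2 = set(leaf_labels(t1)), set(leaf_labels(t2))
    if l1 != l2:
        only1 = sorted(l1 - l2)
        only2 = sorted(l2 - l1)
        raise InputError(
            f"leaf sets differ (only in first: {only1}; only in second: {only2})"
        )
    c1, c2 = _to_common_namespace(t1, t2)
    c1.is_rooted = False
    c2.is_rooted = False
    c1.encode_bipartitions()
    c2.encode_bipartitions()
    return int(treecompare.symmetric_difference(c1, c2))


def is_monophyletic(tree: dendropy.Tree, group: Iterable[str]) -> bool:
    """True iff some clade of the rooted tree contains exactly ``group``."""
    group = set(group)
    if not group:
        raise InputError("empty group")
    labels = set(leaf_labels(tree))
    unknown = group - labels
    if unknown:
        raise InputError(f"unknown leaves: {', '.join(sorted(unknown))}")
    if len(group) == 1:
        return True
    mrca = tree.mrca(taxon_labels=group)
    if mrca is None:
        return False
    under = {lf.taxon.label for lf in mrca.leaf_iter()}
    return under == group
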