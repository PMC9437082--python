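"""Faith's phylogenetic diversity and the PD gain attributable to uncultured taxa.

Faith's PD of a leaf subset is the sum of branch lengths over the union of
root-to-leaf paths (root-inclusive by default, matching the common `pd`
implementation; a root-exclusive toggle is provided).  The relative PD gain
contributed by lineages absent from the cultured subset is

    gain% = 100 * (PD_all - PD_cultured) / PD_cultured.

Trees are plain Newick with branch lengths; parsing is delegated to
scikit-bio's ``TreeNode`` with added duplicate-label validation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable

from skbio import TreeNode

__all__ = ["PDGain", "parse_newick", "write_newick", "faith_pd", "pd_gain", "total_branch_length"]


@dataclass
class PDGain:
    pd_all: float
    pd_subset: float

    @property
    def gain_percent(self) -> float:
        return 100.0 * (self.pd_all - self.pd_subset) / self.pd_subset


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a rooted tree, validating leaf labels."""
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except Exception as err:
        raise ValueError(f"malformed Newick: {err}") from err
    names = [t.name for t in tree.tips()]
    if any(n is None for n in names):
        raise ValueError("unlabeled leaf in Newick input")
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length at {node.name!r}")
    return tree


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def total_branch_length(tree: TreeNode) -> float:
    return sum(n.length or 0.0 for n in tree.traverse(include_self=True))


def faith_pd(tree: TreeNode, leaves: Iterable[str], include_root: bool = True) -> float:
    """Sum of branch lengths on the union of root paths of the selected leaves.

    ``include_root=True`` counts every edge from a selected leaf up to and
    including the root's own stem; the root-exclusive variant stops below any
    edge shared by *all* selected leaves' paths only at the root itself.
    """
    wanted = set(leaves)
    if not wanted:
        raise ValueError("leaf subset must be nonempty")
    tips = {t.name: t for t in tree.tips()}
    unknown = sorted(wanted - tips.keys())
    if unknown:
        raise ValueError(f"unknown leaves: {unknown}")
    covered: set[int] = set()
    total = 0.0
    for name in wanted:
        node = tips[name]
        while node is not None:
            nid = id(node)
            if nid in covered:
                break
            covered.add(nid)
            if node.parent is not None or include_root:
                total += node.length or 0.0
            node = node.parent
    return total


def pd_gain(tree: TreeNode, cultured_leaves: Iterable[str], include_root: bool = True) -> PDGain:
    """PD of the whole tree vs the cultured subset, and the uncultured gain."""
    cultured = set(cultured_leaves)
    if not cultured:
        raise ValueError("cultured leaf set must be nonempty (gain undefined)")
    all_leaves = {t.name for t in tree.tips()}
    pd_all = faith_pd(tree, all_leaves, include_root=include_root)
    pd_subset = faith_pd(tree, cultured, include_root=include_root)
    return PDGain(pd_all=pd_all, pd_subset=pd_subset)
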