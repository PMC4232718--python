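"""Rooted phylogenies with branch-partition tags.

Trees are parsed with dendropy from Newick.  Branch partition tags — the
foreground/background labelling used by two-ratio and clade codon models —
are encoded in Newick as a ``#k`` suffix on the node label subtending the
branch (``(A#1:0.1,B:0.2)#1:0.05`` puts the branches to A and to the (A,B)
ancestor in partition 1).  Untagged branches are partition 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import dendropy

__all__ = ["Branch", "PhyloTree"]


@dataclass
class Branch:
    """One branch = the edge above a non-root node."""

    index: int
    name: str
    length: float
    tag: int


def _split_tag(label: str | None) -> tuple[str | None, int | None]:
    if label is None or "#" not in label:
        return label, None
    base, _, k = label.rpartition("#")
    try:
        tag = int(k)
    except ValueError as exc:
        raise ValueError(f"malformed branch tag in label {label!r}") from exc
    return (base or None), tag


class PhyloTree:
    """A rooted tree with branch lengths (expected substitutions/codon)
    and one partition tag per branch."""

    def __init__(self, dtree: dendropy.Tree):
        dtree.is_rooted = True
        self._tree = dtree
        self._extract_tags()
        self._reindex()

    # -- construction ---------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"invalid Newick: {exc}") from exc
        return cls(dtree)

    @classmethod
    def read_newick(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    def _extract_tags(self) -> None:
        for node in self._tree:
            label = node.taxon.label if node.taxon is not None else node.label
            base, tag = _split_tag(label)
            if node.taxon is not None:
                if base is None:
                    raise ValueError("leaf with empty label")
                node.taxon.label = base
            else:
                node.label = base
            node.partition_tag = tag if tag is not None else 0

    def _reindex(self) -> None:
        self.postorder: list[dendropy.Node] = list(
            self._tree.postorder_node_iter()
        )
        self.root = self._tree.seed_node
        labels = [lf.taxon.label for lf in self._tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels are not unique")
        self.leaf_labels: list[str] = labels
        self._leaf_by_label = {
            lf.taxon.label: lf for lf in self._tree.leaf_node_iter()
        }
        self.branches: list[Branch] = []
        for node in self.postorder:
            if node is self.root:
                node.branch_index = None
                continue
            length = node.edge.length
            if length is None:
                length = 0.0
            length = float(length)
            if not math.isfinite(length) or length < 0:
                raise ValueError(
                    f"branch length {length!r} above {self._node_name(node)} "
                    "must be finite and >= 0"
                )
            idx = len(self.branches)
            node.branch_index = idx
            self.branches.append(
                Branch(idx, self._node_name(node), length, int(node.partition_tag))
            )

    def _node_name(self, node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        if node.label:
            return node.label
        leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
        return "stem(" + "+".join(leaves) + ")"

    # -- queries --------------------------------------------------------
    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def leaf_set(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def branch(self, name: str) -> Branch:
        for br in self.branches:
            if br.name == name:
                return br
        raise KeyError(f"no branch named {name!r}")

    def node_of_branch(self, index: int) -> dendropy.Node:
        for node in self.postorder:
            if getattr(node, "branch_index", None) == index:
                return node
        raise KeyError(index)

    def mrca(self, taxa: Iterable[str]) -> dendropy.Node:
        """Least common ancestor of ``taxa`` under the rooted topology."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("mrca of an empty taxon set is undefined")
        unknown = [t for t in taxa if t not in self._leaf_by_label]
        if unknown:
            raise KeyError(f"taxa not in tree: {unknown}")
        nodes = [self._leaf_by_label[t] for t in taxa]
        if len(nodes) == 1:
            return nodes[0]
        # intersect root-paths
        paths = []
        for nd in nodes:
            path = []
            cur = nd
            while cur is not None:
                path.append(cur)
                cur = cur.parent_node
            paths.append(path)
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # deepest common ancestor = first on any root-path
        for nd in paths[0]:
            if nd in common:
                return nd
        raise RuntimeError("unreachable: rooted tree always has an MRCA")

    # -- tagging --------------------------------------------------------
    def set_tag(self, branch_name: str, tag: int) -> None:
        br = self.branch(branch_name)
        br.tag = int(tag)
        self.node_of_branch(br.index).partition_tag = int(tag)

    def tag_clade(self, taxa: Iterable[str], tag: int, include_stem: bool = True) -> list[str]:
        """Tag the stem branch of MRCA(taxa) and every descendant branch.

        Returns the names of the branches tagged.  This is the default
        "foreground = mapped origin branch plus descendants" rule used when
        deriving model partitions from mapped inactivation events.
        """
        anc = self.mrca(taxa)
        tagged = []
        nodes = list(anc.preorder_iter())
        if not include_stem:
            nodes = nodes[1:]
        for node in nodes:
            if getattr(node, "branch_index", None) is None:
                continue
            br = self.branches[node.branch_index]
            br.tag = int(tag)
            node.partition_tag = int(tag)
            tagged.append(br.name)
        return tagged

    def clear_tags(self) -> None:
        for br in self.branches:
            br.tag = 0
        for node in self.postorder:
            node.partition_tag = 0

    @property
    def tags(self) -> dict[str, int]:
        return {br.name: br.tag for br in self.branches}

    # -- serialization --------------------------------------------------
    def to_newick(self) -> str:
        def render(node: dendropy.Node) -> str:
            if node.is_leaf():
                core = node.taxon.label
            else:
                core = (
                    "("
                    + ",".join(render(ch) for ch in node.child_nodes())
                    + ")"
                    + (node.label or "")
                )
            if node is self.root:
                return core
            br = self.branches[node.branch_index]
            tag = f"#{br.tag}" if br.tag != 0 else ""
            return f"{core}{tag}:{br.length:.10g}"

        return render(self.root) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def copy(self) -> "PhyloTree":
        return PhyloTree.from_newick(self.to_newick())

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({len(self.leaf_labels)} leaves, {self.n_branches} branches)"
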