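"""Placing inactivation events on a species tree (Dollo logic).

An inactivating mutation shared identically by a set of carrier taxa is
assumed to have arisen once and never reverted (Dollo).  If the carriers
form a clade, the event maps to that clade's stem branch; otherwise the
minimal no-reversal explanation places independent origins on the stems of
the maximal carrier-only clades.  When exactly one non-carrier leaf nests
inside the carriers' MRCA, the alternative "single origin on the MRCA stem
plus one reversal" is recorded as a note — point stop codons can revert,
indels essentially never do, so strict Dollo remains the primary call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .orf_scan import InactivationEvent
from .phylo import PhyloTree

__all__ = ["MappedEvent", "map_event", "gene_loss_summary", "mapped_events_table"]


@dataclass
class MappedEvent:
    event: InactivationEvent
    origin_branches: frozenset[str]
    monophyletic: bool
    n_independent_origins: int
    note: str | None = None


def _maximal_carrier_clades(tree: PhyloTree, carriers: frozenset[str]) -> list:
    """Nodes whose leaf set is wholly inside carriers and that are maximal."""
    result = []

    def visit(node) -> bool:
        """Return True if the subtree at node is carrier-only."""
        if node.is_leaf():
            return node.taxon.label in carriers
        flags = [(ch, visit(ch)) for ch in node.child_nodes()]
        if all(f for _, f in flags):
            return True
        for ch, inside in flags:
            if inside:
                result.append(ch)
        return False

    if visit(tree.root):
        # every leaf is a carrier: origin on the root's children? The event
        # predates the root; report the root itself as a single origin.
        result.append(tree.root)
    return result


def map_event(tree: PhyloTree, event: InactivationEvent) -> MappedEvent:
    """Map one event's carriers onto the tree under the Dollo assumption."""
    carriers = frozenset(event.carriers)
    if not carriers:
        raise ValueError("event has no carriers")
    unknown = carriers - set(tree.leaf_labels)
    if unknown:
        raise ValueError(f"carriers not in tree: {sorted(unknown)}")

    clades = _maximal_carrier_clades(tree, carriers)
    names = []
    for node in clades:
        if node is tree.root:
            names.append("root")
        else:
            names.append(tree.branches[node.branch_index].name)
    n_origins = len(clades)
    mrca = tree.mrca(carriers)
    mrca_leaves = tree.leaf_set(mrca)
    monophyletic = mrca_leaves == carriers

    note = None
    if not monophyletic:
        non_carriers = mrca_leaves - carriers
        if len(non_carriers) == 1:
            (rev,) = non_carriers
            stem = (
                "root"
                if mrca is tree.root
                else tree.branches[mrca.branch_index].name
            )
            note = (
                f"alternative: single origin on {stem} with one reversal in {rev}"
            )
    return MappedEvent(
        event=event,
        origin_branches=frozenset(names),
        monophyletic=monophyletic,
        n_independent_origins=n_origins,
        note=note,
    )


def _root_depth(tree: PhyloTree, branch_name: str) -> int:
    if branch_name == "root":
        return 0
    node = tree.node_of_branch(tree.branch(branch_name).index)
    depth = 0
    while node.parent_node is not None:
        depth += 1
        node = node.parent_node
    return depth


def gene_loss_summary(
    tree: PhyloTree,
    mapped_events: Mapping[str, Iterable[MappedEvent]],
    lineages: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Per-gene earliest origin branch per lineage, plus independence calls.

    ``lineages`` maps a lineage name to its leaf set (e.g. cetaceans vs
    Hippopotamidae); default is a single lineage spanning all leaves.  Two
    lineages are called "independent" for a gene when no single event's
    carriers span both — each lineage then lost the gene on its own.
    """
    if lineages is None:
        lineages = {"all": list(tree.leaf_labels)}
    lineages = {k: frozenset(v) for k, v in lineages.items()}
    rows = []
    for gene, events in mapped_events.items():
        events = list(events)
        if not events:
            raise ValueError(f"gene {gene!r} has no mapped events")
        for lin_name, lin_leaves in lineages.items():
            hits = [
                me for me in events if frozenset(me.event.carriers) & lin_leaves
            ]
            if not hits:
                continue
            # earliest = origin branch closest to the root over this lineage
            best: tuple[int, str, MappedEvent] | None = None
            for me in hits:
                for br in me.origin_branches:
                    br_node_leaves = (
                        frozenset(tree.leaf_labels)
                        if br == "root"
                        else tree.leaf_set(
                            tree.node_of_branch(tree.branch(br).index)
                        )
                    )
                    if not br_node_leaves & lin_leaves:
                        continue
                    depth = _root_depth(tree, br)
                    if best is None or depth < best[0]:
                        best = (depth, br, me)
            if best is None:
                continue
            others = [k for k in lineages if k != lin_name]
            independent = all(
                not any(
                    (frozenset(me.event.carriers) & lin_leaves)
                    and (frozenset(me.event.carriers) & lineages[o])
                    for me in events
                )
                for o in others
            ) if others else False
            rows.append(
                dict(
                    gene=gene,
                    lineage=lin_name,
                    earliest_origin_branch=best[1],
                    event_kind=best[2].event.disruption.kind,
                    n_events_in_lineage=len(hits),
                    independent=independent,
                )
            )
    return pd.DataFrame(rows)


def mapped_events_table(mapped: Iterable[MappedEvent]) -> pd.DataFrame:
    rows = []
    for me in mapped:
        d = me.event.disruption
        rows.append(
            dict(
                gene=me.event.gene,
                kind=d.kind,
                ref_codon_start=d.ref_codon_start,
                length_nt=d.length_nt,
                stop_codon=d.stop_codon or "",
                carriers=",".join(sorted(me.event.carriers)),
                origin_branches=";".join(sorted(me.origin_branches)),
                monophyletic=me.monophyletic,
                n_independent_origins=me.n_independent_origins,
                note=me.note or "",
            )
        )
    return pd.DataFrame(rows)
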