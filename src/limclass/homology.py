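"""Homology groups: human basal clades and nearest-neighbor assignment.

A homology group is one of the clades of human LIM domains radiating from
the midpoint root of the strict consensus between the human-only gene tree
and the human restriction of the multi-species gene tree. Non-human LIM
domains are then assigned on the rooted multi-species tree: for each
non-human leaf, walk to the nearest ancestor whose subtree contains at
least one human leaf; if every human leaf below that node belongs to a
single group, the leaf joins it, otherwise the leaf is unclassifiable (the
groups observed under the deciding node are recorded for audit).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy

from .trees import TreeError, basal_clades

__all__ = [
    "HomologyGroup",
    "AssignmentResult",
    "build_homology_groups",
    "assign_nonhuman",
    "dominant_annotation",
    "write_groups_tsv",
    "is_human_leaf",
]


def is_human_leaf(label: str) -> bool:
    return label.startswith("Hs_")


@dataclass
class HomologyGroup:
    """A basal clade of human LIM domains plus its assigned non-human
    members. Ids are deterministic: groups numbered largest-first, ties by
    smallest member label."""

    id: int
    members_human: frozenset[str]
    assigned_nonhuman: set[str] = field(default_factory=set)
    dominant: tuple[str, str] | None = None  # (class name, LIM ordinal)


@dataclass(frozen=True)
class AssignmentResult:
    leaf: str
    group: int | None
    status: str  # assigned | unclassifiable
    mrca_groups: frozenset[int]

    def __post_init__(self) -> None:
        assert (self.status == "assigned") == (len(self.mrca_groups) == 1)


def build_homology_groups(consensus: dendropy.Tree) -> list[HomologyGroup]:
    """One group per clade radiating from the root of the (midpoint-rooted)
    human consensus tree."""
    if not consensus.is_rooted:
        raise TreeError("build_homology_groups requires a rooted tree")
    clades = basal_clades(consensus)
    ordered = sorted(clades, key=lambda c: (-len(c), min(c)))
    return [
        HomologyGroup(id=i + 1, members_human=frozenset(clade))
        for i, clade in enumerate(ordered)
    ]


def assign_nonhuman(
    tree: dendropy.Tree, groups: Sequence[HomologyGroup]
) -> list[AssignmentResult]:
    """Nearest-neighbor assignment of non-human leaves on the rooted
    multi-species tree.

    Every human leaf of the tree must belong to exactly one group. Results
    are deterministic and independent of traversal order; each non-human
    leaf yields exactly one result. Assigned leaves are also recorded on
    the groups' ``assigned_nonhuman`` sets.
    """
    if not tree.is_rooted:
        raise TreeError("assign_nonhuman requires a rooted tree")
    group_of: dict[str, int] = {}
    for g in groups:
        for label in g.members_human:
            if label in group_of:
                raise ValueError(f"human leaf {label} in multiple groups")
            group_of[label] = g.id
    by_id = {g.id: g for g in groups}

    # postorder: set of groups of human leaves under each node
    groups_below: dict[dendropy.Node, frozenset[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if is_human_leaf(label):
                if label not in group_of:
                    raise ValueError(
                        f"human leaf {label} belongs to no homology group"
                    )
                groups_below[node] = frozenset({group_of[label]})
            else:
                groups_below[node] = frozenset()
        else:
            acc: set[int] = set()
            for child in node.child_nodes():
                acc |= groups_below[child]
            groups_below[node] = frozenset(acc)

    results = []
    for leaf in sorted(
        tree.leaf_node_iter(), key=lambda l: l.taxon.label
    ):
        label = leaf.taxon.label
        if is_human_leaf(label):
            continue
        node = leaf
        while node is not None and not groups_below[node]:
            node = node.parent_node
        if node is None:
            results.append(
                AssignmentResult(label, None, "unclassifiable", frozenset())
            )
            continue
        seen = groups_below[node]
        if len(seen) == 1:
            gid = next(iter(seen))
            by_id[gid].assigned_nonhuman.add(label)
            results.append(AssignmentResult(label, gid, "assigned", seen))
        else:
            results.append(
                AssignmentResult(label, None, "unclassifiable", seen)
            )
    return results


def dominant_annotation(
    group: HomologyGroup,
    classes: Mapping[str, tuple[str, str]],
) -> tuple[str, str, bool]:
    """Modal (class, LIM ordinal) among the group's human members.

    ``classes`` maps leaf label to its (class name, ordinal). Ties are
    broken alphabetically; the third return value reports whether a tie
    occurred.
    """
    if not group.members_human:
        raise ValueError(f"group {group.id} has no human members")
    counts = Counter(classes[label] for label in group.members_human)
    top = max(counts.values())
    winners = sorted(pair for pair, n in counts.items() if n == top)
    cls, ordinal = winners[0]
    tie = len(winners) > 1
    group.dominant = (cls, ordinal)
    return cls, ordinal, tie


def write_groups_tsv(
    groups: Sequence[HomologyGroup],
    assignments: Sequence[AssignmentResult],
    path: str,
) -> None:
    """Group-membership table: leaf label, group id, human/assigned status,
    dominant class/position where known."""
    assignment_of = {a.leaf: a for a in assignments}
    with open(path, "w") as out:
        out.write(
            "leaf\tgroup\tstatus\tdominant_class\tdominant_position"
            "\tmrca_groups\n"
        )
        rows = []
        for g in groups:
            dom_cls, dom_ord = g.dominant or ("", "")
            for label in sorted(g.members_human):
                rows.append((label, str(g.id), "member", dom_cls, dom_ord, ""))
            for label in sorted(g.assigned_nonhuman):
                rows.append((label, str(g.id), "assigned", dom_cls, dom_ord, ""))
        for a in assignments:
            if a.status == "unclassifiable":
                rows.append(
                    (
                        a.leaf,
                        "",
                        "unclassifiable",
                        "",
                        "",
                        ",".join(str(g) for g in sorted(a.mrca_groups)),
                    )
                )
        for row in sorted(rows):
            out.write("\t".join(row) + "\n")
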