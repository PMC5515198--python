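"""Ring-diagram (sunburst) aggregation of progression pathways.

Pathways are aggregated into a prefix tree: the root is the breast
primary (ring 0), ring k holds the distribution of k-th metastatic
steps among patients sharing a prefix. Each node's arc percentage is
taken relative to the full eligible cohort, so sectors shrink outward
as patients stop progressing. Co-occurring site-sets become a single
sector with a canonical sorted label ("bone+liver").
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field

from .pathways import Pathway
from .sites import BREAST


@dataclass
class RingNode:
    label: str
    ring: int
    count: int
    arc_pct: float
    children: list["RingNode"] = field(default_factory=list)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self.walk())


def step_label(step: frozenset[str]) -> str:
    return "+".join(sorted(step))


def build_ring_diagram(pathways: list[Pathway], max_rings: int = 7) -> RingNode:
    """Prefix tree over pathway step sequences, truncated at ``max_rings``.

    ``max_rings`` counts metastatic rings beyond the breast root; the
    terminal deceased step appears as its own sector. Construction is
    invariant to the input order of pathways (children are sorted by
    descending count, then label).
    """
    if max_rings < 1:
        raise ValueError("max_rings must be at least 1")
    if not pathways:
        raise ValueError("cannot build a ring diagram from zero pathways")
    total = len(pathways)
    root = RingNode(label=BREAST, ring=0, count=total, arc_pct=100.0)

    def insert(node: RingNode, steps: tuple[frozenset[str], ...]) -> None:
        if not steps or node.ring >= max_rings:
            return
        label = step_label(steps[0])
        for child in node.children:
            if child.label == label:
                child.count += 1
                break
        else:
            child = RingNode(label=label, ring=node.ring + 1, count=1, arc_pct=0.0)
            node.children.append(child)
        insert(child, steps[1:])

    for pw in sorted(pathways, key=lambda p: tuple(step_label(s) for s in p.steps)):
        insert(root, pw.steps[1:])

    for node in root.walk():
        node.arc_pct = 100.0 * node.count / total
        node.children.sort(key=lambda c: (-c.count, c.label))
    return root


def _node_to_dict(node: RingNode) -> dict:
    return {
        "site": node.label,
        "ring": node.ring,
        "count": node.count,
        "arc_pct": node.arc_pct,
        "children": [_node_to_dict(c) for c in node.children],
    }


def _node_from_dict(d: dict) -> RingNode:
    return RingNode(
        label=d["site"],
        ring=d["ring"],
        count=d["count"],
        arc_pct=d["arc_pct"],
        children=[_node_from_dict(c) for c in d["children"]],
    )


def export_diagram(tree: RingNode, fmt: str = "json") -> str:
    """Serialise a ring tree.

    ``json``: nested sunburst document. ``csv``: one row per node with a
    "/"-joined path-prefix column. Both round-trip losslessly through
    :func:`import_diagram`.
    """
    if fmt == "json":
        return json.dumps(_node_to_dict(tree), indent=1)
    if fmt == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["path", "site", "ring", "count", "arc_pct"])

        def rows(node: RingNode, prefix: str) -> None:
            path = f"{prefix}/{node.label}" if prefix else node.label
            writer.writerow([path, node.label, node.ring, node.count, repr(node.arc_pct)])
            for c in node.children:
                rows(c, path)

        rows(tree, "")
        return buf.getvalue()
    raise ValueError(f"unknown format {fmt!r}")


def import_diagram(text: str, fmt: str = "json") -> RingNode:
    """Inverse of :func:`export_diagram`."""
    if fmt == "json":
        return _node_from_dict(json.loads(text))
    if fmt == "csv":
        reader = csv.DictReader(io.StringIO(text))
        nodes: dict[str, RingNode] = {}
        root = None
        for row in reader:
            node = RingNode(
                label=row["site"],
                ring=int(row["ring"]),
                count=int(row["count"]),
                arc_pct=float(row["arc_pct"]),
            )
            nodes[row["path"]] = node
            parent_path = row["path"].rsplit("/", 1)[0] if "/" in row["path"] else None
            if parent_path is None:
                root = node
            else:
                nodes[parent_path].children.append(node)
        if root is None:
            raise ValueError("csv document has no root row")
        return root
    raise ValueError(f"unknown format {fmt!r}")
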