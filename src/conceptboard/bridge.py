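"""Compile a chunk hierarchy into blackboard bindings.

The chunk trees produced by the sequence memory and the connection paths
built in the sentence blackboard are structurally similar: a chunk
corresponds to a structure assembly, chunk containment to main<->sub
binding, and sibling order to role bindings.  The correspondence is not a
syntactic theory — chunk trees need not match a linguist's parse — so the
mapping from chunk *categories* to blackboard kinds and roles is supplied
explicitly as a :class:`RoleMap` per corpus.

Compilation is post hoc: it recruits one structure assembly per chunk and
ignites the corresponding WM populations directly, rather than replaying
the sentence through the control circuits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import yaml

from .blackboard import Blackboard

__all__ = [
    "ChunkNode",
    "AttachmentRule",
    "RoleMap",
    "CompileError",
    "compile_tree",
    "tree_from_memory",
    "verify_isomorphism",
]


class CompileError(Exception):
    """A chunk label/category has no mapping, or no attachment applies."""


@dataclass
class ChunkNode:
    """A node of a chunk hierarchy: either a labeled chunk with children,
    or a raw token (category is None)."""

    category: str | None
    children: list["ChunkNode"] = field(default_factory=list)
    token: str | None = None

    @classmethod
    def leaf(cls, token: str) -> "ChunkNode":
        return cls(category=None, token=token)

    @property
    def is_token(self) -> bool:
        return self.token is not None

    def chunk_count(self) -> int:
        if self.is_token:
            return 0
        return 1 + sum(c.chunk_count() for c in self.children)


@dataclass(frozen=True)
class AttachmentRule:
    """How a child chunk of one category binds into the structure.

    Either to its parent's assembly, or to a sibling assembly of a given
    kind (searching preceding siblings first, then following, unless a
    direction is forced).  Rules are tried in order; the first applicable
    one wins.
    """

    child: str
    role: str
    target: str = "parent"  # "parent" | "sibling"
    parent: str | None = None  # restrict to this parent category
    sibling: str | None = None  # sibling category (target == "sibling")
    direction: str = "any"  # "preceding" | "following" | "any"


@dataclass
class RoleMap:
    """Mapping from chunk categories to blackboard kinds plus attachments."""

    kinds: dict[str, str]
    attachments: list[AttachmentRule] = field(default_factory=list)
    #: optional mapping from memory chunk labels to categories
    label_categories: dict[str, str] = field(default_factory=dict)

    def kind_of(self, category: str) -> str:
        if category not in self.kinds:
            raise CompileError(f"no kind mapped for chunk category {category!r}")
        return self.kinds[category]

    @classmethod
    def from_yaml(cls, path) -> "RoleMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        rules = [AttachmentRule(**r) for r in doc.get("attachments", [])]
        return cls(doc["kinds"], rules, doc.get("label_categories", {}))


def compile_tree(
    tree: ChunkNode, role_map: RoleMap, blackboard: Blackboard
) -> list[tuple[str, str, str]]:
    """Recruit assemblies for every chunk and ignite the bindings.

    Token leaves bind their word to the enclosing chunk's assembly; chunk
    children bind per the role map's attachment rules.  Returns the
    resulting (element, role, element) triples; the blackboard's own
    bound_structure agrees with them.
    """
    if tree.is_token:
        raise CompileError("cannot compile a bare token")
    _compile_chunk(tree, None, role_map, blackboard)
    return blackboard.bound_structure()


def _compile_chunk(
    chunk: ChunkNode,
    parent_name: str | None,
    role_map: RoleMap,
    blackboard: Blackboard,
) -> str:
    kind = role_map.kind_of(chunk.category)
    sa = blackboard.recruit(kind)
    # recruit children first so sibling attachments can look both ways
    child_names: list[tuple[ChunkNode, str | None]] = []
    for child in chunk.children:
        if child.is_token:
            node = blackboard.word_node(child.token, sa.name)
            blackboard.ignite(node)
            child_names.append((child, None))
        else:
            child_names.append((child, _compile_chunk(child, sa.name, role_map, blackboard)))
    for idx, (child, name) in enumerate(child_names):
        if name is None:
            continue
        rule = _applicable_rule(child, idx, child_names, chunk, role_map)
        if rule.target == "parent":
            node = blackboard.role_node(sa.name, rule.role, name, rule.role)
        else:
            sib = _find_sibling(idx, child_names, rule, role_map)
            if sib is None:
                raise CompileError(
                    f"no {rule.sibling!r} sibling for {child.category!r} chunk"
                )
            node = blackboard.role_node(sib, rule.role, name, rule.role)
        blackboard.ignite(node)
    return sa.name


def _applicable_rule(child, idx, child_names, parent, role_map) -> AttachmentRule:
    for rule in role_map.attachments:
        if rule.child != child.category:
            continue
        if rule.parent is not None and rule.parent != parent.category:
            continue
        if rule.target == "sibling" and _find_sibling(idx, child_names, rule, role_map) is None:
            continue
        return rule
    raise CompileError(
        f"no attachment rule for {child.category!r} under {parent.category!r}"
    )


def _find_sibling(idx, child_names, rule: AttachmentRule, role_map) -> str | None:
    order: list[int] = []
    if rule.direction in ("preceding", "any"):
        order += list(range(idx - 1, -1, -1))
    if rule.direction in ("following", "any"):
        order += list(range(idx + 1, len(child_names)))
    for j in order:
        sibling, name = child_names[j]
        if name is not None and sibling.category == rule.sibling:
            return name
    return None


def tree_from_memory(
    memory, viewpoint: str, start: int, end: int, role_map: RoleMap
) -> ChunkNode:
    """Rebuild the chunk hierarchy over one extent of the base sequence.

    Uses the stored chunk extents of the memory; labels are translated to
    categories through the role map's ``label_categories``.  The extent
    must be tiled by chunks at level 0 and covered at two or more levels.
    """
    hier = memory.hierarchies[viewpoint]
    tokens = hier.layers[0].sequence[start:end]
    level0 = [c for c in hier.layers[0].chunks if start <= c.start and c.end <= end]
    if not level0 or level0[0].start != start or level0[-1].end != end:
        raise CompileError("extent is not tiled by level-0 chunks")

    def category(label: str) -> str:
        if label not in role_map.label_categories:
            raise CompileError(f"no category for chunk label {label!r}")
        return role_map.label_categories[label]

    children = []
    for c in level0:
        leaf_tokens = hier.layers[0].sequence[c.start : c.end]
        children.append(
            ChunkNode(category(c.label), [ChunkNode.leaf(t) for t in leaf_tokens])
        )
    if len(children) == 1:
        return children[0]
    # wrap in the covering level-1 chunk when one exists, else a root
    lvl1 = hier.layers[1].chunks if len(hier.layers) > 1 else []
    for c in lvl1:
        sub = hier.layers[1].sequence[c.start : c.end]
        if len(sub) == len(children):
            return ChunkNode(category(c.label), children)
    raise CompileError("extent is not covered by a chunk at two or more levels")


def verify_isomorphism(
    compiled: nx.Graph, reference: nx.Graph
) -> tuple[bool, str]:
    """Label-preserving graph isomorphism decision with a mismatch report.

    Node labels (word or assembly kind) and edge roles must both be
    preserved.  On failure the report names the first discrepancy found
    (counts of labels, edge roles, or overall structure).
    """
    def node_match(a, b):
        return a.get("label") == b.get("label")

    def edge_match(a, b):
        return a.get("role") == b.get("role")

    if nx.is_isomorphic(compiled, reference, node_match=node_match, edge_match=edge_match):
        return True, "isomorphic"

    def label_counts(g):
        out: dict[str, int] = {}
        for _, data in g.nodes(data=True):
            out[data.get("label")] = out.get(data.get("label"), 0) + 1
        return out

    def role_counts(g):
        out: dict[str, int] = {}
        for _, _, data in g.edges(data=True):
            out[data.get("role")] = out.get(data.get("role"), 0) + 1
        return out

    lc, lr = label_counts(compiled), label_counts(reference)
    if lc != lr:
        diff = {k: (lc.get(k, 0), lr.get(k, 0)) for k in set(lc) | set(lr) if lc.get(k, 0) != lr.get(k, 0)}
        return False, f"node label counts differ (compiled, reference): {diff}"
    rc, rr = role_counts(compiled), role_counts(reference)
    if rc != rr:
        diff = {k: (rc.get(k, 0), rr.get(k, 0)) for k in set(rc) | set(rr) if rc.get(k, 0) != rr.get(k, 0)}
        return False, f"edge role counts differ (compiled, reference): {diff}"
    return False, "same label and role counts but no label-preserving isomorphism"
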