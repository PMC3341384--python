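"""Generalized suffix tree over token sequences (Ukkonen's construction).

Rows of the stamped transition matrix are token strings; building one
compressed trie of all their suffixes makes every repeated pattern — every
set of genes sharing a transition pattern over a contiguous column interval
— an internal node.  Tokens are arbitrary hashable values; here they are
``(symbol, column)`` tuples plus per-row ``('$', row)`` terminators.

The construction is online and amortized linear in the total number of
tokens: each string is inserted with Ukkonen's algorithm (active point,
suffix links, rule 1/2/3 extensions), restarting from the root so that
suffixes shared with previously inserted strings are matched, not
re-inserted.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Sequence

import numpy as np

Token = Hashable


class Node:
    """Suffix-tree node; the edge *into* the node is stored on the node.

    ``(string_id, start, end)`` index into the builder's string store; a
    leaf under construction has ``end = None`` (the open end of Ukkonen's
    rule 1), frozen to the string length once its string is fully inserted.
    """

    __slots__ = (
        "children", "parent", "suffix_link",
        "string_id", "start", "end",
        "leaf_row", "leaf_suffix_start",
        "leaf_count", "path_len", "leaf_lo", "leaf_hi",
    )

    def __init__(self, string_id: int = -1, start: int = 0, end: int | None = 0):
        self.children: dict[Token, "Node"] = {}
        self.parent: "Node" | None = None
        self.suffix_link: "Node" | None = None
        self.string_id = string_id
        self.start = start
        self.end = end
        self.leaf_row: int | None = None          # string id, for leaves
        self.leaf_suffix_start: int | None = None  # suffix position, for leaves
        self.leaf_count = 0
        self.path_len = 0
        self.leaf_lo = 0   # subtree leaves occupy [leaf_lo, leaf_hi) of the
        self.leaf_hi = 0   # tree's DFS leaf ordering (Euler-tour range)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def edge_tokens(self, strings: Sequence[Sequence[Token]]) -> Sequence[Token]:
        return strings[self.string_id][self.start:self.end]


class GeneralizedSuffixTree:
    """Compressed trie of all suffixes of a set of token strings."""

    def __init__(self, strings: Iterable[Sequence[Token]]):
        self.strings: list[Sequence[Token]] = []
        self.root = Node()
        self.root.suffix_link = self.root
        self._leaf_end = -1  # open end during the current string's insertion
        terminators: set[Token] = set()
        for s in strings:
            if not s:
                raise ValueError("cannot insert an empty string")
            if s[-1] in terminators:
                raise ValueError(f"duplicate terminator across rows: {s[-1]!r}")
            terminators.add(s[-1])
            self._insert(s)
        self._annotate()

    # -- Ukkonen ---------------------------------------------------------

    def _edge_len(self, node: Node) -> int:
        end = self._leaf_end + 1 if node.end is None else node.end
        return end - node.start

    def _insert(self, s: Sequence[Token]) -> None:
        sid = len(self.strings)
        self.strings.append(s)
        root = self.root
        active_node = root
        active_edge = 0   # index into s of the first token of the active edge
        active_length = 0
        remainder = 0
        new_leaves: list[Node] = []

        for i, tok in enumerate(s):
            self._leaf_end = i
            remainder += 1
            last_internal: Node | None = None
            while remainder > 0:
                if active_length == 0:
                    active_edge = i
                edge_key = s[active_edge]
                child = active_node.children.get(edge_key)
                if child is None:
                    leaf = Node(sid, i, None)
                    leaf.leaf_row = sid
                    leaf.leaf_suffix_start = i - remainder + 1
                    leaf.parent = active_node
                    active_node.children[edge_key] = leaf
                    new_leaves.append(leaf)
                    if last_internal is not None:
                        last_internal.suffix_link = active_node
                        last_internal = None
                else:
                    edge_len = self._edge_len(child)
                    if active_length >= edge_len:
                        # walk down into the child and retry this extension
                        active_edge += edge_len
                        active_length -= edge_len
                        active_node = child
                        continue
                    on_edge = self.strings[child.string_id][child.start + active_length]
                    if on_edge == tok:
                        # rule 3: suffix already present — end of phase
                        active_length += 1
                        if last_internal is not None:
                            last_internal.suffix_link = active_node
                        break
                    # rule 2 with edge split
                    split = Node(child.string_id, child.start, child.start + active_length)
                    split.parent = active_node
                    active_node.children[edge_key] = split
                    child.start += active_length
                    child.parent = split
                    split.children[self.strings[child.string_id][child.start]] = child
                    leaf = Node(sid, i, None)
                    leaf.leaf_row = sid
                    leaf.leaf_suffix_start = i - remainder + 1
                    leaf.parent = split
                    split.children[tok] = leaf
                    new_leaves.append(leaf)
                    if last_internal is not None:
                        last_internal.suffix_link = split
                    last_internal = split
                remainder -= 1
                if active_node is root and active_length > 0:
                    active_length -= 1
                    active_edge = i - remainder + 1
                elif active_node is not root:
                    active_node = active_node.suffix_link or root
        # freeze open leaf edges of this string
        for leaf in new_leaves:
            leaf.end = len(s)

    # -- post-construction annotations ----------------------------------

    def _annotate(self) -> None:
        """One DFS fills path lengths, leaf counts and Euler leaf ranges.

        Leaves are numbered in DFS order into ``_leaf_row_order`` so any
        subtree's rows are a contiguous slice — row recovery per node then
        costs one array slice instead of a subtree walk.
        """
        leaf_rows: list[int] = []
        internal: list[Node] = []
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                node.leaf_hi = len(leaf_rows)
                node.leaf_count = node.leaf_hi - node.leaf_lo
                continue
            node.leaf_lo = len(leaf_rows)
            if node.is_leaf:
                leaf_rows.append(node.leaf_row)  # type: ignore[arg-type]
                node.leaf_hi = len(leaf_rows)
                node.leaf_count = 1
                continue
            if node is not self.root:
                internal.append(node)
            stack.append((node, True))
            for c in node.children.values():
                c.path_len = node.path_len + (c.end - c.start)
                stack.append((c, False))
        self._leaf_row_order = np.asarray(leaf_rows, dtype=np.int64)
        self._internal = internal

    # -- queries ---------------------------------------------------------

    def internal_nodes(self) -> list[Node]:
        """All internal nodes except the root, in DFS order."""
        return list(self._internal)

    def leaf_rows_under(self, node: Node):
        """Distinct string ids among the leaves of ``node``'s subtree, sorted."""
        return np.unique(self._leaf_row_order[node.leaf_lo:node.leaf_hi])

    def first_path_token(self, node: Node) -> Token:
        """First token on the root-to-``node`` path."""
        while node.parent is not None and node.parent is not self.root:
            node = node.parent
        return self.strings[node.string_id][node.start]

    def n_leaves(self) -> int:
        return self.root.leaf_count

    def contains(self, pattern: Sequence[Token]) -> bool:
        """Substring membership: does any inserted string contain ``pattern``?"""
        node = self.root
        i = 0
        while i < len(pattern):
            child = node.children.get(pattern[i])
            if child is None:
                return False
            edge = child.edge_tokens(self.strings)
            for tok in edge:
                if i == len(pattern):
                    return True
                if tok != pattern[i]:
                    return False
                i += 1
            node = child
        return True

    def incoming_suffix_links(self) -> dict[int, list[Node]]:
        """Map ``id(target)`` -> internal nodes whose suffix link points at it."""
        incoming: dict[int, list[Node]] = {}
        for node in self.internal_nodes():
            sl = node.suffix_link
            if sl is not None and sl is not self.root:
                incoming.setdefault(id(sl), []).append(node)
        return incoming
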