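"""CSG expression trees over exact solids.

A CSG node is itself a :class:`~molcsg.primitives.Solid`: union,
intersection and (ordered) difference nodes implement point containment
by boolean logic, segment intersection by interval-set algebra on the
operand results, and surface-cube seeding by the setwise union of the
operand seeds.  Seeds are unioned without filtering so that disconnected
regions of the final solid are never lost; the downstream corner
classification discards cubes that do not straddle the output surface.
"""

from __future__ import annotations

import numpy as np

from .intervals import IntervalSet
from .primitives import Segment, Solid

UNION = "U"
INTERSECTION = "I"
DIFFERENCE = "D"

_OPS = frozenset((UNION, INTERSECTION, DIFFERENCE))


class CsgNode(Solid):
    """Binary CSG operation node.  DIFFERENCE is ordered: left minus right."""

    def __init__(self, op: str, left: Solid, right: Solid):
        if op not in _OPS:
            raise ValueError(f"unknown CSG operation {op!r}")
        self.op = op
        self.left = left
        self.right = right

    def contains(self, points: np.ndarray) -> np.ndarray:
        a = self.left.contains(points)
        b = self.right.contains(points)
        if self.op == UNION:
            return a | b
        if self.op == INTERSECTION:
            return a & b
        return a & ~b

    def intersect_segment(self, seg: Segment) -> IntervalSet:
        a = self.left.intersect_segment(seg)
        b = self.right.intersect_segment(seg)
        if self.op == UNION:
            return a | b
        if self.op == INTERSECTION:
            return a & b
        return a - b

    def starting_cubes(self, lattice) -> set:
        return self.left.starting_cubes(lattice) | self.right.starting_cubes(lattice)

    def bounds(self):
        alo, ahi = self.left.bounds()
        if self.op == DIFFERENCE:
            return alo, ahi
        blo, bhi = self.right.bounds()
        if self.op == UNION:
            return np.minimum(alo, blo), np.maximum(ahi, bhi)
        # intersection cannot exceed either operand box
        lo = np.maximum(alo, blo)
        hi = np.minimum(ahi, bhi)
        if np.any(lo > hi):  # disjoint boxes: empty output, keep a sliver
            mid = 0.5 * (lo + hi)
            return mid, mid
        return lo, hi

    def leaves(self):
        yield from self.left.leaves()
        yield from self.right.leaves()

    def __repr__(self):
        return f"({self.op} {self.left!r} {self.right!r})"


def union(left: Solid, right: Solid) -> CsgNode:
    return CsgNode(UNION, left, right)


def intersection(left: Solid, right: Solid) -> CsgNode:
    return CsgNode(INTERSECTION, left, right)


def difference(left: Solid, right: Solid) -> CsgNode:
    return CsgNode(DIFFERENCE, left, right)


def union_all(solids) -> Solid:
    """Balanced union tree over a list of solids."""
    nodes = list(solids)
    if not nodes:
        raise ValueError("union of no solids")
    while len(nodes) > 1:
        nxt = []
        for i in range(0, len(nodes) - 1, 2):
            nxt.append(CsgNode(UNION, nodes[i], nodes[i + 1]))
        if len(nodes) % 2:
            nxt.append(nodes[-1])
        nodes = nxt
    return nodes[0]


# ---------------------------------------------------------------------------
# Prefix expression parsing, e.g.  (D (U s1.json s2.json) mesh.off)


def tokenize_expression(text: str):
    return text.replace("(", " ( ").replace(")", " ) ").split()


def parse_expression(text: str, leaf_loader) -> Solid:
    """Parse a parenthesized prefix CSG expression.

    Grammar::

        expr  := leaf | '(' op expr expr ')'
        op    := 'U' | 'I' | 'D'
        leaf  := any non-parenthesis token, resolved by ``leaf_loader``

    ``leaf_loader(token)`` must return a Solid for each leaf token (for
    the command-line interface, tokens are file paths).
    """
    tokens = tokenize_expression(text)
    pos = 0

    def parse():
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError("unexpected end of CSG expression")
        tok = tokens[pos]
        pos += 1
        if tok == "(":
            op = tokens[pos]
            pos += 1
            if op not in _OPS:
                raise ValueError(f"unknown CSG operator {op!r}")
            left = parse()
            right = parse()
            if pos >= len(tokens) or tokens[pos] != ")":
                raise ValueError("expected ')' in CSG expression")
            pos += 1
            return CsgNode(op, left, right)
        if tok == ")":
            raise ValueError("unexpected ')' in CSG expression")
        return leaf_loader(tok)

    node = parse()
    if pos != len(tokens):
        raise ValueError("trailing tokens in CSG expression")
    return node
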