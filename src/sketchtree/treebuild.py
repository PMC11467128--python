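"""Neighbor-joining tree construction and Newick serialization.

Implements classical neighbor-joining (Saitou-Nei): repeatedly join the pair
(i, j) minimizing

    Q(i, j) = (n - 2) * d(i, j) - R_i - R_j,      R_i = sum_m d(i, m)

with branch lengths from the standard split formula; negative limb lengths
are clamped to zero and the deficit moved to the sister edge. The final
three nodes form a trifurcating root, so the output is an unrooted tree.

``dnj`` is an accelerated variant: each row is scanned in increasing
distance order and abandoned once the lower bound
``(n-2)*d(i,j) - R_i - max(R)`` exceeds the best Q seen, so most Q values
are never evaluated. Only pairs that provably cannot be minimal are pruned,
and both methods share the same arithmetic and lexicographic (row, column)
tie-break, so dnj selects the identical join at every iteration and returns
the identical topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix

_NEWICK_SPECIAL = set("()[]{}:;,'\" \t\n")


@dataclass
class TreeNode:
    """Node of a phylogenetic tree; a tree is its root node.

    ``length`` is the branch length of the edge to the parent (None at the
    root). NJ output is unrooted: its root trifurcates.
    """

    name: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        """Depth-first, parents before children."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def newick(self, decimals: int = 6) -> str:
        return _to_newick(self, decimals) + ";"

    def leaf_distances(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        names = self.leaf_names()
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        values = np.zeros((n, n))

        def below(node):
            # leaf index -> distance from node
            if node.is_leaf:
                return {index[node.name]: 0.0}
            merged = {}
            groups = []
            for child in node.children:
                sub = {i: d + (child.length or 0.0) for i, d in below(child).items()}
                for g in groups:
                    for i, di in g.items():
                        for j, dj in sub.items():
                            values[i, j] = values[j, i] = di + dj
                groups.append(sub)
                merged.update(sub)
            return merged

        below(self)
        return DistanceMatrix(labels=tuple(names), values=values)


def _validate_matrix(m: DistanceMatrix, min_n: int = 3) -> None:
    if m.n < min_n:
        raise ValueError(f"need at least {min_n} taxa, got {m.n}")
    if not np.all(np.isfinite(m.values)):
        raise ValueError("distance matrix contains non-finite entries")


def _join_lengths(d_ij: float, r_i: float, r_j: float, n: int) -> tuple[float, float]:
    """NJ limb lengths with negative-branch clamping (deficit to sister)."""
    li = 0.5 * d_ij + (r_i - r_j) / (2.0 * (n - 2))
    lj = d_ij - li
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _select_nj(D: np.ndarray, R: np.ndarray) -> tuple[int, int]:
    """Full Q-matrix scan; first row-major minimum = lowest (i, j) pair."""
    n = D.shape[0]
    Q = (n - 2) * D - R[:, None] - R[None, :]
    Q[np.tril_indices(n)] = np.inf
    flat = int(np.argmin(Q))
    return flat // n, flat % n

def _select_dnj(D: np.ndarray, R: np.ndarray) -> tuple[int, int]:
    """Bound-pruned scan; provably selects the same pair as ``_select_nj``.

    Scans each row in increasing distance; once the row-wise lower bound
    exceeds the current best Q the rest of the row cannot contain the
    minimum and is skipped. Q is evaluated with the same expression and
    operand order as the full scan, so results are bitwise identical.
    """
    n = D.shape[0]
    r_max = float(np.max(R))
    best_q = np.inf
    best_pair = None
    for i in range(n):
        order = np.argsort(D[i], kind="stable")
        for j in order:
            j = int(j)
            if j == i:
                continue
            bound = (n - 2) * D[i, j] - R[i] - r_max
            if bound > best_q:
                break  # remaining j in this row are farther: larger bound
            q = (n - 2) * D[i, j] - R[i] - R[j]
            pair = (i, j) if i < j else (j, i)
            if q < best_q or (q == best_q and pair < best_pair):
                best_q = q
                best_pair = pair
    return best_pair


def _agglomerate(m: DistanceMatrix, select) -> TreeNode:
    D = m.values.astype(float).copy()
    nodes = [TreeNode(name=lbl) for lbl in m.labels]
    while len(nodes) > 3:
        n = len(nodes)
        R = D.sum(axis=1)
        i, j = select(D, R)
        li, lj = _join_lengths(D[i, j], R[i], R[j], n)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        parent = TreeNode(children=[child_i, child_j])
        new_row = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        # collapse j into i, then drop j
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        keep = [x for x in range(n) if x != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]
    # trifurcating root from the last three nodes
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for node, ln in zip(nodes, lengths):
        node.length = max(ln, 0.0)
    return TreeNode(children=list(nodes))


def nj(m: DistanceMatrix) -> TreeNode:
    """Canonical neighbor-joining; deterministic, lowest-(i,j) tie-break."""
    _validate_matrix(m)
    return _agglomerate(m, _select_nj)


def dnj(m: DistanceMatrix) -> TreeNode:
    """Accelerated NJ via bound-based candidate pruning; same topology as nj."""
    _validate_matrix(m)
    return _agglomerate(m, _select_dnj)


# ---------------------------------------------------------------------------
# Newick


def _quote_name(name: str) -> str:
    if name and not (_NEWICK_SPECIAL & set(name)):
        return name
    return "'" + name.replace("'", "''") + "'"


def _to_newick(node: TreeNode, decimals: int) -> str:
    if node.is_leaf:
        body = _quote_name(node.name or "")
    else:
        inner = ",".join(_to_newick(c, decimals) for c in node.children)
        body = f"({inner})"
        if node.name:
            body += _quote_name(node.name)
    if node.length is not None:
        body += f":{node.length:.{decimals}f}"
    return body


def write_newick(tree: TreeNode, path, decimals: int = 6) -> None:
    """Write standard Newick; branch lengths fixed-point, names quoted as needed."""
    with open(path, "w") as fh:
        fh.write(tree.newick(decimals=decimals))
        fh.write("\n")


class _NewickParser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, message: str):
        raise ValueError(f"Newick parse error at position {self.pos}: {message}")

    def peek(self):
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self):
        while self.peek() and self.peek() in " \t\r\n":
            self.pos += 1

    def parse(self) -> TreeNode:
        self.skip_ws()
        node = self.parse_node()
        self.skip_ws()
        if self.peek() != ";":
            self.error("expected ';' at end of tree")
        self.pos += 1
        self.skip_ws()
        if self.pos != len(self.text):
            self.error("trailing content after ';'")
        names = node.leaf_names()
        dupes = sorted({x for x in names if names.count(x) > 1})
        if dupes:
            raise ValueError(f"duplicate leaf names in Newick tree: {dupes}")
        return node

    def parse_node(self) -> TreeNode:
        self.skip_ws()
        node = TreeNode()
        if self.peek() == "(":
            self.pos += 1
            while True:
                node.children.append(self.parse_node())
                self.skip_ws()
                ch = self.peek()
                if ch == ",":
                    self.pos += 1
                    continue
                if ch == ")":
                    self.pos += 1
                    break
                self.error("expected ',' or ')' in subtree (unbalanced parentheses?)")
        name = self.parse_name()
        node.name = name or None
        self.skip_ws()
        if self.peek() == ":":
            self.pos += 1
            node.length = self.parse_number()
        if node.is_leaf and node.name is None:
            self.error("leaf without a name")
        return node

    def parse_name(self) -> str:
        self.skip_ws()
        if self.peek() == "'":
            self.pos += 1
            out = []
            while True:
                ch = self.peek()
                if ch == "":
                    self.error("unterminated quoted name")
                self.pos += 1
                if ch == "'":
                    if self.peek() == "'":  # escaped quote
                        out.append("'")
                        self.pos += 1
                    else:
                        return "".join(out)
                else:
                    out.append(ch)
        out = []
        while self.peek() and self.peek() not in "():;,'[]\t\r\n ":
            out.append(self.peek())
            self.pos += 1
        return "".join(out)

    def parse_number(self) -> float:
        self.skip_ws()
        start = self.pos
        while self.peek() and self.peek() in "0123456789+-.eE":
            self.pos += 1
        token = self.text[start : self.pos]
        try:
            return float(token)
        except ValueError:
            self.error(f"bad branch length {token!r}")


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string; errors carry the offending position."""
    return _NewickParser(text).parse()


def read_newick(path) -> TreeNode:
    with open(path) as fh:
        return parse_newick(fh.read())


# ---------------------------------------------------------------------------
# plain-text rendering


def render_text(tree: TreeNode) -> str:
    """Deterministic ASCII rendering; leaf order equals Newick order."""
    lines = [tree.name if tree.is_leaf else "+" + (tree.name or "")]

    def walk(node: TreeNode, prefix: str) -> None:
        for idx, child in enumerate(node.children):
            last = idx == len(node.children) - 1
            branch = "`-" if last else "|-"
            label = (child.name or "") if child.is_leaf else "+" + (child.name or "")
            lines.append(f"{prefix}{branch} {label}")
            if child.children:
                walk(child, prefix + ("   " if last else "|  "))

    walk(tree, "")
    return "\n".join(lines) + "\n"
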