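"""Gene-tree parsing and nearest-relative annotation by patristic distance.

Each putative TF is assigned the gene symbol of its closest relative in a
user-supplied gene tree, where "closest" means the smallest patristic
distance — the sum of branch lengths along the unique path between two
leaves. Patristic distances are independent of root placement, so rooted and
unrooted Newick inputs are both accepted and no rooting is performed.

Branch lengths are required: edges without lengths raise by default, with an
explicit opt-in to substitute unit lengths (turning patristic distance into
node-path length). Distance comparisons use exact ordering on the summed
values — ties in real trees are exact duplicates of path sums, and ties are
surfaced via a tie count rather than hidden behind an epsilon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


class NewickParseError(ValueError):
    """Malformed Newick input; carries the 0-based text position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(eq=False)  # identity semantics: nodes are hashable graph vertices
class TreeNode:
    label: Optional[str] = None
    length: Optional[float] = None  # length of the edge to the parent; None at the root
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class GeneTree:
    """A rooted tree over labelled leaves with per-edge branch lengths.

    Leaf labels are unique; ``leaves`` preserves parse order. Internal node
    labels (typically support values) are retained but unused by annotation.
    """

    def __init__(self, root: TreeNode, source: Optional[str] = None):
        self.root = root
        self.source = source
        self.leaves: list[TreeNode] = [n for n in self._postorder() if n.is_leaf]
        labels = [leaf.label for leaf in self.leaves]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf label(s): {sorted(dupes)}")
        self._leaf_by_label = {leaf.label: leaf for leaf in self.leaves}

    def _postorder(self) -> Iterable[TreeNode]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves]

    def __contains__(self, label: str) -> bool:
        return label in self._leaf_by_label

    def leaf(self, label: str) -> TreeNode:
        try:
            return self._leaf_by_label[label]
        except KeyError:
            raise KeyError(f"leaf {label!r} not found in tree") from None

    def n_missing_lengths(self) -> int:
        return sum(1 for n in self._postorder() if n is not self.root and n.length is None)

    def resolve_branch_lengths(self, fill: Optional[float] = None) -> None:
        """Validate branch lengths, optionally filling missing ones with ``fill``.

        With ``fill=None`` (default), any non-root edge lacking a length is
        an error: silently substituting unit edges would distort
        nearest-relative choices. Pass ``fill=1.0`` to opt into node-path
        distances.
        """
        missing = self.n_missing_lengths()
        if missing:
            if fill is None:
                raise ValueError(
                    f"{missing} edge(s) lack branch lengths; pass fill=1.0 (unit branch "
                    "lengths) to treat patristic distance as node-path length"
                )
            for n in self._postorder():
                if n is not self.root and n.length is None:
                    n.length = float(fill)
        for n in self._postorder():
            if n is not self.root and n.length is not None and n.length < 0:
                raise ValueError(f"negative branch length {n.length} on edge above {n.label!r}")

    def _require_lengths(self) -> None:
        if self.n_missing_lengths():
            self.resolve_branch_lengths(None)  # raises with guidance


# --- Newick parsing ---------------------------------------------------------

_UNQUOTED_STOP = set("(),:;[]")


class _NewickScanner:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> NewickParseError:
        return NewickParseError(msg, self.pos)

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self) -> str:
        ch = self.peek()
        self.pos += 1
        return ch

    def read_label(self) -> Optional[str]:
        self.skip_ws()
        if self.peek() == "'":
            # quoted label; '' is an escaped quote
            self.pos += 1
            out = []
            while True:
                if self.pos >= len(self.text):
                    raise self.error("unterminated quoted label")
                ch = self.take()
                if ch == "'":
                    if self.peek() == "'":
                        out.append("'")
                        self.pos += 1
                    else:
                        return "".join(out)
                else:
                    out.append(ch)
        start = self.pos
        while self.pos < len(self.text):
            ch = self.text[self.pos]
            if ch in _UNQUOTED_STOP or ch.isspace():
                break
            self.pos += 1
        label = self.text[start : self.pos]
        return label or None

    def read_length(self) -> Optional[float]:
        self.skip_ws()
        if self.peek() != ":":
            return None
        self.pos += 1
        self.skip_ws()
        start = self.pos
        while self.pos < len(self.text) and (
            self.text[self.pos] not in _UNQUOTED_STOP and not self.text[self.pos].isspace()
        ):
            self.pos += 1
        token = self.text[start : self.pos]
        try:
            value = float(token)
        except ValueError:
            self.pos = start
            raise self.error(f"invalid branch length {token!r}")
        if value < 0:
            self.pos = start
            raise self.error(f"negative branch length {token}")
        return value

    def parse_clade(self) -> TreeNode:
        self.skip_ws()
        node = TreeNode()
        if self.peek() == "(":
            open_pos = self.pos
            self.pos += 1
            while True:
                child = self.parse_clade()
                child.parent = node
                node.children.append(child)
                self.skip_ws()
                ch = self.peek()
                if ch == ",":
                    self.pos += 1
                    continue
                if ch == ")":
                    self.pos += 1
                    break
                self.pos = open_pos
                raise self.error("unbalanced parentheses: '(' never closed")
            node.label = self.read_label()  # internal label, e.g. support value
        else:
            node.label = self.read_label()
            if node.label is None:
                raise self.error("expected a leaf label or '('")
        node.length = self.read_length()
        return node


def parse_newick(text: str, source: Optional[str] = None) -> GeneTree:
    """Parse a single ';'-terminated Newick statement into a :class:`GeneTree`.

    Quoted labels (with ``''`` escapes), underscores (kept literal),
    internal-node labels and scientific-notation branch lengths are
    supported. Unbalanced parentheses, duplicate leaf labels, and empty
    input are errors.
    """
    scanner = _NewickScanner(text)
    scanner.skip_ws()
    if scanner.pos >= len(text):
        raise NewickParseError("empty Newick string", 0)
    root = scanner.parse_clade()
    scanner.skip_ws()
    if scanner.peek() != ";":
        if scanner.peek() == ")":
            raise scanner.error("unbalanced parentheses: unmatched ')'")
        raise scanner.error("expected ';' terminating the Newick statement")
    scanner.pos += 1
    scanner.skip_ws()
    if scanner.pos < len(text):
        raise scanner.error("trailing characters after ';'")
    return GeneTree(root, source=source)


def read_newick(path) -> GeneTree:
    """Read one Newick tree from a file."""
    text = Path(path).read_text()
    return parse_newick(text, source=Path(path).name)


def _format_label(label: Optional[str]) -> str:
    if not label:
        return ""
    if any(ch in _UNQUOTED_STOP or ch.isspace() or ch == "'" for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _node_to_newick(node: TreeNode) -> str:
    if node.is_leaf:
        out = _format_label(node.label)
    else:
        out = "(" + ",".join(_node_to_newick(c) for c in node.children) + ")" + _format_label(node.label)
    if node.length is not None:
        out += f":{node.length!r}"
    return out


def to_newick(tree: GeneTree) -> str:
    """Serialize a tree back to a ';'-terminated Newick statement.

    Labels needing protection are quoted; branch lengths are written with
    full precision so parse → serialize → parse is the identity.
    """
    return _node_to_newick(tree.root) + ";"


# --- Patristic distances ----------------------------------------------------


def _distances_from(tree: GeneTree, start: TreeNode) -> dict[TreeNode, float]:
    """Single-source distances over the tree viewed as an undirected graph."""
    dist = {start: 0.0}
    stack = [start]
    while stack:
        node = stack.pop()
        d = dist[node]
        neighbors = list(node.children)
        if node.parent is not None:
            neighbors.append(node.parent)
        for nb in neighbors:
            if nb in dist:
                continue
            # the connecting edge belongs to whichever endpoint is the child
            edge = node.length if nb is node.parent else nb.length
            dist[nb] = d + edge
            stack.append(nb)
    return dist


def patristic_distance(tree: GeneTree, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths along the unique path between two leaves."""
    tree._require_lengths()
    a, b = tree.leaf(leaf_a), tree.leaf(leaf_b)
    if a is b:
        return 0.0
    return _distances_from(tree, a)[b]


def all_pairs_patristic(tree: GeneTree) -> tuple[list[str], np.ndarray]:
    """All leaf-to-leaf patristic distances in a single post-order traversal.

    Returns ``(labels, matrix)`` with labels in parse order; entry (i, j)
    equals ``patristic_distance(tree, labels[i], labels[j])``. At each
    internal node, distances are set for every leaf pair whose path crosses
    that node (pairs drawn from distinct child subtrees), which visits each
    pair exactly once.
    """
    tree._require_lengths()
    labels = tree.leaf_labels
    index = {leaf: i for i, leaf in enumerate(tree.leaves)}
    n = len(labels)
    mat = np.zeros((n, n), dtype=float)
    # depths[node] = list of (leaf_index, distance from node down to that leaf)
    depths: dict[int, list[tuple[int, float]]] = {}
    for node in tree._postorder():
        if node.is_leaf:
            depths[id(node)] = [(index[node], 0.0)]
            continue
        groups = []
        for child in node.children:
            below = depths.pop(id(child))
            edge = child.length if child.length is not None else 0.0
            groups.append([(i, d + edge) for i, d in below])
        merged: list[tuple[int, float]] = []
        for gi, group in enumerate(groups):
            for gj in range(gi + 1, len(groups)):
                for i, di in group:
                    for j, dj in groups[gj]:
                        mat[i, j] = mat[j, i] = di + dj
            merged.extend(group)
        depths[id(node)] = merged
    return labels, mat


# --- Leaf metadata ----------------------------------------------------------


@dataclass
class LeafMetadata:
    """Cross-reference from sequence/leaf id to gene symbol (+ optional source tag)."""

    mapping: dict[str, tuple[str, Optional[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, leaf_id: str) -> bool:
        return leaf_id in self.mapping

    def symbol(self, leaf_id: str) -> str:
        return self.mapping[leaf_id][0]

    def source_tag(self, leaf_id: str) -> Optional[str]:
        return self.mapping[leaf_id][1]


_HEADER_WORDS = {
    "seq_id", "sequence_id", "id", "leaf", "leaf_id", "name",
    "gene_symbol", "symbol", "gene", "source", "source_tag", "species", "tag",
}


def read_leaf_metadata(path, has_header: Optional[bool] = None) -> LeafMetadata:
    """Read a TSV mapping sequence id → gene symbol (optional third column: source tag).

    A header row is auto-detected when any first-row cell matches a common
    column name (override with ``has_header``). Duplicate ids are an error;
    rows with an empty symbol are dropped with a warning.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            rows.append(line.split("\t"))
    if not rows:
        warnings.warn(f"metadata file {path} is empty", UserWarning)
        return LeafMetadata()
    if any(len(r) < 2 for r in rows):
        bad = next(i for i, r in enumerate(rows, 1) if len(r) < 2)
        raise ValueError(f"{path}: row {bad} has fewer than 2 tab-separated columns")
    if has_header is None:
        has_header = any(cell.strip().lower() in _HEADER_WORDS for cell in rows[0])
    if has_header:
        rows = rows[1:]
    mapping: dict[str, tuple[str, Optional[str]]] = {}
    n_empty = 0
    for r in rows:
        leaf_id, symbol = r[0].strip(), r[1].strip()
        tag = r[2].strip() if len(r) > 2 and r[2].strip() else None
        if not symbol:
            n_empty += 1
            continue
        if leaf_id in mapping:
            raise ValueError(f"{path}: duplicate sequence id {leaf_id!r} in metadata")
        mapping[leaf_id] = (symbol, tag)
    if n_empty:
        warnings.warn(f"dropped {n_empty} metadata row(s) with an empty gene symbol", UserWarning)
    return LeafMetadata(mapping)


# --- Annotation -------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationRecord:
    """Outcome of nearest-relative annotation for one query leaf.

    ``assigned_symbol``, ``donor_leaf`` and ``patristic_distance`` are all
    ``None`` exactly when no annotated non-query leaf was available.
    ``n_ties`` counts candidates at the minimum distance (1 when unique).
    """

    query_id: str
    assigned_symbol: Optional[str]
    donor_leaf: Optional[str]
    patristic_distance: Optional[float]
    n_ties: int
    tree_source: Optional[str]


def annotate_query(
    tree: GeneTree,
    query_id: str,
    metadata: LeafMetadata,
    exclude_tags: Optional[set] = None,
) -> AnnotationRecord:
    """Assign the query leaf the gene symbol of its closest annotated relative.

    Candidates are leaves other than the query that appear in the metadata
    and whose source tag is not excluded. The donor is the candidate at
    minimum patristic distance; exact-distance ties are broken by
    lexicographically smallest gene symbol (case-insensitive, so "abd-A"
    precedes "Ubx"; then leaf label) and surfaced via ``n_ties``.
    """
    if query_id not in tree:
        raise KeyError(f"query {query_id!r} is not a leaf of the tree")
    excluded = exclude_tags or set()
    tree._require_lengths()
    dist = _distances_from(tree, tree.leaf(query_id))
    candidates = [
        (dist[leaf], metadata.symbol(leaf.label), leaf.label)
        for leaf in tree.leaves
        if leaf.label != query_id
        and leaf.label in metadata
        and metadata.source_tag(leaf.label) not in excluded
    ]
    if not candidates:
        return AnnotationRecord(query_id, None, None, None, 0, tree.source)
    best = min(d for d, _, _ in candidates)
    at_best = sorted(
        ((sym, leaf) for d, sym, leaf in candidates if d == best),
        key=lambda t: (t[0].casefold(), t[0], t[1]),
    )
    symbol, donor = at_best[0]
    return AnnotationRecord(query_id, symbol, donor, best, len(at_best), tree.source)


NEWICK_SUFFIXES = (".nwk", ".newick", ".tree", ".tre", ".txt")


def annotate_trees(
    tree_dir,
    queries: Sequence[str],
    metadata: LeafMetadata,
    exclude_tags: Optional[set] = None,
    unit_branch_lengths: bool = False,
) -> list[AnnotationRecord]:
    """Annotate every query against a directory of Newick gene trees.

    Files are processed in sorted order; per-file parse failures are
    reported and skipped, not fatal. Each query should occur in at most one
    tree (violations are reported; the first tree wins). Queries found in no
    tree receive a record with all-``None`` assignment and no tree source.
    """
    tree_dir = Path(tree_dir)
    if not tree_dir.is_dir():
        raise NotADirectoryError(f"{tree_dir} is not a readable directory")
    trees: list[GeneTree] = []
    paths = sorted(p for p in tree_dir.iterdir() if p.suffix.lower() in NEWICK_SUFFIXES)
    for path in paths:
        try:
            tree = read_newick(path)
            if unit_branch_lengths:
                tree.resolve_branch_lengths(fill=1.0)
            else:
                tree.resolve_branch_lengths(None)
            trees.append(tree)
        except (NewickParseError, ValueError) as exc:
            warnings.warn(f"skipping unparseable tree {path.name}: {exc}", UserWarning)
    home: dict[str, GeneTree] = {}
    for q in queries:
        hosts = [t for t in trees if q in t]
        if len(hosts) > 1:
            warnings.warn(
                f"query {q!r} appears in {len(hosts)} trees "
                f"({[t.source for t in hosts]}); using {hosts[0].source}",
                UserWarning,
            )
        if hosts:
            home[q] = hosts[0]
    records = []
    for q in queries:
        if q in home:
            records.append(annotate_query(home[q], q, metadata, exclude_tags))
        else:
            records.append(AnnotationRecord(q, None, None, None, 0, None))
    return records


def annotations_to_frame(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    rows = [
        {
            "query_id": r.query_id,
            "assigned_symbol": r.assigned_symbol if r.assigned_symbol is not None else "NONE",
            "donor_leaf": r.donor_leaf if r.donor_leaf is not None else "NONE",
            "patristic_distance": r.patristic_distance if r.patristic_distance is not None else "NONE",
            "n_ties": r.n_ties,
            "tree_source": r.tree_source if r.tree_source is not None else "NONE",
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["query_id", "assigned_symbol", "donor_leaf", "patristic_distance", "n_ties", "tree_source"],
    )


def write_annotations_tsv(records: Sequence[AnnotationRecord], path) -> None:
    annotations_to_frame(records).to_csv(path, sep="\t", index=False)
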