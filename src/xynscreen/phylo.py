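"""Distance-based phylogenetics for catalytic-domain sequences.

This module builds the family tree consumed by the clade screen: fast k-mer
guide distances, global pairwise alignment with a linear gap penalty,
classic progressive multiple alignment over a UPGMA guide tree, p-distances
from the alignment, UPGMA and neighbor-joining reconstruction, column
resampling bootstrap supports, and Newick interchange.

Design notes
------------
* All tie-breaks are fixed so every operation is deterministic: alignment
  traceback prefers diagonal, then up (consume the first sequence), then
  left; agglomerative joins pick the lexicographically smallest label pair.
* Neighbor joining is exact on additive distance matrices, which is the
  property the test oracles exercise; negative branch length estimates are
  clamped to zero with a warning, as is standard practice.
* Bootstrap supports are percentages (0-100) of column-resampled replicate
  trees that contain the same leaf bipartition; values below 50 are
  conventionally treated as non-significant downstream.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

logger = logging.getLogger("xynscreen.phylo")

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
_GAP = 20  # profile column index reserved for the gap symbol

DEFAULT_GAP_PENALTY = -4.0
_TOL = 1e-7


class NewickParseError(ValueError):
    """Malformed Newick text; carries the character position of the fault."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def load_blosum62() -> np.ndarray:
    """Return BLOSUM62 as a dense 20x20 array in ``AA_ORDER`` order."""
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            out[i, j] = mat[a, b]
    return out


# ---------------------------------------------------------------------------
# Tree container
# ---------------------------------------------------------------------------

class Node:
    """A tree node: leaves carry a name, internal edges may carry support."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.support: int | None = None
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Rooted or unrooted (trifurcating root) tree with branch lengths and
    integer bootstrap supports on internal edges."""

    root: Node

    def postorder(self) -> Iterable[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def leafsets(self) -> dict[int, frozenset[str]]:
        """Map id(node) -> frozenset of leaf names under that node."""
        out: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[id(node)] = frozenset([node.name])
            else:
                acc: set[str] = set()
                for c in node.children:
                    acc |= out[id(c)]
                out[id(node)] = frozenset(acc)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each normalised to the side that does
        not contain the lexicographically smallest leaf."""
        names = self.leaf_names()
        all_leaves = frozenset(names)
        ref = min(names)
        sets = self.leafsets()
        out: set[frozenset[str]] = set()
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = sets[id(node)]
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return out

    def copy(self) -> "PhyloTree":
        return read_newick(write_newick(self))

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return write_newick(self)


# ---------------------------------------------------------------------------
# Newick IO
# ---------------------------------------------------------------------------

def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string. Numeric internal-node labels are interpreted
    as bootstrap supports; anything else becomes the node name."""
    text = text.strip()
    if not text.endswith(";"):
        raise NewickParseError("missing terminating ';'", len(text))
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if text[pos] == "(":
            pos += 1
            while True:
                node.add(parse_node())
                if pos >= len(text):
                    raise NewickParseError("unmatched '('", pos)
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise NewickParseError(f"unexpected character {text[pos]!r}", pos)
        # label (leaf name or internal support/name)
        start = pos
        while pos < len(text) and text[pos] not in ",():;":
            pos += 1
        label = text[start:pos]
        if label:
            if node.children:
                try:
                    node.support = int(round(float(label)))
                except ValueError:
                    node.name = label
            else:
                node.name = label
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",():;":
                pos += 1
            try:
                node.length = float(text[start:pos])
            except ValueError:
                raise NewickParseError("invalid branch length", start) from None
        return node

    root = parse_node()
    if pos >= len(text) or text[pos] != ";":
        raise NewickParseError("trailing characters before ';'", pos)
    return PhyloTree(root)


def _fmt_len(x: float) -> str:
    return f"{x:.6g}"


def write_newick(tree: PhyloTree) -> str:
    def render(node: Node) -> str:
        if node.is_leaf:
            s = node.name or ""
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.support is not None:
                s += str(node.support)
            elif node.name:
                s += node.name
        if node.length is not None:
            s += f":{_fmt_len(node.length)}"
        return s

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal matrix over named taxa."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be nonnegative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - (shared k-mers / min total k-mers); multiset counting.

    Cheap alignment-free distance used only for guide trees.
    """
    if len(a) < k or len(b) < k:
        raise ValueError(f"sequences must be at least k={k} residues long")

    def counts(s: str) -> dict[str, int]:
        c: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            c[w] = c.get(w, 0) + 1
        return c

    ca, cb = counts(a), counts(b)
    shared = sum(min(n, cb.get(w, 0)) for w, n in ca.items())
    denom = min(len(a), len(b)) - k + 1
    return 1.0 - shared / denom


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Gapped rows over a shared coordinate system ('-' is the gap)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def encoded(self) -> np.ndarray:
        """Integer matrix, residues 0-19 and gap -1."""
        code = np.full((len(self.rows), self.length), -1, dtype=np.int8)
        for i, row in enumerate(self.rows):
            for j, ch in enumerate(row):
                if ch != "-":
                    code[i, j] = AA_INDEX[ch]
        return code

    def resample_columns(self, idx: Sequence[int]) -> "Alignment":
        rows = ["".join(r[j] for j in idx) for r in self.rows]
        return Alignment(list(self.ids), rows)


def _profile(rows: list[str]) -> np.ndarray:
    """Column frequency profile (L, 21); index 20 is the gap symbol."""
    L = len(rows[0])
    prof = np.zeros((L, 21))
    for row in rows:
        for j, ch in enumerate(row):
            prof[j, _GAP if ch == "-" else AA_INDEX[ch]] += 1
    prof /= len(rows)
    return prof


def _extended_matrix(matrix: np.ndarray, gap: float) -> np.ndarray:
    """21x21 score matrix: residue-gap pairs cost the gap penalty,
    gap-gap pairs cost nothing."""
    S = np.zeros((21, 21))
    S[:20, :20] = matrix
    S[:20, _GAP] = gap
    S[_GAP, :20] = gap
    return S


def _align_profiles(
    fa: np.ndarray, fb: np.ndarray, S: np.ndarray, gap: float
) -> tuple[list[str], float]:
    """Global profile-profile alignment; returns the edit path and score.

    The DP row recurrence is vectorised with a prefix-max scan: with linear
    gaps, H[i, j] = max(A[j], H[i, j-1] + g) unrolls to a running maximum of
    A[k] - g*k.  Traceback prefers diagonal, then up, then left.
    """
    La, Lb = fa.shape[0], fb.shape[0]
    P = fa @ S @ fb.T  # column-pair sum-of-pairs scores
    H = np.empty((La + 1, Lb + 1))
    jj = np.arange(Lb + 1)
    H[0] = gap * jj
    for i in range(1, La + 1):
        prev = H[i - 1]
        cand = np.empty(Lb + 1)
        cand[0] = gap * i
        cand[1:] = np.maximum(prev[:-1] + P[i - 1], prev[1:] + gap)
        H[i] = np.maximum.accumulate(cand - gap * jj) + gap * jj

    path: list[str] = []
    i, j = La, Lb
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0 and abs(h - (H[i - 1, j - 1] + P[i - 1, j - 1])) < _TOL:
            path.append("D")
            i, j = i - 1, j - 1
        elif i > 0 and abs(h - (H[i - 1, j] + gap)) < _TOL:
            path.append("U")
            i -= 1
        else:
            path.append("L")
            j -= 1
    path.reverse()
    return path, float(H[La, Lb])


def _apply_path(rows_a: list[str], rows_b: list[str], path: list[str]) -> list[str]:
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    i = j = 0
    for move in path:
        take_a = move in ("D", "U")
        take_b = move in ("D", "L")
        for r, row in enumerate(rows_a):
            out_a[r] += row[i] if take_a else "-"
        for r, row in enumerate(rows_b):
            out_b[r] += row[j] if take_b else "-"
        if take_a:
            i += 1
        if take_b:
            j += 1
    return out_a + out_b


def global_align(
    a: str,
    b: str,
    matrix: np.ndarray | None = None,
    gap: float = DEFAULT_GAP_PENALTY,
) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences under a linear gap model.

    Returns ``(aligned_a, aligned_b, score)``.  Deterministic traceback:
    diagonal beats up (gap in ``b``) beats left (gap in ``a``).
    """
    if matrix is None:
        matrix = load_blosum62()
    S = _extended_matrix(matrix, gap)
    fa = _profile([a]) if a else np.zeros((0, 21))
    fb = _profile([b]) if b else np.zeros((0, 21))
    path, score = _align_profiles(fa, fb, S, gap)
    merged = _apply_path([a], [b], path)
    return merged[0], merged[1], score


def progressive_msa(
    seqs: Sequence[tuple[str, str]],
    matrix: np.ndarray | None = None,
    gap: float = DEFAULT_GAP_PENALTY,
    k: int = 3,
) -> Alignment:
    """Progressive multiple alignment over a UPGMA guide tree.

    ``seqs`` is an ordered list of ``(id, residues)``.  Guide distances are
    k-mer distances; profiles are merged leaf-to-root with sum-of-pairs
    profile-profile alignment.  Output row order follows the input order.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa requires at least 2 sequences")
    ids = [s[0] for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    by_id = dict(seqs)
    if matrix is None:
        matrix = load_blosum62()
    S = _extended_matrix(matrix, gap)

    k_eff = min(k, min(len(s) for _, s in seqs))
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = kmer_distance(seqs[i][1], seqs[j][1], k_eff)
    guide = upgma(DistanceMatrix(ids, D))

    def merge(node: Node) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.name], [by_id[node.name]]
        sub = [merge(c) for c in node.children]
        acc_ids, acc_rows = sub[0]
        for nxt_ids, nxt_rows in sub[1:]:
            path, _ = _align_profiles(_profile(acc_rows), _profile(nxt_rows), S, gap)
            acc_rows = _apply_path(acc_rows, nxt_rows, path)
            acc_ids = acc_ids + nxt_ids
        return acc_ids, acc_rows

    out_ids, out_rows = merge(guide.root)
    order = {name: i for i, name in enumerate(out_ids)}
    rows = [out_rows[order[name]] for name in ids]
    return Alignment(ids, rows)


def pdist_from_msa(aln: Alignment) -> DistanceMatrix:
    """Pairwise p-distances: 1 - identity over columns where neither row is
    gapped.  Pairs with no comparable column get distance 1 with a warning."""
    code = aln.encoded()
    n = len(aln.ids)
    D = np.zeros((n, n))
    present = code >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            m = int(both.sum())
            if m == 0:
                logger.warning(
                    "no comparable columns between %s and %s; distance set to 1",
                    aln.ids[i], aln.ids[j],
                )
                d = 1.0
            else:
                ident = int((code[i][both] == code[j][both]).sum())
                d = 1.0 - ident / m
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(aln.ids), D)


# ---------------------------------------------------------------------------
# Tree building
# ---------------------------------------------------------------------------

def _min_pair(score: np.ndarray, labels: list[str]) -> tuple[int, int]:
    """Index pair minimising ``score``; ties broken by the lexicographically
    smallest sorted label pair."""
    n = score.shape[0]
    iu = np.triu_indices(n, 1)
    vals = score[iu]
    best = vals.min()
    mask = vals <= best + 1e-12 * max(1.0, abs(best))
    cands = list(zip(iu[0][mask], iu[1][mask]))
    key = lambda ij: tuple(sorted((labels[ij[0]], labels[ij[1]])))
    i, j = min(cands, key=key)
    return int(i), int(j)


def upgma(D: DistanceMatrix) -> PhyloTree:
    """UPGMA agglomeration with arithmetic-mean updates (rooted, ultrametric
    if the input is).  Ties: smallest label pair."""
    n = len(D.labels)
    if n < 2:
        raise ValueError("upgma requires at least 2 taxa")
    mat = D.values.copy()
    nodes = [Node(name=lbl) for lbl in D.labels]
    labels = list(D.labels)  # cluster tie-break label = min member label
    heights = [0.0] * n
    sizes = [1] * n
    while len(nodes) > 1:
        m = len(nodes)
        view = mat + np.where(np.eye(m, dtype=bool), np.inf, 0.0)
        i, j = _min_pair(view, labels)
        h = mat[i, j] / 2.0
        parent = Node()
        for idx in (i, j):
            child = nodes[idx]
            child.length = h - heights[idx]
            parent.add(child)
        new_row = (sizes[i] * mat[i] + sizes[j] * mat[j]) / (sizes[i] + sizes[j])
        keep = [x for x in range(m) if x not in (i, j)]
        mat = np.vstack([mat[keep][:, keep], new_row[keep]])
        mat = np.hstack([mat, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]
        labels = [labels[x] for x in keep] + [min(labels[i], labels[j])]
        heights = [heights[x] for x in keep] + [h]
        sizes = [sizes[x] for x in keep] + [sizes[i] + sizes[j]]
    return PhyloTree(nodes[0])


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining (unrooted; root is trifurcating).

    Exact on additive matrices.  Negative branch length estimates are
    clamped to 0 with a warning.  Ties: smallest label pair.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor_joining requires at least 3 taxa")

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                logger.warning("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    mat = D.values.copy()
    nodes = [Node(name=lbl) for lbl in D.labels]
    labels = list(D.labels)
    while len(nodes) > 3:
        m = len(nodes)
        r = mat.sum(axis=1)
        Q = (m - 2) * mat - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = _min_pair(Q, labels)
        dij = mat[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = Node()
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent.add(nodes[i])
        parent.add(nodes[j])
        new_row = 0.5 * (mat[i] + mat[j] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        mat = np.vstack([mat[keep][:, keep], new_row[keep]])
        mat = np.hstack([mat, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]
        labels = [labels[x] for x in keep] + [min(labels[i], labels[j])]
    # connect the last three through one internal node
    a, b, c = nodes
    dab, dac, dbc = mat[0, 1], mat[0, 2], mat[1, 2]
    root = Node()
    a.length = clamp(0.5 * (dab + dac - dbc))
    b.length = clamp(0.5 * (dab + dbc - dac))
    c.length = clamp(0.5 * (dac + dbc - dab))
    for x in (a, b, c):
        root.add(x)
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_supports(
    aln: Alignment,
    builder: Callable[[Alignment], PhyloTree] | None = None,
    n_reps: int = 1000,
    seed: int | None = None,
) -> PhyloTree:
    """Column-resampling bootstrap.

    Builds the main tree from the full alignment, then ``n_reps`` replicate
    trees from alignments of columns drawn with replacement; each internal
    edge of the main tree gets the percentage (0-100, rounded) of replicates
    containing the same bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if builder is None:
        builder = lambda a: neighbor_joining(pdist_from_msa(a))
    tree = builder(aln)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    L = aln.length
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        rep = builder(aln.resample_columns(list(idx)))
        for bip in rep.bipartitions():
            counts[bip] = counts.get(bip, 0) + 1

    names = tree.leaf_names()
    all_leaves = frozenset(names)
    ref = min(names)
    sets = tree.leafsets()
    for node in tree.postorder():
        if node is tree.root or node.is_leaf:
            continue
        side = sets[id(node)]
        if ref in side:
            side = all_leaves - side
        if not (1 < len(side) < len(all_leaves) - 1):
            continue  # trivial edge: support undefined
        node.support = int(round(100 * counts.get(side, 0) / n_reps))
    return tree
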