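"""Catalytic-domain phylogenetics.

The family tree is inferred from validated catalytic domains in four stages,
each an explicit, testable primitive: global pairwise alignment with affine
gaps under BLOSUM62; progressive multiple alignment guided by single-linkage
clustering on 3-mer distances with mean-of-pairs profile merging; corrected
pairwise distances (p or Kimura-corrected, d = -ln(1 - p - p^2/5)); and
neighbor joining with column-resampling bootstrap supports expressed as
percentages. Trees serialise to Newick with supports as internal-node labels
and branch lengths to six decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import GAP, RESIDUES, check_sequence
from .matrices import ScoreTable, blosum62

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "UndefinedDistanceError",
    "pairwise_align",
    "progressive_msa",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_tree",
    "summarize_clades",
    "leaf_distance_matrix",
    "robinson_foulds",
]

_NEG = -1.0e30
_GAP_CODE = 20
_RES_INDEX = {r: i for i, r in enumerate(RESIDUES)}
# 'X' in sequences entering alignment is scored as zero against everything
_X_CODE = 21


def _matrix_array(matrix: ScoreTable | None) -> np.ndarray:
    m = matrix if matrix is not None else blosum62()
    arr = np.zeros((22, 22))
    for a, ia in _RES_INDEX.items():
        for b, ib in _RES_INDEX.items():
            arr[ia, ib] = m[(a, b)]
    return arr


def _encode(seq: str) -> np.ndarray:
    return np.array(
        [_GAP_CODE if c == GAP else _RES_INDEX.get(c, _X_CODE) for c in seq.upper()],
        dtype=np.int8,
    )


# --- affine-gap dynamic programming ----------------------------------------


def _affine_dp(S: np.ndarray, gap_open: float, gap_extend: float):
    """Global alignment over a precomputed column-score matrix.

    A gap run of length L costs ``gap_open + (L-1)*gap_extend``. Three-state
    Gotoh recursion with all inter-state transitions allowed; deterministic
    tie-breaking prefers diagonal, then up (gap in the second profile), then
    left. Returns (score, moves) with moves in {'D','U','L'}.
    """
    la, lb = S.shape
    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)  # up: consumes a row of A
    Y = np.full((la + 1, lb + 1), _NEG)  # left: consumes a row of B
    pM = np.zeros((la + 1, lb + 1), dtype=np.int8)
    pX = np.zeros((la + 1, lb + 1), dtype=np.int8)
    pY = np.zeros((la + 1, lb + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -(gap_open + (i - 1) * gap_extend)
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, lb + 1):
        Y[0, j] = -(gap_open + (j - 1) * gap_extend)
        pY[0, j] = 0 if j == 1 else 2

    def pick(cm, cx, cy):
        if cm >= cx and cm >= cy:
            return cm, 0
        if cx >= cy:
            return cx, 1
        return cy, 2

    for i in range(1, la + 1):
        Si = S[i - 1]
        for j in range(1, lb + 1):
            v, p = pick(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = Si[j - 1] + v
            pM[i, j] = p
            v, p = pick(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend, Y[i - 1, j] - gap_open)
            X[i, j] = v
            pX[i, j] = p
            v, p = pick(M[i, j - 1] - gap_open, X[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
            Y[i, j] = v
            pY[i, j] = p

    score, state = pick(M[la, lb], X[la, lb], Y[la, lb])
    moves = []
    i, j = la, lb
    while i > 0 or j > 0:
        if state == 0:
            moves.append("D")
            state = pM[i, j]
            i, j = i - 1, j - 1
        elif state == 1:
            moves.append("U")
            state = pX[i, j]
            i -= 1
        else:
            moves.append("L")
            state = pY[i, j]
            j -= 1
    moves.reverse()
    return float(score), moves


def pairwise_align(
    a: str,
    b: str,
    matrix: ScoreTable | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
):
    """Global affine-gap alignment of two residue strings.

    Returns ``(score, (aligned_a, aligned_b))``; a length-L gap costs
    ``gap_open + (L-1)*gap_extend``. Empty inputs are allowed.
    """
    sa, sb = check_sequence(a), check_sequence(b)
    B = _matrix_array(matrix)
    ea, eb = _encode(sa), _encode(sb)
    S = B[np.ix_(ea, eb)] if len(ea) and len(eb) else np.zeros((len(ea), len(eb)))
    score, moves = _affine_dp(S, gap_open, gap_extend)
    ra, rb = [], []
    i = j = 0
    for mv in moves:
        if mv == "D":
            ra.append(sa[i])
            rb.append(sb[j])
            i += 1
            j += 1
        elif mv == "U":
            ra.append(sa[i])
            rb.append(GAP)
            i += 1
        else:
            ra.append(GAP)
            rb.append(sb[j])
            j += 1
    return score, ("".join(ra), "".join(rb))


# --- multiple alignment -----------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    """Gapped equal-length rows over an ordered id list."""

    ids: tuple
    rows: tuple

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def to_array(self) -> np.ndarray:
        return np.vstack([_encode(r) for r in self.rows])


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if min(len(a), len(b)) < k:
        return 1.0
    ca: dict = {}
    for i in range(len(a) - k + 1):
        ca[a[i : i + k]] = ca.get(a[i : i + k], 0) + 1
    shared = 0
    cb: dict = {}
    for i in range(len(b) - k + 1):
        w = b[i : i + k]
        cb[w] = cb.get(w, 0) + 1
        if cb[w] <= ca.get(w, 0):
            shared += 1
    return 1.0 - shared / (min(len(a), len(b)) - k + 1)


def _profile_counts(rows: list) -> np.ndarray:
    L = len(rows[0])
    C = np.zeros((L, 22))
    for r in rows:
        C[np.arange(L), _encode(r)] += 1.0
    return C


def progressive_msa(
    records,
    matrix: ScoreTable | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Alignment:
    """Progressive multiple alignment of SequenceRecord-like inputs.

    Guide order comes from single-linkage clustering on 3-mer distances;
    profiles are merged with mean-of-pairs column scores (gap pairs score 0).
    De-gapping any output row recovers its input sequence exactly.
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    recs = [(r.id, check_sequence(r.sequence)) for r in records]
    n = len(recs)
    if n < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    B = _matrix_array(matrix)
    B[_GAP_CODE, :] = 0.0
    B[:, _GAP_CODE] = 0.0

    if n == 2:
        _, (ra, rb) = pairwise_align(recs[0][1], recs[1][1], matrix, gap_open, gap_extend)
        return Alignment((recs[0][0], recs[1][0]), (ra, rb))

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _kmer_distance(recs[i][1], recs[j][1])
    Z = linkage(squareform(D, checks=False), method="single")

    # profiles: (ids, rows)
    profiles: dict = {i: ([recs[i][0]], [recs[i][1]]) for i in range(n)}
    for step, (a, b, _, _) in enumerate(Z):
        pa, pb = profiles.pop(int(a)), profiles.pop(int(b))
        ca, cb = _profile_counts(pa[1]), _profile_counts(pb[1])
        S = (ca @ B @ cb.T) / (len(pa[1]) * len(pb[1]))
        _, moves = _affine_dp(S, gap_open, gap_extend)
        rows_a = ["" for _ in pa[1]]
        rows_b = ["" for _ in pb[1]]
        i = j = 0
        for mv in moves:
            if mv in ("D", "U"):
                for k, r in enumerate(pa[1]):
                    rows_a[k] += r[i]
                i += 1
            else:
                for k in range(len(pa[1])):
                    rows_a[k] += GAP
            if mv in ("D", "L"):
                for k, r in enumerate(pb[1]):
                    rows_b[k] += r[j]
                j += 1
            else:
                for k in range(len(pb[1])):
                    rows_b[k] += GAP
        profiles[n + step] = (pa[0] + pb[0], rows_a + rows_b)

    ids, rows = profiles.popitem()[1]
    # restore input order
    order = {rid: k for k, (rid, _) in enumerate(recs)}
    pairs = sorted(zip(ids, rows), key=lambda t: order[t[0]])
    return Alignment(tuple(p[0] for p in pairs), tuple(p[1] for p in pairs))


# --- distances --------------------------------------------------------------


class UndefinedDistanceError(ValueError):
    """A sequence pair shares no gap-free alignment columns."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    ids: tuple
    values: np.ndarray = field(compare=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any() or not np.isfinite(v).all():
            raise ValueError("distances must be finite and non-negative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.ids)


def _pairwise_p(arr: np.ndarray):
    """Mismatch fractions over gap-free column pairs; returns (p, n_valid)."""
    nongap = arr != _GAP_CODE
    valid = nongap[:, None, :] & nongap[None, :, :]
    mism = (arr[:, None, :] != arr[None, :, :]) & valid
    nv = valid.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(nv > 0, mism.sum(axis=2) / np.maximum(nv, 1), np.nan)
    return p, nv


def _correct(p: np.ndarray, correction: str, saturation_p: float, max_distance: float):
    if correction == "p":
        return p.copy()
    if correction != "kimura":
        raise ValueError(f"unknown distance correction {correction!r}")
    arg = 1.0 - p - 0.2 * p * p
    d = np.where(
        (p >= saturation_p) | (arg <= 0.0), max_distance, -np.log(np.clip(arg, 1e-12, None))
    )
    return np.minimum(d, max_distance)


def distance_matrix(
    aln: Alignment,
    correction: str = "kimura",
    saturation_p: float = 0.85,
    max_distance: float = 10.0,
) -> DistanceMatrix:
    """Pairwise distances from an alignment, excluding gapped column pairs.

    ``p`` is the raw mismatch fraction; ``kimura`` applies the protein
    correction d = -ln(1 - p - p^2/5), capped at ``max_distance`` once
    p reaches ``saturation_p``.
    """
    arr = aln.to_array()
    p, nv = _pairwise_p(arr)
    if (nv == 0).any():
        bad = np.argwhere(nv == 0)
        i, j = next((a, b) for a, b in bad if a != b)
        raise UndefinedDistanceError(
            f"no comparable columns between {aln.ids[i]!r} and {aln.ids[j]!r}"
        )
    d = _correct(p, correction, saturation_p, max_distance)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(tuple(aln.ids), d)


# --- trees ------------------------------------------------------------------


class TreeNode:
    """One node of an (un)rooted tree; leaves carry names."""

    __slots__ = ("name", "branch_length", "support", "children")

    def __init__(self, name=None, branch_length=0.0, support=None, children=None):
        self.name = name
        self.branch_length = float(branch_length)
        self.support = support
        self.children = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Unrooted tree represented with a (usually trifurcating) root node."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversal ----------------------------------------------------------

    def _iter_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self):
        return [n for n in self._iter_nodes() if n.is_leaf]

    def leaf_names(self):
        return sorted(n.name for n in self.leaves())

    def _bipartition_nodes(self):
        """Map canonical internal bipartitions to their subtree nodes."""
        full = frozenset(self.leaf_names())
        ref = min(full)

        out = {}

        def leafset(node):
            if node.is_leaf:
                return frozenset({node.name})
            s = frozenset().union(*(leafset(c) for c in node.children))
            if node is not self.root and 1 < len(s) < len(full) - 1:
                canon = s if ref not in s else full - s
                out[canon] = node
            return s

        leafset(self.root)
        return out

    def bipartitions(self):
        """Canonical non-trivial bipartitions as a frozenset of leaf-name sets."""
        return frozenset(self._bipartition_nodes().keys())

    # -- newick --------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node):
            if node.is_leaf:
                return f"{node.name}:{node.branch_length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.branch_length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        label = "" if self.root.support is None else f"{self.root.support:g}"
        return f"({inner}){label};"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        s = text.strip()
        if not s.endswith(";"):
            raise ValueError("newick string must end with ';'")
        s = s[:-1]
        pos = 0

        def parse_node():
            nonlocal pos
            node = TreeNode()
            if s[pos] == "(":
                pos += 1
                node.children.append(parse_node())
                while s[pos] == ",":
                    pos += 1
                    node.children.append(parse_node())
                if s[pos] != ")":
                    raise ValueError(f"expected ')' at position {pos}")
                pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            label = s[start:pos]
            if label:
                if node.is_leaf:
                    node.name = label
                else:
                    node.support = float(label)
            if pos < len(s) and s[pos] == ":":
                pos += 1
                start = pos
                while pos < len(s) and s[pos] not in ",()":
                    pos += 1
                node.branch_length = float(s[start:pos])
            return node

        root = parse_node()
        if pos != len(s):
            raise ValueError(f"trailing newick content at position {pos}")
        return cls(root)


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference (RF) distance over canonical bipartitions."""
    if t1.leaf_names() != t2.leaf_names():
        raise ValueError("trees must share the same leaf set")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    return len(b1 ^ b2)


def leaf_distance_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Additive path-length distances between all leaf pairs."""
    names = tree.leaf_names()
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    d = np.zeros((n, n))

    def walk(node):
        # returns {leaf_index: distance to this node}
        if node.is_leaf:
            return {idx[node.name]: 0.0}
        maps = [
            {k: v + c.branch_length for k, v in walk(c).items()} for c in node.children
        ]
        for a in range(len(maps)):
            for b in range(a + 1, len(maps)):
                for i, di in maps[a].items():
                    for j, dj in maps[b].items():
                        d[i, j] = d[j, i] = di + dj
        merged = {}
        for m in maps:
            merged.update(m)
        return merged

    walk(tree.root)
    return DistanceMatrix(tuple(names), d)


# --- neighbor joining -------------------------------------------------------


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Standard NJ agglomeration with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (sorted) pair of subtree representative ids; negative branch lengths are
    clamped to zero with the deficit shifted onto the sister edge.
    """
    n = len(D)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    if n == 2:
        h = D.values[0, 1] / 2.0
        root = TreeNode(
            children=[TreeNode(D.ids[0], h), TreeNode(D.ids[1], h)]
        )
        return PhyloTree(root)

    nodes = [TreeNode(name) for name in D.ids]
    reps = [str(name) for name in D.ids]  # tie-break representatives
    d = D.values.copy()
    active = list(range(n))

    def join(i_pos: int, j_pos: int):
        nonlocal d, active, nodes, reps
        i, j = active[i_pos], active[j_pos]
        m = len(active)
        r = d[np.ix_(active, active)].sum(axis=1)
        dij = d[i, j]
        if m > 2:
            li = dij / 2.0 + (r[i_pos] - r[j_pos]) / (2.0 * (m - 2))
        else:
            li = dij / 2.0
        lj = dij - li
        if li < 0:
            li, lj = 0.0, max(lj + li, 0.0)
        elif lj < 0:
            li, lj = max(li + lj, 0.0), 0.0
        u = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        # distances to the new node
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k not in (i, j):
                new_row[k] = max(0.0, (d[i, k] + d[j, k] - dij) / 2.0)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(u)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if Q[a, b] <= qmin + 1e-12:
                    key = tuple(sorted((reps[active[a]], reps[active[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        join(best[1], best[2])

    # resolve the final three around a central trifurcation
    a, b, c = active
    la = max(0.0, (d[a, b] + d[a, c] - d[b, c]) / 2.0)
    lb = max(0.0, (d[a, b] + d[b, c] - d[a, c]) / 2.0)
    lc = max(0.0, (d[a, c] + d[b, c] - d[a, b]) / 2.0)
    for k, lk in ((a, la), (b, lb), (c, lc)):
        nodes[k].branch_length = lk
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root)


# --- bootstrap --------------------------------------------------------------


def bootstrap_tree(
    msa: Alignment,
    n_reps: int = 100,
    seed: int = 0,
    correction: str = "kimura",
    saturation_p: float = 0.85,
    max_distance: float = 10.0,
    keep_replicates: bool = False,
):
    """NJ tree with bootstrap supports from column resampling.

    Exactly ``n_reps`` replicates are drawn (columns resampled with
    replacement from a single seeded stream); the support of an internal
    edge is the percentage of replicate trees containing the same
    bipartition. Replicate pairs left without comparable columns fall back
    to the saturation distance cap.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = neighbor_joining(distance_matrix(msa, correction, saturation_p, max_distance))
    bip_nodes = base._bipartition_nodes()
    counts = {bip: 0 for bip in bip_nodes}
    arr = msa.to_array()
    ncols = arr.shape[1]
    rng = np.random.default_rng(seed)
    replicates = []
    for _ in range(n_reps):
        idx = rng.integers(0, ncols, size=ncols)
        p, nv = _pairwise_p(arr[:, idx])
        d = _correct(np.nan_to_num(p, nan=1.0), correction, saturation_p, max_distance)
        d[nv == 0] = max_distance
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
        t = neighbor_joining(DistanceMatrix(tuple(msa.ids), d))
        for bip in t.bipartitions():
            if bip in counts:
                counts[bip] += 1
        if keep_replicates:
            replicates.append(t)
    for bip, node in bip_nodes.items():
        node.support = 100.0 * counts[bip] / n_reps
    if keep_replicates:
        return base, replicates
    return base


def summarize_clades(tree: PhyloTree, metadata) -> "pd.DataFrame":
    """Per-clade leaf counts and monophyly flags.

    ``metadata`` maps leaf id -> clade label; leaves without a label (or
    with an empty one) are grouped as ``unmapped``. A clade is monophyletic
    when its leaves form a subtree (a bipartition side), are a single leaf,
    or are the entire tree.
    """
    import pandas as pd

    names = tree.leaf_names()
    full = frozenset(names)
    ref = min(full)
    bips = tree.bipartitions()
    groups: dict = {}
    for leaf in names:
        clade = metadata.get(leaf) if hasattr(metadata, "get") else None
        clade = clade or "unmapped"
        groups.setdefault(clade, set()).add(leaf)
    rows = []
    for clade in sorted(groups):
        ls = frozenset(groups[clade])
        canon = ls if ref not in ls else full - ls
        mono = len(ls) == 1 or ls == full or canon in bips
        rows.append({"clade": clade, "n_leaves": len(ls), "monophyletic": bool(mono)})
    return pd.DataFrame(rows, columns=["clade", "n_leaves", "monophyletic"])
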