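"""Desk-scale alignment and tree building for kinase-domain phylogenetics.

The tree protocol mirrors the classical workflow for domain phylogenies:
extract the domain regions, align them, trim alignment columns containing
more than 25% gaps, estimate pairwise maximum-likelihood distances under
the WAG substitution model, build a neighbor-joining tree with deterministic
tie-breaking, and attach column-bootstrap support percentages to internal
edges. A full ML tree search is deliberately replaced by WAG-ML distances +
NJ: at the scale of this package the quantity of interest is planted-clade
recovery, for which distance NJ is exact on additive inputs and consistent
under the model.

Alignment is a profile-profile Gotoh dynamic program under affine gaps
(gap of length L costs open + (L-1) * extend), merged leaf-to-root along a
k-mer/UPGMA guide tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from .profiles import AA, AA_INDEX, encode
from .wag import WAGModel, default_model

GAP = "-"

#: default affine gap penalties and saturation bound
GAP_OPEN = 10.0
GAP_EXTEND = 0.5
DISTANCE_CAP = 10.0


# ---------------------------------------------------------------------------
# containers


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows keyed by ordered ids."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("ragged alignment")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


class TreeNode:
    """A minimal phylogenetic tree node (children + branch length)."""

    __slots__ = ("name", "length", "support", "children")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 children: list["TreeNode"] | None = None):
        self.name = name
        self.length = length
        self.support: float | None = None
        self.children: list[TreeNode] = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.walk() if n.is_leaf]

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.0f}"
            return f"({inner}){label}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"


def parse_newick(text: str) -> TreeNode:
    """Parse a (rooted) newick string with branch lengths."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick must end with ';'")
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        # label
        start = pos
        while pos < len(text) and text[pos] not in ",():;":
            pos += 1
        if pos > start:
            node.name = text[start:pos]
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",();":
                pos += 1
            node.length = float(text[start:pos])
        return node

    root = parse_node()
    if text[pos] != ";":
        raise ValueError("trailing characters in newick")
    return root


# ---------------------------------------------------------------------------
# pairwise and progressive alignment

_BLOSUM62: np.ndarray | None = None


def blosum62() -> np.ndarray:
    """BLOSUM62 as a dense 20x20 array in the package residue order."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices
        mat = substitution_matrices.load("BLOSUM62")
        arr = np.zeros((20, 20))
        for i, a in enumerate(AA):
            for j, b in enumerate(AA):
                arr[i, j] = mat[a, b]
        _BLOSUM62 = arr
    return _BLOSUM62


def _gotoh(pair: np.ndarray, gap_open: float, gap_extend: float
           ) -> tuple[list[int | None], list[int | None], float]:
    """Affine-gap global DP over a precomputed pair-score matrix.

    Returns aligned index paths for the two inputs (None marks a gap) and
    the optimal score. Tie-breaking prefers match over a gap in the second
    input over a gap in the first, which makes co-optimal alignments
    deterministic.
    """
    n, m = pair.shape
    neg = -np.inf
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)   # gap in B (consumes A)
    Y = np.full((n + 1, m + 1), neg)   # gap in A (consumes B)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0:M 1:X 2:Y
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0: from M, 1: from X
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + (i - 1) * gap_extend)
        ptr_x[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + (j - 1) * gap_extend)
        ptr_y[0, j] = 0 if j == 1 else 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best, state = M[i - 1, j - 1], 0
            if X[i - 1, j - 1] > best:
                best, state = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best:
                best, state = Y[i - 1, j - 1], 2
            M[i, j] = best + pair[i - 1, j - 1]
            ptr_m[i, j] = state
            a, b = M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend
            X[i, j], ptr_x[i, j] = (a, 0) if a >= b else (b, 1)
            a, b = M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend
            Y[i, j], ptr_y[i, j] = (a, 0) if a >= b else (b, 1)
    score = M[n, m]
    state = 0
    if X[n, m] > score:
        score, state = X[n, m], 1
    if Y[n, m] > score:
        score, state = Y[n, m], 2
    # traceback
    path_a: list[int | None] = []
    path_b: list[int | None] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            prev = ptr_m[i, j]
            path_a.append(i - 1)
            path_b.append(j - 1)
            i, j, state = i - 1, j - 1, prev
        elif state == 1:
            prev = ptr_x[i, j]
            path_a.append(i - 1)
            path_b.append(None)
            i, state = i - 1, 0 if prev == 0 else 1
        else:
            prev = ptr_y[i, j]
            path_a.append(None)
            path_b.append(j - 1)
            j, state = j - 1, 0 if prev == 0 else 2
    path_a.reverse()
    path_b.reverse()
    return path_a, path_b, float(score)


def pairwise_align(
    a: str,
    b: str,
    matrix: np.ndarray | None = None,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences under affine gaps."""
    if matrix is None:
        matrix = blosum62()
    enc_a, enc_b = encode(a), encode(b)
    n, m = enc_a.size, enc_b.size
    if n == 0 and m == 0:
        return "", "", 0.0
    if n == 0 or m == 0:
        gap_len = max(n, m)
        cost = -(gap_open + (gap_len - 1) * gap_extend)
        if n == 0:
            return GAP * m, b, cost
        return a, GAP * n, cost
    padded = np.zeros((21, 21))
    padded[:20, :20] = matrix
    pair = padded[enc_a[:, None], enc_b[None, :]]
    path_a, path_b, score = _gotoh(pair, gap_open, gap_extend)
    out_a = "".join(a[i] if i is not None else GAP for i in path_a)
    out_b = "".join(b[j] if j is not None else GAP for j in path_b)
    return out_a, out_b, score


def _profile_frequencies(rows: list[str]) -> np.ndarray:
    """(n_cols, 20) residue frequencies; gaps count as missing mass."""
    n_cols = len(rows[0])
    freqs = np.zeros((n_cols, 20))
    for row in rows:
        for j, c in enumerate(row):
            idx = AA_INDEX.get(c.upper())
            if idx is not None:
                freqs[j, idx] += 1
    return freqs / len(rows)


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    def counts(s: str) -> dict[str, int]:
        d: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            d[kmer] = d.get(kmer, 0) + 1
        return d
    ca, cb = counts(a), counts(b)
    shared = sum(min(ca[x], cb[x]) for x in ca if x in cb)
    total = max(1, min(len(a), len(b)) - k + 1)
    return 1.0 - shared / total


def progressive_align(
    sequences: Sequence[tuple[str, str]],
    matrix: np.ndarray | None = None,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> MultipleAlignment:
    """Progressive multiple alignment along a k-mer/UPGMA guide tree.

    Profiles are merged leaf-to-root with the affine-gap DP; the output
    preserves the input row order.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("no sequences to align")
    ids = [sid for sid, _ in sequences]
    if len(sequences) == 1:
        return MultipleAlignment(ids=ids, rows=[sequences[0][1]])
    if matrix is None:
        matrix = blosum62()

    n = len(sequences)
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            condensed.append(_kmer_distance(sequences[i][1], sequences[j][1]))
    merges = linkage(np.array(condensed), method="average")

    # cluster id -> (member indices, aligned rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seq]) for i, (_, seq) in enumerate(sequences)
    }
    for step, (left, right, _, _) in enumerate(merges):
        a_members, a_rows = clusters.pop(int(left))
        b_members, b_rows = clusters.pop(int(right))
        fa = _profile_frequencies(a_rows)
        fb = _profile_frequencies(b_rows)
        pair = fa @ matrix @ fb.T
        path_a, path_b, _ = _gotoh(pair, gap_open, gap_extend)
        new_a = [
            "".join(row[i] if i is not None else GAP for i in path_a)
            for row in a_rows
        ]
        new_b = [
            "".join(row[j] if j is not None else GAP for j in path_b)
            for row in b_rows
        ]
        clusters[n + step] = (a_members + b_members, new_a + new_b)

    members, rows = clusters.popitem()[1]
    order = np.argsort(members)
    return MultipleAlignment(
        ids=[ids[members[i]] for i in order],
        rows=[rows[i] for i in order],
    )


def trim_gap_columns(
    msa: MultipleAlignment, max_gap_fraction: float = 0.25
) -> tuple[MultipleAlignment, list[int]]:
    """Drop alignment columns whose gap fraction strictly exceeds the cap.

    Returns the trimmed alignment and the retained (0-based) column
    indices. An alignment whose columns are all dropped comes back empty;
    the caller decides how loudly to warn.
    """
    kept = []
    for j in range(msa.n_cols):
        column = msa.column(j)
        gap_fraction = sum(1 for c in column if c in "-.") / msa.n_rows
        if gap_fraction <= max_gap_fraction:
            kept.append(j)
    rows = ["".join(row[j] for j in kept) for row in msa.rows]
    return MultipleAlignment(ids=list(msa.ids), rows=rows), kept


# ---------------------------------------------------------------------------
# WAG maximum-likelihood distances


def _gamma_rates(shape: float, n_categories: int = 4) -> np.ndarray:
    quantiles = (np.arange(n_categories) + 0.5) / n_categories
    rates = gamma_dist.ppf(quantiles, a=shape, scale=1.0 / shape)
    return rates / rates.mean()


def wag_distance(
    row_i: str,
    row_j: str,
    model: WAGModel | None = None,
    cap: float = DISTANCE_CAP,
    gamma_shape: float | None = None,
) -> float:
    """Pairwise ML distance (expected substitutions/site) under WAG.

    Maximises the pairwise likelihood over the branch length by bounded
    scalar optimisation; saturated pairs are capped. Columns where either
    row is gapped or non-standard are ignored; with no shared columns the
    distance is undefined (nan). ``gamma_shape`` switches on discrete
    4-category gamma rate heterogeneity.
    """
    if len(row_i) != len(row_j):
        raise ValueError("rows must be aligned (equal length)")
    if model is None:
        model = default_model()
    enc_i, enc_j = encode(row_i), encode(row_j)
    mask = (enc_i >= 0) & (enc_j >= 0)
    if not mask.any():
        return float("nan")
    counts = np.zeros((20, 20))
    np.add.at(counts, (enc_i[mask], enc_j[mask]), 1.0)
    if counts.sum() == np.trace(counts):
        return 0.0

    rates = None if gamma_shape is None else _gamma_rates(gamma_shape)

    def nll(t: float) -> float:
        if rates is None:
            p = model.transition_matrix(t)
        else:
            p = np.mean([model.transition_matrix(t * r) for r in rates], axis=0)
        return -(counts * np.log(p)).sum()

    result = minimize_scalar(nll, bounds=(1e-6, cap), method="bounded",
                             options={"xatol": 1e-6})
    t_hat = float(result.x)
    if t_hat > cap - 1e-3:
        return cap
    return t_hat


def distance_matrix(
    msa: MultipleAlignment,
    model: WAGModel | None = None,
    gamma_shape: float | None = None,
) -> np.ndarray:
    """Symmetric WAG-ML distance matrix over alignment rows."""
    n = msa.n_rows
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = wag_distance(
                msa.rows[i], msa.rows[j], model=model, gamma_shape=gamma_shape
            )
    return D


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(D: np.ndarray, ids: Sequence[str]) -> TreeNode:
    """Standard NJ agglomeration with deterministic tie-breaking.

    The matrix must be symmetric with a zero diagonal and finite entries.
    Joins pick the minimum-Q pair, ties broken by the lowest index pair;
    negative branch lengths are clamped to zero. The result is unrooted,
    represented as a root of degree three (or a cherry for two taxa).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n != D.shape[1] or len(ids) != n:
        raise ValueError("distance matrix / ids mismatch")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.isfinite(D).all():
        raise ValueError("undefined distances in matrix")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    active = list(range(n))
    work = D.copy()

    while len(active) > 3:
        m = len(active)
        sub = work[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = np.unravel_index(np.argmin(q), q.shape)
        ai, aj = sorted((int(best[0]), int(best[1])))
        i_idx, j_idx = active[ai], active[aj]
        d_ij = work[i_idx, j_idx]
        li = 0.5 * d_ij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = d_ij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[i_idx], nodes[j_idx]
        child_i.length, child_j.length = li, lj
        parent = TreeNode(children=[child_i, child_j])
        # distances to the new node
        new_row = np.zeros(work.shape[0] + 1)
        for ak in active:
            if ak in (i_idx, j_idx):
                continue
            new_row[ak] = 0.5 * (work[i_idx, ak] + work[j_idx, ak] - d_ij)
        work = np.pad(work, ((0, 1), (0, 1)))
        work[-1, :-1] = new_row[:-1]
        work[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i_idx, j_idx)]
        active.append(work.shape[0] - 1)

    # final three-way join (three-point formulas)
    a, b, c = active
    dab, dac, dbc = work[a, b], work[a, c], work[b, c]
    la = max(0.5 * (dab + dac - dbc), 0.0)
    lb = max(0.5 * (dab + dbc - dac), 0.0)
    lc = max(0.5 * (dac + dbc - dab), 0.0)
    nodes[a].length, nodes[b].length, nodes[c].length = la, lb, lc
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


# ---------------------------------------------------------------------------
# bipartitions, bootstrap, clades


def bipartitions(tree: TreeNode, nontrivial_only: bool = True
                 ) -> dict[frozenset, TreeNode]:
    """Map each edge's canonical leaf-side to its child node.

    The canonical side is the one *not* containing the lexicographically
    smallest leaf, so the same split compares equal regardless of rooting.
    """
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    out: dict[frozenset, TreeNode] = {}
    for node in tree.walk():
        if node is tree:
            continue
        side = frozenset(node.leaf_names())
        if ref in side:
            side = all_leaves - side
        if nontrivial_only and not (2 <= len(side) <= len(all_leaves) - 2):
            continue
        out[side] = node
    return out


def robinson_foulds(tree_a: TreeNode, tree_b: TreeNode) -> int:
    """Symmetric-difference (RF) distance over nontrivial bipartitions."""
    ba = set(bipartitions(tree_a))
    bb = set(bipartitions(tree_b))
    return len(ba ^ bb)


def bootstrap_support(
    msa: MultipleAlignment,
    n_replicates: int = 100,
    seed: int = 0,
    model: WAGModel | None = None,
    gamma_shape: float | None = None,
) -> tuple[TreeNode, dict[frozenset, float]]:
    """Column bootstrap: resample columns, rebuild distances + NJ, count.

    Support for each internal edge of the full-alignment tree is the
    percentage of replicate trees containing the same bipartition; values
    are attached to the tree's internal nodes. Deterministic per seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if model is None:
        model = default_model()
    D = distance_matrix(msa, model=model, gamma_shape=gamma_shape)
    tree = neighbor_joining(D, msa.ids)
    splits = bipartitions(tree)
    counts = {split: 0 for split in splits}
    rng = np.random.default_rng(seed)
    n_cols = msa.n_cols
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rows = ["".join(row[j] for j in cols) for row in msa.rows]
        rep = MultipleAlignment(ids=list(msa.ids), rows=rows)
        rep_tree = neighbor_joining(
            distance_matrix(rep, model=model, gamma_shape=gamma_shape),
            rep.ids,
        )
        rep_splits = set(bipartitions(rep_tree))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    support = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    for split, node in splits.items():
        node.support = support[split]
    return tree, support


def evaluate_type_clades(
    tree: TreeNode, type_labels: dict[str, str]
) -> dict[str, dict]:
    """Per-type monophyly on the unrooted tree, with bootstrap support.

    A type is monophyletic when its leaves form one side of some edge
    (single leaves are trivially monophyletic). The reported support is the
    bootstrap value attached to the corresponding internal edge, when one
    exists.
    """
    leaves = tree.leaf_names()
    missing = [l for l in leaves if l not in type_labels]
    if missing:
        raise ValueError(f"unlabeled leaves: {missing}")
    all_set = frozenset(leaves)
    sides: dict[frozenset, TreeNode] = {}
    for node in tree.walk():
        if node is tree:
            continue
        sides[frozenset(node.leaf_names())] = node
    report: dict[str, dict] = {}
    for t in sorted(set(type_labels.values())):
        group = frozenset(l for l in leaves if type_labels[l] == t)
        mono = (
            len(group) == 1
            or group == all_set
            or group in sides
            or (all_set - group) in sides
        )
        node = sides.get(group) or sides.get(all_set - group)
        support = node.support if (node is not None and not node.is_leaf) else None
        report[t] = {
            "n_leaves": len(group),
            "monophyletic": bool(mono),
            "support": support,
        }
    return report


def write_phylip(D: np.ndarray, ids: Sequence[str], path) -> None:
    """Square PHYLIP-style distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(ids)}\n")
        for i, name in enumerate(ids):
            row = " ".join(f"{v:.6f}" for v in D[i])
            fh.write(f"{name[:30]:<32s}{row}\n")
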