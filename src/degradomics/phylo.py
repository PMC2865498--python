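"""Bootstrap parsimony phylogenetics for ambiguous gene families.

Progressive multiple alignment (neighbor-joining guide tree, profile
merges under the shared BLOSUM62/11/1 scheme), column bootstrap, Fitch
small parsimony with gaps as missing data, exhaustive topology search up
to 8 taxa (stepwise addition plus NNI hill-climbing beyond), majority-rule
consensus retaining only bipartitions present in STRICTLY more than the
threshold number of replicates, and outgroup rooting.

Trees are unrooted until :func:`root_with_outgroup`; supports are
bootstrap replicate counts carried on internal edges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from ._scoring import AA20, GAP_CHAR, GAP_EXTEND, GAP_OPEN, MATRIX, encode
from .orthomap import pairwise_protein_score

_WILDCARD = np.uint32((1 << 20) - 1)
_AA_BIT = {aa: np.uint32(1 << i) for i, aa in enumerate(AA20)}
_NEG = -1e30


# ---------------------------------------------------------------------------
# alignment container


@dataclass
class Alignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_fasta(self, path) -> None:
        Path(path).write_text(
            "".join(f">{i}\n{r}\n" for i, r in zip(self.ids, self.rows))
        )

    def to_phylip(self, path) -> None:
        """Sequential PHYLIP (relaxed names, padded to >= 10 characters)."""
        width = max(10, max(len(i) for i in self.ids) + 1)
        lines = [f" {len(self.ids)} {self.ncol}"]
        for i, r in zip(self.ids, self.rows):
            lines.append(f"{i:<{width}}{r}")
        Path(path).write_text("\n".join(lines) + "\n")


def read_fasta_alignment(path) -> Alignment:
    ids, rows = [], []
    seq: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if ids:
                rows.append("".join(seq))
            ids.append(line[1:].split()[0])
            seq = []
        else:
            seq.append(line.strip())
    if ids:
        rows.append("".join(seq))
    return Alignment(ids, rows)


# ---------------------------------------------------------------------------
# progressive alignment


def _profile_freqs(rows: list[str]) -> np.ndarray:
    L = len(rows[0])
    F = np.zeros((L, MATRIX.shape[0]), dtype=np.float64)
    enc_rows = [encode(r.replace(GAP_CHAR, "\0")) for r in rows]
    for r, row in zip(rows, enc_rows):
        for j, c in enumerate(r):
            if c != GAP_CHAR:
                F[j, row[j]] += 1.0
    return F / len(rows)


def _merge_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str], float]:
    """Global affine profile-profile alignment; gaps score 0 in columns."""
    FA = _profile_freqs(rows_a)
    FB = _profile_freqs(rows_b)
    S = FA @ MATRIX.astype(np.float64) @ FB.T
    n, m = S.shape
    go = float(GAP_OPEN + GAP_EXTEND)
    ge = float(GAP_EXTEND)
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in B (consumes A rows)
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in A (consumes B rows)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(go + (i - 1) * ge)
    for j in range(1, m + 1):
        Iy[0, j] = -(go + (j - 1) * ge)
    idx = np.arange(m + 1, dtype=np.float64)
    for i in range(1, n + 1):
        prev = np.maximum(np.maximum(M[i - 1, :-1], Ix[i - 1, :-1]), Iy[i - 1, :-1])
        M[i, 1:] = prev + S[i - 1, :]
        Ix[i, :] = np.maximum(M[i - 1, :] - go, Ix[i - 1, :] - ge)
        run = np.maximum.accumulate(M[i, :] + ge * idx)
        Iy[i, 1:] = run[:-1] - go - ge * (idx[1:] - 1.0)
    # traceback (tolerant float comparisons; prefer M, then Ix, then Iy)
    i, j = n, m
    state = max(
        (("M", M[n, m]), ("Ix", Ix[n, m]), ("Iy", Iy[n, m])), key=lambda t: t[1]
    )[0]
    score = max(M[n, m], Ix[n, m], Iy[n, m])
    ops: list[str] = []
    eps = 1e-6
    while i > 0 or j > 0:
        if state == "M":
            ops.append("M")
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            if abs(M[i, j] - target) < eps:
                state = "M"
            elif abs(Ix[i, j] - target) < eps:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            ops.append("D")
            target = Ix[i, j]
            i -= 1
            state = "M" if abs(M[i, j] - go - target) < eps else "Ix"
            if i == 0 and j == 0:
                state = "M"
        else:
            ops.append("I")
            target = Iy[i, j]
            j -= 1
            state = "M" if abs(M[i, j] - go - target) < eps else "Iy"
            if i == 0 and j == 0:
                state = "M"
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "M":
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ia += 1
            ib += 1
        elif op == "D":
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k in range(len(rows_b)):
                out_b[k] += GAP_CHAR
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += GAP_CHAR
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
    return out_a, out_b, float(score)


def progressive_align(sequences: Mapping[str, str]) -> Alignment:
    """Progressive multiple alignment over a neighbor-joining guide tree.

    Pairwise guide distances are score-based: d(a, b) = (S(a,a) + S(b,b))/2
    - S(a,b), clipped at zero.  Taxa are processed in lexicographic order
    so the result is independent of input order.
    """
    ids = sorted(sequences)
    if len(ids) < 2:
        raise ValueError("progressive alignment needs >= 2 sequences")
    if len(ids) == 2:
        a, b, _ = _merge_profiles([sequences[ids[0]]], [sequences[ids[1]]])
        return Alignment(ids, [a[0], b[0]])
    self_scores = {i: pairwise_protein_score(sequences[i], sequences[i]) for i in ids}
    dm = np.zeros((len(ids), len(ids)))
    for x, y in itertools.combinations(range(len(ids)), 2):
        s = pairwise_protein_score(sequences[ids[x]], sequences[ids[y]])
        d = max(0.0, (self_scores[ids[x]] + self_scores[ids[y]]) / 2.0 - s)
        dm[x, y] = dm[y, x] = d
    guide = nj(DistanceMatrix(dm, ids))

    def min_tip(node) -> str:
        if node.is_tip():
            return node.name
        return min(min_tip(c) for c in node.children)

    def build(node) -> tuple[list[str], list[str]]:
        if node.is_tip():
            return [node.name], [sequences[node.name]]
        children = sorted(node.children, key=min_tip)
        acc_ids, acc_rows = build(children[0])
        for child in children[1:]:
            cid, crows = build(child)
            acc_rows, crows, _ = _merge_profiles(acc_rows, crows)
            acc_ids += cid
            acc_rows += crows
        return acc_ids, acc_rows

    out_ids, out_rows = build(guide)
    return Alignment(out_ids, out_rows)


def bootstrap_resample(
    alignment: Alignment, replicates: int, rng_seed: int
) -> list[Alignment]:
    """Column bootstrap: each replicate resamples columns with replacement."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if alignment.ncol == 0 or not alignment.rows:
        raise ValueError("empty alignment")
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(replicates):
        idx = rng.integers(0, alignment.ncol, alignment.ncol)
        out.append(
            Alignment(
                list(alignment.ids),
                ["".join(row[i] for i in idx) for row in alignment.rows],
            )
        )
    return out


# ---------------------------------------------------------------------------
# trees


class Clade:
    __slots__ = ("name", "children", "support")

    def __init__(self, name=None, children=(), support=None):
        self.name = name
        self.children = list(children)
        self.support = support

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    root: Clade
    rooted: bool = False

    def leaf_names(self) -> frozenset[str]:
        return frozenset(self.root.leaves())

    def bipartitions(self) -> dict[frozenset, float | None]:
        """Non-trivial bipartitions as canonical clades (side excluding the
        lexicographically smallest taxon), with their supports."""
        all_leaves = self.leaf_names()
        ref = min(all_leaves)
        out: dict[frozenset, float | None] = {}

        def walk(node: Clade) -> frozenset:
            if not node.children:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            side = below if ref not in below else all_leaves - below
            if 1 < len(side) < len(all_leaves) - 1:
                out[side] = node.support
            return below

        for child in self.root.children:
            walk(child)
        return out

    def to_newick(self) -> str:
        def fmt(node: Clade) -> str:
            if not node.children:
                return node.name
            inner = ",".join(fmt(c) for c in sorted(node.children, key=_clade_key))
            label = "" if node.support is None else str(int(round(node.support)))
            return f"({inner}){label}"

        return fmt(self.root) + ";"

    def ascii(self) -> str:
        lines: list[str] = []

        def walk(node: Clade, depth: int) -> None:
            label = node.name or (
                "" if node.support is None else f"[{int(round(node.support))}]"
            )
            lines.append("  " * depth + "+-- " + (label or "*"))
            for c in sorted(node.children, key=_clade_key):
                walk(c, depth + 1)

        walk(self.root, 0)
        return "\n".join(lines)


def _clade_key(node: Clade) -> str:
    return min(node.leaves())


def write_newick(tree: Tree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# adjacency form: leaves are taxon strings, internal nodes are ints


def _node_key(n):
    return (0, n) if isinstance(n, str) else (1, str(n))


def _adjacency(tree: Tree):
    """Clade tree -> (adjacency dict, edge-support dict)."""
    adj: dict = {}
    supports: dict = {}
    counter = itertools.count()

    def add_edge(u, v, support=None):
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
        if support is not None:
            supports[frozenset((u, v))] = support

    def walk(node: Clade):
        if not node.children:
            return node.name
        me = next(counter)
        adj.setdefault(me, [])
        for c in node.children:
            cid = walk(c)
            add_edge(me, cid, c.support)
        return me

    walk(tree.root)
    return adj, supports


def _tree_from_adjacency(adj, supports=None, root=None) -> Tree:
    supports = supports or {}
    if root is None:
        leaves = sorted(n for n in adj if isinstance(n, str))
        root = adj[leaves[0]][0] if len(adj) > 1 else leaves[0]

    def build(node, parent) -> Clade:
        if isinstance(node, str):
            return Clade(name=node)
        children = [
            build(n, node) for n in sorted(adj[node], key=_node_key) if n != parent
        ]
        c = Clade(children=children)
        return c

    def attach_supports(node, parent, clade: Clade):
        if parent is not None:
            clade.support = supports.get(frozenset((node, parent)))
        kids = [n for n in sorted(adj[node], key=_node_key) if n != parent]
        for n, sub in zip(kids, clade.children):
            attach_supports(n, node, sub)

    root_clade = build(root, None)
    attach_supports(root, None, root_clade)
    return Tree(root_clade, rooted=False)


def _edges(adj):
    seen = set()
    for u, nbrs in adj.items():
        for v in nbrs:
            e = frozenset((u, v))
            if e not in seen:
                seen.add(e)
                yield tuple(sorted(e, key=_node_key))


def _side_leaves(adj, u, v) -> frozenset:
    """Leaves on u's side of edge (u, v)."""
    out = []
    stack = [(u, v)]
    while stack:
        node, parent = stack.pop()
        if isinstance(node, str):
            out.append(node)
            continue
        for n in adj[node]:
            if n != parent:
                stack.append((n, node))
    return frozenset(out)


def _adj_bipartitions(adj) -> frozenset:
    leaves = frozenset(n for n in adj if isinstance(n, str))
    ref = min(leaves)
    out = set()
    for u, v in _edges(adj):
        if isinstance(u, str) or isinstance(v, str):
            continue
        side = _side_leaves(adj, u, v)
        side = side if ref not in side else leaves - side
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Fitch parsimony


def _leaf_masks(alignment: Alignment) -> dict[str, np.ndarray]:
    masks = {}
    for taxon, row in zip(alignment.ids, alignment.rows):
        m = np.empty(len(row), dtype=np.uint32)
        for j, c in enumerate(row):
            m[j] = _AA_BIT.get(c, _WILDCARD)
        masks[taxon] = m
    return masks


def _fitch_from_masks(adj, masks: dict[str, np.ndarray]) -> int:
    leaves = sorted(n for n in adj if isinstance(n, str))
    if len(leaves) <= 2:
        return 0
    start = leaves[0]
    root = adj[start][0]
    order = []
    stack = [(root, start)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        if not isinstance(node, str):
            for n in adj[node]:
                if n != parent:
                    stack.append((n, node))
    value: dict = {}
    total = 0
    for node, parent in reversed(order):
        if isinstance(node, str):
            value[node] = masks[node]
            continue
        kids = [n for n in adj[node] if n != parent]
        m = value[kids[0]]
        for k in kids[1:]:
            inter = m & value[k]
            empty = inter == 0
            total += int(empty.sum())
            m = np.where(empty, m | value[k], inter)
        value[node] = m
    inter = value[root] & masks[start]
    total += int((inter == 0).sum())
    return total


def parsimony_score(tree, alignment: Alignment) -> int:
    """Fitch minimal-mutation count summed over columns.

    Gaps (and 'X'/'*') are missing data: a wildcard state that never
    forces a change.  The score is invariant under rerooting.
    """
    adj = tree if isinstance(tree, dict) else _adjacency(tree)[0]
    tree_leaves = frozenset(n for n in adj if isinstance(n, str))
    if tree_leaves != frozenset(alignment.ids):
        raise ValueError("tree leaves do not match alignment taxa")
    return _fitch_from_masks(adj, _leaf_masks(alignment))


# ---------------------------------------------------------------------------
# topology search

EXHAUSTIVE_MAX_TAXA = 8


def _enumerate_topologies(taxa: Sequence[str]):
    """All unrooted binary topologies; (2n-5)!! of them."""
    taxa = sorted(taxa)
    base = {0: [taxa[0], taxa[1], taxa[2]]}
    for t in taxa[:3]:
        base[t] = [0]

    def expand(adj, next_taxa, next_internal):
        if not next_taxa:
            yield adj
            return
        taxon = next_taxa[0]
        for u, v in sorted(_edges(adj), key=lambda e: (_node_key(e[0]), _node_key(e[1]))):
            new = {k: list(vs) for k, vs in adj.items()}
            w = next_internal
            new[u][new[u].index(v)] = w
            new[v][new[v].index(u)] = w
            new[w] = [u, v, taxon]
            new[taxon] = [w]
            yield from expand(new, next_taxa[1:], next_internal + 1)

    yield from expand(base, taxa[3:], 1)


def _insert_leaf(adj, u, v, taxon, internal_id):
    new = {k: list(vs) for k, vs in adj.items()}
    new[u][new[u].index(v)] = internal_id
    new[v][new[v].index(u)] = internal_id
    new[internal_id] = [u, v, taxon]
    new[taxon] = [internal_id]
    return new


def _nni_neighbors(adj):
    """All nearest-neighbor-interchange rearrangements, deterministic order."""
    out = []
    for u, v in sorted(_edges(adj), key=lambda e: (_node_key(e[0]), _node_key(e[1]))):
        if isinstance(u, str) or isinstance(v, str):
            continue
        us = sorted((n for n in adj[u] if n != v), key=_node_key)
        vs = sorted((n for n in adj[v] if n != u), key=_node_key)
        b = us[1]
        for c in vs:
            new = {k: list(x) for k, x in adj.items()}
            new[u][new[u].index(b)] = c
            new[v][new[v].index(c)] = b
            new[b][new[b].index(u)] = v
            new[c][new[c].index(v)] = u
            out.append(new)
    return out


def parsimony_search(alignment: Alignment) -> list[Tree]:
    """Most-parsimonious unrooted topologies for an alignment.

    Up to 8 taxa the search is exhaustive and returns ALL minimum-score
    trees; beyond that, deterministic stepwise addition (taxa in
    lexicographic order) followed by NNI hill-climbing returns the local
    optimum plus any equal-score trees in its final neighborhood.
    """
    n = len(alignment.ids)
    if n < 3:
        raise ValueError("parsimony search needs >= 3 taxa")
    masks = _leaf_masks(alignment)
    taxa = sorted(alignment.ids)
    if n <= EXHAUSTIVE_MAX_TAXA:
        best_score = None
        best: list = []
        seen = set()
        for adj in _enumerate_topologies(taxa):
            s = _fitch_from_masks(adj, masks)
            if best_score is None or s < best_score:
                best_score, best, seen = s, [adj], {_adj_bipartitions(adj)}
            elif s == best_score:
                key = _adj_bipartitions(adj)
                if key not in seen:
                    seen.add(key)
                    best.append(adj)
        return [_tree_from_adjacency(a) for a in best]
    # stepwise addition
    adj = {0: [taxa[0], taxa[1], taxa[2]]}
    for t in taxa[:3]:
        adj[t] = [0]
    next_internal = 1
    for taxon in taxa[3:]:
        best_adj, best_s = None, None
        for u, v in sorted(_edges(adj), key=lambda e: (_node_key(e[0]), _node_key(e[1]))):
            cand = _insert_leaf(adj, u, v, taxon, next_internal)
            s = _fitch_from_masks(cand, masks)
            if best_s is None or s < best_s:
                best_adj, best_s = cand, s
        adj = best_adj
        next_internal += 1
    # NNI descent with plateau exploration: equal-score rearrangements are
    # followed too (parsimony landscapes are full of ties), within a
    # deterministic evaluation budget
    cur_score = _fitch_from_masks(adj, masks)
    best_trees = [adj]
    frontier = [adj]
    visited = {_adj_bipartitions(adj)}
    evals = 0
    while frontier and evals < 600:
        next_frontier = []
        for t in frontier:
            for cand in _nni_neighbors(t):
                key = _adj_bipartitions(cand)
                if key in visited:
                    continue
                visited.add(key)
                s = _fitch_from_masks(cand, masks)
                evals += 1
                if s < cur_score:
                    cur_score = s
                    best_trees = [cand]
                    next_frontier = [cand]
                    break
                if s == cur_score:
                    best_trees.append(cand)
                    next_frontier.append(cand)
            else:
                continue
            break
        frontier = next_frontier[:30]
    return [_tree_from_adjacency(a) for a in best_trees[:20]]


# ---------------------------------------------------------------------------
# consensus and rooting


def majority_consensus(trees, threshold: float) -> Tree:
    """Majority-rule consensus under a strict "more than" display rule.

    ``trees`` is one entry per bootstrap replicate: a Tree, or a list of
    equally parsimonious Trees (each then contributes its bipartitions at
    weight 1/k).  A bipartition is retained iff its total weight is
    STRICTLY greater than ``threshold``; everything else collapses into
    polytomies.  Supports are the (possibly fractional) weights.
    """
    reps = [[t] if isinstance(t, Tree) else list(t) for t in trees]
    if not reps:
        raise ValueError("no trees")
    leaves = reps[0][0].leaf_names()
    for rep in reps:
        for t in rep:
            if t.leaf_names() != leaves:
                raise ValueError("inconsistent leaf sets across replicates")
    weights: dict[frozenset, float] = {}
    for rep in reps:
        w = 1.0 / len(rep)
        for t in rep:
            for bp in t.bipartitions():
                weights[bp] = weights.get(bp, 0.0) + w
    retained = {bp: w for bp, w in weights.items() if w > threshold}
    clades = sorted(retained, key=lambda bp: (-len(bp), sorted(bp)))
    for a, b in itertools.combinations(clades, 2):
        if a & b and not (a <= b or b <= a):
            raise ValueError(
                "retained bipartitions are incompatible at this threshold"
            )
    root = Clade(children=[Clade(name=n) for n in sorted(leaves)])
    leafsets: dict[int, frozenset] = {}

    def clade_leafset(node: Clade) -> frozenset:
        key = id(node)
        if key not in leafsets:
            leafsets[key] = frozenset(node.leaves())
        return leafsets[key]

    for bp in clades:
        node = root
        while True:
            host = next(
                (
                    c
                    for c in node.children
                    if c.children and bp <= clade_leafset(c)
                ),
                None,
            )
            if host is None:
                break
            node = host
        grouped = [c for c in node.children if clade_leafset(c) <= bp]
        node.children = [c for c in node.children if c not in grouped]
        new = Clade(children=grouped, support=retained[bp])
        leafsets[id(new)] = bp
        node.children.append(new)
    return Tree(root, rooted=False)


def root_with_outgroup(tree: Tree, outgroup: Iterable[str]) -> Tree:
    """Root on the edge separating the outgroup clade from the ingroup.

    The outgroup must be a single taxon or form a clade in the unrooted
    tree; otherwise the violating bipartition is reported.
    """
    og = frozenset(outgroup)
    leaves = tree.leaf_names()
    if not og or not og <= leaves:
        raise ValueError("outgroup taxa missing from tree")
    if og == leaves:
        raise ValueError("outgroup cannot contain every taxon")
    adj, supports = _adjacency(tree)
    target = None
    for u, v in _edges(adj):
        side = _side_leaves(adj, u, v)
        if side == og or leaves - side == og:
            target = (u, v) if side == og else (v, u)
            break
    if target is None:
        # diagnose: report a bipartition that splits the outgroup
        for u, v in _edges(adj):
            side = _side_leaves(adj, u, v)
            for s in (side, leaves - side):
                if s & og and s - og and og - s:
                    raise ValueError(
                        f"outgroup is not monophyletic: bipartition "
                        f"{sorted(s)} splits it"
                    )
        raise ValueError("outgroup is not monophyletic")
    u, v = target  # u is on the outgroup side
    sup = supports.get(frozenset((u, v)))

    def build(node, parent) -> Clade:
        if isinstance(node, str):
            return Clade(name=node)
        kids = [n for n in sorted(adj[node], key=_node_key) if n != parent]
        c = Clade(children=[build(k, node) for k in kids])
        for k, sub in zip(kids, c.children):
            if sub.support is None:
                sub.support = supports.get(frozenset((node, k)))
        return c

    left = build(u, v)
    right = build(v, u)
    left.support = sup
    right.support = sup
    return Tree(Clade(children=[left, right]), rooted=True)
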