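"""Compact maximum-parsimony engine.

Fitch optimisation for unordered, equally weighted characters; consistency
and retention indices; exhaustive enumeration of unrooted binary topologies
(with branch-and-bound pruning) for small taxon sets; a random-addition +
branch-swapping heuristic search that retains all equally parsimonious
trees; nonparametric bootstrap over characters; and the incongruence length
difference (ILD, partition-homogeneity) permutation test.

Implementation notes
--------------------
State sets are packed one byte per character into Python big integers, so a
Fitch pass over a tree is a handful of word-parallel bit operations per
internal node (the classical "has-zero-byte" trick detects characters whose
child state sets are disjoint).  This keeps the thousands of heuristic
searches inside a bootstrap or ILD run fast without native code.  The fast
path requires unit character weights; arbitrary positive weights fall back
to a per-character evaluation.

Branch swapping uses SPR by default (NNI optional).  TBR would gain little
at the tens-of-taxa scale this engine targets and SPR keeps the search
directly testable against the exhaustive enumeration.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable, Iterator, Literal, Sequence

import dendropy

from reticulator.alignment import IUPAC_DNA, Alignment

Missing = None


@dataclass(frozen=True)
class Column:
    """One character: its alphabet and per-taxon state sets (None=missing)."""

    alphabet: tuple[str, ...]
    states: tuple[frozenset[str] | None, ...]


class CharacterMatrix:
    """Taxa x characters, unordered multistate with missing data.

    Characters may mix alphabets (DNA blocks and binary indel blocks are the
    common case); each column carries its own alphabet.  Missing data and
    full-ambiguity symbols are equivalent for parsimony purposes.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        columns: Sequence[Column],
        weights: Sequence[float] | None = None,
    ) -> None:
        self.taxa: tuple[str, ...] = tuple(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        self.columns: tuple[Column, ...] = tuple(columns)
        for col in self.columns:
            if len(col.states) != len(self.taxa):
                raise ValueError("column state vector does not match taxa")
            if len(col.alphabet) > 7:
                raise ValueError("alphabets above 7 states are not supported")
        if weights is None:
            self.weights: tuple[float, ...] = (1.0,) * len(self.columns)
        else:
            self.weights = tuple(float(w) for w in weights)
            if len(self.weights) != len(self.columns):
                raise ValueError("one weight per character required")
            if any(w <= 0 for w in self.weights):
                raise ValueError("weights must be positive")
        self._packed_cache: dict[tuple[str, ...], list[int]] = {}

    # -- construction -------------------------------------------------

    @classmethod
    def from_alignment(
        cls,
        aln: Alignment,
        gap_as: Literal["missing", "state"] = "missing",
    ) -> "CharacterMatrix":
        """DNA characters from an alignment; gaps score missing by default."""
        alphabet = ("A", "C", "G", "T")
        columns = []
        for j in range(aln.length):
            states: list[frozenset[str] | None] = []
            for row in aln.rows:
                sym = row[j]
                if sym == "-" and gap_as == "state":
                    states.append(frozenset("-"))
                elif sym in ("-", "?", "N"):
                    states.append(Missing)
                else:
                    states.append(IUPAC_DNA[sym])
            if gap_as == "state" and any(s == frozenset("-") for s in states):
                columns.append(Column(alphabet + ("-",), tuple(states)))
            else:
                columns.append(Column(alphabet, tuple(states)))
        return cls(aln.ids, columns)

    @classmethod
    def from_binary(cls, taxa: Sequence[str], rows: Sequence[str]) -> "CharacterMatrix":
        """Binary (0/1/?) characters, e.g. coded indels."""
        if len(taxa) != len(rows):
            raise ValueError("one row per taxon required")
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError("rows of unequal length")
        n_char = lengths.pop() if lengths else 0
        alphabet = ("0", "1")
        columns = []
        for j in range(n_char):
            states: list[frozenset[str] | None] = []
            for row in rows:
                sym = row[j]
                states.append(Missing if sym == "?" else frozenset(sym))
            columns.append(Column(alphabet, tuple(states)))
        return cls(taxa, columns)

    @classmethod
    def from_indel_characters(cls, characters, taxa: Sequence[str]) -> "CharacterMatrix":
        rows = []
        for t in taxa:
            rows.append(
                "".join(
                    "?" if c.states[t] is Missing else str(c.states[t]) for c in characters
                )
            )
        return cls(taxa, CharacterMatrix.from_binary(taxa, rows).columns)

    # -- basics --------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return len(self.columns)

    def subset_characters(self, indices: Sequence[int]) -> "CharacterMatrix":
        return CharacterMatrix(
            self.taxa,
            [self.columns[i] for i in indices],
            [self.weights[i] for i in indices],
        )

    def subset_taxa(self, taxa: Sequence[str]) -> "CharacterMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        columns = [
            Column(c.alphabet, tuple(c.states[i] for i in idx)) for c in self.columns
        ]
        return CharacterMatrix(taxa, columns, self.weights)

    def concat(self, other: "CharacterMatrix") -> "CharacterMatrix":
        """Concatenate character blocks over the same taxon set."""
        if set(self.taxa) != set(other.taxa):
            raise ValueError("taxon sets differ")
        other = other.subset_taxa(self.taxa)
        return CharacterMatrix(
            self.taxa, self.columns + other.columns, self.weights + other.weights
        )

    def has_unit_weights(self) -> bool:
        return all(w == 1.0 for w in self.weights)

    # -- parsimony bookkeeping ----------------------------------------

    def informative_mask(self) -> list[bool]:
        """Parsimony-informative characters (>=2 states each seen >=2x).

        Ambiguous (non-singleton) state sets are treated as missing for the
        purpose of this count, as for the Fitch step bounds.
        """
        mask = []
        for col in self.columns:
            counts: dict[str, int] = {}
            for s in col.states:
                if s is not Missing and len(s) == 1:
                    (sym,) = s
                    counts[sym] = counts.get(sym, 0) + 1
            mask.append(sum(1 for n in counts.values() if n >= 2) >= 2)
        return mask

    def informative_only(self) -> "CharacterMatrix":
        mask = self.informative_mask()
        return self.subset_characters([i for i, m in enumerate(mask) if m])

    def packed(self, taxa: Sequence[str] | None = None) -> tuple[list[int], int, int]:
        """Byte-pack state sets per taxon; returns (codes, LO, HI) masks."""
        order = self.taxa if taxa is None else tuple(taxa)
        cached = self._packed_cache.get(order)
        if cached is not None:
            codes = cached
        else:
            codes = []
            idx = [self.taxa.index(t) for t in order]
            for i in idx:
                packed = 0
                for j, col in enumerate(self.columns):
                    s = col.states[i]
                    if s is Missing:
                        mask = (1 << len(col.alphabet)) - 1
                    else:
                        mask = 0
                        for sym in s:
                            mask |= 1 << col.alphabet.index(sym)
                        if mask == 0:
                            raise ValueError("state outside declared alphabet")
                    packed |= mask << (8 * j)
                codes.append(packed)
            self._packed_cache[order] = codes
        n = self.n_char
        lo = int.from_bytes(b"\x01" * n, "little") if n else 0
        hi = int.from_bytes(b"\x80" * n, "little") if n else 0
        return codes, lo, hi


@dataclass(frozen=True)
class TreeScore:
    """Tree length with consistency and retention indices.

    ci = (sum of per-character minimum steps) / length;
    ri = (max steps - length) / (max steps - min steps).
    """

    length: float
    ci: float
    ri: float


# ---------------------------------------------------------------------
# unrooted binary trees
# ---------------------------------------------------------------------


class PhyloTree:
    """An unrooted binary tree over named leaves.

    Internally: leaves are integers ``0..n-1`` in ``taxa`` order, internal
    nodes are ``n..2n-3`` (degree 3), and the topology is an adjacency map.
    """

    def __init__(self, taxa: Sequence[str], adj: dict[int, list[int]]) -> None:
        self.taxa: tuple[str, ...] = tuple(taxa)
        self.adj: dict[int, list[int]] = {u: sorted(vs) for u, vs in adj.items()}
        n = len(self.taxa)
        for u, vs in self.adj.items():
            deg = len(vs)
            if u < n and deg != 1:
                raise ValueError(f"leaf {u} has degree {deg}")
            if u >= n and deg != 3:
                raise ValueError(f"internal node {u} has degree {deg}")

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, each as the side without the first taxon."""
        out = set()
        n = self.n_leaves
        for mask in _split_masks(self.adj, n):
            out.add(frozenset(self.taxa[i] for i in range(n) if mask >> i & 1))
        return frozenset(out)

    def topology_id(self) -> frozenset[int]:
        return frozenset(_split_masks(self.adj, self.n_leaves))

    def to_newick(self) -> str:
        n = self.n_leaves
        if n == 1:
            return f"{self.taxa[0]};"

        def sub(node: int, parent: int) -> str:
            if node < n:
                return self.taxa[node]
            parts = [sub(v, node) for v in self.adj[node] if v != parent]
            return "(" + ",".join(parts) + ")"

        root = self.adj[0][0]
        if n == 2:
            return f"({self.taxa[0]},{self.taxa[1]});"
        parts = [self.taxa[0]] + [sub(v, root) for v in self.adj[root] if v != 0]
        return "(" + ",".join(parts) + ");"

    @classmethod
    def from_newick(cls, text: str, taxa: Sequence[str] | None = None) -> "PhyloTree":
        """Parse a Newick string; a rooted bifurcation at the base is smoothed."""
        tree = dendropy.Tree.get(data=text, schema="newick")
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        order = tuple(taxa) if taxa is not None else tuple(sorted(labels))
        if set(order) != set(labels):
            raise ValueError("taxa do not match newick leaves")
        index = {t: i for i, t in enumerate(order)}
        n = len(order)
        adj: dict[int, list[int]] = {}
        next_internal = [n]
        node_ids: dict[int, int] = {}

        def get_id(nd) -> int:
            key = id(nd)
            if key not in node_ids:
                if nd.is_leaf():
                    node_ids[key] = index[nd.taxon.label]
                else:
                    node_ids[key] = next_internal[0]
                    next_internal[0] += 1
                adj[node_ids[key]] = []
            return node_ids[key]

        for edge in tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            u, v = get_id(edge.tail_node), get_id(edge.head_node)
            adj[u].append(v)
            adj[v].append(u)
        # smooth degree-2 nodes left by rooted input
        for node in [u for u in adj if u >= n and len(adj[u]) == 2]:
            x, y = adj[node]
            adj[x][adj[x].index(node)] = y
            adj[y][adj[y].index(node)] = x
            del adj[node]
        return cls(order, adj)

    @classmethod
    def from_splits_of(cls, taxa: Sequence[str], adj: dict[int, list[int]]) -> "PhyloTree":
        return cls(taxa, {u: list(vs) for u, vs in adj.items()})

    def relabel(self, mapping: dict[str, str]) -> "PhyloTree":
        return PhyloTree([mapping.get(t, t) for t in self.taxa], self.adj)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.to_newick()})"


# -- adjacency-level helpers (leaves are ints) ------------------------


def _copy_adj(adj: dict[int, list[int]]) -> dict[int, list[int]]:
    return {u: list(vs) for u, vs in adj.items()}


def _edges(adj: dict[int, list[int]]) -> list[tuple[int, int]]:
    out = []
    for u in sorted(adj):
        for v in adj[u]:
            if u < v:
                out.append((u, v))
    return out


def _insert_leaf(adj: dict[int, list[int]], edge: tuple[int, int], leaf: int, inode: int) -> None:
    u, v = edge
    adj[u][adj[u].index(v)] = inode
    adj[v][adj[v].index(u)] = inode
    adj[inode] = [u, v, leaf]
    adj[leaf] = [inode]


def _remove_leaf(adj: dict[int, list[int]], leaf: int, inode: int) -> None:
    u, v = (x for x in adj[inode] if x != leaf)
    adj[u][adj[u].index(inode)] = v
    adj[v][adj[v].index(inode)] = u
    del adj[inode]
    del adj[leaf]


def _split_masks(adj: dict[int, list[int]], n: int) -> list[int]:
    """Bitmask (over leaves) of each non-trivial split, side without leaf 0."""
    masks = []
    below: dict[tuple[int, int], int] = {}

    def mask_below(node: int, parent: int) -> int:
        key = (node, parent)
        if key in below:
            return below[key]
        if node < n:
            m = 1 << node
        else:
            m = 0
            for v in adj[node]:
                if v != parent:
                    m |= mask_below(v, node)
        below[key] = m
        return m

    full = (1 << n) - 1
    for u, v in _edges(adj):
        if u >= n and v >= n:
            m = mask_below(v, u)
            if m & 1:
                m = full & ~m
            masks.append(m)
    return masks


def _fitch_len_packed(
    adj: dict[int, list[int]],
    codes: Sequence[int],
    n: int,
    lo: int,
    hi: int,
    stop_above: float | None = None,
) -> int:
    """Unweighted Fitch length via byte-packed state sets.

    Roots the unrooted tree at leaf 0's incident edge; counts, per internal
    node, the characters whose child state sets have empty intersection.
    """
    if n < 2 or not lo:
        return 0
    r0 = 0 if 0 in adj else min(k for k in adj if k < n)
    root = adj[r0][0]
    length = 0
    sets: dict[int, int] = {}
    stack: list[tuple[int, int, bool]] = [(root, r0, False)]
    while stack:
        node, parent, done = stack.pop()
        if node < n:
            sets[node] = codes[node]
            continue
        if not done:
            stack.append((node, parent, True))
            for v in adj[node]:
                if v != parent:
                    stack.append((v, node, False))
            continue
        children = [v for v in adj[node] if v != parent]
        a = sets[children[0]]
        b = sets[children[1]]
        t = a & b
        z = ~(t | ((t | hi) - lo)) & hi
        if z:
            length += z.bit_count()
            if stop_above is not None and length > stop_above:
                return length
            zf = z | (z - (z >> 7))
            t = (t & ~zf) | ((a | b) & zf)
        sets[node] = t
    if root < n:  # two-leaf tree
        t = codes[r0] & codes[root]
        z = ~(t | ((t | hi) - lo)) & hi
        return length + z.bit_count()
    t = codes[r0] & sets[root]
    z = ~(t | ((t | hi) - lo)) & hi
    return length + z.bit_count()


def _fitch_len_weighted(
    adj: dict[int, list[int]],
    matrix: CharacterMatrix,
    order: Sequence[str],
) -> float:
    """Per-character Fitch with arbitrary positive weights (slow path)."""
    n = len(order)
    total = 0.0
    for j, col in enumerate(matrix.columns):
        full = frozenset(col.alphabet)
        idx = {t: i for i, t in enumerate(matrix.taxa)}
        leaf_sets = [col.states[idx[t]] or full for t in order]
        changes = 0
        r0 = 0 if 0 in adj else min(k for k in adj if k < n)
        root = adj[r0][0]
        sets: dict[int, frozenset[str]] = {}
        stack: list[tuple[int, int, bool]] = [(root, r0, False)]
        while stack:
            node, parent, done = stack.pop()
            if node < n:
                sets[node] = leaf_sets[node]
                continue
            if not done:
                stack.append((node, parent, True))
                for v in adj[node]:
                    if v != parent:
                        stack.append((v, node, False))
                continue
            a, b = (sets[v] for v in adj[node] if v != parent)
            t = a & b
            if not t:
                changes += 1
                t = a | b
            sets[node] = t
        top = sets[root] if root >= n else leaf_sets[root]
        if not (leaf_sets[r0] & top):
            changes += 1
        total += changes * matrix.weights[j]
    return total


# ---------------------------------------------------------------------
# public scoring
# ---------------------------------------------------------------------


def fitch_length(tree: PhyloTree, matrix: CharacterMatrix) -> float:
    """Minimum number of (weighted) state changes of ``matrix`` on ``tree``.

    Missing states act as full-alphabet ambiguity at the leaves.  Tree
    leaves must all have data rows; the matrix may contain extra taxa.
    """
    missing = set(tree.taxa) - set(matrix.taxa)
    if missing:
        raise KeyError(f"taxa without data rows: {sorted(missing)}")
    if matrix.has_unit_weights():
        codes, lo, hi = matrix.packed(tree.taxa)
        return float(_fitch_len_packed(tree.adj, codes, tree.n_leaves, lo, hi))
    return _fitch_len_weighted(tree.adj, matrix, tree.taxa)


def fitch_bounds(matrix: CharacterMatrix) -> list[tuple[int, int]]:
    """Per-character (min steps m, extra-steps bound g).

    m = (number of distinct singleton observed states) - 1;
    g = (taxa with a singleton state) - (largest single-state count).
    Ambiguous state sets count as missing.
    """
    bounds = []
    for col in matrix.columns:
        counts: dict[str, int] = {}
        for s in col.states:
            if s is not Missing and len(s) == 1:
                (sym,) = s
                counts[sym] = counts.get(sym, 0) + 1
        if not counts:
            bounds.append((0, 0))
            continue
        m = len(counts) - 1
        g = sum(counts.values()) - max(counts.values())
        bounds.append((m, g))
    return bounds


def tree_score(length: float, matrix: CharacterMatrix) -> TreeScore:
    bounds = fitch_bounds(matrix)
    m_sum = sum(m * w for (m, _), w in zip(bounds, matrix.weights))
    g_sum = sum(g * w for (_, g), w in zip(bounds, matrix.weights))
    max_steps = m_sum + g_sum
    ci = 1.0 if length == 0 else m_sum / length
    denom = max_steps - m_sum
    if denom > 0:
        ri = (max_steps - length) / denom
        ri = min(max(ri, 0.0), 1.0)
    else:
        ri = 1.0 if length <= m_sum else 0.0
    return TreeScore(length, ci, ri)


@dataclass
class MPResult:
    """Best trees found together with their (shared) score."""

    trees: list[PhyloTree]
    score: TreeScore

    @property
    def length(self) -> float:
        return self.score.length


# ---------------------------------------------------------------------
# search
# ---------------------------------------------------------------------


def _make_scorer(matrix: CharacterMatrix, taxa: Sequence[str]) -> Callable:
    n = len(taxa)
    if matrix.has_unit_weights():
        codes, lo, hi = matrix.packed(taxa)

        def score(adj, stop_above=None):
            return _fitch_len_packed(adj, codes, n, lo, hi, stop_above)

    else:

        def score(adj, stop_above=None):
            return _fitch_len_weighted(adj, matrix, taxa)

    return score


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! unrooted binary topologies on n labelled leaves."""
    count = 1
    for k in range(3, n + 1):
        count *= 2 * k - 5
    return count


def exhaustive_mp(matrix: CharacterMatrix, keep_max: int = 10000) -> MPResult:
    """All minimum-length unrooted binary trees by enumeration (4-9 taxa).

    Enumeration inserts taxa one at a time on every edge, pruning partial
    trees whose Fitch length already exceeds the best complete length
    (adding leaves can never decrease parsimony length).
    """
    n = matrix.n_taxa
    if not 4 <= n <= 9:
        raise ValueError(f"exhaustive search supports 4-9 taxa, got {n}")
    taxa = matrix.taxa
    score = _make_scorer(matrix, taxa)

    adj: dict[int, list[int]] = {n: [0, 1, 2], 0: [n], 1: [n], 2: [n]}
    best: list[float] = [float("inf")]
    best_trees: list[dict[int, list[int]]] = []

    def recurse(next_leaf: int, next_internal: int) -> None:
        s = score(adj, stop_above=best[0])
        if s > best[0]:
            return
        if next_leaf == n:
            if s < best[0]:
                best[0] = s
                best_trees.clear()
            if len(best_trees) < keep_max:
                best_trees.append(_copy_adj(adj))
            return
        for edge in _edges(adj):
            _insert_leaf(adj, edge, next_leaf, next_internal)
            recurse(next_leaf + 1, next_internal + 1)
            _remove_leaf(adj, next_leaf, next_internal)

    recurse(3, n + 1)
    trees = [PhyloTree(taxa, a) for a in best_trees]
    return MPResult(trees, tree_score(best[0], matrix))


def _stepwise_addition(
    order: Sequence[int],
    n: int,
    score: Callable,
    rng: random.Random,
) -> dict[int, list[int]]:
    a, b, c = order[0], order[1], order[2]
    adj: dict[int, list[int]] = {n: [a, b, c], a: [n], b: [n], c: [n]}
    next_internal = n + 1
    for leaf in order[3:]:
        best_s = None
        best_edges = []
        for edge in _edges(adj):
            _insert_leaf(adj, edge, leaf, next_internal)
            s = score(adj, stop_above=best_s)
            _remove_leaf(adj, leaf, next_internal)
            if best_s is None or s < best_s:
                best_s = s
                best_edges = [edge]
            elif s == best_s:
                best_edges.append(edge)
        edge = best_edges[rng.randrange(len(best_edges))]
        _insert_leaf(adj, edge, leaf, next_internal)
        next_internal += 1
    return adj


def _nni_neighbors(adj: dict[int, list[int]], n: int) -> Iterator[dict[int, list[int]]]:
    for u, v in _edges(adj):
        if u < n or v < n:
            continue
        u_nbrs = [x for x in adj[u] if x != v]
        v_nbrs = [x for x in adj[v] if x != u]
        for swap_v in v_nbrs:
            b = u_nbrs[1]
            new = _copy_adj(adj)
            new[u][new[u].index(b)] = swap_v
            new[v][new[v].index(swap_v)] = b
            new[b][new[b].index(u)] = v
            new[swap_v][new[swap_v].index(v)] = u
            yield new


def _spr_neighbors(adj: dict[int, list[int]], n: int) -> Iterator[dict[int, list[int]]]:
    for u in sorted(adj):
        if u < n:
            continue
        for v in list(adj[u]):
            # prune the subtree on the v side of edge (u, v)
            base = _copy_adj(adj)
            base[u].remove(v)
            base[v].remove(u)
            x, y = base[u]
            base[x][base[x].index(u)] = y
            base[y][base[y].index(u)] = x
            del base[u]
            # edges of the remaining component (avoid the pruned side)
            remaining = set()
            stack = [x]
            seen = {x}
            while stack:
                node = stack.pop()
                for w in base[node]:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
                    if node < w:
                        remaining.add((node, w))
            for a, b in sorted(remaining):
                if {a, b} == {x, y}:
                    continue  # reattachment there recreates the input tree
                new = _copy_adj(base)
                new[a][new[a].index(b)] = u
                new[b][new[b].index(a)] = u
                new[u] = [a, b, v]
                new[v].append(u)
                yield new


def heuristic_mp(
    matrix: CharacterMatrix,
    n_random_addition: int = 100,
    swapper: Literal["NNI", "SPR"] = "SPR",
    seed: int | None = None,
    keep_max: int = 1000,
) -> MPResult:
    """Random-addition starts + branch swapping, keeping all best trees.

    Each replicate builds a tree by stepwise addition in a random taxon
    order and hill-climbs (first improvement, deterministic neighbour
    order) to a local optimum.  All distinct topologies at the globally
    best length are then collected by flooding through equal-length
    neighbours (MULTREES semantics), up to ``keep_max`` trees.
    Deterministic for a given seed.
    """
    n = matrix.n_taxa
    if n < 4:
        raise ValueError("need at least 4 taxa")
    taxa = matrix.taxa
    score = _make_scorer(matrix, taxa)
    neighbor_fn = _spr_neighbors if swapper == "SPR" else _nni_neighbors
    rng = random.Random(seed)

    best_len = float("inf")
    optima: dict[frozenset[int], dict[int, list[int]]] = {}
    for _ in range(max(1, n_random_addition)):
        order = list(range(n))
        rng.shuffle(order)
        adj = _stepwise_addition(order, n, score, rng)
        cur = score(adj)
        improved = True
        while improved:
            improved = False
            for nb in neighbor_fn(adj, n):
                s = score(nb, stop_above=cur)
                if s < cur:
                    adj, cur = nb, s
                    improved = True
                    break
        if cur < best_len:
            best_len = cur
            optima.clear()
        if cur == best_len:
            optima[frozenset(_split_masks(adj, n))] = adj

    # MULTREES: flood through equal-length neighbours
    frontier = list(optima.values())
    while frontier and len(optima) < keep_max:
        adj = frontier.pop()
        for nb in neighbor_fn(adj, n):
            if score(nb, stop_above=best_len) == best_len:
                key = frozenset(_split_masks(nb, n))
                if key not in optima:
                    optima[key] = nb
                    frontier.append(nb)
                    if len(optima) >= keep_max:
                        break

    trees = [PhyloTree(taxa, a) for a in optima.values()]
    trees.sort(key=lambda t: t.to_newick())
    return MPResult(trees, tree_score(float(best_len), matrix))


# ---------------------------------------------------------------------
# bootstrap and ILD
# ---------------------------------------------------------------------


def bootstrap_support(
    matrix: CharacterMatrix,
    n_reps: int = 1000,
    seed: int | None = None,
    n_random_addition: int = 3,
    swapper: Literal["NNI", "SPR"] = "NNI",
    keep_max: int = 64,
) -> dict[frozenset[str], float]:
    """Nonparametric bootstrap over characters.

    Characters are resampled with replacement; each replicate is searched
    with reduced settings and a split counts as recovered when it appears
    in the strict consensus of that replicate's best trees.  Returns
    support fractions for every split seen in any replicate.
    """
    rng = random.Random(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        idx = [rng.randrange(matrix.n_char) for _ in range(matrix.n_char)]
        rep = matrix.subset_characters(idx)
        result = heuristic_mp(
            rep,
            n_random_addition=n_random_addition,
            swapper=swapper,
            seed=rng.randrange(2**31),
            keep_max=keep_max,
        )
        split_sets = [t.splits() for t in result.trees]
        strict = frozenset.intersection(*split_sets) if split_sets else frozenset()
        for split in strict:
            counts[split] = counts.get(split, 0) + 1
    return {split: c / n_reps for split, c in counts.items()}


def majority_rule_consensus(
    trees: Sequence[PhyloTree], cutoff: float = 0.5
) -> dict[frozenset[str], float]:
    """Split frequencies across trees; splits above ``cutoff`` retained."""
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for split in t.splits():
            counts[split] = counts.get(split, 0) + 1
    n = len(trees)
    return {s: c / n for s, c in counts.items() if c / n > cutoff}


@dataclass(frozen=True)
class ILDResult:
    d_obs: float
    p_value: float
    d_perm: tuple[float, ...]


def ild_test(
    part1: CharacterMatrix,
    part2: CharacterMatrix,
    n_reps: int = 1000,
    seed: int | None = None,
    informative_only: bool = True,
    n_random_addition: int = 2,
    swapper: Literal["NNI", "SPR"] = "NNI",
) -> ILDResult:
    """Incongruence length difference (partition homogeneity) test.

    D = L(combined) - L(part1) - L(part2), lengths from heuristic searches.
    Permutation replicates reassign the pooled characters at random into
    pseudo-partitions of the original sizes; the upper tail counts
    replicates with D_perm >= D_obs, with add-one correction:
    p = (1 + #{D_perm >= D_obs}) / (n_reps + 1).
    """
    if set(part1.taxa) != set(part2.taxa):
        raise ValueError("partitions must share the same taxon set")
    part2 = part2.subset_taxa(part1.taxa)
    if informative_only:
        part1 = part1.informative_only()
        part2 = part2.informative_only()

    # canonical partition order makes the p-value exactly invariant to
    # swapping the two partitions (D is symmetric already)
    def _fingerprint(m: CharacterMatrix) -> tuple:
        return (m.n_char, tuple(sorted(str(c.states) for c in m.columns)))

    if _fingerprint(part2) < _fingerprint(part1):
        part1, part2 = part2, part1
    combined = part1.concat(part2)
    rng = random.Random(seed)

    def best_len(m: CharacterMatrix) -> float:
        if m.n_char == 0 or m.n_taxa < 4:
            return 0.0
        return heuristic_mp(
            m,
            n_random_addition=n_random_addition,
            swapper=swapper,
            seed=rng.randrange(2**31),
            keep_max=1,
        ).length

    l_comb = best_len(combined)
    d_obs = l_comb - best_len(part1) - best_len(part2)

    n1 = part1.n_char
    n_total = combined.n_char
    d_perm = []
    count = 0
    for _ in range(n_reps):
        idx = list(range(n_total))
        rng.shuffle(idx)
        p1 = combined.subset_characters(sorted(idx[:n1]))
        p2 = combined.subset_characters(sorted(idx[n1:]))
        d = l_comb - best_len(p1) - best_len(p2)
        d_perm.append(d)
        if d >= d_obs:
            count += 1
    p = (1 + count) / (n_reps + 1)
    return ILDResult(d_obs, p, tuple(d_perm))
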