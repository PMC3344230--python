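"""Independent oracles and small simulators shared across the test suite.

Everything here is deliberately written *differently* from the library code
it checks: brute-force enumeration instead of Fitch, per-column scanning
instead of gap-run bookkeeping, exhaustive assignment search instead of
branch-and-bound.
"""

from __future__ import annotations

import random
from itertools import product

from reticulator.parsimony import CharacterMatrix, PhyloTree, _edges, _insert_leaf


def brute_force_fitch(tree: PhyloTree, matrix: CharacterMatrix) -> float:
    """Minimum changes by enumerating all internal-node state assignments.

    A leaf contributes 0 on its pendant edge iff its neighbour's assigned
    state lies in the leaf's (possibly ambiguous) state set, else 1 — exact
    because a leaf can always copy its neighbour's state when allowed.
    """
    n = tree.n_leaves
    internal = sorted(u for u in tree.adj if u >= n)
    internal_edges = [
        (u, v) for u in tree.adj for v in tree.adj[u] if u < v and u >= n and v >= n
    ]
    pendant = [(leaf, tree.adj[leaf][0]) for leaf in range(n)]
    total = 0.0
    taxon_index = {t: i for i, t in enumerate(matrix.taxa)}
    for j, col in enumerate(matrix.columns):
        alph = col.alphabet
        leaf_sets = [
            col.states[taxon_index[tree.taxa[i]]] or frozenset(alph) for i in range(n)
        ]
        best = None
        for assign in product(alph, repeat=len(internal)):
            amap = dict(zip(internal, assign))
            cost = sum(1 for u, v in internal_edges if amap[u] != amap[v])
            cost += sum(1 for leaf, nb in pendant if amap[nb] not in leaf_sets[leaf])
            if best is None or cost < best:
                best = cost
        total += best * matrix.weights[j]
    return total


def random_unrooted_tree(taxa: list[str], rng: random.Random) -> PhyloTree:
    n = len(taxa)
    adj = {n: [0, 1, 2], 0: [n], 1: [n], 2: [n]}
    next_internal = n + 1
    for leaf in range(3, n):
        edge = rng.choice(_edges(adj))
        _insert_leaf(adj, edge, leaf, next_internal)
        next_internal += 1
    return PhyloTree(taxa, adj)


def markov_binary_characters(
    tree: PhyloTree, n_char: int, rng: random.Random, flip: float
) -> CharacterMatrix:
    """Binary characters evolved along the tree (per-edge flip probability)."""
    n = tree.n_leaves
    rows = {t: [] for t in tree.taxa}
    for _ in range(n_char):
        state = {0: rng.randint(0, 1)}
        root = tree.adj[0][0]
        state[root] = state[0] if rng.random() > flip else 1 - state[0]
        stack = [(root, 0)]
        while stack:
            node, parent = stack.pop()
            for v in tree.adj[node]:
                if v == parent:
                    continue
                state[v] = state[node] if rng.random() > flip else 1 - state[node]
                stack.append((v, node))
        for i, t in enumerate(tree.taxa):
            rows[t].append(str(state[i]))
    return CharacterMatrix.from_binary(tree.taxa, ["".join(rows[t]) for t in tree.taxa])


def perfect_split_characters(
    tree: PhyloTree, n_char: int, rng: random.Random
) -> CharacterMatrix:
    """Characters that are indicator variables of random non-trivial splits."""
    splits = sorted(tree.splits(), key=sorted)
    cols = []
    for _ in range(n_char):
        s = splits[rng.randrange(len(splits))]
        cols.append({t: ("1" if t in s else "0") for t in tree.taxa})
    rows = ["".join(c[t] for c in cols) for t in tree.taxa]
    return CharacterMatrix.from_binary(tree.taxa, rows)


def random_gappy_alignment(rng: random.Random, max_taxa=8, max_cols=60):
    from reticulator.alignment import Alignment

    n = rng.randint(2, max_taxa)
    length = rng.randint(4, max_cols)
    rows = []
    for _ in range(n):
        row = [rng.choice("ACGT") for _ in range(length)]
        for _ in range(rng.randint(0, 3)):
            start = rng.randrange(length)
            end = min(length, start + rng.randint(1, 6))
            for j in range(start, end):
                row[j] = "-"
        if all(c == "-" for c in row):
            row[0] = "A"
        rows.append("".join(row))
    return Alignment(tuple(f"s{i}" for i in range(n)), tuple(rows))


def indel_states_by_column_scan(aln, treat_terminal_gaps_as="missing"):
    """Classify (sequence, extent) states by direct column scanning.

    Independent re-derivation of simple indel coding: an extent scores 1
    for a sequence iff its columns are all gaps with non-gap (or boundary)
    flanks and the containing maximal run qualifies for coding; 0 iff no
    gap column overlaps; missing otherwise.
    """
    length = aln.length
    extents = set()
    for _, row in aln.items():
        j = 0
        while j < length:
            if row[j] == "-":
                start = j
                while j < length and row[j] == "-":
                    j += 1
                terminal = start == 0 or j == length
                if not terminal or treat_terminal_gaps_as == "coded":
                    extents.add((start, j))
            else:
                j += 1
    result = {}
    for start, end in sorted(extents):
        for sid, row in aln.items():
            overlap = any(row[j] == "-" for j in range(start, end))
            if not overlap:
                state = 0
            else:
                exact = (
                    all(row[j] == "-" for j in range(start, end))
                    and (start == 0 or row[start - 1] != "-")
                    and (end == length or row[end] != "-")
                )
                if exact and treat_terminal_gaps_as == "missing":
                    # the containing maximal run IS [start, end); terminal?
                    if start == 0 or end == length:
                        exact = False
                state = 1 if exact else None
            result[(start, end), sid] = state
    return result


def brute_force_network_cost(cross_lists, support_options_fn):
    """Minimum presumed-node count over all full cross assignments."""
    import itertools

    taxa = sorted(cross_lists)
    best = None
    choices_per_taxon = []
    for tid in taxa:
        opts = []
        for cross in cross_lists[tid]:
            for _, mset in support_options_fn(cross.mother):
                for _, fset in support_options_fn(cross.father):
                    opts.append(mset | fset)
        choices_per_taxon.append(opts)
    for combo in itertools.product(*choices_per_taxon):
        used = frozenset().union(*combo) if combo else frozenset()
        if best is None or len(used) < best:
            best = len(used)
    return best


def match_haplotype_labels(inferred: dict, truth: dict) -> dict:
    """Greedy majority matching of inferred group labels to truth labels."""
    from collections import Counter

    pairs = Counter((inferred[i], truth[i]) for i in truth if i in inferred)
    mapping = {}
    for (inf, tru), _ in pairs.most_common():
        if inf not in mapping and tru not in mapping.values():
            mapping[inf] = tru
    return mapping
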