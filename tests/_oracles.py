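"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration or direct
closed forms — and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import random

from adgrl4evo.core_io import DatedTree, TreeNode

GAP = "-"


# ---------------------------------------------------------------------------
# Exhaustive affine-gap global alignment
# ---------------------------------------------------------------------------


def brute_force_affine_score(a: str, b: str, sub, open_: float, extend: float) -> float:
    """Best global alignment score by enumerating every monotone alignment
    path; affine gap cost open + (k-1)*extend for a run of k gaps.

    ``sub(x, y)`` gives the substitution score. Exponential: lengths <= 7.
    """
    best = [float("-inf")]

    def walk(i: int, j: int, score: float, last: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + sub(a[i], b[j]), "D")
        if i < len(a):
            cost = extend if last == "U" else open_
            walk(i + 1, j, score - cost, "U")
        if j < len(b):
            cost = extend if last == "L" else open_
            walk(i, j + 1, score - cost, "L")

    walk(0, 0, 0.0, "")
    return best[0]


def enumerate_msa_sp_scores(seqs, sub, open_, extend, max_cols):
    """Yield the sum-of-pairs score of every gap-patterned alignment of the
    given sequences with at most ``max_cols`` columns. Tiny inputs only."""
    n = len(seqs)

    def pair_sp(rows):
        total = 0.0
        for x in range(n):
            for y in range(x + 1, n):
                total += _pair_score(rows[x], rows[y], sub, open_, extend)
        return total

    for ncols in range(max(len(s) for s in seqs), max_cols + 1):
        for rows in _gap_patterns(seqs, ncols):
            yield rows, pair_sp(rows)


def _gap_patterns(seqs, ncols):
    choices = []
    for s in seqs:
        opts = []
        for positions in itertools.combinations(range(ncols), len(s)):
            row = [GAP] * ncols
            for p, c in zip(positions, s):
                row[p] = c
            opts.append("".join(row))
        choices.append(opts)
    for combo in itertools.product(*choices):
        yield list(combo)


def _pair_score(ra, rb, sub, open_, extend):
    score = 0.0
    last = ""
    for x, y in zip(ra, rb):
        if x == GAP and y == GAP:
            continue
        if x == GAP or y == GAP:
            state = "U" if y == GAP else "L"
            score -= extend if state == last else open_
            last = state
        else:
            score += sub(x, y)
            last = "D"
    return score


# ---------------------------------------------------------------------------
# Conservation score by direct class enumeration
# ---------------------------------------------------------------------------


def conservation_oracle(column, table) -> int:
    """Count homogeneous classes by naked enumeration over the table."""
    entries = [c.upper() for c in column]
    if GAP not in entries and len(set(entries)) == 1 and entries[0] != "X":
        return 11
    count = 0
    for cls in table.classes:
        members = table.members[cls]
        flags = {
            (c in members) if c not in (GAP, "X") else False for c in entries
        }
        if len(flags) == 1:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Random dated trees and additive matrices
# ---------------------------------------------------------------------------


def random_dated_tree(n_tips: int, rng: random.Random) -> DatedTree:
    """Random binary topology with strictly decreasing rootward ages."""
    nodes = [TreeNode(label=f"t{i}") for i in range(n_tips)]
    height = 1.0
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(age=height)
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
        height += rng.uniform(0.5, 2.0)
    return DatedTree(nodes[0])


def random_branch_tree(n_tips: int, rng: random.Random):
    """Random binary tree with arbitrary positive branch lengths; returns
    (children map as nested tuples, leaf-pair path distances, newick)."""

    class N:
        def __init__(self, label=None):
            self.label = label
            self.children = []
            self.length = 0.0

    leaves = [N(f"t{i}") for i in range(n_tips)]
    pool = list(leaves)
    while len(pool) > 1:
        i, j = sorted(rng.sample(range(len(pool)), 2))
        b = pool.pop(j)
        a = pool.pop(i)
        p = N()
        a.length = rng.uniform(0.1, 3.0)
        b.length = rng.uniform(0.1, 3.0)
        p.children = [a, b]
        pool.append(p)
    root = pool[0]

    # path distances via per-leaf ancestor accumulation
    paths = {}

    def collect(node, anc):
        here = [(n, d) for n, d in anc] + [(node, 0.0)]
        if not node.children:
            paths[node.label] = {id(n): d for n, d in here}
        for ch in node.children:
            collect(ch, [(n, d + ch.length) for n, d in here])

    collect(root, [])
    labels = sorted(paths)
    import numpy as np

    D = np.zeros((len(labels), len(labels)))
    for x in range(len(labels)):
        for y in range(x + 1, len(labels)):
            pa, pb = paths[labels[x]], paths[labels[y]]
            shared = [k for k in pa if k in pb]
            d = min(pa[k] + pb[k] for k in shared)
            D[x, y] = D[y, x] = d

    def newick(node):
        if not node.children:
            return f"{node.label}:{node.length:.10f}"
        inner = ",".join(newick(c) for c in node.children)
        return f"({inner}):{node.length:.10f}"

    return labels, D, newick(root)[: newick(root).rfind(":")] + ";"


# ---------------------------------------------------------------------------
# Directional parsimony by exhaustive labelling
# ---------------------------------------------------------------------------


def min_transition_labellings(tree: DatedTree, tip_labels: dict[str, str]):
    """All minimum-transition labellings over {V1, V2, V3} with tips fixed,
    root fixed to V1, under the single constraint that no edge reverts a
    derived state to V1.

    Returns (min_transitions, list of labellings keyed by id(node)).
    """
    internals = [nd for nd in tree.nodes() if not nd.is_leaf]
    free = [nd for nd in internals if nd.parent is not None]
    results = []
    best = [float("inf")]
    states = ["V1", "V2", "V3"]

    def ok(parent_state, child_state):
        # irreversibility: a derived lineage never reverts to V1
        return not (parent_state != "V1" and child_state == "V1")

    for combo in itertools.product(states, repeat=len(free)):
        lab = {id(tree.root): "V1"}
        for nd, st in zip(free, combo):
            lab[id(nd)] = st
        for lf in tree.leaves():
            lab[id(lf)] = tip_labels[lf.label]
        cost = 0
        valid = True
        for nd in tree.nodes():
            for ch in nd.children:
                if not ok(lab[id(nd)], lab[id(ch)]):
                    valid = False
                    break
                if lab[id(nd)] != lab[id(ch)]:
                    cost += 1
            if not valid:
                break
        if not valid:
            continue
        if cost < best[0]:
            best[0] = cost
            results.clear()
        if cost == best[0]:
            results.append(dict(lab))
    return best[0], results
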