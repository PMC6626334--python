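"""Neighbor-joining tree construction and the receptor-family comparative
analyses: nearest-relative ranking of domain sets and presence-order scans.

NJ is the canonical Saitou-Nei agglomeration. Ties in the Q matrix are broken
by the lowest (i, j) index pair in the current working order, so output is
deterministic; negative branch lengths (possible on non-additive input) are
clamped to zero and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from adgrl4evo.alignment import (
    DistanceMatrix,
    ScoringScheme,
    global_align,
    p_distance,
)
from adgrl4evo.core_io import PresenceMatrix, ProteinRecord

log = logging.getLogger(__name__)


@dataclass
class NJNode:
    """Node of an unrooted NJ tree; ``edge_length`` is the branch above."""

    label: str | None = None
    edge_length: float = 0.0
    children: list["NJNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["NJNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass(frozen=True)
class UnrootedTree:
    """An unrooted phylogram; the stored root is the final NJ join and is
    topologically arbitrary."""

    root: NJNode

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(lf.label for lf in self.root.leaves())

    def to_newick(self) -> str:
        def render(nd: NJNode) -> str:
            if nd.is_leaf:
                body = nd.label
            else:
                body = "(" + ",".join(render(c) for c in nd.children) + ")"
            return f"{body}:{nd.edge_length:.10g}"

        inner = ",".join(render(c) for c in self.root.children)
        return f"({inner});"

    def path_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length sums (the additive metric of the tree)."""
        leaves = sorted(self.root.leaves(), key=lambda lf: lf.label)
        labels = tuple(lf.label for lf in leaves)
        depth: dict[int, float] = {}
        parent: dict[int, NJNode | None] = {id(self.root): None}

        def walk(nd: NJNode, d: float) -> None:
            depth[id(nd)] = d
            for c in nd.children:
                parent[id(c)] = nd
                walk(c, d + c.edge_length)

        walk(self.root, 0.0)

        def ancestors(nd: NJNode) -> list[NJNode]:
            out = [nd]
            while parent[id(out[-1])] is not None:
                out.append(parent[id(out[-1])])
            return out

        n = len(leaves)
        d = np.zeros((n, n))
        anc = [ancestors(lf) for lf in leaves]
        for i in range(n):
            seen = {id(a): depth[id(a)] for a in anc[i]}
            for j in range(i + 1, n):
                for a in anc[j]:
                    if id(a) in seen:
                        lca_depth = depth[id(a)]
                        break
                d[i, j] = d[j, i] = (
                    depth[id(leaves[i])] + depth[id(leaves[j])] - 2 * lca_depth
                )
        return DistanceMatrix(labels, d)


def nj_tree(d: DistanceMatrix) -> UnrootedTree:
    """Saitou-Nei neighbor joining.

    Requires n >= 3. On an additive matrix the result is the unique tree
    realising the distances. The last three lineages are joined at an
    unresolved trifurcation, which serves as the (arbitrary) root.
    """
    n = len(d)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes = [NJNode(label=lab) for lab in d.labels]
    D = d.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) pair among the minima of Q
        qmin = Q.min()
        ii, jj = min(
            (a, b)
            for a in range(m)
            for b in range(a + 1, m)
            if Q[a, b] <= qmin + 1e-12
        )
        i, j = active[ii], active[jj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp(li, nodes[i]), _clamp(lj, nodes[j])
        new = NJNode()
        nodes[i].edge_length = li
        nodes[j].edge_length = lj
        new.children = [nodes[i], nodes[j]]
        # distances from the new node to the remainder
        dk = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, dk])
        D = np.hstack([D, np.append(dk, 0.0)[:, None]])
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    root = NJNode()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].edge_length = _clamp(length, nodes[idx])
        root.children.append(nodes[idx])
    return UnrootedTree(root)


def _clamp(length: float, node: NJNode) -> float:
    if length < 0:
        log.warning(
            "negative NJ branch length %.6g at %s clamped to 0",
            length,
            node.label or "(internal)",
        )
        return 0.0
    return float(length)


# ---------------------------------------------------------------------------
# Domain nearest-relative ranking
# ---------------------------------------------------------------------------


def nearest_relative(
    query_domains: list[ProteinRecord],
    panel: dict[str, list[ProteinRecord]],
    s: ScoringScheme | None = None,
) -> list[tuple[str, float]]:
    """Rank panel receptors by the minimum pairwise p-distance between any
    query domain and any of the receptor's domains (ascending).

    Records whose ids coincide with a query id are excluded, so a receptor
    never competes with the query's own entries. Raises on an empty panel.
    """
    if not panel:
        raise ValueError("empty receptor panel")
    if not query_domains:
        raise ValueError("no query domains")
    if s is None:
        s = ScoringScheme.blosum62()
    query_ids = {q.id for q in query_domains}
    ranking = []
    for receptor in sorted(panel):
        candidates = [r for r in panel[receptor] if r.id not in query_ids]
        if not candidates:
            continue
        best = min(
            p_distance(*global_align(q, r, s)[0])
            for q in query_domains
            for r in candidates
        )
        ranking.append((receptor, best))
    if not ranking:
        raise ValueError("panel contains only the query's own records")
    ranking.sort(key=lambda t: (t[1], t[0]))
    return ranking


# ---------------------------------------------------------------------------
# Presence-order analysis
# ---------------------------------------------------------------------------


def presence_first_taxon(
    m: PresenceMatrix, families: dict[str, list[str]] | None = None
) -> tuple[dict[str, int | None], dict[str, int | None]]:
    """Earliest taxon (lowest column index; taxa ordered oldest to youngest)
    in which each gene is present; ``None`` for genes absent everywhere.

    When gene families are given, each family gets the minimum over its
    members — the first appearance of any member.
    """
    first: dict[str, int | None] = {}
    for gene in m.genes:
        row = m.row(gene)
        first[gene] = next((k for k, v in enumerate(row) if v), None)
    fam_first: dict[str, int | None] = {}
    for fam, members in (families or {}).items():
        hits = [first[g] for g in members if first.get(g) is not None]
        fam_first[fam] = min(hits) if hits else None
    return first, fam_first
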