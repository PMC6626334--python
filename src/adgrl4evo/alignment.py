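"""Affine-gap global protein alignment, pairwise distances, progressive MSA.

The aligner is a standard three-state (Gotoh) dynamic programme maximising

    sum of substitution scores  -  sum over gaps of [open + (k-1) * extend]

for gaps of length ``k``, i.e. the first column of a gap costs ``open`` and
every further column ``extend``. Terminal gaps are penalised like internal
ones (true global alignment: the inputs are full-length orthologues).
Traceback tie-break, in order of preference: diagonal (match) > up (gap in
the second sequence) > left (gap in the first); alignments are therefore
bit-reproducible.

Defaults are Clustal-like: BLOSUM62 (shipped as a text data file), gap open
10, gap extend 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from adgrl4evo.core_io import GAP, AlignmentMatrix, ProteinRecord

_NEG = -1e30  # effectively -infinity for the DP


def _load_blosum62() -> tuple[str, np.ndarray]:
    text = (
        resources.files("adgrl4evo.data").joinpath("blosum62.txt").read_text()
    )
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    order = "".join(lines[0].split())
    mat = np.array(
        [[int(x) for x in line.split()[1:]] for line in lines[1:]], dtype=float
    )
    return order, mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus positive affine gap penalties."""

    alphabet: str
    matrix: np.ndarray = field(repr=False)
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("matrix shape does not match alphabet")
        if not np.array_equal(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def blosum62(cls, gap_open: float = 10.0, gap_extend: float = 1.0) -> "ScoringScheme":
        order, mat = _load_blosum62()
        return cls(order, mat, gap_open, gap_extend)

    def index(self, residue: str) -> int:
        i = self.alphabet.find(residue)
        if i < 0:
            raise KeyError(f"residue {residue!r} not in scoring alphabet")
        return i

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[self.index(a), self.index(b)])


# ---------------------------------------------------------------------------
# Core three-state DP, shared by sequence-sequence and profile-profile steps
# ---------------------------------------------------------------------------


def _gotoh(S: np.ndarray, open_: float, extend: float):
    """Maximal global affine alignment over a position-score matrix ``S``
    (``S[i, j]`` = score of pairing position ``i`` of A with ``j`` of B).

    Returns ``(score, path)``; path entries are ``('D', i, j)``, ``('U', i,
    None)`` (A position against a gap) or ``('L', None, j)``.
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in B (consuming A) — "up"
    Y = np.full((n + 1, m + 1), _NEG)  # gap in A (consuming B) — "left"
    M[0, 0] = 0.0
    if n:
        X[1:, 0] = -(open_ + extend * np.arange(n))
    if m:
        Y[0, 1:] = -(open_ + extend * np.arange(m))

    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + S[i - 1]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - open_, X[i - 1, 1:] - extend
        )
        X[i, 0] = np.maximum(
            np.maximum(M[i - 1, 0], Y[i - 1, 0]) - open_, X[i - 1, 0] - extend
        )
        # Y has a within-row recurrence; solved with a running maximum:
        # Y[i, j] = max_{k < j} (max(M,X)[i, k] - open - extend*(j-1-k))
        W = np.maximum(M[i, :-1], X[i, :-1]) - open_ + extend * np.arange(m)
        Y[i, 1:] = np.maximum.accumulate(W) - extend * np.arange(m)

    # Traceback, preference diagonal > up > left at every decision.
    i, j = n, m
    state = max(
        (("M", M[n, m]), ("X", X[n, m]), ("Y", Y[n, m])),
        key=lambda kv: (kv[1], {"M": 2, "X": 1, "Y": 0}[kv[0]]),
    )[0]
    score = {"M": M, "X": X, "Y": Y}[state][n, m]
    path = []
    while i > 0 or j > 0:
        if state == "M":
            path.append(("D", i - 1, j - 1))
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            for cand, mat in (("M", M), ("X", X), ("Y", Y)):
                if np.isclose(mat[i, j], target, rtol=0, atol=1e-6):
                    state = cand
                    break
        elif state == "X":
            path.append(("U", i - 1, None))
            val = X[i, j]
            i -= 1
            if np.isclose(M[i, j] - open_, val, rtol=0, atol=1e-6):
                state = "M"
            elif np.isclose(X[i, j] - extend, val, rtol=0, atol=1e-6):
                state = "X"
            else:
                state = "Y"
        else:
            path.append(("L", None, j - 1))
            val = Y[i, j]
            j -= 1
            if np.isclose(M[i, j] - open_, val, rtol=0, atol=1e-6):
                state = "M"
            elif np.isclose(X[i, j] - open_, val, rtol=0, atol=1e-6):
                state = "X"
            else:
                state = "Y"
    path.reverse()
    return float(score), path


def global_align(
    a: str | ProteinRecord, b: str | ProteinRecord, s: ScoringScheme | None = None
) -> tuple[tuple[str, str], float]:
    """Optimal affine-gap global alignment of two protein sequences.

    Returns ``((gapped_a, gapped_b), score)``. Raises on empty input.
    """
    if s is None:
        s = ScoringScheme.blosum62()
    sa = a.residues if isinstance(a, ProteinRecord) else a
    sb = b.residues if isinstance(b, ProteinRecord) else b
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    ia = np.array([s.index(c) for c in sa])
    ib = np.array([s.index(c) for c in sb])
    S = s.matrix[np.ix_(ia, ib)]
    score, path = _gotoh(S, s.gap_open, s.gap_extend)
    ga, gb = [], []
    for kind, i, j in path:
        ga.append(sa[i] if kind in ("D", "U") else GAP)
        gb.append(sb[j] if kind in ("D", "L") else GAP)
    return ("".join(ga), "".join(gb)), score


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def __len__(self) -> int:
        return len(self.labels)


def p_distance(row_a: str, row_b: str) -> float:
    """1 - identical pairs / aligned non-double-gap columns."""
    ident = cols = 0
    for x, y in zip(row_a, row_b):
        if x == GAP and y == GAP:
            continue
        cols += 1
        if x == y:
            ident += 1
    if cols == 0:
        raise ValueError("no aligned columns between sequences")
    return 1.0 - ident / cols


def distance_matrix(
    records: list[ProteinRecord],
    s: ScoringScheme | None = None,
    correction: str = "p-distance",
) -> DistanceMatrix:
    """Pairwise p-distances from affine global alignments.

    ``correction='p-distance'`` (the default) and ``'none'`` both report the
    raw mismatch proportion: the p-distance is itself an uncorrected
    distance, and no multiple-hit correction is applied in either mode.
    """
    if correction not in ("p-distance", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    if len(records) < 2:
        raise ValueError("need at least two records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    if s is None:
        s = ScoringScheme.blosum62()
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # canonical argument order: with several co-optimal alignments
            # the tie-break depends on orientation, so fix it by record id
            # to make the distance a function of the pair alone
            a, b = sorted((records[i], records[j]), key=lambda r: r.id)
            (ga, gb), _ = global_align(a, b, s)
            d[i, j] = d[j, i] = p_distance(ga, gb)
    return DistanceMatrix(tuple(ids), d)


# ---------------------------------------------------------------------------
# Progressive MSA
# ---------------------------------------------------------------------------


def _profile_counts(rows: list[str], s: ScoringScheme) -> np.ndarray:
    """Per-column residue counts (columns x alphabet); gaps contribute nothing."""
    k = len(s.alphabet)
    counts = np.zeros((len(rows[0]), k))
    for row in rows:
        for j, c in enumerate(row):
            if c != GAP:
                counts[j, s.index(c)] += 1
    return counts


def _align_profiles(
    rows_a: list[str], rows_b: list[str], s: ScoringScheme
) -> tuple[list[str], list[str]]:
    """Profile-profile affine alignment with sum-of-pairs substitution
    averaging over non-gap residue pairs; existing gaps are never removed."""
    ca = _profile_counts(rows_a, s)
    cb = _profile_counts(rows_b, s)
    na = ca.sum(axis=1)
    nb = cb.sum(axis=1)
    pairs = np.outer(na, nb)
    S = ca @ s.matrix @ cb.T
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(pairs > 0, S / np.maximum(pairs, 1), 0.0)
    _, path = _gotoh(S, s.gap_open, s.gap_extend)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    for kind, i, j in path:
        if kind == "D":
            for r, row in zip(out_a, rows_a):
                r.append(row[i])
            for r, row in zip(out_b, rows_b):
                r.append(row[j])
        elif kind == "U":
            for r, row in zip(out_a, rows_a):
                r.append(row[i])
            for r in out_b:
                r.append(GAP)
        else:
            for r in out_a:
                r.append(GAP)
            for r, row in zip(out_b, rows_b):
                r.append(row[j])
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_msa(
    records: list[ProteinRecord], s: ScoringScheme | None = None
) -> AlignmentMatrix:
    """Progressive multiple alignment over a neighbor-joining guide tree.

    Pairwise p-distances feed NJ; profiles are merged in post-order by
    profile-profile affine alignment ("once a gap, always a gap").
    """
    from adgrl4evo.phylo import nj_tree  # local import; phylo uses this module

    if s is None:
        s = ScoringScheme.blosum62()
    if len(records) < 2:
        raise ValueError("need at least two records")
    by_id = {r.id: r for r in records}
    if len(records) == 2:
        (ga, gb), _ = global_align(records[0], records[1], s)
        return AlignmentMatrix(
            (records[0].id, records[1].id),
            (ga, gb),
            (records[0].species, records[1].species),
        )

    guide = nj_tree(distance_matrix(records, s))

    def merge(node) -> tuple[list[str], list[str]]:
        if not node.children:
            return [node.label], [by_id[node.label].residues]
        ids, rows = merge(node.children[0])
        for child in node.children[1:]:
            ids_b, rows_b = merge(child)
            rows, rows_b = _align_profiles(rows, rows_b, s)
            ids = ids + ids_b
            rows = rows + rows_b
        return ids, rows

    ids, rows = merge(guide.root)
    order = {r.id: k for k, r in enumerate(records)}
    ranked = sorted(zip(ids, rows), key=lambda t: order[t[0]])
    ids = tuple(t[0] for t in ranked)
    rows = tuple(t[1] for t in ranked)
    species = tuple(by_id[i].species for i in ids)
    return AlignmentMatrix(ids, rows, species)
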