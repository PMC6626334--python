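"""Physico-chemical column conservation scoring and hotspot mapping.

Each alignment column is scored by how many of ten named physico-chemical
residue classes (hydrophobic, polar, small, tiny, aliphatic, aromatic,
proline, positive, negative, charged — the Taylor Venn classification) are
*homogeneous* across the column: every entry in the class, or every entry
out of it. A gap carries the empty property set, so a gapped column can
never be fully conserved. The score therefore runs 0-10, with 11 reserved
as a sentinel for gap-free single-residue columns (absolute identity).

This emulates the AMAS-style conservation annotation drawn under published
alignment figures; the property table is configurable and the shipped
default lives in ``data/taylor_properties.tsv``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from adgrl4evo.core_io import (
    AMINO_ACIDS,
    GAP,
    AlignmentMatrix,
    DomainTable,
    ValidationError,
)

IDENTITY_SCORE = 11  # sentinel: gap-free, single residue type


@dataclass(frozen=True)
class PropertyTable:
    """Residue -> set of physico-chemical class names; gap -> empty set."""

    classes: tuple[str, ...]
    members: dict[str, frozenset[str]]  # class -> residues

    def __post_init__(self) -> None:
        for cls in self.classes:
            if cls not in self.members:
                raise ValidationError(f"class {cls!r} has no member set")
        covered = set().union(*self.members.values())
        missing = set(AMINO_ACIDS) - covered
        # every standard residue must appear in at least the lookup domain;
        # residues carrying no property (e.g. under a reduced table) are
        # permitted but the default table covers all twenty.
        if missing and set(self.classes) == set(DEFAULT_CLASSES):
            raise ValidationError(f"residues without any property: {sorted(missing)}")

    def properties_of(self, residue: str) -> frozenset[str]:
        if residue == GAP:
            return frozenset()
        if residue == "X":  # unknown residue: no asserted properties
            return frozenset()
        if residue not in AMINO_ACIDS:
            raise ValidationError(f"unknown residue {residue!r}")
        return frozenset(c for c in self.classes if residue in self.members[c])

    @classmethod
    def default(cls) -> "PropertyTable":
        text = (
            resources.files("adgrl4evo.data")
            .joinpath("taylor_properties.tsv")
            .read_text()
        )
        rows = [
            line.split("\t")
            for line in text.splitlines()
            if line.strip() and not line.startswith("#") and not line.startswith("class")
        ]
        members = {name: frozenset(res) for name, res in rows}
        return cls(tuple(members), members)


DEFAULT_CLASSES = (
    "hydrophobic",
    "polar",
    "small",
    "tiny",
    "aliphatic",
    "aromatic",
    "proline",
    "positive",
    "negative",
    "charged",
)


def score_column(column: Sequence[str], table: PropertyTable | None = None) -> int:
    """Number of property classes homogeneous across the column (0-10), or
    11 for a gap-free column of a single residue type."""
    if not column:
        raise ValueError("empty alignment column")
    if table is None:
        table = PropertyTable.default()
    entries = [str(c).upper() for c in column]
    bad = set(entries) - set(AMINO_ACIDS) - {GAP, "X"}
    if bad:
        raise ValidationError(f"unknown residue(s) {sorted(bad)} in column")
    if GAP not in entries and len(set(entries)) == 1 and entries[0] != "X":
        return IDENTITY_SCORE
    sets = [table.properties_of(c) for c in entries]
    score = 0
    for cls in table.classes:
        inside = [cls in s for s in sets]
        if all(inside) or not any(inside):
            score += 1
    return score


@dataclass(frozen=True)
class ConservationTrack:
    """Per-position integer conservation scores.

    Either alignment-indexed (``positions`` = 1..columns) or, after
    projection, indexed by the ungapped residue numbers of a reference row.
    """

    scores: tuple[int, ...]
    positions: tuple[int, ...]
    reference_id: str | None = None
    reference_residues: str | None = None

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.positions):
            raise ValidationError("scores and positions differ in length")
        if any(not (0 <= s <= IDENTITY_SCORE) for s in self.scores):
            raise ValidationError("scores must lie in [0, 11]")

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        cols = {"position": self.positions, "score": self.scores}
        if self.reference_residues is not None:
            cols["ref_residue"] = tuple(self.reference_residues)
        return pd.DataFrame(cols)


def conservation_track(
    aln: AlignmentMatrix,
    table: PropertyTable | None = None,
    reference: str | None = None,
) -> ConservationTrack:
    """Column-wise conservation scores; with ``reference`` given, columns
    gapped in that row are dropped and positions renumbered by reference
    residue (1-based)."""
    if table is None:
        table = PropertyTable.default()
    scores = [score_column(aln.column(j), table) for j in range(aln.n_columns)]
    if reference is None:
        return ConservationTrack(
            tuple(scores), tuple(range(1, aln.n_columns + 1))
        )
    ref_row = aln.row(reference)  # raises KeyError when absent
    proj_scores = []
    residues = []
    for c, sc in zip(ref_row, scores):
        if c != GAP:
            proj_scores.append(sc)
            residues.append(c)
    return ConservationTrack(
        tuple(proj_scores),
        tuple(range(1, len(proj_scores) + 1)),
        reference_id=reference,
        reference_residues="".join(residues),
    )


def region_rankings(
    track: ConservationTrack,
    domains: DomainTable | Iterable[tuple[str, int, int]],
    window: int,
    k: int = 3,
) -> tuple[list[tuple[str, float]], list[tuple[int, int, float]]]:
    """Rank annotated domains by mean projected score and report the top-k
    sliding windows.

    Domain ties break toward the more N-terminal start; window ties toward
    the leftmost window. ``window`` must not exceed the track length.
    Returns ``(domain_ranking, windows)`` with windows as (start, end, mean)
    in 1-based inclusive track coordinates.
    """
    n = len(track)
    if window < 1 or window > n:
        raise ValueError(f"window {window} outside 1..{n}")
    if isinstance(domains, DomainTable):
        dom_iter = [
            (str(r["domain_type"]), int(r["start"]), int(r["end"]))
            for _, r in domains.df.iterrows()
        ]
    else:
        dom_iter = list(domains)
    scores = np.asarray(track.scores, dtype=float)
    ranking = []
    for name, s, e in dom_iter:
        if not (1 <= s <= e <= n):
            raise ValueError(f"domain {name!r} interval ({s},{e}) outside track")
        ranking.append((name, float(scores[s - 1 : e].mean()), s))
    ranking.sort(key=lambda t: (-t[1], t[2]))
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    means = (csum[window:] - csum[:-window]) / window
    order = sorted(range(len(means)), key=lambda i: (-means[i], i))
    windows = [(i + 1, i + window, float(means[i])) for i in order[:k]]
    return [(name, mean) for name, mean, _ in ranking], windows


def hotspot_intervals(
    track: ConservationTrack, quantile: float = 0.9
) -> list[tuple[int, int]]:
    """Runs of positions in the top (1 - quantile) tail of the projected
    score distribution — the "highly conserved region" report."""
    scores = np.asarray(track.scores, dtype=float)
    thr = float(np.quantile(scores, quantile))
    runs = []
    start = None
    for pos, sc in zip(track.positions, track.scores):
        if sc >= thr:
            if start is None:
                start = pos
            end = pos
        elif start is not None:
            runs.append((start, end))
            start = None
    if start is not None:
        runs.append((start, end))
    return runs
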