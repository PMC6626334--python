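"""Readers and writers for the formats the pipeline touches, with strict validation.

Conventions used throughout the package:

* protein coordinates are 1-based inclusive (the convention of the domain
  databases the annotation tables come from);
* the alignment gap character is ``'-'``; ``'.'`` is rejected;
* node ages are in million years (mya), tips at age 0, ages non-decreasing
  toward the root;
* every validation failure raises, nothing is silently repaired.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file could not be parsed as the requested format."""


class ValidationError(ValueError):
    """A parsed object violates a structural invariant."""


#: The 20 standard amino acids plus X (unknown residue).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")

GAP = "-"

#: Controlled vocabulary for domain annotations. Anything else must carry an
#: explicit ``OTHER:`` prefix so that typos cannot leak into classification.
DOMAIN_TYPES = frozenset(
    {"SIGNAL", "EGF", "EGF_CA1", "EGF_CA2", "GAIN", "GPS", "TM7", "ICD"}
)

#: The EGF-class domain types whose presence/absence defines the receptor
#: variants (plain EGF domain, Ca2+-binding EGF domains 1 and 2).
EGF_CLASS = ("EGF", "EGF_CA1", "EGF_CA2")


# ---------------------------------------------------------------------------
# Protein records and alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence: 20 standard residues plus X, never empty."""

    id: str
    species: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record requires a non-empty id")
        if not self.residues:
            raise ValidationError(f"{self.id}: empty residue string")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.id}: illegal residue character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentMatrix:
    """A multiple alignment: equal-length gapped rows over ``'-'`` gaps.

    Ungapping any row must yield a valid :class:`ProteinRecord` sequence.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValidationError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate row ids in alignment")
        if not self.rows:
            raise ValidationError("empty alignment")
        n = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != n:
                raise ValidationError(f"row {rid}: length {len(row)} != {n}")
            if "." in row:
                raise ValidationError(f"row {rid}: '.' gaps are not accepted")
            bad = set(row) - PROTEIN_ALPHABET - {GAP}
            if bad:
                raise ValidationError(f"row {rid}: illegal characters {sorted(bad)}")
            if not row.replace(GAP, ""):
                raise ValidationError(f"row {rid}: all-gap row")
        if not self.species:
            object.__setattr__(self, "species", tuple("" for _ in self.ids))

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> tuple[str, ...]:
        return tuple(row[j] for row in self.rows)

    def ungapped(self) -> list[ProteinRecord]:
        return [
            ProteinRecord(rid, sp, row.replace(GAP, ""))
            for rid, sp, row in zip(self.ids, self.species, self.rows)
        ]

    def row(self, rid: str) -> str:
        try:
            return self.rows[self.ids.index(rid)]
        except ValueError:
            raise KeyError(f"no alignment row with id {rid!r}") from None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein FASTA. Header: ``>id [species...]``.

    Raises :class:`FormatError` naming the offending line for malformed
    headers or characters outside the residue alphabet.
    """
    with open(path) as fh:
        text = fh.read()
    _scan_fasta_text(text, str(path))
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        species = rec.description.partition(" ")[2].strip()
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, species, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def _scan_fasta_text(text: str, name: str) -> None:
    in_record = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if len(line) == 1:
                raise FormatError(f"{name}, line {lineno}: empty FASTA header")
            in_record = True
            continue
        if not in_record:
            raise FormatError(f"{name}, line {lineno}: sequence before any header")
        bad = set(line.upper()) - PROTEIN_ALPHABET
        if bad:
            raise FormatError(
                f"{name}, line {lineno}: illegal residue character(s) {sorted(bad)}"
            )


def write_fasta(records: Iterable[ProteinRecord], path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapping residues at ``wrap`` columns."""
    if wrap < 1:
        raise ValueError("wrap width must be >= 1")
    recs = list(records)
    ids = [r.id for r in recs]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate record ids")
    with open(path, "w") as fh:
        for r in recs:
            header = f">{r.id} {r.species}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(r.residues), wrap):
                fh.write(r.residues[i : i + wrap] + "\n")


def read_alignment_fasta(path) -> AlignmentMatrix:
    """Read a gapped FASTA alignment into an :class:`AlignmentMatrix`."""
    with open(path) as fh:
        entries = list(SeqIO.parse(fh, "fasta"))
    if not entries:
        raise FormatError(f"{path}: no FASTA records found")
    ids = tuple(e.id for e in entries)
    species = tuple(e.description.partition(" ")[2].strip() for e in entries)
    rows = tuple(str(e.seq).upper() for e in entries)
    return AlignmentMatrix(ids, rows, species)


def write_alignment_fasta(aln: AlignmentMatrix, path, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        SeqIO.write(
            (
                SeqRecord(Seq(row), id=rid, description=sp)
                for rid, sp, row in zip(aln.ids, aln.species, aln.rows)
            ),
            fh,
            "fasta",
        )


# ---------------------------------------------------------------------------
# Dated trees
# ---------------------------------------------------------------------------


class TreeNode:
    """A node of a :class:`DatedTree`: label, age (mya), optional 95% CI."""

    __slots__ = ("label", "age", "ci", "children", "parent")

    def __init__(self, label: str | None = None, age: float = 0.0,
                 ci: tuple[float, float] | None = None):
        self.label = label
        self.age = age
        self.ci = ci
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterator["TreeNode"]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list["TreeNode"]:
        return [nd for nd in self.preorder() if nd.is_leaf]

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(nd.label for nd in self.leaves())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.label!r} age={self.age} {kind}>"


class DatedTree:
    """A rooted, time-calibrated tree: tips at age 0, ages increase rootward.

    Nodes may carry 95% confidence intervals on their ages (mya). The tree is
    validated on construction and after every read.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.validate()

    # -- structure ----------------------------------------------------------

    def nodes(self) -> list[TreeNode]:
        return list(self.root.preorder())

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_labels(self) -> frozenset[str]:
        return self.root.leaf_labels()

    def internal_nodes(self) -> list[TreeNode]:
        return [nd for nd in self.nodes() if not nd.is_leaf]

    def find_leaf(self, label: str) -> TreeNode:
        for nd in self.leaves():
            if nd.label == label:
                return nd
        raise KeyError(f"no tip labelled {label!r}")

    def mrca(self, labels: Iterable[str]) -> TreeNode:
        """Most recent common ancestor of the given tip labels."""
        want = set(labels)
        if not want:
            raise ValueError("mrca of an empty label set")
        missing = want - set(self.leaf_labels())
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        node = self.find_leaf(next(iter(want)))
        while not want <= {lf.label for lf in node.leaves()}:
            node = node.parent
        return node

    def validate(self) -> None:
        labels = [nd.label for nd in self.leaves()]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate tip labels")
        for nd in self.nodes():
            if nd.is_leaf:
                if nd.label is None:
                    raise ValidationError("unlabelled tip")
                if abs(nd.age) > 1e-9:
                    raise ValidationError(f"tip {nd.label!r} has age {nd.age} != 0")
                nd.age = 0.0
            for ch in nd.children:
                if nd.age < ch.age - 1e-9:
                    raise ValidationError(
                        f"age monotonicity violated: node age {nd.age} < "
                        f"child {ch.label or '(internal)'} age {ch.age}"
                    )
            if nd.ci is not None:
                lo, hi = nd.ci
                if not (lo <= nd.age + 1e-9 and nd.age <= hi + 1e-9):
                    raise ValidationError(
                        f"CI ({lo}, {hi}) does not bracket age {nd.age}"
                    )

    # -- serialisation ------------------------------------------------------

    def to_newick(self, dialect: str = "branch_lengths") -> str:
        if dialect not in ("branch_lengths", "annotations"):
            raise ValueError(f"unknown Newick dialect {dialect!r}")

        def fmt(x: float) -> str:
            return f"{x:.6f}".rstrip("0").rstrip(".")

        def render(nd: TreeNode) -> str:
            if nd.is_leaf:
                body = _quote_label(nd.label)
            else:
                body = "(" + ",".join(render(c) for c in nd.children) + ")"
                if nd.label:
                    body += _quote_label(nd.label)
            if dialect == "annotations":
                ann = f"[&age={fmt(nd.age)}"
                if nd.ci is not None:
                    ann += f",ci={{{fmt(nd.ci[0])},{fmt(nd.ci[1])}}}"
                body += ann + "]"
            if nd.parent is not None:
                body += ":" + fmt(nd.parent.age - nd.age)
            return body

        return render(self.root) + ";"


_LABEL_UNSAFE = re.compile(r"[\s()\[\]:;,']")


def _quote_label(label: str) -> str:
    if _LABEL_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_newick_dated(path, dialect: str = "branch_lengths") -> DatedTree:
    """Read one rooted dated tree from a Newick file.

    ``dialect='branch_lengths'``: branch lengths are in mya and the tree must
    be ultrametric (all root-to-tip path sums equal); ages follow from depths.

    ``dialect='annotations'``: each node carries a ``[&age=A]`` comment,
    optionally with ``ci={lo,hi}``, placed between the node and its branch
    length; branch lengths are ignored apart from a consistency check.
    """
    if dialect not in ("branch_lengths", "annotations"):
        raise ValueError(f"unknown Newick dialect {dialect!r}")
    with open(path) as fh:
        # leading '#' lines are header comments, as in the package's TSVs
        text = "\n".join(
            line for line in fh.read().splitlines() if not line.startswith("#")
        )
    return _tree_from_newick_text(text, dialect, name=str(path))


def _tree_from_newick_text(text: str, dialect: str, name: str = "<newick>") -> DatedTree:
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"{name}: Newick parse error: {exc}") from exc

    def label_of(nd) -> str | None:
        if nd.taxon is not None:
            return nd.taxon.label
        return nd.label

    def convert(nd) -> TreeNode:
        out = TreeNode(label=label_of(nd))
        for ch in nd.child_nodes():
            out.add_child(convert(ch))
        return out

    root = convert(dtree.seed_node)

    if dialect == "annotations":
        for nd, src in zip(root.preorder(), dtree.seed_node.preorder_iter()):
            ann = {a.name: a.value for a in src.annotations}
            if "age" in ann:
                nd.age = float(ann["age"])
            elif nd.is_leaf:
                nd.age = 0.0
            else:
                raise FormatError(
                    f"{name}: internal node missing [&age=...] annotation"
                )
            if "ci" in ann:
                lo, hi = (float(v) for v in ann["ci"])
                nd.ci = (lo, hi)
    else:
        depths: dict[int, float] = {id(root): 0.0}
        for nd, src in zip(root.preorder(), dtree.seed_node.preorder_iter()):
            if nd.parent is not None:
                if src.edge.length is None:
                    raise FormatError(f"{name}: branch without a length")
                depths[id(nd)] = depths[id(nd.parent)] + src.edge.length
        tip_depths = [depths[id(lf)] for lf in root.leaves()]
        height = max(tip_depths)
        if height > 0 and max(tip_depths) - min(tip_depths) > 1e-6 * max(height, 1.0):
            raise ValidationError(
                f"{name}: tree is not ultrametric (tip depths range "
                f"{min(tip_depths):g}..{max(tip_depths):g})"
            )
        for nd in root.preorder():
            nd.age = height - depths[id(nd)]
            if nd.is_leaf:
                nd.age = 0.0

    return DatedTree(root)


def write_newick_dated(tree: DatedTree, path, dialect: str = "branch_lengths") -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(dialect=dialect) + "\n")


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------


DOMAIN_COLUMNS = ["species", "protein_id", "domain_type", "start", "end", "source_db"]
SIMILARITY_COLUMNS = ["species", "group", "gene", "pct_similarity"]


@dataclass(frozen=True)
class DomainTable:
    """Per-protein domain annotations: 1-based inclusive protein coordinates."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in DOMAIN_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"domain table missing column(s) {missing}")
        bad_rows = []
        for idx, row in self.df.iterrows():
            tok = str(row["domain_type"])
            if tok not in DOMAIN_TYPES and not tok.startswith("OTHER:"):
                bad_rows.append((idx, f"unknown domain_type {tok!r}"))
            if not (1 <= int(row["start"]) <= int(row["end"])):
                bad_rows.append((idx, f"bad interval {row['start']}..{row['end']}"))
        for pid, sub in self.df.groupby("protein_id"):
            ivals = sorted(
                (int(r["start"]), int(r["end"])) for _, r in sub.iterrows()
            )
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    bad_rows.append(
                        (pid, f"overlapping domains ({s1},{e1}) and ({s2},{e2})")
                    )
        if bad_rows:
            detail = "; ".join(f"{k}: {msg}" for k, msg in bad_rows)
            raise ValidationError(f"invalid domain table rows: {detail}")

    def for_protein(self, protein_id: str) -> pd.DataFrame:
        sub = self.df[self.df["protein_id"] == protein_id]
        return sub.sort_values("start").reset_index(drop=True)

    def proteins(self) -> list[str]:
        return list(dict.fromkeys(self.df["protein_id"]))

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class PresenceMatrix:
    """Gene x taxon presence grid; taxa ordered oldest to youngest."""

    genes: tuple[str, ...]
    taxa: tuple[str, ...]
    values: tuple[tuple[bool, ...], ...]

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon columns")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene rows")
        for g, row in zip(self.genes, self.values):
            if len(row) != len(self.taxa):
                raise ValidationError(f"row {g!r} is not rectangular")

    def row(self, gene: str) -> tuple[bool, ...]:
        try:
            return self.values[self.genes.index(gene)]
        except ValueError:
            raise KeyError(f"no gene {gene!r} in presence matrix") from None

    def present_taxa(self, gene: str) -> list[str]:
        return [t for t, v in zip(self.taxa, self.row(gene)) if v]


def read_tables(path, schema: str):
    """Read a TSV with one of the fixed schemas ``domain`` | ``presence`` |
    ``similarity`` into the corresponding validated object."""
    if schema == "domain":
        df = _read_tsv(path, DOMAIN_COLUMNS)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        return DomainTable(df)
    if schema == "presence":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        if df.columns[0] != "gene":
            raise ValidationError(
                f"{path}: presence table must start with a 'gene' column"
            )
        taxa = tuple(df.columns[1:])
        genes = tuple(df["gene"])
        ok = {"0", "1"}
        vals = []
        for _, r in df.iterrows():
            cells = [str(r[t]) for t in taxa]
            bad = [c for c in cells if c not in ok]
            if bad:
                raise ValidationError(
                    f"{path}: presence values must be 0/1, got {bad[:3]}"
                )
            vals.append(tuple(c == "1" for c in cells))
        return PresenceMatrix(genes, taxa, tuple(vals))
    if schema == "similarity":
        df = _read_tsv(path, SIMILARITY_COLUMNS)
        df["pct_similarity"] = df["pct_similarity"].astype(float)
        bad = df[(df["pct_similarity"] < 0) | (df["pct_similarity"] > 100)]
        if len(bad):
            raise ValidationError(
                f"{path}: pct_similarity outside [0, 100] in rows "
                f"{list(bad.index)}"
            )
        if (df["group"].astype(str).str.len() == 0).any():
            raise ValidationError(f"{path}: empty group labels")
        return df
    raise ValueError(f"unknown table schema {schema!r}")


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return df
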