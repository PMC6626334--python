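"""Round-trip and validation behaviour of the format layer."""

import random

import pytest

from adgrl4evo.core_io import (
    AlignmentMatrix,
    DatedTree,
    FormatError,
    ProteinRecord,
    TreeNode,
    ValidationError,
    read_fasta,
    read_newick_dated,
    read_tables,
    write_fasta,
    write_newick_dated,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def test_fasta_round_trip(tmp_path):
    recs = [
        ProteinRecord("p1", "human", "MKVLAW"),
        ProteinRecord("p2", "mouse lemur", "CCDDEE"),
    ]
    path = tmp_path / "a.fasta"
    write_fasta(recs, path)
    back = read_fasta(path)
    assert [(r.id, r.species, r.residues) for r in back] == [
        (r.id, r.species, r.residues) for r in recs
    ]


def test_fasta_wrapped_lines_concatenate(tmp_path):
    seq = "MKVLAWCDTYHH" * 5
    path = tmp_path / "w.fasta"
    write_fasta([ProteinRecord("p", "sp", seq)], path, wrap=25)
    assert sum(1 for l in path.read_text().splitlines() if not l.startswith(">")) == 3
    assert read_fasta(path)[0].residues == seq


def test_fasta_illegal_residue_names_line(tmp_path):
    path = tmp_path / "bad.fasta"
    path.write_text(">p1 sp\nMKVL\nAJML\n")
    with pytest.raises(FormatError, match="line 3"):
        read_fasta(path)


def test_fasta_random_round_trip(tmp_path):
    rng = random.Random(7)
    recs = [
        ProteinRecord(
            f"r{i}",
            f"sp{i}",
            "".join(rng.choice(AA) for _ in range(rng.randint(1, 200))),
        )
        for i in range(20)
    ]
    path = tmp_path / "r.fasta"
    write_fasta(recs, path, wrap=rng.randint(10, 80))
    back = read_fasta(path)
    assert [(r.id, r.residues) for r in back] == [(r.id, r.residues) for r in recs]


@pytest.mark.parametrize("residues", ["", "MKJL", "MK*L"])
def test_protein_record_rejects_bad_residues(residues):
    with pytest.raises(ValidationError):
        ProteinRecord("p", "sp", residues)


def test_alignment_matrix_invariants():
    aln = AlignmentMatrix(("a", "b"), ("MK-L", "MKVL"))
    assert aln.n_columns == 4
    assert [r.residues for r in aln.ungapped()] == ["MKL", "MKVL"]
    with pytest.raises(ValidationError):
        AlignmentMatrix(("a", "b"), ("MK-L", "MKV"))
    with pytest.raises(ValidationError):
        AlignmentMatrix(("a", "b"), ("MK.L", "MKVL"))  # '.' gaps rejected


# --- dated Newick ----------------------------------------------------------


def test_branch_length_dialect_ages(tmp_path):
    path = tmp_path / "t.nwk"
    path.write_text("((A:1,B:1):2,C:3);\n")
    tree = read_newick_dated(path, dialect="branch_lengths")
    assert tree.root.age == pytest.approx(3.0)
    (ab,) = [n for n in tree.internal_nodes() if n is not tree.root]
    assert ab.age == pytest.approx(1.0)
    assert all(lf.age == 0.0 for lf in tree.leaves())


def test_newick_round_trip_both_dialects(tmp_path):
    rng = random.Random(11)
    for trial in range(10):
        tree = _random_dated(rng, n=rng.randint(2, 12))
        for dialect in ("branch_lengths", "annotations"):
            path = tmp_path / f"{trial}_{dialect}.nwk"
            write_newick_dated(tree, path, dialect=dialect)
            back = read_newick_dated(path, dialect=dialect)
            assert back.leaf_labels() == tree.leaf_labels()
            orig = {frozenset(n.leaf_labels()): n.age for n in tree.internal_nodes()}
            got = {frozenset(n.leaf_labels()): n.age for n in back.internal_nodes()}
            assert set(got) == set(orig)
            for k in orig:
                assert got[k] == pytest.approx(orig[k], abs=1e-5)


def test_annotation_dialect_preserves_ci(tmp_path):
    path = tmp_path / "ci.nwk"
    path.write_text("((A[&age=0]:10,B[&age=0]:10)[&age=10,ci={8,12}]:5,C[&age=0]:15)[&age=15];\n")
    tree = read_newick_dated(path, dialect="annotations")
    node = tree.mrca(["A", "B"])
    assert node.age == 10.0 and node.ci == (8.0, 12.0)
    write_newick_dated(tree, path, dialect="annotations")
    assert read_newick_dated(path, dialect="annotations").mrca(["A", "B"]).ci == (8.0, 12.0)


def test_child_older_than_parent_rejected(tmp_path):
    path = tmp_path / "bad.nwk"
    path.write_text("((A[&age=0]:1,B[&age=0]:1)[&age=20]:1,C[&age=0]:1)[&age=5];\n")
    with pytest.raises(ValidationError):
        read_newick_dated(path, dialect="annotations")


def test_non_ultrametric_branch_lengths_rejected(tmp_path):
    path = tmp_path / "nu.nwk"
    path.write_text("((A:1,B:2):2,C:3);\n")
    with pytest.raises(ValidationError):
        read_newick_dated(path, dialect="branch_lengths")


def test_unbalanced_parentheses_rejected(tmp_path):
    path = tmp_path / "ub.nwk"
    path.write_text("((A:1,B:1):2,C:3;\n")
    with pytest.raises(FormatError):
        read_newick_dated(path)


def _random_dated(rng, n):
    nodes = [TreeNode(label=f"t{i}") for i in range(n)]
    height = 0.0
    while len(nodes) > 1:
        height += rng.uniform(0.5, 3.0)
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        b, a = nodes.pop(j), nodes.pop(i)
        p = TreeNode(age=height)
        p.add_child(a)
        p.add_child(b)
        nodes.append(p)
    return DatedTree(nodes[0])


# --- tables ----------------------------------------------------------------

DOMAIN_HEADER = "species\tprotein_id\tdomain_type\tstart\tend\tsource_db\n"


def test_domain_table_reads_rows(tmp_path):
    path = tmp_path / "d.tsv"
    path.write_text(
        DOMAIN_HEADER
        + "human\th1\tEGF\t25\t62\tPfam\n"
        + "human\th1\tEGF_CA1\t66\t105\tSMART\n"
        + "human\th1\tGAIN\t110\t339\tCDD\n"
    )
    table = read_tables(path, "domain")
    assert len(table) == 3
    assert table.proteins() == ["h1"]


def test_domain_table_overlap_rejected(tmp_path):
    path = tmp_path / "d.tsv"
    path.write_text(
        DOMAIN_HEADER
        + "human\th1\tEGF\t10\t50\tPfam\n"
        + "human\th1\tEGF_CA1\t40\t60\tPfam\n"
    )
    with pytest.raises(ValidationError, match="overlap"):
        read_tables(path, "domain")


def test_domain_table_unknown_type_needs_other_prefix(tmp_path):
    good = tmp_path / "g.tsv"
    good.write_text(DOMAIN_HEADER + "human\th1\tOTHER:HRM\t10\t50\tPfam\n")
    assert len(read_tables(good, "domain")) == 1
    bad = tmp_path / "b.tsv"
    bad.write_text(DOMAIN_HEADER + "human\th1\tHRM\t10\t50\tPfam\n")
    with pytest.raises(ValidationError, match="HRM"):
        read_tables(bad, "domain")


def test_presence_matrix_early_vertebrate_pattern(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text(
        "gene\tlamprey\tbony_fish\tmammal\n"
        "ADGRL4\t0\t1\t1\n"
        "VEGFR2\t0\t1\t1\n"
        "VEGFR1\t1\t1\t1\n"
    )
    m = read_tables(path, "presence")
    assert m.row("ADGRL4") == (False, True, True)
    assert m.row("VEGFR1") == (True, True, True)
    assert m.taxa.index("lamprey") == 0


def test_similarity_table_range_checked(tmp_path):
    path = tmp_path / "s.tsv"
    path.write_text(
        "species\tgroup\tgene\tpct_similarity\nzebrafish\tbony_fish\tADGRL4\t140\n"
    )
    with pytest.raises(ValidationError):
        read_tables(path, "similarity")
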