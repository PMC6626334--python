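"""Affine global alignment against exhaustive and third-party oracles."""

import random

import numpy as np
import pytest
from Bio import Align as BioAlign

from _oracles import brute_force_affine_score, enumerate_msa_sp_scores
from adgrl4evo.alignment import (
    distance_matrix,
    global_align,
    p_distance,
    progressive_msa,
)
from adgrl4evo.core_io import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def test_self_alignment_is_gap_free_diagonal_sum(blosum):
    seq = "MKVLAWCDTYHH"
    (ga, gb), score = global_align(seq, seq, blosum)
    assert ga == gb == seq
    assert score == sum(blosum.score(c, c) for c in seq)


def test_known_small_alignment(blosum):
    (ga, gb), score = global_align("AW", "AAW", blosum)
    assert (ga, gb) == ("-AW", "AAW")
    assert score == blosum.score("A", "A") + blosum.score("W", "W") - blosum.gap_open


def test_empty_sequence_rejected(blosum):
    with pytest.raises(ValueError):
        global_align("", "ACD", blosum)


def test_score_matches_brute_force_enumeration(cheap_scheme):
    """Exhaustive-path oracle over all pairs of random sequences, len <= 6."""
    rng = random.Random(1234)
    for _ in range(200):
        a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 6)))
        b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 6)))
        (ga, gb), score = global_align(a, b, cheap_scheme)
        expected = brute_force_affine_score(
            a, b, cheap_scheme.score, cheap_scheme.gap_open, cheap_scheme.gap_extend
        )
        assert score == pytest.approx(expected), (a, b)
        # the reported alignment must realise the reported score
        assert _score_alignment(ga, gb, cheap_scheme) == pytest.approx(score)


def test_score_matches_biopython_aligner(blosum):
    """Independent cross-check against Biopython's pairwise aligner."""
    aligner = BioAlign.PairwiseAligner()
    aligner.substitution_matrix = BioAlign.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -blosum.gap_open
    aligner.extend_gap_score = -blosum.gap_extend
    aligner.mode = "global"
    rng = random.Random(99)
    for _ in range(25):
        a = "".join(rng.choice(AA) for _ in range(rng.randint(5, 40)))
        b = "".join(rng.choice(AA) for _ in range(rng.randint(5, 40)))
        _, score = global_align(a, b, blosum)
        assert score == pytest.approx(aligner.score(a, b))


def _score_alignment(ga, gb, scheme):
    score = 0.0
    last = ""
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            state = "U" if y == "-" else "L"
            score -= scheme.gap_extend if state == last else scheme.gap_open
            last = state
        else:
            score += scheme.score(x, y)
            last = "D"
    return score


# --- distances -------------------------------------------------------------


def test_identical_sequences_have_zero_distance(blosum):
    recs = [ProteinRecord("a", "", "MKVLAW"), ProteinRecord("b", "", "MKVLAW")]
    dm = distance_matrix(recs, blosum)
    assert dm.get("a", "b") == 0.0


def test_p_distance_counts_mismatch_columns():
    assert p_distance("MKVL", "MKCL") == pytest.approx(0.25)
    assert p_distance("MK-L", "MKCL") == pytest.approx(0.25)  # gap column counts
    assert p_distance("--", "AA") == pytest.approx(1.0)


def test_distance_matrix_invariant_under_reordering(blosum):
    rng = random.Random(5)
    recs = [
        ProteinRecord(f"r{i}", "", "".join(rng.choice(AA) for _ in range(30)))
        for i in range(5)
    ]
    dm = distance_matrix(recs, blosum)
    shuffled = recs[::-1]
    dm2 = distance_matrix(shuffled, blosum)
    for a in dm.labels:
        for b in dm.labels:
            assert dm.get(a, b) == pytest.approx(dm2.get(a, b))
    assert np.allclose(np.diag(dm.values), 0)


# --- progressive MSA -------------------------------------------------------


def _records(seqs):
    return [ProteinRecord(f"s{i}", "", s) for i, s in enumerate(seqs)]


def test_msa_of_identical_sequences_has_no_gaps(blosum):
    aln = progressive_msa(_records(["MKVLAW"] * 4), blosum)
    assert all(row == "MKVLAW" for row in aln.rows)


def test_msa_rows_ungap_to_inputs(blosum):
    rng = random.Random(17)
    seqs = [
        "".join(rng.choice(AA) for _ in range(rng.randint(10, 25))) for _ in range(6)
    ]
    aln = progressive_msa(_records(seqs), blosum)
    assert len({len(r) for r in aln.rows}) == 1
    assert aln.n_columns <= sum(len(s) for s in seqs)
    by_id = dict(zip(aln.ids, aln.rows))
    for i, s in enumerate(seqs):
        assert by_id[f"s{i}"].replace("-", "") == s


def test_msa_matches_exhaustive_sum_of_pairs_on_easy_triplet(cheap_scheme):
    """On a deletion-only triplet the progressive result attains the optimal
    sum-of-pairs score found by exhaustive gap-pattern enumeration."""
    seqs = ["MKWC", "MKW", "MKWC"]
    aln = progressive_msa(_records(seqs), cheap_scheme)
    ours = _sp_score(aln.rows, cheap_scheme)
    best = max(
        score
        for _, score in enumerate_msa_sp_scores(
            seqs, cheap_scheme.score, cheap_scheme.gap_open,
            cheap_scheme.gap_extend, max_cols=5,
        )
    )
    assert ours == pytest.approx(best)


def _sp_score(rows, scheme):
    total = 0.0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            ra = "".join(
                x for x, y in zip(rows[i], rows[j]) if not (x == "-" and y == "-")
            )
            rb = "".join(
                y for x, y in zip(rows[i], rows[j]) if not (x == "-" and y == "-")
            )
            total += _score_alignment(ra, rb, scheme)
    return total
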