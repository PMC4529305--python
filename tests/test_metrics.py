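"""N50, ORF detection, Unigene grouping and the assembly summary."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from potoroo import metrics as me
from potoroo.errors import GroupingError
from potoroo.sequtil import revcomp, translate, STOP_CODONS


def n50_oracle(lengths):
    """Sort-and-accumulate reference implementation."""
    xs = sorted(lengths, reverse=True)
    half = sum(xs) / 2
    acc = 0
    for x in xs:
        acc += x
        if acc >= half:
            return x


def brute_force_orf(seq, min_codons):
    """Exhaustive six-frame scan, independent of the scanning implementation."""
    best = None
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            spans = []
            # ATG .. stop
            for ci, c in enumerate(codons):
                if c != "ATG":
                    continue
                for cj in range(ci, len(codons)):
                    if codons[cj] in STOP_CODONS:
                        spans.append((ci, cj + 1, False, False))
                        break
                else:
                    spans.append((ci, len(codons), False, True))
            # edge .. first stop
            for cj, c in enumerate(codons):
                if c in STOP_CODONS:
                    if codons[0] != "ATG":
                        spans.append((0, cj + 1, True, False))
                    break
            for ci, cj, p5, p3 in spans:
                start, end = frame + 3 * ci, frame + 3 * cj
                prot = translate(s[start:end]).rstrip("*")
                if len(prot) < min_codons:
                    continue
                key = (p5 or p3, -len(prot), strand == "-", frame, start)
                if best is None or key < best[0]:
                    best = (key, (strand, frame, start, end, prot))
    return best[1] if best else None


@pytest.mark.parametrize("lengths,expected", [
    ([500], 500),
    ([8, 7, 6, 5, 4, 3, 2], 6),
    ([1, 1, 1, 1], 1),
    ([10, 10], 10),
])
def test_n50_examples(lengths, expected):
    assert me.n50(lengths) == expected


def test_n50_empty_is_error():
    with pytest.raises(ValueError):
        me.n50([])


@given(st.lists(st.integers(1, 5000), min_size=1, max_size=60))
def test_n50_matches_oracle_and_is_a_member(lengths):
    result = me.n50(lengths)
    assert result == n50_oracle(lengths)
    assert result in lengths


def test_find_best_orf_hand_example():
    t = me.TranscriptRecord("x", "TTATGGGGTAATT")
    orf = me.find_best_orf(t, min_codons=2)
    assert (orf.start, orf.end) == (2, 11)
    assert orf.protein == "MG"
    assert orf.strand == "+"
    assert not orf.five_prime_partial and not orf.three_prime_partial


def test_find_best_orf_all_a_has_none():
    t = me.TranscriptRecord("x", "A" * 500)
    assert me.find_best_orf(t, min_codons=100) is None


def test_find_best_orf_strand_symmetry():
    fwd = "CCATG" + "GCT" * 30 + "TGACC"
    t1 = me.TranscriptRecord("f", fwd)
    t2 = me.TranscriptRecord("r", revcomp(fwd))
    o1 = me.find_best_orf(t1, min_codons=10)
    o2 = me.find_best_orf(t2, min_codons=10)
    assert o1.protein == o2.protein
    assert o1.strand == "+" and o2.strand == "-"


def test_find_best_orf_matches_brute_force_on_random_sequences():
    rng = np.random.default_rng(17)
    for _ in range(60):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        t = me.TranscriptRecord("x", seq)
        mine = me.find_best_orf(t, min_codons=20)
        ref = brute_force_orf(seq, 20)
        if ref is None:
            assert mine is None
        else:
            assert (mine.strand, mine.frame, mine.start, mine.end, mine.protein) == ref


def test_group_unigenes_prefix_rule():
    tx = [me.TranscriptRecord(t, "ACGT") for t in ("g1_seq1", "g1_seq2", "g2_seq1")]
    unis = me.group_unigenes(tx)
    assert [(u.unigene_id, len(u.member_transcript_ids)) for u in unis] == [
        ("g1", 2), ("g2", 1)]


def test_group_unigenes_empty():
    assert me.group_unigenes([]) == []


def test_group_unigenes_unparseable_id_raises():
    with pytest.raises(GroupingError):
        me.group_unigenes([me.TranscriptRecord("oddname", "ACGT")])


def test_group_unigenes_truth_map_and_order_independence(sim_world):
    _, genes, isoforms = sim_world
    tx = [me.TranscriptRecord(i.transcript_id, i.sequence) for i in isoforms]
    unis = me.group_unigenes(tx)
    truth = {}
    for i in isoforms:
        truth.setdefault(i.gene_id, set()).add(i.transcript_id)
    assert {u.unigene_id: set(u.member_transcript_ids) for u in unis} == truth
    shuffled = list(reversed(tx))
    assert me.group_unigenes(shuffled) == unis


def test_classify_clusters_by_definition():
    unis = [
        me.UnigeneRecord("a", ["a_seq1"], True, 3),
        me.UnigeneRecord("b", ["b_seq1"], True, 1),
        me.UnigeneRecord("c", ["c_seq1"], False, 0),
    ]
    assert me.classify_clusters(unis) == (1, 1)
    non = [me.UnigeneRecord("x", ["x_seq1"], False, 0)]
    assert me.classify_clusters(non) == (0, 0)


def test_assembly_stats_arithmetic():
    tx = [me.TranscriptRecord(f"g1_seq{i + 1}", "A" * L)
          for i, L in enumerate([100, 200, 300, 400])]
    orfs = []
    unis = me.group_unigenes(tx)
    stats = me.assembly_stats(tx, orfs, unis)
    assert stats.mean_length == pytest.approx(250.0)
    assert stats.n50 == n50_oracle([100, 200, 300, 400])
    assert stats.n_transcripts_without_orf == 4


def test_assembly_stats_empty():
    stats = me.assembly_stats([], [], [])
    assert stats.n_transcripts == 0 and stats.n50 == 0


@given(st.lists(st.integers(0, 5), min_size=1, max_size=30))
def test_partition_identities_hold(coding_counts):
    """clusters + singletons = coding Unigenes; ORF split partitions transcripts."""
    tx, coding_ids = [], set()
    for g, k in enumerate(coding_counts):
        n_iso = max(k, 1)
        for i in range(n_iso):
            tid = f"g{g}_seq{i + 1}"
            tx.append(me.TranscriptRecord(tid, "ACGT"))
            if i < k:
                coding_ids.add(tid)
    unis = me.group_unigenes(tx, coding_ids=coding_ids)
    orfs = [me.OrfRecord(t, "+", 0, 0, 3, "M") for t in sorted(coding_ids)]
    stats = me.assembly_stats(tx, orfs, unis)
    assert stats.n_transcripts_with_orf + stats.n_transcripts_without_orf == stats.n_transcripts
    assert stats.n_clusters + stats.n_singletons == stats.n_unigenes_with_orf
    assert stats.n_unigenes_with_orf + stats.n_unigenes_without_orf == stats.n_unigenes


def test_truly_coding_unigenes_recovered(sim_world):
    """Every locus whose planted ORF clears min_codons is called coding."""
    _, genes, isoforms = sim_world
    tx = [me.TranscriptRecord(i.transcript_id, i.sequence) for i in isoforms]
    orfs = [o for o in (me.find_best_orf(t, 100) for t in tx) if o]
    unis = me.group_unigenes(tx, coding_ids={o.transcript_id for o in orfs})
    called = {u.unigene_id for u in unis if u.coding}
    truly = {g.gene_id for g in genes
             if g.coding and (g.orf_span[1] - g.orf_span[0]) // 3 - 1 >= 100}
    assert truly <= called
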