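"""Mapping truth recovery, TPM/FPKM arithmetic, EM behaviour, complexity."""

import numpy as np
import pytest

from potoroo import abundance as ab
from potoroo import metrics as me
from potoroo import synthetic as syn
from potoroo.sequtil import revcomp


@pytest.fixture(scope="module")
def mapped(sim_world, sim_reads_clean):
    _, _, isoforms = sim_world
    tx = [me.TranscriptRecord(i.transcript_id, i.sequence) for i in isoforms]
    return tx, ab.map_reads(sim_reads_clean, tx)


def test_error_free_pairs_map_to_truth_coordinates(sim_reads_clean, mapped):
    tx, alignments = mapped
    by_pair = {}
    for a in alignments:
        by_pair.setdefault(a.pair_id, []).append(a)
    n_hit = 0
    for r in sim_reads_clean:
        tid, s, e = r.truth
        placements = by_pair.get(r.pair_id, [])
        if any(a.transcript_id == tid and a.fragment_start == s
               and a.fragment_end == e and a.concordant for a in placements):
            n_hit += 1
    assert n_hit == len(sim_reads_clean)


def test_shared_region_yields_two_records():
    rng = np.random.default_rng(8)
    shared = "".join(rng.choice(list("ACGT"), size=400))
    tail_a = "".join(rng.choice(list("ACGT"), size=200))
    tail_b = "".join(rng.choice(list("ACGT"), size=200))
    tx = [me.TranscriptRecord("a_seq1", shared + tail_a),
          me.TranscriptRecord("b_seq1", shared + tail_b)]
    pair = syn.ReadPairRecord(
        "p", shared[:150], revcomp(shared[250:400]),
        "I" * 150, "I" * 150, ("a_seq1", 0, 400))
    recs = ab.map_reads([pair], tx)
    assert {r.transcript_id for r in recs} == {"a_seq1", "b_seq1"}
    assert all(r.fragment_start == 0 and r.fragment_end == 400 for r in recs)


def test_long_fragment_flagged_discordant():
    seq = "".join(np.random.default_rng(9).choice(list("ACGT"), size=1200))
    tx = [me.TranscriptRecord("t_seq1", seq)]
    pair = syn.ReadPairRecord("p", seq[:150], revcomp(seq[750:900]),
                              "I" * 150, "I" * 150, ("t_seq1", 0, 900))
    recs = ab.map_reads([pair], tx, ab.MapParams(max_fragment=800))
    assert len(recs) == 1
    assert not recs[0].concordant
    assert recs[0].fragment_end - recs[0].fragment_start == 900


def test_single_transcript_gets_all_tpm():
    tx = [me.TranscriptRecord("t_seq1", "ACGT" * 300)]
    al = [ab.AlignmentRecord(f"p{i}", "t_seq1", 0, 275, "F") for i in range(7)]
    recs = ab.estimate_abundance(al, tx)
    assert recs[0].tpm == pytest.approx(1e6)


def test_tpm_closed_form_two_transcripts():
    """counts 10/10 at effective lengths 1000/2000 -> 2:1 TPM split."""
    tx = [me.TranscriptRecord("a_seq1", "A" * 1274),   # eff len 1000
          me.TranscriptRecord("b_seq1", "A" * 2274)]   # eff len 2000
    al = []
    for i in range(10):
        al.append(ab.AlignmentRecord(f"a{i}", "a_seq1", 0, 275, "F"))
        al.append(ab.AlignmentRecord(f"b{i}", "b_seq1", 0, 275, "F"))
    recs = {r.transcript_id: r for r in ab.estimate_abundance(al, tx, mode="unique")}
    assert recs["a_seq1"].tpm == pytest.approx(666666.7, abs=0.1)
    assert recs["b_seq1"].tpm == pytest.approx(333333.3, abs=0.1)
    assert recs["a_seq1"].fpkm == pytest.approx(1e9 * 10 / (1000 * 20))


def test_em_splits_identical_transcripts_evenly():
    seq = "ACGTGGTACA" * 60
    tx = [me.TranscriptRecord("a_seq1", seq), me.TranscriptRecord("b_seq1", seq)]
    al = []
    for i in range(40):
        al.append(ab.AlignmentRecord(f"p{i}", "a_seq1", 0, 275, "F"))
        al.append(ab.AlignmentRecord(f"p{i}", "b_seq1", 0, 275, "F"))
    recs = {r.transcript_id: r for r in ab.estimate_abundance(al, tx, mode="em")}
    assert recs["a_seq1"].tpm == pytest.approx(500000.0, abs=1e-3)
    assert recs["a_seq1"].est_count == pytest.approx(20.0, abs=1e-6)


def test_zero_mapped_pairs_gives_zero_records():
    tx = [me.TranscriptRecord("t_seq1", "ACGT" * 100)]
    recs = ab.estimate_abundance([], tx)
    assert recs[0].tpm == 0.0 and recs[0].est_count == 0.0


@pytest.mark.parametrize("mode", ["unique", "uniform", "em"])
def test_tpm_conservation_all_modes(mapped, mode):
    tx, alignments = mapped
    recs = ab.estimate_abundance(alignments, tx, mode=mode)
    total = sum(r.tpm for r in recs)
    if total:
        assert total == pytest.approx(1e6, rel=1e-6)


def test_em_log_likelihood_is_nondecreasing():
    seq_a = "ACGTGGTACA" * 60
    tx = [me.TranscriptRecord("a_seq1", seq_a),
          me.TranscriptRecord("b_seq1", seq_a[:480])]
    by_pair = {}
    rng = np.random.default_rng(3)
    for i in range(30):
        if rng.random() < 0.5:
            by_pair[f"p{i}"] = ["a_seq1", "b_seq1"]
        else:
            by_pair[f"p{i}"] = ["a_seq1"]
    lls = []
    for n_iter in range(1, 8):
        counts = ab._em_counts(by_pair, tx, 275.0, tol=0.0, max_iter=n_iter)
        lls.append(ab.em_log_likelihood(by_pair, tx, counts))
    for a, b in zip(lls, lls[1:]):
        assert b >= a - 1e-9


def test_unigene_rollup_sums_and_conserves(mapped):
    tx, alignments = mapped
    recs = ab.estimate_abundance(alignments, tx)
    grouping = {t.transcript_id: t.transcript_id.rsplit("_seq", 1)[0] for t in tx}
    unis = ab.unigene_abundance(recs, grouping)
    assert sum(u.tpm for u in unis) == pytest.approx(sum(r.tpm for r in recs))
    one = {r.transcript_id: r for r in recs}
    g = unis[0].transcript_id
    members = [t for t in grouping if grouping[t] == g]
    assert unis[0].tpm == pytest.approx(sum(one[m].tpm for m in members))


def test_unigene_rollup_identity_grouping(mapped):
    tx, alignments = mapped
    recs = ab.estimate_abundance(alignments, tx)
    ident = {t.transcript_id: t.transcript_id for t in tx}
    out = ab.unigene_abundance(recs, ident)
    assert {r.transcript_id: r.tpm for r in out} == {r.transcript_id: r.tpm for r in recs}


def test_unigene_rollup_missing_transcript_raises(mapped):
    tx, alignments = mapped
    recs = ab.estimate_abundance(alignments, tx)
    with pytest.raises(KeyError):
        ab.unigene_abundance(recs, {})


def test_complexity_hand_count():
    al = [
        ab.AlignmentRecord("p1", "t1", 10, 200, "F"),
        ab.AlignmentRecord("p2", "t1", 10, 210, "F"),
        ab.AlignmentRecord("p3", "t1", 20, 200, "F"),
        ab.AlignmentRecord("p4", "t2", 10, 200, "F"),
    ]
    res = ab.library_complexity(al, 4, seed=0)
    # mate keys: F starts {t1:10,10,20, t2:10} -> 3 unique of 4
    #            R ends   {t1:200,210,200, t2:200} -> 3 unique of 4
    assert res.unpaired_complexity == pytest.approx(6 / 8)
    assert res.paired_complexity == pytest.approx(1.0)


def test_complexity_bounds():
    distinct = [ab.AlignmentRecord(f"p{i}", "t", i, i + 100, "F") for i in range(20)]
    res = ab.library_complexity(distinct, 20, seed=1)
    assert res.paired_complexity == pytest.approx(1.0)
    dup = [ab.AlignmentRecord(f"p{i}", "t", 5, 105, "F") for i in range(20)]
    res2 = ab.library_complexity(dup, 20, seed=1)
    assert res2.paired_complexity == pytest.approx(1 / 20)
    assert res2.unpaired_complexity == pytest.approx(2 / 40)


def test_complexity_matches_brute_force_set_count(mapped):
    _, alignments = mapped
    res = ab.library_complexity(alignments, 10**9, seed=2)
    uniq = {a.pair_id: a for a in alignments if a.concordant}
    solo = [a for a in uniq.values()
            if sum(1 for b in alignments if b.pair_id == a.pair_id and b.concordant) == 1]
    mates = set()
    frags = set()
    for a in solo:
        mates.add((a.transcript_id, "F", a.fragment_start))
        mates.add((a.transcript_id, "R", a.fragment_end))
        frags.add((a.transcript_id, a.fragment_start, a.fragment_end))
    assert res.n_sampled_pairs == len(solo)
    assert res.unpaired_complexity == pytest.approx(len(mates) / (2 * len(solo)))
    assert res.paired_complexity == pytest.approx(len(frags) / len(solo))


def test_complexity_empty_is_flagged():
    res = ab.library_complexity([], 10, seed=0)
    assert res.undefined


def test_alignment_tsv_round_trip(tmp_path, mapped):
    _, alignments = mapped
    path = tmp_path / "aln.tsv"
    ab.write_alignments_tsv(alignments[:50], path)
    back = ab.read_alignments_tsv(path)
    assert back == alignments[:50]


def test_sam_reader_minimal(tmp_path):
    sam = tmp_path / "m.sam"
    sam.write_text(
        "@HD\tVN:1.6\n"
        "p1\t99\tt1\t11\t60\t100M\t=\t211\t300\t" + "A" * 100 + "\t" + "I" * 100 + "\n"
        "p1\t147\tt1\t211\t60\t100M\t=\t11\t-300\t" + "A" * 100 + "\t" + "I" * 100 + "\n"
    )
    recs = ab.read_alignments_sam(sam)
    assert len(recs) == 1
    assert (recs[0].fragment_start, recs[0].fragment_end) == (10, 310)
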