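"""Candidate enumeration, consensus selection and off-target screening."""

import numpy as np
import pytest

from potoroo import metrics as me
from potoroo import sirna as si
from potoroo.errors import ConfigError
from potoroo.sequtil import revcomp


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_candidates(iso_seqs, canonical_id, orf_span, k):
    """Substring-intersection oracle for candidate enumeration."""
    orf = iso_seqs[canonical_id][orf_span[0] : orf_span[1]]
    out = []
    seen = set()
    for off in range(len(orf) - k + 1):
        w = orf[off : off + k]
        if w not in seen and all(w in s for s in iso_seqs.values()):
            seen.add(w)
            out.append(w)
    return out


def test_single_isoform_candidate_count():
    rng = np.random.default_rng(1)
    orf = _random_seq(rng, 25)
    cands = si.enumerate_candidates({"g_seq1": orf}, "g_seq1", (0, 25))
    assert len(cands) == 7  # 25 - 19 + 1


def test_upstream_exon_change_keeps_candidates():
    rng = np.random.default_rng(2)
    upstream = _random_seq(rng, 120)
    orf = _random_seq(rng, 90)
    iso = {"g_seq1": upstream + orf, "g_seq2": orf}
    cands = si.enumerate_candidates(iso, "g_seq1", (120, 210))
    solo = si.enumerate_candidates({"g_seq1": upstream + orf}, "g_seq1", (120, 210))
    assert [c.sequence for c in cands] == [c.sequence for c in solo]


def test_orf_internal_exon_skip_removes_windows_oracle():
    rng = np.random.default_rng(3)
    e1, e2, e3 = _random_seq(rng, 60), _random_seq(rng, 45), _random_seq(rng, 60)
    iso = {"g_seq1": e1 + e2 + e3, "g_seq2": e1 + e3}
    span = (0, len(e1 + e2 + e3))
    cands = [c.sequence for c in si.enumerate_candidates(iso, "g_seq1", span)]
    assert cands == brute_candidates(iso, "g_seq1", span, 19)
    # windows fully inside the retained exons survive; junction-spanning ones don't
    assert e1[:19] in cands
    assert (e1[-10:] + e2[:9]) not in cands


def test_short_orf_warns_and_returns_empty():
    with pytest.warns(UserWarning):
        assert si.enumerate_candidates({"g_seq1": "ACGTACGTAC"}, "g_seq1", (0, 10)) == []


def test_composition_scorer_bottoms_out_on_homopolymer():
    poly = si.score_composition("G" * 19)
    rng = np.random.default_rng(4)
    others = [si.score_composition(_random_seq(rng, 19)) for _ in range(30)]
    assert poly <= min(others)


def test_asymmetry_prefers_au_rich_3prime_end():
    a = "GCGCGCGCGCGCGCGCGAA"
    b = "GCGCGCGCGCGCGCGCGGC"
    assert si.score_asymmetry(a) > si.score_asymmetry(b)


def test_scorer_tie_order_is_by_sequence():
    cands = [si.SirnaCandidate(s, "g", {}) for s in ["TTTTAGCATGCATGCAGCA", "AAAAGCATGCATGCAGCAT"]]
    lists = si.score_candidates(cands, ["gc_window"], top_n=5)
    seqs = [s for s, _, _ in lists["gc_window"]]
    scores = {s: sc for s, sc, _ in lists["gc_window"]}
    if scores[seqs[0]] == scores[seqs[1]]:
        assert seqs == sorted(seqs)


def test_unknown_scorer_is_config_error():
    with pytest.raises(ConfigError):
        si.score_candidates([si.SirnaCandidate("A" * 19, "g", {})], ["nope"])


def test_consensus_rule_application():
    lists = {
        "s1": [("A", 1.0, 1), ("B", 0.9, 2)],
        "s2": [("A", 1.0, 1), ("C", 0.8, 2)],
        "s3": [("C", 1.0, 1)],
    }
    picked = si.consensus_select(lists, si.DesignParams(min_agree=2))
    assert [p[0] for p in picked] == ["A", "C"]
    union = si.consensus_select(lists, si.DesignParams(min_agree=1))
    assert {p[0] for p in union} == {"A", "B", "C"}
    assert si.consensus_select(lists, si.DesignParams(min_agree=4)) == []


def test_offtarget_index_posting_count():
    t = me.TranscriptRecord("t_seq1", "".join(
        np.random.default_rng(5).choice(list("ACGT"), size=100)))
    idx = si.OfftargetIndex([t])
    assert sum(len(v) for v in idx.contig_table.values()) == 100 - 16 + 1


def test_planted_16mer_recovered():
    rng = np.random.default_rng(6)
    plant = _random_seq(rng, 16)
    seq = _random_seq(rng, 50) + plant + _random_seq(rng, 50)
    idx = si.OfftargetIndex([me.TranscriptRecord("t_seq1", seq)])
    assert any(tid == "t_seq1" and pos == 50 for tid, pos in idx.contig_table.get(plant, []))


def test_own_gene_hits_are_excluded():
    rng = np.random.default_rng(7)
    seq = _random_seq(rng, 300)
    cand = seq[100:119]
    tx = [me.TranscriptRecord("g_seq1", seq)]
    idx = si.OfftargetIndex(tx)
    verdict, hits = si.offtarget_screen(cand, idx, {"g_seq1"})
    assert verdict == "pass" and hits == []


def test_hamming_rule_without_contiguous_stretch():
    """One central substitution: 18/19 positions match but max run is 9 < 16."""
    rng = np.random.default_rng(8)
    cand = _random_seq(rng, 19)
    decoy = cand[:9] + ("A" if cand[9] != "A" else "C") + cand[10:]
    offtarget = _random_seq(rng, 40) + decoy + _random_seq(rng, 40)
    tx = [me.TranscriptRecord("x_seq1", offtarget)]
    idx = si.OfftargetIndex(tx)
    verdict, hits = si.offtarget_screen(cand, idx, set())
    assert verdict == "discard"
    assert any(h.match_type == "hamming_ge" and h.matched_positions == 18 for h in hits)


def test_contiguous_rule_without_hamming():
    """A verbatim 16-mer plus 3 mismatches: Hamming 16 < 18, still discarded."""
    rng = np.random.default_rng(9)
    cand = _random_seq(rng, 19)
    sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
    decoy = "".join(sub[c] for c in cand[:3]) + cand[3:]
    offtarget = _random_seq(rng, 30) + decoy + _random_seq(rng, 30)
    tx = [me.TranscriptRecord("x_seq1", offtarget)]
    idx = si.OfftargetIndex(tx)
    verdict, hits = si.offtarget_screen(cand, idx, set())
    assert verdict == "discard"
    assert any(h.match_type == "contiguous_ge" and h.matched_length == 16 for h in hits)


def test_reverse_complement_decoy_is_caught_and_switchable():
    rng = np.random.default_rng(10)
    cand = _random_seq(rng, 19)
    offtarget = _random_seq(rng, 30) + revcomp(cand) + _random_seq(rng, 30)
    tx = [me.TranscriptRecord("x_seq1", offtarget)]
    both = si.DesignParams(search_both_orientations=True)
    verdict, _ = si.offtarget_screen(cand, si.OfftargetIndex(tx, both), set(), both)
    assert verdict == "discard"
    sense = si.DesignParams(search_both_orientations=False)
    verdict2, _ = si.offtarget_screen(cand, si.OfftargetIndex(tx, sense), set(), sense)
    assert verdict2 == "pass"


def test_screen_matches_brute_force_on_random_transcriptomes():
    rng = np.random.default_rng(11)
    params = si.DesignParams()
    for _ in range(10):
        tx = [me.TranscriptRecord(f"t{i}_seq1", _random_seq(rng, 400))
              for i in range(6)]
        idx = si.OfftargetIndex(tx, params)
        for _ in range(10):
            cand = _random_seq(rng, 19)
            fast, _ = si.offtarget_screen(cand, idx, {"t0_seq1"}, params)
            slow = si.brute_force_screen(cand, tx, {"t0_seq1"}, params)
            assert fast == slow


def test_screening_monotone_in_transcriptome():
    rng = np.random.default_rng(12)
    cand = _random_seq(rng, 19)
    base = [me.TranscriptRecord("a_seq1", _random_seq(rng, 300))]
    extra = base + [me.TranscriptRecord("b_seq1", _random_seq(rng, 100) + cand)]
    params = si.DesignParams()
    v1, _ = si.offtarget_screen(cand, si.OfftargetIndex(base, params), set(), params)
    v2, _ = si.offtarget_screen(cand, si.OfftargetIndex(extra, params), set(), params)
    assert not (v1 == "discard" and v2 == "pass")
    assert v2 == "discard"


def test_design_end_to_end_with_planted_clean_region(sim_world):
    genome, genes, isoforms = sim_world
    tx = [me.TranscriptRecord(i.transcript_id, i.sequence) for i in isoforms]
    g = next(g for g in genes if g.coding)
    report = si.design(g.gene_id, tx, g.orf_span, canonical_id=f"{g.gene_id}_seq1")
    assert report.attrition["enumerated"] > 0
    assert set(report.shortlist) <= set(report.consensus)
    for sc in report.candidates:
        if sc.candidate.sequence in report.shortlist:
            assert sc.verdict == "pass" and not sc.hits
    # determinism
    report2 = si.design(g.gene_id, tx, g.orf_span, canonical_id=f"{g.gene_id}_seq1")
    assert report2.shortlist == report.shortlist
    assert report2.attrition == report.attrition


def test_duplicated_gene_under_other_ids_kills_all_candidates(sim_world):
    genome, genes, isoforms = sim_world
    g = next(g for g in genes if g.coding)
    own = [me.TranscriptRecord(i.transcript_id, i.sequence)
           for i in isoforms if i.gene_id == g.gene_id]
    copies = [me.TranscriptRecord(f"zz{k}_seq1", own[0].sequence) for k in range(2)]
    report = si.design(g.gene_id, own + copies, g.orf_span,
                       canonical_id=f"{g.gene_id}_seq1")
    assert report.shortlist == []
    assert report.attrition["passed_screen"] == 0
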