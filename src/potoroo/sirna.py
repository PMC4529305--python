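"""Consensus siRNA design with k-mer off-target screening.

The design procedure: enumerate every 19-mer window of the target locus's
canonical open reading frame that is conserved verbatim across all of the
locus's isoforms; rank the windows with several independent scorers and
keep those recommended by at least ``min_agree`` of them (the 2-of-3
consensus rule); then discard any survivor that matches elsewhere in the
transcriptome in >= ``ham_discard`` of its positions (Hamming similarity,
no indels) or shares a contiguous exact stretch of >= ``contig_discard``
nucleotides with an off-target transcript.  Both the candidate and its
reverse complement are screened by default, since either strand of the
duplex can silence.

The three built-in scorers are documented rule-based stand-ins for
published web design tools (whose exact models are out of scope); the
consensus and discard rules are the procedure's substance and are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError
from .sequtil import revcomp


@dataclass
class DesignParams:
    k: int = 19
    min_agree: int = 2
    top_n: int = 10
    ham_discard: int = 18       # >= this many matching positions discards
    contig_discard: int = 16    # >= this long an exact stretch discards
    search_both_orientations: bool = True

    def __post_init__(self):
        if self.contig_discard > self.k or self.ham_discard > self.k:
            raise ValueError("discard thresholds cannot exceed k")


@dataclass
class SirnaCandidate:
    sequence: str
    target_unigene: str
    position_per_isoform: dict
    in_orf: bool = True


@dataclass
class OfftargetHit:
    candidate: str
    transcript_id: str
    offset: int
    orientation: str            # S: candidate as-is; A: reverse complement
    match_type: str             # hamming_ge | contiguous_ge
    matched_positions: int = 0
    matched_length: int = 0


@dataclass
class ScoredCandidate:
    candidate: SirnaCandidate
    scores: dict = field(default_factory=dict)
    ranks: dict = field(default_factory=dict)
    n_lists: int = 0
    best_rank: int | None = None
    consensus: bool = False
    verdict: str = ""
    hits: list = field(default_factory=list)


@dataclass
class DesignReport:
    target_unigene: str
    params: DesignParams
    candidates: list            # ScoredCandidate, candidate enumeration order
    consensus: list             # sequences, consensus order
    shortlist: list             # sequences that also pass screening
    attrition: dict = field(default_factory=dict)


# ----------------------------------------------------------------- candidates

def enumerate_candidates(isoform_seqs: dict, canonical_id: str,
                         orf_span: tuple, params: DesignParams | None = None) -> list:
    """Sense-strand k-windows of the canonical ORF present in every isoform.

    ``orf_span`` is the ORF interval on the canonical isoform (0-based,
    half-open).  Positions record the first occurrence per isoform.
    Deterministic order: by offset on the canonical isoform.
    """
    params = params or DesignParams()
    k = params.k
    canonical = isoform_seqs[canonical_id].upper()
    orf = canonical[orf_span[0] : orf_span[1]]
    if len(orf) < k:
        import warnings

        warnings.warn(f"ORF shorter than k={k}; no candidates")
        return []
    others = {tid: s.upper() for tid, s in isoform_seqs.items()}
    out = []
    seen = set()
    for off in range(len(orf) - k + 1):
        window = orf[off : off + k]
        if window in seen:
            continue
        positions = {}
        for tid, seq in others.items():
            pos = seq.find(window)
            if pos < 0:
                break
            positions[tid] = pos
        else:
            seen.add(window)
            out.append(SirnaCandidate(
                sequence=window,
                target_unigene=canonical_id.rsplit("_seq", 1)[0],
                position_per_isoform=positions,
            ))
    return out


# -------------------------------------------------------------------- scorers

# nearest-neighbour duplex stability (kcal/mol, RNA/RNA, 37C); more negative
# is more stable.  Used only to compare the two duplex ends.
_NN_DG = {
    "AA": -0.93, "AC": -2.24, "AG": -2.08, "AT": -1.10,
    "CA": -2.11, "CC": -3.26, "CG": -2.36, "CT": -2.08,
    "GA": -2.35, "GC": -3.42, "GG": -3.26, "GT": -2.24,
    "TA": -1.33, "TC": -2.35, "TG": -2.11, "TT": -0.93,
}


def score_gc_window(seq: str) -> float:
    """Prefers 30-52% GC; score falls off linearly outside that window."""
    gc = 100.0 * sum(1 for b in seq if b in "GC") / len(seq)
    if 30.0 <= gc <= 52.0:
        return 1.0
    dist = (30.0 - gc) if gc < 30.0 else (gc - 52.0)
    return max(0.0, 1.0 - dist / 50.0)


def score_asymmetry(seq: str) -> float:
    """3'-sense-end instability via the nearest-neighbour end difference.

    A duplex whose 3' sense end is less stable than its 5' end loads the
    intended guide strand preferentially; the score is the stability
    difference (5' end minus 3' end), so A/U-rich 3' ends score higher.
    """
    dg5 = _NN_DG.get(seq[:2], -2.0)
    dg3 = _NN_DG.get(seq[-2:], -2.0)
    return dg3 - dg5  # dg negative: less stable 3' end => higher score


def _longest_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _self_complementarity(seq: str, min_len: int = 5) -> int:
    """Length of the longest substring whose reverse complement also occurs."""
    best = 0
    rc = revcomp(seq)
    for length in range(min_len, len(seq) + 1):
        found = False
        for i in range(len(seq) - length + 1):
            if seq[i : i + length] in rc:
                found = True
                break
        if found:
            best = length
        else:
            break
    return best


def score_composition(seq: str) -> float:
    """Penalises mononucleotide runs >= 4 and self-complementary stretches."""
    run = _longest_run(seq)
    run_penalty = max(0, run - 3)
    hairpin_penalty = max(0, _self_complementarity(seq) - 4)
    return -(run_penalty + 0.5 * hairpin_penalty)


BUILTIN_SCORERS = {
    "gc_window": score_gc_window,
    "asymmetry": score_asymmetry,
    "composition": score_composition,
}


def score_candidates(candidates: list, scorers=None, top_n: int = 10) -> dict:
    """Per-scorer ranked top-n lists; ties break by candidate sequence.

    ``scorers`` may be names of built-ins or (name, callable) pairs.
    Returns {scorer_name: [(sequence, score, rank), ...]}.
    """
    if not scorers:
        scorers = list(BUILTIN_SCORERS)
    resolved = []
    for s in scorers:
        if isinstance(s, str):
            if s not in BUILTIN_SCORERS:
                raise ConfigError(f"unknown scorer {s!r}; built-ins: {sorted(BUILTIN_SCORERS)}")
            resolved.append((s, BUILTIN_SCORERS[s]))
        else:
            resolved.append(s)
    out = {}
    for name, fn in resolved:
        scored = sorted(((c.sequence, float(fn(c.sequence))) for c in candidates),
                        key=lambda t: (-t[1], t[0]))
        out[name] = [(seq, sc, rank) for rank, (seq, sc) in enumerate(scored[:top_n], start=1)]
    return out


def consensus_select(per_scorer: dict, params: DesignParams | None = None) -> list:
    """Sequences on >= ``min_agree`` of the top-n lists.

    Ordered by (number of lists descending, best rank ascending, sequence).
    Returns [(sequence, n_lists, best_rank), ...].
    """
    params = params or DesignParams()
    membership: dict[str, list] = {}
    for name in sorted(per_scorer):
        for seq, _score, rank in per_scorer[name]:
            membership.setdefault(seq, []).append(rank)
    picked = [(seq, len(ranks), min(ranks)) for seq, ranks in membership.items()
              if len(ranks) >= params.min_agree]
    picked.sort(key=lambda t: (-t[1], t[2], t[0]))
    return picked


# ------------------------------------------------------------------ screening

class OfftargetIndex:
    """Exact k-mer postings over transcript sense strands.

    Holds one table of ``contig_discard``-mers (rule b) and seed tables over
    a pigeonhole split of the candidate length for the Hamming rule (rule
    a): with m = k - ham_discard mismatches allowed, the candidate is split
    into m + 1 seeds, at least one of which must match exactly.
    """

    def __init__(self, transcripts, params: DesignParams | None = None):
        if not transcripts:
            raise ValueError("transcript set is empty")
        self.params = params or DesignParams()
        p = self.params
        self.seqs = {t.transcript_id: t.sequence.upper() for t in transcripts}
        self.contig_table: dict[str, list] = {}
        for tid, seq in self.seqs.items():
            for i in range(len(seq) - p.contig_discard + 1):
                self.contig_table.setdefault(seq[i : i + p.contig_discard], []).append((tid, i))
        n_seeds = (p.k - p.ham_discard) + 1
        bounds = [round(i * p.k / n_seeds) for i in range(n_seeds + 1)]
        self.seed_spans = list(zip(bounds, bounds[1:]))
        self.seed_tables: list[dict] = []
        for a, b in self.seed_spans:
            w = b - a
            table: dict[str, list] = {}
            for tid, seq in self.seqs.items():
                for i in range(len(seq) - w + 1):
                    table.setdefault(seq[i : i + w], []).append((tid, i))
            self.seed_tables.append(table)


def _hamming_matches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x == y)


def _longest_shared_at(window: str, cand: str) -> int:
    """Longest run of positionwise agreement between two same-length strings."""
    best = run = 0
    for x, y in zip(window, cand):
        run = run + 1 if x == y else 0
        best = max(best, run)
    return best


def offtarget_screen(candidate: str, index: OfftargetIndex,
                     target_members, params: DesignParams | None = None):
    """(verdict, hits) for one candidate against the indexed transcriptome.

    Hits on the target locus's own isoforms (``target_members``) never
    count.  Discard iff some off-target window matches in >= ``ham_discard``
    of k positions, or a contiguous >= ``contig_discard``-mer of the
    candidate occurs exactly off-target; otherwise pass.
    """
    params = params or index.params
    if len(candidate) != params.k:
        raise ValueError(f"candidate length {len(candidate)} != k={params.k}")
    candidate = candidate.upper()
    members = set(target_members)
    hits: list[OfftargetHit] = []
    queries = [("S", candidate)]
    if params.search_both_orientations:
        queries.append(("A", revcomp(candidate)))
    for orient, q in queries:
        # rule (a): Hamming similarity over aligned k-windows, via pigeonhole seeds
        window_starts = set()
        for (a, b), table in zip(index.seed_spans, index.seed_tables):
            for tid, pos in table.get(q[a:b], ()):
                if tid in members:
                    continue
                start = pos - a
                if start >= 0 and start + params.k <= len(index.seqs[tid]):
                    window_starts.add((tid, start))
        for tid, start in sorted(window_starts):
            window = index.seqs[tid][start : start + params.k]
            matches = _hamming_matches(q, window)
            if matches >= params.ham_discard:
                hits.append(OfftargetHit(candidate, tid, start, orient,
                                         "hamming_ge", matched_positions=matches))
        # rule (b): exact contiguous stretch >= contig_discard
        w = params.contig_discard
        seen = set()
        for off in range(params.k - w + 1):
            sub = q[off : off + w]
            for tid, pos in index.contig_table.get(sub, ()):
                if tid in members:
                    continue
                # extend to the maximal shared stretch around this match
                s_off, s_pos = off, pos
                tseq = index.seqs[tid]
                while s_off > 0 and s_pos > 0 and q[s_off - 1] == tseq[s_pos - 1]:
                    s_off -= 1
                    s_pos -= 1
                length = w
                e_off, e_pos = off + w, pos + w
                while e_off < params.k and e_pos < len(tseq) and q[e_off] == tseq[e_pos]:
                    e_off += 1
                    e_pos += 1
                length = e_off - s_off
                key = (tid, s_pos, length, orient)
                if key in seen:
                    continue
                seen.add(key)
                hits.append(OfftargetHit(candidate, tid, s_pos, orient,
                                         "contiguous_ge", matched_length=length))
    verdict = "discard" if hits else "pass"
    return verdict, hits


# ------------------------------------------------------------------- pipeline

def design(target_unigene: str, transcripts, orf_span: tuple,
           canonical_id: str | None = None,
           params: DesignParams | None = None, scorers=None) -> DesignReport:
    """End-to-end design for one locus: enumerate, score, consensus, screen."""
    params = params or DesignParams()
    members = {t.transcript_id for t in transcripts
               if t.transcript_id.rsplit("_seq", 1)[0] == target_unigene}
    if not members:
        raise ValueError(f"unigene {target_unigene} not present in the transcriptome")
    iso_seqs = {t.transcript_id: t.sequence for t in transcripts
                if t.transcript_id in members}
    canonical_id = canonical_id or sorted(members)[0]
    candidates = enumerate_candidates(iso_seqs, canonical_id, orf_span, params)
    per_scorer = score_candidates(candidates, scorers, params.top_n)
    consensus = consensus_select(per_scorer, params)
    index = OfftargetIndex(transcripts, params)
    by_seq = {c.sequence: ScoredCandidate(candidate=c) for c in candidates}
    for name, lst in per_scorer.items():
        for seq, score, rank in lst:
            by_seq[seq].scores[name] = score
            by_seq[seq].ranks[name] = rank
    shortlist = []
    for seq, n_lists, best_rank in consensus:
        sc = by_seq[seq]
        sc.n_lists, sc.best_rank, sc.consensus = n_lists, best_rank, True
        verdict, hits = offtarget_screen(seq, index, members, params)
        sc.verdict, sc.hits = verdict, hits
        if verdict == "pass":
            shortlist.append(seq)
    report = DesignReport(
        target_unigene=target_unigene,
        params=params,
        candidates=list(by_seq.values()),
        consensus=[seq for seq, _, _ in consensus],
        shortlist=shortlist,
        attrition={
            "enumerated": len(candidates),
            "consensus": len(consensus),
            "passed_screen": len(shortlist),
        },
    )
    return report


def brute_force_screen(candidate: str, transcripts, target_members,
                       params: DesignParams | None = None) -> str:
    """Exhaustive screening verdict; the independent oracle for the index path.

    Scans every window of every off-target transcript counting positionwise
    matches, and searches every >= ``contig_discard`` substring of the
    candidate, in both orientations.  Quadratic and only suitable for small
    transcriptomes.
    """
    params = params or DesignParams()
    members = set(target_members)
    queries = [candidate.upper()]
    if params.search_both_orientations:
        queries.append(revcomp(candidate.upper()))
    for q in queries:
        for t in transcripts:
            if t.transcript_id in members:
                continue
            seq = t.sequence.upper()
            for start in range(len(seq) - params.k + 1):
                if _hamming_matches(q, seq[start : start + params.k]) >= params.ham_discard:
                    return "discard"
            w = params.contig_discard
            for off in range(params.k - w + 1):
                if q[off : off + w] in seq:
                    return "discard"
    return "pass"
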