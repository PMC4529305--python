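"""Assembly-level statistics: N50, ORF calling, Unigene grouping, clusters.

The ORF caller is a longest-ORF scanner over all six frames with allowances
for transcript-edge partial ORFs; it stands in for Markov-model ORF
extraction tools and is deliberately simple, configurable and
oracle-testable.  Unigenes (inferred transcription loci) are recovered from
assembler-style hierarchical identifiers (``<locus>_seq<k>``) rather than by
re-clustering sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import GroupingError
from .sequtil import revcomp, translate

_UNIGENE_RE = re.compile(r"^(?P<unigene>.+)_seq\d+$")


@dataclass
class TranscriptRecord:
    transcript_id: str
    sequence: str
    unigene_id: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.transcript_id}")
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValueError(f"non-ACGTN characters in {self.transcript_id}")


@dataclass
class OrfRecord:
    transcript_id: str
    strand: str           # + or -
    frame: int            # 0, 1, 2
    start: int            # transcript coords on the reported strand, half-open
    end: int
    protein: str
    five_prime_partial: bool = False
    three_prime_partial: bool = False


@dataclass
class UnigeneRecord:
    unigene_id: str
    member_transcript_ids: list = field(default_factory=list)
    coding: bool = False
    n_coding_isoforms: int = 0


@dataclass
class AssemblyStats:
    n_transcripts: int = 0
    mean_length: float = 0.0
    n50: int = 0
    n_transcripts_with_orf: int = 0
    n_transcripts_without_orf: int = 0
    n_unigenes: int = 0
    n_unigenes_with_orf: int = 0
    n_unigenes_without_orf: int = 0
    n_clusters: int = 0
    n_singletons: int = 0
    mean_isoforms_per_coding_unigene: float = 0.0
    no_coding_unigenes: bool = False


def n50(lengths) -> int:
    """Largest length L such that contigs of length >= L hold half the bases."""
    lengths = list(lengths)
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    half = sum(lengths) / 2.0
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def _frame_candidates(seq: str, frame: int):
    """Candidate ORFs in one forward frame of ``seq``.

    Yields (start, end, five_partial, three_partial) in sequence
    coordinates; candidates are ATG-to-stop, edge-to-stop (5' partial) and
    ATG-to-edge (3' partial).  ``end`` includes the stop codon when present.
    """
    n = len(seq)
    n_codons = (n - frame) // 3
    stops: list[int] = []   # codon indices
    starts: list[int] = []
    for ci in range(n_codons):
        codon = seq[frame + 3 * ci : frame + 3 * ci + 3]
        if codon in ("TAA", "TAG", "TGA"):
            stops.append(ci)
        elif codon == "ATG":
            starts.append(ci)
    prev_stop = -1
    si = 0
    for stop in stops:
        if prev_stop == -1 and stop >= 0:
            # transcript-edge-to-stop; complete when the edge codon is ATG
            edge_is_start = bool(starts) and starts[0] == 0
            yield (frame, frame + 3 * (stop + 1), not edge_is_start, False)
        while si < len(starts) and starts[si] <= stop:
            ci = starts[si]
            if ci > prev_stop and not (prev_stop == -1 and ci == 0):
                yield (frame + 3 * ci, frame + 3 * (stop + 1), False, False)
            si += 1
        prev_stop = stop
    # 3'-partial tail: ATG-to-edge after the last stop
    for ci in starts:
        if ci > prev_stop:
            yield (frame + 3 * ci, frame + 3 * n_codons, False, True)


def find_best_orf(transcript: TranscriptRecord, min_codons: int = 100) -> OrfRecord | None:
    """Best ORF over all six frames, or None if none reaches ``min_codons``.

    Complete (ATG-to-stop) ORFs are preferred over transcript-edge partial
    ones; within a class the longest wins.  ``min_codons`` counts amino
    acids (the stop codon is excluded).  Ties are broken toward the plus
    strand, then the lowest frame, then the smallest start coordinate.
    """
    seq = transcript.sequence.upper()
    best = None
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            for start, end, p5, p3 in _frame_candidates(s, frame):
                prot = translate(s[start:end]).rstrip("*")
                if len(prot) < min_codons or "*" in prot:
                    continue
                key = (p5 or p3, -len(prot), strand == "-", frame, start)
                if best is None or key < best[0]:
                    best = (key, OrfRecord(
                        transcript_id=transcript.transcript_id,
                        strand=strand, frame=frame, start=start, end=end,
                        protein=prot, five_prime_partial=p5, three_prime_partial=p3,
                    ))
    return best[1] if best else None


def group_unigenes(transcripts, coding_ids=None, truth_map=None) -> list:
    """Group transcripts into Unigenes.

    The key is the explicit ``unigene_id`` when present, else ``truth_map``
    (transcript_id -> unigene_id), else the identifier prefix before the
    final ``_seq<k>`` suffix.  Deterministic and order-independent: output is
    sorted by unigene_id, members sorted by transcript_id.
    """
    coding_ids = set(coding_ids or ())
    groups: dict[str, list] = {}
    for t in transcripts:
        if t.unigene_id:
            key = t.unigene_id
        elif truth_map and t.transcript_id in truth_map:
            key = truth_map[t.transcript_id]
        else:
            m = _UNIGENE_RE.match(t.transcript_id)
            if not m:
                raise GroupingError(
                    f"cannot infer a locus for transcript id {t.transcript_id!r}"
                )
            key = m.group("unigene")
        groups.setdefault(key, []).append(t.transcript_id)
    out = []
    for key in sorted(groups):
        members = sorted(groups[key])
        n_coding = sum(1 for m in members if m in coding_ids)
        out.append(UnigeneRecord(
            unigene_id=key, member_transcript_ids=members,
            coding=n_coding >= 1, n_coding_isoforms=n_coding,
        ))
    return out


def classify_clusters(unigenes) -> tuple[int, int]:
    """(clusters, singletons): loci with >=2 vs exactly 1 coding isoform."""
    n_clusters = sum(1 for u in unigenes if u.n_coding_isoforms >= 2)
    n_singletons = sum(1 for u in unigenes if u.n_coding_isoforms == 1)
    return n_clusters, n_singletons


def mean_isoforms_per_coding_unigene(n_coding_transcripts: int, n_coding_unigenes: int) -> float:
    """Average isoform multiplicity of protein-coding loci."""
    if n_coding_unigenes == 0:
        return 0.0
    return n_coding_transcripts / n_coding_unigenes


def assembly_stats(transcripts, orfs, unigenes) -> AssemblyStats:
    """Fill every assembly summary field from the three component lists."""
    n = len(transcripts)
    if n == 0:
        return AssemblyStats(no_coding_unigenes=True)
    lengths = [len(t.sequence) for t in transcripts]
    orf_ids = {o.transcript_id for o in orfs}
    n_with = sum(1 for t in transcripts if t.transcript_id in orf_ids)
    n_uni_with = sum(1 for u in unigenes if u.coding)
    clusters, singletons = classify_clusters(unigenes)
    return AssemblyStats(
        n_transcripts=n,
        mean_length=sum(lengths) / n,
        n50=n50(lengths),
        n_transcripts_with_orf=n_with,
        n_transcripts_without_orf=n - n_with,
        n_unigenes=len(unigenes),
        n_unigenes_with_orf=n_uni_with,
        n_unigenes_without_orf=len(unigenes) - n_uni_with,
        n_clusters=clusters,
        n_singletons=singletons,
        mean_isoforms_per_coding_unigene=mean_isoforms_per_coding_unigene(n_with, n_uni_with),
        no_coding_unigenes=n_uni_with == 0,
    )
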