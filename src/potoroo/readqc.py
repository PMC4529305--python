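"""Read trimming, base-level statistics, and in-silico coverage normalization.

One merged trimming rule set with a fixed order of operations replaces the
chained external trimmers typically used on raw Illumina data:

1. adapter clip at the best read-suffix / adapter-prefix overlap
   (>= 5 nt, >= 90% identity);
2. removal of up to ``trim_ns_right`` trailing Ns;
3. quality trimming of terminal bases below ``qual_trim_threshold`` from
   both ends;
4. rejection of mates shorter than ``min_len`` or with mean quality below
   ``min_mean_qual`` (a pair is rejected when either mate is).

Digital normalization caps k-mer coverage at ``max_cov`` using the median
multiplicity of each mate's canonical k-mers against a streaming count
table, in a single order-dependent pass.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace
from statistics import median
from typing import Iterable, Iterator

from .errors import FormatError
from .sequtil import ascii_to_phred, canonical_kmer
from .synthetic import ReadPairRecord


@dataclass
class TrimParams:
    adapter: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
    qual_trim_threshold: int = 28
    min_mean_qual: float = 28.0
    min_len: int = 20
    trim_ns_right: int = 2
    norm_k: int = 25
    max_cov: int = 30

    def __post_init__(self):
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if min(self.qual_trim_threshold, self.min_mean_qual, self.trim_ns_right,
               self.norm_k, self.max_cov) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class QcStats:
    total_raw_reads: int = 0
    total_clean_reads: int = 0
    total_nucleotides: int = 0
    q20_pct: float = 0.0
    gc_pct: float = 0.0
    q20_read_pct: float = 0.0  # per-read variant: reads whose every base is >= Q20


def _find_adapter(seq: str, adapter: str, min_overlap: int = 5,
                  min_identity: float = 0.9) -> int | None:
    """Best clip point: position where the adapter prefix starts in the read.

    Scores candidate positions by number of matching bases over the overlap
    between the read suffix and the adapter prefix; ties go to the leftmost
    position (longest removal).
    """
    best_pos, best_key = None, (-1, -1.0)
    n = len(seq)
    for i in range(0, n - min_overlap + 1):
        overlap = min(n - i, len(adapter))
        if overlap < min_overlap:
            break
        matches = sum(1 for a, b in zip(seq[i : i + overlap], adapter) if a == b)
        identity = matches / overlap
        if identity >= min_identity and (matches, identity) > best_key:
            best_key, best_pos = (matches, identity), i
    return best_pos


def _trim_mate(seq: str, qual: str, params: TrimParams):
    """Returns (seq, qual, reason); reason is None when the mate survives."""
    if len(seq) != len(qual):
        raise FormatError(f"sequence length {len(seq)} != quality length {len(qual)}")
    pos = _find_adapter(seq, params.adapter)
    if pos is not None:
        seq, qual = seq[:pos], qual[:pos]
    stripped = 0
    while seq and stripped < params.trim_ns_right and seq[-1] in "Nn":
        seq, qual = seq[:-1], qual[:-1]
        stripped += 1
    phred = ascii_to_phred(qual)
    lo, hi = 0, len(seq)
    while lo < hi and phred[lo] < params.qual_trim_threshold:
        lo += 1
    while hi > lo and phred[hi - 1] < params.qual_trim_threshold:
        hi -= 1
    seq, qual, phred = seq[lo:hi], qual[lo:hi], phred[lo:hi]
    if len(seq) < params.min_len:
        return seq, qual, "min_len"
    if sum(phred) / len(phred) < params.min_mean_qual:
        return seq, qual, "mean_qual"
    return seq, qual, None


def trim_read_pair(pair: ReadPairRecord, params: TrimParams):
    """Trim both mates; returns ``(trimmed_pair, None)`` or ``(None, reason)``."""
    s1, q1, r1 = _trim_mate(pair.mate1_seq, pair.mate1_qual, params)
    s2, q2, r2 = _trim_mate(pair.mate2_seq, pair.mate2_qual, params)
    reason = r1 or r2
    if reason is not None:
        return None, reason
    return replace(pair, mate1_seq=s1, mate1_qual=q1, mate2_seq=s2, mate2_qual=q2), None


def trim_pairs(pairs: Iterable[ReadPairRecord], params: TrimParams):
    """Trim a stream; returns (kept pairs, Counter of rejection reasons)."""
    kept, reasons = [], Counter()
    for pair in pairs:
        trimmed, reason = trim_read_pair(pair, params)
        if trimmed is None:
            reasons[reason] += 1
        else:
            kept.append(trimmed)
    return kept, reasons


def base_stats(reads: Iterable[tuple[str, str]], total_raw_reads: int | None = None) -> QcStats:
    """Per-base statistics over a stream of (sequence, quality) records.

    ``q20_pct`` is the percentage of base calls with Phred >= 20; ``gc_pct``
    excludes Ns from numerator and denominator.  ``q20_read_pct`` is the
    per-read alternative (reads with all bases >= Q20).
    """
    n_reads = n_bases = n_q20 = n_gc = n_acgt = n_reads_q20 = 0
    for seq, qual in reads:
        n_reads += 1
        n_bases += len(seq)
        phred = ascii_to_phred(qual)
        good = sum(1 for q in phred if q >= 20)
        n_q20 += good
        if good == len(phred) and phred:
            n_reads_q20 += 1
        up = seq.upper()
        gc = up.count("G") + up.count("C")
        n_gc += gc
        n_acgt += gc + up.count("A") + up.count("T")
    if n_reads == 0:
        warnings.warn("base_stats called on an empty stream")
        return QcStats(total_raw_reads=total_raw_reads or 0)
    return QcStats(
        total_raw_reads=total_raw_reads if total_raw_reads is not None else n_reads,
        total_clean_reads=n_reads,
        total_nucleotides=n_bases,
        q20_pct=100.0 * n_q20 / n_bases if n_bases else 0.0,
        gc_pct=100.0 * n_gc / n_acgt if n_acgt else 0.0,
        q20_read_pct=100.0 * n_reads_q20 / n_reads,
    )


def pair_seq_quals(pairs: Iterable[ReadPairRecord]) -> Iterator[tuple[str, str]]:
    for p in pairs:
        yield p.mate1_seq, p.mate1_qual
        yield p.mate2_seq, p.mate2_qual


def _mate_kmers(seq: str, k: int) -> list[str]:
    return [canonical_kmer(seq[i : i + k]) for i in range(len(seq) - k + 1)]


def normalize_by_kmer_coverage(pairs: Iterable[ReadPairRecord], params: TrimParams) -> list:
    """Single-pass digital normalization to a ``max_cov`` k-mer ceiling.

    A pair is accepted iff the median multiplicity (in the table built from
    previously accepted pairs) of at least one mate's canonical k-mers is
    <= ``max_cov``; accepted pairs then update the table.  The output is a
    subsequence of the input, order-dependent by design.
    """
    k = params.norm_k
    table: Counter = Counter()
    kept = []
    for pair in pairs:
        km1 = _mate_kmers(pair.mate1_seq, k)
        km2 = _mate_kmers(pair.mate2_seq, k)
        accept = False
        for kms in (km1, km2):
            if kms and median(table[km] for km in kms) <= params.max_cov:
                accept = True
                break
        if accept:
            kept.append(pair)
            # one fragment contributes one unit of coverage: each distinct
            # k-mer of the pair is counted once
            for km in set(km1) | set(km2):
                table[km] += 1
    return kept
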