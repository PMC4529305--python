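"""Read-to-transcript assignment, TPM/FPKM estimation, library complexity.

The mapper is a seeded exact/near-exact matcher (31-mer seed, ungapped
extension with a mismatch budget) sufficient for validating abundance
arithmetic on simulated data.  The estimator implements the TPM and FPKM
formulas with three multi-mapper policies: ``unique`` (drop), ``uniform``
(split 1/n) and ``em`` (iterative fractional assignment proportional to
current abundance over effective length).  The EM is a minimal resolver,
not a full generative model: it carries no fragment-length or quality
likelihood.

Library complexity follows the duplicate-detection convention: unique read
(or fragment) start sites divided by mapped reads (or pairs); values near 1
mean no PCR "jackpot" amplification.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .sequtil import revcomp


@dataclass
class MapParams:
    seed_len: int = 31
    max_mismatch: int = 2
    max_fragment: int = 800
    fragment_mean: float = 275.0


@dataclass
class AlignmentRecord:
    pair_id: str
    transcript_id: str
    fragment_start: int
    fragment_end: int
    orientation: str      # F: mate1 on the forward strand; R: flipped
    concordant: bool = True


@dataclass
class AbundanceRecord:
    transcript_id: str
    length: int
    est_count: float
    effective_length: float
    tpm: float
    fpkm: float


@dataclass
class ComplexityResult:
    n_sampled_pairs: int
    n_mapped_pairs: int
    unpaired_complexity: float
    paired_complexity: float
    undefined: bool = False


class TranscriptIndex:
    """Exact k-mer index over transcript sequences for seeded lookup."""

    def __init__(self, transcripts, seed_len: int = 31):
        self.seed_len = seed_len
        self.seqs = {t.transcript_id: t.sequence.upper() for t in transcripts}
        self.table: dict[str, list] = {}
        for tid, seq in self.seqs.items():
            for i in range(len(seq) - seed_len + 1):
                self.table.setdefault(seq[i : i + seed_len], []).append((tid, i))


def _place_mate(seq: str, index: TranscriptIndex, max_mismatch: int):
    """All (tid, start, strand, mismatches) placements of one mate.

    The seed is the first seed_len-mer of the mate (forward strand) or of
    its reverse complement (reverse strand); extension is ungapped.
    """
    out = []
    k = index.seed_len
    for strand, s in (("F", seq), ("R", revcomp(seq))):
        if len(s) < k:
            continue
        for tid, pos in index.table.get(s[:k], ()):
            tseq = index.seqs[tid]
            end = pos + len(s)
            if end > len(tseq):
                continue
            mism = sum(1 for a, b in zip(s, tseq[pos:end]) if a != b)
            if mism <= max_mismatch:
                out.append((tid, pos, strand, mism))
    return out


def map_reads(pairs: Iterable, transcripts, params: MapParams | None = None,
              index: TranscriptIndex | None = None) -> list:
    """Map read pairs; returns AlignmentRecords for all equally-best placements.

    A placement is concordant when both mates land on one transcript in
    inward orientation with a fragment no longer than ``max_fragment``;
    longer fragments are reported with ``concordant=False``.
    """
    params = params or MapParams()
    if index is None:
        index = TranscriptIndex(transcripts, params.seed_len)
    records: list[AlignmentRecord] = []
    for pair in pairs:
        p1 = _place_mate(pair.mate1_seq, index, params.max_mismatch)
        p2 = _place_mate(pair.mate2_seq, index, params.max_mismatch)
        cands = []
        for tid1, pos1, strand1, m1 in p1:
            for tid2, pos2, strand2, m2 in p2:
                if tid1 != tid2 or strand1 == strand2:
                    continue
                if strand1 == "F":
                    fs, fe = pos1, pos2 + len(pair.mate2_seq)
                    orient = "F"
                else:
                    fs, fe = pos2, pos1 + len(pair.mate1_seq)
                    orient = "R"
                if fs > fe - 1:
                    continue  # outward-facing mates
                frag = fe - fs
                cands.append((m1 + m2, tid1, fs, fe, orient, frag <= params.max_fragment))
        if not cands:
            continue
        best = min(c[0] for c in cands)
        seen = set()
        for mism, tid, fs, fe, orient, conc in cands:
            if mism != best or (tid, fs, fe) in seen:
                continue
            seen.add((tid, fs, fe))
            records.append(AlignmentRecord(pair.pair_id, tid, fs, fe, orient, conc))
    return records


def effective_length(length: int, fragment_mean: float) -> float:
    return max(length - fragment_mean + 1.0, 1.0)


def _counts_to_records(counts, transcripts, fragment_mean, n_pairs) -> list:
    el = {t.transcript_id: effective_length(len(t.sequence), fragment_mean)
          for t in transcripts}
    rate_sum = sum(counts.get(tid, 0.0) / el[tid] for tid in el)
    out = []
    for t in transcripts:
        tid = t.transcript_id
        c = counts.get(tid, 0.0)
        tpm = 1e6 * (c / el[tid]) / rate_sum if rate_sum > 0 else 0.0
        fpkm = 1e9 * c / (el[tid] * n_pairs) if n_pairs > 0 else 0.0
        out.append(AbundanceRecord(tid, len(t.sequence), c, el[tid], tpm, fpkm))
    return out


def estimate_abundance(alignments, transcripts, mode: str = "em",
                       fragment_mean: float = 275.0, tol: float = 1e-8,
                       max_iter: int = 1000) -> list:
    """Per-transcript counts, TPM and FPKM from concordant alignments."""
    if mode not in ("unique", "uniform", "em"):
        raise ValueError(f"unknown mode {mode!r}")
    by_pair: dict[str, list[str]] = {}
    for a in alignments:
        if a.concordant:
            by_pair.setdefault(a.pair_id, []).append(a.transcript_id)
    n_pairs = len(by_pair)
    if n_pairs == 0:
        return _counts_to_records({}, transcripts, fragment_mean, 0)
    counts: dict[str, float] = {}
    if mode == "unique":
        for tids in by_pair.values():
            if len(tids) == 1:
                counts[tids[0]] = counts.get(tids[0], 0.0) + 1.0
    elif mode == "uniform":
        for tids in by_pair.values():
            w = 1.0 / len(tids)
            for tid in tids:
                counts[tid] = counts.get(tid, 0.0) + w
    else:
        counts = _em_counts(by_pair, transcripts, fragment_mean, tol, max_iter)
    return _counts_to_records(counts, transcripts, fragment_mean, n_pairs)


def _em_counts(by_pair, transcripts, fragment_mean, tol, max_iter) -> dict:
    tids = [t.transcript_id for t in transcripts]
    idx = {tid: i for i, tid in enumerate(tids)}
    el = np.array([effective_length(len(t.sequence), fragment_mean) for t in transcripts])
    # collapse pairs sharing a placement set
    classes: dict[tuple, int] = {}
    for placements in by_pair.values():
        key = tuple(sorted(set(idx[t] for t in placements)))
        classes[key] = classes.get(key, 0) + 1
    theta = np.full(len(tids), 1.0 / len(tids))
    for _ in range(max_iter):
        c = np.zeros(len(tids))
        for key, n in classes.items():
            ks = np.fromiter(key, dtype=int)
            w = theta[ks] / el[ks]
            s = w.sum()
            if s <= 0:
                w = np.full(len(ks), 1.0 / len(ks))
            else:
                w = w / s
            c[ks] += n * w
        new_theta = c / c.sum()
        delta = np.abs(new_theta - theta).max()
        theta = new_theta
        if delta < tol:
            break
    total = sum(classes.values())
    return {tid: float(theta[i] * total) for i, tid in enumerate(tids) if theta[i] > 0}


def em_log_likelihood(by_pair, transcripts, counts, fragment_mean: float = 275.0) -> float:
    """Data log-likelihood of an assignment state (for monotonicity checks)."""
    el = {t.transcript_id: effective_length(len(t.sequence), fragment_mean)
          for t in transcripts}
    total = sum(counts.values()) or 1.0
    theta = {tid: c / total for tid, c in counts.items()}
    ll = 0.0
    for placements in by_pair.values():
        p = sum(theta.get(tid, 0.0) / el[tid] for tid in set(placements))
        ll += np.log(p) if p > 0 else -np.inf
    return float(ll)


def unigene_abundance(records, grouping: dict) -> list:
    """Roll isoform abundances up to their locus; TPM and counts are summed.

    ``grouping`` maps transcript_id -> unigene_id and must cover every record.
    """
    by_uni: dict[str, AbundanceRecord] = {}
    for r in records:
        if r.transcript_id not in grouping:
            raise KeyError(f"transcript {r.transcript_id} missing from grouping")
        uid = grouping[r.transcript_id]
        agg = by_uni.get(uid)
        if agg is None:
            by_uni[uid] = AbundanceRecord(uid, r.length, r.est_count,
                                          r.effective_length, r.tpm, r.fpkm)
        else:
            agg.est_count += r.est_count
            agg.tpm += r.tpm
            agg.fpkm += r.fpkm
            agg.length = max(agg.length, r.length)
            agg.effective_length = max(agg.effective_length, r.effective_length)
    return [by_uni[k] for k in sorted(by_uni)]


def library_complexity(alignments, sample_size: int, seed: int,
                       include_multi_best: bool = False) -> ComplexityResult:
    """Unique start-site fractions over a random sample of concordant pairs.

    Unpaired complexity counts distinct (transcript, mate orientation,
    mate 5' start) keys over both mates divided by 2 x pairs; paired
    complexity counts distinct (transcript, fragment start, fragment end)
    keys divided by pairs.  Multi-mapped pairs are excluded by default;
    ``include_multi_best`` keeps their first placement instead.
    """
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    by_pair: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        if a.concordant:
            by_pair.setdefault(a.pair_id, []).append(a)
    chosen = []
    for pid in sorted(by_pair):
        placements = by_pair[pid]
        if len(placements) == 1:
            chosen.append(placements[0])
        elif include_multi_best:
            chosen.append(placements[0])
    if not chosen:
        return ComplexityResult(0, 0, 0.0, 0.0, undefined=True)
    rng = np.random.default_rng(seed)
    n = min(sample_size, len(chosen))
    picks = rng.choice(len(chosen), size=n, replace=False)
    sample = [chosen[i] for i in picks]
    mate_keys = set()
    frag_keys = set()
    for a in sample:
        mate_keys.add((a.transcript_id, "F", a.fragment_start))
        mate_keys.add((a.transcript_id, "R", a.fragment_end))
        frag_keys.add((a.transcript_id, a.fragment_start, a.fragment_end))
    return ComplexityResult(
        n_sampled_pairs=n,
        n_mapped_pairs=len(chosen),
        unpaired_complexity=len(mate_keys) / (2 * n),
        paired_complexity=len(frag_keys) / n,
    )


# ------------------------------------------------------------------ file I/O

ALIGNMENT_COLUMNS = ["pair_id", "transcript_id", "fragment_start",
                     "fragment_end", "orientation", "concordant"]
ABUNDANCE_COLUMNS = ["transcript_id", "length", "effective_length",
                     "expected_count", "TPM", "FPKM"]


def write_alignments_tsv(alignments, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(ALIGNMENT_COLUMNS)
        for a in alignments:
            w.writerow([a.pair_id, a.transcript_id, a.fragment_start,
                        a.fragment_end, a.orientation, int(a.concordant)])


def read_alignments_tsv(path) -> list:
    out = []
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        if header != ALIGNMENT_COLUMNS:
            raise ValueError(f"unexpected alignment columns: {header}")
        for row in r:
            out.append(AlignmentRecord(row[0], row[1], int(row[2]), int(row[3]),
                                       row[4], bool(int(row[5]))))
    return out


def read_alignments_sam(path) -> list:
    """Minimal SAM reader: concordant pairs from proper-pair flagged mate 1."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            flag = int(f[1])
            if flag & 0x4 or not flag & 0x2 or not flag & 0x40:
                continue  # unmapped, not proper pair, or not mate 1
            tlen = int(f[8])
            pos = int(f[3]) - 1
            if tlen > 0:
                fs, fe, orient = pos, pos + tlen, "F"
            else:
                fe = pos + len(f[9])
                fs, orient = fe + tlen, "R"
            out.append(AlignmentRecord(f[0], f[2], fs, fe, orient, True))
    return out


def write_abundance_tsv(records, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(ABUNDANCE_COLUMNS)
        for r in records:
            w.writerow([r.transcript_id, r.length, f"{r.effective_length:.2f}",
                        f"{r.est_count:.2f}", f"{r.tpm:.2f}", f"{r.fpkm:.2f}"])
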