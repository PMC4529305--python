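"""Exon-structure inference by exact-match chaining of mRNA against genomic DNA.

Exons are recovered as a collinear chain of exact match blocks (length >=
``min_block``) between the mature transcript and the genomic sequence,
chosen by dynamic programming to maximise total transcript coverage.
Genomic gaps between chained blocks are introns; canonical GT..AG splice
motifs are annotated when present but never enforced.  The approach assumes
transcript and genome are identical over exons (same species or a very
close relative); it is an exact chainer, not a mismatch-tolerant spliced
aligner.

The comparison table assigns exon ordinals along the genome by interval
overlap across isoforms, producing the familiar exon x isoform matrix of
lengths with absences and length variants flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sequtil import revcomp


@dataclass
class ExonBlock:
    genome_start: int
    genome_end: int
    tx_start: int
    tx_end: int
    exon_index: int = 0          # 1-based ordinal along the genome
    donor_acceptor: str = ""     # e.g. "GT..AG" of the downstream intron
    strand: str = "+"            # orientation of the mrna against the genome

    def __post_init__(self):
        if self.genome_end - self.genome_start != self.tx_end - self.tx_start:
            raise ValueError("exon block must be gap-free")


@dataclass
class ExonComparison:
    ordinals: list               # [(genome_start, genome_end), ...] per ordinal
    table: dict                  # isoform -> [length | None, ...]
    variant: list = field(default_factory=list)  # per-ordinal bool


def _match_blocks(mrna: str, genome: str, min_block: int) -> list:
    """Maximal exact match blocks of length >= min_block, via seeded extension."""
    seeds: dict[str, list] = {}
    for j in range(len(genome) - min_block + 1):
        seeds.setdefault(genome[j : j + min_block], []).append(j)
    # per-diagonal match runs: collect seed hits grouped by (j - i)
    diag_hits: dict[int, list] = {}
    for i in range(len(mrna) - min_block + 1):
        for j in seeds.get(mrna[i : i + min_block], ()):
            diag_hits.setdefault(j - i, []).append(i)
    blocks = []
    for diag, starts in diag_hits.items():
        starts.sort()
        run_start = prev = starts[0]
        for i in starts[1:] + [None]:
            if i is not None and i == prev + 1:
                prev = i
                continue
            blocks.append((run_start, prev + min_block, run_start + diag, prev + min_block + diag))
            if i is not None:
                run_start = prev = i
    return sorted(set(blocks))


def infer_exons(mrna: str, genome: str, min_block: int = 20, min_intron: int = 30) -> list:
    """Chain of exon blocks maximising transcript coverage.

    Returns ExonBlocks ordered along the transcript (equivalently the
    genome).  Empty when no exact match of ``min_block`` exists.  Ties in
    coverage are broken toward fewer blocks, then leftmost genomic starts.
    """
    if not mrna or not genome:
        raise ValueError("mrna and genome must be non-empty")
    mrna, genome = mrna.upper(), genome.upper()
    best_blocks: list = []
    best_cov = -1
    for strand, query in (("+", mrna), ("-", revcomp(mrna))):
        cands = _match_blocks(query, genome, min_block)
        if not cands:
            continue
        blocks = _chain_and_place(query, genome, cands, min_intron, strand)
        cov = sum(b.tx_end - b.tx_start for b in blocks)
        if cov > best_cov:
            best_cov, best_blocks = cov, blocks
    return best_blocks


def _chain_and_place(mrna: str, genome: str, cands: list,
                     min_intron: int, strand: str) -> list:
    chain = chain_blocks(cands)
    trimmed = _trim_chain(chain)
    placed = _place_junctions(trimmed, genome, min_intron)
    # merge blocks adjacent in both coordinate systems
    merged = [list(placed[0])]
    for ts, te, gs, ge in placed[1:]:
        if merged[-1][1] == ts and merged[-1][3] == gs:
            merged[-1][1], merged[-1][3] = te, ge
        else:
            merged.append([ts, te, gs, ge])
    out = []
    for idx, (ts, te, gs, ge) in enumerate(merged, start=1):
        motif = ""
        if idx < len(merged):
            next_gs = merged[idx][2]
            if next_gs - ge >= min_intron:
                intron = genome[ge:next_gs]
                motif = f"{intron[:2]}..{intron[-2:]}"
        out.append(ExonBlock(genome_start=gs, genome_end=ge, tx_start=ts,
                             tx_end=te, exon_index=idx, donor_acceptor=motif,
                             strand=strand))
    return out


def chain_gain(prev_block: tuple | None, block: tuple) -> int:
    """Transcript coverage a block adds after a predecessor, or -1 if unchainable.

    Maximal match blocks around a splice junction overlap by a few
    nucleotides when exon ends resemble intron ends; the later block is
    conceptually trimmed at its front so chains stay collinear.
    """
    ts, te, gs, ge = block
    if prev_block is None:
        return te - ts
    tjs, tje, gjs, gje = prev_block
    overlap = max(0, tje - ts, gje - gs)
    gain = (te - ts) - overlap
    # require genomic order consistent with the transcript order after trim
    if gain <= 0 or gs + overlap < gje or ts + overlap < tje:
        return -1
    return gain


def chain_blocks(cands: list) -> list:
    """Collinear chain of candidate blocks maximising union transcript coverage.

    Dynamic programming over blocks sorted by transcript start; ties break
    toward fewer blocks, then leftmost chain end.
    """
    cands = sorted(cands)
    n = len(cands)
    score = [c[1] - c[0] for c in cands]
    nblocks = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            gain = chain_gain(cands[j], cands[i])
            if gain < 0:
                continue
            cand_score = score[j] + gain
            if (cand_score, -(nblocks[j] + 1)) > (score[i], -nblocks[i]):
                score[i] = cand_score
                nblocks[i] = nblocks[j] + 1
                prev[i] = j
    best = max(range(n), key=lambda i: (score[i], -nblocks[i], -cands[i][0]))
    chain = []
    i = best
    while i != -1:
        chain.append(cands[i])
        i = prev[i]
    chain.reverse()
    return chain


def _trim_chain(chain: list) -> list:
    """Resolve overlaps by trimming each block's front against its predecessor."""
    out = [tuple(chain[0])]
    for ts, te, gs, ge in chain[1:]:
        _, ptje, _, pgje = out[-1]
        o = max(0, ptje - ts, pgje - gs)
        out.append((ts + o, te, gs + o, ge))
    return out


def _place_junctions(chain: list, genome: str, min_intron: int) -> list:
    """Slide ambiguous splice junctions to canonical GT..AG when possible.

    When maximal blocks overlap around a junction the cut point is free
    within the overlap; all placements spell the same transcript.  The cut
    whose intron starts with GT and ends with AG is preferred; otherwise
    the junction stays at the default (earlier block extended fully).
    """
    if len(chain) < 2:
        return chain
    blocks = [list(b) for b in chain]
    for i in range(len(blocks) - 1):
        ts, te, gs, ge = blocks[i]
        nts, nte, ngs, nge = blocks[i + 1]
        if ngs - ge < min_intron or te != nts:
            continue
        # moving the cut left by k shifts the last k exon bases across the
        # junction; legal while those genome bases agree on both sides
        max_k = 0
        while (max_k < te - ts - 1 and ge - max_k - 1 >= 0 and ngs - max_k - 1 >= 0
               and genome[ge - max_k - 1] == genome[ngs - max_k - 1]):
            max_k += 1
        chosen = 0
        for k in range(0, max_k + 1):
            g_end = ge - k       # intron start
            g_start = ngs - k    # intron end (exclusive)
            if genome[g_end : g_end + 2] == "GT" and genome[g_start - 2 : g_start] == "AG":
                chosen = k
                break
        if chosen:
            blocks[i][1] -= chosen
            blocks[i][3] -= chosen
            blocks[i + 1][0] -= chosen
            blocks[i + 1][2] -= chosen
    return [tuple(b) for b in blocks]


def chain_coverage(blocks) -> int:
    return sum(b.tx_end - b.tx_start for b in blocks)


def uncovered_ends(mrna: str, blocks) -> tuple[int, int]:
    """Unchained transcript prefix/suffix lengths (0, 0 for full coverage)."""
    if not blocks:
        return len(mrna), len(mrna)
    return blocks[0].tx_start, len(mrna) - blocks[-1].tx_end


def compare_exon_tables(chains: dict) -> ExonComparison:
    """Exon x isoform presence/length matrix over a shared genomic sequence.

    Exon ordinals are connected components of genomic intervals overlapping
    by >= 1 nt across isoforms, ordered by genomic start.  Cells hold the
    isoform's block length or None when absent; an ordinal is flagged
    variant when lengths differ or any isoform lacks it.
    """
    intervals = []
    for iso in sorted(chains):
        for b in chains[iso]:
            intervals.append((b.genome_start, b.genome_end, iso, b))
    if not intervals:
        return ExonComparison(ordinals=[], table={iso: [] for iso in chains})
    intervals.sort(key=lambda t: (t[0], t[1]))
    clusters: list[list] = [[intervals[0]]]
    cur_end = intervals[0][1]
    for iv in intervals[1:]:
        if iv[0] < cur_end:       # >= 1 nt overlap with the running cluster
            clusters[-1].append(iv)
            cur_end = max(cur_end, iv[1])
        else:
            clusters.append([iv])
            cur_end = iv[1]
    ordinals = [(min(iv[0] for iv in cl), max(iv[1] for iv in cl)) for cl in clusters]
    table = {iso: [None] * len(clusters) for iso in chains}
    for ordinal, cl in enumerate(clusters):
        for gs, ge, iso, b in cl:
            if table[iso][ordinal] is not None:
                raise ValueError(
                    f"isoform {iso} has two blocks in exon ordinal {ordinal + 1}"
                )
            table[iso][ordinal] = ge - gs
    variant = []
    for ordinal in range(len(clusters)):
        lengths = {table[iso][ordinal] for iso in table}
        variant.append(len(lengths) > 1)
    return ExonComparison(ordinals=ordinals, table=table, variant=variant)


def blocks_to_bed12(name: str, chrom: str, blocks) -> str:
    """One BED12 line describing a chained isoform."""
    if not blocks:
        raise ValueError("empty chain")
    start = blocks[0].genome_start
    end = blocks[-1].genome_end
    sizes = ",".join(str(b.genome_end - b.genome_start) for b in blocks)
    starts = ",".join(str(b.genome_start - start) for b in blocks)
    return "\t".join(map(str, [chrom, start, end, name, 0, "+", start, end,
                               "0,0,0", len(blocks), sizes, starts]))
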