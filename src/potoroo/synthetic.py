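"""Ground-truthed simulator: genome, spliced isoforms, paired-end reads.

The generator emulates the statistical structure of a poly(A)-selected,
non-stranded paired-end library sequenced from a multi-isoform
transcriptome: spliced genes with introns, coding and non-coding loci, a
bimodal log-abundance distribution over coding loci, ~275 bp inserts read
with 150 nt mates, linear quality decay, and adapter read-through when the
insert is shorter than the read.  Every record carries its ground truth so
downstream stages (trimming, mapping, abundance estimation, ORF calling,
exon inference, siRNA screening) can be validated exactly.

Coordinates are 0-based, half-open throughout.  Minus-strand genes are
stored as plus-strand exon intervals with a strand flag; the mature
transcript is the reverse complement of the concatenated exon sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .errors import SizingError
from .sequtil import revcomp, write_fasta, write_fastq, phred_to_ascii, STOP_CODONS

# 33-nt prefix of a standard library adapter; identity is irrelevant to the
# algorithms, any string is accepted via SimConfig.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# sense codons only (no stop), used to build clean open reading frames
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


@dataclass
class SimConfig:
    """All knobs of the simulator; a fixed seed gives byte-identical output.

    Abundances: coding loci draw log10 TPM from a two-component Gaussian
    mixture (weight, mean1, sd1, mean2, sd2) which reproduces the bimodal
    shape seen in deeply sequenced transcriptomes; non-coding loci draw from
    a single low component (mean, sd).
    """

    n_genes: int = 50
    isoform_mean: float = 3.7          # geometric distribution mean
    coding_fraction: float = 0.5
    coding_mixture: tuple = (0.5, 0.3, 0.4, 1.5, 0.5)
    noncoding_component: tuple = (0.0, 0.4)
    fragment_mean: float = 275.0
    fragment_sd: float = 25.0
    read_len: int = 150
    adapter: str = DEFAULT_ADAPTER
    qual_start: float = 38.0           # mean Phred at first cycle
    qual_end: float = 30.0             # mean Phred at last cycle
    qual_jitter_sd: float = 3.0
    qual_floor: int = 2
    seed: int = 0
    # gene geometry
    min_intron: int = 30
    exon_count_range: tuple = (3, 8)
    min_exon: int = 40
    orf_codon_range: tuple = (120, 400)
    utr5_range: tuple = (50, 200)
    utr3_range: tuple = (100, 300)
    intron_range: tuple = (60, 400)
    intergenic_range: tuple = (100, 300)
    noncoding_len_range: tuple = (400, 1500)
    genome_length: int | None = None   # None: sized automatically

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items() if k in known}
        return cls(**kwargs)


@dataclass
class GeneModel:
    """A spliced gene placed on a chromosome.

    ``exons`` are plus-strand genomic intervals sorted by start regardless of
    ``strand``; ``orf_span`` is in mature-transcript coordinates of the
    canonical (all-exon) isoform and its length is divisible by 3.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list          # [(start, end), ...] 0-based half-open, sorted
    coding: bool
    orf_span: tuple | None = None

    def mature_sequence(self, genome: dict) -> str:
        chrom = genome[self.chrom]
        seq = "".join(chrom[s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class IsoformTruth:
    transcript_id: str
    gene_id: str
    exon_choice: list    # genomic intervals actually used, sorted by start
    sequence: str
    true_tpm: float
    coding: bool = False


@dataclass
class ReadPairRecord:
    pair_id: str
    mate1_seq: str
    mate2_seq: str
    mate1_qual: str
    mate2_qual: str
    truth: tuple         # (transcript_id, fragment_start, fragment_end)
    flipped: bool = False


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # one independent, reproducible stream per stage
    return np.random.default_rng([stage, config.seed])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _strip_internal_starts(utr: str) -> str:
    # avoid planting ATG in UTRs so the designed ORF stays the longest one
    return utr.replace("ATG", "ACG")


def _make_mature(rng: np.random.Generator, config: SimConfig, coding: bool) -> tuple[str, tuple | None]:
    if not coding:
        n = int(rng.integers(config.noncoding_len_range[0], config.noncoding_len_range[1] + 1))
        return _random_seq(rng, n), None
    utr5 = _strip_internal_starts(_random_seq(rng, int(rng.integers(*_inc(config.utr5_range)))))
    utr3 = _random_seq(rng, int(rng.integers(*_inc(config.utr3_range))))
    n_codons = int(rng.integers(*_inc(config.orf_codon_range)))
    body = "".join(str(c) for c in rng.choice(_SENSE_CODONS, size=n_codons - 2))
    orf = "ATG" + body + str(rng.choice(list(STOP_CODONS)))
    mature = utr5 + orf + utr3
    span = (len(utr5), len(utr5) + len(orf))
    assert (span[1] - span[0]) % 3 == 0
    return mature, span


def _inc(rng_pair: tuple) -> tuple:
    return rng_pair[0], rng_pair[1] + 1


def _split_exons(rng: np.random.Generator, length: int, n_exons: int, min_exon: int) -> list:
    """Cut [0, length) into n_exons pieces each >= min_exon (fewer if too short)."""
    n_exons = max(1, min(n_exons, length // min_exon))
    while n_exons > 1:
        free = length - n_exons * min_exon
        cuts = np.sort(rng.integers(0, free + 1, size=n_exons - 1))
        bounds = [0]
        for i, c in enumerate(cuts):
            bounds.append(int(c) + (i + 1) * min_exon)
        bounds.append(length)
        if all(b - a >= min_exon for a, b in zip(bounds, bounds[1:])):
            return list(zip(bounds, bounds[1:]))
        n_exons -= 1  # pragma: no cover - fallback for tiny lengths
    return [(0, length)]


def generate_genome(config: SimConfig) -> tuple[dict, list]:
    """Build one chromosome carrying ``n_genes`` non-overlapping genes.

    Returns ``({chrom: sequence}, [GeneModel, ...])``.  Raises
    :class:`SizingError` if ``genome_length`` is set and too small.
    """
    if config.n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = _rng(config, 1)
    chrom_parts: list[str] = []
    genes: list[GeneModel] = []
    pos = 0
    n_coding = int(round(config.n_genes * config.coding_fraction))
    for g in range(config.n_genes):
        spacer = _random_seq(rng, int(rng.integers(*_inc(config.intergenic_range))))
        chrom_parts.append(spacer)
        pos += len(spacer)
        coding = g < n_coding
        mature, orf_span = _make_mature(rng, config, coding)
        n_exons = int(rng.integers(*_inc(config.exon_count_range)))
        pieces = _split_exons(rng, len(mature), n_exons, config.min_exon)
        strand = "+" if rng.random() < 0.5 else "-"
        # transcript-order exon sequences
        tx_exons = [mature[a:b] for a, b in pieces]
        genomic_exons = tx_exons if strand == "+" else [revcomp(s) for s in reversed(tx_exons)]
        exon_intervals = []
        for i, exon_seq in enumerate(genomic_exons):
            if i > 0:
                ilen = int(rng.integers(*_inc(config.intron_range)))
                ilen = max(ilen, config.min_intron)
                intron = "GT" + _random_seq(rng, ilen - 4) + "AG"
                chrom_parts.append(intron)
                pos += ilen
            exon_intervals.append((pos, pos + len(exon_seq)))
            chrom_parts.append(exon_seq)
            pos += len(exon_seq)
        genes.append(GeneModel(
            gene_id=f"g{g + 1}", chrom="chr1", strand=strand,
            exons=exon_intervals, coding=coding, orf_span=orf_span,
        ))
    tail = _random_seq(rng, int(rng.integers(*_inc(config.intergenic_range))))
    chrom_parts.append(tail)
    pos += len(tail)
    if config.genome_length is not None and pos > config.genome_length:
        raise SizingError(
            f"placed genes need {pos} nt but genome_length={config.genome_length}; "
            "reduce n_genes or raise genome_length"
        )
    genome = {"chr1": "".join(chrom_parts)}
    for gene in genes:
        assert gene.mature_sequence(genome)  # placement sanity
    return genome, genes


def _isoform_sequence(gene: GeneModel, genome: dict, intervals: list) -> str:
    chrom = genome[gene.chrom]
    seq = "".join(chrom[s:e] for s, e in intervals)
    return revcomp(seq) if gene.strand == "-" else seq


def generate_transcriptome(genes: list, genome: dict, config: SimConfig) -> list:
    """Emit >=1 isoform per gene with mixture-drawn, renormalised TPMs.

    Isoform 1 is the canonical all-exon transcript; variants skip one
    internal exon or shorten the 3'-terminal exon.  Coding status of each
    isoform is true iff the gene's ORF sequence survives verbatim.
    """
    rng = _rng(config, 2)
    isoforms: list[IsoformTruth] = []
    unigene_rows: list[tuple[int, int]] = []  # (first_index, count) per gene
    for gene in genes:
        n_iso = int(min(rng.geometric(1.0 / config.isoform_mean), 6))
        variants: list[list] = [list(gene.exons)]
        for _ in range(n_iso - 1):
            intervals = [list(iv) for iv in gene.exons]
            if len(intervals) >= 3 and rng.random() < 0.6:
                drop = int(rng.integers(1, len(intervals) - 1))
                intervals.pop(drop)
            elif len(intervals) == 1 and rng.random() < 0.6:
                warnings.warn(
                    f"gene {gene.gene_id} has a single exon; skip-variant "
                    "falls back to an identical isoform"
                )
            else:
                # shorten the transcript-3' terminal exon
                ti = -1 if gene.strand == "+" else 0
                s, e = intervals[ti]
                room = (e - s) - config.min_exon
                if room > 10:
                    d = int(rng.integers(10, room + 1))
                    if gene.strand == "+":
                        intervals[ti] = [s, e - d]
                    else:
                        intervals[ti] = [s + d, e]
            variants.append([tuple(iv) for iv in intervals])
        first = len(isoforms)
        orf_seq = None
        if gene.coding:
            mature = gene.mature_sequence(genome)
            orf_seq = mature[gene.orf_span[0] : gene.orf_span[1]]
        for k, intervals in enumerate(variants, start=1):
            seq = _isoform_sequence(gene, genome, intervals)
            coding = bool(orf_seq) and orf_seq in seq
            isoforms.append(IsoformTruth(
                transcript_id=f"{gene.gene_id}_seq{k}",
                gene_id=gene.gene_id,
                exon_choice=[tuple(iv) for iv in intervals],
                sequence=seq,
                true_tpm=0.0,
                coding=coding,
            ))
        unigene_rows.append((first, len(variants)))
    if not isoforms:
        return isoforms
    # locus-level abundances from the mixture, split over isoforms
    w, m1, s1, m2, s2 = config.coding_mixture
    m0, s0 = config.noncoding_component
    weights = np.empty(len(isoforms))
    for gene, (first, count) in zip(genes, unigene_rows):
        if gene.coding:
            if rng.random() < w:
                log_tpm = rng.normal(m1, s1)
            else:
                log_tpm = rng.normal(m2, s2)
        else:
            log_tpm = rng.normal(m0, s0)
        unigene_tpm = 10.0 ** log_tpm
        split = rng.dirichlet(np.ones(count))
        weights[first : first + count] = unigene_tpm * split
    weights *= 1e6 / weights.sum()
    for iso, tpm in zip(isoforms, weights):
        iso.true_tpm = float(tpm)
    return isoforms


def _quality_vector(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    pos = np.arange(n)
    denom = max(config.read_len - 1, 1)
    mean = config.qual_start + (config.qual_end - config.qual_start) * pos / denom
    q = mean + rng.normal(0.0, config.qual_jitter_sd, size=n)
    return np.clip(np.rint(q), config.qual_floor, 40).astype(int)


def _apply_errors(rng: np.random.Generator, seq: str, quals: np.ndarray) -> str:
    p_err = 10.0 ** (-quals / 10.0)
    hits = np.nonzero(rng.random(len(seq)) < p_err)[0]
    if len(hits) == 0:
        return seq
    chars = list(seq)
    for i in hits:
        alt = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alt[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_reads(isoforms: list, config: SimConfig, n_pairs: int,
                   error_free: bool = False) -> list:
    """Draw ``n_pairs`` read pairs.

    Fragment counts are multinomial with probability proportional to
    ``true_tpm * max(length - fragment_mean + 1, 1)``; fragment lengths are
    Normal(fragment_mean, fragment_sd) truncated to [read_len/2, length];
    mates read inward from the fragment ends; fragments shorter than the
    read run into the adapter; orientation flips with probability 0.5
    (non-stranded library); substitutions are injected at the per-base rate
    implied by each quality value (suppressed when ``error_free``).
    """
    rng = _rng(config, 3)
    min_frag = max(int(np.ceil(config.read_len / 2)), 1)
    usable = []
    for iso in isoforms:
        if len(iso.sequence) < min_frag:
            warnings.warn(
                f"isoform {iso.transcript_id} ({len(iso.sequence)} nt) shorter than "
                f"the minimum fragment {min_frag}; excluded from sampling"
            )
        elif iso.true_tpm > 0:
            usable.append(iso)
    total = sum(i.true_tpm for i in isoforms)
    if total <= 0:
        raise ValueError("total true_tpm must be > 0")
    w = np.array([
        i.true_tpm * max(len(i.sequence) - config.fragment_mean + 1, 1.0)
        for i in usable
    ])
    counts = rng.multinomial(n_pairs, w / w.sum())
    # adapter followed by random filler covers worst-case read-through
    reads: list[ReadPairRecord] = []
    pair_no = 0
    for iso, c in zip(usable, counts):
        tx = iso.sequence
        L = len(tx)
        for _ in range(int(c)):
            flen = _draw_fragment(rng, config, L, min_frag)
            start = int(rng.integers(0, L - flen + 1))
            frag = tx[start : start + flen]
            flipped = bool(rng.random() < 0.5)
            if flipped:
                frag = revcomp(frag)
            m1 = _read_through(rng, frag, config)
            m2 = _read_through(rng, revcomp(frag), config)
            q1 = _quality_vector(rng, config, len(m1))
            q2 = _quality_vector(rng, config, len(m2))
            if not error_free:
                m1 = _apply_errors(rng, m1, q1)
                m2 = _apply_errors(rng, m2, q2)
            reads.append(ReadPairRecord(
                pair_id=f"pair{pair_no}",
                mate1_seq=m1, mate2_seq=m2,
                mate1_qual=phred_to_ascii(q1), mate2_qual=phred_to_ascii(q2),
                truth=(iso.transcript_id, start, start + flen),
                flipped=flipped,
            ))
            pair_no += 1
    return reads


def _draw_fragment(rng: np.random.Generator, config: SimConfig, L: int, lo: int) -> int:
    hi = L
    if config.fragment_sd <= 0:
        return int(min(max(round(config.fragment_mean), lo), hi))
    for _ in range(100):
        f = int(round(rng.normal(config.fragment_mean, config.fragment_sd)))
        if lo <= f <= hi:
            return f
    return int(min(max(round(config.fragment_mean), lo), hi))


def _read_through(rng: np.random.Generator, frag: str, config: SimConfig) -> str:
    n = config.read_len
    if len(frag) >= n:
        return frag[:n]
    fill = config.adapter
    while len(frag) + len(fill) < n:
        fill += _random_seq(rng, n - len(frag) - len(fill))
    return frag + fill[: n - len(frag)]


# ---------------------------------------------------------------- file output

def write_truth_tables(isoforms: list, reads: list | None, outdir) -> None:
    """TSV truth tables: isoform TPMs and per-pair fragment coordinates."""
    import os

    with open(os.path.join(outdir, "isoform_truth.tsv"), "w") as fh:
        fh.write("transcript_id\tgene_id\tlength\tcoding\ttrue_tpm\n")
        for iso in isoforms:
            fh.write(f"{iso.transcript_id}\t{iso.gene_id}\t{len(iso.sequence)}\t"
                     f"{int(iso.coding)}\t{iso.true_tpm:.6f}\n")
    if reads is not None:
        with open(os.path.join(outdir, "fragment_truth.tsv"), "w") as fh:
            fh.write("pair_id\ttranscript_id\tfragment_start\tfragment_end\tflipped\n")
            for r in reads:
                t, s, e = r.truth
                fh.write(f"{r.pair_id}\t{t}\t{s}\t{e}\t{int(r.flipped)}\n")


def write_outputs(genome: dict, isoforms: list, reads: list, outdir, config: SimConfig) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    write_fasta(os.path.join(outdir, "genome.fasta"), sorted(genome.items()))
    write_fasta(os.path.join(outdir, "transcripts.fasta"),
                [(i.transcript_id, i.sequence) for i in isoforms])
    write_fastq(os.path.join(outdir, "reads_1.fastq"),
                [(r.pair_id + "/1", r.mate1_seq, r.mate1_qual) for r in reads])
    write_fastq(os.path.join(outdir, "reads_2.fastq"),
                [(r.pair_id + "/2", r.mate2_seq, r.mate2_qual) for r in reads])
    write_truth_tables(isoforms, reads, outdir)
    config.to_yaml(os.path.join(outdir, "sim_config.yaml"))
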