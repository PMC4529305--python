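"""Small sequence helpers shared across modules."""

from __future__ import annotations

import gzip
from typing import IO, Iterable, Iterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = ("TAA", "TAG", "TGA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide string codon by codon; unknown codons become X."""
    n = len(seq) - len(seq) % 3
    return "".join(STANDARD_TABLE.get(seq[i : i + 3], "X") for i in range(0, n, 3))


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def gc_percent(seq: str) -> float:
    """GC over unambiguous bases only; 0.0 when no A/C/G/T present."""
    gc = seq.count("G") + seq.count("C") + seq.count("g") + seq.count("c")
    at = seq.count("A") + seq.count("T") + seq.count("a") + seq.count("t")
    denom = gc + at
    return 100.0 * gc / denom if denom else 0.0


def _open(path, mode: str = "rt") -> IO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with _open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    with _open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out.append((name, "".join(chunks)))
    return out


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> None:
    with _open(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    with _open(path) as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            if len(seq) != len(qual):
                raise ValueError(f"length mismatch for record {header}")
            yield header[1:], seq, qual


def phred_to_ascii(quals) -> str:
    return "".join(chr(int(q) + 33) for q in quals)


def ascii_to_phred(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]
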