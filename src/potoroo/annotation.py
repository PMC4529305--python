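"""Annotation-report parsing and abundance-stratified summaries.

The report format is a tab-separated table with one row per transcript-level
annotation: columns ``component`` (locus id), ``trans_derived`` (transcript
id), ``prot_id``, ``TopBlastHit``, ``Pfam``, ``eggnog``, ``gene_ontology``
and ``prot_seq``.  Within a column, multiple hits are backtick (`)
delimited, subfields are caret (^) delimited, and missing values are a
single dot (.).  Example gene-ontology cell::

    GO:0006355^P^regulation of transcription`GO:0005515^F^protein binding

Summaries reproduce common survey plots: the annotation rate of loci above
and below an abundance rank cutoff, the most frequent GO terms with the
number of loci they span, and five-number box/whisker statistics of TPM
distributions (whiskers at the most extreme data points within 1.5 IQR of
the quartiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

COLUMNS = ["component", "trans_derived", "prot_id", "TopBlastHit",
           "Pfam", "eggnog", "gene_ontology", "prot_seq"]

_ASPECTS = {"P", "F", "C"}


@dataclass
class AnnotationRecord:
    unigene_id: str
    transcript_id: str = ""
    protein_id: str | None = None
    top_hit: tuple | None = None
    pfam_hits: list = field(default_factory=list)
    eggnog: tuple | None = None
    go_terms: list = field(default_factory=list)  # (term_id, aspect, name)
    protein_seq: str | None = None


@dataclass
class TermFrequency:
    term_id: str
    name: str
    n_unigenes: int
    cumulative_unique_unigenes: int


@dataclass
class DistributionSummary:
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: list


def _split_multi(cell: str) -> list[str]:
    return [] if cell == "." else cell.split("`")


def _parse_go_cell(cell: str, line_no: int) -> list:
    terms = []
    seen = set()
    for part in _split_multi(cell):
        sub = part.split("^")
        if len(sub) < 3:
            raise FormatError(f"line {line_no}: malformed GO entry {part!r}")
        term_id, aspect, name = sub[0], sub[1], "^".join(sub[2:])
        if aspect not in _ASPECTS:
            raise FormatError(f"line {line_no}: invalid GO aspect {aspect!r}")
        if term_id not in seen:
            seen.add(term_id)
            terms.append((term_id, aspect, name))
    return terms


def parse_annotation_report(path) -> list:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != COLUMNS:
            raise FormatError(f"line 1: expected columns {COLUMNS}, got {header}")
        for line_no, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(COLUMNS):
                raise FormatError(
                    f"line {line_no}: expected {len(COLUMNS)} columns, got {len(cells)}"
                )
            comp, trans, prot, top, pfam, egg, go, pseq = cells
            top_hit = tuple(top.split("^")) if top != "." else None
            eggnog = tuple(egg.split("^", 1)) if egg != "." else None
            records.append(AnnotationRecord(
                unigene_id=comp,
                transcript_id=trans,
                protein_id=None if prot == "." else prot,
                top_hit=top_hit,
                pfam_hits=[tuple(p.split("^")) for p in _split_multi(pfam)],
                eggnog=eggnog,
                go_terms=_parse_go_cell(go, line_no),
                protein_seq=None if pseq == "." else pseq,
            ))
    return records


def write_annotation_report(records, path) -> None:
    def cell(value) -> str:
        return value if value else "."

    with open(path, "w") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join([
                r.unigene_id,
                r.transcript_id,
                cell(r.protein_id),
                cell("^".join(r.top_hit) if r.top_hit else ""),
                cell("`".join("^".join(p) for p in r.pfam_hits)),
                cell("^".join(r.eggnog) if r.eggnog else ""),
                cell("`".join(f"{t}^{a}^{n}" for t, a, n in r.go_terms)),
                cell(r.protein_seq),
            ]) + "\n")


def _annotated_unigenes(records, aspect: str = "P") -> set:
    return {r.unigene_id for r in records
            if any(a == aspect for _, a, _ in r.go_terms)}


def annotation_rate_by_abundance(unigene_tpms: dict, records, rank_cutoff: int,
                                 aspect: str = "P") -> list:
    """Annotation rate in the top ``rank_cutoff`` loci by TPM vs the rest.

    Returns two (n_annotated, n_total, fraction) triples; a locus counts as
    annotated when it carries at least one GO term of ``aspect``
    (biological process by default).  Ranking ties break by id.
    """
    if rank_cutoff < 1:
        raise ValueError("rank_cutoff must be >= 1")
    annotated = _annotated_unigenes(records, aspect)
    ranked = sorted(unigene_tpms, key=lambda u: (-unigene_tpms[u], u))
    strata = [ranked[:rank_cutoff], ranked[rank_cutoff:]]
    out = []
    for ids in strata:
        n_ann = sum(1 for u in ids if u in annotated)
        out.append((n_ann, len(ids), n_ann / len(ids) if ids else 0.0))
    return out


def term_frequency(records, top_k: int, aspect: str = "P") -> tuple[list, int]:
    """Most frequent GO terms and the number of distinct loci they span.

    Terms are ranked by the number of loci annotated with them (ties by
    term id); the second return value is the size of the union of loci
    covered by the top ``top_k`` terms.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    term_unigenes: dict[str, set] = {}
    names: dict[str, str] = {}
    for r in records:
        for term_id, a, name in r.go_terms:
            if a != aspect:
                continue
            term_unigenes.setdefault(term_id, set()).add(r.unigene_id)
            names.setdefault(term_id, name)
    ranked = sorted(term_unigenes, key=lambda t: (-len(term_unigenes[t]), t))[:top_k]
    covered: set = set()
    out = []
    for term_id in ranked:
        covered |= term_unigenes[term_id]
        out.append(TermFrequency(term_id, names[term_id],
                                 len(term_unigenes[term_id]), len(covered)))
    return out, len(covered)


def tpm_distribution_summary(values) -> DistributionSummary:
    """Box/whisker five-number summary with interpolated quartiles.

    Whiskers sit on the most extreme data points within 1.5 IQR of the
    quartiles; points beyond them are outliers.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarise an empty distribution")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    whisker_lo = float(inside.min())
    whisker_hi = float(inside.max())
    outliers = sorted(float(v) for v in vals[(vals < lo_fence) | (vals > hi_fence)])
    return DistributionSummary(float(med), float(q1), float(q3),
                               whisker_lo, whisker_hi, outliers)


def synthesize_annotations(unigenes, rng, n_terms: int = 40,
                           annotate_fraction: float = 0.5) -> list:
    """Synthetic annotation records for coding loci (fixture generator).

    Draws GO biological-process term usage from a Zipf-like distribution so
    term-frequency summaries have realistic shape.  Clearly synthetic: term
    ids and names are generated, not taken from any ontology release.
    """
    pool = [(f"GO:{7000000 + i:07d}", "P", f"synthetic process {i}") for i in range(n_terms)]
    weights = 1.0 / np.arange(1, n_terms + 1)
    weights /= weights.sum()
    records = []
    for u in unigenes:
        if not u.coding or rng.random() > annotate_fraction:
            continue
        k = 1 + int(rng.integers(0, 4))
        picks = rng.choice(n_terms, size=min(k, n_terms), replace=False, p=weights)
        terms = [pool[int(i)] for i in sorted(picks)]
        records.append(AnnotationRecord(
            unigene_id=u.unigene_id,
            transcript_id=u.member_transcript_ids[0],
            protein_id=u.member_transcript_ids[0] + ".p1",
            go_terms=terms,
        ))
    return records
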