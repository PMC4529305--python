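"""Configuration-driven orchestration of the full analysis pipeline.

One flat YAML config drives a run from synthetic generation (or user
FASTA/FASTQ) through QC, assembly metrics, abundance, complexity,
completeness, annotation summaries and siRNA design, emitting a
Table-style text report plus TSV/JSON artifacts.  One seed governs all
stochastic stages; per-stage streams are derived inside the generators, so
a fixed config is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import yaml

from . import abundance as ab
from . import annotation as an
from . import completeness as comp
from . import exons as ex
from . import metrics as me
from . import readqc as qc
from . import sirna as si
from . import synthetic as syn
from .errors import ConfigError

log = logging.getLogger("potoroo")

STAGES = ["synth", "qc", "metrics", "abundance", "complexity",
          "completeness", "annotation", "sirna", "exons"]

# stage -> stages it needs
_DEPS = {
    "qc": ["synth"],
    "metrics": ["synth"],
    "abundance": ["qc", "metrics"],
    "complexity": ["abundance"],
    "completeness": ["metrics"],
    "annotation": ["metrics", "abundance"],
    "sirna": ["metrics"],
    "exons": ["synth"],
}


@dataclass
class PipelineConfig:
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    sim: syn.SimConfig = field(default_factory=syn.SimConfig)
    n_pairs: int = 20000
    trim: qc.TrimParams = field(default_factory=qc.TrimParams)
    scoring: comp.ScoringParams = field(default_factory=comp.ScoringParams)
    design: si.DesignParams = field(default_factory=si.DesignParams)
    min_codons: int = 100
    rank_cutoff: int = 10
    top_k: int = 10
    complexity_sample: int = 10000
    n_reference_proteins: int = 5
    seed: int = 0
    outdir: str = "potoroo_out"
    inputs: str = "synthetic"     # or a directory with transcripts.fasta etc.
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages in config: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        if self.inputs != "synthetic" and not os.path.isdir(self.inputs):
            raise ConfigError(f"inputs directory does not exist: {self.inputs}")
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        bad = []
        for key, val in raw.items():
            if key == "sim":
                kwargs["sim"] = syn.SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                                                 for k, v in val.items()})
            elif key == "trim":
                kwargs["trim"] = qc.TrimParams(**val)
            elif key == "scoring":
                kwargs["scoring"] = comp.ScoringParams(**val)
            elif key == "design":
                kwargs["design"] = si.DesignParams(**val)
            elif key in cls.__dataclass_fields__:
                kwargs[key] = val
            else:
                bad.append(key)
        if bad:
            raise ConfigError(f"invalid config keys: {sorted(bad)}")
        return cls(**kwargs)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _check_deps(config: PipelineConfig) -> None:
    on = {s for s in STAGES if config.stages.get(s, True)}
    for stage in sorted(on):
        missing = [d for d in _DEPS.get(stage, []) if d not in on]
        if missing:
            raise ConfigError(
                f"stage {stage!r} requires disabled stage(s) {missing}"
            )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; returns the run report."""
    logging.basicConfig(level=config.log_level)
    _check_deps(config)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "timings_sec": {},
    }
    state: dict = {}
    for stage in STAGES:
        if not config.stages.get(stage, True):
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FNS[stage](config, state, report)
        except Exception:
            report["failed_stage"] = stage
            log.exception("stage %s failed", stage)
            raise
        dt = time.perf_counter() - t0
        report["timings_sec"][stage] = round(dt, 3)
        log.info("stage %s done in %.2fs", stage, dt)
    _recheck_identities(report)
    return report


def _stage_synth(config, state, report):
    if config.inputs == "synthetic":
        genome, genes = syn.generate_genome(config.sim)
        isoforms = syn.generate_transcriptome(genes, genome, config.sim)
        reads = syn.simulate_reads(isoforms, config.sim, config.n_pairs)
        state.update(genome=genome, genes=genes, isoforms=isoforms, reads=reads)
    else:
        from .sequtil import read_fasta, read_fastq

        tx = read_fasta(os.path.join(config.inputs, "transcripts.fasta"))
        state["isoforms"] = [
            syn.IsoformTruth(tid, tid.rsplit("_seq", 1)[0], [], seq, 0.0)
            for tid, seq in tx
        ]
        r1 = list(read_fastq(os.path.join(config.inputs, "reads_1.fastq")))
        r2 = list(read_fastq(os.path.join(config.inputs, "reads_2.fastq")))
        state["reads"] = [
            syn.ReadPairRecord(a[0].rstrip("/1"), a[1], b[1], a[2], b[2], ("", 0, 0))
            for a, b in zip(r1, r2)
        ]
        state["genome"], state["genes"] = {}, []
    report["stages"]["synth"] = {
        "n_genes": len(state["genes"]),
        "n_isoforms": len(state["isoforms"]),
        "n_read_pairs": len(state["reads"]),
    }


def _stage_qc(config, state, report):
    raw = state["reads"]
    raw_stats = qc.base_stats(qc.pair_seq_quals(raw))
    kept, reasons = qc.trim_pairs(raw, config.trim)
    clean_stats = qc.base_stats(qc.pair_seq_quals(kept), total_raw_reads=2 * len(raw))
    normalized = qc.normalize_by_kmer_coverage(kept, config.trim)
    state["clean_pairs"] = kept
    state["normalized_pairs"] = normalized
    report["stages"]["qc"] = {
        "total_raw_reads": 2 * len(raw),
        "total_clean_reads": 2 * len(kept),
        "rejected_pairs": dict(reasons),
        "raw_q20_pct": round(raw_stats.q20_pct, 2),
        "q20_pct": round(clean_stats.q20_pct, 2),
        "gc_pct": round(clean_stats.gc_pct, 2),
        "total_nucleotides": clean_stats.total_nucleotides,
        "normalized_pairs": len(normalized),
    }


def _stage_metrics(config, state, report):
    transcripts = [me.TranscriptRecord(i.transcript_id, i.sequence)
                   for i in state["isoforms"]]
    orfs = [o for o in (me.find_best_orf(t, config.min_codons) for t in transcripts)
            if o is not None]
    unigenes = me.group_unigenes(transcripts, coding_ids={o.transcript_id for o in orfs})
    stats = me.assembly_stats(transcripts, orfs, unigenes)
    state.update(transcripts=transcripts, orfs=orfs, unigenes=unigenes, assembly=stats)
    report["stages"]["metrics"] = asdict(stats)


def _stage_abundance(config, state, report):
    params = ab.MapParams(fragment_mean=config.sim.fragment_mean)
    alignments = ab.map_reads(state["clean_pairs"], state["transcripts"], params)
    records = ab.estimate_abundance(alignments, state["transcripts"], mode="em",
                                    fragment_mean=config.sim.fragment_mean)
    grouping = {t.transcript_id: t.transcript_id.rsplit("_seq", 1)[0]
                for t in state["transcripts"]}
    uni_records = ab.unigene_abundance(records, grouping)
    state.update(alignments=alignments, abundance=records, unigene_abundance=uni_records)
    n_conc = len({a.pair_id for a in alignments if a.concordant})
    report["stages"]["abundance"] = {
        "n_aligned_pairs": n_conc,
        "n_alignment_records": len(alignments),
        "tpm_sum": round(sum(r.tpm for r in records), 3),
        "n_transcripts_nonzero": sum(1 for r in records if r.est_count > 0),
    }


def _stage_complexity(config, state, report):
    res = ab.library_complexity(state["alignments"], config.complexity_sample,
                                seed=config.seed)
    report["stages"]["complexity"] = asdict(res)


def _stage_completeness(config, state, report):
    genes = [g for g in state["genes"] if g.coding]
    genome = state["genome"]
    refs = {}
    for g in genes[: config.n_reference_proteins]:
        mature = g.mature_sequence(genome)
        orf_nt = mature[g.orf_span[0] : g.orf_span[1]]
        from .sequtil import translate

        refs[f"ref_{g.gene_id}"] = translate(orf_nt).rstrip("*")
    targets = {o.transcript_id: o.protein for o in state["orfs"]}
    calls = comp.assess_core_set(refs, targets, config.scoring)
    tally = {"complete": 0, "partial": 0, "absent": 0}
    for c in calls:
        tally[c.status] += 1
    state["completeness_calls"] = calls
    report["stages"]["completeness"] = {"n_refs": len(refs), **tally}


def _stage_annotation(config, state, report):
    import numpy as np

    rng = np.random.default_rng([7, config.seed])
    records = an.synthesize_annotations(state["unigenes"], rng)
    uni_tpm = {r.transcript_id: r.tpm for r in state["unigene_abundance"]}
    strata = an.annotation_rate_by_abundance(uni_tpm, records, config.rank_cutoff)
    terms, span = an.term_frequency(records, config.top_k)
    coding_tpms = [uni_tpm[u.unigene_id] for u in state["unigenes"]
                   if u.coding and u.unigene_id in uni_tpm]
    summary = an.tpm_distribution_summary(coding_tpms) if coding_tpms else None
    report["stages"]["annotation"] = {
        "n_annotated_unigenes": len({r.unigene_id for r in records}),
        "strata": [{"n_annotated": a, "n_total": b, "fraction": round(f, 4)}
                   for a, b, f in strata],
        "top_terms": [asdict(t) for t in terms],
        "top_term_span": span,
        "coding_tpm_summary": asdict(summary) if summary else None,
    }


def _stage_sirna(config, state, report):
    target = None
    for g in state["genes"]:
        if g.coding:
            target = g
            break
    if target is None:
        report["stages"]["sirna"] = {"skipped": "no coding gene"}
        return
    canonical = f"{target.gene_id}_seq1"
    rep = si.design(target.gene_id, state["transcripts"], target.orf_span,
                    canonical_id=canonical, params=config.design)
    state["design_report"] = rep
    report["stages"]["sirna"] = {
        "target_unigene": rep.target_unigene,
        **rep.attrition,
        "shortlist": rep.shortlist[:10],
    }


def _stage_exons(config, state, report):
    genome = state["genome"]
    results = {}
    for g in state["genes"]:
        if not g.coding or len(g.exons) < 3:
            continue
        chrom = genome[g.chrom]
        iso_chains = {}
        for iso in state["isoforms"]:
            if iso.gene_id != g.gene_id:
                continue
            iso_chains[iso.transcript_id] = ex.infer_exons(iso.sequence, chrom)
        if iso_chains:
            cmp_table = ex.compare_exon_tables(iso_chains)
            results[g.gene_id] = {
                "n_exon_ordinals": len(cmp_table.ordinals),
                "n_variant_exons": sum(cmp_table.variant),
                "n_isoforms": len(iso_chains),
            }
        if len(results) >= 3:
            break
    report["stages"]["exons"] = results


_STAGE_FNS = {
    "synth": _stage_synth,
    "qc": _stage_qc,
    "metrics": _stage_metrics,
    "abundance": _stage_abundance,
    "complexity": _stage_complexity,
    "completeness": _stage_completeness,
    "annotation": _stage_annotation,
    "sirna": _stage_sirna,
    "exons": _stage_exons,
}


def _recheck_identities(report: dict) -> None:
    """Re-assert the partition identities from the emitted report alone."""
    m = report["stages"].get("metrics")
    if m:
        assert m["n_transcripts_with_orf"] + m["n_transcripts_without_orf"] == m["n_transcripts"]
        assert m["n_clusters"] + m["n_singletons"] == m["n_unigenes_with_orf"]
        assert m["n_unigenes_with_orf"] + m["n_unigenes_without_orf"] == m["n_unigenes"]
    q = report["stages"].get("qc")
    if q:
        assert q["total_clean_reads"] <= q["total_raw_reads"]


# Table-style row labels for the text report
_TABLE_ROWS = [
    ("Total raw reads", ("qc", "total_raw_reads")),
    ("Total clean reads", ("qc", "total_clean_reads")),
    ("Total nucleotides", ("qc", "total_nucleotides")),
    ("Q20 percentage", ("qc", "q20_pct")),
    ("GC percentage", ("qc", "gc_pct")),
    ("N50 of transcripts", ("metrics", "n50")),
    ("Mean length of transcripts", ("metrics", "mean_length")),
    ("Total transcripts assembled", ("metrics", "n_transcripts")),
    ("Transcripts with open reading frames", ("metrics", "n_transcripts_with_orf")),
    ("Transcripts without open reading frames", ("metrics", "n_transcripts_without_orf")),
    ("Total Unigenes", ("metrics", "n_unigenes")),
    ("Unigenes with open reading frames", ("metrics", "n_unigenes_with_orf")),
    ("Distinct protein coding clusters", ("metrics", "n_clusters")),
    ("Distinct protein coding singletons", ("metrics", "n_singletons")),
    ("Mean isoforms per coding Unigene", ("metrics", "mean_isoforms_per_coding_unigene")),
    ("Unpaired library complexity", ("complexity", "unpaired_complexity")),
    ("Paired library complexity", ("complexity", "paired_complexity")),
    ("Complete reference orthologs", ("completeness", "complete")),
    ("Partial reference orthologs", ("completeness", "partial")),
]


def write_reports(report: dict, outdir) -> list:
    """Emit report.json, report.tsv and a Table-style text summary."""
    os.makedirs(outdir, exist_ok=True)
    files = []
    jpath = os.path.join(outdir, "report.json")
    with open(jpath, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files.append(jpath)
    tpath = os.path.join(outdir, "report.tsv")
    with open(tpath, "w") as fh:
        fh.write("stage\tkey\tvalue\n")
        for stage, block in report["stages"].items():
            for key, value in block.items():
                fh.write(f"{stage}\t{key}\t{json.dumps(value)}\n")
    files.append(tpath)
    spath = os.path.join(outdir, "summary_table.txt")
    with open(spath, "w") as fh:
        for label, (stage, key) in _TABLE_ROWS:
            block = report["stages"].get(stage)
            if block is None or key not in block:
                continue
            value = block[key]
            if isinstance(value, float):
                value = round(value, 2)
            fh.write(f"{label}\t{value}\n")
    files.append(spath)
    return files
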