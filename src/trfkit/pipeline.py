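"""End-to-end pipeline: configuration, trimming, report writers.

Binds the stages together: reference construction, read trimming (optional),
alignment, 5'-addition detection, per-read classification, tRF aggregation
and filtering, NR quantification at all hierarchy levels, mismatch pileups
and modification calls, and cleavage profiling. All thresholds default to the
method's canonical values; any override is echoed into the run manifest.
Outputs are plain TSV/FASTA files plus a JSON manifest, and a run is
deterministic given its inputs and seed.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .align import AlignConfig, ReadAligner, hits_to_frame
from .additions import addition_composition, detect_additions, dominant_additions
from .classify import (
    build_trf_records,
    classify_reads,
    filter_trfs,
    trf_table,
)
from .cleavage import (
    collect_end_counts,
    call_cleavage_sites,
    extract_flanks,
    project_virtual,
    sites_table,
)
from .modcall import (
    build_pileup,
    call_sites,
    global_mismatch_fraction,
    mr_histogram,
    treatment_contrast,
)
from .quantify import expression_matrix, gene_weight_table, sample_correlation, trf_expression
from .refdb import (
    HIERARCHY_LEVELS,
    build_reference,
    families_table,
    filter_genes,
    hierarchy_table,
    load_annotations,
    write_reference_fasta,
)
from .seqfiles import read_fastq


@dataclass
class SampleSpec:
    name: str
    fastq: str | None = None
    role: str | None = None  # "control" / "treated" / None


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one run (defaults = canonical values)."""

    out_dir: str = "trfkit_out"
    seed: int = 0
    # reference inputs
    bed: str | None = None
    structure: str | None = None
    genome: str | None = None
    flank: int = 60
    min_score: float = 30.0
    # samples
    samples: list[SampleSpec] = field(default_factory=list)
    libprep: str = "a_tailing"
    adapter: str | None = None
    min_qual: int = 0
    # alignment / tRF filters
    min_identity: float = 0.96
    min_length: int = 18
    min_support: int = 500
    hc_support: int = 1000
    hc_samples: int = 2
    # modification calling
    min_mr: float = 0.8
    mod_min_reads: int = 200
    # cleavage
    cleavage_min_reads: int = 1000
    cleavage_min_samples: int = 2
    flank_width: int = 7
    flank_min_reads: int = 100
    virtual_axis: int = 70

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        samples = [SampleSpec(**s) for s in raw.pop("samples", [])]
        return cls(samples=samples, **raw)


@dataclass
class PipelineResult:
    ref: object
    hits_by_sample: dict
    read_table: pd.DataFrame
    records: list
    retained: list
    high_confidence: list
    totals: dict
    matrices: dict
    outputs: dict


class StageError(RuntimeError):
    """Pipeline failure carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def trim_reads(
    reads, adapter: str | None, min_qual: int = 0, min_len: int = 18
):
    """Minimal 3'-adapter clip + quality filter (plumbing, not the method).

    The adapter is removed at its first exact-or-1-mismatch occurrence; reads
    ending up shorter than ``min_len`` are discarded and counted.
    """
    kept, stats = [], {"input": 0, "kept": 0, "discarded_short": 0, "low_qual": 0}
    for rid, seq, qual in reads:
        stats["input"] += 1
        if min_qual > 0 and qual:
            mean_q = sum(ord(c) - 33 for c in qual) / len(qual)
            if mean_q < min_qual:
                stats["low_qual"] += 1
                continue
        if adapter:
            cut = _find_adapter(seq, adapter)
            if cut is not None:
                seq, qual = seq[:cut], qual[:cut]
        if len(seq) < min_len:
            stats["discarded_short"] += 1
            continue
        stats["kept"] += 1
        kept.append((rid, seq, qual))
    return kept, stats


def _find_adapter(seq: str, adapter: str) -> int | None:
    n, m = len(seq), len(adapter)
    for i in range(n):
        window = seq[i : i + m]
        span = len(window)
        if span == 0:
            break
        mism = sum(a != b for a, b in zip(window, adapter[:span]))
        # full occurrence: <=1 mismatch; 3'-terminal partial: exact only
        if (span == m and mism <= 1) or (span < m and mism == 0 and span >= 5):
            return i
    return None


def _md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path, index=False):
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(
    config: PipelineConfig,
    ref=None,
    reads_by_sample: dict[str, list] | None = None,
    log=sys.stderr,
) -> PipelineResult:
    """Run every stage and write the report files.

    ``ref`` / ``reads_by_sample`` may be passed directly (e.g. from the
    simulator); otherwise they are loaded from the configured paths.
    """
    # validate inputs before any computation
    if reads_by_sample is None:
        for spec in config.samples:
            if not spec.fastq or not Path(spec.fastq).exists():
                raise StageError(
                    "input", f"missing FASTQ for sample {spec.name}: {spec.fastq}"
                )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(name, df, index=False):
        path = out / name
        _write_tsv(df, path, index=index)
        outputs[name] = str(path)

    # -- stage: refdb ------------------------------------------------------
    if ref is None:
        if not (config.bed and config.structure and config.genome):
            raise StageError("refdb", "bed/structure/genome paths are required")
        try:
            annotations = load_annotations(config.bed, config.structure)
            part = filter_genes(annotations, min_score=config.min_score)
            ref = build_reference(part.nuclear, config.genome, flank=config.flank)
        except (ValueError, OSError) as exc:
            raise StageError("refdb", str(exc)) from exc
    write_reference_fasta(ref, out / "reference.fa")
    outputs["reference.fa"] = str(out / "reference.fa")
    emit("families.tsv", families_table(ref))
    emit("hierarchy.tsv", hierarchy_table(ref))

    # -- stage: input reads ------------------------------------------------
    if reads_by_sample is None:
        reads_by_sample = {
            spec.name: list(read_fastq(spec.fastq)) for spec in config.samples
        }
    totals = {s: float(len(r)) for s, r in reads_by_sample.items()}  # N pre-trim

    roles = {spec.name: spec.role for spec in config.samples}

    # -- stage: trim + map -------------------------------------------------
    aligner = ReadAligner(
        ref,
        AlignConfig(
            min_identity=config.min_identity, min_length=config.min_length
        ),
    )
    hits_by_sample: dict[str, list] = {}
    map_stats = {}
    for sample in sorted(reads_by_sample):
        reads = reads_by_sample[sample]
        if config.adapter:
            reads, tstats = trim_reads(
                reads, config.adapter, config.min_qual, config.min_length
            )
        else:
            tstats = {"input": len(reads), "kept": len(reads)}
        hits, mstats = aligner.map_reads((r[0], r[1]) for r in reads)
        hits_by_sample[sample] = hits
        map_stats[sample] = {"trim": tstats, "map": vars(mstats)}
        print(f"[map] {sample}: {mstats.mapped} mapped reads", file=log)
        emit(f"hits_{sample}.tsv", hits_to_frame(hits))

    # -- stage: additions (before classification: sets untemplated_5p) -----
    events = detect_additions(hits_by_sample, ref)
    emit("additions.tsv", events)

    # -- stage: classify ---------------------------------------------------
    read_table = classify_reads(hits_by_sample, ref)
    records = build_trf_records(read_table)
    retained, high_conf = filter_trfs(
        records,
        min_support=config.min_support,
        hc_support=config.hc_support,
        hc_samples=config.hc_samples,
        min_len=config.min_length,
    )
    samples = sorted(reads_by_sample)
    if totals:
        trf_expression(records, totals)
    emit("trf_table.tsv", trf_table(retained, samples))
    emit("trf_table_all.tsv", trf_table(records, samples))
    comp = addition_composition(read_table)
    emit("addition_composition.tsv", comp)
    emit("addition_dominant.tsv", dominant_additions(comp))

    # -- stage: quantify ---------------------------------------------------
    matrices = {}
    weights = gene_weight_table(hits_by_sample)
    for level in HIERARCHY_LEVELS:
        mat = expression_matrix(weights, ref, level, totals)
        matrices[level] = mat
        emit(f"expr_{level}.tsv", mat, index=True)
    if len(samples) >= 2:
        r2, order, flagged = sample_correlation(matrices["family"])
        matrices["correlation"] = r2
        emit("correlation.tsv", r2, index=True)
        (out / "correlation_order.txt").write_text("\n".join(order) + "\n")
        if flagged:
            print(f"[quantify] zero-variance samples: {flagged}", file=log)

    # -- stage: modcall ----------------------------------------------------
    profile = build_pileup(hits_by_sample, ref)
    emit("mismatch_profile.tsv", profile)
    calls = call_sites(
        profile, min_mr=config.min_mr, min_reads=config.mod_min_reads
    )
    emit("mod_calls.tsv", calls)
    emit("mr_histogram.tsv", mr_histogram(profile))
    gmf = global_mismatch_fraction(hits_by_sample)
    emit(
        "mismatch_fraction.tsv",
        pd.DataFrame(
            [{"sample": s, "mismatched_read_fraction": f} for s, f in sorted(gmf.items())]
        ),
    )
    controls = [s for s in samples if roles.get(s) == "control"]
    treateds = [s for s in samples if roles.get(s) == "treated"]
    if controls and treateds:
        contrast = treatment_contrast(
            calls[calls["sample"].isin(controls)],
            calls[calls["sample"].isin(treateds)],
        )
        emit("mod_contrast.tsv", contrast)

    # -- stage: cleavage ---------------------------------------------------
    cprof = collect_end_counts(hits_by_sample, ref, libprep=config.libprep)
    emit("cleavage_profile.tsv", cprof.counts)
    emit("virtual_axis.tsv", project_virtual(cprof, axis_len=config.virtual_axis))
    csites = call_cleavage_sites(
        cprof,
        min_reads=config.cleavage_min_reads,
        min_samples=config.cleavage_min_samples,
    )
    extract_flanks(
        cprof,
        ref,
        width=config.flank_width,
        min_reads=config.flank_min_reads,
        path=out / "cleavage_flanks.fa",
    )
    outputs["cleavage_flanks.fa"] = str(out / "cleavage_flanks.fa")
    emit("cleavage_sites.tsv", sites_table(csites, samples))

    # -- manifest ----------------------------------------------------------
    manifest = {
        "trfkit_version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("samples", "out_dir")
        },
        "totals_pre_trim": totals,
        "mapping": map_stats,
        "n_trfs_retained": len(retained),
        "n_trfs_high_confidence": len(high_conf),
        "n_cleavage_sites": len(csites),
        "inputs_md5": {
            p: _md5(p)
            for p in (config.bed, config.structure, config.genome)
            if p and Path(p).exists()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest.json"] = str(out / "manifest.json")

    return PipelineResult(
        ref=ref,
        hits_by_sample=hits_by_sample,
        read_table=read_table,
        records=records,
        retained=retained,
        high_confidence=high_conf,
        totals=totals,
        matrices=matrices,
        outputs=outputs,
    )
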