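"""Seeded synthetic small-RNA-seq reads with full ground truth.

The simulator emulates the features of tRNA-seq libraries that the pipeline
measures: fragment populations drawn from the twelve structural tRF classes,
per-site reverse-transcription mismatch signatures of base modifications,
RT early stops, untemplated 5' nucleotide additions, and the two
library-preparation chemistries that differ in how an early RT stop
manifests — under ``template_switch`` the cDNA (and hence the read) is
5'-truncated at the stop site but survives; under ``a_tailing`` (adaptor
ligation at both ends) the truncated cDNA cannot be amplified and the read
is lost.

Every emitted read has exactly one ground-truth record, and one RNG stream is
derived per ``(seed, sample index)`` so adding samples never perturbs earlier
ones. Reads are emitted adapter-free by default (the pipeline's input
contract is adapter-trimmed FASTQ); an optional 3' fill pads reads to the
read length with adapter + poly-A to exercise trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import GeneModel, TRF_CLASSES, classify_fragment
from .refdb import TRNAGeneAnnotation, TRNAReferenceSet, build_reference
from .seqfiles import revcomp, write_fasta, write_fastq

_BASES = "ACGT"

#: default RT misread when a modified base is copied (fixed transition-like map)
_MISREAD = {"A": "G", "C": "T", "G": "A", "T": "C"}

#: default fragment-class probabilities. Full-length tRNA sits at 15% (tRNA
#: pools carry 14-23% full-length molecules), halves and 3'-tRFs dominate the
#: fragment fraction, flank-overlapping classes and flank-only reads are rare.
DEFAULT_CLASS_MIX = {
    "Full_tRNA": 0.15,
    "5_tRNA_halves": 0.15,
    "3_tRNA_halves": 0.15,
    "5_tRFs": 0.10,
    "3_tRFs": 0.20,
    "i_tRFs": 0.10,
    "Full_U_tRNA": 0.02,
    "5_U_tRNA_halves": 0.02,
    "3_U_tRNA_halves": 0.02,
    "5_U_tRF": 0.02,
    "3_U_tRF": 0.02,
    "other": 0.05,
}

_ANTICODON_TABLE = [
    ("Glu", "CTC"),
    ("Gly", "GCC"),
    ("His", "GTG"),
    ("Lys", "CTT"),
    ("Val", "TAC"),
    ("Arg", "ACG"),
    ("Asp", "GTC"),
    ("Leu", "CAA"),
    ("Pro", "AGG"),
    ("Ala", "AGC"),
]


@dataclass(frozen=True)
class ModSite:
    """A modified base: mismatch emission and RT early stop are independent."""

    gene_id: str
    mature_pos: int
    mismatch_rate: float
    early_stop_rate: float = 0.0
    alt_base: str | None = None


@dataclass
class SimConfig:
    seed: int = 0
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    mod_sites: list[ModSite] = field(default_factory=list)
    addition_rates: dict[str, float] = field(default_factory=dict)
    libprep: str = "a_tailing"
    seq_error: float = 0.0
    depth: int = 10_000
    n_samples: int = 2
    read_length: int = 100
    fill_adapter: str | None = None

    def __post_init__(self):
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1 (got {total})")
        unknown = set(self.class_mix) - set(TRF_CLASSES)
        if unknown:
            raise ValueError(f"unknown tRF classes in class_mix: {sorted(unknown)}")
        if self.libprep not in ("template_switch", "a_tailing"):
            raise ValueError("libprep must be template_switch or a_tailing")
        rates = [self.seq_error, *self.addition_rates.values()]
        rates += [m.mismatch_rate for m in self.mod_sites]
        rates += [m.early_stop_rate for m in self.mod_sites]
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if sum(self.addition_rates.values()) > 1:
            raise ValueError("addition rates must sum to <= 1")


# ---------------------------------------------------------------------------
# toy gene sets


def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def make_toy_gene_set(
    seed: int,
    n_genes: int,
    flank: int = 60,
    upstream: str = "AA",
) -> tuple[list[TRNAGeneAnnotation], dict[str, str]]:
    """Deterministic toy annotations + genome for desk-scale runs.

    Genes are 70-90 nt (mature), the anticodon sits at mature positions
    33-36, the first gene carries one intron, and (for ``n_genes >= 2``) the
    second gene shares the first gene's mature sequence at a second locus so
    families and multi-mapping are exercised. The ``upstream`` bases are
    placed immediately 5' of every gene so configured untemplated additions
    (G/T by default) always mismatch the template.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng([int(seed), 91])
    annotations: list[TRNAGeneAnnotation] = []
    chrom = "chrSim"
    pieces: list[str] = [_random_seq(rng, 80)]
    cursor = 80

    shared_mature: str | None = None
    for i in range(n_genes):
        if n_genes >= 2 and i == 1:
            aa, anticodon = _ANTICODON_TABLE[0]
        else:
            aa, anticodon = _ANTICODON_TABLE[i % len(_ANTICODON_TABLE)]
        if n_genes >= 2 and i == 1 and shared_mature is not None:
            mature = shared_mature
        else:
            L = int(rng.integers(70, 91))
            mature = list(_random_seq(rng, L))
            mature[33:36] = anticodon
            mature = "".join(mature)
        if i == 0:
            shared_mature = mature
            intron_len = int(rng.integers(10, 21))
            intron = _random_seq(rng, intron_len)
            gene_seq = mature[:38] + intron + mature[38:]
            introns = ((38, 38 + intron_len),)
        else:
            gene_seq = mature
            introns = ()

        up = _random_seq(rng, flank - len(upstream)) + upstream
        down = _random_seq(rng, flank)
        region = up + gene_seq + down
        strand = "-" if (i >= 2 and i % 2 == 0) else "+"
        insert = revcomp(region) if strand == "-" else region
        start = cursor + flank
        end = start + len(gene_seq)
        pieces.append(insert)
        cursor += len(insert)

        if n_genes >= 2 and i in (0, 1):
            symbol = f"tRNA-{aa}-{anticodon}-1-{i + 1}"
        else:
            symbol = f"tRNA-{aa}-{anticodon}-{i + 1}-1"
        annotations.append(
            TRNAGeneAnnotation(
                gene_id=symbol,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                amino_acid=aa,
                anticodon=anticodon,
                anticodon_interval=(33, 36),
                intron_intervals=introns,
                trnascan_score=float(np.round(rng.uniform(40, 90), 1)),
            )
        )
    pieces.append(_random_seq(rng, 80))
    return annotations, {chrom: "".join(pieces)}


def make_toy_reference(
    seed: int, n_genes: int, flank: int = 60
) -> TRNAReferenceSet:
    annotations, genome = make_toy_gene_set(seed, n_genes, flank=flank)
    return build_reference(annotations, genome, flank=flank)


# ---------------------------------------------------------------------------
# fragment sampling


def _draw_interval(cls, L: int, ac0: int, ac1: int, read_length: int, rng):
    """(start, end, uses_cca) of a templated fragment of the requested class."""
    cca = False
    if cls == "Full_tRNA":
        s, e = 0, L
        if rng.random() < 0.5:
            e, cca = L + 3, True
    elif cls == "Full_U_tRNA":
        u = int(rng.integers(3, 6))
        d = int(rng.integers(0, max(1, min(6, read_length - L - u + 1))))
        s, e = -u, L + d
    elif cls == "5_tRNA_halves":
        s, e = 0, int(rng.integers(ac0, ac1 + 2))
    elif cls == "5_U_tRNA_halves":
        s, e = -int(rng.integers(3, 11)), int(rng.integers(ac0, ac1 + 2))
    elif cls == "3_tRNA_halves":
        s, e = int(rng.integers(ac0 - 1, ac1 + 1)), L
        if rng.random() < 0.5:
            e, cca = L + 3, True
    elif cls == "3_U_tRNA_halves":
        s = int(rng.integers(ac0 - 1, ac1 + 1))
        e = L + int(rng.integers(3, 11))
    elif cls == "5_tRFs":
        s, e = 0, int(rng.integers(18, ac0))
    elif cls == "5_U_tRF":
        s, e = -int(rng.integers(3, 11)), int(rng.integers(18, ac0))
    elif cls == "3_tRFs":
        s, e = int(rng.integers(ac1 + 1, L - 17)), L
        if rng.random() < 0.5:
            e, cca = L + 3, True
    elif cls == "3_U_tRF":
        s = int(rng.integers(ac1 + 1, L - 17))
        e = L + int(rng.integers(3, 11))
    elif cls == "i_tRFs":
        s = int(rng.integers(3, L - 20))
        e = int(rng.integers(s + 18, L - 2))
    elif cls == "other":
        if rng.random() < 0.5:
            s = -int(rng.integers(19, 61))
            e = int(rng.integers(s + 18, 1))
        else:
            s = L + int(rng.integers(0, 43))
            e = int(rng.integers(s + 18, L + 61))
    else:
        raise ValueError(f"unknown class {cls!r}")
    if e - s < 18:
        raise ValueError(f"class {cls} produced a fragment shorter than 18 nt")
    return s, e, cca


def _fragment_sequence(gref, s: int, e: int, uses_cca: bool) -> str:
    if uses_cca:
        return gref.sequences["mature_cca"][s:e]
    flank = gref.flank
    return gref.sequences["pre_spliced"][flank + s : flank + e]


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    config: SimConfig, ref: TRNAReferenceSet
) -> tuple[dict[str, list[tuple[str, str, str]]], pd.DataFrame]:
    """Simulate FASTQ reads per sample plus a per-read ground-truth table."""
    gene_ids = sorted(ref.genes)
    feasible = [g for g in gene_ids if len(ref.genes[g].mature) >= 60]
    if not feasible:
        raise ValueError("no gene long enough to draw all fragment classes")
    classes = sorted(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    mods_by_gene: dict[str, list[ModSite]] = {}
    for site in config.mod_sites:
        if site.gene_id not in ref.genes:
            raise ValueError(f"mod site on unknown gene {site.gene_id}")
        mods_by_gene.setdefault(site.gene_id, []).append(site)
    add_strings = sorted(config.addition_rates)
    add_probs = [config.addition_rates[a] for a in add_strings]

    samples: dict[str, list[tuple[str, str, str]]] = {}
    truth_rows = []
    for s_idx in range(config.n_samples):
        sample = f"S{s_idx + 1}"
        rng = np.random.default_rng([int(config.seed), s_idx])
        reads: list[tuple[str, str, str]] = []
        for r_idx in range(config.depth):
            read_id = f"{sample}:r{r_idx:06d}"
            gid = feasible[int(rng.integers(0, len(feasible)))]
            gref = ref.genes[gid]
            model = GeneModel.from_gene(gref)
            cls = classes[int(rng.choice(len(classes), p=probs))]
            s, e, uses_cca = _draw_interval(
                cls,
                model.mature_len,
                model.anticodon_start,
                model.anticodon_end,
                config.read_length,
                rng,
            )
            frag = list(_fragment_sequence(gref, s, e, uses_cca))

            # untemplated 5' addition on fragments starting at the mature start
            addition = ""
            if s == 0 and add_strings:
                u = rng.random()
                acc = 0.0
                for a, p in zip(add_strings, add_probs):
                    acc += p
                    if u < acc:
                        addition = a
                        break
            # modification signatures on covered sites
            applied_mm = []
            stop_at = None
            for site in mods_by_gene.get(gid, ()):
                if not (s <= site.mature_pos < min(e, model.mature_len)):
                    continue
                if site.mismatch_rate and rng.random() < site.mismatch_rate:
                    idx = site.mature_pos - s
                    alt = site.alt_base or _MISREAD[frag[idx]]
                    frag[idx] = alt
                    applied_mm.append(site.mature_pos)
                if site.early_stop_rate and rng.random() < site.early_stop_rate:
                    # RT runs 3'->5'; the most 3' triggered site dominates
                    if stop_at is None or site.mature_pos > stop_at:
                        stop_at = site.mature_pos

            emitted = True
            final_s, final_add = s, addition
            if stop_at is not None:
                if config.libprep == "a_tailing":
                    emitted = False
                else:
                    final_s = stop_at + 1
                    frag = frag[final_s - s :]
                    final_add = ""
                    applied_mm = [p for p in applied_mm if p >= final_s]
                    if not frag:  # stop at the fragment's last base
                        emitted = False

            seq = final_add + "".join(frag) if emitted else ""
            if emitted and config.seq_error > 0:
                seq = list(seq)
                errs = np.nonzero(rng.random(len(seq)) < config.seq_error)[0]
                for j in errs:
                    seq[j] = _BASES[
                        (_BASES.index(seq[j]) + int(rng.integers(1, 4))) % 4
                    ]
                seq = "".join(seq)
            if emitted and len(seq) > config.read_length:
                seq = seq[: config.read_length]
            if emitted and config.fill_adapter and len(seq) < config.read_length:
                fill = config.fill_adapter + "A" * config.read_length
                seq = (seq + fill)[: config.read_length]

            true_class = (
                classify_fragment(
                    final_s - len(final_add),
                    min(e, final_s - len(final_add) + config.read_length),
                    model,
                    uses_cca=uses_cca,
                    untemplated_5p=len(final_add),
                )
                if emitted
                else ""
            )
            truth_rows.append(
                {
                    "read_id": read_id,
                    "sample": sample,
                    "gene_id": gid,
                    "family_id": ref.gene_family[gid],
                    "requested_class": cls,
                    "true_class": true_class,
                    "emitted": emitted,
                    "start": final_s,
                    "end": e,
                    "uses_cca": uses_cca,
                    "addition": final_add,
                    "mismatch_positions": ";".join(map(str, applied_mm)),
                    "truncated_at": -1 if stop_at is None else stop_at,
                }
            )
            if emitted:
                reads.append((read_id, seq, "I" * len(seq)))
        samples[sample] = reads
    truth = pd.DataFrame(truth_rows)
    return samples, truth


def write_simulation(
    out_dir,
    config: SimConfig,
    annotations: list[TRNAGeneAnnotation],
    genome: dict[str, str],
    ref: TRNAReferenceSet,
    samples: dict[str, list],
    truth: pd.DataFrame,
) -> dict[str, str]:
    """Write FASTQs, ground truth, and the reference inputs for the CLI."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_fasta(out / "genome.fa", sorted(genome.items()))
    paths["genome"] = str(out / "genome.fa")
    with open(out / "annotations.bed", "w") as fh:
        for ann in annotations:
            fh.write(
                f"{ann.chrom}\t{ann.start}\t{ann.end}\t{ann.gene_id}\t0\t{ann.strand}\n"
            )
    paths["bed"] = str(out / "annotations.bed")
    with open(out / "structure.tsv", "w") as fh:
        fh.write("gene_id\tanticodon_start\tanticodon_end\tintrons\tscore\tis_pseudo\n")
        for ann in annotations:
            introns = (
                ";".join(f"{a}-{b}" for a, b in ann.intron_intervals) or "."
            )
            fh.write(
                f"{ann.gene_id}\t{ann.anticodon_interval[0]}\t"
                f"{ann.anticodon_interval[1]}\t{introns}\t{ann.trnascan_score}\t"
                f"{int(ann.is_pseudo)}\n"
            )
    paths["structure"] = str(out / "structure.tsv")
    for sample, reads in samples.items():
        p = out / f"{sample}.fastq.gz"
        write_fastq(p, reads)
        paths[sample] = str(p)
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    paths["truth"] = str(out / "ground_truth.tsv")
    return paths
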