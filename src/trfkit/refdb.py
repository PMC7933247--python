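"""tRNA reference construction.

Every tRNA gene is expanded into four transcript variants that together serve
as the alignment target set:

* ``pre_intron``   – unspliced precursor: gene body plus 60-bp genomic flanks,
  introns retained;
* ``pre_spliced``  – spliced precursor: gene body plus flanks, introns removed;
* ``mature``       – spliced transcript without flanks;
* ``mature_cca``   – mature transcript with the post-transcriptionally added
  3' CCA.

All coordinates are 0-based half-open. All stored sequences are on the sense
(transcript) strand; for minus-strand genes the flanks are taken from the
genomic strand and reverse-complemented. Each variant carries a coordinate
map back to mature-tRNA coordinates where 5'-flank positions are negative,
3'-flank (and CCA) positions are >= the mature length, and intron positions
carry the :data:`INTRON` sentinel.

Genes sharing an identical mature sequence are grouped into one tRNA family
named ``tRFM#<symbol>`` after the member with the smallest transcript/locus
identifier, and every gene is labelled at six nested hierarchy levels
(amino acid, isoacceptor, isodecoder, family, gene, transcript).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqfiles import read_fasta, revcomp, write_fasta

INTRON = -(1 << 30)

VARIANTS = ("pre_intron", "pre_spliced", "mature", "mature_cca")

HIERARCHY_LEVELS = (
    "amino_acid",
    "isoacceptor",
    "isodecoder",
    "family",
    "gene",
    "transcript",
)

_MITO_CHROMS = {"chrM", "chrMT", "MT", "M"}

_VALID_GENOME = set("ACGTN")


@dataclass(frozen=True)
class TRNAGeneAnnotation:
    """One tRNA gene locus plus its structural annotation.

    ``anticodon_interval`` is expressed in mature-tRNA (sense, spliced)
    coordinates; ``intron_intervals`` in unspliced gene-local sense
    coordinates (0 = first transcribed base).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    amino_acid: str
    anticodon: str
    anticodon_interval: tuple[int, int]
    intron_intervals: tuple[tuple[int, int], ...] = ()
    trnascan_score: float = 0.0
    is_mito: bool = False
    is_pseudo: bool = False

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"{self.gene_id}: start must be < end (got {self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        a0, a1 = self.anticodon_interval
        if a1 - a0 != 3:
            raise ValueError(f"{self.gene_id}: anticodon interval must span 3 nt")
        if a0 < 0 or a1 > self.mature_length:
            raise ValueError(
                f"{self.gene_id}: anticodon interval outside the mature sequence"
            )
        last = 0
        for i0, i1 in self.intron_intervals:
            if i0 < last or i1 <= i0 or i1 > self.gene_length:
                raise ValueError(
                    f"{self.gene_id}: intron intervals must be disjoint, ordered "
                    "and inside the gene body"
                )
            last = i1

    @property
    def gene_length(self) -> int:
        return self.end - self.start

    @property
    def intron_length(self) -> int:
        return sum(i1 - i0 for i0, i1 in self.intron_intervals)

    @property
    def mature_length(self) -> int:
        return self.gene_length - self.intron_length


@dataclass
class GeneReference:
    """The four sequence variants of one gene plus coordinate maps."""

    gene: TRNAGeneAnnotation
    flank: int
    sequences: dict[str, str]
    to_mature: dict[str, np.ndarray]
    mature_index: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def mature(self) -> str:
        return self.sequences["mature"]

    def variant_to_mature(self, variant: str, pos: int) -> int:
        """Mature coordinate of a variant position (INTRON for intronic)."""
        return int(self.to_mature[variant][pos])

    def mature_to_variant(self, variant: str, mature_pos: int) -> int:
        """Inverse of :meth:`variant_to_mature` for mapped positions."""
        arr = self.to_mature[variant]
        L = len(self.mature)
        if mature_pos < 0 or mature_pos >= L:
            hits = np.nonzero(arr == mature_pos)[0]
            if len(hits) == 0:
                raise IndexError(
                    f"{self.gene.gene_id}:{variant} has no position mapping to "
                    f"mature coordinate {mature_pos}"
                )
            return int(hits[0])
        return int(self.mature_index[variant][mature_pos])


@dataclass(frozen=True)
class TRNAFamily:
    """Genes sharing an identical mature sequence."""

    family_id: str
    member_gene_ids: tuple[str, ...]


class TRNAReferenceSet:
    """Per-gene variant sequences, families, and hierarchy labels."""

    def __init__(self, genes: dict[str, GeneReference], flank: int):
        self.genes = genes
        self.flank = flank
        self.families: list[TRNAFamily] = []
        self.gene_family: dict[str, str] = {}
        self.hierarchy: dict[str, dict[str, str]] = {}
        group_families(self)
        assign_hierarchy(self)

    def __len__(self) -> int:
        return len(self.genes)

    def family_members(self, family_id: str) -> tuple[str, ...]:
        for fam in self.families:
            if fam.family_id == family_id:
                return fam.member_gene_ids
        raise KeyError(family_id)

    def family_representative(self, family_id: str) -> GeneReference:
        """Member with the smallest symbol; family members share one mature."""
        members = sorted(self.family_members(family_id), key=symbol_sort_key)
        return self.genes[members[0]]

    def iter_records(self):
        for gid, gref in self.genes.items():
            for variant in VARIANTS:
                yield f"{gid}|{variant}", gref.sequences[variant]


def symbol_sort_key(gene_id: str):
    """Natural-number-aware sort key for GtRNAdb-style gene symbols."""
    tokens = re.split(r"(\d+)", gene_id)
    return tuple(
        (0, int(t), "") if t.isdigit() else (1, 0, t) for t in tokens if t
    )


# ---------------------------------------------------------------------------
# loading


def _parse_intervals(text: str, line_no: int):
    text = text.strip()
    if text in ("", ".", "-"):
        return ()
    out = []
    for chunk in text.split(";"):
        m = re.fullmatch(r"\s*(\d+)\s*-\s*(\d+)\s*", chunk)
        if not m:
            raise ValueError(
                f"malformed interval {chunk!r} in structure file line {line_no}"
            )
        out.append((int(m.group(1)), int(m.group(2))))
    return tuple(out)


def _parse_symbol(gene_id: str) -> tuple[str, str]:
    parts = gene_id.split("-")
    if len(parts) >= 3:
        return parts[1], parts[2]
    return "Und", "NNN"


def load_annotations(bed_path, structure_path) -> list[TRNAGeneAnnotation]:
    """Read gene loci (BED6+) plus a structure table into annotations.

    The structure table is TSV with a header line and columns
    ``gene_id  anticodon_start  anticodon_end  introns  score`` and an
    optional ``is_pseudo`` column. ``introns`` uses ``start-end`` pairs in
    unspliced gene-local coordinates, ``;``-separated, or ``.`` for none.
    The anticodon interval is given in mature (spliced, sense) coordinates.
    """
    structure: dict[str, dict] = {}
    with open(structure_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for name in ("gene_id", "anticodon_start", "anticodon_end", "score"):
            if name not in col:
                raise ValueError(f"structure file missing column {name!r}")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                rec = {
                    "anticodon_start": int(fields[col["anticodon_start"]]),
                    "anticodon_end": int(fields[col["anticodon_end"]]),
                    "score": float(fields[col["score"]]),
                    "introns": _parse_intervals(
                        fields[col["introns"]] if "introns" in col else ".",
                        line_no,
                    ),
                    "is_pseudo": bool(int(fields[col["is_pseudo"]]))
                    if "is_pseudo" in col
                    else False,
                }
            except (ValueError, IndexError) as exc:
                if "malformed interval" in str(exc):
                    raise
                raise ValueError(
                    f"malformed structure record at line {line_no}: {exc}"
                ) from exc
            structure[fields[col["gene_id"]]] = rec

    genes = []
    with open(bed_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"BED line {line_no}: expected >= 6 fields")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"BED line {line_no}: malformed interval") from exc
            if end <= start:
                raise ValueError(
                    f"BED line {line_no}: end <= start for gene {name}"
                )
            if name not in structure:
                raise ValueError(f"no structure record for gene {name}")
            rec = structure[name]
            aa, anticodon = _parse_symbol(name)
            genes.append(
                TRNAGeneAnnotation(
                    gene_id=name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    amino_acid=aa,
                    anticodon=anticodon,
                    anticodon_interval=(rec["anticodon_start"], rec["anticodon_end"]),
                    intron_intervals=rec["introns"],
                    trnascan_score=rec["score"],
                    is_mito=chrom in _MITO_CHROMS,
                    is_pseudo=rec["is_pseudo"],
                )
            )
    return genes


@dataclass
class GenePartition:
    """Score/pseudo-filtered genes, nuclear and mitochondrial kept apart."""

    nuclear: list[TRNAGeneAnnotation]
    mito: list[TRNAGeneAnnotation]


def filter_genes(
    genes: list[TRNAGeneAnnotation], min_score: float = 30.0
) -> GenePartition:
    """Drop pseudo genes and genes scoring below ``min_score``.

    Mitochondrial genes pass the same filters but are routed to a separate
    partition rather than silently removed.
    """
    keep = [
        g for g in genes if not g.is_pseudo and g.trnascan_score >= min_score
    ]
    return GenePartition(
        nuclear=[g for g in keep if not g.is_mito],
        mito=[g for g in keep if g.is_mito],
    )


# ---------------------------------------------------------------------------
# building


def _splice(gene_seq: str, introns) -> str:
    pieces, cursor = [], 0
    for i0, i1 in introns:
        pieces.append(gene_seq[cursor:i0])
        cursor = i1
    pieces.append(gene_seq[cursor:])
    return "".join(pieces)


def build_gene_reference(
    gene: TRNAGeneAnnotation,
    genome: dict[str, str],
    flank: int = 60,
    validate_anticodon: bool = True,
) -> GeneReference:
    if gene.chrom not in genome:
        raise ValueError(f"{gene.gene_id}: contig {gene.chrom!r} not in genome")
    contig = genome[gene.chrom]
    if gene.start - flank < 0 or gene.end + flank > len(contig):
        raise ValueError(
            f"{gene.gene_id}: locus too close to the edge of {gene.chrom} for "
            f"{flank}-bp flanks"
        )
    region = contig[gene.start - flank : gene.end + flank].upper()
    bad = set(region) - _VALID_GENOME
    if bad:
        raise ValueError(
            f"{gene.gene_id}: non-ACGTN genome characters {sorted(bad)}"
        )
    if gene.strand == "-":
        region = revcomp(region)
    # region is now the sense-strand precursor: 5' flank + gene body + 3' flank
    gene_seq = region[flank : flank + gene.gene_length]
    mature = _splice(gene_seq, gene.intron_intervals)
    L = len(mature)
    if validate_anticodon:
        a0, a1 = gene.anticodon_interval
        found = mature[a0:a1]
        if found != gene.anticodon.upper().replace("U", "T"):
            raise ValueError(
                f"{gene.gene_id}: anticodon {gene.anticodon} not found at mature "
                f"positions {a0}-{a1} (saw {found})"
            )

    sequences = {
        "pre_intron": region,
        "pre_spliced": region[:flank] + mature + region[flank + gene.gene_length :],
        "mature": mature,
        "mature_cca": mature + "CCA",
    }

    # gene-body map: unspliced gene-local position -> mature coordinate
    body = np.full(gene.gene_length, INTRON, dtype=np.int64)
    cursor = 0
    intron_mask = np.zeros(gene.gene_length, dtype=bool)
    for i0, i1 in gene.intron_intervals:
        intron_mask[i0:i1] = True
    for pos in range(gene.gene_length):
        if not intron_mask[pos]:
            body[pos] = cursor
            cursor += 1

    five = np.arange(-flank, 0, dtype=np.int64)
    three = np.arange(L, L + flank, dtype=np.int64)
    to_mature = {
        "pre_intron": np.concatenate([five, body, three]),
        "pre_spliced": np.concatenate(
            [five, np.arange(L, dtype=np.int64), three]
        ),
        "mature": np.arange(L, dtype=np.int64),
        "mature_cca": np.arange(L + 3, dtype=np.int64),
    }
    mature_index = {}
    for variant, arr in to_mature.items():
        inv = np.full(L, -1, dtype=np.int64)
        mask = (arr >= 0) & (arr < L)
        inv[arr[mask]] = np.nonzero(mask)[0]
        mature_index[variant] = inv

    return GeneReference(
        gene=gene,
        flank=flank,
        sequences=sequences,
        to_mature=to_mature,
        mature_index=mature_index,
    )


def build_reference(
    genes: list[TRNAGeneAnnotation],
    genome,
    flank: int = 60,
    validate_anticodon: bool = True,
) -> TRNAReferenceSet:
    """Build the four-variant reference for a gene set.

    ``genome`` may be a ``{chrom: sequence}`` dict or a FASTA path.
    Intronless genes still emit all four variants (``pre_intron`` equal to
    ``pre_spliced``) so the per-gene variant count is constant; duplicate
    sequences are deduplicated at alignment time.
    """
    if not isinstance(genome, dict):
        genome = read_fasta(genome)
    refs = {
        g.gene_id: build_gene_reference(g, genome, flank, validate_anticodon)
        for g in genes
    }
    return TRNAReferenceSet(refs, flank)


# ---------------------------------------------------------------------------
# grouping


def group_families(ref: TRNAReferenceSet) -> list[TRNAFamily]:
    """Partition genes into families of identical mature sequence."""
    by_seq: dict[str, list[str]] = {}
    for gid in sorted(ref.genes, key=symbol_sort_key):
        by_seq.setdefault(ref.genes[gid].mature, []).append(gid)
    families = []
    for members in by_seq.values():
        head = min(members, key=symbol_sort_key)
        families.append(
            TRNAFamily(family_id=f"tRFM#{head}", member_gene_ids=tuple(members))
        )
    families.sort(key=lambda f: symbol_sort_key(f.family_id))
    ref.families = families
    ref.gene_family = {
        gid: fam.family_id for fam in families for gid in fam.member_gene_ids
    }
    return families


def assign_hierarchy(ref: TRNAReferenceSet) -> dict[str, dict[str, str]]:
    """Label every gene at the six nested hierarchy levels."""
    if not ref.gene_family:
        group_families(ref)
    labels = {}
    for gid, gref in ref.genes.items():
        ann = gref.gene
        iso = f"{ann.amino_acid}-{ann.anticodon}"
        # GtRNAdb symbols are tRNA-<aa>-<anticodon>-<transcript>-<locus>;
        # the isodecoder drops the locus field.
        isodecoder = gid.rsplit("-", 1)[0]
        if isodecoder.startswith("tRNA-"):
            isodecoder = isodecoder[len("tRNA-") :]
        labels[gid] = {
            "amino_acid": ann.amino_acid,
            "isoacceptor": iso,
            "isodecoder": isodecoder,
            "family": ref.gene_family[gid],
            "gene": gid,
            "transcript": gid,
        }
    ref.hierarchy = labels
    return labels


# ---------------------------------------------------------------------------
# export


def write_reference_fasta(ref: TRNAReferenceSet, path) -> None:
    write_fasta(path, ref.iter_records())


def families_table(ref: TRNAReferenceSet) -> pd.DataFrame:
    rows = [
        {
            "family_id": fam.family_id,
            "n_members": len(fam.member_gene_ids),
            "members": ",".join(fam.member_gene_ids),
        }
        for fam in ref.families
    ]
    return pd.DataFrame(rows, columns=["family_id", "n_members", "members"])


def hierarchy_table(ref: TRNAReferenceSet) -> pd.DataFrame:
    rows = [
        {"gene_id": gid, **labels} for gid, labels in sorted(ref.hierarchy.items())
    ]
    return pd.DataFrame(rows)
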