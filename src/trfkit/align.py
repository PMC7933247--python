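"""Read-to-tRNA assignment.

Reads are placed end-to-end (ungapped) on the four-variant reference via a
k-mer seed index with exhaustive verification at candidate offsets. Identity
is matches / read length; only placements tied at the maximal identity and at
or above the 96% floor are kept, and a multi-mapped read's hits are weighted
1/k so its total assigned weight is 1.

Within one gene, a read contained in several variants is collapsed to the
variant requiring the fewest post-transcriptional assumptions: ``mature`` if
the read needs no flank or CCA bases, ``mature_cca`` if it uses CCA bases,
otherwise the precursor (spliced preferred over unspliced). Hits across
different genes — including genes with identical mature sequences — are kept
separate and re-aggregated at the family level downstream.

The k-mer seed (k = 12) is exact for this contract: a read of length L may
carry at most floor(0.04 L) mismatches, which always leaves an intact 12-mer
for L >= 18.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .refdb import INTRON, TRNAReferenceSet, VARIANTS

_VARIANT_RANK = {v: i for i, v in enumerate(("mature", "mature_cca", "pre_spliced", "pre_intron"))}


@dataclass
class AlignConfig:
    min_identity: float = 0.96
    min_length: int = 18
    allow_indels: bool = False
    kmer_size: int = 12

    def __post_init__(self):
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.allow_indels:
            raise NotImplementedError(
                "only ungapped end-to-end placement is implemented"
            )


@dataclass
class AlignmentHit:
    """One retained placement of a read on a gene's chosen variant."""

    read_id: str
    gene_id: str
    variant: str
    start: int
    end: int
    identity: float
    weight: float
    mismatches: tuple[tuple[int, str, str], ...]
    read_seq: str
    mature_start: int | None
    mature_end: int | None
    uses_cca: bool
    untemplated_5p: int = 0
    trf_class: str | None = None
    family_id: str | None = None


@dataclass
class MappingStats:
    mapped: int = 0
    unmapped: int = 0
    too_short: int = 0
    reasons: dict = field(default_factory=dict)


class ReadAligner:
    """Seed-and-extend aligner over a :class:`TRNAReferenceSet`."""

    def __init__(self, ref: TRNAReferenceSet, config: AlignConfig | None = None):
        self.ref = ref
        self.config = config or AlignConfig()
        k = self.config.kmer_size
        # deduplicate identical variant sequences before indexing
        self._seqs: list[str] = []
        self._occurrences: list[list[tuple[str, str]]] = []
        seen: dict[str, int] = {}
        for gid in sorted(ref.genes):
            for variant in VARIANTS:
                seq = ref.genes[gid].sequences[variant]
                sid = seen.get(seq)
                if sid is None:
                    sid = len(self._seqs)
                    seen[seq] = sid
                    self._seqs.append(seq)
                    self._occurrences.append([])
                self._occurrences[sid].append((gid, variant))
        self._arrays = [
            np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in self._seqs
        ]
        self._index: dict[str, list[tuple[int, int]]] = {}
        for sid, seq in enumerate(self._seqs):
            for pos in range(len(seq) - k + 1):
                self._index.setdefault(seq[pos : pos + k], []).append((sid, pos))

    # -- placement ---------------------------------------------------------

    def _candidate_placements(self, read: str):
        k = self.config.kmer_size
        cands = set()
        for i in range(len(read) - k + 1):
            for sid, pos in self._index.get(read[i : i + k], ()):
                off = pos - i
                if off >= 0 and off + len(read) <= len(self._seqs[sid]):
                    cands.add((sid, off))
        return cands

    def map_read(self, read: str, read_id: str = "read") -> list[AlignmentHit]:
        """All best-identity hits of one read (empty list if unmapped)."""
        read = read.upper()
        L = len(read)
        if L < self.config.min_length:
            return []
        arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8)
        best_mm = None
        placements: list[tuple[int, int, int]] = []
        max_mm = int(L * (1.0 - self.config.min_identity) + 1e-9)
        for sid, off in self._candidate_placements(read):
            mm = int(np.count_nonzero(self._arrays[sid][off : off + L] != arr))
            if mm > max_mm:
                continue
            if best_mm is None or mm < best_mm:
                best_mm = mm
                placements = [(sid, off, mm)]
            elif mm == best_mm:
                placements.append((sid, off, mm))
        if not placements:
            return []

        # group the tied placements by gene, then pick one variant per gene
        per_gene: dict[str, list[tuple[str, int]]] = {}
        for sid, off, _mm in placements:
            for gid, variant in self._occurrences[sid]:
                per_gene.setdefault(gid, []).append((variant, off))
        identity = (L - best_mm) / L
        hits = []
        weight = 1.0 / len(per_gene)
        for gid in sorted(per_gene):
            variant, off = min(
                per_gene[gid], key=lambda vo: (_VARIANT_RANK[vo[0]], vo[1])
            )
            hits.append(
                self._make_hit(read_id, read, arr, gid, variant, off, identity, weight)
            )
        return hits

    def _make_hit(self, read_id, read, arr, gid, variant, off, identity, weight):
        gref = self.ref.genes[gid]
        seq_arr = np.frombuffer(
            gref.sequences[variant].encode("ascii"), dtype=np.uint8
        )
        L = len(read)
        diff = np.nonzero(seq_arr[off : off + L] != arr)[0]
        mismatches = tuple(
            (off + int(j), read[int(j)], chr(seq_arr[off + int(j)])) for j in diff
        )
        vals = gref.to_mature[variant][off : off + L]
        mapped = vals[vals != INTRON]
        if len(mapped):
            mature_start, mature_end = int(mapped[0]), int(mapped[-1]) + 1
        else:
            mature_start = mature_end = None
        L_mat = len(gref.mature)
        uses_cca = variant == "mature_cca" and mature_end is not None and (
            mature_end > L_mat
        )
        # a read carrying both a 5' addition and the 3' CCA fits no single
        # variant; it places on the precursor with the CCA as an apparent 3'
        # overhang. Recognize the overhang as untemplated CCA when its bases
        # read CCA and at least one mismatches the genomic trailer.
        if (
            variant in ("pre_intron", "pre_spliced")
            and mature_end is not None
            and L_mat < mature_end <= L_mat + 3
        ):
            k3 = mature_end - L_mat
            if read[-k3:] == "CCA"[:k3]:
                tail = set(range(off + L - k3, off + L))
                if any(p in tail for p, _rb, _tb in mismatches):
                    uses_cca = True
        return AlignmentHit(
            read_id=read_id,
            gene_id=gid,
            variant=variant,
            start=off,
            end=off + L,
            identity=identity,
            weight=weight,
            mismatches=mismatches,
            read_seq=read,
            mature_start=mature_start,
            mature_end=mature_end,
            uses_cca=uses_cca,
        )

    def map_reads(self, reads) -> tuple[list[AlignmentHit], MappingStats]:
        """Map an iterable of ``(read_id, sequence)`` pairs."""
        stats = MappingStats()
        hits: list[AlignmentHit] = []
        for read_id, seq in reads:
            if len(seq) < self.config.min_length:
                stats.too_short += 1
                continue
            h = self.map_read(seq, read_id)
            if h:
                stats.mapped += 1
                hits.extend(h)
            else:
                stats.unmapped += 1
        return hits, stats


def assign_weights(hits_by_read: dict[str, list[AlignmentHit]]) -> None:
    """Re-normalize weights to 1/k over each read's retained hits (in place)."""
    for hits in hits_by_read.values():
        if not hits:
            continue
        w = 1.0 / len(hits)
        for h in hits:
            h.weight = w


# ---------------------------------------------------------------------------
# TSV interchange


_HIT_COLUMNS = [
    "read_id",
    "gene_id",
    "variant",
    "start",
    "end",
    "identity",
    "weight",
    "mismatches",
    "read_seq",
    "mature_start",
    "mature_end",
    "uses_cca",
    "untemplated_5p",
]


def hits_to_frame(hits: list[AlignmentHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append(
            {
                "read_id": h.read_id,
                "gene_id": h.gene_id,
                "variant": h.variant,
                "start": h.start,
                "end": h.end,
                "identity": round(h.identity, 6),
                "weight": h.weight,
                "mismatches": ";".join(
                    f"{p}:{rb}>{tb}" for p, rb, tb in h.mismatches
                ),
                "read_seq": h.read_seq,
                "mature_start": "" if h.mature_start is None else h.mature_start,
                "mature_end": "" if h.mature_end is None else h.mature_end,
                "uses_cca": int(h.uses_cca),
                "untemplated_5p": h.untemplated_5p,
            }
        )
    return pd.DataFrame(rows, columns=_HIT_COLUMNS)


def frame_to_hits(frame: pd.DataFrame) -> list[AlignmentHit]:
    hits = []
    for row in frame.itertuples(index=False):
        mismatches = []
        if isinstance(row.mismatches, str) and row.mismatches:
            for chunk in row.mismatches.split(";"):
                pos, change = chunk.split(":")
                rb, tb = change.split(">")
                mismatches.append((int(pos), rb, tb))
        ms = row.mature_start
        me = row.mature_end
        blank = lambda v: v == "" or (isinstance(v, float) and np.isnan(v))
        hits.append(
            AlignmentHit(
                read_id=str(row.read_id),
                gene_id=row.gene_id,
                variant=row.variant,
                start=int(row.start),
                end=int(row.end),
                identity=float(row.identity),
                weight=float(row.weight),
                mismatches=tuple(mismatches),
                read_seq=row.read_seq,
                mature_start=None if blank(ms) else int(ms),
                mature_end=None if blank(me) else int(me),
                uses_cca=bool(int(row.uses_cca)),
                untemplated_5p=int(row.untemplated_5p),
            )
        )
    return hits
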