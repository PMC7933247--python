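"""tRF structural classification, identifiers, and support filters.

A fragment is placed into one of twelve structural classes from its span in
mature-tRNA coordinates (5' flank negative, 3' flank/CCA >= mature length):

``Full_tRNA``/``Full_U_tRNA`` cover the whole mature span (``U`` = extends
into a flank); the four "halves" classes are anticodon-cleavage products
anchored at one mature terminus; ``5_tRFs``/``3_tRFs`` are terminus-anchored
fragments that stop short of the anticodon; ``5_U_tRF``/``3_U_tRF`` are their
flank-overlapping counterparts; ``i_tRFs`` are internal fragments; ``other``
collects fragments mapped entirely to the flanking regions.

Rules are applied first-match in the order above, so classification is a
deterministic total function on fragment intervals. Fragment ends are matched
to the termini with a +/-2 nt tolerance (untemplated 5' additions occupy
negative offsets; the 3' CCA counts as a templated terminus), and a fragment
end lies "within the anticodon" if it falls at most one base outside the
anticodon triplet.

Each distinct fragment sequence is minted an identifier ``tRF#<Len>-<SeqCODE>``
where SeqCODE packs the sequence at 2 bits per base, emitted 5 bits per
character over a fixed 32-character alphabet (a documented, reversible codec).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .refdb import TRNAReferenceSet, symbol_sort_key

TRF_CLASSES = (
    "Full_tRNA",
    "Full_U_tRNA",
    "5_tRNA_halves",
    "5_U_tRNA_halves",
    "3_tRNA_halves",
    "3_U_tRNA_halves",
    "5_U_tRF",
    "3_U_tRF",
    "5_tRFs",
    "3_tRFs",
    "i_tRFs",
    "other",
)

#: tolerance (nt) for matching a fragment end to a mature terminus
END_TOLERANCE = 2


@dataclass(frozen=True)
class GeneModel:
    """Per-gene structure needed for classification."""

    mature_len: int
    anticodon_start: int
    anticodon_end: int  # half-open

    @classmethod
    def from_gene(cls, gene_ref) -> "GeneModel":
        ann = gene_ref.gene
        a0, a1 = ann.anticodon_interval
        return cls(
            mature_len=len(gene_ref.mature), anticodon_start=a0, anticodon_end=a1
        )


def classify_fragment(
    start: int,
    end: int,
    model: GeneModel,
    *,
    uses_cca: bool = False,
    untemplated_5p: int | None = None,
) -> str:
    """Class label for a fragment spanning ``[start, end)`` in mature coords.

    ``untemplated_5p=None`` means the templated/untemplated status of any 5'
    overhang is unknown (pure interval classification): a raw start within
    ``[-2, +2]`` then counts as the mature 5' terminus. When additions
    detection has run, pass the number of untemplated leading bases; they are
    stripped and the remaining (templated) start must lie in ``[0, +2]`` —
    a templated 5' overhang then classifies as a flank-overlapping class.
    """
    if end <= start:
        raise ValueError(f"empty fragment interval [{start}, {end})")
    L = model.mature_len
    if start < -(1 << 20) or end > L + (1 << 20):
        raise ValueError("fragment interval outside the variant")

    if end <= 0 or start >= L:
        return "other"  # flank-only (or CCA-only) fragment

    if untemplated_5p is None:
        s, lo5 = start, -END_TOLERANCE
    else:
        s, lo5 = start + untemplated_5p, 0
    at5 = lo5 <= s <= END_TOLERANCE
    into5 = s < lo5

    hi3 = L + 3 if uses_cca else L + END_TOLERANCE
    at3 = L - END_TOLERANCE <= end <= hi3
    into3 = (not uses_cca) and end > L + END_TOLERANCE

    if (at5 or into5) and (at3 or into3):
        return "Full_U_tRNA" if (into5 or into3) else "Full_tRNA"

    if at5 or into5:
        # 5'-anchored: where does the 3' end fall relative to the anticodon?
        if model.anticodon_start <= end <= model.anticodon_end + 1:
            return "5_U_tRNA_halves" if into5 else "5_tRNA_halves"
        if end < model.anticodon_start:
            return "5_U_tRF" if into5 else "5_tRFs"
        return "i_tRFs"

    if at3 or into3:
        if model.anticodon_start - 1 <= s <= model.anticodon_end:
            return "3_U_tRNA_halves" if into3 else "3_tRNA_halves"
        if s > model.anticodon_end:
            return "3_U_tRF" if into3 else "3_tRFs"
        return "i_tRFs"

    return "i_tRFs"


# ---------------------------------------------------------------------------
# identifier codec

#: digits + uppercase letters minus the ambiguous I, L, O, Q
SEQCODE_ALPHABET = "0123456789ABCDEFGHJKMNPRSTUVWXYZ"
_CHAR_INDEX = {c: i for i, c in enumerate(SEQCODE_ALPHABET)}
_BASE_BITS = {"A": 0, "C": 1, "G": 2, "T": 3}
_BITS_BASE = "ACGT"


@dataclass(frozen=True)
class TRFIdentifier:
    length: int
    seq_code: str

    def __str__(self) -> str:
        return f"tRF#{self.length}-{self.seq_code}"


def seq_code_length(n_bases: int) -> int:
    return math.ceil(2 * n_bases / 5)


def encode_trf_id(sequence: str) -> TRFIdentifier:
    """Deterministic, injective identifier for an ACGT fragment sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    value = 0
    for base in sequence:
        try:
            value = (value << 2) | _BASE_BITS[base]
        except KeyError:
            raise ValueError(f"non-ACGT base {base!r} in sequence") from None
    nbits = 2 * len(sequence)
    pad = (-nbits) % 5
    value <<= pad
    nchars = (nbits + pad) // 5
    chars = []
    for shift in range((nchars - 1) * 5, -1, -5):
        chars.append(SEQCODE_ALPHABET[(value >> shift) & 0x1F])
    return TRFIdentifier(length=len(sequence), seq_code="".join(chars))


def decode_trf_id(ident: TRFIdentifier | str) -> str:
    """Invert :func:`encode_trf_id`."""
    if isinstance(ident, str):
        ident = parse_trf_id(ident)
    expected = seq_code_length(ident.length)
    if len(ident.seq_code) != expected:
        raise ValueError(
            f"code length {len(ident.seq_code)} inconsistent with a "
            f"{ident.length}-nt sequence (expected {expected})"
        )
    value = 0
    for ch in ident.seq_code:
        try:
            value = (value << 5) | _CHAR_INDEX[ch]
        except KeyError:
            raise ValueError(f"invalid SeqCODE character {ch!r}") from None
    nbits = 2 * ident.length
    value >>= (-nbits) % 5
    bases = []
    for shift in range(nbits - 2, -1, -2):
        bases.append(_BITS_BASE[(value >> shift) & 0x3])
    return "".join(bases)


def parse_trf_id(text: str) -> TRFIdentifier:
    if not text.startswith("tRF#") or "-" not in text:
        raise ValueError(f"not a tRF identifier: {text!r}")
    length, code = text[4:].split("-", 1)
    return TRFIdentifier(length=int(length), seq_code=code)


# ---------------------------------------------------------------------------
# per-read classification and tRF records


def classify_hit(hit, ref: TRNAReferenceSet) -> str:
    """Class label of one alignment hit, in its gene's mature coordinates."""
    model = GeneModel.from_gene(ref.genes[hit.gene_id])
    if hit.mature_start is None:
        return "other"
    return classify_fragment(
        hit.mature_start,
        hit.mature_end,
        model,
        uses_cca=hit.uses_cca,
        untemplated_5p=hit.untemplated_5p,
    )


def classify_reads(
    hits_by_sample: dict[str, list], ref: TRNAReferenceSet
) -> pd.DataFrame:
    """Per-read classification table; also annotates hits in place.

    The representative hit of a multi-mapped read is the one on the
    lexicographically smallest gene symbol; family members share a mature
    sequence so their class labels agree.
    """
    rows = []
    for sample in sorted(hits_by_sample):
        by_read: dict[str, list] = {}
        for hit in hits_by_sample[sample]:
            by_read.setdefault(hit.read_id, []).append(hit)
        for read_id, hits in by_read.items():
            for h in hits:
                h.trf_class = classify_hit(h, ref)
                h.family_id = ref.gene_family[h.gene_id]
            rep = min(hits, key=lambda h: symbol_sort_key(h.gene_id))
            rows.append(
                {
                    "sample": sample,
                    "read_id": read_id,
                    "sequence": rep.read_seq,
                    "trf_class": rep.trf_class,
                    "addition": rep.read_seq[: rep.untemplated_5p],
                    "families": ";".join(
                        sorted({h.family_id for h in hits})
                    ),
                    "genes": ";".join(sorted(h.gene_id for h in hits)),
                    "n_hits": len(hits),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "read_id",
            "sequence",
            "trf_class",
            "addition",
            "families",
            "genes",
            "n_hits",
        ],
    )


@dataclass
class TRFRecord:
    """One distinct fragment sequence with per-sample read support."""

    trf_id: TRFIdentifier
    sequence: str
    trf_class: str
    family_ids: tuple[str, ...]
    support: dict[str, float] = field(default_factory=dict)
    nr: dict[str, float] = field(default_factory=dict)
    addition: str = ""
    high_confidence: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


def build_trf_records(read_table: pd.DataFrame) -> list[TRFRecord]:
    """Aggregate the per-read table into distinct-sequence tRF records."""
    records: dict[str, TRFRecord] = {}
    for row in read_table.itertuples(index=False):
        rec = records.get(row.sequence)
        if rec is None:
            rec = TRFRecord(
                trf_id=encode_trf_id(row.sequence),
                sequence=row.sequence,
                trf_class=row.trf_class,
                family_ids=tuple(row.families.split(";")),
                addition=row.addition,
            )
            records[row.sequence] = rec
        rec.support[row.sample] = rec.support.get(row.sample, 0.0) + 1.0
    return sorted(records.values(), key=lambda r: (-max(r.support.values()), r.sequence))


def filter_trfs(
    records: list[TRFRecord],
    min_support: int = 500,
    hc_support: int = 1000,
    hc_samples: int = 2,
    min_len: int = 18,
) -> tuple[list[TRFRecord], list[TRFRecord]]:
    """Apply the support filters; returns (retained, high-confidence).

    Retention requires length >= ``min_len`` and support strictly above
    ``min_support`` in at least one sample; the high-confidence flag requires
    support strictly above ``hc_support`` in at least ``hc_samples`` samples.
    """
    retained, high_conf = [], []
    for rec in records:
        if rec.length < min_len:
            continue
        if not any(v > min_support for v in rec.support.values()):
            continue
        retained.append(rec)
        if sum(v > hc_support for v in rec.support.values()) >= hc_samples:
            rec.high_confidence = True
            high_conf.append(rec)
    return retained, high_conf


def trf_table(records: list[TRFRecord], samples: list[str]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "trf_id": str(rec.trf_id),
            "sequence": rec.sequence,
            "length": rec.length,
            "trf_class": rec.trf_class,
            "families": ";".join(rec.family_ids),
            "addition": rec.addition,
            "high_confidence": int(rec.high_confidence),
        }
        for s in samples:
            row[f"support_{s}"] = rec.support.get(s, 0.0)
            if rec.nr:
                row[f"NR_{s}"] = rec.nr.get(s, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
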