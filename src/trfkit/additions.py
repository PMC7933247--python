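"""Untemplated 5' nucleotide additions (G-1, T-1, dinucleotides).

A read whose alignment starts 1-3 bases 5' of the mature tRNA start carries a
5' overhang. The overhang is an *addition* only if its innermost (-1) base
mismatches the templated upstream genomic base — otherwise the read is simply
a precursor fragment. A dinucleotide overhang counts as an addition whenever
the -1 base mismatches, even if the -2 base happens to match the template
(the -1 mismatch is the untemplated signature).

Detection annotates each hit's ``untemplated_5p`` in place (classification
then strips the addition bases before matching the fragment start to the
mature terminus), and emits one weighted event row per (hit, sample).
Addition strings supported by fewer than 50 weighted reads in a sample are
flagged low-confidence unless the same string recurs in at least two samples.
"""

from __future__ import annotations

import pandas as pd

from .refdb import TRNAReferenceSet

MAX_ADDITION_LEN = 3

#: class groups used for composition panels
CLASS_GROUPS = {
    "Full_tRNA": "full",
    "Full_U_tRNA": "full",
    "5_tRNA_halves": "5_halves",
    "5_U_tRNA_halves": "5_halves",
    "3_tRNA_halves": "3_halves",
    "3_U_tRNA_halves": "3_halves",
}


def detect_additions(
    hits_by_sample: dict[str, list],
    ref: TRNAReferenceSet,
    max_len: int = MAX_ADDITION_LEN,
    low_conf_support: float = 50.0,
) -> pd.DataFrame:
    """Detect untemplated 5' additions; annotates hit.untemplated_5p in place.

    Returns one row per (sample, hit) addition event with the event's
    alignment weight as support.
    """
    rows = []
    for sample in sorted(hits_by_sample):
        for hit in hits_by_sample[sample]:
            hit.untemplated_5p = 0
            ms = hit.mature_start
            if ms is None or ms >= 0 or ms < -max_len:
                continue
            if hit.variant not in ("pre_intron", "pre_spliced"):
                continue
            k = -ms
            # variant position of mature coordinate -1 under the read
            minus_one = hit.start + k - 1
            if not any(pos == minus_one for pos, _rb, _tb in hit.mismatches):
                continue  # templated overhang: a precursor fragment
            hit.untemplated_5p = k
            rows.append(
                {
                    "sample": sample,
                    "read_id": hit.read_id,
                    "gene_id": hit.gene_id,
                    "family_id": ref.gene_family[hit.gene_id],
                    "addition": hit.read_seq[:k],
                    "weight": hit.weight,
                }
            )
    events = pd.DataFrame(
        rows,
        columns=["sample", "read_id", "gene_id", "family_id", "addition", "weight"],
    )
    if len(events):
        support = (
            events.groupby(["addition", "sample"])["weight"].sum().rename("support")
        )
        n_samples = events.groupby("addition")["sample"].nunique()
        flagged = {
            (add, sample): bool(sup < low_conf_support and n_samples[add] < 2)
            for (add, sample), sup in support.items()
        }
        events["low_confidence"] = [
            flagged[(row.addition, row.sample)]
            for row in events.itertuples(index=False)
        ]
    else:
        events["low_confidence"] = pd.Series(dtype=bool)
    return events


def addition_composition(
    read_table: pd.DataFrame, families: list[str] | None = None
) -> pd.DataFrame:
    """Per (class group, sample) composition of 5' additions.

    ``read_table`` is the per-read classification table (one row per read,
    with its detected ``addition`` string, possibly empty). Fractions within
    each group/sample — including the no-addition remainder — sum to 1.
    """
    df = read_table
    if families is not None:
        fams = set(families)
        df = df[
            df["families"].map(lambda s: bool(fams & set(s.split(";"))))
        ]
    if df.empty:
        return pd.DataFrame(
            columns=["group", "sample", "addition", "count", "fraction"]
        )
    df = df.assign(
        group=df["trf_class"].map(CLASS_GROUPS).fillna("other_classes"),
        addition=df["addition"].replace("", "none"),
    )
    frames = []
    for scope in (df, df.assign(group="all")):
        counts = (
            scope.groupby(["group", "sample", "addition"])
            .size()
            .rename("count")
            .reset_index()
        )
        totals = counts.groupby(["group", "sample"])["count"].transform("sum")
        counts["fraction"] = counts["count"] / totals
        frames.append(counts)
    return pd.concat(frames, ignore_index=True).sort_values(
        ["group", "sample", "addition"], ignore_index=True
    )


def dominant_additions(composition: pd.DataFrame) -> pd.DataFrame:
    """The most frequent addition string (additions only) per sample."""
    adds = composition[
        (composition["group"] == "all") & (composition["addition"] != "none")
    ]
    if adds.empty:
        return pd.DataFrame(columns=["sample", "addition", "fraction"])
    idx = adds.groupby("sample")["fraction"].idxmax()
    return adds.loc[idx, ["sample", "addition", "fraction"]].reset_index(drop=True)
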