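"""Modification-site detection from reverse-transcription mismatch pileups.

Base modifications that survive library preparation leave a mismatch
signature: the reverse transcriptase misreads the modified base, so the
mismatch ratio MR = (weighted mismatching reads) / (weighted coverage) at the
position is driven toward 1. Pileups are built at the family level — genes
within a family share one mature sequence — in mature coordinates, using
alignment weights (a read assigned at weight 0.5 contributes 0.5 coverage).

A site is called a candidate modification when MR strictly exceeds 0.8 with
strictly more than 200 supporting reads (coverage). Comparing a demethylase
(AlkB-style) treated sample against its control separates alkylation-
sensitive methylations (control-only calls, the m1A58 pattern), modifications
unmasked by demethylation (treated-only, the 37A pattern), and treatment-
resistant sites such as m2,2G26 or the wobble A34 inosine (called in both).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .refdb import TRNAReferenceSet

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


def build_pileup(
    hits_by_sample: dict[str, list], ref: TRNAReferenceSet
) -> pd.DataFrame:
    """Weighted per-(family, mature position, sample) mismatch pileup.

    Columns: family, position, sample, coverage, mismatch, mr, and the
    read-base composition counts A/C/G/T.
    """
    fam_len = {
        fam.family_id: len(ref.family_representative(fam.family_id).mature)
        for fam in ref.families
    }
    fam_seq = {
        fid: ref.family_representative(fid).mature for fid in fam_len
    }
    cov: dict[tuple[str, str], np.ndarray] = {}
    mis: dict[tuple[str, str], np.ndarray] = {}
    comp: dict[tuple[str, str], np.ndarray] = {}

    for sample in sorted(hits_by_sample):
        for hit in hits_by_sample[sample]:
            fid = ref.gene_family[hit.gene_id]
            if hit.mature_start is None:
                continue
            L = fam_len[fid]
            lo = max(hit.mature_start, 0)
            hi = min(hit.mature_end, L)
            if hi <= lo:
                continue
            key = (fid, sample)
            if key not in cov:
                cov[key] = np.zeros(L)
                mis[key] = np.zeros(L)
                comp[key] = np.zeros((4, L))
            cov[key][lo:hi] += hit.weight
            gref = ref.genes[hit.gene_id]
            to_mature = gref.to_mature[hit.variant]
            for pos, read_base, _tmpl in hit.mismatches:
                m = int(to_mature[pos])
                if 0 <= m < L:
                    mis[key][m] += hit.weight
                    if read_base in _BASE_IDX:
                        comp[key][_BASE_IDX[read_base], m] += hit.weight

    rows = []
    for (fid, sample), coverage in sorted(cov.items()):
        mismatch = mis[(fid, sample)]
        composition = comp[(fid, sample)]
        seq = fam_seq[fid]
        covered = np.nonzero(coverage > 0)[0]
        for m in covered:
            base_counts = composition[:, m].copy()
            ref_base = seq[m]
            if ref_base in _BASE_IDX:
                base_counts[_BASE_IDX[ref_base]] += coverage[m] - mismatch[m]
            rows.append(
                {
                    "family": fid,
                    "position": int(m),
                    "sample": sample,
                    "coverage": float(coverage[m]),
                    "mismatch": float(mismatch[m]),
                    "mr": float(mismatch[m] / coverage[m]),
                    "A": float(base_counts[0]),
                    "C": float(base_counts[1]),
                    "G": float(base_counts[2]),
                    "T": float(base_counts[3]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "family",
            "position",
            "sample",
            "coverage",
            "mismatch",
            "mr",
            "A",
            "C",
            "G",
            "T",
        ],
    )


def call_sites(
    profile: pd.DataFrame,
    min_mr: float = 0.8,
    min_reads: float = 200,
    position_labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Candidate modification sites: MR > ``min_mr`` and coverage > ``min_reads``.

    Both thresholds are strict inequalities. ``position_labels`` optionally
    maps mature coordinates to canonical tRNA nomenclature labels (9, 26, 34,
    37, 58, ...); the mapping is an annotation input, not inferred.
    """
    if profile.empty:
        return profile.assign(label=pd.Series(dtype=str))
    calls = profile[
        (profile["mr"] > min_mr) & (profile["coverage"] > min_reads)
    ].copy()
    labels = position_labels or {}
    calls["label"] = [
        labels.get(p, str(p)) for p in calls["position"]
    ]
    return calls.reset_index(drop=True)


def treatment_contrast(
    calls_control: pd.DataFrame, calls_treated: pd.DataFrame
) -> pd.DataFrame:
    """Label each called (family, position) site by its treatment status."""
    if calls_control is None or calls_treated is None:
        raise ValueError("both control and treated call sets are required")
    key = ["family", "position"]
    ctrl = (
        set(map(tuple, calls_control[key].itertuples(index=False)))
        if len(calls_control)
        else set()
    )
    trt = (
        set(map(tuple, calls_treated[key].itertuples(index=False)))
        if len(calls_treated)
        else set()
    )
    rows = []
    for fam, pos in sorted(ctrl | trt):
        if (fam, pos) in ctrl and (fam, pos) in trt:
            status = "both"
        elif (fam, pos) in ctrl:
            status = "control_only"
        else:
            status = "treated_only"
        rows.append({"family": fam, "position": pos, "status": status})
    return pd.DataFrame(rows, columns=["family", "position", "status"])


def global_mismatch_fraction(hits_by_sample: dict[str, list]) -> dict[str, float]:
    """Per sample: fraction of mapped reads carrying >= 1 mismatch.

    A multi-mapped read counts once, as mismatched if any of its weighted
    hits mismatches (family members share sequence, so hits agree in
    practice).
    """
    out = {}
    for sample, hits in hits_by_sample.items():
        reads: dict[str, bool] = {}
        for h in hits:
            reads[h.read_id] = reads.get(h.read_id, False) or bool(h.mismatches)
        out[sample] = (
            sum(reads.values()) / len(reads) if reads else 0.0
        )
    return out


def mr_histogram(profile: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Histogram of per-site MR over mismatched sites, one row per bin/sample.

    The two-peak shape (near 0 and near 1) is the diagnostic separating
    sequencing noise from near-stoichiometric modifications.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    sites = profile[profile["mismatch"] > 0]
    for sample, grp in sites.groupby("sample"):
        counts, _ = np.histogram(grp["mr"], bins=edges)
        for i, c in enumerate(counts):
            rows.append(
                {
                    "sample": sample,
                    "bin_lo": edges[i],
                    "bin_hi": edges[i + 1],
                    "n_sites": int(c),
                }
            )
    return pd.DataFrame(rows, columns=["sample", "bin_lo", "bin_hi", "n_sites"])
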