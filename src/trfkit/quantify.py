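"""Abundance quantification and sample correlation.

The relative abundance of any entity (tRF, gene, family, isodecoder,
isoacceptor, amino-acid group) in a sample is the normalized read number

    NR = M * 1e9 / N

where M is the entity's weighted mapped-read count and N the total number of
reads in the sample's FASTQ (counted before trimming and mapping, so filtered
reads still contribute to N). NR is additive: an entity's NR at a coarse
hierarchy level is the sum over its members, and the per-sample total at any
level equals (total mapped weight) * 1e9 / N.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .refdb import HIERARCHY_LEVELS, TRNAReferenceSet


def normalized_reads(m: float, n: float) -> float:
    """NR = M * 1e9 / N."""
    if n <= 0:
        raise ValueError("total read count N must be positive")
    if m < 0:
        raise ValueError("mapped count M must be non-negative")
    return m * 1e9 / n


def gene_weight_table(hits_by_sample: dict[str, list]) -> pd.DataFrame:
    """Long table of assigned weights: sample, read_id, gene_id, weight."""
    rows = [
        {
            "sample": sample,
            "read_id": h.read_id,
            "gene_id": h.gene_id,
            "weight": h.weight,
        }
        for sample in sorted(hits_by_sample)
        for h in hits_by_sample[sample]
    ]
    return pd.DataFrame(rows, columns=["sample", "read_id", "gene_id", "weight"])


def expression_matrix(
    weights: pd.DataFrame,
    ref: TRNAReferenceSet,
    level: str,
    totals: dict[str, float],
) -> pd.DataFrame:
    """Entity x sample matrix of NR at one hierarchy level."""
    if level not in HIERARCHY_LEVELS:
        raise ValueError(
            f"unknown hierarchy level {level!r}; expected one of {HIERARCHY_LEVELS}"
        )
    labels = {gid: ref.hierarchy[gid][level] for gid in ref.genes}
    df = weights.assign(entity=weights["gene_id"].map(labels))
    mat = (
        df.pivot_table(
            index="entity", columns="sample", values="weight", aggfunc="sum"
        )
        .reindex(columns=sorted(totals))
        .fillna(0.0)
    )
    for sample in mat.columns:
        mat[sample] = mat[sample] * 1e9 / totals[sample]
    mat.columns.name = None
    mat.index.name = level
    return mat


def trf_expression(records, totals: dict[str, float]) -> pd.DataFrame:
    """tRF-level NR matrix; also fills each record's ``nr`` dict in place."""
    rows = {}
    for rec in records:
        nr = {
            s: normalized_reads(rec.support.get(s, 0.0), totals[s])
            for s in sorted(totals)
        }
        rec.nr = nr
        rows[str(rec.trf_id)] = nr
    mat = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=sorted(totals)
    )
    mat.index.name = "trf_id"
    return mat.fillna(0.0)


def sample_correlation(
    matrix: pd.DataFrame, log_offset: float = 1.0
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Pairwise r^2 of log10(NR + offset) profiles plus a display order.

    Returns ``(r2, clustered_order, zero_variance_samples)``. Zero-variance
    profiles get r^2 = 0 against everything (flagged, not an error); the
    clustering (average linkage on 1 - r^2) is display-only.
    """
    samples = list(matrix.columns)
    if len(samples) < 2:
        raise ValueError("sample correlation needs at least two samples")
    X = np.log10(matrix.to_numpy(dtype=float) + log_offset)
    stds = X.std(axis=0)
    # constant profiles can carry ~1e-16 float fuzz; treat them as flat
    tol = 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))
    stds = np.where(stds <= tol, 0.0, stds)
    flagged = [s for s, sd in zip(samples, stds) if sd == 0]
    n = len(samples)
    r2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                r2[i, j] = 1.0
            elif stds[i] == 0 or stds[j] == 0:
                r2[i, j] = r2[j, i] = 0.0
            else:
                r = np.corrcoef(X[:, i], X[:, j])[0, 1]
                r2[i, j] = r2[j, i] = r * r
    r2df = pd.DataFrame(r2, index=samples, columns=samples)
    dist = 1.0 - r2
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    order = (
        [samples[i] for i in leaves_list(average(squareform(dist, checks=False)))]
        if n > 2
        else samples
    )
    return r2df, order, flagged
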