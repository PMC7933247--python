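"""Cleavage-site profiling from fragment end positions.

Every mapped fragment contributes exactly one 5'-end and one 3'-end boundary
per family (weighted by its alignment weight). Boundaries are between-base
cut coordinates in mature space: a cut after mature position i is boundary
i + 1, so boundary 0 is the mature 5' terminus and boundary L the 3' terminus.
A fragment ending inside the post-transcriptional CCA ends at the terminus,
not at a cleavage site.

Family profiles are projected onto a fixed 70-bin virtual tRNA axis
(position p of a length-L family maps to bin floor(p * 70 / L)) so end-peak
positions can be aggregated across families of different lengths. Sites are
called at >= 1000 supporting reads in >= 2 samples; terminal boundaries are
reported separately, and for template-switch libraries the 5'-end side is
excluded from calling by default because early RT stops are indistinguishable
from genuine 5' cleavage there. Seven-base sequence contexts (3 bases 5' +
4 bases 3' of the cut) around >= 100-read sites are exported for external
motif discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .refdb import TRNAReferenceSet
from .seqfiles import write_fasta


@dataclass
class CleavageProfile:
    """Weighted 5'/3' fragment-end counts per (family, boundary, sample)."""

    counts: pd.DataFrame
    family_len: dict[str, int]
    samples: list[str]
    libprep: str | None = None


@dataclass
class CleavageSite:
    family: str
    boundary: int
    side: str  # "five" or "three"
    support: dict[str, float] = field(default_factory=dict)
    flank7: str | None = None


def collect_end_counts(
    hits_by_sample: dict[str, list],
    ref: TRNAReferenceSet,
    libprep: str | None = None,
) -> CleavageProfile:
    """Accumulate weighted fragment-end boundaries per family and sample."""
    fam_len = {
        fam.family_id: len(ref.family_representative(fam.family_id).mature)
        for fam in ref.families
    }
    acc: dict[tuple[str, int, str], dict[str, float]] = {}
    for sample in sorted(hits_by_sample):
        for hit in hits_by_sample[sample]:
            if hit.mature_start is None:
                continue
            fid = ref.gene_family[hit.gene_id]
            L = fam_len[fid]
            five = hit.mature_start + hit.untemplated_5p
            three = min(hit.mature_end, L) if hit.uses_cca else hit.mature_end
            for boundary, side in ((five, "five"), (three, "three")):
                key = (fid, boundary, side)
                acc.setdefault(key, {})
                acc[key][sample] = acc[key].get(sample, 0.0) + hit.weight
    samples = sorted(hits_by_sample)
    rows = []
    for (fid, boundary, side), per_sample in sorted(acc.items()):
        row = {"family": fid, "boundary": boundary, "side": side}
        for s in samples:
            row[s] = per_sample.get(s, 0.0)
        rows.append(row)
    counts = pd.DataFrame(rows, columns=["family", "boundary", "side", *samples])
    return CleavageProfile(
        counts=counts, family_len=fam_len, samples=samples, libprep=libprep
    )


def project_virtual(profile: CleavageProfile, axis_len: int = 70) -> pd.DataFrame:
    """Sum end counts onto the fixed virtual-tRNA axis.

    Only boundaries within the mature span [0, L] are projected; counts are
    summed unnormalized over families and samples, and frequencies computed
    at the end.
    """
    five = [0.0] * axis_len
    three = [0.0] * axis_len
    for row in profile.counts.itertuples(index=False):
        L = profile.family_len[row.family]
        if not 0 <= row.boundary <= L:
            continue
        b = min(row.boundary * axis_len // L, axis_len - 1)
        total = sum(getattr(row, s) for s in profile.samples)
        if row.side == "five":
            five[b] += total
        else:
            three[b] += total
    out = pd.DataFrame(
        {"bin": range(axis_len), "five_count": five, "three_count": three}
    )
    for side in ("five", "three"):
        total = out[f"{side}_count"].sum()
        out[f"{side}_freq"] = out[f"{side}_count"] / total if total else 0.0
    return out


def call_cleavage_sites(
    profile: CleavageProfile,
    min_reads: float = 1000,
    min_samples: int = 2,
    include_five_prime: bool | None = None,
    include_terminal: bool = False,
) -> list[CleavageSite]:
    """Sites supported by >= ``min_reads`` reads in >= ``min_samples`` samples.

    Thresholds are inclusive. For template-switch libraries the 5'-end side
    defaults to excluded (early RT stops mimic 5' cleavage); pass
    ``include_five_prime=True`` to override.
    """
    if include_five_prime is None:
        include_five_prime = profile.libprep != "template_switch"
    sites = []
    for row in profile.counts.itertuples(index=False):
        if row.side == "five" and not include_five_prime:
            continue
        L = profile.family_len[row.family]
        if not 0 <= row.boundary <= L:
            continue
        if not include_terminal and row.boundary in (0, L):
            continue
        support = {s: getattr(row, s) for s in profile.samples}
        if sum(v >= min_reads for v in support.values()) >= min_samples:
            sites.append(
                CleavageSite(
                    family=row.family,
                    boundary=row.boundary,
                    side=row.side,
                    support=support,
                )
            )
    return sites


def extract_flanks(
    profile: CleavageProfile,
    ref: TRNAReferenceSet,
    width: int = 7,
    min_reads: float = 100,
    min_samples: int = 1,
    path=None,
) -> list[tuple[str, str]]:
    """Unique sequence contexts around cleavage sites, for motif discovery.

    The window of ``width`` bases splits (width-1)//2 bases 5' and the rest
    3' of the cut boundary (3+4 for the default 7). Windows running past the
    precursor edge are padded with N. Deduplicated by sequence; optionally
    written as FASTA.
    """
    sites = call_cleavage_sites(
        profile, min_reads=min_reads, min_samples=min_samples
    )
    left = (width - 1) // 2
    seen: dict[str, str] = {}
    for site in sites:
        gref = ref.family_representative(site.family)
        ctx = gref.sequences["pre_spliced"]
        cut = gref.flank + site.boundary
        lo, hi = cut - left, cut + (width - left)
        window = (
            "N" * max(0, -lo)
            + ctx[max(0, lo) : min(len(ctx), hi)]
            + "N" * max(0, hi - len(ctx))
        )
        site.flank7 = window
        if window not in seen:
            seen[window] = f"{site.family}|{site.side}|{site.boundary}"
    records = sorted((name, seq) for seq, name in seen.items())
    if path is not None:
        write_fasta(path, records)
    return records


def sites_table(sites: list[CleavageSite], samples: list[str]) -> pd.DataFrame:
    rows = []
    for s in sites:
        row = {
            "family": s.family,
            "boundary": s.boundary,
            "side": s.side,
            "flank7": s.flank7 or "",
        }
        for name in samples:
            row[f"support_{name}"] = s.support.get(name, 0.0)
        rows.append(row)
    cols = ["family", "boundary", "side", "flank7"] + [
        f"support_{s}" for s in samples
    ]
    return pd.DataFrame(rows, columns=cols)
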