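"""Fragment-end profiling, virtual-axis projection, cleavage-site calling."""

from __future__ import annotations

import numpy as np
import pytest

from trfkit.align import ReadAligner
from trfkit.additions import detect_additions
from trfkit.cleavage import (
    call_cleavage_sites,
    collect_end_counts,
    extract_flanks,
    project_virtual,
)
from trfkit.simulate import SimConfig, simulate_reads


def _hits_for(toy_ref, config):
    samples, truth = simulate_reads(config, toy_ref)
    aligner = ReadAligner(toy_ref)
    hits = {
        s: aligner.map_reads((r[0], r[1]) for r in reads)[0]
        for s, reads in samples.items()
    }
    detect_additions(hits, toy_ref)
    return hits, truth


class TestCollectEndCounts:
    def test_identical_fragments_one_peak_per_side(self, toy_ref):
        gref = toy_ref.genes["tRNA-His-GTG-3-1"]
        frag = gref.mature[0:35]
        aligner = ReadAligner(toy_ref)
        hits = {"S1": []}
        for i in range(100):
            hits["S1"].extend(aligner.map_read(frag, f"r{i}"))
        profile = collect_end_counts(hits, toy_ref)
        fam = toy_ref.gene_family["tRNA-His-GTG-3-1"]
        five = profile.counts[
            (profile.counts.family == fam) & (profile.counts.side == "five")
        ]
        three = profile.counts[
            (profile.counts.family == fam) & (profile.counts.side == "three")
        ]
        assert list(five.boundary) == [0] and five.S1.iloc[0] == 100.0
        assert list(three.boundary) == [35] and three.S1.iloc[0] == 100.0

    def test_weights_halve_counts(self, toy_ref):
        fam2 = next(f for f in toy_ref.families if len(f.member_gene_ids) == 2)
        shared = toy_ref.genes[fam2.member_gene_ids[0]].mature[0:35]
        aligner = ReadAligner(toy_ref)
        hits = {"S1": aligner.map_read(shared, "r0")}
        assert len(hits["S1"]) == 2  # two genes, weight 0.5 each
        profile = collect_end_counts(hits, toy_ref)
        five = profile.counts[profile.counts.side == "five"]
        # both hits fall in the same family, so the family total is 1 read
        assert five.S1.sum() == pytest.approx(1.0)

    def test_end_count_conservation(self, toy_ref, clean_hits):
        profile = collect_end_counts(clean_hits, toy_ref)
        for sample in profile.samples:
            per_side = profile.counts.groupby("side")[sample].sum()
            assert per_side["five"] == pytest.approx(per_side["three"])

    def test_programmed_cut_recovered_exactly(self, toy_ref):
        """Fixed anticodon-boundary cuts put the peaks where the ground
        truth says."""
        config = SimConfig(
            seed=51,
            depth=2000,
            n_samples=2,
            class_mix={"5_tRNA_halves": 0.5, "3_tRNA_halves": 0.5},
        )
        hits, truth = _hits_for(toy_ref, config)
        profile = collect_end_counts(hits, toy_ref)
        emitted = truth[truth.emitted]
        for fam, grp in emitted.groupby("family_id"):
            fam_counts = profile.counts[profile.counts.family == fam]
            L = profile.family_len[fam]
            expected_three = {
                min(int(e), L) for e in grp[grp.requested_class == "5_tRNA_halves"].end
            }
            observed_three = set(
                fam_counts[fam_counts.side == "three"].boundary
            )
            assert expected_three <= observed_three


class TestProjectVirtual:
    def test_length_70_identity_mapping(self, toy_ref):
        import pandas as pd

        from trfkit.cleavage import CleavageProfile

        counts = pd.DataFrame(
            [
                {"family": "f", "boundary": 35, "side": "five", "S1": 10.0},
                {"family": "f", "boundary": 35, "side": "three", "S1": 4.0},
            ]
        )
        profile = CleavageProfile(
            counts=counts, family_len={"f": 70}, samples=["S1"]
        )
        axis = project_virtual(profile)
        assert axis.loc[35, "five_count"] == 10.0
        assert axis.loc[35, "three_count"] == 4.0

    def test_scaling_example_72_to_70(self):
        import pandas as pd

        from trfkit.cleavage import CleavageProfile

        counts = pd.DataFrame(
            [{"family": "f", "boundary": 36, "side": "five", "S1": 1.0}]
        )
        profile = CleavageProfile(
            counts=counts, family_len={"f": 72}, samples=["S1"]
        )
        axis = project_virtual(profile)
        assert axis.loc[35, "five_count"] == 1.0  # floor(36 * 70 / 72) = 35

    def test_mass_conservation_over_bins(self, toy_ref, clean_hits):
        profile = collect_end_counts(clean_hits, toy_ref)
        axis = project_virtual(profile)
        in_span = profile.counts[
            profile.counts.apply(
                lambda r: 0 <= r.boundary <= profile.family_len[r.family], axis=1
            )
        ]
        for side in ("five", "three"):
            total_in = in_span[in_span.side == side][profile.samples].sum().sum()
            assert axis[f"{side}_count"].sum() == pytest.approx(total_in)
        for side in ("five", "three"):
            assert axis[f"{side}_freq"].sum() == pytest.approx(1.0)


class TestCallSites:
    def _profile(self, supports, boundary=35, L=72):
        import pandas as pd

        from trfkit.cleavage import CleavageProfile

        samples = sorted(supports)
        counts = pd.DataFrame(
            [
                {
                    "family": "f",
                    "boundary": boundary,
                    "side": "three",
                    **supports,
                }
            ]
        )
        return CleavageProfile(
            counts=counts, family_len={"f": L}, samples=samples
        )

    def test_1000_in_two_samples_called(self):
        sites = call_cleavage_sites(self._profile({"S1": 1000.0, "S2": 1000.0}))
        assert len(sites) == 1

    def test_999_plus_huge_single_sample_not_called(self):
        sites = call_cleavage_sites(self._profile({"S1": 999.0, "S2": 1e6}))
        assert sites == []

    def test_monotone_in_min_reads(self):
        prof = self._profile({"S1": 1500.0, "S2": 1200.0})
        low = call_cleavage_sites(prof, min_reads=1000)
        high = call_cleavage_sites(prof, min_reads=1300)
        assert len(high) <= len(low)

    def test_terminal_boundaries_excluded_by_default(self):
        term = self._profile({"S1": 5000.0, "S2": 5000.0}, boundary=72)
        assert call_cleavage_sites(term) == []
        assert len(call_cleavage_sites(term, include_terminal=True)) == 1

    def test_five_prime_suppressed_for_template_switch(self):
        import pandas as pd

        from trfkit.cleavage import CleavageProfile

        counts = pd.DataFrame(
            [
                {"family": "f", "boundary": 35, "side": "five", "S1": 2000.0,
                 "S2": 2000.0},
                {"family": "f", "boundary": 40, "side": "three", "S1": 2000.0,
                 "S2": 2000.0},
            ]
        )
        prof = CleavageProfile(
            counts=counts,
            family_len={"f": 72},
            samples=["S1", "S2"],
            libprep="template_switch",
        )
        sides = {s.side for s in call_cleavage_sites(prof)}
        assert sides == {"three"}
        both = {s.side for s in call_cleavage_sites(prof, include_five_prime=True)}
        assert both == {"five", "three"}


class TestExtractFlanks:
    def test_window_split_3_plus_4(self, toy_ref):
        gref = toy_ref.genes["tRNA-His-GTG-3-1"]
        fam = toy_ref.gene_family["tRNA-His-GTG-3-1"]
        aligner = ReadAligner(toy_ref)
        hits = {"S1": [], "S2": []}
        frag = gref.mature[0:35]
        for i in range(150):
            hits["S1"].extend(aligner.map_read(frag, f"a{i}"))
            hits["S2"].extend(aligner.map_read(frag, f"b{i}"))
        profile = collect_end_counts(hits, toy_ref)
        records = extract_flanks(profile, toy_ref, min_reads=100, min_samples=2)
        ctx = gref.sequences["pre_spliced"]
        expected = ctx[60 + 35 - 3 : 60 + 35 + 4]
        assert (f"{fam}|three|35", expected) in records

    def test_duplicate_windows_deduplicated(self, toy_ref):
        import pandas as pd

        from trfkit.cleavage import CleavageProfile

        fam = toy_ref.families[0].family_id
        L = len(toy_ref.family_representative(fam).mature)
        # a matched 5'/3' pair at one cut shares a single sequence context
        counts = pd.DataFrame(
            [
                {"family": fam, "boundary": 35, "side": "three", "S1": 500.0},
                {"family": fam, "boundary": 35, "side": "five", "S1": 500.0},
            ]
        )
        profile = CleavageProfile(
            counts=counts, family_len={fam: L}, samples=["S1"]
        )
        records = extract_flanks(profile, toy_ref, min_reads=100, min_samples=1)
        assert len(records) == 1

    def test_simulated_cut_motif_recovered(self, toy_ref):
        config = SimConfig(
            seed=52,
            depth=4000,
            n_samples=2,
            class_mix={"Full_tRNA": 1.0},
        )
        hits, _truth = _hits_for(toy_ref, config)
        profile = collect_end_counts(hits, toy_ref)
        # full-length reads only: no internal site passes, terminal excluded
        assert call_cleavage_sites(profile, min_reads=100, min_samples=2) == []

    def test_edge_window_padded_with_n(self, toy_ref):
        import pandas as pd

        from trfkit.cleavage import CleavageProfile

        fam = toy_ref.families[0].family_id
        gref = toy_ref.family_representative(fam)
        L = len(gref.mature)
        counts = pd.DataFrame(
            [{"family": fam, "boundary": L - 1, "side": "three",
              "S1": 500.0, "S2": 500.0}]
        )
        profile = CleavageProfile(
            counts=counts, family_len={fam: L}, samples=["S1", "S2"]
        )
        records = extract_flanks(profile, toy_ref, min_reads=100, min_samples=1)
        assert all(len(seq) == 7 for _n, seq in records)
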