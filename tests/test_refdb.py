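"""Reference construction: loading, filtering, variants, families, hierarchy."""

from __future__ import annotations

import pytest

from trfkit.refdb import (
    HIERARCHY_LEVELS,
    INTRON,
    TRNAGeneAnnotation,
    VARIANTS,
    build_reference,
    filter_genes,
    group_families,
    load_annotations,
    symbol_sort_key,
)
from trfkit.seqfiles import revcomp


def _write_inputs(tmp_path, bed_rows, structure_rows):
    bed = tmp_path / "genes.bed"
    bed.write_text("".join("\t".join(map(str, r)) + "\n" for r in bed_rows))
    st = tmp_path / "structure.tsv"
    header = "gene_id\tanticodon_start\tanticodon_end\tintrons\tscore\n"
    st.write_text(
        header + "".join("\t".join(map(str, r)) + "\n" for r in structure_rows)
    )
    return bed, st


class TestLoadAnnotations:
    def test_count_in_equals_count_out(self, tmp_path):
        bed, st = _write_inputs(
            tmp_path,
            [
                ("chr1", 100, 172, "tRNA-Glu-CTC-1-1", 0, "+"),
                ("chr1", 400, 472, "tRNA-Gly-GCC-2-1", 0, "+"),
                ("chr1", 700, 772, "tRNA-His-GTG-1-1", 0, "-"),
            ],
            [
                ("tRNA-Glu-CTC-1-1", 33, 36, ".", 66.0),
                ("tRNA-Gly-GCC-2-1", 33, 36, ".", 70.0),
                ("tRNA-His-GTG-1-1", 33, 36, ".", 50.0),
            ],
        )
        genes = load_annotations(bed, st)
        assert len(genes) == 3
        assert genes[0].amino_acid == "Glu" and genes[0].anticodon == "CTC"

    def test_missing_structure_record_names_gene(self, tmp_path):
        bed, st = _write_inputs(
            tmp_path,
            [("chr1", 100, 172, "tRNA-Glu-CTC-1-1", 0, "+")],
            [("tRNA-Gly-GCC-2-1", 33, 36, ".", 66.0)],
        )
        with pytest.raises(ValueError, match="tRNA-Glu-CTC-1-1"):
            load_annotations(bed, st)

    def test_end_before_start_rejected(self, tmp_path):
        bed, st = _write_inputs(
            tmp_path,
            [("chr1", 172, 100, "tRNA-Glu-CTC-1-1", 0, "+")],
            [("tRNA-Glu-CTC-1-1", 33, 36, ".", 66.0)],
        )
        with pytest.raises(ValueError, match="end <= start"):
            load_annotations(bed, st)

    def test_malformed_interval_reports_line(self, tmp_path):
        bed, st = _write_inputs(
            tmp_path,
            [("chr1", 100, 172, "tRNA-Glu-CTC-1-1", 0, "+")],
            [("tRNA-Glu-CTC-1-1", 33, 36, "bogus", 66.0)],
        )
        with pytest.raises(ValueError, match="line 2"):
            load_annotations(bed, st)


class TestFilterGenes:
    def _gene(self, gid="tRNA-Glu-CTC-1-1", score=50.0, mito=False, pseudo=False):
        return TRNAGeneAnnotation(
            gene_id=gid,
            chrom="chrM" if mito else "chr1",
            start=100,
            end=172,
            strand="+",
            amino_acid="Glu",
            anticodon="CTC",
            anticodon_interval=(33, 36),
            trnascan_score=score,
            is_mito=mito,
            is_pseudo=pseudo,
        )

    def test_score_boundary_is_inclusive_at_30(self):
        genes = [
            self._gene("tRNA-Glu-CTC-1-1", 29.9),
            self._gene("tRNA-Glu-CTC-1-2", 30.0),
            self._gene("tRNA-Glu-CTC-1-3", 55.0),
        ]
        part = filter_genes(genes)
        assert {g.trnascan_score for g in part.nuclear} == {30.0, 55.0}

    def test_all_pseudo_gives_empty_nuclear_set(self):
        part = filter_genes([self._gene(pseudo=True), self._gene(pseudo=True)])
        assert part.nuclear == [] and part.mito == []

    def test_mito_gene_routed_to_mito_partition_only(self):
        part = filter_genes([self._gene(score=60.0, mito=True)])
        assert part.nuclear == []
        assert [g.gene_id for g in part.mito] == ["tRNA-Glu-CTC-1-1"]


class TestBuildReference:
    def test_intronless_gene_pre_intron_length(self, toy_ref):
        for gid, gref in toy_ref.genes.items():
            if not gref.gene.intron_intervals:
                assert len(gref.sequences["pre_intron"]) == gref.gene.gene_length + 120

    def test_variant_count_always_four(self, toy_ref):
        for gref in toy_ref.genes.values():
            assert tuple(gref.sequences) == VARIANTS

    def test_intron_gene_lengths(self, toy_ref):
        gref = next(
            g for g in toy_ref.genes.values() if g.gene.intron_intervals
        )
        L = len(gref.mature)
        intron_len = gref.gene.intron_length
        assert len(gref.sequences["pre_intron"]) - L == 120 + intron_len
        assert len(gref.sequences["pre_spliced"]) == L + 120
        assert gref.sequences["mature_cca"] == gref.mature + "CCA"

    def test_minus_strand_sequences_are_sense(self, toy_annotations, toy_ref):
        annotations, genome = toy_annotations
        minus = next(a for a in annotations if a.strand == "-")
        gref = toy_ref.genes[minus.gene_id]
        genomic = genome[minus.chrom][minus.start : minus.end]
        assert gref.sequences["pre_intron"][60 : 60 + minus.gene_length] == revcomp(
            genomic
        )
        a0, a1 = minus.anticodon_interval
        assert gref.mature[a0:a1] == minus.anticodon

    def test_coordinate_round_trip(self, toy_ref):
        for gref in toy_ref.genes.values():
            L = len(gref.mature)
            for variant in VARIANTS:
                for m in range(0, L, 7):
                    v = gref.mature_to_variant(variant, m)
                    assert gref.variant_to_mature(variant, v) == m

    def test_intron_positions_are_sentinel(self, toy_ref):
        gref = next(g for g in toy_ref.genes.values() if g.gene.intron_intervals)
        i0, i1 = gref.gene.intron_intervals[0]
        arr = gref.to_mature["pre_intron"]
        assert all(arr[60 + p] == INTRON for p in range(i0, i1))

    def test_gene_too_close_to_contig_edge(self):
        ann = TRNAGeneAnnotation(
            gene_id="tRNA-Glu-CTC-1-1",
            chrom="c",
            start=10,
            end=82,
            strand="+",
            amino_acid="Glu",
            anticodon="CTC",
            anticodon_interval=(33, 36),
        )
        with pytest.raises(ValueError, match="too close"):
            build_reference([ann], {"c": "A" * 300}, validate_anticodon=False)

    def test_non_acgtn_genome_rejected(self):
        ann = TRNAGeneAnnotation(
            gene_id="tRNA-Glu-CTC-1-1",
            chrom="c",
            start=100,
            end=172,
            strand="+",
            amino_acid="Glu",
            anticodon="CTC",
            anticodon_interval=(33, 36),
        )
        with pytest.raises(ValueError, match="non-ACGTN"):
            build_reference([ann], {"c": "A" * 150 + "X" + "A" * 150},
                            validate_anticodon=False)


class TestFamiliesAndHierarchy:
    def test_identical_mature_sequences_share_family(self, toy_ref):
        fams = {f.family_id: f.member_gene_ids for f in toy_ref.families}
        assert fams["tRFM#tRNA-Glu-CTC-1-1"] == (
            "tRNA-Glu-CTC-1-1",
            "tRNA-Glu-CTC-1-2",
        )

    def test_family_id_uses_smallest_member_symbol(self, toy_ref):
        for fam in toy_ref.families:
            smallest = min(fam.member_gene_ids, key=symbol_sort_key)
            assert fam.family_id == f"tRFM#{smallest}"

    def test_families_partition_gene_set_order_invariant(self, toy_annotations):
        annotations, genome = toy_annotations
        ref_fwd = build_reference(annotations, genome)
        ref_rev = build_reference(list(reversed(annotations)), genome)
        assert sorted(f.family_id for f in ref_fwd.families) == sorted(
            f.family_id for f in ref_rev.families
        )
        members = [g for f in ref_fwd.families for g in f.member_gene_ids]
        assert sorted(members) == sorted(ref_fwd.genes)

    def test_singleton_families_allowed(self, toy_ref):
        assert any(len(f.member_gene_ids) == 1 for f in toy_ref.families)

    def test_symbol_parsing_levels(self, toy_ref):
        labels = toy_ref.hierarchy["tRNA-Glu-CTC-1-1"]
        assert labels["amino_acid"] == "Glu"
        assert labels["isoacceptor"] == "Glu-CTC"
        assert labels["isodecoder"] == "Glu-CTC-1"

    def test_hierarchy_levels_are_nested(self, toy_ref):
        genes = sorted(toy_ref.genes)
        for coarse, fine in zip(HIERARCHY_LEVELS, HIERARCHY_LEVELS[1:]):
            fine_to_coarse = {}
            for gid in genes:
                fl = toy_ref.hierarchy[gid][fine]
                cl = toy_ref.hierarchy[gid][coarse]
                assert fine_to_coarse.setdefault(fl, cl) == cl

    def test_natural_sort_key_orders_numeric_fields(self):
        symbols = ["tRNA-Glu-CTC-10-1", "tRNA-Glu-CTC-2-1", "tRNA-Glu-CTC-1-2"]
        assert sorted(symbols, key=symbol_sort_key) == [
            "tRNA-Glu-CTC-1-2",
            "tRNA-Glu-CTC-2-1",
            "tRNA-Glu-CTC-10-1",
        ]
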