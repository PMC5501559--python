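"""GFF3 feature models, promoters, introns, annotation and level bins."""

import pytest

import plantrrbs as p
from plantrrbs.annotate_features import (
    AnnotationConfig,
    annotate_calls,
    summarize_categories,
    write_annotations_tsv,
    write_bin_matrix,
)
from plantrrbs.meth_call import MethylationCall
from plantrrbs.read_simulator import write_gff3


class TestInferIntrons:
    def test_gap_between_exons(self):
        assert p.infer_introns([(100, 200), (300, 400)]) == [(200, 300)]

    def test_single_exon(self):
        assert p.infer_introns([(100, 200)]) == []

    def test_touching_exons(self):
        assert p.infer_introns([(100, 200), (200, 300)]) == []

    def test_unsorted_input_and_idempotence(self):
        exons = [(300, 400), (100, 200), (500, 600)]
        introns = p.infer_introns(exons)
        assert introns == [(200, 300), (400, 500)]
        # intron inference on exons+introns as blocks leaves no new gaps
        assert p.infer_introns(sorted(exons) + introns) == []


class TestPromoterWindow:
    def test_plus_strand(self):
        assert p.promoter_window(2500, 4000, "+", 10_000) == (500, 2500)

    def test_plus_strand_clipped_at_origin(self):
        assert p.promoter_window(1000, 3000, "+", 10_000) == (0, 1000)

    def test_minus_strand_clipped_at_contig_end(self):
        assert p.promoter_window(2000, 4000, "-", 4500) == (4000, 4500)

    def test_promoter_never_overlaps_own_gene(self):
        for strand in "+-":
            s, e = p.promoter_window(3000, 5000, strand, 10_000)
            assert e <= 3000 or s >= 5000


@pytest.fixture(scope="module")
def overlap_model(tmp_path_factory):
    """Hand-built GFF3: a protein-coding gene with two exons (intron
    between), overlapped by a non-coding gene, plus an isolated gene."""
    gff = """##gff-version 3
c\tx\tgene\t1001\t3000\t.\t+\t.\tID=pc1;biotype=protein_coding
c\tx\tmRNA\t1001\t3000\t.\t+\t.\tID=pc1.t;Parent=pc1
c\tx\texon\t1001\t1800\t.\t+\t.\tID=pc1.e1;Parent=pc1.t
c\tx\texon\t2201\t3000\t.\t+\t.\tID=pc1.e2;Parent=pc1.t
c\tx\tCDS\t1101\t1800\t.\t+\t0\tID=pc1.c1;Parent=pc1.t
c\tx\tgene\t1501\t2600\t.\t-\t.\tID=nc1;biotype=ncRNA
c\tx\tncRNA\t1501\t2600\t.\t-\t.\tID=nc1.t;Parent=nc1
c\tx\texon\t1501\t2600\t.\t-\t.\tID=nc1.e1;Parent=nc1.t
c\tx\tgene\t8001\t9000\t.\t+\t.\tID=pc2
c\tx\tmRNA\t8001\t9000\t.\t+\t.\tID=pc2.t;Parent=pc2
c\tx\texon\t8001\t9000\t.\t+\t.\tID=pc2.e;Parent=pc2.t
c\tx\tCDS\t8001\t9000\t.\t+\t0\tID=pc2.c;Parent=pc2.t
"""
    path = tmp_path_factory.mktemp("gff") / "overlap.gff3"
    path.write_text(gff)
    return p.load_gff3(path, {"c": 20_000})


class TestAnnotatePositions:
    def test_exonic_position_gets_full_label_stack(self, overlap_model):
        # 1200 (0-based) is in pc1 exon1 + CDS, outside nc1
        labels = p.annotate_positions([("c", 1200, "+")], overlap_model)[("c", 1200, "+")]
        assert labels == {"protein_coding_gene", "transcript", "exon", "CDS"}

    def test_overlap_drops_children_keeps_intron(self, overlap_model):
        # 2000 is inside pc1's intron (1800..2200) and inside nc1's exon
        key = ("c", 2000, "+")
        labels = p.annotate_positions([key], overlap_model)[key]
        assert labels == {"protein_coding_gene", "non_coding_gene", "intron"}

    def test_biotype_fallback_to_cds_presence(self, overlap_model):
        # pc2 has no biotype attribute but CDS children -> protein coding
        key = ("c", 8500, "+")
        labels = p.annotate_positions([key], overlap_model)[key]
        assert "protein_coding_gene" in labels

    def test_promoter_upstream_of_plus_gene(self, overlap_model):
        # pc2 starts at 8000 (0-based); 1500 nt upstream is promoter-only
        key = ("c", 6500, "+")
        labels = p.annotate_positions([key], overlap_model)[key]
        assert labels == {"promoter"}

    def test_intergenic_position_unlabelled(self, overlap_model):
        key = ("c", 15_000, "+")
        assert p.annotate_positions([key], overlap_model)[key] == set()

    def test_unknown_contig_gives_no_labels(self, overlap_model):
        key = ("zzz", 10, "+")
        assert p.annotate_positions([key], overlap_model)[key] == set()


class TestSummarizeCategories:
    def test_gene_and_neighbour_promoter_both_counted(self, overlap_model):
        # 2900 is in pc1 gene body; is it also in a promoter? place an
        # explicit double-labelled case instead: position in nc1 exon and
        # pc1 gene counts gene once though two genes overlap
        ann = p.annotate_positions([("c", 2000, "+"), ("c", 6500, "+")], overlap_model)
        counts = summarize_categories(ann)
        assert counts["annotated"] == 1
        assert counts["not_annotated"] == 1  # promoter-only position
        assert counts["gene"] == 1
        assert counts["promoter"] == 1

    def test_promoter_inside_not_annotated_superset(self, overlap_model):
        ann = p.annotate_positions([("c", 6500, "+")], overlap_model)
        counts = summarize_categories(ann)
        assert counts["not_annotated"] == 1 and counts["promoter"] == 1

    def test_category_sums_exceed_distinct_positions(self, overlap_model):
        keys = [("c", pos, "+") for pos in (1200, 2000, 6500, 15_000)]
        ann = p.annotate_positions(keys, overlap_model)
        counts = summarize_categories(ann)
        label_total = sum(
            v for k, v in counts.items() if k not in ("annotated", "not_annotated")
        )
        assert label_total >= len([k for k in keys if ann[k]])


class TestBinLevels:
    def test_uniform_levels_one_per_bin(self):
        levels = [x / 100 for x in range(5, 100, 10)]
        bins = p.bin_levels({"gene": levels})["gene"]
        assert bins == [0.1] * 10

    def test_boundary_levels(self):
        bins = p.bin_levels({"f": [0.0, 1.0]})["f"]
        assert bins[0] == 0.5 and bins[-1] == 0.5

    def test_proportions_sum_to_one(self, sim_dataset):
        by_ctx: dict = {}
        for call in sim_dataset.calls:
            by_ctx.setdefault(call.context, []).append(call.level)
        bins = p.bin_levels(by_ctx)
        for feature, props in bins.items():
            assert sum(props) == pytest.approx(1.0, abs=1e-9)

    def test_level_outside_range_rejected(self):
        with pytest.raises(ValueError):
            p.bin_levels({"f": [1.2]})


@pytest.fixture(scope="module")
def synthetic(tmp_path_factory):
    genome = p.random_genome({"chr1": 25_000}, seed=70)
    genes = p.synthetic_annotation(genome, seed=71)
    path = tmp_path_factory.mktemp("syn") / "syn.gff3"
    write_gff3(genes, path)
    model = p.load_gff3(path, {"chr1": 25_000})
    return genome, genes, model


class TestSyntheticGff3RoundTrip:

    def test_annotation_matches_interval_scan_oracle(self, synthetic):
        """Model lookups equal a brute-force overlap scan of the gene
        models, including derived introns and promoter windows."""
        genome, genes, model = synthetic
        config = AnnotationConfig()
        for pos in range(0, 25_000, 97):
            expected = set()
            for g in genes:
                if g.start <= pos < g.end:
                    expected.add("protein_coding_gene" if g.coding else "non_coding_gene")
                    expected.add("transcript")
                    if any(s <= pos < e for s, e in g.exons):
                        expected.add("exon")
                        if g.coding:
                            expected.add("CDS")
                    for s, e in p.infer_introns(list(g.exons)):
                        if s <= pos < e:
                            expected.add("intron")
                ps, pe = p.promoter_window(
                    g.start, g.end, g.strand, 25_000, config.promoter_len
                )
                if ps <= pos < pe:
                    expected.add("promoter")
            assert model.labels_at("chr1", pos) == expected

    def test_intron_exon_disjoint(self, synthetic):
        _, genes, _ = synthetic
        for g in genes:
            for intron in p.infer_introns(list(g.exons)):
                for exon in g.exons:
                    assert intron[1] <= exon[0] or intron[0] >= exon[1]


def test_annotate_calls_and_outputs(tmp_path, overlap_model):
    calls = [
        MethylationCall("c", 1200, "+", "CG", 8, 2),
        MethylationCall("c", 6500, "+", "CHG", 1, 9),
        MethylationCall("c", 15_000, "+", "CHH", 5, 5),
    ]
    annotations, by_feature = annotate_calls(calls, overlap_model)
    assert by_feature["promoter"] == [0.1]
    assert by_feature["not_annotated"] == [0.5]
    assert 0.8 in by_feature["exon"]
    write_annotations_tsv(annotations, tmp_path / "ann.tsv")
    lines = (tmp_path / "ann.tsv").read_text().splitlines()
    assert "c\t15000\t+\tnot_annotated" in lines
    write_bin_matrix(p.bin_levels(by_feature), tmp_path / "bins.tsv")
    assert (tmp_path / "bins.tsv").read_text().startswith("feature\t")
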