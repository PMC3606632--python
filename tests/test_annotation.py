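import collections

import pytest

import sagelight as sl
from sagelight import annotation as an
from sagelight.genes import GeneModel
from sagelight.mapping import TagHit


def hit(tag, count, chrom, pos, strand):
    return TagHit(tag=tag, count=count, hits=((chrom, pos, strand),),
                  multiplicity_class="unique")


@pytest.fixture
def plus_gene_windows():
    model = GeneModel("g1", "chr1", "+", 2000, 3000)
    return model, an.GeneWindows([model])


class TestClassifyHit:
    def test_promoter_sense_with_offset(self, plus_gene_windows):
        _, windows = plus_gene_windows
        cls = an.classify_hit(("chr1", 1950, "+"), windows)
        assert cls.category == an.UTR5_SENSE
        assert cls.gene_id == "g1" and cls.offset == -50

    def test_antisense_in_coding_region(self, plus_gene_windows):
        _, windows = plus_gene_windows
        cls = an.classify_hit(("chr1", 2500, "-"), windows)
        assert cls.category == an.CDS_ANTISENSE and cls.gene_id == "g1"

    def test_just_outside_window_unclassified(self, plus_gene_windows):
        _, windows = plus_gene_windows
        cls = an.classify_hit(("chr1", 2000 - 501, "+"), windows)
        assert cls.category == an.UNCLASSIFIED and cls.gene_id is None

    def test_window_boundaries_inclusive(self, plus_gene_windows):
        _, windows = plus_gene_windows
        assert an.classify_hit(("chr1", 1500, "+"), windows).offset == -500
        assert an.classify_hit(("chr1", 1999, "+"), windows).offset == -1
        utr3 = an.classify_hit(("chr1", 3001, "+"), windows)
        assert utr3.category == an.UTR3_SENSE and utr3.offset == 1
        assert an.classify_hit(("chr1", 3500, "+"), windows).offset == 500

    def test_minus_strand_gene_mirrored(self):
        model = GeneModel("g2", "chr1", "-", 3000, 2000)
        windows = an.GeneWindows([model])
        cls = an.classify_hit(("chr1", 3050, "-"), windows)
        assert cls.category == an.UTR5_SENSE and cls.offset == -50
        assert an.classify_hit(("chr1", 2500, "-"), windows).category == an.CDS_SENSE
        assert an.classify_hit(("chr1", 2500, "+"), windows).category == an.CDS_ANTISENSE

    def test_sense_outranks_antisense_on_overlap(self):
        # divergent pair: promoter of a overlaps promoter of b on opposite strands
        a = GeneModel("a", "chr1", "+", 2000, 3000)
        b = GeneModel("b", "chr1", "-", 1600, 800)
        windows = an.GeneWindows([a, b])
        # position 1900: utr5 of a (sense for +), utr5-antisense region of b
        cls = an.classify_hit(("chr1", 1900, "+"), windows)
        assert cls.category == an.UTR5_SENSE and cls.gene_id == "a"
        cls = an.classify_hit(("chr1", 1900, "-"), windows)
        assert cls.category == an.UTR5_SENSE and cls.gene_id == "b"

    def test_nearest_start_breaks_ties(self):
        a = GeneModel("a", "chr1", "+", 2000, 3000)
        b = GeneModel("b", "chr1", "+", 2200, 3200)
        windows = an.GeneWindows([a, b])
        cls = an.classify_hit(("chr1", 1950, "+"), windows)
        assert cls.gene_id == "a"  # 50 bp from a's start, 250 from b's
        cls = an.classify_hit(("chr1", 2150, "+"), windows)
        assert cls.gene_id == "b"  # inside a's CDS but 50 bp from b's start


class TestAnnotateLibrary:
    def test_no_antisense_when_simulated_without(self, toy_genome, toy_truths,
                                                 toy_index, toy_windows):
        genome, models = toy_genome
        truths = [sl.ExpressionTruth(t.gene_id, t.abundance_myc, t.abundance_pri,
                                     t.is_deg, t.true_log2_fold, t.tss_profile,
                                     antisense_fraction=0.0)
                  for t in toy_truths]
        sim = sl.simulate_reads(genome, models, truths,
                                n_reads_per_stage=(300, 300), seed=21)
        from sagelight import ditags as dt
        from conftest import ditag_reads
        tags = list(dt.extract_library(ditag_reads(sim.reads_myc), sl.DitagLayout()))
        table = dt.collapse_and_filter(tags, "Myc", drop_singletons=False)
        hits, _ = sl.map_tags(table, toy_index)
        _, summary = an.annotate_library(sl.unique_hits(hits), toy_windows)
        for cat in (an.UTR5_ANTISENSE, an.CDS_ANTISENSE, an.UTR3_ANTISENSE):
            assert summary["categories"][cat]["tags"] == 0

    def test_utr5_sense_equals_sense_truth(self, toy_reads, toy_pipeline_outputs):
        for stage, data in toy_pipeline_outputs.items():
            truth = toy_reads.truth[toy_reads.truth.stage == stage]
            sense = (truth.orientation == "sense").sum()
            assert data["ann_summary"]["categories"][an.UTR5_SENSE]["tags"] == sense

    def test_categories_partition_unique_total(self, toy_pipeline_outputs):
        for data in toy_pipeline_outputs.values():
            s = data["ann_summary"]
            assert sum(v["tags"] for v in s["categories"].values()) == \
                s["total_unique_tags"]

    def test_strand_flip_swaps_sense_antisense(self, toy_genome, toy_pipeline_outputs):
        genome, models = toy_genome
        flipped_models = [
            GeneModel(m.gene_id, m.chromosome,
                      "-" if m.strand == "+" else "+",
                      m.coding_end, m.coding_start)
            for m in models
        ]
        flipped = an.GeneWindows(flipped_models,
                                 chrom_lengths={c: len(s) for c, s in genome.items()})
        data = toy_pipeline_outputs["Myc"]
        unique = [h for h, _ in data["classified"]]
        _, flipped_summary = an.annotate_library(unique, flipped)
        orig = data["ann_summary"]["categories"]
        new = flipped_summary["categories"]
        # a strand flip turns the gene's CDS sense tags into antisense ones
        assert new[an.CDS_ANTISENSE]["tags"] == orig[an.CDS_SENSE]["tags"]
        assert new[an.CDS_SENSE]["tags"] == orig[an.CDS_ANTISENSE]["tags"]

    def test_rejects_multimapped_hits(self, toy_windows):
        multi = TagHit("ACGTACGTACGTACG", 1,
                       (("chr1", 10, "+"), ("chr1", 99, "+")), "multi_2_4")
        with pytest.raises(ValueError, match="unique"):
            an.annotate_library([multi], toy_windows)


class TestTssCatalogs:
    def test_single_site_single_preferred(self):
        h = hit("A" * 15, 7, "chr1", 1960, "+")
        cls = an.TagClassification(an.UTR5_SENSE, "g1", -40)
        catalogs = an.build_tss_catalogs([(h, cls)])
        assert catalogs[0].sites == {1960: 7}
        assert catalogs[0].preferred_sites == [1960]

    def test_two_preferred_sites_recovered(self, toy_genome, toy_index, toy_windows):
        genome, models = toy_genome
        gene = models[0]
        truths = [sl.ExpressionTruth(gene.gene_id, 1.0, 1.0, False, 0.0,
                                     [(30, 0.6), (80, 0.4)],
                                     antisense_fraction=0.0)]
        sim = sl.simulate_reads(genome, [gene], truths,
                                n_reads_per_stage=(250, 10), seed=33)
        from sagelight import ditags as dt
        from conftest import ditag_reads
        tags = list(dt.extract_library(ditag_reads(sim.reads_myc), sl.DitagLayout()))
        table = dt.collapse_and_filter(tags, "Myc", drop_singletons=False)
        hits, _ = sl.map_tags(table, toy_index)
        classified, _ = an.annotate_library(sl.unique_hits(hits), toy_windows)
        catalogs = an.build_tss_catalogs(classified)
        cat = next(c for c in catalogs if c.gene_id == gene.gene_id)
        sign = -1 if gene.strand == "+" else 1
        expected = {gene.coding_start + sign * 30, gene.coding_start + sign * 80}
        assert set(cat.preferred_sites) == expected

    def test_occurrences_conserved(self, toy_pipeline_outputs):
        for data in toy_pipeline_outputs.values():
            catalogs = an.build_tss_catalogs(data["classified"])
            total = sum(sum(c.sites.values()) for c in catalogs)
            assert total == data["ann_summary"]["categories"][an.UTR5_SENSE]["tags"]

    def test_catalogued_sites_are_true_tss(self, toy_reads, toy_pipeline_outputs):
        for stage, data in toy_pipeline_outputs.items():
            truth = toy_reads.truth[(toy_reads.truth.stage == stage)
                                    & (toy_reads.truth.orientation == "sense")]
            true_sites = set(zip(truth.gene_id, truth.tss_pos))
            catalogs = an.build_tss_catalogs(data["classified"])
            for c in catalogs:
                for pos in c.sites:
                    assert (c.gene_id, pos) in true_sites
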