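import collections
import math

import numpy as np
import pytest

import sagelight as sl
from sagelight.simulate import (_draw_tss_profile, simulate_tag_counts,
                                write_fasta, write_fastq)
from sagelight.layout import DitagLayout, revcomp


class TestGenerateGenome:
    def test_empty_gene_set(self):
        spec = sl.SyntheticGenomeSpec(n_chromosomes=1, chromosome_length=5000,
                                      n_genes=0, seed=3)
        genome, models = sl.generate_genome(spec)
        assert models == []
        assert len(genome["chr1"]) == 5000

    def test_same_seed_identical_output(self, toy_spec, tmp_path):
        g1, m1 = sl.generate_genome(toy_spec)
        g2, m2 = sl.generate_genome(toy_spec)
        assert g1 == g2 and m1 == m2
        write_fasta(g1, tmp_path / "a.fa")
        write_fasta(g2, tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_windows_inside_chromosome(self, toy_genome):
        genome, models = toy_genome
        for m in models:
            lo, hi = m.span
            assert lo - 500 >= 1
            assert hi + 500 <= len(genome[m.chromosome])

    def test_duplicated_region_creates_repeated_kmers(self):
        spec = sl.SyntheticGenomeSpec(n_chromosomes=1, chromosome_length=8000,
                                      n_genes=2, duplicated_region_fraction=0.1,
                                      gene_length_range=(600, 900), seed=5)
        genome, _ = sl.generate_genome(spec)
        seq = genome["chr1"]
        # brute-force 20-mer occurrence scan
        counts = collections.Counter(seq[i:i + 20] for i in range(len(seq) - 19))
        assert max(counts.values()) >= 2

    def test_infeasible_packing_raises(self):
        spec = sl.SyntheticGenomeSpec(n_chromosomes=1, chromosome_length=3000,
                                      n_genes=5, seed=0)
        with pytest.raises(sl.PackingError):
            sl.generate_genome(spec)


class TestSimulateTruth:
    def test_null_case_no_degs(self):
        truths = sl.simulate_truth([f"g{i}" for i in range(50)],
                                   deg_fraction=0.0, seed=4)
        assert all(not t.is_deg for t in truths)
        assert all(math.isclose(t.abundance_myc, t.abundance_pri, rel_tol=1e-12)
                   for t in truths)

    def test_deterministic_deg_count(self):
        truths = sl.simulate_truth([f"g{i}" for i in range(300)],
                                   deg_fraction=1 / 3, seed=4)
        assert sum(t.is_deg for t in truths) == 100

    def test_fold_range_bounds(self):
        truths = sl.simulate_truth([f"g{i}" for i in range(200)],
                                   deg_fraction=0.4, fold_range=(3, 8), seed=9)
        for t in truths:
            if t.is_deg:
                assert math.log2(3) - 1e-9 <= abs(t.true_log2_fold) <= 3 + 1e-9

    def test_shares_normalised(self, toy_truths):
        assert math.isclose(sum(t.abundance_myc for t in toy_truths), 1.0)
        assert math.isclose(sum(t.abundance_pri for t in toy_truths), 1.0)

    def test_tss_profiles_valid(self, toy_truths):
        for t in toy_truths:
            assert math.isclose(sum(w for _, w in t.tss_profile), 1.0)
            assert all(1 <= off <= 500 for off, _ in t.tss_profile)
            assert 1 <= len(t.tss_profile) <= 3

    def test_fold_below_threshold_rejected(self):
        with pytest.raises(ValueError, match="fold_range"):
            sl.simulate_truth(["a", "b"], fold_range=(2, 8), deg_fold_threshold=3.0)


class TestSimulateReads:
    def test_truth_rows_two_per_read(self, toy_reads):
        assert len(toy_reads.truth) == 2 * (800 + 1000)

    def test_error_free_tags_match_genome(self, toy_genome, toy_reads):
        genome, models = toy_genome
        strand_of = {m.gene_id: m for m in models}
        for row in toy_reads.truth.sample(200, random_state=0).itertuples():
            seq = genome[row.chromosome]
            k = len(row.tag)
            if row.strand == "+":
                assert seq[row.tss_pos - 1:row.tss_pos - 1 + k] == row.tag
            else:
                assert revcomp(seq[row.tss_pos - k:row.tss_pos]) == row.tag

    def test_sense_tags_start_at_profile_tss(self, toy_genome, toy_truths, toy_reads):
        _, models = toy_genome
        model_of = {m.gene_id: m for m in models}
        truth_of = {t.gene_id: t for t in toy_truths}
        sense = toy_reads.truth[toy_reads.truth.orientation == "sense"]
        for row in sense.itertuples():
            m = model_of[row.gene_id]
            offsets = {off for off, _ in truth_of[row.gene_id].tss_profile}
            assert abs(m.offset_from_start(row.tss_pos)) in offsets

    def test_same_seed_identical_fastq(self, toy_genome, toy_truths, tmp_path):
        genome, models = toy_genome
        sims = [sl.simulate_reads(genome, models, toy_truths,
                                  n_reads_per_stage=(50, 60), seed=42)
                for _ in range(2)]
        paths = []
        for i, sim in enumerate(sims):
            p = tmp_path / f"r{i}.fastq"
            write_fastq(sim.reads_myc, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_abundance_sampling_within_binomial_bound(self, toy_genome):
        genome, models = toy_genome
        two = models[:2]
        truths = [
            sl.ExpressionTruth(two[0].gene_id, 0.8, 0.8, False, 0.0,
                               [(30, 1.0)], antisense_fraction=0.0),
            sl.ExpressionTruth(two[1].gene_id, 0.2, 0.2, False, 0.0,
                               [(40, 1.0)], antisense_fraction=0.0),
        ]
        sim = sl.simulate_reads(genome, two, truths,
                                n_reads_per_stage=(5000, 10), seed=6)
        myc = sim.truth[sim.truth.stage == "Myc"]
        frac = (myc.gene_id == two[0].gene_id).mean()
        sd = math.sqrt(0.8 * 0.2 / 10_000)
        assert abs(frac - 0.8) <= 3 * sd

    def test_adapter_collision_warns(self, toy_genome, toy_truths):
        genome, models = toy_genome
        probe = genome["chr1"][100:125]
        layout = DitagLayout(adapter_5=probe)
        with pytest.warns(UserWarning, match="extraction may be ambiguous"):
            sl.simulate_reads(genome, models, toy_truths, layout=layout,
                              n_reads_per_stage=(5, 5), seed=1)

    def test_invalid_error_rate(self, toy_genome, toy_truths):
        genome, models = toy_genome
        with pytest.raises(ValueError):
            sl.simulate_reads(genome, models, toy_truths, error_rate=0.5)


def test_tag_counts_match_expected_shares():
    truths = sl.simulate_truth([f"g{i}" for i in range(100)],
                               deg_fraction=0.2, seed=11)
    df = simulate_tag_counts(truths, (20_000, 30_000), seed=12)
    assert df.count_myc.sum() == 20_000 and df.count_pri.sum() == 30_000
    # each observed count within 5 sd of its expectation
    for row in df.itertuples():
        for obs, exp in ((row.count_myc, row.expected_myc),
                         (row.count_pri, row.expected_pri)):
            sd = math.sqrt(max(exp, 1.0))
            assert abs(obs - exp) <= 5 * sd


def test_tss_profile_generator_weights_sorted():
    rng = np.random.default_rng(0)
    for _ in range(100):
        profile = _draw_tss_profile(rng)
        weights = [w for _, w in profile]
        assert weights == sorted(weights, reverse=True)
        assert math.isclose(sum(weights), 1.0)
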