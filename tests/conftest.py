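import pytest

import sagelight as sl
from sagelight import annotation as an
from sagelight import ditags as dt


@pytest.fixture(scope="session")
def toy_spec():
    return sl.SyntheticGenomeSpec(
        n_chromosomes=2, chromosome_length=40_000, n_genes=20, seed=7)


@pytest.fixture(scope="session")
def toy_genome(toy_spec):
    genome, models = sl.generate_genome(toy_spec)
    return genome, models


@pytest.fixture(scope="session")
def toy_truths(toy_genome):
    _, models = toy_genome
    return sl.simulate_truth(models, deg_fraction=1 / 3, fold_range=(3, 8), seed=1)


@pytest.fixture(scope="session")
def toy_reads(toy_genome, toy_truths):
    genome, models = toy_genome
    return sl.simulate_reads(genome, models, toy_truths,
                             n_reads_per_stage=(800, 1000),
                             error_rate=0.0, seed=2)


@pytest.fixture(scope="session")
def toy_index(toy_genome):
    genome, _ = toy_genome
    return sl.build_index(genome, range(15, 21))


@pytest.fixture(scope="session")
def toy_windows(toy_genome):
    genome, models = toy_genome
    return an.GeneWindows(models, chrom_lengths={c: len(s) for c, s in genome.items()})


def ditag_reads(raw_reads):
    """Convert simulator read tuples to DitagRead records."""
    return [dt.DitagRead(rid, seq, tuple(quals)) for rid, seq, quals in raw_reads]


@pytest.fixture(scope="session")
def toy_pipeline_outputs(toy_reads, toy_index, toy_windows):
    """Extract, map and annotate both toy libraries once for reuse."""
    out = {}
    for stage, raw in (("Myc", toy_reads.reads_myc), ("S1-Pri", toy_reads.reads_pri)):
        tags = list(dt.extract_library(ditag_reads(raw), sl.DitagLayout()))
        table = dt.collapse_and_filter(tags, stage, drop_singletons=False)
        hits, map_summary = sl.map_tags(table, toy_index)
        unique = sl.unique_hits(hits)
        classified, ann_summary = an.annotate_library(unique, toy_windows)
        out[stage] = {
            "tags": tags, "table": table, "hits": hits,
            "map_summary": map_summary, "classified": classified,
            "ann_summary": ann_summary,
        }
    return out
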