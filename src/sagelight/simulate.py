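"""Synthetic two-stage 5'-SAGE study generator.

Produces a toy genome with flat gene models, a per-gene expression ground
truth (expected tag shares in each of two developmental stages, TSS site
profiles, antisense fractions, differential-expression status), and ditag
FASTQ read sets whose every emitted tag is recorded in a truth table. The
defaults emulate, at desk scale, a two-library study with unequal depths,
15-20 bp 5' tags packaged two per ~100 bp read, TSS arrays concentrated
within 500 bp upstream of the start codon with one or two preferred sites, a
minority antisense fraction, and a designated one-third DEG subset with
known fold changes.

All randomness flows from explicit integer seeds; identical seeds reproduce
byte-identical FASTA/GFF3/FASTQ output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genes import GeneModel, DEFAULT_UTR_LENGTH
from .layout import DitagLayout, revcomp

BASES = np.array(list("ACGT"))


class PackingError(ValueError):
    """Genes plus their flanking windows and spacing do not fit the chromosome."""


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Study conditions for the toy genome.

    Defaults give 2 chromosomes x 70 kb holding 60 genes — a miniature of a
    tens-of-Mb fungal genome with >13,000 genes, small enough for exhaustive
    oracle checks.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 70_000
    n_genes: int = 60
    gene_length_range: Tuple[int, int] = (600, 1400)
    intergenic_min: int = 1100
    gc_content: float = 0.5
    duplicated_region_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.duplicated_region_fraction <= 1.0:
            raise ValueError("duplicated_region_fraction must be in [0, 1]")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("gene_length_range low > high")


@dataclass
class ExpressionTruth:
    """Ground-truth expression of one gene in the two stages."""

    gene_id: str
    abundance_myc: float          # expected tag share in the Myc library
    abundance_pri: float          # expected tag share in the S1-Pri library
    is_deg: bool
    true_log2_fold: float         # log2(share_myc / share_pri)
    tss_profile: List[Tuple[int, float]]  # (offset upstream of start codon in [1,500], weight)
    antisense_fraction: float = 0.0

    def __post_init__(self) -> None:
        w = sum(wt for _, wt in self.tss_profile)
        if self.tss_profile and not math.isclose(w, 1.0, rel_tol=1e-9):
            raise ValueError(f"{self.gene_id}: tss_profile weights sum to {w}, not 1")
        for off, _ in self.tss_profile:
            if not 1 <= off <= DEFAULT_UTR_LENGTH:
                raise ValueError(f"{self.gene_id}: TSS offset {off} outside [1, 500]")


# ---------------------------------------------------------------------------
# genome

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p)


def generate_genome(
    spec: SyntheticGenomeSpec,
) -> Tuple[Dict[str, str], List[GeneModel]]:
    """Generate chromosome sequences and gene models.

    Genes are packed left to right with at least ``intergenic_min`` bases
    between coding spans, and every gene's [start-500, stop+500] window lies
    within its chromosome. A ``duplicated_region_fraction`` > 0 copies that
    fraction of each chromosome's sequence to a second location, creating
    exact internal repeats (hence multi-mapping tags).
    """
    rng = np.random.default_rng(spec.seed)
    margin = DEFAULT_UTR_LENGTH + 1
    genes_per_chrom = _split_evenly(spec.n_genes, spec.n_chromosomes)

    genome: Dict[str, str] = {}
    models: List[GeneModel] = []
    gene_no = 0
    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        seq = _random_sequence(rng, spec.chromosome_length, spec.gc_content)
        n_here = genes_per_chrom[ci]
        lengths = rng.integers(spec.gene_length_range[0], spec.gene_length_range[1] + 1,
                               size=n_here)
        # distribute leftover space as random extra gaps
        slack = spec.chromosome_length - (margin * 2 + int(lengths.sum())
                                          + n_here * spec.intergenic_min)
        if n_here and slack < 0:
            raise PackingError(
                f"{chrom}: {n_here} genes totalling {int(lengths.sum())} bp with "
                f"{spec.intergenic_min} bp spacing and {margin} bp margins exceed "
                f"{spec.chromosome_length} bp"
            )
        extra = _random_partition(rng, max(slack, 0), n_here + 1)
        pos = margin + extra[0]
        for gi in range(n_here):
            gene_no += 1
            lo = pos
            hi = lo + int(lengths[gi]) - 1
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"SYN_{gene_no:05d}"
            if strand == "+":
                models.append(GeneModel(gid, chrom, "+", lo, hi))
            else:
                models.append(GeneModel(gid, chrom, "-", hi, lo))
            pos = hi + 1 + spec.intergenic_min + extra[gi + 1]
        if spec.duplicated_region_fraction > 0:
            seq = _duplicate_region(rng, seq, spec.duplicated_region_fraction)
        genome[chrom] = "".join(seq)
    return genome, models


def _split_evenly(n: int, k: int) -> List[int]:
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def _random_partition(rng: np.random.Generator, total: int, k: int) -> List[int]:
    """Split ``total`` into k non-negative integers, uniformly at random."""
    if k == 1:
        return [total]
    if total == 0:
        return [0] * k
    cuts = np.sort(rng.integers(0, total + 1, size=k - 1))
    parts = np.diff(np.concatenate(([0], cuts, [total])))
    return [int(p) for p in parts]


def _duplicate_region(rng: np.random.Generator, seq: np.ndarray,
                      fraction: float) -> np.ndarray:
    """Copy a random segment of ``fraction``·len(seq) bases over another,
    non-overlapping location, producing an exact internal duplication."""
    n = len(seq)
    seg = max(int(round(fraction * n)), 20)
    seg = min(seg, n // 3)
    src = int(rng.integers(0, n // 2 - seg))
    dst = int(rng.integers(n // 2, n - seg))
    out = seq.copy()
    out[dst:dst + seg] = seq[src:src + seg]
    return out


# ---------------------------------------------------------------------------
# expression truth

def simulate_truth(
    models: Sequence[Union[GeneModel, str]],
    deg_fraction: float = 1 / 3,
    fold_range: Tuple[float, float] = (3.0, 8.0),
    seed: int = 0,
    deg_fold_threshold: float = 3.0,
    antisense_fraction: float = 0.15,
    abundance_sigma: float = 1.2,
) -> List[ExpressionTruth]:
    """Assign each gene expected tag shares in the two stages.

    A ``deg_fraction`` of genes (deterministic count, rounded) are flagged as
    differentially expressed with fold changes drawn uniformly from
    ``fold_range``; directions alternate so both stages gain DEGs. Shares are
    constructed so that each DEG's Myc/Pri share ratio equals its drawn fold
    exactly and non-DEG genes have identical shares in both stages, with each
    stage's shares summing to 1 (the up-in-Pri group's masses are rescaled by
    a common factor to balance the two stages).
    """
    if not 0.0 <= deg_fraction <= 1.0:
        raise ValueError("deg_fraction must be in [0, 1]")
    if fold_range[0] < deg_fold_threshold:
        raise ValueError("fold_range low must be >= deg_fold_threshold")
    gene_ids = [getattr(m, "gene_id", m) for m in models]
    n = len(gene_ids)
    rng = np.random.default_rng(seed)

    baseline = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n)
    n_deg = int(round(deg_fraction * n))
    order = rng.permutation(n)
    deg_idx = order[:n_deg]
    up_myc = deg_idx[0::2]
    up_pri = deg_idx[1::2]
    folds = rng.uniform(fold_range[0], fold_range[1], size=n)

    a_myc = baseline.copy()
    a_pri = baseline.copy()
    # per-gene split preserving each gene's total mass: ratio == fold exactly
    for idx, up_in_myc in ((up_myc, True), (up_pri, False)):
        f = folds[idx]
        hi = baseline[idx] * 2 * f / (1 + f)
        lo = baseline[idx] * 2 / (1 + f)
        if up_in_myc:
            a_myc[idx], a_pri[idx] = hi, lo
        else:
            a_myc[idx], a_pri[idx] = lo, hi
    # balance the two stages by scaling the up-in-Pri masses
    surplus = float(np.sum(a_myc[up_myc] - a_pri[up_myc]))
    deficit = float(np.sum(a_pri[up_pri] - a_myc[up_pri]))
    if len(up_myc) and len(up_pri) and deficit > 0:
        gamma = surplus / deficit
        a_myc[up_pri] *= gamma
        a_pri[up_pri] *= gamma
    z_myc, z_pri = a_myc.sum(), a_pri.sum()
    s_myc, s_pri = a_myc / z_myc, a_pri / z_pri

    truths: List[ExpressionTruth] = []
    is_deg = np.zeros(n, dtype=bool)
    is_deg[deg_idx] = True
    for i, gid in enumerate(gene_ids):
        truths.append(ExpressionTruth(
            gene_id=gid,
            abundance_myc=float(s_myc[i]),
            abundance_pri=float(s_pri[i]),
            is_deg=bool(is_deg[i]),
            true_log2_fold=float(np.log2(s_myc[i] / s_pri[i])),
            tss_profile=_draw_tss_profile(rng),
            antisense_fraction=antisense_fraction,
        ))
    return truths


def _draw_tss_profile(rng: np.random.Generator) -> List[Tuple[int, float]]:
    """One or two preferred TSSs (plus an occasional minor site), all within
    500 bp upstream of the start codon and concentrated within ~200 bp."""
    n_sites = int(rng.choice([1, 2, 3], p=[0.45, 0.40, 0.15]))
    offsets: List[int] = []
    while len(offsets) < n_sites:
        off = 1 + int(min(rng.exponential(scale=60.0), DEFAULT_UTR_LENGTH - 1))
        if off not in offsets:
            offsets.append(off)
    if n_sites == 1:
        weights = [1.0]
    else:
        w1 = rng.uniform(0.5, 0.7)
        rest = np.sort(rng.dirichlet(np.ones(n_sites - 1)))[::-1] * (1 - w1)
        weights = [float(w1)] + [float(w) for w in rest]
    total = sum(weights)
    return [(off, w / total) for off, w in zip(offsets, weights)]


# ---------------------------------------------------------------------------
# reads

@dataclass
class SimulatedReads:
    """Ditag read sets for both stages plus the emitted-tag truth table."""

    reads_myc: List[Tuple[str, str, List[int]]]   # (read_id, sequence, qualities)
    reads_pri: List[Tuple[str, str, List[int]]]
    truth: pd.DataFrame  # read_id, mate, stage, gene_id, chromosome, tss_pos, strand, orientation, tag


def simulate_reads(
    genome: Dict[str, str],
    models: Sequence[GeneModel],
    truths: Sequence[ExpressionTruth],
    layout: Optional[DitagLayout] = None,
    n_reads_per_stage: Tuple[int, int] = (3000, 4000),
    error_rate: float = 0.0,
    seed: int = 0,
    base_quality: int = 40,
    degraded_fraction: float = 0.0,
    degraded_quality: int = 8,
    stage_labels: Tuple[str, str] = ("Myc", "S1-Pri"),
) -> SimulatedReads:
    """Emit two ditag FASTQ-ready read sets with a per-tag truth table.

    Each read packages two tags drawn independently from the stage's tag
    pool: gene chosen proportionally to its expected share, TSS offset drawn
    from the gene's profile, tag sequence read off the coding strand from the
    TSS (or the opposite strand from within the gene body, with probability
    ``antisense_fraction``). Substitution errors are applied per base at
    ``error_rate``. Qualities are constant ``base_quality`` except for a
    ``degraded_fraction`` of reads carrying ``degraded_quality`` bases, to
    exercise the quality filter.
    """
    if layout is None:
        layout = DitagLayout()
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    if min(n_reads_per_stage) <= 0:
        raise ValueError("n_reads_per_stage must be positive")
    for probe in (layout.adapter_5, layout.linker, layout.adapter_3):
        for chrom, seq in genome.items():
            if probe in seq or revcomp(probe) in seq:
                warnings.warn(
                    f"layout sequence {probe[:10]}... occurs in {chrom}; "
                    "ditag extraction may be ambiguous", stacklevel=2)

    rng = np.random.default_rng(seed)
    model_by_id = {m.gene_id: m for m in models}
    shares = {
        label: np.array([t.abundance_myc if si == 0 else t.abundance_pri
                         for t in truths])
        for si, label in enumerate(stage_labels)
    }
    read_sets: List[List[Tuple[str, str, List[int]]]] = []
    rows: List[tuple] = []
    for si, label in enumerate(stage_labels):
        n_reads = n_reads_per_stage[si]
        p = shares[label]
        p = p / p.sum()
        gene_draws = rng.choice(len(truths), size=2 * n_reads, p=p)
        reads: List[Tuple[str, str, List[int]]] = []
        for ri in range(n_reads):
            read_id = f"{label.replace('-', '')}_{ri + 1:07d}"
            tags = []
            for mate in (1, 2):
                gi = int(gene_draws[2 * ri + mate - 1])
                truth = truths[gi]
                model = model_by_id[truth.gene_id]
                tag, tss_pos, strand, orientation = _draw_tag(
                    rng, genome, model, truth, layout)
                tag = _apply_errors(rng, tag, error_rate)
                rows.append((read_id, mate, label, truth.gene_id,
                             model.chromosome, tss_pos, strand, orientation, tag))
                tags.append(tag)
            seq = layout.assemble(tags[0], tags[1])
            q = base_quality
            if degraded_fraction and rng.random() < degraded_fraction:
                q = degraded_quality
            reads.append((read_id, seq, [q] * len(seq)))
        read_sets.append(reads)
    truth_df = pd.DataFrame(rows, columns=[
        "read_id", "mate", "stage", "gene_id", "chromosome",
        "tss_pos", "strand", "orientation", "tag"])
    return SimulatedReads(read_sets[0], read_sets[1], truth_df)


def _draw_tag(rng, genome, model: GeneModel, truth: ExpressionTruth,
              layout: DitagLayout, max_resample: int = 50):
    """Pick one tag: returns (sequence in transcript orientation of the tag,
    genomic position of its 5' end, strand it reads on, 'sense'|'antisense')."""
    chrom_seq = genome[model.chromosome]
    lo, hi = model.span
    tlo, thi = layout.tag_length_range
    for _ in range(max_resample):
        length = int(rng.integers(tlo, thi + 1))
        if truth.antisense_fraction and rng.random() < truth.antisense_fraction:
            # antisense: 5' end uniform within the coding span, reading on the
            # strand opposite the gene, staying inside the span
            if model.strand == "+":
                start5 = int(rng.integers(lo + length - 1, hi + 1))
                if start5 - length + 1 < 1:
                    continue
                frag = chrom_seq[start5 - length:start5]
                return revcomp(frag), start5, "-", "antisense"
            else:
                start5 = int(rng.integers(lo, hi - length + 2))
                if start5 + length - 1 > len(chrom_seq):
                    continue
                frag = chrom_seq[start5 - 1:start5 + length - 1]
                return frag, start5, "+", "antisense"
        offsets, weights = zip(*truth.tss_profile)
        off = int(rng.choice(offsets, p=weights))
        if model.strand == "+":
            tss = model.coding_start - off
            if tss < 1 or tss + length - 1 > len(chrom_seq):
                continue
            return chrom_seq[tss - 1:tss + length - 1], tss, "+", "sense"
        else:
            tss = model.coding_start + off
            if tss > len(chrom_seq) or tss - length + 1 < 1:
                continue
            frag = chrom_seq[tss - length:tss]
            return revcomp(frag), tss, "-", "sense"
    raise RuntimeError(f"{model.gene_id}: could not place a tag within the chromosome")


def _apply_errors(rng, tag: str, error_rate: float) -> str:
    if error_rate <= 0:
        return tag
    out = list(tag)
    hits = np.nonzero(rng.random(len(tag)) < error_rate)[0]
    for i in hits:
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[int(rng.integers(3))]
    return "".join(out)


# ---------------------------------------------------------------------------
# count-level simulation (for calibration studies at large gene numbers)

def simulate_tag_counts(
    truths: Sequence[ExpressionTruth],
    n_tags: Tuple[int, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-gene 5'-tag counts for both stages by multinomial sampling
    from the expected shares, bypassing sequence-level simulation. Columns:
    gene_id, count_myc, count_pri, is_deg, true_log2_fold, expected_myc,
    expected_pri."""
    rng = np.random.default_rng(seed)
    p_myc = np.array([t.abundance_myc for t in truths])
    p_pri = np.array([t.abundance_pri for t in truths])
    p_myc = p_myc / p_myc.sum()
    p_pri = p_pri / p_pri.sum()
    c_myc = rng.multinomial(n_tags[0], p_myc)
    c_pri = rng.multinomial(n_tags[1], p_pri)
    return pd.DataFrame({
        "gene_id": [t.gene_id for t in truths],
        "count_myc": c_myc,
        "count_pri": c_pri,
        "is_deg": [t.is_deg for t in truths],
        "true_log2_fold": [t.true_log2_fold for t in truths],
        "expected_myc": p_myc * n_tags[0],
        "expected_pri": p_pri * n_tags[1],
    })


# ---------------------------------------------------------------------------
# synthetic functional-annotation stand-ins (domain table + homology reports)

SYNTHETIC_FB_SPECIES = ("Lbi", "Pch", "Ppl", "Sco", "Pos", "Abi", "Led")
SYNTHETIC_OUTGROUPS = ("Sce", "Cne", "Uma", "Afu")


def simulate_functional_annotations(
    gene_ids: Sequence[str],
    seed: int = 0,
    n_domains: int = 40,
    domain_rate: float = 0.6,
):
    """Synthetic domain assignments and per-species best-hit e-value tables.

    Stand-in for externally computed domain and homology-search reports so
    that the enrichment stage of a fully synthetic run has inputs. Domains
    are Zipf-weighted over a small vocabulary; every gene gets a homology
    profile that is broadly conserved, basidiomycete-restricted, or
    genome-unique.
    """
    from .enrichment import DomainAssignment

    rng = np.random.default_rng(seed)
    weights = 1.0 / np.arange(1, n_domains + 1)
    weights /= weights.sum()
    assignments = []
    for gid in gene_ids:
        k = rng.poisson(domain_rate)
        for di in rng.choice(n_domains, size=min(k, 3), replace=False, p=weights):
            e = 10.0 ** rng.uniform(-60, -21)
            assignments.append(DomainAssignment(gid, f"DOM{di + 1:03d}", float(e)))
    reports: Dict[str, Dict[str, float]] = {
        sp: {} for sp in SYNTHETIC_FB_SPECIES + SYNTHETIC_OUTGROUPS}
    for gid in gene_ids:
        profile = rng.choice(["conserved", "basidio", "unique"], p=[0.7, 0.15, 0.15])
        if profile == "conserved":
            for sp in SYNTHETIC_FB_SPECIES + SYNTHETIC_OUTGROUPS:
                if rng.random() < 0.8:
                    reports[sp][gid] = float(10.0 ** rng.uniform(-120, -15))
        elif profile == "basidio":
            n_sp = int(rng.integers(2, len(SYNTHETIC_FB_SPECIES) + 1))
            for sp in rng.choice(SYNTHETIC_FB_SPECIES, size=n_sp, replace=False):
                reports[sp][gid] = float(10.0 ** rng.uniform(-80, -11))
        else:
            if rng.random() < 0.3:  # a stray weak hit, still species-unique
                sp = str(rng.choice(SYNTHETIC_FB_SPECIES))
                reports[sp][gid] = float(10.0 ** rng.uniform(-8, -3))
    return assignments, reports, SYNTHETIC_FB_SPECIES


# ---------------------------------------------------------------------------
# writers

def write_fasta(genome: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_fastq(reads: Iterable[Tuple[str, str, List[int]]], path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, quals in reads:
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{read_id}\n{seq}\n+\n{qstr}\n")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
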