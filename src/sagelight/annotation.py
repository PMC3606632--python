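"""Classify uniquely mapped tags against gene models and build TSS catalogs.

Every uniquely mapped tag position falls into exactly one of seven
categories: sense or antisense relative to the putative 5'-UTR window (the
500 bp upstream of the start codon), the coding region, or the putative
3'-UTR window (500 bp downstream of the stop codon) — or unclassified when
it touches no gene's windows. When the windows of several genes overlap,
sense assignments outrank antisense ones and, within each orientation,
5'-UTR > coding > 3'-UTR, with the gene whose start codon is nearest
breaking remaining ties. Tags in the sense 5'-UTR window define each gene's
TSS catalogue; the highest-occupancy site (plus the runner-up when it holds
at least half the top site's tags) is reported as the preferred TSS.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .genes import GeneModel, DEFAULT_UTR_LENGTH
from .mapping import TagHit

UTR5_SENSE = "utr5_sense"
UTR5_ANTISENSE = "utr5_antisense"
CDS_SENSE = "cds_sense"
CDS_ANTISENSE = "cds_antisense"
UTR3_SENSE = "utr3_sense"
UTR3_ANTISENSE = "utr3_antisense"
UNCLASSIFIED = "unclassified"
CATEGORIES = (UTR5_SENSE, UTR5_ANTISENSE, CDS_SENSE, CDS_ANTISENSE,
              UTR3_SENSE, UTR3_ANTISENSE, UNCLASSIFIED)

#: smaller rank wins when a position lies in several genes' windows
_PRIORITY = {UTR5_SENSE: 0, CDS_SENSE: 1, UTR3_SENSE: 2,
             UTR5_ANTISENSE: 3, CDS_ANTISENSE: 4, UTR3_ANTISENSE: 5}


@dataclass(frozen=True)
class TagClassification:
    category: str
    gene_id: Optional[str] = None
    offset: Optional[int] = None  # vs coding_start (5'-UTR/CDS) or coding_end (3'-UTR)

    def __post_init__(self) -> None:
        if (self.category == UNCLASSIFIED) != (self.gene_id is None):
            raise ValueError("gene_id must be set exactly when classified")


@dataclass
class TssCatalog:
    """Per-gene array of transcription start sites with preferred sites."""

    gene_id: str
    sites: Dict[int, int]          # genomic TSS coordinate -> tag occurrences
    preferred_sites: List[int]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError(f"{self.gene_id}: empty TSS catalogue")
        if any(c <= 0 for c in self.sites.values()):
            raise ValueError(f"{self.gene_id}: non-positive site count")
        if not set(self.preferred_sites) <= set(self.sites):
            raise ValueError(f"{self.gene_id}: preferred site not in catalogue")


class GeneWindows:
    """Interval lookup of all gene windows on each chromosome."""

    def __init__(self, models: Sequence[GeneModel],
                 utr_length: int = DEFAULT_UTR_LENGTH,
                 chrom_lengths: Optional[Dict[str, int]] = None):
        self.utr_length = utr_length
        self._trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
        for m in models:
            clen = (chrom_lengths or {}).get(m.chromosome)
            for region, (lo, hi) in (
                ("utr5", m.utr5_window(utr_length, clen)),
                ("cds", m.span),
                ("utr3", m.utr3_window(utr_length, clen)),
            ):
                if lo <= hi:  # window may vanish entirely off a chromosome end
                    # intervaltree is half-open; +1 makes [lo, hi] inclusive
                    self._trees[m.chromosome].addi(lo, hi + 1, (region, m))

    def overlapping(self, chromosome: str, position: int):
        return self._trees[chromosome][position] if chromosome in self._trees else []


def classify_hit(
    hit: Tuple[str, int, str], windows: GeneWindows
) -> TagClassification:
    """Assign one uniquely mapped tag position to a single category."""
    chromosome, position, strand = hit
    best: Optional[Tuple[int, int, str, GeneModel, str]] = None
    for iv in windows.overlapping(chromosome, position):
        region, model = iv.data
        sense = strand == model.strand
        category = f"{region}_{'sense' if sense else 'antisense'}"
        start_distance = abs(position - model.coding_start)
        key = (_PRIORITY[category], start_distance, model.gene_id)
        if best is None or key < best[:3]:
            best = (*key, model, category)
    if best is None:
        return TagClassification(category=UNCLASSIFIED)
    _, _, _, model, category = best
    if category in (UTR3_SENSE, UTR3_ANTISENSE):
        offset = model.offset_from_end(position)
    else:
        offset = model.offset_from_start(position)
    return TagClassification(category=category, gene_id=model.gene_id, offset=offset)


def annotate_library(
    hits: Sequence[TagHit], windows: GeneWindows
) -> Tuple[List[Tuple[TagHit, TagClassification]], Dict[str, dict]]:
    """Classify every uniquely mapped tag; summarise occurrence-weighted
    counts and percentages per category (the categories partition the
    uniquely mapped total exactly)."""
    results: List[Tuple[TagHit, TagClassification]] = []
    occ = {cat: 0 for cat in CATEGORIES}
    total = 0
    for h in hits:
        if len(h.hits) != 1:
            raise ValueError(f"tag {h.tag}: annotate_library requires unique hits")
        cls = classify_hit(h.hits[0], windows)
        results.append((h, cls))
        occ[cls.category] += h.count
        total += h.count
    summary = {
        "total_unique_tags": total,
        "categories": {
            cat: {"tags": occ[cat],
                  "percent": (100.0 * occ[cat] / total) if total else 0.0}
            for cat in CATEGORIES
        },
    }
    return results, summary


def build_tss_catalogs(
    classified: Sequence[Tuple[TagHit, TagClassification]],
) -> List[TssCatalog]:
    """Build one TSS catalogue per gene from sense promoter-window tags.

    The preferred sites are the top-occupancy coordinate plus the second one
    when its count reaches half the first's. Ties break deterministically on
    (count desc, coordinate asc).
    """
    sites: Dict[str, Dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for hit, cls in classified:
        if cls.category != UTR5_SENSE:
            continue
        _, position, _ = hit.hits[0]
        sites[cls.gene_id][position] += hit.count
    catalogs = []
    for gene_id in sorted(sites):
        gene_sites = dict(sites[gene_id])
        ranked = sorted(gene_sites.items(), key=lambda kv: (-kv[1], kv[0]))
        preferred = [ranked[0][0]]
        if len(ranked) > 1 and ranked[1][1] * 2 >= ranked[0][1]:
            preferred.append(ranked[1][0])
        catalogs.append(TssCatalog(gene_id=gene_id, sites=gene_sites,
                                   preferred_sites=preferred))
    return catalogs


# ---------------------------------------------------------------------------
# table output

def write_classifications(
    classified: Sequence[Tuple[TagHit, TagClassification]], path
) -> None:
    with open(path, "w") as fh:
        fh.write("tag\tcount\tchromosome\tposition\tstrand\tcategory\tgene_id\toffset\n")
        for hit, cls in classified:
            chrom, pos, strand = hit.hits[0]
            fh.write(f"{hit.tag}\t{hit.count}\t{chrom}\t{pos}\t{strand}\t"
                     f"{cls.category}\t{cls.gene_id or '.'}\t"
                     f"{cls.offset if cls.offset is not None else '.'}\n")


def write_tss_catalogs(catalogs: Sequence[TssCatalog], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tposition\tcount\tpreferred\n")
        for cat in catalogs:
            for pos in sorted(cat.sites):
                pref = "yes" if pos in cat.preferred_sites else "no"
                fh.write(f"{cat.gene_id}\t{pos}\t{cat.sites[pos]}\t{pref}\n")


def write_tss_bed(catalogs: Sequence[TssCatalog],
                  models: Sequence[GeneModel], path) -> None:
    """BED track (0-based half-open) of all catalogued TSS positions."""
    strand_of = {m.gene_id: m.strand for m in models}
    chrom_of = {m.gene_id: m.chromosome for m in models}
    with open(path, "w") as fh:
        for cat in catalogs:
            for pos in sorted(cat.sites):
                fh.write(f"{chrom_of[cat.gene_id]}\t{pos - 1}\t{pos}\t"
                         f"{cat.gene_id}\t{cat.sites[pos]}\t{strand_of[cat.gene_id]}\n")
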