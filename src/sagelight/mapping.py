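"""Exact-match tag-to-genome mapping with multiplicity classification.

Tags are short (15-20 bp) and mapped with no mismatches on both strands, so
a per-length hash index over all genomic k-mers suffices at the scales this
package targets. Hit coordinates follow the 5'-end-in-transcript-orientation
convention: a minus-strand hit reports the *higher* genomic coordinate of
the matched window, so that the reported position of a 5' tag is its
candidate transcription start site on either strand.

Tags matching exactly one genomic location are the only ones that flow into
annotation and expression; multi-mapped and unmapped tags are kept in the
summary (binned as 2-4, 5-10, >=11 matches, or no match) but barred from
further analysis, since they cannot be confidently assigned.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

from .ditags import TagCountTable
from .layout import revcomp

logger = logging.getLogger(__name__)

UNIQUE = "unique"
MULTI_2_4 = "multi_2_4"
MULTI_5_10 = "multi_5_10"
MULTI_11_PLUS = "multi_11_plus"
UNMAPPED = "unmapped"
CLASSES = (UNIQUE, MULTI_2_4, MULTI_5_10, MULTI_11_PLUS, UNMAPPED)


def multiplicity_class(n_hits: int) -> str:
    if n_hits == 0:
        return UNMAPPED
    if n_hits == 1:
        return UNIQUE
    if n_hits <= 4:
        return MULTI_2_4
    if n_hits <= 10:
        return MULTI_5_10
    return MULTI_11_PLUS


@dataclass(frozen=True)
class TagHit:
    tag: str
    count: int
    hits: Tuple[Tuple[str, int, str], ...]  # (chromosome, 5'-position, strand)
    multiplicity_class: str


class GenomeIndex:
    """Hash lookup from k-mer to genomic hits, for a fixed set of lengths."""

    def __init__(self, genome: Dict[str, str], lengths: Iterable[int]):
        lengths = sorted(set(lengths))
        if not lengths:
            raise ValueError("lengths must be non-empty")
        self.lengths: FrozenSet[int] = frozenset(lengths)
        self._tables: Dict[int, Dict[str, List[Tuple[str, int, str]]]] = {}
        for k in lengths:
            table: Dict[str, List[Tuple[str, int, str]]] = defaultdict(list)
            for chrom in sorted(genome):
                seq = genome[chrom].upper()
                if len(seq) < k:
                    logger.info("chromosome %s shorter than %d bp; contributes "
                                "no %d-mers", chrom, k, k)
                    continue
                for i in range(len(seq) - k + 1):
                    window = seq[i:i + k]
                    # forward: 5' end at 1-based position i+1
                    table[window].append((chrom, i + 1, "+"))
                    # reverse: the tag reading 5'->3' on the minus strand has
                    # its 5' end at the window's high coordinate i+k
                    table[revcomp(window)].append((chrom, i + k, "-"))
            self._tables[k] = dict(table)

    def query(self, tag: str) -> List[Tuple[str, int, str]]:
        k = len(tag)
        if k not in self._tables:
            raise KeyError(f"index not built for tag length {k}")
        return sorted(self._tables[k].get(tag.upper(), []))


def build_index(genome: Dict[str, str], lengths: Iterable[int]) -> GenomeIndex:
    return GenomeIndex(genome, lengths)


def map_tags(
    table: TagCountTable, index: GenomeIndex
) -> Tuple[List[TagHit], Dict[str, dict]]:
    """Map every distinct tag and summarise occurrence-weighted class counts.

    Returns the tag hits plus a summary dict in the layout of a tag
    extraction / genome mapping report: per class, occurrence-weighted count
    and percentage of total valid tags.
    """
    missing = {len(t) for t in table.entries} - set(index.lengths)
    if missing:
        raise KeyError(f"index not built for tag lengths {sorted(missing)}")
    hits_out: List[TagHit] = []
    class_occurrences = {cls: 0 for cls in CLASSES}
    for tag in sorted(table.entries):
        count = table.entries[tag]
        hits = tuple(index.query(tag))
        cls = multiplicity_class(len(hits))
        class_occurrences[cls] += count
        hits_out.append(TagHit(tag=tag, count=count, hits=hits,
                               multiplicity_class=cls))
    total = table.total_valid_tags
    summary = {
        "stage": table.stage,
        "total_valid_tags": total,
        "classes": {
            cls: {
                "tags": class_occurrences[cls],
                "percent": (100.0 * class_occurrences[cls] / total) if total else 0.0,
            }
            for cls in CLASSES
        },
    }
    return hits_out, summary


def unique_hits(hits: Sequence[TagHit]) -> List[TagHit]:
    """Only tags with a single exact genome match are retained downstream."""
    return [h for h in hits if h.multiplicity_class == UNIQUE]


def write_hits(hits: Sequence[TagHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("tag\tcount\tchromosome\tposition\tstrand\tclass\n")
        for h in hits:
            if h.hits:
                for chrom, pos, strand in h.hits:
                    fh.write(f"{h.tag}\t{h.count}\t{chrom}\t{pos}\t{strand}\t"
                             f"{h.multiplicity_class}\n")
            else:
                fh.write(f"{h.tag}\t{h.count}\t.\t.\t.\t{h.multiplicity_class}\n")


def read_hits(path) -> List[TagHit]:
    grouped: Dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["tag", "count"]:
            raise ValueError(f"{path}: not a tag-hits table")
        for line in fh:
            tag, count, chrom, pos, strand, cls = line.rstrip("\n").split("\t")
            rec = grouped.setdefault(tag, {"count": int(count), "hits": [], "class": cls})
            if chrom != ".":
                rec["hits"].append((chrom, int(pos), strand))
    return [
        TagHit(tag=t, count=r["count"], hits=tuple(sorted(r["hits"])),
               multiplicity_class=r["class"])
        for t, r in sorted(grouped.items())
    ]
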