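"""Tag extraction: quality filtering, ditag splitting, collapsing to counts.

A ditag read carries two 5' tags between fixed adapter/linker sequences (see
:mod:`sagelight.layout`). Extraction locates those sequences by exact match,
reports the second tag reverse-complemented back to transcript orientation,
and rejects reads whose adapters cannot be found or whose tags fall outside
the configured length range. Collapsing sums identical tag sequences into a
count table; singleton tags (count 1) are discarded by default, as is usual
for pyrosequenced SAGE libraries where singletons are dominated by
sequencing error.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from Bio import SeqIO

from .layout import DitagLayout, revcomp

VALID_ALPHABET = set("ACGTN")

#: reason codes for invalid ditags
NO_ADAPTER = "no_adapter"
NO_LINKER = "no_linker"
BAD_TAG_LENGTH = "bad_tag_length"


@dataclass(frozen=True)
class DitagRead:
    """One raw sequencing read holding a two-tag ditag with qualities."""

    read_id: str
    sequence: str
    qualities: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")
        bad = set(self.sequence.upper()) - VALID_ALPHABET
        if bad:
            raise ValueError(f"{self.read_id}: invalid characters {sorted(bad)}")

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0


@dataclass
class TagCountTable:
    """Collapsed tag counts for one library."""

    stage: str
    entries: Dict[str, int]
    total_valid_tags: int

    def __post_init__(self) -> None:
        if self.total_valid_tags != sum(self.entries.values()):
            raise ValueError("total_valid_tags inconsistent with entries")


@dataclass
class ProcessingStats:
    """Header rows of a tag-extraction summary report."""

    reads_in: int = 0
    reads_quality_failed: int = 0
    ditags_invalid: int = 0
    invalid_reasons: Counter = field(default_factory=Counter)
    tags_extracted: int = 0
    singletons_removed: int = 0

    def as_dict(self) -> dict:
        return {
            "reads_in": self.reads_in,
            "reads_quality_failed": self.reads_quality_failed,
            "ditags_invalid": self.ditags_invalid,
            "invalid_reasons": dict(self.invalid_reasons),
            "tags_extracted": self.tags_extracted,
            "singletons_removed": self.singletons_removed,
        }


def read_fastq(path) -> Iterator[DitagRead]:
    """Stream a FASTQ file (Sanger Phred+33) as :class:`DitagRead` records."""
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield DitagRead(rec.id, str(rec.seq).upper(),
                            tuple(rec.letter_annotations["phred_quality"]))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record in {path}: {exc}") from exc


def quality_filter(
    reads: Iterable[DitagRead],
    min_mean_q: float = 20.0,
    min_base_q: int = 10,
    stats: Optional[ProcessingStats] = None,
) -> Iterator[DitagRead]:
    """Retain reads with mean quality >= ``min_mean_q`` and no base below
    ``min_base_q``; discarded reads are tallied in ``stats``."""
    if min_mean_q < 0 or min_base_q < 0:
        raise ValueError("quality thresholds must be >= 0")
    for read in reads:
        if stats is not None:
            stats.reads_in += 1
        if (read.qualities and read.mean_quality >= min_mean_q
                and min(read.qualities) >= min_base_q):
            yield read
        elif stats is not None:
            stats.reads_quality_failed += 1


@dataclass(frozen=True)
class Extraction:
    """Result of splitting one ditag: two tags, or an invalid-reason code."""

    tag1: Optional[str] = None
    tag2: Optional[str] = None
    reason: Optional[str] = None

    @property
    def valid(self) -> bool:
        return self.reason is None


def extract_tags(read: DitagRead, layout: DitagLayout) -> Extraction:
    """Split a ditag read into its two 5' tags.

    Adapters and linker are located by exact match. The second tag is
    reverse-complemented back to transcript orientation. Reads failing
    adapter/linker recognition or yielding tags outside the layout's length
    range come back invalid with a reason code — never an exception.
    """
    seq = read.sequence
    if not (seq.startswith(layout.adapter_5) and seq.endswith(layout.adapter_3)):
        return Extraction(reason=NO_ADAPTER)
    inner = seq[len(layout.adapter_5):len(seq) - len(layout.adapter_3)]
    lo, hi = layout.tag_length_range
    pos = inner.find(layout.linker)
    while pos != -1:
        tag1 = inner[:pos]
        tag2 = revcomp(inner[pos + len(layout.linker):])
        if lo <= len(tag1) <= hi and lo <= len(tag2) <= hi:
            # Ns cannot be matched exactly against the genome
            if "N" in tag1 or "N" in tag2:
                return Extraction(reason=BAD_TAG_LENGTH)
            return Extraction(tag1=tag1, tag2=tag2)
        pos = inner.find(layout.linker, pos + 1)
    if layout.linker not in inner:
        return Extraction(reason=NO_LINKER)
    return Extraction(reason=BAD_TAG_LENGTH)


def extract_library(
    reads: Iterable[DitagRead],
    layout: DitagLayout,
    stats: Optional[ProcessingStats] = None,
) -> Iterator[str]:
    """Extract tags from every read, yielding individual tag sequences."""
    for read in reads:
        result = extract_tags(read, layout)
        if result.valid:
            if stats is not None:
                stats.tags_extracted += 2
            yield result.tag1
            yield result.tag2
        elif stats is not None:
            stats.ditags_invalid += 1
            stats.invalid_reasons[result.reason] += 1


def collapse_and_filter(
    tags: Iterable[str],
    stage: str,
    drop_singletons: bool = True,
    stats: Optional[ProcessingStats] = None,
) -> TagCountTable:
    """Sum identical tag sequences; optionally discard singleton tags."""
    counts = Counter(tags)
    if drop_singletons:
        removed = sum(1 for c in counts.values() if c == 1)
        counts = {t: c for t, c in counts.items() if c > 1}
        if stats is not None:
            stats.singletons_removed = removed
    else:
        counts = dict(counts)
    return TagCountTable(stage=stage, entries=counts,
                         total_valid_tags=sum(counts.values()))


def write_tag_table(table: TagCountTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("tag\tcount\n")
        for tag in sorted(table.entries):
            fh.write(f"{tag}\t{table.entries[tag]}\n")


def read_tag_table(path, stage: str) -> TagCountTable:
    entries: Dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("tag\t"):
            raise ValueError(f"{path}: expected 'tag\\tcount' header")
        for line in fh:
            tag, count = line.rstrip("\n").split("\t")
            entries[tag] = int(count)
    return TagCountTable(stage=stage, entries=entries,
                         total_valid_tags=sum(entries.values()))
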