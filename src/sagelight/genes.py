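"""Protein-coding gene models and their derived promoter / UTR windows.

Coordinates are 1-based and inclusive throughout, matching GFF3. A gene model
stores only its translation start and stop; the putative 5'-UTR (promoter)
window — the ``utr_length`` bases immediately upstream of the start codon —
and the 3'-UTR window downstream of the stop codon are derived on demand and
never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, TextIO, Tuple

#: Default length (bases) of the putative 5'- and 3'-UTR windows.
DEFAULT_UTR_LENGTH = 500


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene with strand and translation start/stop.

    ``coding_start`` is the genomic coordinate of the first base of the start
    codon *in transcript orientation*; ``coding_end`` is the last base of the
    stop codon. For a minus-strand gene ``coding_start > coding_end``
    genomically.
    """

    gene_id: str
    chromosome: str
    strand: str  # '+' or '-'
    coding_start: int
    coding_end: int
    exons: Optional[Tuple[Tuple[int, int], ...]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.strand == "+" and self.coding_start > self.coding_end:
            raise ValueError(f"{self.gene_id}: coding_start downstream of coding_end")
        if self.strand == "-" and self.coding_start < self.coding_end:
            raise ValueError(f"{self.gene_id}: coding_start downstream of coding_end")

    @property
    def span(self) -> Tuple[int, int]:
        """Genomic (low, high) of the coding region, inclusive."""
        lo, hi = sorted((self.coding_start, self.coding_end))
        return lo, hi

    def utr5_window(self, utr_length: int = DEFAULT_UTR_LENGTH,
                    chrom_length: Optional[int] = None) -> Tuple[int, int]:
        """Genomic (low, high) of the promoter window, offsets (-utr_length, -1).

        Clipped at chromosome ends when ``chrom_length`` is given.
        """
        if self.strand == "+":
            lo, hi = self.coding_start - utr_length, self.coding_start - 1
        else:
            lo, hi = self.coding_start + 1, self.coding_start + utr_length
        return _clip(lo, hi, chrom_length)

    def utr3_window(self, utr_length: int = DEFAULT_UTR_LENGTH,
                    chrom_length: Optional[int] = None) -> Tuple[int, int]:
        """Genomic (low, high) of the window at offsets (+1, +utr_length)
        downstream of the stop codon."""
        if self.strand == "+":
            lo, hi = self.coding_end + 1, self.coding_end + utr_length
        else:
            lo, hi = self.coding_end - utr_length, self.coding_end - 1
        return _clip(lo, hi, chrom_length)

    def offset_from_start(self, pos: int) -> int:
        """Signed offset of ``pos`` relative to the start codon in transcript
        orientation: -1 is the base immediately upstream, +1 the first coding
        base beyond it (the start-codon base itself is offset 0)."""
        return pos - self.coding_start if self.strand == "+" else self.coding_start - pos

    def offset_from_end(self, pos: int) -> int:
        """Signed offset relative to the stop codon (+1 immediately downstream)."""
        return pos - self.coding_end if self.strand == "+" else self.coding_end - pos


def _clip(lo: int, hi: int, chrom_length: Optional[int]) -> Tuple[int, int]:
    lo = max(lo, 1)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return lo, hi


# ---------------------------------------------------------------------------
# GFF3 round-trip for flat (single-CDS) gene models.

def write_gff3(models: Sequence[GeneModel], handle: TextIO, source: str = "sagelight") -> None:
    handle.write("##gff-version 3\n")
    for m in models:
        lo, hi = m.span
        attrs = f"ID={m.gene_id}"
        handle.write(
            f"{m.chromosome}\t{source}\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\t{attrs}\n"
        )


def read_gff3(handle: TextIO) -> list[GeneModel]:
    """Read gene features from a GFF3 stream into :class:`GeneModel` objects."""
    models = []
    for lineno, line in enumerate(handle, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"GFF3 line {lineno}: expected 9 columns, got {len(fields)}")
        chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
        if ftype != "gene":
            continue
        gene_id = None
        for kv in attrs.split(";"):
            if kv.startswith("ID="):
                gene_id = kv[3:]
        if gene_id is None:
            raise ValueError(f"GFF3 line {lineno}: gene feature without ID attribute")
        lo, hi = int(start), int(end)
        if strand == "+":
            cs, ce = lo, hi
        else:
            cs, ce = hi, lo
        models.append(GeneModel(gene_id, chrom, strand, cs, ce))
    return models
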