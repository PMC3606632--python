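"""Ditag geometry: how two 5' tags are packaged into one ~100 bp sequencing unit.

A ditag read is laid out as::

    adapter_5 + tag1 + linker + revcomp(tag2) + adapter_3

i.e. the two tags are ligated tail-to-tail (blunt ligation of the MmeI-cut
ends), so the second tag appears reverse-complemented. Tag lengths vary with
the MmeI cut position; 15-20 bp by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DitagLayout:
    adapter_5: str = "GCCTCCCTCGCGCCATCAGTTCCGG"
    linker: str = "TCCGACGTATCGAG"
    adapter_3: str = "CCGGAACTGATGGCGCGAGGGAGGC"
    tag_length_range: Tuple[int, int] = (15, 20)
    ditag_total_length: int = 100

    def __post_init__(self) -> None:
        lo, hi = self.tag_length_range
        if not (0 < lo <= hi):
            raise ValueError("tag_length_range must satisfy 0 < low <= high")
        for name in ("adapter_5", "linker", "adapter_3"):
            s = getattr(self, name)
            if not s or set(s) - set("ACGT"):
                raise ValueError(f"{name} must be a non-empty ACGT string")

    @property
    def fixed_length(self) -> int:
        """Length contributed by adapters and linker alone."""
        return len(self.adapter_5) + len(self.linker) + len(self.adapter_3)

    def read_length_range(self) -> Tuple[int, int]:
        lo, hi = self.tag_length_range
        return self.fixed_length + 2 * lo, self.fixed_length + 2 * hi

    def assemble(self, tag1: str, tag2: str) -> str:
        """Build the read sequence carrying ``tag1`` and ``tag2`` (both given
        in transcript orientation)."""
        return self.adapter_5 + tag1 + self.linker + revcomp(tag2) + self.adapter_3
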